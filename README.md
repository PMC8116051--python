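# catrack

Analysis toolkit for two-photon, ratiometric calcium imaging of migrating
cells: event segmentation on cell tracks, event-aligned kinetics, motility
pause statistics, and gene-signature filtering — plus simulators that
generate every input with known ground truth.

## What it does

- **track_model** — reads/writes per-timepoint cell-track tables (track id,
  frame, 3D position in µm, calcium-bound/unbound channel intensities,
  condition, run id), computes the bound/unbound calcium ratio and the
  instantaneous / 20 s-smoothed speed, and exports a flow-cytometry-like
  per-timepoint table. A compatibility reader ingests spot-tracking exports
  split across position/intensity sheets.
- **event_detection** — estimates the background calcium ratio from
  nonselecting-condition tracks (reference value 0.675), segments signaling
  events by hysteresis thresholding (trigger ≥ 0.2 above background for ≥ 2
  consecutive timepoints; release < 0.1 above background for 2 consecutive
  timepoints), and reports first-complete-event durations,
  percent-elevated-timepoint fractions, and event frequency (events merged
  across nonsignaling gaps < 4 min, divided by cumulative track time).
- **kinetics** — event-onset-aligned mean ± SD ratio/speed profiles with
  per-timepoint cell counts, and per-track pause indices (nonsignaling
  minus signaling mean instantaneous speed).
- **synthetic_data** — persistent-random-walk track simulator with
  Poisson-arriving square (or rise–decay) calcium events and an
  event-coupled speed drop, and an expression-matrix simulator with a
  planted three-population signature; both fully seeded.
- **signature** — dual-criteria preselection-DP gene signature (log2 fold
  change > 1 of CD69⁻ DP over both DN4 and CD69⁺ DP, plus either combined
  expression > 2000 a.u. or both fold changes > 2; Rag1/Rag2 excluded),
  ion-channel candidate filtering (> 20 reads in ≥ 1 sample and padj < 0.05
  in ≥ 1 stage, Tmie always included), and replicate-averaged row-z-scored
  hierarchical clustering (Euclidean, complete linkage) into k groups.

## CLI

Every stage is a subcommand of `catrack`; flags override an optional YAML
`--config`, outputs are written atomically together with a `manifest.json`
(parameters, seed, input digests, version).

```sh
catrack simulate-tracks --out-dir out/sim --seed 1 --n-tracks 100 --duration-s 1200
catrack detect   --tracks out/sim/tracks.csv --out-dir out/det --background 0.675
catrack align    --tracks out/sim/tracks.csv --out-dir out/ali --background 0.675 --plot
catrack motility --tracks out/sim/tracks.csv --out-dir out/mot --background 0.675
catrack export-timepoints --tracks out/sim/tracks.csv --out-dir out/tp --background 0.675
catrack simulate-expression --out-dir out/expr --seed 1
catrack signature --expression out/expr/expression.csv --samples out/expr/samples.csv --out-dir out/sig
catrack ion-filter --candidates cand.txt --de de.csv --counts counts.csv --out-dir out/ion
catrack cluster --expression subset.csv --k 4 --out-dir out/clu
```

Omit `--background` to estimate it from nonselecting tracks in the input.

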