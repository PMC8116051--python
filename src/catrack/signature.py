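"""Gene-signature filtering and heatmap-style scaling/clustering.

Implements three computations on gene-by-sample expression data:

* a dual-criteria "preselection DP" signature: genes with a fold increase
  in CD69- DP thymocytes over both the DN4 precursor and the CD69+ DP
  progeny, admitted through either a high-expression branch or a
  strong-fold-change branch;
* an ion-channel candidate filter based on read support and differential-
  expression adjusted p-values (the DE results are consumed, not computed);
* replicate-averaged, row z-scored hierarchical clustering of an expression
  subset into k groups.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "ExpressionMatrix",
    "SignatureCriteria",
    "IonChannelFilterParams",
    "derive_preselection_signature",
    "filter_ion_channels",
    "scale_and_cluster",
    "load_expression_matrix",
    "load_geo_series_matrix",
    "GEO_POPULATION_MAP",
]

GEO_POPULATION_MAP = {
    "T.DN4.Th": "DN4",
    "T.DP.Th": "DP69neg",
    "T.DP69+.Th": "DP69pos",
}


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values plus sample annotations.

    ``values``: DataFrame indexed by gene id, one column per sample.
    ``samples``: DataFrame with columns ``sample_id``, ``population`` and
    optionally ``replicate`` (and, for RNA-seq use, ``genotype``/``stage``).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        missing = set(self.values.columns) - set(self.samples["sample_id"])
        if missing:
            raise ValueError(f"unannotated samples: {sorted(missing)[:5]}")
        vals = self.values.to_numpy(float)
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError("expression values must be finite and >= 0")

    def population_means(self) -> pd.DataFrame:
        """Replicate-mean expression per population (genes x populations)."""
        ann = self.samples.set_index("sample_id")["population"]
        return self.values.T.groupby(self.values.columns.map(ann)).mean().T


@dataclass(frozen=True)
class SignatureCriteria:
    """Thresholds for the dual-criteria preselection signature.

    A gene passes when log2 fold changes of DP69neg over both DN4 and
    DP69pos exceed ``lfc_min`` AND it clears either the expression branch
    (combined expression > ``combined_expr_min``) or the strong-fold-change
    branch (both log2 fold changes > ``lfc_strong``). ``combined_mode``
    selects how "combined expression" is computed from the three population
    means: ``"sum"`` (default), ``"dp69neg"`` or ``"max"``. Set
    ``log_scale=True`` when values are already log2 (fold changes become
    differences and the pseudocount is ignored).
    """

    lfc_min: float = 1.0
    combined_expr_min: float = 2000.0
    lfc_strong: float = 2.0
    exclude_genes: tuple[str, ...] = ("Rag1", "Rag2")
    pseudocount: float = 1.0
    combined_mode: str = "sum"
    log_scale: bool = False

    def __post_init__(self) -> None:
        if not self.lfc_strong > self.lfc_min > 0:
            raise ValueError("must have lfc_strong > lfc_min > 0")
        if self.combined_expr_min <= 0:
            raise ValueError("combined_expr_min must be > 0")
        if self.combined_mode not in ("sum", "dp69neg", "max"):
            raise ValueError("combined_mode must be 'sum', 'dp69neg' or 'max'")


def derive_preselection_signature(
    expr: ExpressionMatrix, criteria: SignatureCriteria | None = None
) -> pd.DataFrame:
    """Apply the dual-criteria filter; returns per-gene diagnostics.

    Requires populations ``DN4``, ``DP69neg`` and ``DP69pos``. The result
    is indexed by gene, restricted to passing genes, ordered by descending
    ``min(lfc_vs_dn4, lfc_vs_dp69pos)``, with columns: the three population
    means, the two log2 fold changes, ``combined_expr``, and ``branch``
    ("expression", "fold_change", or "both").
    """
    criteria = criteria or SignatureCriteria()
    means = expr.population_means()
    needed = ("DN4", "DP69neg", "DP69pos")
    missing = [p for p in needed if p not in means.columns]
    if missing:
        raise ValueError(f"missing populations: {missing}")

    if criteria.log_scale:
        l1 = means["DP69neg"] - means["DN4"]
        l2 = means["DP69neg"] - means["DP69pos"]
        linear = 2.0 ** means[list(needed)]
    else:
        eps = criteria.pseudocount
        l1 = np.log2((means["DP69neg"] + eps) / (means["DN4"] + eps))
        l2 = np.log2((means["DP69neg"] + eps) / (means["DP69pos"] + eps))
        linear = means[list(needed)]

    if criteria.combined_mode == "sum":
        combined = linear.sum(axis=1)
    elif criteria.combined_mode == "dp69neg":
        combined = linear["DP69neg"]
    else:
        combined = linear.max(axis=1)

    fold_ok = (l1 > criteria.lfc_min) & (l2 > criteria.lfc_min)
    expr_branch = combined > criteria.combined_expr_min
    strong_branch = (l1 > criteria.lfc_strong) & (l2 > criteria.lfc_strong)
    keep = fold_ok & (expr_branch | strong_branch)
    keep &= ~means.index.isin(criteria.exclude_genes)

    out = pd.DataFrame(
        {
            "mean_dn4": means["DN4"],
            "mean_dp69neg": means["DP69neg"],
            "mean_dp69pos": means["DP69pos"],
            "lfc_vs_dn4": l1,
            "lfc_vs_dp69pos": l2,
            "combined_expr": combined,
        }
    )[keep]
    branch = np.where(
        expr_branch[keep] & strong_branch[keep],
        "both",
        np.where(expr_branch[keep], "expression", "fold_change"),
    )
    out["branch"] = branch
    order = np.minimum(out["lfc_vs_dn4"], out["lfc_vs_dp69pos"]).sort_values(ascending=False)
    return out.loc[order.index]


@dataclass(frozen=True)
class IonChannelFilterParams:
    """Read-support and significance thresholds for the candidate filter."""

    min_reads: float = 20.0
    padj_max: float = 0.05
    always_include: tuple[str, ...] = ("Tmie",)

    def __post_init__(self) -> None:
        if self.min_reads <= 0 or self.padj_max <= 0:
            raise ValueError("thresholds must be > 0")


def filter_ion_channels(
    candidates: Sequence[str],
    de: pd.DataFrame,
    counts: pd.DataFrame,
    params: IonChannelFilterParams | None = None,
) -> list[str]:
    """Filter a curated candidate list by expression and DE significance.

    Keeps candidates with more than ``min_reads`` reads in at least one
    sample of ``counts`` (genes x samples) AND adjusted p-value below
    ``padj_max`` in at least one stage of ``de`` (columns ``gene``,
    ``stage``, ``padj``), then unions ``always_include``. Candidates absent
    from the DE table are dropped with a warning (unless always included).
    Order: filtered candidates in input order, then missing always-include
    genes.
    """
    params = params or IonChannelFilterParams()
    if not {"gene", "stage", "padj"} <= set(de.columns):
        raise ValueError("de table needs columns gene, stage, padj")
    bad_p = ~de["padj"].between(0.0, 1.0) & de["padj"].notna()
    if bad_p.any():
        raise ValueError("padj values must lie in [0, 1]")
    sig_genes = set(de.loc[de["padj"] < params.padj_max, "gene"])
    de_genes = set(de["gene"])
    kept: list[str] = []
    for gene in candidates:
        if gene in params.always_include:
            kept.append(gene)
            continue
        if gene not in de_genes:
            warnings.warn(f"candidate {gene!r} absent from DE results; dropped")
            continue
        expressed = gene in counts.index and (counts.loc[gene] > params.min_reads).any()
        if expressed and gene in sig_genes:
            kept.append(gene)
    for gene in params.always_include:
        if gene not in kept:
            kept.append(gene)
    return kept


def scale_and_cluster(
    expr: pd.DataFrame,
    groups: Mapping[str, str] | None = None,
    k: int = 4,
    *,
    column_order: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Replicate-average, row z-score, and hierarchically cluster genes.

    Parameters
    ----------
    expr : DataFrame
        Genes x samples.
    groups : mapping, optional
        sample -> group (e.g. "genotype:stage"); columns are averaged per
        group before scaling. ``None`` treats each column as its own group.
    k : int
        Number of clusters to cut the complete-linkage Euclidean tree into.
    column_order : sequence, optional
        Developmental ordering of the averaged columns, used both to order
        the output and to number clusters 1..k by the position of their
        peak mean expression (default: first-appearance order).

    Returns ``(scaled, labels)``: the row-scaled averaged matrix and an
    integer cluster label per gene. Constant rows scale to zero with a
    warning.
    """
    if groups is not None:
        grouper = expr.columns.map(dict(groups))
        if grouper.isna().any():
            raise ValueError("every sample needs a group")
        order = column_order or list(dict.fromkeys(grouper))
        avg = expr.T.groupby(grouper).mean().T[list(order)]
    else:
        avg = expr.copy()
        if column_order is not None:
            avg = avg[list(column_order)]
    if len(avg) < k:
        raise ValueError(f"need at least k={k} rows, got {len(avg)}")

    mat = avg.to_numpy(float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    const = sd[:, 0] == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant row(s) scaled to zeros")
        sd[const] = 1.0
    scaled = pd.DataFrame((mat - mean) / sd, index=avg.index, columns=avg.columns)

    if k == len(scaled):
        raw = np.arange(1, k + 1)
    else:
        Z = linkage(scaled.to_numpy(), method="complete", metric="euclidean")
        raw = fcluster(Z, t=k, criterion="maxclust")

    # renumber clusters by developmental position of their peak mean expression
    peaks = {}
    for c in np.unique(raw):
        profile = scaled.to_numpy()[raw == c].mean(axis=0)
        peaks[c] = (int(np.argmax(profile)), float(-profile.max()))
    relabel = {c: i + 1 for i, c in enumerate(sorted(peaks, key=lambda c: peaks[c]))}
    labels = pd.Series([relabel[c] for c in raw], index=scaled.index, name="cluster")
    return scaled, labels


# ---------------------------------------------------------------------------
# I/O helpers


def load_expression_matrix(
    values_path: str | Path, samples_path: str | Path
) -> ExpressionMatrix:
    """Load a gene-by-sample delimited matrix plus its annotation sidecar."""

    def _sep(p: str | Path) -> str:
        return "\t" if "\t" in Path(p).open().readline() else ","

    values = pd.read_csv(values_path, sep=_sep(values_path), index_col=0)
    samples = pd.read_csv(samples_path, sep=_sep(samples_path))
    if "sample_id" not in samples.columns or "population" not in samples.columns:
        raise ValueError("sample sidecar needs sample_id and population columns")
    return ExpressionMatrix(values, samples)


def load_geo_series_matrix(
    path: str | Path,
    population_map: Mapping[str, str] | None = None,
    *,
    unlog: bool = True,
) -> ExpressionMatrix:
    """Parse a GEO series-matrix file restricted to mapped populations.

    Keeps samples whose title starts with a key of ``population_map``
    (default: the DN4 / CD69- DP / CD69+ DP thymocyte populations of the
    ImmGen Phase 1 arrays, GSE15907). Series matrices store log2 RMA
    intensities; ``unlog=True`` (default) returns linear-scale values so
    the default signature criteria apply directly.
    """
    population_map = population_map or GEO_POPULATION_MAP
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    titles: list[str] = []
    accessions: list[str] = []
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("!Sample_title"):
                titles = [t.strip().strip('"') for t in line.rstrip("\n").split("\t")[1:]]
            elif line.startswith("!Sample_geo_accession"):
                accessions = [t.strip().strip('"') for t in line.rstrip("\n").split("\t")[1:]]
            elif line.startswith("!series_matrix_table_begin"):
                table = pd.read_csv(fh, sep="\t", index_col=0)
                break
        else:
            raise ValueError(f"{path}: no series matrix table found")
    if not titles:
        raise ValueError(f"{path}: no !Sample_title line found")
    table = table.loc[~table.index.astype(str).str.startswith("!")]
    if accessions and list(table.columns) == accessions:
        table.columns = titles

    keep_cols, pops, reps = [], [], []
    counters: dict[str, int] = {}
    for title in table.columns:
        for prefix, pop in population_map.items():
            if str(title).startswith(prefix):
                counters[pop] = counters.get(pop, 0) + 1
                keep_cols.append(title)
                pops.append(pop)
                reps.append(counters[pop])
                break
    if not keep_cols:
        raise ValueError("no samples matched the population map")
    values = table[keep_cols].astype(float)
    if unlog:
        values = 2.0**values
    samples = pd.DataFrame({"sample_id": keep_cols, "population": pops, "replicate": reps})
    return ExpressionMatrix(values, samples)
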