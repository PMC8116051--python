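import numpy as np
import pandas as pd
import pytest

from catrack.signature import (
    ExpressionMatrix,
    IonChannelFilterParams,
    SignatureCriteria,
    derive_preselection_signature,
    filter_ion_channels,
    load_expression_matrix,
    load_geo_series_matrix,
    scale_and_cluster,
)


def build_matrix(rows: dict[str, dict[str, float]], n_reps: int = 3) -> ExpressionMatrix:
    """Expression matrix from per-gene population means (replicates identical)."""
    pops = ("DN4", "DP69neg", "DP69pos")
    cols, pop_labels, reps = [], [], []
    for pop in pops:
        for r in range(1, n_reps + 1):
            cols.append(f"{pop}_r{r}")
            pop_labels.append(pop)
            reps.append(r)
    data = {
        gene: [vals[pop] for pop in pops for _ in range(n_reps)] for gene, vals in rows.items()
    }
    values = pd.DataFrame.from_dict(data, orient="index", columns=cols)
    samples = pd.DataFrame({"sample_id": cols, "population": pop_labels, "replicate": reps})
    return ExpressionMatrix(values, samples)


class TestSignatureCriteria:
    def test_invariants(self):
        with pytest.raises(ValueError):
            SignatureCriteria(lfc_min=2.0, lfc_strong=1.0)
        with pytest.raises(ValueError):
            SignatureCriteria(combined_expr_min=0)
        with pytest.raises(ValueError):
            SignatureCriteria(combined_mode="median")


class TestDeriveSignature:
    def test_all_equal_matrix_empty(self):
        expr = build_matrix({f"g{i}": {"DN4": 100, "DP69neg": 100, "DP69pos": 100} for i in range(5)})
        assert len(derive_preselection_signature(expr)) == 0

    def test_constructed_branches(self):
        # 3 genes pass via expression (lfc in (1,2], combined > 2000),
        # 2 via strong fold change (lfc > 2, combined <= 2000)
        rows = {}
        for g in ("e1", "e2", "e3"):
            rows[g] = {"DN4": 500, "DP69neg": 1500, "DP69pos": 500}  # lfc ~1.58, sum 2500
        for g in ("f1", "f2"):
            rows[g] = {"DN4": 50, "DP69neg": 500, "DP69pos": 50}  # lfc ~3.3, sum 600
        rows["neither"] = {"DN4": 900, "DP69neg": 1000, "DP69pos": 900}
        rows["low_lfc_high_expr"] = {"DN4": 4000, "DP69neg": 5000, "DP69pos": 4000}
        expr = build_matrix(rows)
        res = derive_preselection_signature(expr)
        assert sorted(res.index) == ["e1", "e2", "e3", "f1", "f2"]
        assert set(res.loc[["e1", "e2", "e3"], "branch"]) == {"expression"}
        assert set(res.loc[["f1", "f2"], "branch"]) == {"fold_change"}

    def test_both_branch_label(self):
        expr = build_matrix({"g": {"DN4": 200, "DP69neg": 2000, "DP69pos": 200}})
        res = derive_preselection_signature(expr)
        assert res.loc["g", "branch"] == "both"

    def test_rag_genes_excluded(self):
        rows = {
            "Rag1": {"DN4": 100, "DP69neg": 2000, "DP69pos": 100},
            "Rag2": {"DN4": 100, "DP69neg": 2000, "DP69pos": 100},
            "Keep": {"DN4": 100, "DP69neg": 2000, "DP69pos": 100},
        }
        res = derive_preselection_signature(build_matrix(rows))
        assert list(res.index) == ["Keep"]

    def test_missing_population_raises(self):
        expr = build_matrix({"g": {"DN4": 1, "DP69neg": 1, "DP69pos": 1}})
        expr.samples = expr.samples[expr.samples["population"] != "DN4"]
        expr.values = expr.values[expr.samples["sample_id"]]
        with pytest.raises(ValueError, match="DN4"):
            derive_preselection_signature(expr)

    def test_monotone_in_lfc_min(self):
        rng = np.random.default_rng(0)
        rows = {
            f"g{i}": {
                "DN4": float(rng.uniform(10, 2000)),
                "DP69neg": float(rng.uniform(10, 4000)),
                "DP69pos": float(rng.uniform(10, 2000)),
            }
            for i in range(200)
        }
        expr = build_matrix(rows)
        loose = derive_preselection_signature(expr, SignatureCriteria(lfc_min=0.5))
        tight = derive_preselection_signature(expr, SignatureCriteria(lfc_min=1.5))
        assert set(tight.index) <= set(loose.index)

    def test_combined_mode_variants(self):
        # sum 2300 > 2000 but DP69neg alone (1500) and max (1500) fall short
        expr = build_matrix({"g": {"DN4": 400, "DP69neg": 1500, "DP69pos": 400}})
        assert len(derive_preselection_signature(expr, SignatureCriteria())) == 1
        for mode in ("dp69neg", "max"):
            res = derive_preselection_signature(
                expr, SignatureCriteria(combined_mode=mode)
            )
            assert len(res) == 0

    def test_log_scale_mode(self):
        expr = build_matrix(
            {"g": {"DN4": np.log2(300), "DP69neg": np.log2(1500), "DP69pos": np.log2(300)}}
        )
        res = derive_preselection_signature(expr, SignatureCriteria(log_scale=True))
        assert list(res.index) == ["g"]
        assert res.loc["g", "lfc_vs_dn4"] == pytest.approx(np.log2(5))

    def test_ordered_by_descending_min_lfc(self):
        rows = {
            "weak": {"DN4": 400, "DP69neg": 1300, "DP69pos": 400},
            "strong": {"DN4": 100, "DP69neg": 2000, "DP69pos": 100},
        }
        res = derive_preselection_signature(build_matrix(rows))
        assert list(res.index) == ["strong", "weak"]


class TestIonChannelFilter:
    def _de(self, rows):
        return pd.DataFrame(rows, columns=["gene", "stage", "padj"])

    def test_empty_candidates_gives_always_include(self):
        de = self._de([("X", "early", 0.01)])
        counts = pd.DataFrame({"s1": [100]}, index=["X"])
        assert filter_ion_channels([], de, counts) == ["Tmie"]

    def test_construction_four_of_ten(self):
        genes = [f"c{i}" for i in range(10)]
        rows, counts_rows = [], {}
        for i, g in enumerate(genes):
            passing = i < 4
            rows.append((g, "early", 0.01 if passing else 0.5))
            counts_rows[g] = [100 if passing else 5, 1]
        de = self._de(rows)
        counts = pd.DataFrame.from_dict(counts_rows, orient="index", columns=["s1", "s2"])
        kept = filter_ion_channels(genes, de, counts)
        assert kept == ["c0", "c1", "c2", "c3", "Tmie"]

    def test_needs_both_criteria(self):
        de = self._de([("sig_lowreads", "early", 0.001), ("nonsig_highreads", "early", 0.9)])
        counts = pd.DataFrame(
            {"s1": [2, 500]}, index=["sig_lowreads", "nonsig_highreads"]
        )
        kept = filter_ion_channels(["sig_lowreads", "nonsig_highreads"], de, counts)
        assert kept == ["Tmie"]

    def test_any_stage_suffices(self):
        de = self._de([("g", "early", 0.9), ("g", "late", 0.01)])
        counts = pd.DataFrame({"s1": [100]}, index=["g"])
        assert filter_ion_channels(["g"], de, counts) == ["g", "Tmie"]

    def test_missing_candidate_warns(self):
        de = self._de([("present", "early", 0.01)])
        counts = pd.DataFrame({"s1": [100]}, index=["present"])
        with pytest.warns(UserWarning, match="absent"):
            kept = filter_ion_channels(["present", "ghost"], de, counts)
        assert kept == ["present", "Tmie"]

    def test_reads_threshold_is_strict(self):
        de = self._de([("g", "early", 0.01)])
        counts = pd.DataFrame({"s1": [20.0]}, index=["g"])  # not > 20
        assert filter_ion_channels(["g"], de, counts) == ["Tmie"]

    def test_bad_padj_rejected(self):
        de = self._de([("g", "early", 1.5)])
        counts = pd.DataFrame({"s1": [100]}, index=["g"])
        with pytest.raises(ValueError, match="padj"):
            filter_ion_channels(["g"], de, counts)


class TestScaleAndCluster:
    def _archetypes(self, n_per=5, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        early = np.tile([5.0, 5.0, 1.0, 1.0, 1.0, 1.0], (n_per, 1))
        late = np.tile([1.0, 1.0, 1.0, 1.0, 5.0, 5.0], (n_per, 1))
        mat = np.vstack([early, late]) + rng.normal(0, noise, (2 * n_per, 6))
        genes = [f"e{i}" for i in range(n_per)] + [f"l{i}" for i in range(n_per)]
        return pd.DataFrame(mat, index=genes, columns=[f"s{i}" for i in range(6)])

    def test_rows_zscored(self):
        expr = self._archetypes()
        scaled, _ = scale_and_cluster(expr, k=2)
        np.testing.assert_allclose(scaled.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(scaled.std(axis=1, ddof=1), 1.0, rtol=1e-9)

    def test_two_archetypes_perfect_partition(self):
        expr = self._archetypes()
        _, labels = scale_and_cluster(expr, k=2)
        early_labels = set(labels[[f"e{i}" for i in range(5)]])
        late_labels = set(labels[[f"l{i}" for i in range(5)]])
        assert len(early_labels) == 1 and len(late_labels) == 1
        assert early_labels != late_labels
        # numbering follows developmental (column) order of the peak
        assert early_labels == {1} and late_labels == {2}

    def test_k_equals_rows(self):
        expr = self._archetypes(n_per=2)
        _, labels = scale_and_cluster(expr, k=4)
        assert sorted(labels) == [1, 2, 3, 4]

    def test_replicate_averaging_with_groups(self):
        expr = self._archetypes()
        expr2 = pd.concat([expr, expr.add_suffix("_b", axis=1)], axis=1)
        groups = {c: c.replace("_b", "") for c in expr2.columns}
        scaled, labels = scale_and_cluster(expr2, groups, k=2)
        ref_scaled, ref_labels = scale_and_cluster(expr, k=2)
        np.testing.assert_allclose(scaled.to_numpy(), ref_scaled.to_numpy(), atol=1e-12)
        assert labels.tolist() == ref_labels.tolist()

    def test_row_order_invariance(self):
        expr = self._archetypes()
        perm = expr.sample(frac=1.0, random_state=1)
        _, labels = scale_and_cluster(expr, k=2)
        _, labels_perm = scale_and_cluster(perm, k=2)
        assert labels_perm.sort_index().tolist() == labels.sort_index().tolist()

    def test_affine_rescaling_of_row_invariant(self):
        expr = self._archetypes()
        expr2 = expr.copy()
        expr2.loc["e0"] = expr2.loc["e0"] * 7.0 + 3.0
        s1, l1 = scale_and_cluster(expr, k=2)
        s2, l2 = scale_and_cluster(expr2, k=2)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-9)
        assert l1.tolist() == l2.tolist()

    def test_constant_row_warns_scales_to_zero(self):
        expr = self._archetypes()
        expr.loc["const"] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            scaled, _ = scale_and_cluster(expr, k=2)
        np.testing.assert_allclose(scaled.loc["const"], 0.0)

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="at least"):
            scale_and_cluster(self._archetypes(n_per=1), k=4)


class TestIO:
    def test_load_expression_matrix(self, tmp_path):
        (tmp_path / "expr.csv").write_text("gene,s1,s2\ng1,1.0,2.0\ng2,3.0,4.0\n")
        (tmp_path / "samples.csv").write_text(
            "sample_id,population,replicate\ns1,DN4,1\ns2,DP69neg,1\n"
        )
        em = load_expression_matrix(tmp_path / "expr.csv", tmp_path / "samples.csv")
        assert em.values.shape == (2, 2)

    def test_duplicate_gene_ids_rejected(self):
        values = pd.DataFrame([[1.0], [2.0]], index=["g", "g"], columns=["s1"])
        samples = pd.DataFrame({"sample_id": ["s1"], "population": ["DN4"]})
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionMatrix(values, samples)

    def test_geo_series_matrix_parser(self, tmp_path):
        titles = [
            "T.DN4.Th#1", "T.DN4.Th#2", "T.DN4.Th#3",
            "T.DP.Th#1", "T.DP.Th#2", "T.DP.Th#3",
            "T.DP69+.Th#1", "T.DP69+.Th#2", "T.DP69+.Th#3",
            "B.Fo.Sp#1",
        ]
        gsms = [f"GSM{i}" for i in range(10)]
        lines = [
            "!Series_title\t\"demo\"",
            "!Sample_title\t" + "\t".join(f'"{t}"' for t in titles),
            "!Sample_geo_accession\t" + "\t".join(f'"{g}"' for g in gsms),
            "!series_matrix_table_begin",
            "ID_REF\t" + "\t".join(gsms),
            "probeA\t" + "\t".join(["10.0"] * 10),
            "probeB\t" + "\t".join(["5.0"] * 10),
            "!series_matrix_table_end",
        ]
        p = tmp_path / "series_matrix.txt"
        p.write_text("\n".join(lines) + "\n")
        em = load_geo_series_matrix(p)
        assert em.values.shape == (2, 9)  # non-thymocyte sample dropped
        assert sorted(em.samples["population"].unique()) == ["DN4", "DP69neg", "DP69pos"]
        assert em.values.loc["probeA"].iloc[0] == pytest.approx(2.0**10)
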