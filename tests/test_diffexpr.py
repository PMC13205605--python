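"""QC, normalization, differential expression and enrichment tests."""

import numpy as np
import pytest
import scipy.stats

import ferrosig as fs

from conftest import exact_wilcoxon_oracle


def _counts(values, conditions=None):
    values = np.asarray(values)
    return fs.ExpressionMatrix(
        values=values,
        gene_ids=[f"G{i}" for i in range(values.shape[0])],
        obs_ids=[f"C{i}" for i in range(values.shape[1])],
        condition=None if conditions is None else np.asarray(conditions, dtype=object),
        layer=fs.Layer.RAW_COUNTS,
    )


class TestQCFilter:
    def test_cell_below_min_genes_removed(self):
        # 10 cells x 250 genes; cell 0 expresses only 150 genes
        rng = np.random.default_rng(1)
        counts = rng.poisson(3.0, size=(250, 10)) + 1  # every gene detected
        counts[150:, 0] = 0
        m = _counts(counts)
        out = fs.qc_filter(m, fs.QCThresholds(min_cells_per_gene=0))
        assert "C0" not in out.obs_ids
        assert out.n_obs == 9

    def test_high_mito_cell_removed(self):
        counts = np.full((4, 3), 3, dtype=int)
        counts[0] = [1, 10, 1]  # mito fractions 0.1, 10/19, 0.1
        m = fs.ExpressionMatrix(
            counts, ["MT-ND1", "A", "B", "C"], ["C0", "C1", "C2"],
            layer=fs.Layer.RAW_COUNTS,
        )
        out = fs.qc_filter(
            m, fs.QCThresholds(min_cells_per_gene=0, min_genes_per_cell=0,
                               max_mito_fraction=0.20)
        )
        assert out.obs_ids == ["C0", "C2"]

    def test_gene_in_two_of_ten_surviving_cells_removed(self):
        counts = np.ones((5, 10), dtype=int)
        counts[0, 2:] = 0  # gene G0 detected in 2 cells only
        m = _counts(counts)
        out = fs.qc_filter(m, fs.QCThresholds(min_genes_per_cell=0))
        assert "G0" not in out.gene_ids
        assert out.n_genes == 4

    def test_zero_thresholds_return_input_unchanged(self):
        rng = np.random.default_rng(2)
        m = _counts(rng.poisson(1.0, size=(20, 8)))
        out = fs.qc_filter(
            m, fs.QCThresholds(min_cells_per_gene=0, min_genes_per_cell=0,
                               max_mito_fraction=1.0)
        )
        assert np.array_equal(out.values, m.values)
        assert out.gene_ids == m.gene_ids and out.obs_ids == m.obs_ids

    def test_error_reports_stage_counts_when_nothing_survives(self):
        m = _counts(np.zeros((5, 4), dtype=int))
        with pytest.raises(ValueError, match="no cells survive"):
            fs.qc_filter(m, fs.QCThresholds(min_genes_per_cell=1))


class TestNormalize:
    def test_closed_form_single_cell(self):
        m = _counts([[1], [0]])
        out = fs.normalize(m, scale_factor=10.0)
        assert out.layer is fs.Layer.LOG_NORMALIZED
        np.testing.assert_allclose(out.values[:, 0], [np.log(11.0), 0.0])

    def test_library_size_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(4.0, size=(30, 2)) + 1
        doubled = counts.copy()
        doubled[:, 1] = counts[:, 1] * 2
        a = fs.normalize(_counts(counts))
        b = fs.normalize(_counts(doubled))
        np.testing.assert_allclose(a.values[:, 1], b.values[:, 1], rtol=1e-12)

    def test_matches_elementwise_formula_oracle(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(2.0, size=(40, 12))
        counts[:, 0] += 1  # guard against an all-zero column
        out = fs.normalize(_counts(counts), scale_factor=1e4)
        colsum = counts.sum(axis=0)
        expected = np.log1p(1e4 * counts / colsum)
        assert np.max(np.abs(out.values - expected)) < 1e-12

    def test_zero_total_column_names_observation(self):
        counts = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="C1"):
            fs.normalize(_counts(counts))


class TestZscore:
    def test_hand_computed_row(self):
        m = fs.ExpressionMatrix(
            np.array([[1.0, 2.0, 3.0]]), ["A"], ["a", "b", "c"],
            layer=fs.Layer.LOG_NORMALIZED,
        )
        out = fs.zscore(m)
        np.testing.assert_allclose(out.values[0], [-1.0, 0.0, 1.0])

    def test_constant_gene_becomes_zeros_and_means_vanish(self):
        rng = np.random.default_rng(5)
        values = rng.normal(5.0, 2.0, size=(10, 6))
        values[3] = 7.0
        m = fs.ExpressionMatrix(
            values, [f"G{i}" for i in range(10)], [f"S{i}" for i in range(6)],
            layer=fs.Layer.LOG_NORMALIZED,
        )
        out = fs.zscore(m)
        assert not out.values[3].any()
        np.testing.assert_allclose(out.values.mean(axis=1), 0.0, atol=1e-12)

    def test_single_observation_rejected(self):
        m = fs.ExpressionMatrix(np.array([[1.0]]), ["A"], ["s"],
                                layer=fs.Layer.LOG_NORMALIZED)
        with pytest.raises(ValueError):
            fs.zscore(m)


def _log_matrix(values, conditions):
    values = np.asarray(values, dtype=float)
    return fs.ExpressionMatrix(
        values=values,
        gene_ids=[f"G{i}" for i in range(values.shape[0])],
        obs_ids=[f"C{i}" for i in range(values.shape[1])],
        condition=np.asarray(conditions, dtype=object),
        layer=fs.Layer.LOG_NORMALIZED,
    )


class TestDifferentialExpression:
    def test_identical_gene_is_ns_with_zero_lfc(self):
        rng = np.random.default_rng(6)
        values = rng.gamma(2.0, 1.0, size=(5, 12))
        values[0] = np.tile(values[0, :6], 2)  # same values in both groups
        m = _log_matrix(values, ["a"] * 6 + ["b"] * 6)
        diff = fs.differential_expression(m, "a", "b", min_pct=0.0)
        row = diff.table.set_index("gene").loc["G0"]
        assert row["log2_fc"] == 0.0
        assert row["direction"] == "ns"

    def test_small_sample_pvalue_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        values = rng.gamma(2.0, 1.0, size=(10, 6))  # distinct with prob 1
        m = _log_matrix(values, ["a"] * 3 + ["b"] * 3)
        diff = fs.differential_expression(m, "a", "b", min_pct=0.0)
        for i, p in enumerate(diff.table["p_value"]):
            expected = exact_wilcoxon_oracle(values[i, :3], values[i, 3:])
            assert p == pytest.approx(expected, abs=1e-12)

    def test_pvalues_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        values = rng.gamma(2.0, 1.0, size=(20, 60))
        m1 = _log_matrix(values, ["a"] * 30 + ["b"] * 30)
        m2 = _log_matrix(np.sqrt(values), ["a"] * 30 + ["b"] * 30)  # strictly monotone
        p1 = fs.differential_expression(m1, "a", "b", min_pct=0.0).table["p_value"]
        p2 = fs.differential_expression(m2, "a", "b", min_pct=0.0).table["p_value"]
        np.testing.assert_allclose(p1, p2, rtol=1e-10)

    def test_fdr_invariant_under_gene_order_permutation(self):
        rng = np.random.default_rng(9)
        values = rng.gamma(2.0, 1.0, size=(30, 40))
        cond = ["a"] * 20 + ["b"] * 20
        diff1 = fs.differential_expression(_log_matrix(values, cond), "a", "b", min_pct=0.0)
        perm = rng.permutation(30)
        m2 = fs.ExpressionMatrix(
            values[perm], [f"G{i}" for i in perm],
            [f"C{i}" for i in range(40)],
            condition=np.asarray(cond, dtype=object), layer=fs.Layer.LOG_NORMALIZED,
        )
        diff2 = fs.differential_expression(m2, "a", "b", min_pct=0.0)
        f1 = diff1.table.set_index("gene")["fdr"]
        f2 = diff2.table.set_index("gene")["fdr"]
        np.testing.assert_allclose(f1.sort_index(), f2.sort_index(), rtol=1e-12)

    def test_min_pct_filter_drops_undetected_genes(self):
        values = np.zeros((2, 20))
        values[0] = 1.0
        values[1, 0] = 0.5  # detected in 10% of one group, below the cut
        m = _log_matrix(values, ["a"] * 10 + ["b"] * 10)
        diff = fs.differential_expression(m, "a", "b", min_pct=0.2)
        assert list(diff.table["gene"]) == ["G0"]

    def test_unknown_label_rejected(self, small_log_matrix):
        with pytest.raises(ValueError, match="nope"):
            fs.differential_expression(small_log_matrix, "nope", "b")

    def test_planted_effect_recovery_rate(self):
        """Planted 2-fold changes at 200 cells/group are recovered >= 90%."""
        hits = total = 0
        for seed in range(20):
            params = fs.ScSimParams(
                n_genes=400, n_cells_per_condition=200, n_background_de=20,
                n_decoy_regulators=20, seed=1000 + seed,
            )
            matrix, truth = fs.simulate_sc(params)
            norm = fs.normalize(fs.qc_filter(matrix))
            diff = fs.differential_expression(norm, "resistant", "sensitive")
            calls = diff.table.set_index("gene")["direction"]
            planted = truth[truth["group"].str.startswith("signature")]
            for _, row in planted.iterrows():
                want = "up" if row["lfc"] > 0 else "down"
                total += 1
                hits += int(calls.get(row["gene"], "ns") == want)
        assert hits / total >= 0.9


class TestFisherEnrichment:
    def _diff_from_table(self, n11, n12, n21, n22):
        """Build a DE result and catalog realizing a given 2x2 table."""
        genes, directions, roles = [], [], {}
        k = 0
        for count, is_up, is_role in (
            (n11, True, True), (n12, True, False), (n21, False, True), (n22, False, False),
        ):
            for _ in range(count):
                g = f"G{k}"; k += 1
                genes.append(g)
                directions.append("up" if is_up else "ns")
                if is_role:
                    roles[g] = fs.Role.SUPPRESSOR
        import pandas as pd
        table = pd.DataFrame({
            "gene": genes, "log2_fc": 1.0, "p_value": 0.5, "fdr": 0.5,
            "pct_in_a": 1.0, "pct_in_b": 1.0, "direction": directions,
        })
        diff = fs.DifferentialResult(table, "a", "b", 0.25, 0.01)
        catalog = fs.RegulatorCatalog(entries=roles)
        return diff, catalog

    def test_matches_hypergeometric_tail(self):
        diff, catalog = self._diff_from_table(5, 5, 5, 85)
        res = fs.fisher_direction_enrichment(diff, catalog, "up", "suppressor")
        # P(X >= 5) with N=100, K=10 role genes, n=10 draws
        expected = scipy.stats.hypergeom.sf(4, 100, 10, 10)
        assert res.p_value == pytest.approx(expected, rel=1e-12)
        assert res.contingency.tolist() == [[5, 5], [5, 85]]

    def test_no_in_direction_genes_gives_p_one(self):
        diff, catalog = self._diff_from_table(0, 0, 10, 90)
        res = fs.fisher_direction_enrichment(diff, catalog, "up", "suppressor")
        assert res.p_value == 1.0
        assert res.continuity_corrected

    def test_transposed_table_gives_same_p(self):
        diff, catalog = self._diff_from_table(5, 5, 5, 85)
        res = fs.fisher_direction_enrichment(diff, catalog, "up", "suppressor")
        transposed = scipy.stats.fisher_exact(
            res.contingency.T, alternative="greater"
        )[1]
        assert res.p_value == pytest.approx(transposed, rel=1e-12)

    def test_empty_catalog_overlap_rejected(self):
        diff, _ = self._diff_from_table(5, 5, 5, 85)
        catalog = fs.RegulatorCatalog(entries={"ABSENT": fs.Role.DRIVER})
        with pytest.raises(ValueError, match="universe"):
            fs.fisher_direction_enrichment(diff, catalog, "up", "suppressor")
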