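"""Analysis engines: wiring of the statistical kernel over matrices and
modules, layer contracts, and agreement with per-cell oracles."""

import numpy as np
import pandas as pd
import pytest

import heatmod as hm
from heatmod.engines import TEST_LAYERS
from heatmod.matrix import DataError


class TestEnrichment:
    def test_shape_and_n_layer_for_partitioning_modules(self, event_matrix):
        mm = hm.ModuleMap({f"m{i}": [f"g{j}" for j in range(1 + 10 * i, 11 + 10 * i)]
                           for i in range(4)})
        cfg = hm.TestConfig(test_kind="binomial_exact", module_min_size=1)
        res = hm.run_enrichment(event_matrix, mm, cfg)
        assert res.shape == (4, 10)
        assert res.layer_names == TEST_LAYERS
        assert (res.layer("n").to_numpy() == 10).all()

    def test_module_covering_all_rows_fisher_degenerate(self, event_matrix):
        mm = hm.ModuleMap({"everything": event_matrix.row_ids})
        cfg = hm.TestConfig(test_kind="fisher_exact", module_min_size=1)
        res = hm.run_enrichment(event_matrix, mm, cfg)
        assert (res.layer("p_right").to_numpy() == 1.0).all()

    def test_incompatible_test_and_matrix_rejected(self, small_matrix,
                                                   small_modules, event_matrix):
        with pytest.raises(DataError):
            hm.run_enrichment(small_matrix, small_modules,
                              hm.TestConfig(test_kind="fisher_exact"))
        with pytest.raises(DataError):
            hm.run_enrichment(event_matrix, small_modules,
                              hm.TestConfig(test_kind="zscore_bootstrap", seed=1))

    def test_no_surviving_module_is_error(self, small_matrix):
        mm = hm.ModuleMap({"alien": ["not_a_gene"]})
        with pytest.raises(DataError):
            hm.run_enrichment(small_matrix, mm,
                              hm.TestConfig(seed=1, module_min_size=1))

    def test_planted_module_has_smallest_p(self):
        spec = hm.FixtureSpec(seed=21, n_genes=300, n_samples=3, n_modules=10,
                              module_size_min=30, module_size_max=60,
                              shift_delta=2.0, n_planted=1)
        m, mm, truth = hm.make_expression_fixture(spec)
        cfg = hm.TestConfig(seed=22, bootstrap_iterations=1_000)
        res = hm.run_enrichment(m, mm, cfg)
        for col in res.col_ids:
            assert res.layer("p_right")[col].idxmin() == truth["planted_modules"][0]

    def test_binomial_cells_match_kernel_oracle(self, event_matrix):
        mm = hm.ModuleMap({"m1": [f"g{j}" for j in range(1, 13)]})
        cfg = hm.TestConfig(test_kind="binomial_exact", module_min_size=1,
                            mtc="none")
        res = hm.run_enrichment(event_matrix, mm, cfg)
        df = event_matrix.df
        for col in event_matrix.col_ids:
            k = int(df[col].iloc[0:12].sum())
            p0 = float(df[col].mean())
            expect = hm.binomial_exact(k, 12, p0)
            assert res.layer("p_right").at["m1", col] == expect.p_right
            assert res.layer("observed").at["m1", col] == k

    def test_correction_is_per_column(self, event_matrix):
        mm = hm.ModuleMap({f"m{i}": [f"g{j}" for j in range(1 + 8 * i, 9 + 8 * i)]
                           for i in range(5)})
        cfg = hm.TestConfig(test_kind="fisher_exact", module_min_size=1, mtc="bh")
        res = hm.run_enrichment(event_matrix, mm, cfg)
        for col in res.col_ids:
            raw = res.layer("p_right")[col].to_numpy()
            np.testing.assert_allclose(
                res.layer("p_right_corrected")[col].to_numpy(),
                hm.adjust_pvalues(raw, "bh"), atol=1e-15)


class TestOncodrive:
    def test_all_zero_row_binomial_p_right_one(self):
        vals = np.zeros((3, 5))
        vals[1, :] = [1, 0, 1, 0, 0]
        m = hm.BinaryMatrix(vals, ["quiet", "active", "silent"],
                            [f"s{i}" for i in range(5)])
        res = hm.run_oncodrive(m, hm.TestConfig(test_kind="binomial_exact"))
        assert res.layer("p_right").at["quiet", "all"] == 1.0
        assert res.col_ids == ["all"]

    def test_planted_high_rate_gene_ranks_first(self):
        spec = hm.FixtureSpec(seed=31, n_genes=200, n_samples=40,
                              module_size_max=20, event_rate=0.1,
                              planted_rate=0.9, n_planted_genes=1)
        m, truth = hm.make_event_fixture(spec)
        res = hm.run_oncodrive(m, hm.TestConfig(test_kind="binomial_exact"))
        assert res.layer("p_right")["all"].idxmin() == truth["planted_genes"][0]

    def test_single_column_matrix_rejected(self):
        m = hm.BinaryMatrix(np.zeros((4, 1)))
        with pytest.raises(DataError):
            hm.run_oncodrive(m, hm.TestConfig(test_kind="binomial_exact"))

    def test_consistency_with_singleton_module_global_background(self):
        """A gene's per-row binomial result equals the kernel applied to the
        singleton gene set with the whole-matrix event rate."""
        m, _ = hm.make_event_fixture(hm.FixtureSpec(
            seed=33, n_genes=30, n_samples=12, module_size_max=10,
            event_rate=0.25))
        res = hm.run_oncodrive(m, hm.TestConfig(test_kind="binomial_exact",
                                                mtc="none"))
        flat = m.values[~np.isnan(m.values)]
        global_rate = flat.mean()
        for gene in m.row_ids[:5]:
            row = m.df.loc[gene].to_numpy()
            expect = hm.binomial_exact(int(row.sum()), row.size, global_rate)
            assert res.layer("p_right").at[gene, "all"] == expect.p_right


class TestCombination:
    def _as_pmatrix(self, values, rows):
        return hm.DataMatrix(np.asarray(values, dtype=float).reshape(-1, 1),
                             rows, ["exp"])

    def test_single_input_is_identity(self):
        rows = ["g1", "g2", "g3"]
        inp = self._as_pmatrix([0.01, 0.6, 0.3], rows)
        res = hm.run_combination([inp])
        np.testing.assert_allclose(res.layer("combined_p")["combined"].to_numpy(),
                                   [0.01, 0.6, 0.3], rtol=1e-9)

    def test_all_half_inputs_stay_half(self):
        rows = ["g1", "g2"]
        inputs = [self._as_pmatrix([0.5, 0.5], rows) for _ in range(4)]
        res = hm.run_combination(inputs)
        np.testing.assert_allclose(res.layer("combined_p").to_numpy(), 0.5,
                                   atol=1e-12)

    def test_rowwise_oracle_equality_and_union_of_rows(self):
        rng = np.random.default_rng(41)
        a = self._as_pmatrix(rng.random(4), ["g1", "g2", "g3", "g4"])
        b = self._as_pmatrix(rng.random(3), ["g2", "g3", "g5"])
        res = hm.run_combination([a, b])
        assert res.row_ids == ["g1", "g2", "g3", "g4", "g5"]
        for g in res.row_ids:
            ps = [float(f.df.at[g, "exp"]) if g in f.df.index else np.nan
                  for f in (a, b)]
            expect = hm.weighted_z_combine(ps)[0]
            got = res.layer("combined_p").at[g, "combined"]
            assert got == pytest.approx(expect, rel=1e-12)
        assert res.layer("n_inputs_used").at["g1", "combined"] == 1
        assert res.layer("n_inputs_used").at["g2", "combined"] == 2

    def test_user_weights_applied_per_input(self):
        a = self._as_pmatrix([0.01], ["g"])
        b = self._as_pmatrix([0.8], ["g"])
        cfg = hm.CombineConfig(weight_mode="user", weights=[3.0, 1.0])
        res = hm.run_combination([a, b], cfg=cfg)
        expect = hm.weighted_z_combine([0.01, 0.8], [3.0, 1.0])[0]
        assert res.layer("combined_p").at["g", "combined"] == pytest.approx(expect)


class TestCorrelation:
    def test_symmetric_with_unit_diagonal(self, small_matrix):
        res = hm.run_correlation(small_matrix, axis="columns")
        r = res.layer("r").to_numpy()
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_duplicate_columns_correlate_perfectly(self):
        v = np.random.default_rng(5).standard_normal((8, 2))
        m = hm.DataMatrix(np.hstack([v, v[:, :1]]), col_ids=["a", "b", "a2"])
        res = hm.run_correlation(m)
        assert res.layer("r").at["a", "a2"] == pytest.approx(1.0)

    def test_pairs_match_pearson_oracle(self):
        rng = np.random.default_rng(6)
        m = hm.DataMatrix(rng.standard_normal((10, 6)))
        res = hm.run_correlation(m, axis="rows")
        for i, a in enumerate(m.row_ids):
            for b in m.row_ids[i + 1:]:
                expect = hm.pearson(m.df.loc[a], m.df.loc[b])
                assert res.layer("r").at[a, b] == pytest.approx(expect["r"])
                assert res.layer("p_two").at[a, b] == pytest.approx(expect["p_two"])

    def test_too_few_shared_observations_is_missing(self):
        vals = np.array([[1.0, 2.0, np.nan, np.nan],
                         [np.nan, np.nan, 1.0, 2.0],
                         [1.0, 2.0, 3.0, 4.0]])
        m = hm.DataMatrix(vals)
        res = hm.run_correlation(m, axis="rows")
        assert np.isnan(res.layer("r").at["r0", "r1"])


class TestOverlap:
    def test_identical_and_disjoint_columns(self):
        v = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
        m = hm.BinaryMatrix(v, ["g1", "g2", "g3"], ["a", "b", "c"])
        res = hm.run_overlap(m)
        assert res.layer("count_both").at["a", "b"] == 2
        assert res.layer("jaccard").at["a", "b"] == 1.0
        assert res.layer("count_both").at["a", "c"] == 0
        assert res.layer("jaccard").at["a", "c"] == 0.0

    def test_matches_set_oracle_and_invariants(self, event_matrix):
        res = hm.run_overlap(event_matrix, axis="columns")
        df = event_matrix.df
        for a in event_matrix.col_ids:
            sa = set(df.index[df[a] == 1])
            for b in event_matrix.col_ids:
                sb = set(df.index[df[b] == 1])
                both = len(sa & sb)
                assert res.layer("count_both").at[a, b] == both
                assert both <= min(res.layer("count_a").at[a, b],
                                   res.layer("count_b").at[a, b])
                union = len(sa | sb)
                expect_j = both / union if union else 0.0
                assert res.layer("jaccard").at[a, b] == pytest.approx(expect_j)

    def test_missing_counts_as_zero_with_warning(self):
        v = np.array([[1.0, np.nan], [1.0, 1.0], [0.0, 1.0]])
        m = hm.BinaryMatrix(v, col_ids=["a", "b"])
        with pytest.warns(UserWarning, match="missing"):
            res = hm.run_overlap(m)
        assert res.layer("count_both").at["a", "b"] == 1


class TestResultContracts:
    def test_export_reimport_identity_for_every_engine(self, tmp_path,
                                                       event_matrix,
                                                       small_matrix):
        mm = hm.ModuleMap({"m1": [f"g{j}" for j in range(1, 9)],
                           "m2": [f"g{j}" for j in range(9, 17)]})
        results = [
            hm.run_enrichment(event_matrix, mm,
                              hm.TestConfig(test_kind="fisher_exact",
                                            module_min_size=1)),
            hm.run_oncodrive(event_matrix,
                             hm.TestConfig(test_kind="binomial_exact")),
            hm.run_correlation(small_matrix),
            hm.run_overlap(event_matrix),
        ]
        for i, res in enumerate(results):
            path = tmp_path / f"r{i}.tsv"
            hm.write_results_table(res, path)
            assert hm.read_results_table(path) == res

    def test_label_order_follows_input_order(self, event_matrix):
        mm = hm.ModuleMap({"zz": [f"g{j}" for j in range(1, 9)],
                           "aa": [f"g{j}" for j in range(9, 17)]})
        res = hm.run_enrichment(event_matrix, mm,
                                hm.TestConfig(test_kind="fisher_exact",
                                              module_min_size=1))
        assert res.row_ids == ["zz", "aa"]
        assert res.col_ids == event_matrix.col_ids
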