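"""Correctness of the five plasticity measures against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from plastiqtl import plasticity as pl

from conftest import toy_phenotypes


class TestPca:
    def test_rank_one_matrix_loads_entirely_on_pc1(self):
        rng = np.random.default_rng(0)
        a, c = rng.normal(size=50), rng.normal(size=5)
        y = np.outer(a, c)
        res = pl.overall_pca(toy_phenotypes(y))
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(res.scores[:, 1], 0.0, atol=1e-9)

    def test_score_vectors_orthogonal(self):
        y = np.random.default_rng(1).normal(size=(40, 6))
        res = pl.overall_pca(toy_phenotypes(y))
        assert abs(res.scores[:, 0] @ res.scores[:, 1]) < 1e-8

    def test_matches_eigendecomposition_of_covariance_oracle(self):
        # oracle: eigenvectors of the column covariance matrix, scores by
        # projection — an independent route to the same subspace
        rng = np.random.default_rng(2)
        y = rng.normal(size=(50, 5)) @ rng.normal(size=(5, 5))
        res = pl.overall_pca(toy_phenotypes(y))
        yc = y - y.mean(axis=0)
        w, v = np.linalg.eigh(np.cov(yc, rowvar=False))
        order = np.argsort(w)[::-1]
        for k in range(2):
            vec = v[:, order[k]]
            oracle = yc @ vec
            r = np.corrcoef(oracle, res.scores[:, k])[0, 1]
            assert abs(abs(r) - 1.0) < 1e-10
            np.testing.assert_allclose(
                np.abs(oracle), np.abs(res.scores[:, k]), atol=1e-8
            )

    def test_sign_convention_largest_loading_positive(self):
        y = np.random.default_rng(3).normal(size=(30, 4))
        res = pl.overall_pca(toy_phenotypes(y))
        for k in range(2):
            lead = np.argmax(np.abs(res.loadings[:, k]))
            assert res.loadings[lead, k] > 0

    def test_location_shift_invariance(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(30, 4))
        shifted = y + rng.normal(size=4)  # per-environment shift
        a = pl.overall_pca(toy_phenotypes(y))
        b = pl.overall_pca(toy_phenotypes(shifted))
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-8)

    def test_too_few_environments_or_rows_rejected(self):
        with pytest.raises(ValueError, match="2 environments"):
            pl.overall_pca(toy_phenotypes(np.zeros((5, 1))))
        y = np.full((5, 3), np.nan)
        y[:2] = 1.0
        with pytest.raises(ValueError, match="complete rows"):
            pl.overall_pca(toy_phenotypes(y))


class TestVar:
    def test_literal_examples(self):
        y = np.array([[3.0, 3.0, 3.0], [0.0, 2.0, np.nan]])
        v = pl.overall_var(toy_phenotypes(y))
        assert v[0] == 0.0
        assert v[1] == pytest.approx(2.0)  # ((0-1)^2 + (2-1)^2) / 1

    def test_matches_direct_formula_oracle(self):
        y = np.random.default_rng(5).normal(size=(20, 6))
        v = pl.overall_var(toy_phenotypes(y))
        oracle = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) / 5
        np.testing.assert_allclose(v, oracle, rtol=1e-12)

    def test_row_shift_invariance(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(10, 5))
        shifted = y + rng.normal(size=(10, 1))  # per-individual constants
        np.testing.assert_allclose(
            pl.overall_var(toy_phenotypes(y)),
            pl.overall_var(toy_phenotypes(shifted)),
            rtol=1e-10,
        )

    def test_all_missing_row_rejected(self):
        y = np.array([[1.0, 2.0], [np.nan, np.nan]])
        with pytest.raises(ValueError, match="all-missing"):
            pl.overall_var(toy_phenotypes(y))


class TestFwr:
    def test_environment_index_sums_to_zero_and_mean_slope_one(self):
        y = np.random.default_rng(7).normal(size=(25, 6))
        fit = pl.overall_fwr(toy_phenotypes(y))
        assert fit.env_index.sum() == pytest.approx(0.0, abs=1e-10)
        assert fit.slope.mean() == pytest.approx(1.0, abs=1e-10)

    def test_row_equal_to_environment_means_has_slope_one(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(20, 5))
        means = y.mean(axis=0)
        y[0] = means  # row equals the environment means (approximately fixes
        fit = pl.overall_fwr(toy_phenotypes(y))  # the means; recompute below)
        e = fit.env_index
        expected = ((y[0] - y[0].mean()) @ e) / (e @ e)
        assert fit.slope[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_row_has_slope_zero(self):
        y = np.random.default_rng(9).normal(size=(10, 4))
        y[3] = 2.5
        fit = pl.overall_fwr(toy_phenotypes(y))
        assert fit.slope[3] == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_construction_recovered_exactly(self):
        rng = np.random.default_rng(10)
        n, e = 50, 8
        c = rng.normal(size=n)
        b = rng.normal(loc=1.0, scale=0.4, size=n)
        env = rng.normal(size=e)
        env -= env.mean()
        b_mean = b.mean()
        # y = c_i + b_i * E_j has column means c̄ + b̄ E_j, so the fitted
        # index is b̄ E_j and recovered slopes are b_i / b̄
        y = c[:, None] + np.outer(b, env)
        fit = pl.overall_fwr(toy_phenotypes(y))
        np.testing.assert_allclose(fit.slope, b / b_mean, atol=1e-10)

    def test_noisy_slopes_match_covariance_ratio_oracle(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=(30, 10))
        fit = pl.overall_fwr(toy_phenotypes(y))
        e = fit.env_index
        for i in (0, 7, 29):
            oracle = np.cov(y[i], e, ddof=1)[0, 1] / np.var(e, ddof=1)
            assert fit.slope[i] == pytest.approx(oracle, rel=1e-10)

    def test_zero_environmental_spread_rejected(self):
        y = np.tile(np.random.default_rng(12).normal(size=(10, 1)), (1, 4))
        with pytest.raises(ValueError, match="spread"):
            pl.overall_fwr(toy_phenotypes(y))


class TestSpecific:
    def test_diff_arithmetic_and_antisymmetry(self):
        y = np.array([[1.0, 0.0], [2.0, 5.0]])
        p = toy_phenotypes(y, labels=["a", "b"])
        np.testing.assert_allclose(pl.specific_diff(p, "a", "b"), [1.0, -3.0])
        np.testing.assert_allclose(
            pl.specific_diff(p, "a", "b"), -pl.specific_diff(p, "b", "a")
        )

    def test_diff_identical_columns_zero(self):
        y = np.tile(np.random.default_rng(13).normal(size=(6, 1)), (1, 2))
        p = toy_phenotypes(y, labels=["a", "b"])
        np.testing.assert_allclose(pl.specific_diff(p, "a", "b"), 0.0)

    def test_unknown_environment_rejected(self):
        p = toy_phenotypes(np.zeros((4, 2)) + [[0.0, 1.0]], labels=["a", "b"])
        with pytest.raises(KeyError):
            pl.specific_diff(p, "a", "zzz")

    def test_dot_sums_to_pearson_r_against_scipy(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            y = rng.normal(size=(30, 2))
            p = toy_phenotypes(y, labels=["a", "b"])
            total = np.nansum(pl.specific_dot(p, "a", "b"))
            r = stats.pearsonr(y[:, 0], y[:, 1]).statistic
            assert total == pytest.approx(r, abs=1e-10)

    def test_dot_with_self_sums_to_one(self):
        y = np.tile(np.random.default_rng(15).normal(size=(10, 1)), (1, 2))
        p = toy_phenotypes(y, labels=["a", "b"])
        assert np.nansum(pl.specific_dot(p, "a", "b")) == pytest.approx(1.0)

    def test_dot_uncorrelated_columns_sum_to_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        z = np.array([1.0, 1.0, -1.0, -1.0])
        p = toy_phenotypes(np.column_stack([x, z]), labels=["a", "b"])
        assert abs(np.nansum(pl.specific_dot(p, "a", "b"))) < 1e-12

    def test_dot_zero_variance_column_rejected(self):
        y = np.column_stack([np.ones(5), np.arange(5.0)])
        p = toy_phenotypes(y, labels=["a", "b"])
        with pytest.raises(ValueError, match="zero-variance"):
            pl.specific_dot(p, "a", "b")

    def test_dot_location_shift_invariance(self):
        rng = np.random.default_rng(16)
        y = rng.normal(size=(20, 2))
        p1 = toy_phenotypes(y, labels=["a", "b"])
        p2 = toy_phenotypes(y + [10.0, -3.0], labels=["a", "b"])
        np.testing.assert_allclose(
            pl.specific_dot(p1, "a", "b"), pl.specific_dot(p2, "a", "b"), atol=1e-10
        )


class TestAssembly:
    def test_18_environments_give_153_diff_and_153_dot(self):
        rng = np.random.default_rng(17)
        y = rng.normal(size=(20, 18))
        table = pl.all_plasticity(toy_phenotypes(y))
        diff_cols = [c for c in table.columns if c.startswith("DIFF(")]
        dot_cols = [c for c in table.columns if c.startswith("DOT(")]
        assert len(diff_cols) == 153 and len(dot_cols) == 153
        assert table.shape[1] == 4 + 2 * 153

    def test_two_environments_give_one_pair(self):
        y = np.random.default_rng(18).normal(size=(10, 2))
        table = pl.all_plasticity(toy_phenotypes(y, labels=["b", "a"]))
        assert [c for c in table.columns if "(" in c] == ["DIFF(a,b)", "DOT(a,b)"]

    def test_column_order_deterministic_and_lexicographic(self):
        y = np.random.default_rng(19).normal(size=(10, 3))
        p = toy_phenotypes(y, labels=["c", "a", "b"])
        t1 = pl.all_plasticity(p)
        t2 = pl.all_plasticity(p)
        assert list(t1.columns) == list(t2.columns)
        diff_cols = [c for c in t1.columns if c.startswith("DIFF(")]
        assert diff_cols == ["DIFF(a,b)", "DIFF(a,c)", "DIFF(b,c)"]

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_dot_pair_sum_equals_pearson_r_property(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(15, 3)) * rng.uniform(0.5, 3.0, size=3)
        p = toy_phenotypes(y, labels=["a", "b", "c"])
        table = pl.all_plasticity(p, measures="specific")
        corr = np.corrcoef(y, rowvar=False)
        for (i, a), (j, b) in [((0, "a"), (1, "b")), ((0, "a"), (2, "c")),
                               ((1, "b"), (2, "c"))]:
            assert np.nansum(table[f"DOT({a},{b})"]) == pytest.approx(
                corr[i, j], abs=1e-10
            )


class TestHubDrivesSlope:
    def test_high_connectivity_allele_raises_fwr_slope(self):
        # segregants carrying the hub allele respond more strongly to the
        # environments where the hub's epistatic network is active
        from plastiqtl import simulate as sim

        arch = sim.hub_architecture(12, hub_marker=25,
                                    radial_markers=(75, 125, 175), mask_seed=5)
        cfg = sim.SimConfig(
            n_segregants=600,
            chromosomes=tuple(
                sim.ChromosomeSpec(50, 300.0, 750_000) for _ in range(4)
            ),
            n_environments=12,
            seed=55,
            architecture=arch,
            h2_polygenic=0.2,
        )
        g = sim.simulate_cross(cfg)
        phenos, _ = sim.simulate_phenotypes(g, cfg)
        slope = pl.overall_fwr(phenos).slope
        carrier = g.values[:, 25] == 2
        assert slope[carrier].mean() > slope[~carrier].mean()
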