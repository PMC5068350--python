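import itertools

import numpy as np
import pytest
from scipy import stats

from setmean import (PermutationDraw, RotationDraw, anderson_r2f_test,
                     fga_test, fpun_test, freedman_lane_sample, r2f_statistic,
                     reduced_state, rotation_test)

from conftest import make_dataset, simple_design


def all_permutations(n):
    """Identity-first exhaustive permutation array (n! x n)."""
    perms = [list(range(n))] + [list(p) for p in
                                itertools.permutations(range(n))
                                if list(p) != list(range(n))]
    return np.array(perms)


class TestFreedmanLane:
    def test_identity_draw_returns_y_exactly(self, toy):
        Y, design = toy
        state = reduced_state(Y, design, "eud")
        draw = PermutationDraw(np.arange(state.n), 0, observed=True)
        assert freedman_lane_sample(state, draw) is state.Y

    def test_intercept_only_nuisance_permutes_around_column_means(self, rng):
        n = 12
        design = simple_design(rng.normal(size=n))
        Y = rng.normal(2.0, 1.0, size=(n, 3))
        state = reduced_state(Y, design, "z")
        perm = rng.permutation(n)
        Yp = freedman_lane_sample(state, PermutationDraw(perm, 1))
        mu = Y.mean(axis=0)
        np.testing.assert_allclose(Yp, mu + (Y - mu)[perm], atol=1e-12)

    def test_column_means_conserved_under_any_draw(self, rng, toy):
        Y, design = toy
        state = reduced_state(Y, design, "eud")
        for _ in range(5):
            Yp = freedman_lane_sample(
                state, PermutationDraw(rng.permutation(state.n), 1))
            np.testing.assert_allclose(Yp.mean(axis=0), Y.mean(axis=0),
                                       atol=1e-10)

    def test_draw_validation(self):
        with pytest.raises(ValueError):
            PermutationDraw(np.array([0, 0, 1]), 1)
        with pytest.raises(ValueError):
            PermutationDraw(np.array([1, 0, 2]), 0, observed=True)


class TestR2FStatistic:
    def test_orthogonal_focal_gives_zero(self, rng):
        n = 14
        x = rng.normal(size=n)
        design = simple_design(x, nuisance=None)
        state = reduced_state(rng.normal(size=(n, 2)), design, "z")
        Y_orth = state.E_YX - np.outer(state.E_ZX,
                                       state.E_ZX @ state.E_YX) / (state.E_ZX @ state.E_ZX)
        assert r2f_statistic(state, Y_orth) == pytest.approx(0.0, abs=1e-20)

    def test_single_gene_intercept_only_is_squared_pearson(self, rng):
        n = 25
        z = rng.normal(size=n)
        y = rng.normal(size=(n, 1))
        design = simple_design(z)
        state = reduced_state(y, design, "z")
        expected = stats.pearsonr(z, y[:, 0]).statistic ** 2
        assert r2f_statistic(state, y) == pytest.approx(expected, abs=1e-12)

    def test_single_gene_one_covariate_is_squared_partial_correlation(self, rng):
        """Textbook three-regression recipe as the oracle."""
        n = 8
        x = rng.normal(size=n)
        z = 0.5 * x + rng.normal(size=n)
        y = rng.normal(size=(n, 1))
        design = simple_design(z, nuisance=x)
        state = reduced_state(y, design, "z")
        X1 = np.column_stack([np.ones(n), x])
        ry = y[:, 0] - X1 @ np.linalg.lstsq(X1, y[:, 0], rcond=None)[0]
        rz = state.z - X1 @ np.linalg.lstsq(X1, state.z, rcond=None)[0]
        expected = stats.pearsonr(ry, rz).statistic ** 2
        assert r2f_statistic(state, y) == pytest.approx(expected, abs=1e-10)

    def test_statistic_bounded_in_unit_interval(self, rng):
        Y, design = make_dataset(rng, n=15, m=4, beta=0.8)
        state = reduced_state(Y, design, "eud")
        assert 0.0 <= r2f_statistic(state, Y) <= 1.0


class TestAndersonR2F:
    def test_exhaustive_enumeration_matches_sampled_draws(self, rng):
        """n = 6: running each of the 720 permutations once must equal the
        full-enumeration p exactly."""
        n = 6
        z = rng.normal(size=n)
        Y = rng.normal(size=(n, 2))
        design = simple_design(z)
        perms = all_permutations(n)
        res_enum = anderson_r2f_test(Y, design, "z", permutations=perms)
        state = reduced_state(Y, design, "z")
        obs = r2f_statistic(state, Y)
        brute = [r2f_statistic(state, freedman_lane_sample(
            state, PermutationDraw(p, i))) for i, p in enumerate(perms)]
        p_brute = np.mean(np.array(brute) >= obs)
        assert res_enum.p == pytest.approx(p_brute, abs=1e-12)
        assert res_enum.statistic == pytest.approx(obs, rel=1e-10)

    def test_strong_effect_saturates_at_1_over_b(self, rng):
        Y, design = make_dataset(rng, n=50, m=3, beta=1.0)
        res = anderson_r2f_test(Y, design, "eud", n_perm=200, seed=rng)
        assert res.p == pytest.approx(1 / 200)

    def test_null_pvalues_uniform(self, rng):
        pvals = [anderson_r2f_test(*make_dataset(rng, n=20, m=3, n_nuisance=1),
                                   focal="eud", n_perm=200, seed=rng).p
                 for _ in range(400)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestFpun:
    def test_observed_statistic_deterministic(self, rng):
        Y, design = make_dataset(rng, n=30, m=4)
        r1 = fpun_test(Y, design, "eud", n_perm=50, seed=1)
        r2 = fpun_test(Y, design, "eud", n_perm=50, seed=99)
        assert r1.statistic == r2.statistic

    def test_matches_anderson_with_shared_draws_single_gene(self, rng):
        """m = 1, one covariate: both statistics are monotone in the same
        quantity, so identical draws give identical p-values."""
        n = 18
        x = rng.normal(size=n)
        z = 0.4 * x + rng.normal(size=n)
        y = rng.normal(size=(n, 1)) + 0.3 * z[:, None]
        design = simple_design(z, nuisance=x)
        perms = np.vstack([np.arange(n),
                           np.array([rng.permutation(n) for _ in range(199)])])
        p1 = anderson_r2f_test(y, design, "z", permutations=perms).p
        p2 = fpun_test(y, design, "z", permutations=perms).p
        assert p1 == p2

    def test_null_pvalues_uniform(self, rng):
        pvals = [fpun_test(*make_dataset(rng, n=20, m=3, n_nuisance=1),
                           focal="eud", n_perm=200, seed=rng).p
                 for _ in range(400)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestFga:
    def test_identity_iteration_equals_fpun_observed_statistic(self, rng):
        Y, design = make_dataset(rng, n=25, m=3, beta=0.3)
        rf = fpun_test(Y, design, "eud", n_perm=5, seed=0)
        rg = fga_test(Y, design, "eud", n_perm=5, seed=0)
        assert rg.statistic == pytest.approx(rf.statistic, rel=1e-10)

    def test_strong_effect_saturates(self, rng):
        Y, design = make_dataset(rng, n=50, m=3, beta=1.0)
        res = fga_test(Y, design, "eud", n_perm=200, seed=rng)
        assert res.p == pytest.approx(1 / 200)

    def test_agrees_with_fpun_on_null_data(self, rng):
        """Exchangeability violation is mild: p_fga within 0.03 of p_fpun."""
        diffs = []
        for _ in range(50):
            Y, design = make_dataset(rng, n=40, m=4, gene_corr=0.3)
            pg = fga_test(Y, design, "eud", n_perm=400, seed=rng).p
            pp = fpun_test(Y, design, "eud", n_perm=400, seed=rng).p
            diffs.append(pg - pp)
        assert np.mean(np.abs(diffs)) < 0.03

    def test_null_pvalues_uniform(self, rng):
        pvals = [fga_test(*make_dataset(rng, n=20, m=3, n_nuisance=1),
                          focal="eud", n_perm=200, seed=rng).p
                 for _ in range(400)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRotation:
    def test_rotation_draw_requires_unit_norm(self):
        with pytest.raises(ValueError):
            RotationDraw(np.array([1.0, 1.0]), 1)
        RotationDraw(np.array([0.6, 0.8]), 1)  # valid

    def test_single_gene_unmoderated_approximates_t_test(self, rng):
        """m = 1 with moderation disabled: the rotation p matches the
        classical two-sided t-test p within Monte Carlo error."""
        n = 24
        x = rng.normal(size=n)
        z = 0.3 * x + rng.normal(size=n)
        y = rng.normal(size=(n, 1)) + 0.5 * z[:, None]
        design = simple_design(z, nuisance=x)
        from setmean import fit_mvlm
        fit = fit_mvlm(y, design)
        t = fit.tvals("z")[0]
        p_t = 2 * stats.t.sf(abs(t), fit.df_resid)
        res = rotation_test(y, design, "z", n_rot=10_000, seed=rng,
                            moderate=False)
        assert res.p == pytest.approx(p_t, abs=0.02)

    def test_p_at_least_one_over_b(self, rng):
        Y, design = make_dataset(rng, n=50, m=3, beta=1.5)
        res = rotation_test(Y, design, "eud", n_rot=300, seed=rng)
        assert res.p >= 1 / 300
        assert res.p == pytest.approx(1 / 300)

    def test_null_pvalues_uniform(self, rng):
        pvals = [rotation_test(*make_dataset(rng, n=20, m=3, n_nuisance=1),
                               focal="eud", n_rot=200, seed=rng).p
                 for _ in range(400)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_equal_variances_fall_back_to_common_variance(self, rng):
        from setmean._moderation import estimate_prior
        s2 = np.full(6, 1.7)
        d0, s02 = estimate_prior(s2, 10)
        assert np.isinf(d0)
        assert s02 > 0


def test_all_tests_reject_overwhelming_effect_at_floor(rng):
    Y, design = make_dataset(rng, n=60, m=4, beta=2.0)
    B = 250
    for func, kw in [(anderson_r2f_test, {"n_perm": B}),
                     (fpun_test, {"n_perm": B}),
                     (fga_test, {"n_perm": B}),
                     (rotation_test, {"n_rot": B})]:
        res = func(Y, design, "eud", seed=rng, **kw)
        assert res.p == pytest.approx(1 / B), res.method
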