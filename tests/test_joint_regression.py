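"""Modified joint regression: ALS solution, oracles, tests, labels."""

import numpy as np
import pandas as pd
import pytest

from oatmet import (
    DegenerateInputError,
    IntegrityError,
    SyntheticTruth,
    cell_means,
    classify_stability,
    fit_joint_regression,
    simulate_met,
    slope_heterogeneity_test,
    variety_effect_test,
)


def svd_rank1_oracle(Y):
    """Independent solution for complete tables: row means + first SVD
    component of the row-centred matrix, rescaled to mean-1 slopes."""
    V = Y.mean(axis=1)
    R = Y - V[:, None]
    u, s, vt = np.linalg.svd(R)
    beta = u[:, 0] * s[0]
    E = vt[0]
    c = beta.mean()
    return V, beta / c, E * c


class TestFitExamples:
    def test_additive_data_forces_unit_slopes(self):
        f = fit_joint_regression(np.array([[1.0, 3.0], [2.0, 4.0]]))
        assert f.variety_means == pytest.approx([2.0, 3.0])
        assert f.sensitivities == pytest.approx([1.0, 1.0])
        assert f.env_index == pytest.approx([-1.0, 1.0])
        assert f.rss == pytest.approx(0.0, abs=1e-20)
        assert f.exact_fit

    def test_exact_bilinear_data_refit(self):
        f = fit_joint_regression(np.array([[9.0, 11.0], [17.0, 23.0]]))
        assert f.variety_means == pytest.approx([10.0, 20.0])
        assert f.sensitivities == pytest.approx([0.5, 1.5])
        assert f.env_index == pytest.approx([-2.0, 2.0])
        assert f.rss == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("seed", range(5))
    def test_svd_oracle_on_complete_matrices(self, seed):
        rng = np.random.default_rng(seed)
        Y = rng.normal(0.0, 2.0, size=(4, 6)) + rng.normal(size=(4, 1)) * 3
        f = fit_joint_regression(Y)
        R = Y - Y.mean(axis=1, keepdims=True)
        u, s, vt = np.linalg.svd(R)
        rank1 = s[0] * np.outer(u[:, 0], vt[0])
        assert np.abs(np.outer(f.sensitivities, f.env_index) - rank1).max() < 1e-8
        V, b, E = svd_rank1_oracle(Y)
        assert f.variety_means == pytest.approx(V, abs=1e-8)
        assert f.sensitivities == pytest.approx(b, abs=1e-8)
        assert f.env_index == pytest.approx(E, abs=1e-8)


class TestIdentifiabilityAndInvariants:
    def test_constraints_hold(self):
        rng = np.random.default_rng(11)
        f = fit_joint_regression(rng.normal(8.0, 2.0, size=(5, 9)))
        assert f.sensitivities.mean() == pytest.approx(1.0, abs=1e-9)
        assert f.env_index.sum() == pytest.approx(0.0, abs=1e-9)

    def test_fitted_values_invariant_under_rescaling(self):
        rng = np.random.default_rng(12)
        f = fit_joint_regression(rng.normal(8.0, 2.0, size=(4, 8)))
        c = 3.7
        rescaled = (f.variety_means[:, None]
                    + (f.sensitivities / c)[:, None] * (c * f.env_index)[None, :])
        assert rescaled == pytest.approx(f.fitted(), abs=1e-12)

    def test_rss_monotone_across_sweeps(self):
        rng = np.random.default_rng(13)
        f = fit_joint_regression(rng.normal(8.0, 2.0, size=(6, 12)))
        trace = f.rss_trace
        assert np.all(np.diff(trace) <= 1e-9 * trace[:-1] + 1e-12)

    def test_missing_cells_reduce_error_df(self):
        rng = np.random.default_rng(14)
        Y = rng.normal(8.0, 2.0, size=(4, 8))
        complete = fit_joint_regression(Y)
        Ym = Y.copy()
        Ym[0, 0] = np.nan
        Ym[2, 5] = np.nan
        incomplete = fit_joint_regression(Ym)
        assert incomplete.error_df == complete.error_df - 2
        assert incomplete.converged

    def test_recovery_exact_at_zero_noise(self):
        truth = SyntheticTruth(seed=3, sigma_noise=0.0)
        met, realized = simulate_met(truth)
        f = fit_joint_regression(cell_means(met, "yield"))
        assert f.sensitivities == pytest.approx(realized.sensitivities, abs=1e-10)
        assert f.env_index == pytest.approx(realized.env_index, abs=1e-10)
        assert f.variety_means == pytest.approx(
            realized.grand_mean + realized.variety_effects, abs=1e-10
        )


class TestFitValidation:
    def test_single_variety_rejected(self):
        with pytest.raises(IntegrityError):
            fit_joint_regression(np.array([[1.0, 2.0, 3.0]]))

    def test_variety_in_too_few_environments_rejected(self):
        Y = np.random.default_rng(0).normal(size=(3, 5))
        Y[0, 2:] = np.nan  # first variety observed twice only
        with pytest.raises(IntegrityError, match="fewer than 3"):
            fit_joint_regression(Y)

    def test_no_environment_spread_is_degenerate(self):
        with pytest.raises(DegenerateInputError, match="environment"):
            fit_joint_regression(np.array([[5.0, 5.0, 5.0], [7.0, 7.0, 7.0]]))

    def test_nonconvergence_flagged_not_raised(self):
        # incomplete table: the warm start is inexact there, so a
        # one-sweep budget cannot satisfy the stop rule
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(4, 8))
        Y[0, 0] = Y[1, 3] = Y[2, 6] = np.nan
        f = fit_joint_regression(Y, max_iter=1)
        assert not f.converged


class TestHeterogeneityTest:
    def test_additive_data_gives_p_one(self):
        base = np.arange(6.0)
        f = fit_joint_regression(np.vstack([base + 1, base + 2, base + 3]))
        t = slope_heterogeneity_test(f)
        assert t.sum_of_squares == pytest.approx(0.0, abs=1e-16)
        assert t.p_value == 1.0

    def test_exact_rank1_unequal_slopes_sets_exact_fit_flag(self):
        f = fit_joint_regression(np.array([[9.0, 11.0], [17.0, 23.0]]))
        t = slope_heterogeneity_test(f)
        assert t.exact_fit
        assert t.p_value == 0.0

    def test_null_calibration(self):
        """Type-I error of the slope test near its nominal 5% level."""
        rng = np.random.default_rng(2024)
        n_rej = 0
        n_sim = 400
        for _ in range(n_sim):
            E = rng.normal(0.0, 1.0, 22)
            E -= E.mean()
            Y = rng.normal(8.0, 0.5, 4)[:, None] + E[None, :] + rng.normal(
                0.0, 0.3, (4, 22)
            )
            if slope_heterogeneity_test(fit_joint_regression(Y)).p_value < 0.05:
                n_rej += 1
        assert 0.02 <= n_rej / n_sim <= 0.09

    def test_strong_interaction_detected(self):
        rng = np.random.default_rng(8)
        E = np.linspace(-3, 3, 22)
        b = np.array([0.4, 0.8, 1.2, 1.6])
        Y = 8.0 + b[:, None] * E[None, :] + rng.normal(0, 0.1, (4, 22))
        t = slope_heterogeneity_test(fit_joint_regression(Y))
        assert t.p_value < 1e-6


class TestVarietyEffectTest:
    def test_identical_rows_give_p_one(self):
        base = np.array([1.0, 2.0, 4.0, 6.0, 8.0])
        rng = np.random.default_rng(3)
        Y = np.vstack([base, base, base]) + rng.normal(0, 0.2, (3, 5))
        f = fit_joint_regression(Y)
        t = variety_effect_test(f)
        assert t.p_value > 0.05  # no systematic separation

    def test_separated_rows_highly_significant(self):
        rng = np.random.default_rng(4)
        base = np.linspace(-2, 2, 8)
        Y = np.vstack([base, base + 10, base + 20]) + rng.normal(0, 0.05, (3, 8))
        t = variety_effect_test(fit_joint_regression(Y))
        assert t.p_value < 1e-6

    def test_zero_residual_data_flags_exact_fit(self):
        t = variety_effect_test(fit_joint_regression(np.array([[1.0, 3.0], [2.0, 4.0]])))
        assert t.exact_fit


class TestClassifyStability:
    def test_reference_tgw_slope_pattern(self):
        """Slopes like the trial's TGW quadruple with tight errors split
        into one sensitive, one average and two stable varieties."""
        b = np.array([1.381, 0.988, 0.799, 0.808])
        E = np.linspace(-4.5, 4.5, 22)
        V = np.array([41.8, 37.4, 45.4, 41.9])
        rng = np.random.default_rng(6)
        Y = V[:, None] + b[:, None] * E[None, :] + rng.normal(0, 0.35, (4, 22))
        f = fit_joint_regression(Y)
        labels = classify_stability(f)
        assert list(labels) == ["sensitive", "average", "stable", "stable"]

    def test_all_unit_slopes_average(self):
        base = np.linspace(0, 5, 6)
        f = fit_joint_regression(np.vstack([base + 1, base + 2]))
        assert set(classify_stability(f)) == {"average"}

    def test_exact_fit_large_slope_sensitive(self):
        f = fit_joint_regression(np.array([[9.0, 11.0], [17.0, 23.0]]))
        labels = classify_stability(f)
        assert list(labels) == ["stable", "sensitive"]

    def test_statsmodels_cross_check_of_conditional_slopes(self):
        """Given the final E, per-variety OLS via statsmodels reproduces
        b_i and its conditional standard error."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(9)
        Y = 8.0 + rng.normal(1, 0.3, 4)[:, None] * np.linspace(-3, 3, 10)[None, :]
        Y += rng.normal(0, 0.2, Y.shape)
        f = fit_joint_regression(Y)
        X = sm.add_constant(f.env_index)
        mse_pooled = f.residual_mean_square
        for i in range(4):
            res = sm.OLS(Y[i], X).fit()
            assert res.params[1] == pytest.approx(f.sensitivities[i], abs=1e-8)
            se = np.sqrt(mse_pooled / np.sum((f.env_index - f.env_index.mean()) ** 2))
            assert f.se_sensitivities[i] == pytest.approx(se, rel=1e-10)
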