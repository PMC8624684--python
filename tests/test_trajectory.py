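"""Spline basis, period-slope contrasts, mixed-model fits, knot selection."""

import numpy as np
import pandas as pd
import pytest

from mscog.simulate import SimulationConfig, generate_cohort
from mscog.trajectory import (
    CognitiveTrajectoryModel,
    basis_to_period_slopes,
    build_spline_basis,
    fit_mixed_linear,
    fit_mixed_spline,
    select_knots,
)


class TestSplineBasis:
    @pytest.mark.parametrize(
        "t,expected",
        [(3.0, (3, 0, 0)), (10.0, (10, 5, 0)), (20.0, (20, 15, 5)), (5.0, (5, 0, 0))],
    )
    def test_truncated_power_values(self, t, expected):
        np.testing.assert_allclose(build_spline_basis([t])[0], expected)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            build_spline_basis([-0.1])

    def test_continuity_at_knots(self):
        eps = 1e-9
        for k in (5.0, 15.0):
            below = build_spline_basis([k - eps])[0]
            above = build_spline_basis([k + eps])[0]
            np.testing.assert_allclose(below, above, atol=1e-8)

    def test_bad_knots_rejected(self):
        with pytest.raises(ValueError):
            build_spline_basis([1.0], knots=(15, 5))


class TestPeriodSlopes:
    def test_reported_global_cognition_contrasts(self):
        # basis coefficients back-solved from the per-period slopes
        # 0.080 / -0.029 / -0.031 of the global-cognition spline model
        slopes, ses = basis_to_period_slopes([0.080, -0.109, -0.002], np.zeros((3, 3)))
        np.testing.assert_allclose(slopes, [0.080, -0.029, -0.031], atol=1e-12)
        np.testing.assert_allclose(ses, 0.0)

    def test_no_knot_change_keeps_slope(self):
        slopes, _ = basis_to_period_slopes([0.05, 0.0, 0.0])
        np.testing.assert_allclose(slopes, [0.05, 0.05, 0.05])

    def test_delta_method_agrees_with_monte_carlo(self, rng):
        beta = np.array([0.08, -0.1, -0.01])
        cov = np.array([[4e-4, -1e-4, 0.0], [-1e-4, 3e-4, -5e-5], [0.0, -5e-5, 2e-4]])
        _, ses = basis_to_period_slopes(beta, cov)
        draws = rng.multivariate_normal(beta, cov, size=200_000)
        mc = np.cumsum(draws, axis=1).std(axis=0)
        np.testing.assert_allclose(ses, mc, rtol=0.02)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            basis_to_period_slopes([0.1, 0.2], np.zeros((3, 3)))


class TestMixedFits:
    def test_noise_free_linear_slope_exact(self):
        rows = []
        for i in range(6):
            for t in (1.0 + i, 3.0 + i, 6.0 + i):
                rows.append({"subject_id": f"S{i}", "time_since_onset": t, "z": 0.05 * t + 0.2})
        visits = pd.DataFrame(rows)
        baseline = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(6)],
                "age": np.linspace(30, 50, 6),
                "disease_duration": np.linspace(1, 6, 6),
                "education_level": [1, 2, 3, 4, 2, 3],
                "sex": [0, 1, 0, 1, 0, 1],
            }
        )
        res = fit_mixed_linear(visits, baseline, "z", covariates=())
        assert res.period_slopes.loc["overall", "slope"] == pytest.approx(0.05, abs=1e-6)

    def test_noise_free_spline_recovery(self, noise_free_cohort):
        baseline, visits, _ = noise_free_cohort
        res = fit_mixed_spline(visits, baseline, "z_global")
        np.testing.assert_allclose(
            res.period_slopes["slope"].to_numpy(), [0.08, -0.03, -0.03], atol=1e-6
        )

    def test_fixed_effects_equal_gls_oracle(self, default_cohort):
        """Given the fitted variance components, the mixed-model fixed effects
        must equal the closed-form GLS solution computed from scratch."""
        baseline, visits, _ = default_cohort
        model = CognitiveTrajectoryModel(visits, baseline, "z_global")
        res = model.fit()
        mdf = res._mixedlm_results
        X, _ = model._design()
        y = model._df["z_global"].to_numpy()
        groups = model._df["subject_id"].to_numpy()
        tau2 = res.random_intercept_var
        sigma2 = res.residual_var
        XtViX = np.zeros((X.shape[1], X.shape[1]))
        XtViy = np.zeros(X.shape[1])
        for g in pd.unique(groups):
            rows = groups == g
            ni = rows.sum()
            V = sigma2 * np.eye(ni) + tau2 * np.ones((ni, ni))
            Vi = np.linalg.inv(V)
            Xg = X[rows]
            XtViX += Xg.T @ Vi @ Xg
            XtViy += Xg.T @ Vi @ y[rows]
        beta_gls = np.linalg.solve(XtViX, XtViy)
        np.testing.assert_allclose(mdf.fe_params, beta_gls, atol=1e-8)

    def test_aic_identity(self, default_cohort):
        baseline, visits, _ = default_cohort
        res = fit_mixed_spline(visits, baseline, "z_global", method="ml")
        assert res.aic == pytest.approx(2 * res.k_params - 2 * res.llf, abs=1e-10)

    def test_ci_brackets_estimate(self, default_cohort):
        baseline, visits, _ = default_cohort
        res = fit_mixed_spline(visits, baseline, "z_global")
        ps = res.period_slopes
        assert (ps["ci_low"] <= ps["slope"]).all()
        assert (ps["slope"] <= ps["ci_high"]).all()

    def test_summary_mentions_periods(self, default_cohort):
        baseline, visits, _ = default_cohort
        res = fit_mixed_spline(visits, baseline, "z_global")
        text = res.summary()
        assert "0-5 y" in text and "5-15 y" in text and ">15 y" in text

    def test_degenerate_identical_visit_times_rejected(self):
        visits = pd.DataFrame(
            {
                "subject_id": ["a", "a", "b", "b"],
                "time_since_onset": [2.0, 2.0, 1.0, 3.0],
                "z": [0.1, 0.2, 0.3, 0.4],
            }
        )
        baseline = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "age": [40, 45],
                "disease_duration": [2.0, 1.0],
                "education_level": [2, 3],
                "sex": [0, 1],
            }
        )
        with pytest.raises(ValueError, match="identical visit times"):
            CognitiveTrajectoryModel(visits, baseline, "z", covariates=())

    def test_unknown_outcome_rejected(self, default_cohort):
        baseline, visits, _ = default_cohort
        with pytest.raises(ValueError):
            CognitiveTrajectoryModel(visits, baseline, "z_missing")


class TestSelectKnots:
    def test_single_candidate_returned(self, default_cohort):
        baseline, visits, _ = default_cohort
        best, table = select_knots(visits, baseline, "z_global", [(5, 15)])
        assert best == (5.0, 15.0)
        assert len(table) == 1

    def test_duplicate_candidates_tie_reported(self, default_cohort):
        baseline, visits, _ = default_cohort
        best, table = select_knots(visits, baseline, "z_global", [(5, 15), (5, 15)])
        assert best == (5.0, 15.0)
        assert table["tie"].any()
        assert table.loc[0, "selected"]
        assert not table.loc[1, "selected"]

    def test_generating_knots_win_at_moderate_n(self):
        cfg = SimulationConfig(n_subjects=600, seed=31)
        baseline, visits, _ = generate_cohort(cfg)
        best, table = select_knots(visits, baseline, "z_global", [(3, 10), (5, 15), (8, 20)])
        assert best == (5.0, 15.0)
        assert table["converged"].all()

    def test_spline_terms_do_not_help_linear_truth(self):
        """Adding knots to truly linear trajectories should not beat the
        single-slope model by more than chance-level AIC differences."""
        cfg = SimulationConfig(
            n_subjects=250,
            seed=17,
            period_slopes={o: (-0.02, -0.02, -0.02) for o in
                           ("z_global", "z_verbal", "z_visual", "z_attn_ips", "z_fluency")},
        )
        baseline, visits, _ = generate_cohort(cfg)
        lin = fit_mixed_linear(visits, baseline, "z_global", method="ml")
        spl = fit_mixed_spline(visits, baseline, "z_global", method="ml")
        assert lin.aic - spl.aic < 4.0
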