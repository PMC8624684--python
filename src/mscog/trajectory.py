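"""Mixed-effects linear and linear-spline models of cognition over disease duration.

The population trajectory of a cognitive z-score is modelled as a function of
years since disease onset with a subject-level random intercept (optionally a
random slope), adjusted for age at onset, educational level and sex:

    z_ij = b0 + f(t_ij) + c'w_i + u_i (+ v_i t_ij) + e_ij

where ``f`` is either a single straight line or a piecewise-linear spline in
a truncated-power basis with knots at fixed disease durations (default 5 and
15 years), dividing the disease course into three periods. The quantities of
scientific interest are the per-period slopes — linear contrasts of the basis
coefficients — with delta-method standard errors, Wald confidence intervals
and p-values.

Estimation uses statsmodels MixedLM. ML fits are used wherever AIC values are
compared across fixed-effect structures (knot selection); REML is the default
for reported fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

DEFAULT_KNOTS = (5.0, 15.0)
DEFAULT_COVARIATES = ("age_at_onset", "education_level", "sex")


class ConvergenceError(RuntimeError):
    """Mixed-model optimizer failed to converge."""


def build_spline_basis(t, knots=DEFAULT_KNOTS) -> np.ndarray:
    """Truncated-power linear spline basis: ``(t, (t-k1)+, (t-k2)+, ...)``.

    Continuous in ``t`` for any coefficients; one column per period.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if (t < 0).any():
        raise ValueError("time since onset must be >= 0")
    knots = tuple(knots)
    if any(k <= 0 for k in knots) or any(b <= a for a, b in zip(knots, knots[1:])):
        raise ValueError("knots must be strictly increasing and positive")
    cols = [t] + [np.clip(t - k, 0.0, None) for k in knots]
    return np.column_stack(cols)


def basis_to_period_slopes(
    beta, cov: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-period slopes from truncated-power coefficients.

    ``(s1, s2, s3) = (b1, b1+b2, b1+b2+b3)``; standard errors follow from the
    coefficient covariance via the delta method on the cumulative-sum
    contrasts.
    """
    beta = np.asarray(beta, dtype=float)
    L = np.tril(np.ones((beta.size, beta.size)))
    slopes = L @ beta
    if cov is None:
        return slopes, None
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (beta.size, beta.size):
        raise ValueError("covariance shape does not match coefficient length")
    ses = np.sqrt(np.diag(L @ cov @ L.T))
    return slopes, ses


@dataclass
class TrajectoryResults:
    """Fitted trajectory model: per-period slopes, covariate effects, variance components."""

    outcome: str
    knots: tuple[float, ...]
    period_slopes: pd.DataFrame
    covariate_effects: pd.DataFrame
    random_intercept_var: float
    random_slope_var: float | None
    residual_var: float
    llf: float
    aic: float
    k_params: int
    n_subjects: int
    n_observations: int
    converged: bool
    singular: bool
    method: str
    _mixedlm_results: object = None

    def summary(self) -> str:
        lines = [
            f"Cognitive trajectory model: {self.outcome}"
            + (f", knots at {', '.join(str(k) for k in self.knots)} years" if self.knots else ", single slope"),
            f"Subjects: {self.n_subjects}   Observations: {self.n_observations}   "
            f"Method: {self.method.upper()}   logLik: {self.llf:.2f}   AIC: {self.aic:.2f}",
            "",
            self.period_slopes.to_string(float_format=lambda v: f"{v: .4f}"),
            "",
            "Covariate effects:",
            self.covariate_effects.to_string(float_format=lambda v: f"{v: .4f}"),
            "",
            f"Variance components: random intercept {self.random_intercept_var:.4f}"
            + (
                f", random slope {self.random_slope_var:.6f}"
                if self.random_slope_var is not None
                else ""
            )
            + f", residual {self.residual_var:.4f}",
        ]
        if self.singular:
            lines.append("Warning: variance components on the boundary (singular fit).")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "knots": list(self.knots),
            "period_slopes": self.period_slopes.reset_index().to_dict(orient="records"),
            "covariate_effects": self.covariate_effects.reset_index().to_dict(orient="records"),
            "variance_components": {
                "random_intercept": self.random_intercept_var,
                "random_slope": self.random_slope_var,
                "residual": self.residual_var,
            },
            "llf": self.llf,
            "aic": self.aic,
            "n_subjects": self.n_subjects,
            "n_observations": self.n_observations,
            "converged": self.converged,
            "singular": self.singular,
            "method": self.method,
        }


class CognitiveTrajectoryModel:
    """Mixed-effects model of one cognitive outcome over disease duration.

    Parameters
    ----------
    visits
        Long table with ``subject_id``, ``time_since_onset`` and outcome columns.
    baseline
        One row per subject with ``age``, ``disease_duration``,
        ``education_level`` and ``sex`` (age at onset is derived as
        ``age - disease_duration`` and centred).
    outcome
        Name of the z-score column to model.
    knots
        Spline knots in years since onset, or ``None`` for a single slope.
    random_slope
        Add a subject-level random slope on duration.
    """

    def __init__(
        self,
        visits: pd.DataFrame,
        baseline: pd.DataFrame,
        outcome: str,
        knots: tuple[float, ...] | None = DEFAULT_KNOTS,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        random_slope: bool = False,
    ):
        if outcome not in visits.columns:
            raise ValueError(f"outcome {outcome!r} not in visit table")
        self.outcome = outcome
        self.knots = tuple(knots) if knots else ()
        self.covariates = tuple(covariates)
        self.random_slope = random_slope

        df = visits[["subject_id", "time_since_onset", outcome]].merge(
            baseline[["subject_id", "age", "disease_duration", "education_level", "sex"]],
            on="subject_id",
            how="left",
        )
        # complete cases: visits lacking the outcome or any covariate source
        needed = [outcome, "time_since_onset"]
        if covariates:
            needed += ["age", "disease_duration", "education_level", "sex"]
        df = df.dropna(subset=[c for c in needed if c in df.columns])
        df["age_at_onset"] = df["age"] - df["disease_duration"]
        df["age_at_onset"] -= df["age_at_onset"].mean()

        counts = df.groupby("subject_id")["time_since_onset"].agg(["count", "nunique"])
        if (counts["count"] >= 2).sum() < 2:
            raise ValueError("need at least 2 subjects with >=2 visits")
        degenerate = counts.index[(counts["count"] > 1) & (counts["nunique"] == 1)]
        if len(degenerate):
            raise ValueError(
                f"subjects with all-identical visit times: {list(degenerate[:5])}"
            )
        self._df = df.reset_index(drop=True)

    # ------------------------------------------------------------------
    def _design(self) -> tuple[np.ndarray, list[str]]:
        t = self._df["time_since_onset"].to_numpy()
        if self.knots:
            basis = build_spline_basis(t, self.knots)
            names = ["duration_p1"] + [f"duration_after_{k:g}y" for k in self.knots]
        else:
            basis = t[:, None]
            names = ["duration"]
        cols = [np.ones(len(t)), *basis.T]
        names = ["const"] + names
        for c in self.covariates:
            cols.append(self._df[c].to_numpy(dtype=float))
            names.append(c)
        return np.column_stack(cols), names

    def _degenerate_results(self, ols, names, method: str) -> TrajectoryResults:
        """Exact-interpolation limit: all variance components zero."""
        n_basis = 1 + len(self.knots)
        beta = ols.params[1 : 1 + n_basis]
        slopes, _ = basis_to_period_slopes(beta, np.zeros((n_basis, n_basis)))
        labels = self._period_labels()
        zeros = np.zeros(len(slopes))
        period_slopes = pd.DataFrame(
            {"slope": slopes, "se": zeros, "ci_low": slopes, "ci_high": slopes,
             "p_value": np.where(slopes == 0, 1.0, 0.0)},
            index=pd.Index(labels, name="period"),
        )
        cov_rows = [i for i, nm in enumerate(names) if nm in self.covariates or nm == "const"]
        covariate_effects = pd.DataFrame(
            {"estimate": ols.params[cov_rows], "se": np.zeros(len(cov_rows)),
             "p_value": np.full(len(cov_rows), np.nan)},
            index=pd.Index([names[i] for i in cov_rows], name="term"),
        )
        k_re = 2 if self.random_slope else 1
        k_params = len(ols.params) + k_re * (k_re + 1) // 2 + 1
        return TrajectoryResults(
            outcome=self.outcome, knots=self.knots, period_slopes=period_slopes,
            covariate_effects=covariate_effects, random_intercept_var=0.0,
            random_slope_var=0.0 if self.random_slope else None, residual_var=0.0,
            llf=np.inf, aic=-np.inf, k_params=k_params,
            n_subjects=self._df["subject_id"].nunique(), n_observations=len(self._df),
            converged=True, singular=True, method=method.lower(),
        )

    def _period_labels(self) -> list[str]:
        if not self.knots:
            return ["overall"]
        bounds = (0.0,) + self.knots + (np.inf,)
        return [
            f"{a:g}-{b:g} y" if np.isfinite(b) else f">{a:g} y"
            for a, b in zip(bounds, bounds[1:])
        ]

    def fit(self, method: str = "reml", maxiter: int = 200) -> TrajectoryResults:
        """Fit by REML (default) or ML and report per-period slopes."""
        reml = method.lower() == "reml"
        X, names = self._design()
        y = self._df[self.outcome].to_numpy(dtype=float)
        groups = self._df["subject_id"].to_numpy()
        exog_re = (
            np.column_stack([np.ones(len(y)), self._df["time_since_onset"]])
            if self.random_slope
            else np.ones((len(y), 1))
        )

        model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=reml, method="lbfgs", maxiter=maxiter)
            except np.linalg.LinAlgError as exc:
                # degenerate data (e.g. noise-free trajectories) make the
                # profiled likelihood singular; fall back to OLS, which is the
                # mixed-model limit with all variance components at zero
                ols = sm.OLS(y, X).fit()
                if float(ols.ssr) / len(y) < 1e-10:
                    return self._degenerate_results(ols, names, method)
                raise ConvergenceError(f"mixed model failed: {exc}") from exc
        if not res.converged:
            raise ConvergenceError(
                "mixed model did not converge "
                f"(method={method}, n={len(y)}, params={res.params})"
            )

        n_basis = 1 + len(self.knots)
        idx = slice(1, 1 + n_basis)
        beta = res.fe_params[idx]
        cov = np.asarray(res.cov_params())[idx, idx.start : idx.stop]  # noqa: E203
        slopes, ses = basis_to_period_slopes(beta, cov)
        zcrit = stats.norm.ppf(0.975)
        zstat = np.divide(slopes, ses, out=np.full_like(slopes, np.nan), where=ses > 0)
        pvals = 2 * stats.norm.sf(np.abs(zstat))
        labels = self._period_labels()
        period_slopes = pd.DataFrame(
            {
                "slope": slopes,
                "se": ses,
                "ci_low": slopes - zcrit * ses,
                "ci_high": slopes + zcrit * ses,
                "p_value": pvals,
            },
            index=pd.Index(labels, name="period"),
        )

        fe = res.fe_params
        fe_se = np.sqrt(np.diag(np.asarray(res.cov_params())[: len(fe), : len(fe)]))
        cov_rows = [i for i, nm in enumerate(names) if nm in self.covariates or nm == "const"]
        covariate_effects = pd.DataFrame(
            {
                "estimate": fe[cov_rows],
                "se": fe_se[cov_rows],
                "p_value": 2 * stats.norm.sf(np.abs(fe[cov_rows] / fe_se[cov_rows])),
            },
            index=pd.Index([names[i] for i in cov_rows], name="term"),
        )

        # statsmodels reports cov_re on the response scale already
        cov_re = np.atleast_2d(np.asarray(res.cov_re))
        ri_var = float(cov_re[0, 0])
        rs_var = float(cov_re[1, 1]) if self.random_slope else None
        resid_var = float(res.scale)
        k_re = 2 if self.random_slope else 1
        k_params = len(fe) + k_re * (k_re + 1) // 2 + 1  # fixed + RE cov + residual
        aic = 2 * k_params - 2 * float(res.llf)
        singular = ri_var <= 1e-10 or (rs_var is not None and rs_var <= 1e-12)

        results = TrajectoryResults(
            outcome=self.outcome,
            knots=self.knots,
            period_slopes=period_slopes,
            covariate_effects=covariate_effects,
            random_intercept_var=ri_var,
            random_slope_var=rs_var,
            residual_var=resid_var,
            llf=float(res.llf),
            aic=aic,
            k_params=k_params,
            n_subjects=self._df["subject_id"].nunique(),
            n_observations=len(y),
            converged=bool(res.converged),
            singular=singular,
            method=method.lower(),
            _mixedlm_results=res,
        )
        return results


def fit_mixed_linear(
    visits, baseline, outcome, covariates=DEFAULT_COVARIATES, random_slope=False, method="reml"
) -> TrajectoryResults:
    """Single-slope mixed model of the outcome over disease duration."""
    return CognitiveTrajectoryModel(
        visits, baseline, outcome, knots=None, covariates=covariates, random_slope=random_slope
    ).fit(method=method)


def fit_mixed_spline(
    visits,
    baseline,
    outcome,
    knots=DEFAULT_KNOTS,
    covariates=DEFAULT_COVARIATES,
    random_slope=False,
    method="reml",
) -> TrajectoryResults:
    """Linear-spline mixed model returning per-period slopes."""
    return CognitiveTrajectoryModel(
        visits, baseline, outcome, knots=knots, covariates=covariates, random_slope=random_slope
    ).fit(method=method)


def select_knots(
    visits,
    baseline,
    outcome,
    candidates,
    covariates=DEFAULT_COVARIATES,
    random_slope=False,
) -> tuple[tuple[float, ...], pd.DataFrame]:
    """Choose the knot set with minimal AIC under ML fitting.

    Every candidate is fitted by ML (so likelihoods are comparable across
    fixed-effect structures); candidates that fail to converge are flagged
    and excluded rather than aborting the comparison. Ties are broken by
    first occurrence and reported in the table.
    """
    candidates = [tuple(c) for c in candidates]
    if len(candidates) < 2 and len(candidates) != 1:
        raise ValueError("need at least one candidate knot set")
    rows = []
    for cand in candidates:
        try:
            res = fit_mixed_spline(
                visits,
                baseline,
                outcome,
                knots=cand,
                covariates=covariates,
                random_slope=random_slope,
                method="ml",
            )
            rows.append({"knots": cand, "aic": res.aic, "llf": res.llf, "converged": True})
        except (ConvergenceError, ValueError):
            rows.append({"knots": cand, "aic": np.nan, "llf": np.nan, "converged": False})
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["aic"])
    if ok.empty:
        raise ConvergenceError("no candidate knot set converged")
    best_aic = ok["aic"].min()
    winners = ok.index[np.isclose(ok["aic"], best_aic, rtol=0, atol=1e-9)]
    table["selected"] = False
    table.loc[winners[0], "selected"] = True
    table["tie"] = False
    if len(winners) > 1:
        table.loc[winners, "tie"] = True
    return tuple(table.loc[winners[0], "knots"]), table
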