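"""Synthetic longitudinal MS cohort generator.

Emulates the statistical structure the downstream analyses assume: a baseline
table (demographics, clinical variables, lesion volume, 76 regional brain
volumes, acquisition-protocol batch), a visit table of cognitive z-scores over
disease duration following piecewise-linear population trajectories with
subject-level random effects, latent impairment labels drawn from sparse
logistic models on baseline features, MCAR missingness, and additive /
multiplicative protocol (batch) effects on the volumes.

Every latent quantity is returned in a ``truth`` record so recovery can be
checked exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .regions import REGION_VOLUME_COLUMNS

#: longitudinal outcome columns (z-score units)
OUTCOMES = ("z_global", "z_verbal", "z_visual", "z_attn_ips", "z_fluency")

#: impairment label column per outcome
LABEL_COLUMNS = {
    "z_global": "ci_global",
    "z_verbal": "ci_verbal",
    "z_visual": "ci_visual",
    "z_attn_ips": "ci_attn_ips",
    "z_fluency": "ci_fluency",
}

DISEASE_TYPES = ("CIS", "RRMS", "SPMS", "PPMS")

CLINICAL_COLUMNS = (
    "sex",
    "age",
    "education_level",
    "disease_duration",
    "disease_type",
    "edss",
    "dmt_use",
    "n_relapses",
    "lesion_volume",
)

BASELINE_COLUMNS = ("subject_id",) + CLINICAL_COLUMNS + REGION_VOLUME_COLUMNS + ("batch",)


def _default_period_slopes() -> dict[str, tuple[float, float, float]]:
    # Per-period z-score/year changes: a modest early improvement followed by
    # decline for global cognition and verbal memory; domain-specific patterns
    # for the rest (zero where no reliable change is assumed).
    return {
        "z_global": (0.080, -0.029, -0.031),
        "z_verbal": (0.083, -0.041, -0.055),
        "z_visual": (0.0, -0.041, 0.0),
        "z_attn_ips": (0.107, 0.0, -0.035),
        "z_fluency": (0.0, 0.0, 0.0),
    }


def _default_true_coefficients() -> dict[str, dict[str, float]]:
    # Sparse log-odds weights (per SD of the feature) linking baseline
    # features to impairment: low education, disability, lesion load and
    # limbic/cingulate atrophy raise the risk.
    return {
        "ci_global": {
            "education_level": -0.5,
            "edss": 0.8,
            "lesion_volume": 0.8,
            "vol_lh_hippocampus": -0.5,
            "vol_rh_rostralanteriorcingulate": -0.4,
        },
        "ci_verbal": {
            "education_level": -0.6,
            "edss": 0.7,
            "lesion_volume": 0.6,
            "vol_rh_parahippocampal": -0.6,
        },
        "ci_visual": {"lesion_volume": 0.7},
        "ci_attn_ips": {
            "edss": 0.9,
            "lesion_volume": 0.5,
            "vol_rh_hippocampus": -0.4,
        },
        "ci_fluency": {
            "lesion_volume": 0.4,
            "vol_lh_hippocampus": -0.4,
            "vol_rh_rostralanteriorcingulate": -0.4,
        },
    }


def _default_target_prevalence() -> dict[str, float]:
    return {
        "ci_global": 0.36,
        "ci_verbal": 0.27,
        "ci_visual": 0.24,
        "ci_attn_ips": 0.18,
        "ci_fluency": 0.20,
    }


def _default_covariate_effects() -> dict[str, float]:
    # Fixed-effect adjustments shared by all outcomes (applied to centred
    # age at onset, centred education, and the female indicator).
    return {"age_at_onset": -0.01, "education_level": 0.15, "sex": 0.0}


@dataclass
class BatchEffects:
    """Additive shift and variance scale applied to protocol-B volumes.

    ``shift`` and ``scale`` may be scalars (applied to every regional volume)
    or mappings of column name to value.
    """

    shift: float | Mapping[str, float] = 0.0
    scale: float | Mapping[str, float] = 1.0

    def shift_for(self, column: str) -> float:
        if isinstance(self.shift, Mapping):
            return float(self.shift.get(column, 0.0))
        return float(self.shift)

    def scale_for(self, column: str) -> float:
        if isinstance(self.scale, Mapping):
            return float(self.scale.get(column, 1.0))
        return float(self.scale)


@dataclass
class SimulationConfig:
    """All knobs of the generative model, with cohort-realistic defaults."""

    n_subjects: int = 212
    seed: int = 0
    knots: tuple[float, float] = (5.0, 15.0)
    period_slopes: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_period_slopes
    )
    baseline_level: dict[str, float] = field(
        default_factory=lambda: {o: 0.0 for o in OUTCOMES}
    )
    covariate_effects: dict[str, float] = field(default_factory=_default_covariate_effects)
    random_intercept_sd: float = 0.55
    random_slope_sd: float = 0.02
    random_effect_corr: float = 0.0
    residual_sd: float = 0.35
    visits_per_subject_range: tuple[int, int] = (2, 5)
    followup_years_range: tuple[float, float] = (0.9, 7.9)
    disease_duration_range: tuple[float, float] = (0.1, 29.0)
    true_coefficients: dict[str, dict[str, float]] = field(
        default_factory=_default_true_coefficients
    )
    target_prevalence: dict[str, float] = field(default_factory=_default_target_prevalence)
    missing_rate: float = 0.05
    batch_effects: BatchEffects = field(
        default_factory=lambda: BatchEffects(shift=0.25, scale=1.2)
    )
    batch_fraction_b: float = 0.5
    region_volume_mean: float = 10.0
    region_volume_sd: float = 1.0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        knots = tuple(self.knots)
        if any(k <= 0 for k in knots) or any(
            b <= a for a, b in zip(knots, knots[1:])
        ):
            raise ValueError("knots must be strictly increasing and positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for name in ("random_intercept_sd", "random_slope_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.visits_per_subject_range
        if lo < 1 or hi < lo:
            raise ValueError("visits_per_subject_range must be an increasing pair >= 1")
        if not -1.0 <= self.random_effect_corr <= 1.0:
            raise ValueError("random_effect_corr must lie in [-1, 1]")
        if not 0.0 <= self.batch_fraction_b <= 1.0:
            raise ValueError("batch_fraction_b must lie in [0, 1]")
        for out, prev in self.target_prevalence.items():
            if not 0.0 < prev < 1.0:
                raise ValueError(f"target_prevalence[{out}] must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def spline_mean(t, period_slopes: Sequence[float], knots: Sequence[float]) -> np.ndarray:
    """Population piecewise-linear mean at times ``t`` (level 0 at onset)."""
    t = np.asarray(t, dtype=float)
    slopes = np.asarray(period_slopes, dtype=float)
    knots = np.asarray(knots, dtype=float)
    # convert per-period slopes to truncated-power coefficients
    beta = np.concatenate([[slopes[0]], np.diff(slopes)])
    y = beta[0] * t
    for b, k in zip(beta[1:], knots):
        y = y + b * np.clip(t - k, 0.0, None)
    return y


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Logistic intercept b with mean(expit(b + eta)) == target."""

    def f(b: float) -> float:
        return float(np.mean(expit(b + eta))) - target

    return brentq(f, -40.0, 40.0, xtol=1e-10)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate one clean cohort (no batch distortion, no missingness).

    Returns ``(baseline, visits, truth)`` where ``truth`` carries every
    latent parameter: random effects, logistic intercepts, per-subject
    impairment probabilities and labels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    subject_id = np.array([f"S{i:04d}" for i in range(n)])
    sex = (rng.random(n) < 0.68).astype(int)  # 1 = female
    age = np.clip(rng.normal(41.0, 9.47, n), 18.0, 65.0)
    education_level = rng.choice([1, 2, 3, 4], size=n, p=[0.08, 0.40, 0.35, 0.17])
    d_lo, d_hi = config.disease_duration_range
    duration = np.clip(rng.lognormal(mean=np.log(8.2), sigma=0.9, size=n), d_lo, d_hi)
    duration = np.minimum(duration, np.maximum(age - 18.0, d_lo))
    disease_type = rng.choice(DISEASE_TYPES, size=n, p=[0.09, 0.83, 0.06, 0.02])
    edss = np.clip(np.round(rng.gamma(2.0, 1.25, n) * 2.0) / 2.0, 0.0, 10.0)
    dmt_use = (rng.random(n) < 0.52).astype(int)
    n_relapses = rng.poisson(3.0, n)
    lesion_volume = rng.lognormal(mean=np.log(5.16), sigma=1.2, size=n)

    volumes = rng.normal(
        config.region_volume_mean, config.region_volume_sd, size=(n, 76)
    )
    batch = np.where(rng.random(n) < config.batch_fraction_b, "B", "A")

    baseline = pd.DataFrame({"subject_id": subject_id})
    baseline["sex"] = sex
    baseline["age"] = age
    baseline["education_level"] = education_level
    baseline["disease_duration"] = duration
    baseline["disease_type"] = disease_type
    baseline["edss"] = edss
    baseline["dmt_use"] = dmt_use
    baseline["n_relapses"] = n_relapses
    baseline["lesion_volume"] = lesion_volume
    for j, col in enumerate(REGION_VOLUME_COLUMNS):
        baseline[col] = volumes[:, j]
    baseline["batch"] = batch

    # ---- latent impairment labels from the sparse logistic truth model ----
    feature_frame = baseline.drop(columns=["subject_id", "batch", "disease_type"]).astype(
        float
    )
    feature_frame["disease_type_ord"] = (
        pd.Series(disease_type).map({t: i + 1 for i, t in enumerate(DISEASE_TYPES)}).values
    )
    standardized = {c: _standardize(feature_frame[c].to_numpy()) for c in feature_frame}

    intercepts: dict[str, float] = {}
    probabilities: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for outcome, weights in config.true_coefficients.items():
        eta = np.zeros(n)
        for feat, w in weights.items():
            key = "disease_type_ord" if feat == "disease_type" else feat
            if key not in standardized:
                raise ValueError(f"unknown truth-model feature: {feat!r}")
            eta += w * standardized[key]
        b0 = _calibrate_intercept(eta, config.target_prevalence[outcome])
        p = expit(b0 + eta)
        intercepts[outcome] = b0
        probabilities[outcome] = p
        labels[outcome] = (rng.random(n) < p).astype(int)

    # ---- longitudinal visits ----
    re_sd = np.array([config.random_intercept_sd, config.random_slope_sd])
    corr = config.random_effect_corr
    cov = np.array(
        [
            [re_sd[0] ** 2, corr * re_sd[0] * re_sd[1]],
            [corr * re_sd[0] * re_sd[1], re_sd[1] ** 2],
        ]
    )
    rand_eff = rng.multivariate_normal([0.0, 0.0], cov, size=n) if re_sd.any() else np.zeros((n, 2))

    age_at_onset = age - duration
    ce = config.covariate_effects
    cov_shift = (
        ce.get("age_at_onset", 0.0) * (age_at_onset - 30.0)
        + ce.get("education_level", 0.0) * (education_level - 2.5)
        + ce.get("sex", 0.0) * sex
    )

    v_lo, v_hi = config.visits_per_subject_range
    f_lo, f_hi = config.followup_years_range
    rows: list[dict] = []
    for i in range(n):
        n_visits = int(rng.integers(v_lo, v_hi + 1))
        times = [duration[i]]
        if n_visits > 1:
            followup = rng.uniform(f_lo, f_hi)
            gaps = rng.uniform(0.2, 1.0, size=n_visits - 1)
            gaps = gaps / gaps.sum() * followup
            times.extend(duration[i] + np.cumsum(gaps))
        for t in times:
            row = {"subject_id": subject_id[i], "time_since_onset": float(t)}
            for outcome in OUTCOMES:
                mean = (
                    config.baseline_level.get(outcome, 0.0)
                    + spline_mean(t, config.period_slopes[outcome], config.knots)
                    + cov_shift[i]
                    + rand_eff[i, 0]
                    + rand_eff[i, 1] * t
                )
                noise = rng.normal(0.0, config.residual_sd) if config.residual_sd > 0 else 0.0
                row[outcome] = float(mean + noise)
            rows.append(row)
    visits = pd.DataFrame(rows, columns=["subject_id", "time_since_onset"] + list(OUTCOMES))

    truth = {
        "config": config.to_dict(),
        "logistic_intercepts": intercepts,
        "impairment_probabilities": {k: v.tolist() for k, v in probabilities.items()},
        "labels": pd.DataFrame({"subject_id": subject_id, **labels}),
        "random_effects": pd.DataFrame(
            {
                "subject_id": subject_id,
                "intercept": rand_eff[:, 0],
                "slope": rand_eff[:, 1],
            }
        ),
    }
    return baseline, visits, truth


# ---------------------------------------------------------------------------
# per-test score panel (two tests per domain)
# ---------------------------------------------------------------------------

DEFAULT_DOMAIN_MAP: dict[str, str] = {
    "t_verbal_1": "verbal_memory",
    "t_verbal_2": "verbal_memory",
    "t_visual_1": "visual_memory",
    "t_visual_2": "visual_memory",
    "t_attn_1": "attention_ips",
    "t_attn_2": "attention_ips",
    "t_fluency_1": "semantic_fluency",
    "t_fluency_2": "semantic_fluency",
}

_DOMAIN_LABEL = {
    "verbal_memory": "ci_verbal",
    "visual_memory": "ci_visual",
    "attention_ips": "ci_attn_ips",
    "semantic_fluency": "ci_fluency",
}


def generate_test_scores(
    labels: pd.DataFrame,
    seed: int,
    domain_map: Mapping[str, str] = DEFAULT_DOMAIN_MAP,
) -> pd.DataFrame:
    """Per-test z-score panel consistent with latent impairment labels.

    Each impaired domain receives one failing test (z < -1.5); preserved
    tests are drawn above the failure threshold. When the latent global
    label requires >=2 failures but the domains provide fewer, additional
    failures are placed so the >=2-failed-tests rule reproduces it (see
    methods for the rare configurations where the scored global label can
    differ from the latent one).
    """
    rng = np.random.default_rng(seed)
    domains: dict[str, list[str]] = {}
    for test, dom in domain_map.items():
        domains.setdefault(dom, []).append(test)

    records = []
    for _, row in labels.iterrows():
        scores: dict[str, float] = {"subject_id": row["subject_id"]}
        for tests in domains.values():
            for test in tests:
                z = rng.normal(0.1, 0.8)
                if z < -1.4:  # reflect back above the failure threshold
                    z = -1.4 + (-1.4 - z)
                scores[test] = z
        impaired = [
            dom
            for dom, lab in _DOMAIN_LABEL.items()
            if dom in domains and row.get(lab, 0) == 1
        ]
        for dom in impaired:
            scores[domains[dom][0]] = rng.uniform(-2.8, -1.6)
        if row.get("ci_global", 0) == 1:
            n_fail = len(impaired)
            if n_fail == 1 and len(domains[impaired[0]]) > 1:
                scores[domains[impaired[0]][1]] = rng.uniform(-2.8, -1.6)
            elif n_fail == 0:
                # no impaired domain to host the failures: verbal memory
                # (the most frequently affected domain) takes both
                for test in domains["verbal_memory"][:2]:
                    scores[test] = rng.uniform(-2.8, -1.6)
        records.append(scores)
    return pd.DataFrame(records, columns=["subject_id"] + list(domain_map))


# ---------------------------------------------------------------------------
# missingness and batch effects
# ---------------------------------------------------------------------------


def inject_missingness(
    baseline: pd.DataFrame,
    rate: float,
    seed: int,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Set eligible cells missing independently with probability ``rate`` (MCAR).

    ``subject_id`` and ``batch`` are never eligible. Observed cells are
    returned unchanged.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    out = baseline.copy()
    if columns is None:
        columns = [c for c in out.columns if c not in ("subject_id", "batch")]
    else:
        bad = set(columns) - set(out.columns)
        if bad:
            raise ValueError(f"unknown columns: {sorted(bad)}")
        if "subject_id" in columns or "batch" in columns:
            raise ValueError("subject_id and batch cannot be made missing")
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    for col in columns:
        mask = rng.random(len(out)) < rate
        if mask.any():
            if out[col].dtype.kind in "iub":
                out[col] = out[col].astype(float)
            out.loc[mask, col] = np.nan
    return out


def apply_batch_effects(
    baseline: pd.DataFrame,
    batch_effects: BatchEffects,
    batch_col: str = "batch",
    target_batch: str = "B",
) -> pd.DataFrame:
    """Shift and scale protocol-B regional volumes; protocol A is untouched.

    Scaling is about the batch sample mean, so a scale of ``s`` multiplies
    the within-batch variance by ``s**2`` and the shift moves the batch mean
    additively.
    """
    out = baseline.copy()
    seen = set(out[batch_col].unique())
    if target_batch not in seen:
        raise ValueError(f"batch label {target_batch!r} not present in {sorted(seen)}")
    mask = (out[batch_col] == target_batch).to_numpy()
    for col in REGION_VOLUME_COLUMNS:
        if col not in out.columns:
            continue
        shift = batch_effects.shift_for(col)
        scale = batch_effects.scale_for(col)
        if shift == 0.0 and scale == 1.0:
            continue
        x = out.loc[mask, col].to_numpy(dtype=float)
        center = x.mean()
        out.loc[mask, col] = center + scale * (x - center) + shift
    return out


def simulate_dataset(config: SimulationConfig) -> dict:
    """Full study-conditions dataset: cohort + batch effects + missingness.

    Missingness is confined to clinical/demographic columns so the regional
    volumes stay complete for harmonization, mirroring a cohort where the
    MRI-derived features exist for every included subject.
    """
    baseline, visits, truth = generate_cohort(config)
    baseline = apply_batch_effects(baseline, config.batch_effects)
    # age and sex stay complete: demographics are recorded for everyone and
    # they serve as protected covariates during harmonization
    baseline = inject_missingness(
        baseline,
        config.missing_rate,
        seed=config.seed + 1,
        columns=[c for c in CLINICAL_COLUMNS if c not in ("age", "sex")],
    )
    test_scores = generate_test_scores(truth["labels"], seed=config.seed + 2)
    return {
        "baseline": baseline,
        "visits": visits,
        "test_scores": test_scores,
        "truth": truth,
    }
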