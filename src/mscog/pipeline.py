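"""End-to-end orchestration: simulate -> score -> harmonize -> trajectory -> predict.

A single JSON config drives all stages; per-stage seeds are derived from the
master seed by a counter scheme so any stage can be re-run independently.
Each run writes a manifest recording the config hash, seeds, package
versions, per-stage outputs and wall-clock stamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .harmonize import harmonize_baseline
from .lasso_ensemble import EnsembleConfig, ImpairmentLassoEnsemble
from .regions import REGION_VOLUME_COLUMNS
from .scoring import score_panel
from .simulate import LABEL_COLUMNS, OUTCOMES, BatchEffects, SimulationConfig, simulate_dataset
from .trajectory import fit_mixed_spline

STAGES = ("simulate", "score", "harmonize", "trajectory", "predict")


def stage_seed(master: int, index: int) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (master * 1000003 + 7919 * (index + 1)) % (2**31 - 1)


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, cls=_NumpyJSONEncoder))


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, cls=_NumpyJSONEncoder).encode()
    ).hexdigest()[:16]


DEFAULT_CONFIG: dict = {
    "simulation": {},
    "trajectory": {"outcomes": ["z_global"], "knots": [5.0, 15.0]},
    "predict": {"outcomes": ["ci_global"], "n_imputations": 5, "n_folds": 10},
}


def run_pipeline(
    config: dict | str | Path | None = None,
    outdir: str | Path = "mscog_run",
    seed: int = 0,
    skip: tuple[str, ...] = (),
    verbose: bool = False,
) -> dict:
    """Execute all stages on a synthetic cohort; returns the run manifest."""
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    for key in cfg:
        if key not in DEFAULT_CONFIG:
            raise ValueError(f"unknown config section {key!r}")
    unknown = set(skip) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages in skip: {sorted(unknown)}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "versions": _versions(),
        "stages": {},
    }

    def log(msg: str) -> None:
        if verbose:
            import sys

            print(f"[mscog] {msg}", file=sys.stderr)

    def record(stage: str, outputs: dict[str, str], t0: float) -> None:
        manifest["stages"][stage] = {
            "outputs": outputs,
            "seconds": round(time.time() - t0, 3),
            "seed": stage_seed(seed, STAGES.index(stage)),
        }

    # ---- simulate ----
    t0 = time.time()
    sim_overrides = dict(cfg["simulation"])
    if "batch_effects" in sim_overrides and isinstance(sim_overrides["batch_effects"], dict):
        sim_overrides["batch_effects"] = BatchEffects(**sim_overrides["batch_effects"])
    sim_config = SimulationConfig(seed=stage_seed(seed, 0), **sim_overrides)
    log("simulating cohort")
    data = simulate_dataset(sim_config)
    baseline, visits = data["baseline"], data["visits"]
    baseline.to_csv(outdir / "baseline.csv", index=False)
    visits.to_csv(outdir / "visits.csv", index=False)
    data["test_scores"].to_csv(outdir / "test_scores.csv", index=False)
    truth = dict(data["truth"])
    _dump_json(truth, outdir / "truth.json")
    record(
        "simulate",
        {k: f"{k}.csv" for k in ("baseline", "visits", "test_scores")} | {"truth": "truth.json"},
        t0,
    )

    # ---- score ----
    t0 = time.time()
    log("scoring impairment labels")
    labels = score_panel(data["test_scores"])
    labels.to_csv(outdir / "labels.csv", index=False)
    record("score", {"labels": "labels.csv"}, t0)

    # ---- harmonize ----
    t0 = time.time()
    vol_cols = [c for c in REGION_VOLUME_COLUMNS if c in baseline.columns]
    if "harmonize" in skip or baseline["batch"].nunique() < 2:
        log("harmonization skipped")
        harmonized = baseline.copy()
    else:
        log("harmonizing volumes across protocols")
        harmonized = harmonize_baseline(baseline, vol_cols)
    harmonized.to_csv(outdir / "baseline_harmonized.csv", index=False)
    record("harmonize", {"baseline_harmonized": "baseline_harmonized.csv"}, t0)

    # ---- trajectory ----
    t0 = time.time()
    traj_cfg = cfg["trajectory"]
    knots = tuple(traj_cfg.get("knots", (5.0, 15.0)))
    fits = {}
    for outcome in traj_cfg.get("outcomes", list(OUTCOMES)):
        log(f"fitting trajectory model for {outcome}")
        res = fit_mixed_spline(visits, baseline, outcome, knots=knots)
        fits[outcome] = res.to_dict()
    _dump_json(fits, outdir / "fit.json")
    record("trajectory", {"fit": "fit.json"}, t0)

    # ---- predict ----
    t0 = time.time()
    pred_cfg = dict(cfg["predict"])
    outcomes = pred_cfg.pop("outcomes", ["ci_global"])
    performance: dict = {}
    for outcome in outcomes:
        log(f"fitting impairment ensemble for {outcome}")
        econf = EnsembleConfig(seed=stage_seed(seed, 4), **pred_cfg)
        result = ImpairmentLassoEnsemble(harmonized, labels, outcome, econf).fit()
        performance[outcome] = {
            "n_models": result.n_models,
            "representative_index": result.representative_index(),
            **result.performance().to_dict(),
        }
        result.representative_coefficients().to_csv(
            outdir / f"selection_rates_{outcome}.csv", index=False
        )
        result.models_frame().to_csv(outdir / f"models_{outcome}.csv", index=False)
    _dump_json(performance, outdir / "performance.json")
    record(
        "predict",
        {"performance": "performance.json"}
        | {f"selection_rates_{o}": f"selection_rates_{o}.csv" for o in outcomes},
        t0,
    )

    _dump_json(manifest, outdir / "manifest.json")
    return manifest


def render_report(outdir: str | Path) -> str:
    """Markdown summary of a completed run: slope table + prediction metrics."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        "# Cognitive trajectory and impairment-prediction report",
        "",
        f"Config hash `{manifest['config_hash']}`, seed {manifest['seed']}, "
        f"mscog {manifest['versions'].get('mscog', '?')}",
        "",
        "## Cognitive trajectories (per-period slopes, z-score/year)",
        "",
    ]
    fit_path = outdir / "fit.json"
    if not fit_path.exists():
        raise FileNotFoundError("trajectory outputs missing; run the pipeline first")
    fits = json.loads(fit_path.read_text())
    lines.append("| outcome | period | slope | 95% CI | p |")
    lines.append("|---|---|---|---|---|")
    for outcome, fit in fits.items():
        for row in fit["period_slopes"]:
            lines.append(
                f"| {outcome} | {row['period']} | {row['slope']:.3f} "
                f"| {row['ci_low']:.3f} to {row['ci_high']:.3f} | {row['p_value']:.3g} |"
            )
    lines += ["", "## Impairment prediction (pooled out-of-fold)", ""]
    perf_path = outdir / "performance.json"
    performance = json.loads(perf_path.read_text()) if perf_path.exists() else {}
    if not performance:
        lines.append("*no models*")
    else:
        lines.append("| outcome | n | balanced acc (%) | sens (%) | spec (%) | PPV (%) | NPV (%) |")
        lines.append("|---|---|---|---|---|---|---|")
        for outcome, rep in performance.items():
            def pct(d):
                v = d["percent"]
                return "-" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.0f}"

            lines.append(
                f"| {outcome} | {rep['n']} | {rep['balanced_accuracy_percent']:.0f} "
                f"| {pct(rep['sensitivity'])} | {pct(rep['specificity'])} "
                f"| {pct(rep['ppv'])} | {pct(rep['npv'])} |"
            )
    lines.append("")
    return "\n".join(lines)


def _versions() -> dict[str, str]:
    import sklearn
    import statsmodels

    return {
        "mscog": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "scikit-learn": sklearn.__version__,
    }
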