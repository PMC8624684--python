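"""Multiple-imputation x cross-validation logistic-Lasso ensemble.

Predicts binary cognitive-impairment status from baseline features. For each
of ``n_imputations`` stochastic imputations and each of ``n_folds``
stratified outer folds, a full preprocessing + model stack — regression-based
imputer, age residualizer for the anatomical volumes, feature standardizer
and an L1-penalized logistic regression with inner-CV penalty selection — is
fitted on the training part only and applied to the held-out fold. The
ensemble yields per-feature selection rates (how often each predictor enters
a model's support), a representative model chosen by maximal mean Dice
overlap of supports, and pooled out-of-fold performance metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from sklearn.model_selection import StratifiedKFold

from .metrics import PerformanceReport, evaluate_predictions, proportion_percent, select_representative
from .regions import REGION_VOLUME_COLUMNS
from .simulate import DISEASE_TYPES

#: number of points and span (decades above C_min) of the adaptive penalty path
PATH_POINTS = 12
PATH_DECADES = 1.5


def penalty_path(Xs: np.ndarray, y: np.ndarray, n_points: int = PATH_POINTS) -> np.ndarray:
    """Data-driven grid of inverse-penalty values C for the L1 logistic path.

    Mirrors the usual lasso-path construction: below
    ``C_min = 1 / max |X'(y - ybar)|`` every coefficient is zero, so the grid
    spans from just above that point upward on a log scale.
    """
    ybar = y.mean()
    score = np.abs(Xs.T @ (y - ybar)).max()
    c_min = 1.0 / max(score, 1e-12)
    return np.geomspace(1.05 * c_min, c_min * 10**PATH_DECADES, n_points)

#: baseline columns offered to the Lasso (age is a predictor in its own right)
PREDICTOR_COLUMNS = (
    "sex",
    "age",
    "education_level",
    "disease_duration",
    "disease_type",
    "edss",
    "dmt_use",
    "n_relapses",
    "lesion_volume",
) + REGION_VOLUME_COLUMNS

_DISEASE_TYPE_ORD = {t: i + 1.0 for i, t in enumerate(DISEASE_TYPES)}


# ---------------------------------------------------------------------------
# age residualization
# ---------------------------------------------------------------------------


class AgeResidualizer:
    """Remove the linear effect of age from selected (anatomical) features.

    A separate simple regression ``feature ~ age`` is fitted on training rows
    only; ``transform`` replaces each feature by its residual, leaving every
    other column (including age itself) untouched.
    """

    def __init__(self, feature_columns: Sequence[str], age_col: str = "age"):
        self.feature_columns = list(feature_columns)
        self.age_col = age_col
        self.coef_: dict[str, tuple[float, float]] = {}

    def fit(self, df: pd.DataFrame) -> "AgeResidualizer":
        age = df[self.age_col].to_numpy(dtype=float)
        if np.isnan(age).any():
            raise ValueError("age must be observed on fit rows")
        if np.ptp(age) == 0:
            raise ValueError("age is constant on fit rows")
        A = np.column_stack([np.ones_like(age), age])
        Y = df[self.feature_columns].to_numpy(dtype=float)
        coefs, *_ = np.linalg.lstsq(A, Y, rcond=None)
        self.coef_ = {
            col: (float(coefs[0, j]), float(coefs[1, j]))
            for j, col in enumerate(self.feature_columns)
        }
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if not self.coef_:
            raise ValueError("residualizer is not fitted")
        out = df.copy()
        age = df[self.age_col].to_numpy(dtype=float)
        ab = np.array([self.coef_[c] for c in self.feature_columns])
        fitted = ab[:, 0][None, :] + np.outer(age, ab[:, 1])
        out[self.feature_columns] = df[self.feature_columns].to_numpy(dtype=float) - fitted
        return out


def residualize_age(
    features: pd.DataFrame,
    feature_columns: Sequence[str],
    age_col: str = "age",
    fit_rows: np.ndarray | None = None,
) -> tuple[pd.DataFrame, AgeResidualizer]:
    """Fit ``feature ~ age`` on ``fit_rows`` (default: all) and residualize all rows."""
    fit_df = features if fit_rows is None else features.loc[fit_rows]
    res = AgeResidualizer(feature_columns, age_col).fit(fit_df)
    return res.transform(features), res


# ---------------------------------------------------------------------------
# regression-based stochastic imputation
# ---------------------------------------------------------------------------


class RegressionImputer:
    """Draw missing entries from per-column conditional fits.

    For each incomplete column the observed training rows are regressed on
    the remaining columns (mean-completed); a missing cell is replaced by a
    random draw from the fitted conditional distribution — normal with the
    fitted mean and residual SD for continuous columns, fitted category
    probabilities (multinomial logistic) for categorical ones. Observed
    entries are never altered.
    """

    def __init__(self, categorical: Sequence[str] = ()):
        self.categorical = set(categorical)
        self.columns_: list[str] = []
        self.numeric_cols_: list[str] = []
        self.means_: np.ndarray | None = None
        self.models_: dict[str, dict] = {}

    def _numeric_matrix(self, df: pd.DataFrame) -> np.ndarray:
        """Mean-filled numeric design over the imputer's numeric columns."""
        num = df[self.numeric_cols_].apply(pd.to_numeric, errors="coerce")
        X = num.to_numpy(dtype=float)
        nan = np.isnan(X)
        if nan.any():
            X = np.where(nan, self.means_, X)
        return X

    def fit(self, df: pd.DataFrame, columns: Sequence[str] | None = None) -> "RegressionImputer":
        self.columns_ = list(df.columns)
        truly_missing = [c for c in df.columns if df[c].isna().all()]
        if truly_missing:
            raise ValueError(f"columns fully missing: {truly_missing}")
        num = df.apply(pd.to_numeric, errors="coerce")
        # non-numeric (string categorical) columns stay out of the design
        self.numeric_cols_ = [c for c in df.columns if not num[c].isna().all()]
        self.means_ = num[self.numeric_cols_].mean().to_numpy(dtype=float)
        self._col_index = {c: i for i, c in enumerate(self.numeric_cols_)}

        X_full = self._numeric_matrix(df)
        targets = list(columns) if columns is not None else [
            c for c in df.columns if df[c].isna().any()
        ]
        for col in targets:
            obs = df[col].notna().to_numpy()
            covar_idx = [self._col_index[c] for c in self.numeric_cols_ if c != col]
            X = X_full[:, covar_idx]
            y = df[col].to_numpy()
            if col in self.categorical or df[col].dtype == object:
                self.models_[col] = self._fit_categorical(X[obs], y[obs], covar_idx)
            else:
                self.models_[col] = self._fit_continuous(
                    X[obs], y[obs].astype(float), covar_idx
                )
        return self

    @staticmethod
    def _fit_continuous(X: np.ndarray, y: np.ndarray, covar_idx: list[int]) -> dict:
        A = np.column_stack([np.ones(len(X)), X])
        coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        dof = max(len(y) - rank, 1)
        sd = float(np.sqrt((resid**2).sum() / dof))
        if not np.isfinite(sd) or sd == 0:
            sd = max(float(np.std(y, ddof=1)), 1e-8) if len(y) > 1 else 1e-8
        return {"kind": "continuous", "coef": coef, "sd": sd, "covars": covar_idx}

    @staticmethod
    def _fit_categorical(X: np.ndarray, y: np.ndarray, covar_idx: list[int]) -> dict:
        classes = pd.unique(y)
        if len(classes) == 1:
            return {"kind": "constant", "value": classes[0], "covars": covar_idx}
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf = LogisticRegression(max_iter=200).fit((X - mu) / sd, y)
        return {"kind": "categorical", "clf": clf, "mu": mu, "sigma": sd, "covars": covar_idx}

    def transform(self, df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
        out = df.copy()
        X_full = self._numeric_matrix(df)
        for col in df.columns:
            miss = df[col].isna().to_numpy()
            if not miss.any():
                continue
            if col not in self.models_:
                raise ValueError(f"no imputation model fitted for column {col!r}")
            model = self.models_[col]
            X = X_full[np.ix_(miss, model["covars"])]
            if model["kind"] == "continuous":
                mean = model["coef"][0] + X @ model["coef"][1:]
                draws = rng.normal(mean, model["sd"])
                if out[col].dtype.kind in "iub":
                    out[col] = out[col].astype(float)
                out.loc[miss, col] = draws
            elif model["kind"] == "constant":
                out.loc[miss, col] = model["value"]
            else:
                proba = model["clf"].predict_proba((X - model["mu"]) / model["sigma"])
                classes = model["clf"].classes_
                cum = proba.cumsum(axis=1)
                u = rng.random(len(X))
                picks = classes[(u[:, None] < cum).argmax(axis=1)]
                out.loc[miss, col] = picks
        return out


def impute_once(
    df: pd.DataFrame,
    rng: np.random.Generator,
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """One stochastic completion of a table (fit and draw on the same rows)."""
    if not df.isna().any().any():
        return df.copy()
    return RegressionImputer(categorical).fit(df).transform(df, rng)


# ---------------------------------------------------------------------------
# L1-penalized logistic regression with inner-CV penalty selection
# ---------------------------------------------------------------------------


@dataclass
class LassoLogisticFit:
    """Sparse logistic model on internally standardized features."""

    feature_names: list[str]
    coef: np.ndarray          # standardized scale
    intercept: float
    C: float
    mu: np.ndarray
    sigma: np.ndarray

    @property
    def support(self) -> set[str]:
        return {n for n, c in zip(self.feature_names, self.coef) if c != 0.0}

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.mu) / self.sigma
        return expit(self.intercept + Xs @ self.coef)


def _l1_logistic(Xs, y, C, tol=1e-4, max_iter=1000) -> LogisticRegression:
    clf = LogisticRegression(
        l1_ratio=1.0,
        solver="liblinear",
        C=C,
        tol=tol,
        max_iter=max_iter,
        intercept_scaling=100.0,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Xs, y)
    return clf


def fit_lasso_logistic(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    rng: np.random.Generator | None = None,
    penalty: float | str = "cv",
    C_grid: np.ndarray | None = None,
    inner_folds: int = 5,
) -> LassoLogisticFit:
    """L1 logistic fit at a penalty chosen by inner cross-validation.

    ``penalty='cv'`` selects the inverse-regularization C from ``C_grid`` by
    minimizing the mean held-out binomial deviance over stratified inner
    folds (ties go to the sparser, i.e. smaller, C). A float ``penalty`` is a
    fixed lambda (C = 1/lambda); ``penalty=0`` is an essentially unpenalized
    maximum-likelihood fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=0)
    sigma = np.where(sigma == 0, 1.0, sigma)
    Xs = (X - mu) / sigma

    if penalty == "cv":
        if rng is None:
            rng = np.random.default_rng(0)
        if C_grid is None:
            C_grid = penalty_path(Xs, y)
        skf = StratifiedKFold(
            n_splits=inner_folds,
            shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        losses = np.zeros((inner_folds, len(C_grid)))
        for j, (tr, va) in enumerate(skf.split(Xs, y)):
            for k, C in enumerate(C_grid):
                # looser tolerance: these fits only rank penalties
                clf = _l1_logistic(Xs[tr], y[tr], C, tol=1e-3)
                eta = clf.decision_function(Xs[va])
                p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
                losses[j, k] = -np.mean(y[va] * np.log(p) + (1 - y[va]) * np.log1p(-p))
        mean_loss = losses.mean(axis=0)
        k_min = int(np.argmin(mean_loss))
        # one-standard-error rule: strongest penalty within one SE of the
        # minimum mean deviance (C_grid is ascending, so the first qualifying
        # index is the sparsest model)
        se_min = losses[:, k_min].std(ddof=1) / np.sqrt(inner_folds)
        k_sel = int(np.argmax(mean_loss <= mean_loss[k_min] + se_min))
        C = float(C_grid[k_sel])
    else:
        lam = float(penalty)
        if lam < 0:
            raise ValueError("penalty must be >= 0")
        C = 1e8 if lam == 0 else max(1.0 / lam, 1e-12)

    tol = 1e-8 if penalty != "cv" and float(penalty) == 0 else 1e-4
    clf = _l1_logistic(Xs, y, C, tol=tol, max_iter=5000 if tol < 1e-6 else 1000)
    coef = clf.coef_.ravel().copy()
    coef[np.abs(coef) < 1e-12] = 0.0
    return LassoLogisticFit(
        feature_names=list(feature_names),
        coef=coef,
        intercept=float(clf.intercept_[0]),
        C=C,
        mu=mu,
        sigma=sigma,
    )


# ---------------------------------------------------------------------------
# the ensemble
# ---------------------------------------------------------------------------


@dataclass
class EnsembleConfig:
    """Knobs of the imputation x CV ensemble (defaults follow the study design)."""

    n_folds: int = 10
    n_imputations: int = 200
    seed: int = 0
    penalty: float | str = "cv"
    threshold: float = 0.5
    age_col: str = "age"
    anatomical_features: tuple[str, ...] = REGION_VOLUME_COLUMNS
    inner_folds: int = 5
    C_grid: np.ndarray | None = None
    disease_type_encoding: str = "ordinal"  # or "onehot"

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_imputations < 1:
            raise ValueError("n_imputations must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.disease_type_encoding not in ("ordinal", "onehot"):
            raise ValueError("disease_type_encoding must be 'ordinal' or 'onehot'")


@dataclass
class ModelRecord:
    """One (imputation, fold) member of the ensemble."""

    imputation: int
    fold: int
    support: set[str]
    coefficients: dict[str, float]  # standardized scale, nonzero entries
    intercept: float
    C: float
    test_subjects: list[str]
    test_probabilities: np.ndarray


def prepare_features(
    baseline: pd.DataFrame, encoding: str = "ordinal"
) -> pd.DataFrame:
    """Numeric predictor frame from a baseline table (missing values kept).

    Disease type is coded ordinally by clinical severity
    (CIS < RRMS < SPMS < PPMS) by default, or one-hot on request.
    """
    cols = [c for c in PREDICTOR_COLUMNS if c in baseline.columns]
    out = baseline[cols].copy()
    if "disease_type" in out.columns:
        if encoding == "ordinal":
            out["disease_type"] = out["disease_type"].map(_DISEASE_TYPE_ORD).astype(float)
        else:
            dummies = pd.get_dummies(out["disease_type"], prefix="disease_type").astype(float)
            dummies.loc[out["disease_type"].isna().to_numpy(), :] = np.nan
            out = pd.concat([out.drop(columns=["disease_type"]), dummies], axis=1)
    return out.astype(float)


class ImpairmentLassoEnsemble:
    """Model object: baseline features + labels -> fitted ensemble results."""

    def __init__(
        self,
        baseline: pd.DataFrame,
        labels: pd.DataFrame | pd.Series,
        outcome: str = "ci_global",
        config: EnsembleConfig | None = None,
    ):
        self.config = config or EnsembleConfig()
        self.config.validate()
        self.outcome = outcome

        if isinstance(labels, pd.Series):
            lab = labels.rename("label").to_frame()
            lab["subject_id"] = baseline["subject_id"].to_numpy()
        else:
            if outcome not in labels.columns:
                raise ValueError(f"outcome {outcome!r} not in labels")
            lab = labels[["subject_id", outcome]].rename(columns={outcome: "label"})
        merged = baseline.merge(lab, on="subject_id", how="inner").dropna(subset=["label"])
        self.subject_ids = merged["subject_id"].to_numpy()
        self.y = merged["label"].to_numpy(dtype=int)
        if len(np.unique(self.y)) < 2:
            raise ValueError("labels must contain both classes")
        self.features = prepare_features(merged, self.config.disease_type_encoding)
        self.feature_names = list(self.features.columns)
        self._anat = [c for c in self.config.anatomical_features if c in self.feature_names]
        self._categorical = [
            c for c in ("sex", "dmt_use", "education_level", "disease_type")
            if c in self.feature_names
        ]

    # ------------------------------------------------------------------
    def fit(self, folds=None) -> "EnsembleResults":
        """Fit the full ensemble.

        ``folds`` may supply explicit ``(train_idx, test_idx)`` pairs (e.g. to
        reuse an assignment across experiments); by default stratified folds
        are drawn from the config seed and held fixed across imputations.
        """
        cfg = self.config
        n = len(self.y)
        if folds is None:
            skf = StratifiedKFold(
                n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed % (2**32)
            )
            folds = list(skf.split(np.zeros(n), self.y))
        else:
            folds = [(np.asarray(tr), np.asarray(te)) for tr, te in folds]
        for _, (tr, _te) in enumerate(folds):
            if len(np.unique(self.y[tr])) < 2:
                raise ValueError("a fold has single-class training labels")

        missing_cols = [c for c in self.feature_names if self.features[c].isna().any()]
        # the imputer fit is deterministic given the training rows, so one fit
        # per fold serves every imputation (only the draws differ)
        fold_imputers: list[RegressionImputer | None] = []
        for tr, _te in folds:
            if missing_cols:
                fold_imputers.append(
                    RegressionImputer(self._categorical).fit(
                        self.features.iloc[tr], columns=missing_cols
                    )
                )
            else:
                fold_imputers.append(None)

        records: list[ModelRecord] = []
        oof = np.full((n, cfg.n_imputations), np.nan)
        for m in range(cfg.n_imputations):
            for f, (tr, te) in enumerate(folds):
                rng = np.random.default_rng([cfg.seed % (2**31), m, f])
                train = self.features.iloc[tr]
                test = self.features.iloc[te]
                imputer = fold_imputers[f]
                if imputer is not None:
                    train = imputer.transform(train, rng)
                    test = imputer.transform(test, rng)
                if self._anat:
                    resid = AgeResidualizer(self._anat, cfg.age_col).fit(train)
                    train = resid.transform(train)
                    test = resid.transform(test)
                fit = fit_lasso_logistic(
                    train.to_numpy(dtype=float),
                    self.y[tr],
                    self.feature_names,
                    rng=rng,
                    penalty=cfg.penalty,
                    C_grid=cfg.C_grid,
                    inner_folds=cfg.inner_folds,
                )
                probs = fit.predict_proba(test.to_numpy(dtype=float))
                oof[te, m] = probs
                records.append(
                    ModelRecord(
                        imputation=m,
                        fold=f,
                        support=fit.support,
                        coefficients={
                            nm: float(c)
                            for nm, c in zip(fit.feature_names, fit.coef)
                            if c != 0.0
                        },
                        intercept=fit.intercept,
                        C=fit.C,
                        test_subjects=list(self.subject_ids[te]),
                        test_probabilities=probs,
                    )
                )
        return EnsembleResults(
            outcome=self.outcome,
            config=cfg,
            feature_names=self.feature_names,
            subject_ids=self.subject_ids,
            labels=self.y,
            models=records,
            oof_probabilities=oof,
        )


@dataclass
class EnsembleResults:
    """All fitted ensemble members plus pooled out-of-fold predictions."""

    outcome: str
    config: EnsembleConfig
    feature_names: list[str]
    subject_ids: np.ndarray
    labels: np.ndarray
    models: list[ModelRecord]
    oof_probabilities: np.ndarray  # subjects x imputations

    @property
    def n_models(self) -> int:
        return len(self.models)

    def selection_rates(self) -> pd.DataFrame:
        return selection_rates(
            [m.support for m in self.models], self.feature_names
        )

    def representative_index(self) -> int:
        idx, _ = select_representative([m.support for m in self.models])
        return idx

    @property
    def representative_model(self) -> ModelRecord:
        return self.models[self.representative_index()]

    def pooled_predictions(self) -> np.ndarray:
        """Per-subject mean out-of-fold probability across imputations."""
        return np.nanmean(self.oof_probabilities, axis=1)

    def performance(self, threshold: float | None = None) -> PerformanceReport:
        thr = self.config.threshold if threshold is None else threshold
        return evaluate_predictions(self.pooled_predictions(), self.labels, thr)

    def representative_coefficients(self) -> pd.DataFrame:
        """Selection-rate table with the representative model's betas."""
        rep = self.representative_model
        rates = self.selection_rates()
        rates["beta"] = [rep.coefficients.get(f, 0.0) for f in rates["predictor"]]
        return rates[["predictor", "beta", "frequency", "percent"]]

    def summary(self) -> str:
        rates = self.selection_rates()
        top = rates[rates["frequency"] > 0].head(12)
        rep = self.representative_index()
        perf = self.performance()
        return "\n".join(
            [
                f"Impairment prediction ensemble: {self.outcome}",
                f"Models: {self.n_models} "
                f"({self.config.n_imputations} imputations x {self.config.n_folds} folds)"
                f"   representative model: #{rep} "
                f"(imputation {self.models[rep].imputation}, fold {self.models[rep].fold})",
                "",
                "Pooled out-of-fold performance:",
                perf.summary(),
                "",
                "Top predictor selection rates:",
                top.to_string(index=False),
            ]
        )

    def models_frame(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.models):
            rows.append(
                {
                    "model": i,
                    "imputation": m.imputation,
                    "fold": m.fold,
                    "C": m.C,
                    "intercept": m.intercept,
                    "support": ";".join(sorted(m.support)),
                    "coefficients": ";".join(
                        f"{k}={v:.6g}" for k, v in sorted(m.coefficients.items())
                    ),
                }
            )
        return pd.DataFrame(rows)


def selection_rates(
    supports: Sequence[set], feature_names: Sequence[str]
) -> pd.DataFrame:
    """Per-feature selection frequency and rounded percentage over the ensemble."""
    if len(supports) == 0:
        raise ValueError("need at least one model")
    total = len(supports)
    freq = {f: 0 for f in feature_names}
    for s in supports:
        for f in s:
            if f in freq:
                freq[f] += 1
    table = pd.DataFrame(
        {
            "predictor": list(freq),
            "frequency": list(freq.values()),
        }
    )
    table["percent"] = [proportion_percent(f, total) for f in table["frequency"]]
    return table.sort_values(
        ["frequency", "predictor"], ascending=[False, True]
    ).reset_index(drop=True)
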