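"""Parametric empirical-Bayes batch harmonization (ComBat-style).

Removes additive (location) and multiplicative (scale) differences between
acquisition protocols from a subjects x features matrix while preserving
covariate effects. The algorithm follows the canonical parametric ComBat
formulation: features are standardized against a covariate regression with a
pooled variance, per-batch location/scale estimates are shrunk toward
across-feature priors (normal prior on locations, inverse-gamma on scales)
by iterated conditional updates, and the adjusted data are back-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ComBatModel:
    """Fitted harmonization transform.

    Attributes are populated by :meth:`fit`; :meth:`transform` maps a feature
    matrix with known batch labels onto the harmonized scale.
    """

    covariates: tuple[str, ...] = ("age", "sex")
    eb: bool = True
    tol: float = 1e-6
    max_iter: int = 500

    # fitted state
    feature_names_: list[str] = field(default_factory=list, repr=False)
    batches_: list[str] = field(default_factory=list, repr=False)
    grand_mean_: np.ndarray | None = field(default=None, repr=False)
    beta_cov_: np.ndarray | None = field(default=None, repr=False)
    pooled_sd_: np.ndarray | None = field(default=None, repr=False)
    gamma_star_: np.ndarray | None = field(default=None, repr=False)
    delta_star_: np.ndarray | None = field(default=None, repr=False)
    n_iter_: dict[str, int] = field(default_factory=dict, repr=False)

    # ------------------------------------------------------------------
    def fit(
        self,
        features: pd.DataFrame,
        batch: pd.Series | np.ndarray,
        covariates: pd.DataFrame | None = None,
    ) -> "ComBatModel":
        Y = features.to_numpy(dtype=float)
        if np.isnan(Y).any():
            raise ValueError("features must not contain missing values")
        batch = np.asarray(batch).astype(str)
        levels = sorted(pd.unique(batch))
        if len(levels) < 2:
            raise ValueError("harmonization requires at least 2 batches")
        counts = {b: int((batch == b).sum()) for b in levels}
        small = [b for b, c in counts.items() if c < 3]
        if small:
            raise ValueError(f"each batch needs >=3 subjects; too small: {small}")
        for j, name in enumerate(features.columns):
            if Y[:, j].std(ddof=0) == 0:
                raise ValueError(f"feature {name!r} has zero variance")

        n, p = Y.shape
        k = len(levels)
        B = np.zeros((n, k))
        for i, b in enumerate(levels):
            B[:, i] = batch == b

        if covariates is not None and len(covariates.columns) > 0:
            Z = covariates.to_numpy(dtype=float)
            if np.isnan(Z).any():
                raise ValueError("covariates must not contain missing values")
            X = np.hstack([B, Z])
        else:
            Z = np.zeros((n, 0))
            X = B

        theta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        gamma_hat_ls = theta[:k]             # per-batch means on the raw scale
        beta_cov = theta[k:]
        weights = np.array([counts[b] for b in levels], dtype=float) / n
        grand_mean = weights @ gamma_hat_ls
        resid = Y - X @ theta
        pooled_var = (resid**2).mean(axis=0)
        pooled_sd = np.sqrt(pooled_var)

        stand = (Y - grand_mean - Z @ beta_cov) / pooled_sd

        gamma_hat = np.zeros((k, p))
        delta_hat = np.zeros((k, p))
        for i, b in enumerate(levels):
            rows = stand[batch == b]
            gamma_hat[i] = rows.mean(axis=0)
            delta_hat[i] = rows.var(axis=0, ddof=1)

        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        n_iter: dict[str, int] = {}
        if self.eb and p > 1:
            for i, b in enumerate(levels):
                g, d, it = _eb_shrink(
                    stand[batch == b],
                    gamma_hat[i],
                    delta_hat[i],
                    tol=self.tol,
                    max_iter=self.max_iter,
                )
                gamma_star[i], delta_star[i] = g, d
                n_iter[b] = it

        self.feature_names_ = list(features.columns)
        self.batches_ = levels
        self.grand_mean_ = grand_mean
        self.beta_cov_ = beta_cov
        self.pooled_sd_ = pooled_sd
        self.gamma_star_ = gamma_star
        self.delta_star_ = delta_star
        self.n_iter_ = n_iter
        return self

    # ------------------------------------------------------------------
    def transform(
        self,
        features: pd.DataFrame,
        batch: pd.Series | np.ndarray,
        covariates: pd.DataFrame | None = None,
    ) -> pd.DataFrame:
        if self.grand_mean_ is None:
            raise ValueError("model is not fitted")
        if list(features.columns) != self.feature_names_:
            raise ValueError("feature columns differ from those seen at fit time")
        Y = features.to_numpy(dtype=float)
        batch = np.asarray(batch).astype(str)
        unseen = sorted(set(batch) - set(self.batches_))
        if unseen:
            raise ValueError(f"unseen batch labels: {unseen}")
        if covariates is not None and len(covariates.columns) > 0:
            Z = covariates.to_numpy(dtype=float)
        else:
            Z = np.zeros((len(Y), 0))
        cov_part = Z @ self.beta_cov_ if Z.shape[1] else 0.0

        stand = (Y - self.grand_mean_ - cov_part) / self.pooled_sd_
        adj = np.empty_like(stand)
        for i, b in enumerate(self.batches_):
            rows = batch == b
            if not rows.any():
                continue
            adj[rows] = (stand[rows] - self.gamma_star_[i]) / np.sqrt(
                self.delta_star_[i]
            )
        out = adj * self.pooled_sd_ + self.grand_mean_ + cov_part
        return pd.DataFrame(out, index=features.index, columns=self.feature_names_)


def _eb_shrink(
    Zb: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterated conditional EB updates for one batch (all features at once)."""
    nb = Zb.shape[0]
    gbar = gamma_hat.mean()
    t2 = gamma_hat.var(ddof=1)
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    if t2 <= 0 or s2 <= 0:
        return gamma_hat, delta_hat, 0  # prior collapse: no shrinkage possible
    a_prior = (2 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2

    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    it = 0
    for it in range(1, max_iter + 1):
        g_new = (nb * t2 * gamma_hat + d_old * gbar) / (nb * t2 + d_old)
        sse = ((Zb - g_new) ** 2).sum(axis=0)
        d_new = (0.5 * sse + b_prior) / (nb / 2 + a_prior - 1)
        change = max(
            np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
            np.abs(d_new - d_old).max() / max(np.abs(d_old).max(), 1e-12),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old, it


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def fit_harmonization(
    features: pd.DataFrame,
    batch,
    covariates: pd.DataFrame | None = None,
    eb: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ComBatModel:
    return ComBatModel(eb=eb, tol=tol, max_iter=max_iter).fit(features, batch, covariates)


def apply_harmonization(
    model: ComBatModel,
    features: pd.DataFrame,
    batch,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    return model.transform(features, batch, covariates)


def harmonize_baseline(
    baseline: pd.DataFrame,
    feature_columns: list[str],
    batch_col: str = "batch",
    covariate_columns: tuple[str, ...] = ("age", "sex"),
    eb: bool = True,
) -> pd.DataFrame:
    """Harmonize selected columns of a baseline table in place of the originals."""
    cov = baseline[list(covariate_columns)] if covariate_columns else None
    model = fit_harmonization(baseline[feature_columns], baseline[batch_col], cov, eb=eb)
    adjusted = model.transform(baseline[feature_columns], baseline[batch_col], cov)
    out = baseline.copy()
    out[feature_columns] = adjusted
    return out
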