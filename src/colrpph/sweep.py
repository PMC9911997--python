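"""Cut-off-specific binary logistic regressions across blood-loss volumes.

The transformation model asserts one coefficient vector for every
dichotomization of blood loss.  This module provides the descriptive
counterpart: for each cut-off ``y`` on a grid, an ordinary binary logistic
regression of ``1{MBL <= y}`` on the covariates.  Plotting the per-cut-off
coefficients against the constant transformation-model coefficient is the
standard visual check that "constant effects across cut-offs" is tenable.

The 500 mL model — postpartum hemorrhage as conventionally defined for
vaginal deliveries — is just the sweep evaluated at a single cut-off.

Fitting is Newton-Raphson / IRLS with the observed information as the
covariance.  Complete separation is flagged (fit marked non-converged)
rather than silently reported with exploding standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .cohort import MODEL_COVARIATES

__all__ = [
    "BinaryLogisticRegression",
    "SweepResult",
    "fit_binary_logistic",
    "sweep_cutoffs",
]

_IRLS_MAX_ITER = 50
_IRLS_REL_TOL = 1e-10
_SEP_PROB = 1e-8


def _deviance(y, p):
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(y == 1, np.log(p), np.log1p(-p))
    return -2.0 * np.sum(np.where(np.isfinite(ll), ll, -700.0))


def fit_binary_logistic(X: np.ndarray, y01: np.ndarray) -> dict:
    """Maximum-likelihood binary logistic fit on an explicit design matrix.

    Parameters
    ----------
    X : ndarray (n, k)
        Design matrix *including* the intercept column.
    y01 : ndarray (n,)
        Binary outcomes; must contain at least one 0 and one 1.

    Returns
    -------
    dict with ``beta`` (k,), ``vcov`` (k, k; inverse observed information)
    and ``converged`` (False under non-convergence or detected separation).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y01, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X and y01 have inconsistent shapes")
    if y.min() == y.max():
        raise ValueError("degenerate outcome: all responses identical")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y01 must be binary 0/1")
    Xc = X - X.mean(axis=0)
    Xc[:, np.ptp(X, axis=0) == 0] = 1.0  # intercept-like columns
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] < 1e-10 * s[0]:
        raise ValueError("collinear design matrix: rank-deficient to machine precision")

    k = X.shape[1]
    beta = np.zeros(k)
    dev = _deviance(y, np.full_like(y, y.mean()))
    converged = False
    for _ in range(_IRLS_MAX_ITER):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        g = X.T @ (y - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        new_dev = _deviance(y, expit(X @ beta))
        if abs(dev - new_dev) < _IRLS_REL_TOL * (abs(new_dev) + 0.1):
            converged = True
            dev = new_dev
            break
        dev = new_dev

    p = expit(X @ beta)
    grad_norm = float(np.max(np.abs(X.T @ (y - p))))
    saturated = np.any((p > 1.0 - _SEP_PROB) | (p < _SEP_PROB))
    # under complete separation the gradient eventually vanishes
    # numerically, so perfect classification also counts as diverging
    perfectly_classified = bool(np.all((p > 0.5) == (y == 1.0)))
    separated = bool(saturated and (grad_norm > 1e-6 or perfectly_classified))
    if separated:
        warnings.warn(
            "complete or quasi-complete separation detected; coefficients "
            "are diverging",
            RuntimeWarning,
            stacklevel=2,
        )
        converged = False
    w = p * (1.0 - p)
    H = (X * w[:, None]).T @ X
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
    return {"beta": beta, "vcov": vcov, "converged": converged and not separated}


class BinaryLogisticRegression(BaseEstimator):
    """IRLS binary logistic regression with separation detection.

    A deliberately small estimator: intercept added internally, Wald
    covariance from the observed information, ``converged_`` False under
    separation.  Mirrors the reference GLM fit to optimizer precision.
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        D = np.column_stack([np.ones(len(X)), X]) if self.fit_intercept else X
        res = fit_binary_logistic(D, y)
        off = 1 if self.fit_intercept else 0
        self.intercept_ = float(res["beta"][0]) if self.fit_intercept else 0.0
        self.coef_ = res["beta"][off:]
        self.vcov_ = res["vcov"]
        self.converged_ = res["converged"]
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        p = expit(self.intercept_ + X @ self.coef_)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        check_is_fitted(self, "coef_")
        off = 1 if self.fit_intercept else 0
        se = np.sqrt(np.diag(self.vcov_))[off:]
        z = norm.ppf(0.5 * (1 + level))
        names = getattr(
            self, "feature_names_in_",
            [f"x{i}" for i in range(self.n_features_in_)],
        )
        return pd.DataFrame(
            {
                "coef": self.coef_,
                "se": se,
                "or": np.exp(self.coef_),
                "ci_low": np.exp(self.coef_ - z * se),
                "ci_high": np.exp(self.coef_ + z * se),
                "p_value": 2 * norm.sf(np.abs(self.coef_ / se)),
            },
            index=pd.Index(list(names), name="covariate"),
        )


@dataclass
class SweepResult:
    """Per-cut-off binary-logistic coefficients (the Fig-1-style curve)."""

    table: pd.DataFrame  # cutoff_ml, covariate, coef, se, ci_lo, ci_hi, converged, n_below
    grid: np.ndarray
    skipped: list[dict] = field(default_factory=list)

    def for_covariate(self, name: str) -> pd.DataFrame:
        return self.table[self.table["covariate"] == name].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def sweep_cutoffs(
    data,
    covariates=MODEL_COVARIATES,
    grid="auto",
    level: float = 0.95,
    min_per_side: int = 10,
) -> SweepResult:
    """Fit ``1{MBL <= y}`` on the covariates for every cut-off ``y``.

    ``grid="auto"`` uses the unique observed blood-loss values between the
    5th and 95th percentile.  Cut-offs leaving fewer than ``min_per_side``
    subjects on either side are skipped and recorded in ``skipped``.
    """
    df = getattr(data, "df", data)
    y = df["mbl"].to_numpy(dtype=float)
    X = df.loc[:, list(covariates)].to_numpy(dtype=float)
    if isinstance(grid, str) and grid == "auto":
        p5, p95 = np.percentile(y, [5, 95])
        grid_vals = np.unique(y[(y >= p5) & (y <= p95)])
    else:
        grid_vals = np.unique(np.asarray(grid, dtype=float))
    if grid_vals.size == 0:
        raise ValueError("empty cut-off grid")

    D = np.column_stack([np.ones(len(X)), X])
    z = norm.ppf(0.5 * (1 + level))
    rows, skipped = [], []
    for cut in grid_vals:
        below = y <= cut
        n_below = int(below.sum())
        if min(n_below, len(y) - n_below) < min_per_side:
            skipped.append({"cutoff_ml": float(cut), "n_below": n_below})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = fit_binary_logistic(D, below.astype(float))
        se = np.sqrt(np.diag(res["vcov"]))[1:]
        for j, name in enumerate(covariates):
            b = res["beta"][1 + j]
            rows.append(
                {
                    "cutoff_ml": float(cut),
                    "covariate": name,
                    "coef": b,
                    "se": se[j],
                    "ci_lo": b - z * se[j],
                    "ci_hi": b + z * se[j],
                    "converged": res["converged"],
                    "n_below": n_below,
                }
            )
    if not rows:
        raise ValueError(
            "no usable cut-off in the grid (all skipped by the "
            f">={min_per_side}-per-side rule)"
        )
    table = pd.DataFrame(rows)
    used = np.unique(table["cutoff_ml"].to_numpy())
    return SweepResult(table=table, grid=used, skipped=skipped)
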