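"""Synthetic obstetric cohorts with the dependence structure the model assumes.

The generator emulates the study design: three delivery-mode strata
(677 vaginal, 409 elective cesarean, 223 unplanned cesarean), laboratory
covariates whose medians and interquartile ranges match the published
cohort description, a Gaussian copula carrying the targeted platelet-FXIII
rank correlations (0.228 prepartum, 0.293 postpartum), and blood loss drawn
from the transformation model itself:

    Y = h^{-1}(Z - (x - x_ref)' beta),   Z ~ standard logistic,

so that ``logit P(Y <= y | x) = h(y) + (x - x_ref)'beta`` holds exactly and
the fitting machinery can be validated by parameter recovery.

Marginal families are gamma for platelet counts, fibrinogen, FII and FXIII
(positive, right-skewed) and normal for hemoglobin; each is calibrated
numerically so its median and IQR hit the published values.  Rank-scale
correlation targets are converted to Gaussian-copula correlations through
``r = 2 sin(pi * rho_s / 6)``, the exact Spearman relation for the
bivariate normal, so the targeted rank correlations hold in expectation.

One global seed expands into independent per-stream seeds (covariates,
outcome, per-replicate) via ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

from .cohort import (
    DELIVERY_MODES,
    MODEL_COVARIATES,
    OPTIONAL_COLUMNS,
    CohortTable,
    validate_cohort_frame,
)
from .model import ContinuousOutcomeLogisticRegression

__all__ = [
    "TABLE1_TARGETS",
    "MarginalSpec",
    "LogLinearTransform",
    "SimConfig",
    "RecoveryReport",
    "calibrate_marginal",
    "simulate_covariates",
    "simulate_outcome",
    "simulate_cohort",
    "recovery_study",
]

_COPULA_VARS = MODEL_COVARIATES + OPTIONAL_COLUMNS  # 7 variables

#: published per-stratum medians and quartiles used to calibrate marginals:
#: {stratum: {variable: (median, q1, q3)}}
TABLE1_TARGETS: dict[str, dict[str, tuple[float, float, float]]] = {
    "vaginal": {
        "platelets_pre": (204.0, 172.0, 241.0),
        "hemoglobin_pre": (128.0, 121.0, 135.0),
        "fibrinogen_pre": (4.5, 3.9, 5.1),
        "fii_pre": (128.0, 118.0, 140.0),
        "fxiii_pre": (98.5, 86.0, 117.8),
        "platelets_post": (196.0, 160.0, 231.0),
        "fxiii_post": (84.0, 71.0, 95.8),
    },
    "elective_cs": {
        "platelets_pre": (205.0, 169.0, 244.0),
        "hemoglobin_pre": (124.0, 118.0, 131.0),
        "fibrinogen_pre": (4.3, 3.9, 4.8),
        "fii_pre": (128.0, 115.0, 138.0),
        "fxiii_pre": (93.0, 82.0, 107.0),
        "platelets_post": (190.0, 155.0, 225.0),
        "fxiii_post": (78.0, 67.0, 88.0),
    },
    "unplanned_cs": {
        "platelets_pre": (196.0, 170.0, 235.0),
        "hemoglobin_pre": (127.0, 120.0, 134.0),
        "fibrinogen_pre": (4.5, 3.9, 5.2),
        "fii_pre": (128.0, 115.0, 140.0),
        "fxiii_pre": (93.0, 80.2, 111.0),
        "platelets_post": (176.0, 149.5, 215.0),
        "fxiii_post": (72.5, 63.0, 82.0),
    },
}

DEFAULT_STRATUM_SIZES = {"vaginal": 677, "elective_cs": 409, "unplanned_cs": 223}

DEFAULT_RANK_CORR = {
    ("platelets_pre", "fxiii_pre"): 0.228,
    ("platelets_post", "fxiii_post"): 0.293,
}

#: family per covariate: gamma for the positive, right-skewed labs,
#: normal for hemoglobin
_FAMILIES = {
    "platelets_pre": "gamma",
    "hemoglobin_pre": "normal",
    "fibrinogen_pre": "gamma",
    "fii_pre": "gamma",
    "fxiii_pre": "gamma",
    "platelets_post": "gamma",
    "fxiii_post": "gamma",
}


@dataclass(frozen=True)
class MarginalSpec:
    """A calibrated continuous marginal (``gamma`` or ``normal``)."""

    family: str
    params: tuple[float, ...]  # gamma: (shape, scale); normal: (loc, scale)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.family == "gamma":
            return stats.gamma.ppf(u, a=self.params[0], scale=self.params[1])
        if self.family == "normal":
            return stats.norm.ppf(u, loc=self.params[0], scale=self.params[1])
        raise ValueError(f"unknown family {self.family!r}")


def calibrate_marginal(
    family: str, median: float, q1: float, q3: float
) -> MarginalSpec:
    """Choose family parameters so the marginal's median and IQR match.

    For the gamma family, the ratio median/IQR depends only on the shape
    parameter and increases monotonically with it, so a 1-d root find in
    log-shape pins the shape and the scale follows from the median.
    """
    iqr = q3 - q1
    if iqr <= 0 or median <= 0:
        raise ValueError("need positive median and q3 > q1")
    if family == "normal":
        return MarginalSpec("normal", (median, iqr / (2 * stats.norm.ppf(0.75))))
    if family != "gamma":
        raise ValueError(f"unknown family {family!r}")
    target = median / iqr

    def ratio(log_shape):
        a = math.exp(log_shape)
        q = stats.gamma.ppf([0.25, 0.5, 0.75], a=a)
        return q[1] / (q[2] - q[0]) - target

    sol = optimize.brentq(ratio, math.log(1e-2), math.log(1e6))
    shape = math.exp(sol)
    scale = median / stats.gamma.ppf(0.5, a=shape)
    return MarginalSpec("gamma", (shape, scale))


class LogLinearTransform:
    """Monotone baseline ``h(y) = slope * log(y / scale)`` on a support.

    The implied reference distribution of blood loss (at the reference
    covariates) is log-logistic with median ``scale`` and shape ``slope``:
    right-skewed on the mL scale, as measured blood loss is.
    """

    def __init__(self, slope: float = 3.3, scale: float = 400.0,
                 support: tuple[float, float] = (50.0, 6000.0)):
        if slope <= 0 or scale <= 0:
            raise ValueError("slope and scale must be positive")
        self.slope = float(slope)
        self.scale = float(scale)
        self.support = (float(support[0]), float(support[1]))

    def __call__(self, y, derivative: bool = False):
        y = np.asarray(y, dtype=float)
        if derivative:
            return self.slope / y
        return self.slope * np.log(y / self.scale)

    def inverse(self, z):
        y = self.scale * np.exp(np.asarray(z, dtype=float) / self.slope)
        return np.clip(y, *self.support)


def _generic_inverse(h, z, support, grid_size=8192):
    grid = np.linspace(support[0], support[1], grid_size)
    hz = np.asarray(h(grid), dtype=float)
    return np.interp(z, hz, grid, left=support[0], right=support[1])


@dataclass
class SimConfig:
    """Full data-generating specification for a synthetic cohort."""

    stratum_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_STRATUM_SIZES)
    )
    rank_corr: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_RANK_CORR)
    )
    marginals: dict[str, dict[str, MarginalSpec]] | None = None
    h_true: LogLinearTransform | object = field(default_factory=LogLinearTransform)
    beta_true: dict[str, float] = field(
        default_factory=lambda: {"platelets_pre": math.log(1.002)}
    )
    center_at_medians: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stratum_sizes) - set(DELIVERY_MODES)
        if unknown:
            raise ValueError(f"unknown strata {sorted(unknown)}")
        if self.marginals is None:
            self.marginals = {
                s: {
                    v: calibrate_marginal(_FAMILIES[v], *TABLE1_TARGETS[s][v])
                    for v in _COPULA_VARS
                }
                for s in self.stratum_sizes
            }
        self.copula_corr()  # fail early on a non-PSD target matrix

    @property
    def n_total(self) -> int:
        return sum(self.stratum_sizes.values())

    def copula_corr(self) -> np.ndarray:
        """Gaussian-scale correlation matrix hitting the rank targets.

        For a bivariate normal copula the Spearman correlation is
        ``rho_s = (6/pi) asin(r/2)``; inverting gives the Gaussian entry
        ``r = 2 sin(pi rho_s / 6)`` used here.  Unspecified pairs are 0.
        """
        k = len(_COPULA_VARS)
        R = np.eye(k)
        idx = {v: i for i, v in enumerate(_COPULA_VARS)}
        for (a, b), rho_s in self.rank_corr.items():
            if a not in idx or b not in idx:
                raise ValueError(f"unknown variable pair ({a}, {b})")
            r = 2.0 * math.sin(math.pi * rho_s / 6.0)
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
        w = np.linalg.eigvalsh(R)
        if w.min() < -1e-10:
            raise ValueError(
                f"copula correlation matrix is not positive semi-definite "
                f"(smallest eigenvalue {w.min():.3e})"
            )
        return R

    def beta_vector(self, covariates=MODEL_COVARIATES) -> np.ndarray:
        unknown = set(self.beta_true) - set(covariates)
        if unknown:
            raise ValueError(f"beta_true names unknown covariates {sorted(unknown)}")
        return np.array([self.beta_true.get(c, 0.0) for c in covariates])

    def reference_point(self, covariates=MODEL_COVARIATES) -> np.ndarray:
        """Population reference: size-weighted mean of stratum medians."""
        total = self.n_total
        ref = np.zeros(len(covariates))
        for s, n in self.stratum_sizes.items():
            med = np.array([TABLE1_TARGETS[s][c][0] for c in covariates])
            ref += (n / total) * med
        return ref


def simulate_covariates(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw correlated laboratory covariates per stratum (no outcome yet)."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    R = config.copula_corr()
    L = np.linalg.cholesky(R + 1e-12 * np.eye(R.shape[0]))
    frames = []
    for stratum in DELIVERY_MODES:
        n = config.stratum_sizes.get(stratum, 0)
        if n == 0:
            continue
        Z = rng.standard_normal((n, len(_COPULA_VARS))) @ L.T
        U = ndtr(Z)
        cols = {
            v: config.marginals[stratum][v].ppf(U[:, i])
            for i, v in enumerate(_COPULA_VARS)
        }
        frame = pd.DataFrame(cols)
        frame.insert(0, "delivery_mode", stratum)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def simulate_outcome(
    h_true,
    beta_true: np.ndarray,
    X: np.ndarray,
    seed: int = 0,
    x_ref: np.ndarray | None = None,
) -> np.ndarray:
    """Draw blood loss from the transformation model by inversion.

    ``Z ~ logistic``; ``Y = h^{-1}(Z - (x - x_ref)'beta)`` (``x_ref = 0``
    when omitted).  Values of ``Z - eta`` outside the range of ``h`` clamp
    to the support endpoints; a warning reports how many.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.asarray(beta_true, dtype=float)
    eta = (X - (0.0 if x_ref is None else np.asarray(x_ref, float))) @ beta
    rng = np.random.default_rng(seed)
    z = rng.logistic(size=X.shape[0])
    arg = z - eta
    support = h_true.support
    lo, hi = h_true(np.array(support[0])), h_true(np.array(support[1]))
    n_clamped = int(np.count_nonzero((arg < lo) | (arg > hi)))
    if n_clamped:
        warnings.warn(
            f"{n_clamped} simulated outcome(s) clamped to the support "
            f"endpoints {support}",
            RuntimeWarning,
            stacklevel=2,
        )
    if hasattr(h_true, "inverse"):
        y = h_true.inverse(arg)
    else:
        y = _generic_inverse(h_true, arg, support)
    return np.asarray(y, dtype=float)


def simulate_cohort(config: SimConfig, seed: int | None = None) -> CohortTable:
    """A full synthetic cohort: covariates, delivery mode and blood loss."""
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    cov_seed, out_seed = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    df = simulate_covariates(config, seed=cov_seed)
    X = df.loc[:, list(MODEL_COVARIATES)].to_numpy(dtype=float)
    x_ref = config.reference_point() if config.center_at_medians else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        y = simulate_outcome(
            config.h_true, config.beta_vector(), X, seed=out_seed, x_ref=x_ref
        )
    df.insert(0, "mbl", y)
    return validate_cohort_frame(df, provenance=f"synthetic(seed={seed})")


@dataclass
class RecoveryReport:
    """Bias/coverage summary of a simulate-fit round trip."""

    table: pd.DataFrame  # per covariate: truth, mean, bias, mc_se, coverage
    replicates: int
    n_failed: int

    def __str__(self) -> str:
        return (
            f"RecoveryReport({self.replicates} replicates, "
            f"{self.n_failed} failed)\n{self.table}"
        )


def recovery_study(
    config: SimConfig,
    replicates: int = 200,
    seed: int | None = None,
    level: float = 0.95,
    **estimator_params,
) -> RecoveryReport:
    """Repeatedly simulate and refit; report bias, spread and CI coverage.

    Each replicate gets an independent child seed of ``seed``.  Replicates
    whose fit does not converge are recorded, not fatal; more than 10%
    failures triggers a warning.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    seed = config.seed if seed is None else seed
    truth = config.beta_vector()
    z = stats.norm.ppf(0.5 * (1 + level))
    est_rows, cover_rows = [], []
    n_failed = 0
    child_seeds = np.random.SeedSequence(seed).spawn(replicates)
    for child in child_seeds:
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        cohort = simulate_cohort(config, seed=rep_seed)
        est = ContinuousOutcomeLogisticRegression(**estimator_params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            try:
                est.fit(
                    cohort.covariate_matrix(), cohort.mbl
                )
            except Exception:
                n_failed += 1
                continue
        if not est.converged_:
            n_failed += 1
            continue
        fit = est.result_
        m = fit.transform.order + 1
        se = np.sqrt(np.diag(fit.vcov)[m:])
        est_rows.append(fit.beta)
        cover_rows.append(np.abs(fit.beta - truth) <= z * se)
    if n_failed > 0.1 * replicates:
        warnings.warn(
            f"{n_failed}/{replicates} replicates failed to converge",
            RuntimeWarning,
            stacklevel=2,
        )
    if not est_rows:
        raise RuntimeError("all replicates failed")
    B = np.vstack(est_rows)
    C = np.vstack(cover_rows)
    table = pd.DataFrame(
        {
            "truth": truth,
            "mean": B.mean(axis=0),
            "bias": B.mean(axis=0) - truth,
            "mc_se": B.std(axis=0, ddof=1),
            "bias_se": B.std(axis=0, ddof=1) / np.sqrt(B.shape[0]),
            "coverage": C.mean(axis=0),
        },
        index=pd.Index(MODEL_COVARIATES, name="covariate"),
    )
    return RecoveryReport(table=table, replicates=replicates, n_failed=n_failed)
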