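"""Continuous-outcome logistic regression for measured blood loss.

The model is a linear transformation model with a standard-logistic
inverse link,

    logit P(Y <= y | x) = h(y) + x' beta,

where ``Y`` is measured blood loss (mL), ``x`` the prepartum covariates and
``h`` a monotone nondecreasing baseline parameterized in the Bernstein
basis (:mod:`colrpph.bernstein`).  A single coefficient vector ``beta``
applies simultaneously to every dichotomization of ``Y``: the model is
"all possible binary logistic regressions at once", with cut-off-specific
intercepts replaced by the smooth baseline.

Sign convention
---------------
``exp(beta_j)`` is the odds ratio to remain *below* any given cut-off per
one-unit increase of covariate ``j``; an OR above 1 therefore means *less*
bleeding.  Other implementations of this model class write the linear
predictor with the opposite sign — comparisons must flip signs accordingly.

Estimation maximizes the exact-continuous likelihood: each subject
contributes ``log h'(y_i) + log lambda(h(y_i) + x_i'beta)`` where
``lambda`` is the standard-logistic density.  Monotonicity of ``h`` is
enforced through the unconstrained reparameterization
``theta_0 = gamma_0, theta_k = theta_{k-1} + exp(gamma_k)``.  Standard
errors come from the inverse observed information, mapped back to the
``(theta, beta)`` scale (and to original covariate units) by the delta
method; inference is Wald throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .bernstein import BernsteinTransform, basis_eval

__all__ = [
    "ColrSpec",
    "ColrFit",
    "ShiftEffect",
    "ContinuousOutcomeLogisticRegression",
    "negative_loglik",
    "fit_colr",
    "odds_ratios",
    "predict_cdf",
    "pph_prevalence_curve",
    "shift_effect",
]


# ---------------------------------------------------------------------------
# result containers

@dataclass
class ColrSpec:
    """Model specification: covariates and fitting options."""

    covariates: tuple[str, ...]
    order: int = 6
    log_scale: bool = False
    standardize: bool = True
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        self.covariates = tuple(self.covariates)
        if len(self.covariates) == 0:
            raise ValueError("at least one covariate is required")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")


@dataclass
class ColrFit:
    """A fitted transformation model.

    ``beta`` is per original covariate units; ``vcov`` is the joint
    covariance of ``(theta_0..theta_M, beta_1..beta_p)`` on that scale.
    ``x_ref`` holds the training-data covariate medians, the default
    reference subject for prevalence curves and shift effects.
    """

    spec: ColrSpec
    transform: BernsteinTransform
    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    n_obs: int
    convergence: dict
    x_ref: np.ndarray
    clamp_warned: bool = field(default=False, repr=False)

    @property
    def converged(self) -> bool:
        return bool(self.convergence.get("status") == "converged")

    def to_dict(self) -> dict:
        d = {
            "spec": asdict(self.spec),
            "theta": self.transform.theta.tolist(),
            "support": list(self.transform.support),
            "order": self.transform.order,
            "beta": dict(zip(self.spec.covariates, self.beta.tolist())),
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "convergence": self.convergence,
            "x_ref": dict(zip(self.spec.covariates, self.x_ref.tolist())),
        }
        return d


@dataclass
class ShiftEffect:
    """Effect of shifting one covariate by ``delta`` units.

    ``odds_factor = exp(delta * beta)`` multiplies the odds to remain below
    any cut-off; ``pct_rise_below`` is that factor as a percentage rise on
    the odds scale.  ``pct_drop_pph`` is the probability-scale drop of
    P(Y >= threshold) at the reference subject — the two scales answer
    different questions and are reported separately.
    """

    covariate: str
    delta: float
    odds_factor: float
    pct_rise_below: float
    pct_drop_pph: float
    x_ref: np.ndarray
    threshold: float


# ---------------------------------------------------------------------------
# likelihood core

def _log_logistic_density(z: np.ndarray) -> np.ndarray:
    """log lambda(z) with lambda(z) = sigma(z)(1 - sigma(z)), stable in z."""
    az = np.abs(z)
    return -az - 2.0 * np.log1p(np.exp(-az))


def _nll_core(theta, beta, B, D, X):
    """Negative log-likelihood given precomputed basis matrices.

    ``B`` and ``D`` are the Bernstein basis and its y-derivative evaluated
    at the observations; ``X`` is the covariate matrix on whichever scale
    ``beta`` refers to.  Returns +inf when h'(y_i) <= 0 anywhere.
    """
    hp = D @ theta
    if np.any(hp <= 0.0):
        return np.inf
    z = B @ theta + X @ beta
    return -(np.sum(np.log(hp)) + np.sum(_log_logistic_density(z)))


def negative_loglik(
    transform: BernsteinTransform,
    beta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    log_scale: bool = False,
) -> float:
    """Exact-continuous negative log-likelihood of the transformation model.

    Observations at which ``h'`` vanishes make the likelihood degenerate;
    the function then returns ``+inf`` (with a warning) rather than raising.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    u = np.log(y) if log_scale else y
    B = basis_eval(transform.order, transform.support, u)
    D = basis_eval(transform.order, transform.support, u, derivative=True)
    val = _nll_core(np.asarray(transform.theta, float), np.asarray(beta, float), B, D, X)
    if np.isinf(val):
        warnings.warn(
            "h'(y) <= 0 at one or more observations; likelihood is degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(val)


def _theta_from_gamma(gamma: np.ndarray) -> np.ndarray:
    theta = gamma.copy()
    theta[1:] = np.exp(gamma[1:])
    return np.cumsum(theta)


def _nll_grad_gamma(phi, B, D, X, m):
    """Objective and analytic gradient in phi = (gamma, beta_std)."""
    gamma, beta = phi[:m], phi[m:]
    if np.any(gamma[1:] > 500.0):  # exp would overflow; reject the point
        return np.inf, np.zeros_like(phi)
    theta = _theta_from_gamma(gamma)
    hp = D @ theta
    if not np.all(np.isfinite(hp)) or np.any(hp <= 0.0):
        return np.inf, np.zeros_like(phi)
    z = B @ theta + X @ beta
    nll = -(np.sum(np.log(hp)) + np.sum(_log_logistic_density(z)))
    w = 2.0 * expit(z) - 1.0          # -d log lambda / dz
    g_theta = -(D.T @ (1.0 / hp)) + B.T @ w
    g_beta = X.T @ w
    # chain rule: theta_j depends on gamma_k for k <= j
    rev = np.cumsum(g_theta[::-1])[::-1]
    g_gamma = rev.copy()
    g_gamma[1:] *= np.exp(gamma[1:])
    return nll, np.concatenate([g_gamma, g_beta])


def _fd_hessian(fun_grad, phi, args, eps=1e-5):
    """Central finite differences of an analytic gradient."""
    d = phi.size
    H = np.empty((d, d))
    for i in range(d):
        h = eps * max(1.0, abs(phi[i]))
        up = phi.copy(); up[i] += h
        dn = phi.copy(); dn[i] -= h
        gu = fun_grad(up, *args)[1]
        gd = fun_grad(dn, *args)[1]
        H[i] = (gu - gd) / (2.0 * h)
    return 0.5 * (H + H.T)


def _check_collinearity(X: np.ndarray, names: tuple[str, ...]) -> None:
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    _, s, vt = np.linalg.svd(Xc / sd, full_matrices=False)
    if s[-1] < 1e-10 * s[0]:
        load = np.abs(vt[-1])
        cols = [names[i] for i in np.argsort(load)[::-1] if load[i] > 0.1]
        raise ValueError(
            f"collinear design: columns {cols} are linearly dependent "
            "to machine precision"
        )


# ---------------------------------------------------------------------------
# estimator

class ContinuousOutcomeLogisticRegression(BaseEstimator):
    """Transformation-model regression of a continuous outcome.

    Fits ``logit P(Y <= y | x) = h(y) + x'beta`` by maximum likelihood with
    a monotone Bernstein baseline ``h`` of order ``order`` on the observed
    outcome range (extended by ``support_margin`` of the range per side).

    Parameters
    ----------
    order : int, default 6
        Bernstein polynomial order of the baseline transformation.
    log_scale : bool, default False
        Build ``h`` on log(y) instead of raw y.  The study outcome is blood
        loss in mL; the default models the raw scale.
    standardize : bool, default True
        Center/scale covariates internally for optimizer conditioning;
        reported coefficients are always per original covariate units.
    ci_level : float, default 0.95
        Level for Wald confidence intervals.
    tol : float, default 1e-8
        Projected-gradient tolerance of the quasi-Newton stage.
    n_starts : int, default 3
        Number of jittered starting points (seeded; guards against flat
        directions in the baseline parameters).
    random_state : int, default 0
        Seed for the start-point jitter.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        ``beta`` per original covariate units.
    transform_ : BernsteinTransform
        The fitted baseline ``h``.
    vcov_ : ndarray
        Covariance of ``(theta, beta)`` on the reporting scale.
    loglik_ : float
        Maximized log-likelihood.
    result_ : ColrFit
        Full fit snapshot used by the module-level helper functions.
    """

    def __init__(
        self,
        order: int = 6,
        log_scale: bool = False,
        standardize: bool = True,
        ci_level: float = 0.95,
        support_margin: float = 0.01,
        tol: float = 1e-8,
        max_iter: int = 1000,
        n_starts: int = 3,
        random_state: int = 0,
    ):
        self.order = order
        self.log_scale = log_scale
        self.standardize = standardize
        self.ci_level = ci_level
        self.support_margin = support_margin
        self.tol = tol
        self.max_iter = max_iter
        self.n_starts = n_starts
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def _start_values(self, B, u, n_beta, rng):
        n = u.size
        ranks = np.argsort(np.argsort(u, kind="stable"), kind="stable")
        p = (ranks + 0.5) / n
        target = logit(p)
        theta0, *_ = np.linalg.lstsq(B, target, rcond=None)
        theta0 = np.maximum.accumulate(theta0)
        spread = max(target.max() - target.min(), 1.0)
        inc = np.maximum(np.diff(theta0), 1e-3 * spread / max(self.order, 1))
        gamma0 = np.concatenate([[theta0[0]], np.log(inc)])
        starts = [np.concatenate([gamma0, np.zeros(n_beta)])]
        for _ in range(self.n_starts - 1):
            jitter = np.concatenate(
                [rng.normal(0.0, 0.2, gamma0.size), rng.normal(0.0, 0.05, n_beta)]
            )
            starts.append(starts[0] + jitter)
        return starts

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X = check_array(X, dtype=float, ensure_min_samples=2)
        y = np.asarray(y, dtype=float).ravel()
        if y.size != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        if np.any(y <= 0) and self.log_scale:
            raise ValueError("log_scale requires strictly positive outcomes")
        n, p = X.shape
        self.n_features_in_ = p
        if not hasattr(self, "feature_names_in_"):
            self.feature_names_in_ = np.asarray(
                [f"x{i}" for i in range(p)], dtype=object
            )
        names = tuple(self.feature_names_in_)
        m = self.order + 1
        if n <= m + p:
            raise ValueError(
                f"need more observations ({n}) than parameters ({m + p})"
            )
        _check_collinearity(X, names)

        u = np.log(y) if self.log_scale else y
        rng_ = float(u.max() - u.min())
        if rng_ <= 0:
            raise ValueError("outcome is constant; transformation undefined")
        lo = float(u.min() - self.support_margin * rng_)
        hi = float(u.max() + self.support_margin * rng_)
        support = (lo, hi)
        B = basis_eval(self.order, support, u)
        D = basis_eval(self.order, support, u, derivative=True)

        if self.standardize:
            mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
            sd = np.where(sd > 0, sd, 1.0)
        else:
            mu, sd = np.zeros(p), np.ones(p)
        Xs = (X - mu) / sd

        rng = np.random.default_rng(self.random_state)
        best = None
        total_nit = 0
        for phi0 in self._start_values(B, u, p, rng):
            res = optimize.minimize(
                _nll_grad_gamma,
                phi0,
                args=(B, D, Xs, m),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": self.max_iter, "gtol": self.tol, "ftol": 1e-14},
            )
            total_nit += res.nit
            if best is None or res.fun < best.fun:
                best = res
        phi = best.x

        # Newton polish with the observed information for a sharp optimum
        H = _fd_hessian(_nll_grad_gamma, phi, (B, D, Xs, m))
        fval, grad = _nll_grad_gamma(phi, B, D, Xs, m)
        for _ in range(25):
            if np.max(np.abs(grad)) < self.tol:
                break
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                break
            t = 1.0
            while t > 1e-6:
                f_new, g_new = _nll_grad_gamma(phi - t * step, B, D, Xs, m)
                if f_new < fval:
                    break
                t /= 2.0
            else:
                break
            phi = phi - t * step
            fval, grad = f_new, g_new
            H = _fd_hessian(_nll_grad_gamma, phi, (B, D, Xs, m))

        gnorm = float(np.max(np.abs(grad)))
        status = "converged" if gnorm < 1e-5 * max(1.0, abs(fval)) else "not_converged"
        if status != "converged":
            warnings.warn(
                f"optimizer did not reach gradient tolerance (|g|_inf = {gnorm:.2e})",
                RuntimeWarning,
                stacklevel=2,
            )

        gamma, beta_std = phi[:m], phi[m:]
        theta_std = _theta_from_gamma(gamma)

        # covariance in phi, then delta method to original (theta, beta)
        try:
            cov_phi = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov_phi = np.linalg.pinv(H)
        J = np.zeros((m + p, m + p))
        J[:m, 0] = 1.0
        for k in range(1, m):
            J[k:m, k] = np.exp(gamma[k])
        J[:m, m:] = -(mu / sd)[None, :]
        J[m:, m:] = np.diag(1.0 / sd)
        vcov = J @ cov_phi @ J.T
        vcov = 0.5 * (vcov + vcov.T)

        beta = beta_std / sd
        theta = theta_std - float(beta_std @ (mu / sd))

        self.transform_ = BernsteinTransform(self.order, support, theta)
        self.coef_ = beta
        self.theta_ = theta
        self.vcov_ = vcov
        self.loglik_ = float(-fval)
        self.n_iter_ = int(total_nit)
        self.grad_norm_ = gnorm
        self.converged_ = status == "converged"
        spec = ColrSpec(
            covariates=names,
            order=self.order,
            log_scale=self.log_scale,
            standardize=self.standardize,
            ci_level=self.ci_level,
        )
        self.result_ = ColrFit(
            spec=spec,
            transform=self.transform_,
            beta=beta,
            vcov=vcov,
            loglik=self.loglik_,
            n_obs=n,
            convergence={
                "gradient_norm": gnorm,
                "iterations": self.n_iter_,
                "status": status,
            },
            x_ref=np.median(X, axis=0),
        )
        return self

    # -- inference and prediction -----------------------------------------

    def odds_ratios(self, level: float | None = None) -> pd.DataFrame:
        check_is_fitted(self, "result_")
        return odds_ratios(self.result_, level or self.ci_level)

    def predict_cdf(self, X, y):
        check_is_fitted(self, "result_")
        return predict_cdf(self.result_, X, y)

    def predict(self, X):
        """Conditional median blood loss: h^{-1}(-x'beta)."""
        check_is_fitted(self, "result_")
        X = check_array(X, dtype=float)
        z = -(X @ self.coef_)
        med = self.transform_.inverse(z)
        return np.exp(med) if self.log_scale else med

    def prevalence_curve(self, focal, grid, x_ref=None, threshold=500.0, level=None):
        check_is_fitted(self, "result_")
        return pph_prevalence_curve(
            self.result_, focal, grid, x_ref=x_ref, threshold=threshold,
            level=level or self.ci_level,
        )

    def shift_effect(self, covariate, delta, x_ref=None, threshold=500.0):
        check_is_fitted(self, "result_")
        return shift_effect(
            self.result_, covariate, delta, x_ref=x_ref, threshold=threshold
        )


# ---------------------------------------------------------------------------
# module-level operations on a ColrFit

def fit_colr(spec: ColrSpec, data, **fit_kwargs) -> ColrFit:
    """Fit the transformation model to a validated cohort.

    ``data`` is a :class:`~colrpph.cohort.CohortTable` (or a DataFrame with
    the outcome column ``mbl`` and the spec's covariate columns).
    """
    df = getattr(data, "df", data)
    est = ContinuousOutcomeLogisticRegression(
        order=spec.order,
        log_scale=spec.log_scale,
        standardize=spec.standardize,
        ci_level=spec.ci_level,
        **fit_kwargs,
    )
    est.fit(df.loc[:, list(spec.covariates)], df["mbl"].to_numpy(dtype=float))
    return est.result_


def odds_ratios(fit: ColrFit, level: float | None = None) -> pd.DataFrame:
    """Wald odds ratios per one-unit covariate increase.

    OR > 1 means the covariate increases the probability to remain below
    any cut-off (less bleeding).
    """
    level = fit.spec.ci_level if level is None else level
    if not 0.0 < level < 1.0:
        raise ValueError("CI level must lie in (0, 1)")
    m = fit.transform.order + 1
    se = np.sqrt(np.diag(fit.vcov)[m:])
    z_crit = norm.ppf(0.5 * (1.0 + level))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, fit.beta / se, np.inf * np.sign(fit.beta))
    pvals = np.where(fit.beta == 0, 1.0, 2.0 * norm.sf(np.abs(zstat)))
    return pd.DataFrame(
        {
            "coef": fit.beta,
            "se": se,
            "or": np.exp(fit.beta),
            "ci_low": np.exp(fit.beta - z_crit * se),
            "ci_high": np.exp(fit.beta + z_crit * se),
            "p_value": pvals,
        },
        index=pd.Index(fit.spec.covariates, name="covariate"),
    )


def _as_matrix(fit: ColrFit, x) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        x = x.loc[:, list(fit.spec.covariates)].to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != len(fit.spec.covariates):
        raise ValueError(
            f"covariate vector has {x.shape[1]} entries; model expects "
            f"{len(fit.spec.covariates)}"
        )
    return x


def _h_at(fit: ColrFit, y) -> np.ndarray:
    u = np.log(y) if fit.spec.log_scale else np.asarray(y, dtype=float)
    return fit.transform(u, clamp=True)


def predict_cdf(fit: ColrFit, x, y):
    """P(Y <= y | x) = sigma(h(y) + x'beta).

    ``y`` outside the fitted support is clamped to the endpoints (with a
    warning), so the CDF saturates at the support boundary.
    """
    X = _as_matrix(fit, x)
    h = np.asarray(_h_at(fit, y))
    xb = X @ fit.beta
    if h.ndim == 0:
        val = expit(xb + float(h))          # (n_rows,)
        return float(val[0]) if X.shape[0] == 1 and np.ndim(x) == 1 else val
    if X.shape[0] == 1:
        return expit(xb[0] + h)             # (n_y,)
    if h.size == X.shape[0]:
        return expit(xb + h)                # elementwise pairing
    return expit(np.add.outer(xb, h))       # (n_rows, n_y)


def pph_prevalence_curve(
    fit: ColrFit,
    focal: str,
    grid,
    x_ref=None,
    threshold: float = 500.0,
    level: float = 0.95,
) -> pd.DataFrame:
    """P(Y >= threshold) as a function of one covariate, with a Wald band.

    The linear predictor ``eta(x) = h(threshold) + x'beta`` is a smooth
    function of the parameters; its pointwise standard error comes from the
    delta method, ``se(eta)^2 = g' V g`` with gradient
    ``g = (b(threshold), x)`` in ``(theta, beta)``.  The band maps through
    the response function: ``1 - sigma(eta -+ z se)``.
    """
    if focal not in fit.spec.covariates:
        raise ValueError(f"{focal!r} is not a model covariate")
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if x_ref is None:
        x_ref = fit.x_ref
    x_ref = np.asarray(x_ref, dtype=float).ravel()
    j = fit.spec.covariates.index(focal)
    X = np.tile(x_ref, (grid.size, 1))
    X[:, j] = grid

    u = np.log(threshold) if fit.spec.log_scale else threshold
    b = basis_eval(fit.transform.order, fit.transform.support, u, clamp=True)
    eta = fit.transform(u, clamp=True) + X @ fit.beta
    G = np.hstack([np.tile(b, (grid.size, 1)), X])  # d eta / d(theta, beta)
    var = np.einsum("ij,jk,ik->i", G, fit.vcov, G)
    se = np.sqrt(np.maximum(var, 0.0))
    z_crit = norm.ppf(0.5 * (1.0 + level))
    return pd.DataFrame(
        {
            focal: grid,
            "prevalence": 1.0 - expit(eta),
            "ci_low": 1.0 - expit(eta + z_crit * se),
            "ci_high": 1.0 - expit(eta - z_crit * se),
        }
    )


def shift_effect(
    fit: ColrFit,
    covariate: str,
    delta: float,
    x_ref=None,
    threshold: float = 500.0,
) -> ShiftEffect:
    """Odds- and probability-scale effect of a ``delta``-unit covariate shift.

    With ``beta > 0`` a positive shift raises the odds to remain below any
    cut-off by ``exp(delta*beta)`` and lowers the probability of blood loss
    at or above ``threshold`` for the reference subject.
    """
    if covariate not in fit.spec.covariates:
        raise ValueError(f"{covariate!r} is not a model covariate")
    if x_ref is None:
        x_ref = fit.x_ref
    x_ref = np.asarray(x_ref, dtype=float).ravel()
    j = fit.spec.covariates.index(covariate)
    beta_j = float(fit.beta[j])
    odds_factor = float(np.exp(delta * beta_j))
    p1 = 1.0 - predict_cdf(fit, x_ref, threshold)
    x2 = x_ref.copy()
    x2[j] += delta
    p2 = 1.0 - predict_cdf(fit, x2, threshold)
    return ShiftEffect(
        covariate=covariate,
        delta=float(delta),
        odds_factor=odds_factor,
        pct_rise_below=100.0 * (odds_factor - 1.0),
        pct_drop_pph=100.0 * (1.0 - p2 / p1) if p1 > 0 else 0.0,
        x_ref=x_ref,
        threshold=float(threshold),
    )
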