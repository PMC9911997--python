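"""Transformation-model likelihood, fitting, inference and derived quantities."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

from colrpph import (
    BernsteinTransform,
    ColrFit,
    ColrSpec,
    ContinuousOutcomeLogisticRegression,
    SimConfig,
    negative_loglik,
    odds_ratios,
    pph_prevalence_curve,
    predict_cdf,
    shift_effect,
    simulate_cohort,
)

Z95 = norm.ppf(0.975)


def toy_fit(theta, beta, support=(0.0, 1.0), vcov=None, covs=None):
    theta = np.asarray(theta, float)
    beta = np.asarray(beta, float)
    covs = covs or tuple(f"x{i}" for i in range(beta.size))
    order = theta.size - 1
    d = theta.size + beta.size
    return ColrFit(
        spec=ColrSpec(covariates=covs, order=order),
        transform=BernsteinTransform(order, support, theta),
        beta=beta,
        vcov=np.zeros((d, d)) if vcov is None else np.asarray(vcov, float),
        loglik=0.0,
        n_obs=1,
        convergence={"status": "converged"},
        x_ref=np.zeros(beta.size),
    )


# ---------------------------------------------------------------------------
# negative log-likelihood

def test_nll_single_observation_identity_transform():
    # h(y) = y on [0,1]: l = log 1 + log lambda(0.5); direct arithmetic
    t = BernsteinTransform(1, (0, 1), np.array([0.0, 1.0]))
    nll = negative_loglik(t, np.array([0.0]), np.array([[0.0]]), np.array([0.5]))
    s = expit(0.5)
    assert nll == pytest.approx(-math.log(s * (1 - s)), rel=1e-12)
    assert nll == pytest.approx(1.4481540, abs=1e-6)


def test_nll_at_zero_link_is_derivative_term_plus_2log2():
    # h(0.5) = 0 with slope 1: lambda(0) = 1/4, so NLL = -log h' + 2 log 2
    t = BernsteinTransform(1, (0, 1), np.array([-0.5, 0.5]))
    nll = negative_loglik(t, np.array([0.0]), np.array([[0.0]]), np.array([0.5]))
    assert nll == pytest.approx(2 * math.log(2), rel=1e-12)


def test_nll_degenerate_flat_transform_returns_inf_with_warning():
    t = BernsteinTransform(1, (0, 1), np.array([0.3, 0.3]))
    with pytest.warns(RuntimeWarning, match="degenerate"):
        val = negative_loglik(t, np.array([0.0]), np.array([[0.0]]), np.array([0.5]))
    assert math.isinf(val)


def test_nll_matches_quadrature_oracle_on_synthetic_sample():
    """The per-subject log-density must equal the numerical derivative of
    the model CDF, and the implied density must integrate to ~1."""
    rng = np.random.default_rng(3)
    theta = np.array([-12.0, -4.0, -1.0, 0.5, 2.0, 5.0, 12.0])
    t = BernsteinTransform(6, (100.0, 1500.0), theta)
    beta = np.array([0.3, -0.2])
    X = rng.normal(size=(50, 2)) * 0.5
    y = rng.uniform(150, 1400, size=50)

    def cdf(yy, x):
        return expit(t(np.asarray(yy)) + x @ beta)

    eps = 1e-4
    logdens = np.log(
        [(cdf(y[i] + eps, X[i]) - cdf(y[i] - eps, X[i])) / (2 * eps)
         for i in range(50)]
    )
    oracle = -np.sum(logdens)
    nll = negative_loglik(t, beta, X, y)
    assert nll == pytest.approx(oracle, rel=1e-6)

    from scipy.integrate import quad
    total, _ = quad(
        lambda yy: (cdf(yy + eps, X[0]) - cdf(yy - eps, X[0])) / (2 * eps),
        100.0, 1500.0, limit=300,
    )
    assert total == pytest.approx(1.0, abs=1e-3)


# ---------------------------------------------------------------------------
# fitting

def _grid_refine(nll_of, center, widths, rounds=6, pts=11):
    """Independent coarse-to-fine grid search minimizer."""
    center = np.asarray(center, float)
    widths = np.asarray(widths, float)
    for _ in range(rounds):
        axes = [np.linspace(c - w, c + w, pts) for c, w in zip(center, widths)]
        best, best_val = center, np.inf
        for a in axes[0]:
            for b in axes[1]:
                for c in axes[2]:
                    v = nll_of(np.array([a, b, c]))
                    if v < best_val:
                        best, best_val = np.array([a, b, c]), v
        center = best
        widths = widths * (2.0 / (pts - 1))
    return center


def test_fit_agrees_with_grid_search_oracle_binary_covariate():
    rng = np.random.default_rng(12)
    n = 80
    x = (rng.random(n) < 0.5).astype(float)
    h_true = BernsteinTransform(1, (0.0, 1.0), np.array([-2.0, 2.0]))
    z = rng.logistic(size=n)
    y = np.clip((z - 0.8 * x + 2.0) / 4.0, 1e-3, 1 - 1e-3)

    est = ContinuousOutcomeLogisticRegression(order=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est.fit(x[:, None], y)
    support = est.transform_.support

    def nll_of(p):
        th0, dth, b = p
        if dth <= 0:
            return np.inf
        t = BernsteinTransform(1, support, np.array([th0, th0 + dth]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return negative_loglik(t, np.array([b]), x[:, None], y)

    sol = _grid_refine(nll_of, center=[-2.0, 4.0, 0.0], widths=[4.0, 3.9, 3.0])
    assert est.coef_[0] == pytest.approx(sol[2], abs=1e-3)


def test_null_data_gives_calibrated_wald_z_statistics():
    """With all true coefficients zero, |z| < 3 in >= 99% of fits."""
    config = SimConfig(
        stratum_sizes={"vaginal": 400}, beta_true={}, seed=0
    )
    n_fits, n_inside, n_z = 0, 0, 0
    for rep in range(100):
        cohort = simulate_cohort(config, seed=1000 + rep)
        est = ContinuousOutcomeLogisticRegression()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est.fit(cohort.covariate_matrix(), cohort.mbl)
        if not est.converged_:
            continue
        fit = est.result_
        m = fit.transform.order + 1
        se = np.sqrt(np.diag(fit.vcov)[m:])
        zstat = fit.beta / se
        n_fits += 1
        n_z += zstat.size
        n_inside += int(np.sum(np.abs(zstat) < 3))
    assert n_fits >= 95
    assert n_inside / n_z >= 0.99


def test_free_beta_loglik_dominates_null_fit(default_cohort, fitted_default):
    """Likelihood-ratio sanity: the full fit beats the baseline-only fit."""
    from scipy.optimize import minimize
    from colrpph.bernstein import basis_eval

    y = default_cohort.mbl
    t = fitted_default.transform_
    B = basis_eval(t.order, t.support, y)
    D = basis_eval(t.order, t.support, y, derivative=True)

    def nll_gamma(g):
        theta = np.concatenate([[g[0]], g[0] + np.cumsum(np.exp(g[1:]))])
        hp = D @ theta
        if np.any(hp <= 0):
            return np.inf
        z = B @ theta
        return -(np.sum(np.log(hp)) + np.sum(-np.abs(z) - 2 * np.log1p(np.exp(-np.abs(z)))))

    g0 = np.concatenate([[t.theta[0]], np.log(np.maximum(np.diff(t.theta), 1e-6))])
    res = minimize(nll_gamma, g0, method="Nelder-Mead",
                   options={"maxiter": 4000, "fatol": 1e-10})
    assert fitted_default.loglik_ >= -res.fun - 1e-6


def test_collinear_design_rejected_with_column_names(default_cohort):
    X = default_cohort.covariate_matrix().copy()
    X["platelets_twin"] = X["platelets_pre"]
    est = ContinuousOutcomeLogisticRegression()
    with pytest.raises(ValueError, match="collinear"):
        est.fit(X, default_cohort.mbl)


def test_fit_reports_convergence_diagnostics(fitted_default):
    fit = fitted_default.result_
    assert fit.converged
    assert fit.convergence["gradient_norm"] < 1e-2
    assert fit.vcov.shape == (7 + 5, 7 + 5)
    np.testing.assert_allclose(fit.vcov, fit.vcov.T)
    assert np.all(np.diag(fit.vcov) >= 0)


def test_standardization_does_not_change_reported_scale(default_cohort):
    y = default_cohort.mbl
    X = default_cohort.covariate_matrix()
    a = ContinuousOutcomeLogisticRegression(standardize=True).fit(X, y)
    b = ContinuousOutcomeLogisticRegression(standardize=False).fit(X, y)
    np.testing.assert_allclose(a.coef_, b.coef_, rtol=5e-3, atol=5e-6)
    assert a.loglik_ == pytest.approx(b.loglik_, abs=1e-4)


# ---------------------------------------------------------------------------
# odds ratios

def test_null_coefficient_gives_unit_or_and_p_one():
    fit = toy_fit([0.0, 1.0], [0.0], vcov=np.diag([0.1, 0.1, 0.25]))
    tab = odds_ratios(fit)
    row = tab.iloc[0]
    assert row["or"] == 1.0
    assert row["ci_low"] < 1.0 < row["ci_high"]
    assert row["p_value"] == 1.0


def test_or_ci_direct_arithmetic():
    b, se = math.log(1.002), 0.0005
    fit = toy_fit([0.0, 1.0], [b], vcov=np.diag([0.0, 0.0, se**2]))
    row = odds_ratios(fit, level=0.95).iloc[0]
    assert row["ci_low"] == pytest.approx(math.exp(b - Z95 * se), rel=1e-9)
    assert row["ci_high"] == pytest.approx(math.exp(b + Z95 * se), rel=1e-9)
    assert row["ci_low"] <= row["or"] <= row["ci_high"]


def test_or_ci_width_monotone_in_level(fitted_default):
    widths = []
    for level in (0.8, 0.95, 0.99):
        tab = fitted_default.odds_ratios(level)
        widths.append((tab["ci_high"] - tab["ci_low"]).to_numpy())
    assert np.all(widths[0] < widths[1])
    assert np.all(widths[1] < widths[2])


def test_or_invalid_level_rejected(fitted_default):
    with pytest.raises(ValueError, match="level"):
        odds_ratios(fitted_default.result_, level=1.2)


# ---------------------------------------------------------------------------
# prediction and derived quantities

def test_predict_cdf_logistic_symmetry_and_hand_value():
    fit = toy_fit([-1.0, 1.0], [0.5])
    # h(0.5) = 0 for the symmetric linear transform
    assert predict_cdf(fit, np.array([0.0]), 0.5) == pytest.approx(0.5)
    # hand evaluation: h(0.75) = -1*0.25 + 1*0.75 = 0.5; x beta = 0.2
    val = predict_cdf(fit, np.array([0.4]), 0.75)
    assert val == pytest.approx(expit(0.5 + 0.4 * 0.5), rel=1e-12)


def test_predict_cdf_monotone_in_outcome(fitted_default, default_cohort):
    x = default_cohort.covariate_matrix().iloc[:1]
    ys = np.linspace(*fitted_default.transform_.support, 31)
    vals = np.array([fitted_default.predict_cdf(x, yy) for yy in ys])
    assert np.all(np.diff(vals) >= -1e-12)
    assert vals[-1] >= vals.max() - 1e-12


def test_predict_cdf_covariate_length_mismatch(fitted_default):
    with pytest.raises(ValueError, match="expects"):
        fitted_default.predict_cdf(np.array([1.0, 2.0]), 400.0)


def test_prevalence_curve_flat_without_effects():
    fit = toy_fit([-2.0, 0.0, 2.0], [0.0, 0.0], support=(100.0, 900.0))
    curve = pph_prevalence_curve(fit, "x0", [1.0, 5.0, 9.0], x_ref=[0.0, 0.0],
                                 threshold=500.0)
    h500 = fit.transform(500.0)
    np.testing.assert_allclose(curve["prevalence"], 1 - expit(h500))
    # zero covariance collapses the band onto the estimate
    np.testing.assert_allclose(curve["ci_low"], curve["prevalence"])
    np.testing.assert_allclose(curve["ci_high"], curve["prevalence"])


def test_prevalence_band_matches_hand_delta_method():
    theta = np.array([-1.0, 0.5, 2.0])
    beta = np.array([0.04])
    V = np.array(
        [[0.04, 0.01, 0.00, 0.001],
         [0.01, 0.09, 0.02, 0.000],
         [0.00, 0.02, 0.16, 0.002],
         [0.001, 0.000, 0.002, 0.0004]]
    )
    fit = toy_fit(theta, beta, support=(0.0, 1000.0), vcov=V)
    x0, thr = 30.0, 500.0
    curve = pph_prevalence_curve(fit, "x0", [x0], threshold=thr, level=0.95)
    # hand gradient: basis at threshold plus the covariate value
    u = 0.5
    b = np.array([(1 - u) ** 2, 2 * u * (1 - u), u**2])
    g = np.concatenate([b, [x0]])
    eta = b @ theta + x0 * beta[0]
    se = math.sqrt(g @ V @ g)
    assert curve["prevalence"][0] == pytest.approx(1 - expit(eta), rel=1e-12)
    assert curve["ci_low"][0] == pytest.approx(1 - expit(eta + Z95 * se), rel=1e-12)
    assert curve["ci_high"][0] == pytest.approx(1 - expit(eta - Z95 * se), rel=1e-12)


def test_prevalence_curve_decreasing_for_protective_covariate(fitted_default):
    curve = fitted_default.prevalence_curve(
        "platelets_pre", np.linspace(100, 350, 26)
    )
    assert fitted_default.coef_[0] > 0
    assert np.all(np.diff(curve["prevalence"]) < 0)


def test_prevalence_unknown_focal_rejected(fitted_default):
    with pytest.raises(ValueError, match="not a model covariate"):
        fitted_default.prevalence_curve("bogus", [1.0])


def test_shift_effect_direct_exponentiation():
    fit = toy_fit([-8.0, 0.0, 8.0], [math.log(1.002)], support=(0.0, 1000.0),
                  covs=("platelets_pre",))
    eff = shift_effect(fit, "platelets_pre", 50.0, x_ref=[200.0], threshold=500.0)
    assert eff.odds_factor == pytest.approx(1.002**50, rel=1e-12)
    assert eff.pct_rise_below == pytest.approx(10.506, abs=5e-3)
    # probability-scale drop composes two CDF calls
    p1 = 1 - predict_cdf(fit, np.array([200.0]), 500.0)
    p2 = 1 - predict_cdf(fit, np.array([250.0]), 500.0)
    assert eff.pct_drop_pph == pytest.approx(100 * (1 - p2 / p1), rel=1e-12)
    assert eff.pct_drop_pph > 0


def test_zero_shift_is_identity():
    fit = toy_fit([-1.0, 1.0], [0.3], covs=("platelets_pre",))
    eff = shift_effect(fit, "platelets_pre", 0.0, x_ref=[0.0], threshold=0.5)
    assert (eff.odds_factor, eff.pct_rise_below, eff.pct_drop_pph) == (1.0, 0.0, 0.0)


def test_log_scale_fit_runs_and_matches_sign(default_cohort):
    est = ContinuousOutcomeLogisticRegression(log_scale=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est.fit(default_cohort.covariate_matrix(), default_cohort.mbl)
    assert est.converged_
    # the protective platelet effect has the same sign on either scale
    assert est.coef_[0] > 0
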