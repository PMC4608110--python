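"""Treatment-effect estimation on a single cohort.

Two analysis arms:

* **IPTW** (observational design): maximum-likelihood logistic propensity
  model of treatment on the seven outcome predictors ``x4..x10``,
  stabilized inverse-probability weights, then a weighted Cox model of
  survival on treatment with a robust (sandwich) standard error.
* **Crude / RCT**: an unweighted univariate Cox model of survival on
  treatment with the model-based (inverse-information) standard error.
  The randomized analysis and the unadjusted observational analysis are
  numerically the same fit, differing only in interpretation.

The Cox fit itself is a dedicated Newton solver for the case-weighted
partial likelihood with a single covariate.  With continuous event times
ties have probability zero; in the measure-zero case of floating-point
ties the fit falls back to lifelines' Efron handling.  The robust
variance is the weighted score-residual (dfbeta) sandwich, matching
``survival::coxph(..., weights=, robust=TRUE)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.stats import norm

from .dgp import Cohort

__all__ = [
    "EstimationError",
    "PropensityFit",
    "CoxFit",
    "fit_propensity",
    "stabilized_weights",
    "fit_cox",
    "analyze_iptw",
    "analyze_crude",
    "analyze_rct",
]


class EstimationError(RuntimeError):
    """A model fit failed (non-convergence, separation, monotone likelihood)."""


@dataclass(frozen=True)
class PropensityFit:
    """Logistic propensity model fit: intercept + slopes on x4..x10."""

    coefficients: np.ndarray  # length 8: intercept first
    fitted: np.ndarray  # e-hat per subject, in (0,1)
    converged: bool


@dataclass(frozen=True)
class CoxFit:
    """A fitted treatment log-hazard-ratio with its Wald test."""

    log_hr: float
    se: float
    se_type: Literal["model", "robust"]
    n_used: int

    @property
    def z_statistic(self) -> float:
        return self.log_hr / self.se

    @property
    def p_value(self) -> float:
        return float(2.0 * norm.sf(abs(self.z_statistic)))

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.log_hr))


def fit_propensity(cohort: Cohort) -> PropensityFit:
    """ML logistic regression of treatment on the outcome predictors x4..x10.

    The propensity model deliberately uses the predictors of the outcome
    rather than the true treatment-selection covariates: conditioning on
    outcome predictors yields more efficient weighted estimates.
    """
    import statsmodels.api as sm

    z = np.asarray(cohort.treatment, dtype=float)
    if z.sum() < 1 or (1 - z).sum() < 1:
        raise EstimationError("both treatment arms must be present to fit a propensity model")
    design = sm.add_constant(cohort.covariates[:, 3:10], has_constant="add")
    try:
        res = sm.Logit(z, design).fit(disp=0, maxiter=100)
    except Exception as exc:  # perfect separation, singular Hessian, ...
        raise EstimationError(f"propensity model failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise EstimationError("propensity model did not converge")
    fitted = np.asarray(res.predict(design))
    if np.any((fitted <= 0) | (fitted >= 1)):
        raise EstimationError("propensity model produced boundary fitted probabilities")
    return PropensityFit(coefficients=np.asarray(res.params), fitted=fitted, converged=True)


def stabilized_weights(Z: np.ndarray, e_hat: np.ndarray) -> np.ndarray:
    """Stabilized inverse-probability-of-treatment weights.

    ``w_i = Z_i * Pr(Z=1)/e_i + (1-Z_i) * Pr(Z=0)/(1-e_i)`` with the
    marginal probabilities taken from the sample.  Stabilization keeps the
    mean weight near 1 and tames extreme weights; no trimming or
    truncation is applied.
    """
    Z = np.asarray(Z, dtype=float)
    e_hat = np.asarray(e_hat, dtype=float)
    if Z.shape != e_hat.shape:
        raise ValueError("treatment and propensity vectors must have the same length")
    if np.any((e_hat <= 0) | (e_hat >= 1)):
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    p_treat = Z.mean()
    return Z * (p_treat / e_hat) + (1 - Z) * ((1 - p_treat) / (1 - e_hat))


def _cox_newton(time, event, z, w):
    """Newton-Raphson on the weighted Cox partial likelihood, one covariate.

    Returns (beta, information, order, risk-set arrays) for downstream
    variance computation.  Assumes distinct event times (no ties).
    """
    order = np.argsort(time, kind="stable")
    z = z[order]
    d = event[order]
    w = w[order]
    wd = w * d
    sum_wd = wd.sum()
    if sum_wd <= 0:
        raise EstimationError("no events in the data")

    def risk_sums(beta):
        r = w * np.exp(beta * z)
        s0 = np.cumsum(r[::-1])[::-1]
        s1 = np.cumsum((r * z)[::-1])[::-1]
        s2 = np.cumsum((r * z * z)[::-1])[::-1]
        return s0, s1, s2

    # The partial log-likelihood is globally concave in beta for a single
    # covariate, so clamped Newton from 0 converges; the clamp guards
    # against overshoot from a far-off start.
    beta = 0.0
    for _ in range(50):
        s0, s1, s2 = risk_sums(beta)
        zbar = s1 / s0
        score = float(np.sum(wd * (z - zbar)))
        info = float(np.sum(wd * (s2 / s0 - zbar**2)))
        if info <= 0:
            raise EstimationError("non-positive information: monotone partial likelihood")
        step = np.clip(score / info, -1.0, 1.0)
        beta = beta + step
        if abs(beta) > 50:
            raise EstimationError("monotone likelihood: treatment effect estimate diverges")
        if abs(step) < 1e-9 * (1.0 + abs(beta)):
            break
    else:
        raise EstimationError("Cox partial-likelihood Newton iteration did not converge")
    s0, s1, _ = risk_sums(beta)
    return beta, info, order, (z, d, w, s0, s1)


def _robust_variance(beta, info, z, d, w, s0, s1):
    """Weighted score-residual (dfbeta) sandwich variance, single covariate.

    ``var = sum_i (w_i * s_i)^2 / info^2`` where ``s_i`` is the score
    residual of subject *i* — the Lin-Wei estimator extended with case
    weights, as in ``survival::coxph``.
    """
    zbar = s1 / s0
    wd = w * d
    a = np.cumsum(wd / s0)
    b = np.cumsum(wd * zbar / s0)
    resid = d * (z - zbar) - np.exp(beta * z) * (z * a - b)
    return float(np.sum((w * resid) ** 2) / info**2)


def _fit_cox_tied(time, event, z, w, variance):
    # float ties: delegate to lifelines' Efron handling (vanishingly rare here)
    import pandas as pd
    from lifelines import CoxPHFitter

    df = pd.DataFrame({"time": time, "event": event, "z": z, "w": w})
    cph = CoxPHFitter()
    try:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="time",
                event_col="event",
                weights_col="w",
                robust=(variance == "robust"),
                formula="z",
            )
    except Exception as exc:
        raise EstimationError(f"Cox fit failed: {exc}") from exc
    return float(cph.params_.iloc[0]), float(cph.standard_errors_.iloc[0])


def fit_cox(
    time: np.ndarray,
    event: np.ndarray,
    Z: np.ndarray,
    weights: Optional[np.ndarray] = None,
    variance: Literal["model", "robust"] = "model",
) -> CoxFit:
    """Cox proportional-hazards fit of survival on a single covariate.

    Maximizes the (case-weighted) partial likelihood by Newton-Raphson.
    ``variance="model"`` returns the inverse-information standard error;
    ``variance="robust"`` returns the score-residual sandwich appropriate
    for weighted estimation.  The p-value is the two-sided normal tail of
    the Wald statistic.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    z = np.asarray(Z, dtype=float)
    n = len(time)
    if not (len(event) == len(z) == n):
        raise ValueError("time, event and covariate vectors must have equal length")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != n:
            raise ValueError("weights length mismatch")
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise EstimationError("weights must be positive and finite")

    if np.unique(time).size < n:
        log_hr, se = _fit_cox_tied(time, event, z, w, variance)
        return CoxFit(log_hr=log_hr, se=se, se_type=variance, n_used=n)

    beta, info, order, (zs, ds, ws, s0, s1) = _cox_newton(time, event, z, w)
    if variance == "robust":
        var = _robust_variance(beta, info, zs, ds, ws, s0, s1)
    elif variance == "model":
        var = 1.0 / info
    else:
        raise ValueError(f"unknown variance type {variance!r}")
    return CoxFit(log_hr=float(beta), se=float(np.sqrt(var)), se_type=variance, n_used=n)


def analyze_iptw(cohort: Cohort) -> CoxFit:
    """IPTW pipeline: propensity fit -> stabilized weights -> weighted robust Cox."""
    if cohort.design != "observational":
        raise ValueError("IPTW analysis applies to observational cohorts")
    ps = fit_propensity(cohort)
    w = stabilized_weights(cohort.treatment, ps.fitted)
    return fit_cox(cohort.time, cohort.event, cohort.treatment, weights=w, variance="robust")


def analyze_crude(cohort: Cohort) -> CoxFit:
    """Unweighted univariate Cox fit with model-based standard error."""
    return fit_cox(cohort.time, cohort.event, cohort.treatment, variance="model")


# The randomized analysis is the same univariate fit; randomization makes it unbiased.
analyze_rct = analyze_crude
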