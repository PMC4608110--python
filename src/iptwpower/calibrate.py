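"""Scenario calibration: discrimination, prevalence, and marginal effect.

A simulation scenario is specified on interpretable scales — the
c-statistic of the treatment-selection model, the treatment prevalence,
and the *marginal* hazard ratio — but the data-generating process is
parameterized by logistic coefficients and a *conditional* log-hazard
ratio.  This module solves the three inverse problems:

1. ``compute_alpha_auc`` — the slope on ``x7`` that brings the
   treatment-selection model's c-statistic to a target, from the
   closed-form relation between the AUC of a logistic model and the
   variance of its linear predictor: with iid N(0,1) covariates the
   linear predictor is normal, and AUC = Phi(sigma / sqrt(2)), so the
   required total slope variance is ``2 * Phi^{-1}(AUC)^2``.
2. ``calibrate_intercept`` — the intercept that fixes the expected
   treated fraction at a target prevalence, by Gauss-Hermite quadrature
   over the normal linear predictor plus root-finding (deterministic).
3. ``calibrate_conditional_beta`` — the conditional log-hazard ratio
   that induces a target marginal hazard ratio.  Because the Cox model
   is non-collapsible there is no closed form: the solver simulates a
   large counterfactual population (each subject's event time under both
   treatment and control), fits a univariate Cox model to the stacked
   potential outcomes, and root-finds on the conditional coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm, rankdata

from .dgp import (
    OutcomeModelParams,
    TreatmentModelParams,
    draw_covariates,
)
from .estimate import fit_cox

__all__ = [
    "Scenario",
    "CalibrationReport",
    "InfeasibleTargetError",
    "EVENTS_GRID",
    "HR_GRID",
    "PREVALENCE_GRID",
    "AUC_GRID",
    "SELECTION_SLOPES",
    "compute_alpha_auc",
    "calibrate_intercept",
    "calibrate_conditional_beta",
    "treatment_model_for",
    "empirical_cstatistic",
]

# Factorial design of the power study: 13 x 3 x 3 x 5 = 585 observational cells.
EVENTS_GRID: tuple[int, ...] = tuple(range(200, 1000, 100)) + tuple(range(1000, 5001, 1000))
HR_GRID: tuple[float, ...] = (1.10, 1.25, 1.50)
PREVALENCE_GRID: tuple[float, ...] = (0.10, 0.25, 0.50)
AUC_GRID: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)

# weak / moderate / strong treatment-selection odds ratios (used whenever AUC > 0.5)
SELECTION_SLOPES: dict[str, float] = {
    "alpha_w": float(np.log(1.05)),
    "alpha_m": float(np.log(1.10)),
    "alpha_s": float(np.log(1.25)),
}


class InfeasibleTargetError(ValueError):
    """The calibration target cannot be reached under the fixed model structure."""


@dataclass(frozen=True)
class Scenario:
    """One cell of the factorial design.

    ``n_events`` doubles as the sample size because there is no
    censoring.  ``marginal_hr`` is the population-average hazard ratio
    the design should exhibit; ``auc`` is the c-statistic of the
    treatment-selection model (0.5 = randomized-like selection, i.e. no
    confounding).
    """

    n_events: int
    marginal_hr: float
    prevalence: float
    auc: float
    design: Literal["observational", "rct"] = "observational"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be positive")
        if self.marginal_hr <= 0:
            raise ValueError("marginal_hr must be positive")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if not 0.5 <= self.auc < 1:
            raise ValueError("auc must lie in [0.5, 1)")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.design not in ("observational", "rct"):
            raise ValueError(f"unknown design {self.design!r}")

    def validate_paper_grid(self) -> None:
        """Raise if this scenario is not a cell of the published factorial grid."""
        ok = (
            self.n_events in EVENTS_GRID
            and self.marginal_hr in HR_GRID
            and self.prevalence in PREVALENCE_GRID
            and self.auc in AUC_GRID
        )
        if not ok:
            raise ValueError(f"scenario {self} is not on the factorial grid")


@dataclass(frozen=True)
class CalibrationReport:
    """Bookkeeping for a solved calibration problem."""

    target: float
    achieved: float
    iterations: int
    tolerance: float
    population_size: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if abs(self.achieved - self.target) > self.tolerance:
            raise ValueError("calibration report violates its own tolerance")


def compute_alpha_auc(
    target_auc: float,
    alpha_w: float = SELECTION_SLOPES["alpha_w"],
    alpha_m: float = SELECTION_SLOPES["alpha_m"],
    alpha_s: float = SELECTION_SLOPES["alpha_s"],
) -> float:
    """Slope on x7 that brings the selection model's c-statistic to ``target_auc``.

    The seven signed slopes contribute variance ``2*(aW^2 + aM^2 + aS^2)``
    plus ``alpha_auc^2``; setting the total to ``2*Phi^{-1}(AUC)^2`` gives

        alpha_auc = sqrt(2*Phi^{-1}(AUC)^2 - 2*aW^2 - 2*aM^2 - 2*aS^2)

    A target of exactly 0.5 means no selection at all and is handled by
    zeroing every coefficient (see :func:`treatment_model_for`), not by
    this formula.
    """
    if not 0.5 <= target_auc < 1:
        raise ValueError("target c-statistic must lie in [0.5, 1)")
    radicand = 2 * norm.ppf(target_auc) ** 2 - 2 * (alpha_w**2 + alpha_m**2 + alpha_s**2)
    if radicand < 0:
        raise InfeasibleTargetError(
            f"target c-statistic {target_auc} is below what the fixed slopes already induce"
        )
    return float(np.sqrt(radicand))


def _expected_prevalence(alpha_0: float, sigma: float, nodes, wts) -> float:
    # E[expit(alpha_0 + sigma*G)], G ~ N(0,1), by Gauss-Hermite quadrature
    return float(np.sum(wts * expit(alpha_0 + sigma * nodes)))


def calibrate_intercept(
    target_prevalence: float,
    params: TreatmentModelParams | None = None,
    *,
    slope_variance: Optional[float] = None,
    n_nodes: int = 201,
    tol: float = 1e-9,
) -> float:
    """Intercept fixing the expected treated fraction at ``target_prevalence``.

    With iid standard-normal covariates the slope part of the linear
    predictor is N(0, slope_variance), so the expected prevalence is a
    one-dimensional integral, evaluated by Gauss-Hermite quadrature and
    inverted by bracketed root-finding.  Deterministic; accurate to well
    below 1e-6 on the probability scale.
    """
    if not 0 < target_prevalence < 1:
        raise ValueError("target prevalence must lie in (0, 1)")
    if slope_variance is None:
        if params is None:
            raise ValueError("provide either params or slope_variance")
        slope_variance = params.slope_variance
    sigma = float(np.sqrt(slope_variance))
    if sigma == 0.0:
        return float(logit(target_prevalence))
    t, wts = np.polynomial.hermite_e.hermegauss(n_nodes)
    wts = wts / np.sqrt(2 * np.pi)
    lo, hi = logit(target_prevalence) - 6 * sigma - 1, logit(target_prevalence) + 6 * sigma + 1
    return float(
        brentq(
            lambda a0: _expected_prevalence(a0, sigma, t, wts) - target_prevalence,
            lo,
            hi,
            xtol=tol,
        )
    )


def treatment_model_for(auc: float, prevalence: float) -> TreatmentModelParams:
    """Fully calibrated treatment-selection model for a (c-statistic, prevalence) cell.

    At a target c-statistic of 0.5 every coefficient is zero and treatment
    is a pure Bernoulli(prevalence) draw; otherwise the three fixed slopes
    are used, ``alpha_auc`` comes from the closed form, and the intercept
    is calibrated to the prevalence.
    """
    if auc == 0.5:
        return TreatmentModelParams(alpha_0=float(logit(prevalence)))
    a_auc = compute_alpha_auc(auc)
    base = TreatmentModelParams(alpha_0=0.0, **SELECTION_SLOPES, alpha_auc=a_auc)
    a0 = calibrate_intercept(prevalence, base)
    return TreatmentModelParams(alpha_0=a0, **SELECTION_SLOPES, alpha_auc=a_auc)


def calibrate_conditional_beta(
    target_marginal_hr: float,
    oparams: OutcomeModelParams | None = None,
    population_size: int = 1_000_000,
    tolerance: float = 1e-3,
    rng: np.random.Generator | None = None,
) -> tuple[float, CalibrationReport]:
    """Conditional log-hazard ratio inducing a target marginal hazard ratio.

    Simulates ``population_size`` subjects' covariates and, for each
    candidate coefficient, both potential event times (under control and
    under treatment) from the Weibull outcome model; the stacked 2N
    potential outcomes are fit with a univariate Cox model whose
    coefficient estimates the marginal log-hazard ratio.  A bracketed
    root search over ``[0, 3*log(target)]`` (non-collapsibility puts the
    solution above ``log(target)``) drives the stacked estimate to
    ``log(target_marginal_hr)`` within ``tolerance``.

    The two potential-outcome uniforms are drawn independently; coupling
    them would not change the probability limit of the stacked estimate.
    Returns ``(beta_treat, report)``.
    """
    if target_marginal_hr <= 0:
        raise ValueError("target marginal hazard ratio must be positive")
    if population_size < 10**5:
        raise ValueError("population_size must be at least 1e5 for a stable calibration")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    oparams = oparams if oparams is not None else OutcomeModelParams()
    rng = rng if rng is not None else np.random.default_rng()

    log_target = float(np.log(target_marginal_hr))
    if target_marginal_hr == 1.0:
        return 0.0, CalibrationReport(
            target=0.0, achieved=0.0, iterations=0, tolerance=tolerance,
            population_size=population_size,
        )

    n = population_size
    X = draw_covariates(n, rng)
    lp_cov = X @ oparams.covariate_slopes
    u0 = np.maximum(rng.random(n), np.finfo(float).tiny)
    u1 = np.maximum(rng.random(n), np.finfo(float).tiny)
    inv_eta = 1.0 / oparams.eta
    t0 = (-np.log(u0) / (oparams.lam * np.exp(lp_cov))) ** inv_eta
    t1_base = (-np.log(u1) / (oparams.lam * np.exp(lp_cov))) ** inv_eta
    z = np.concatenate([np.zeros(n), np.ones(n)])
    event = np.ones(2 * n)

    evals = 0

    def marginal_loghr(beta: float) -> float:
        nonlocal evals
        evals += 1
        # under PH, adding beta to LP scales the treated times by exp(-beta/eta)
        times = np.concatenate([t0, t1_base * np.exp(-beta * inv_eta)])
        return fit_cox(times, event, z).log_hr

    lo, hi = 0.0, 3.0 * abs(log_target) * np.sign(log_target)
    if log_target < 0:
        lo, hi = hi, lo
    f = lambda b: marginal_loghr(b) - log_target
    f_hi = f(hi)
    if (log_target > 0 and f_hi < 0) or (log_target < 0 and f(lo) > 0):
        raise RuntimeError(
            f"marginal effect target {target_marginal_hr} not bracketed in [{lo}, {hi}]"
        )
    beta = float(brentq(f, lo, hi, xtol=tolerance / 2))
    achieved = marginal_loghr(beta)
    return beta, CalibrationReport(
        target=log_target,
        achieved=achieved,
        iterations=evals,
        tolerance=tolerance,
        population_size=population_size,
    )


def empirical_cstatistic(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney concordance: P(score_treated > score_control) + 0.5*P(tie).

    Rank-based implementation; equivalent to the area under the ROC curve
    of ``scores`` for discriminating ``labels``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute a c-statistic")
    if n1 + n0 != len(labels):
        raise ValueError("labels must be binary 0/1")
    ranks = rankdata(scores)
    u = np.sum(ranks[labels == 1]) - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
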