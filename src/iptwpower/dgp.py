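"""Synthetic cohort generation for observational and randomized designs.

The data-generating process simulates subjects with ten independent
standard-normal baseline covariates.  In the observational design,
treatment is assigned by a logistic treatment-selection model in which
covariates ``x1..x7`` carry signal (two of them, ``x4`` and ``x6``, with
negative signs, encoding a treatment-risk paradox: higher-risk subjects
are less likely to be treated).  Event times follow a Weibull
proportional-hazards model whose linear predictor involves treatment and
covariates ``x4..x10``, generated by inverse-transform sampling.  There
is no censoring: every subject's event is observed, so the number of
events equals the sample size.

The overlap between the two covariate sets (``x4..x7``) is what creates
confounding; ``x1..x3`` are instruments and ``x8..x10`` are pure risk
factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "N_COVARIATES",
    "TreatmentModelParams",
    "OutcomeModelParams",
    "Cohort",
    "DegenerateSampleWarning",
    "draw_covariates",
    "treatment_probabilities",
    "assign_treatment",
    "generate_survival_times",
    "simulate_observational_cohort",
    "simulate_rct_cohort",
]

N_COVARIATES = 10

Design = Literal["observational", "rct"]


class DegenerateSampleWarning(UserWarning):
    """A simulated cohort had fewer than two subjects in one arm and was redrawn."""


@dataclass(frozen=True)
class TreatmentModelParams:
    """Coefficients of the logistic treatment-selection model.

    The linear predictor is::

        alpha_0 + aW*x1 + aM*x2 + aS*x3 - aW*x4 + aM*x5 - aS*x6 + aAUC*x7

    The sign pattern is fixed: ``x4`` and ``x6`` lower the odds of
    treatment while raising outcome risk (treatment-risk paradox:
    higher-risk subjects are less likely to be treated), and
    ``x8..x10`` never enter.  ``alpha_auc`` is the extra slope on
    ``x7`` used to dial the model's discrimination (c-statistic);
    because ``x7`` is also the strongest outcome risk factor, raising
    the c-statistic deepens the confounding of the crude hazard ratio.
    """

    alpha_0: float
    alpha_w: float = 0.0
    alpha_m: float = 0.0
    alpha_s: float = 0.0
    alpha_auc: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha_auc < 0:
            raise ValueError("alpha_auc must be nonnegative")

    @property
    def slopes(self) -> np.ndarray:
        """Signed slope vector over the ten covariate columns."""
        a = np.zeros(N_COVARIATES)
        a[0] = self.alpha_w
        a[1] = self.alpha_m
        a[2] = self.alpha_s
        a[3] = -self.alpha_w
        a[4] = self.alpha_m
        a[5] = -self.alpha_s
        a[6] = self.alpha_auc
        return a

    @property
    def slope_variance(self) -> float:
        """Variance of the slope part of the linear predictor under iid N(0,1) covariates."""
        return float(np.sum(self.slopes**2))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = _check_covariates(X)
        return self.alpha_0 + X @ self.slopes


@dataclass(frozen=True)
class OutcomeModelParams:
    """Weibull proportional-hazards outcome model.

    Hazard for subject *i* is ``lam * eta * t**(eta-1) * exp(LP_i)`` with::

        LP = beta_treat*Z + bW*x4 + bM*x5 + bS*x6 + bVS*x7 + bW*x8 + bM*x9 + bS*x10

    ``beta_treat`` is the *conditional* log-hazard ratio of treatment;
    because the model is non-collapsible, the induced marginal hazard
    ratio is smaller in magnitude (see :mod:`iptwpower.calibrate`).
    Default covariate effects are weak/moderate/strong/very strong
    hazard ratios of 1.25, 1.5, 1.75 and 2.
    """

    beta_treat: float = 0.0
    beta_w: float = field(default_factory=lambda: float(np.log(1.25)))
    beta_m: float = field(default_factory=lambda: float(np.log(1.5)))
    beta_s: float = field(default_factory=lambda: float(np.log(1.75)))
    beta_vs: float = field(default_factory=lambda: float(np.log(2.0)))
    lam: float = 0.00002
    eta: float = 2.0

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.eta <= 0:
            raise ValueError("Weibull scale lam and shape eta must be positive")

    @property
    def covariate_slopes(self) -> np.ndarray:
        b = np.zeros(N_COVARIATES)
        b[3] = self.beta_w
        b[4] = self.beta_m
        b[5] = self.beta_s
        b[6] = self.beta_vs
        b[7] = self.beta_w
        b[8] = self.beta_m
        b[9] = self.beta_s
        return b

    def linear_predictor(self, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
        X = _check_covariates(X)
        return self.beta_treat * np.asarray(Z, dtype=float) + X @ self.covariate_slopes

    def with_beta_treat(self, beta_treat: float) -> "OutcomeModelParams":
        return replace(self, beta_treat=float(beta_treat))


@dataclass(frozen=True)
class Cohort:
    """One simulated dataset: covariates, treatment, uncensored event times."""

    covariates: np.ndarray
    treatment: np.ndarray
    time: np.ndarray
    event: np.ndarray
    design: Design

    def __post_init__(self) -> None:
        n = len(self.treatment)
        if not (self.covariates.shape == (n, N_COVARIATES) and len(self.time) == n == len(self.event)):
            raise ValueError("cohort fields have inconsistent lengths")
        if np.any(self.time <= 0):
            raise ValueError("event times must be strictly positive")

    def __len__(self) -> int:
        return len(self.treatment)

    @property
    def n_treated(self) -> int:
        return int(self.treatment.sum())

    def to_frame(self):
        """Flat per-subject table (x1..x10, z, time, event) for export/debugging."""
        import pandas as pd

        d = {f"x{j + 1}": self.covariates[:, j] for j in range(N_COVARIATES)}
        d.update(z=self.treatment, time=self.time, event=self.event)
        return pd.DataFrame(d)


def _check_covariates(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_COVARIATES:
        raise ValueError(f"covariate matrix must be n x {N_COVARIATES}, got shape {X.shape}")
    return X


def draw_covariates(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an ``n x 10`` matrix of iid standard-normal baseline covariates."""
    if n < 1:
        raise ValueError("subject count must be at least 1")
    return rng.standard_normal((n, N_COVARIATES))


def treatment_probabilities(X: np.ndarray, params: TreatmentModelParams) -> np.ndarray:
    """Per-subject treatment probability from the logistic selection model."""
    from scipy.special import expit

    return expit(params.linear_predictor(X))


def assign_treatment(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli(p_i) treatment indicators."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("treatment probabilities must lie strictly in (0, 1)")
    return (rng.random(p.shape) < p).astype(np.int8)


def _open_uniform(n: int, rng: np.random.Generator) -> np.ndarray:
    # standard_uniform is [0,1); shift off exact zeros so log(u) is finite
    u = rng.random(n)
    tiny = np.finfo(float).tiny
    return np.where(u > 0.0, u, tiny)


def generate_survival_times(
    X: np.ndarray,
    Z: np.ndarray,
    params: OutcomeModelParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Weibull event times by inverse-transform sampling.

    For each subject draws ``u ~ U(0,1)`` (open interval) and returns
    ``T = (-log(u) / (lam * exp(LP)))**(1/eta)``.  With shape ``eta=2``
    and no censoring, ``T**2`` is exponential with rate ``lam*exp(LP)``.
    """
    X = _check_covariates(X)
    Z = np.asarray(Z)
    if len(Z) != X.shape[0]:
        raise ValueError("treatment vector length does not match covariate matrix")
    lp = params.linear_predictor(X, Z)
    u = _open_uniform(len(Z), rng)
    return (-np.log(u) / (params.lam * np.exp(lp))) ** (1.0 / params.eta)


_MAX_REDRAWS = 100


def _finish_cohort(
    X: np.ndarray,
    Z: np.ndarray,
    oparams: OutcomeModelParams,
    rng: np.random.Generator,
    design: Design,
) -> Cohort:
    time = generate_survival_times(X, Z, oparams, rng)
    event = np.ones(len(Z), dtype=np.int8)
    return Cohort(covariates=X, treatment=Z, time=time, event=event, design=design)


def simulate_observational_cohort(
    scenario,
    tparams: TreatmentModelParams,
    oparams: OutcomeModelParams,
    rng: np.random.Generator,
) -> Cohort:
    """Simulate one observational cohort of ``scenario.n_events`` subjects.

    Treatment follows the logistic selection model; event times follow the
    Weibull outcome model.  Cohorts with fewer than two subjects in either
    arm (possible only at small n and low prevalence) are redrawn with a
    :class:`DegenerateSampleWarning`, since a Cox fit on them is undefined.
    """
    n = scenario.n_events
    for _ in range(_MAX_REDRAWS):
        X = draw_covariates(n, rng)
        p = treatment_probabilities(X, tparams)
        Z = assign_treatment(p, rng)
        if 2 <= Z.sum() <= n - 2:
            return _finish_cohort(X, Z, oparams, rng, "observational")
        warnings.warn(
            f"degenerate cohort (n={n}, treated={int(Z.sum())}); redrawing",
            DegenerateSampleWarning,
            stacklevel=2,
        )
    raise RuntimeError("could not draw a non-degenerate cohort; check scenario parameters")


def simulate_rct_cohort(
    scenario,
    oparams: OutcomeModelParams,
    rng: np.random.Generator,
) -> Cohort:
    """Simulate one randomized cohort: Bernoulli(prevalence) treatment, same outcome model.

    Covariates are drawn and stored even though the randomized analysis
    ignores them — they still drive event times and support balance
    diagnostics.
    """
    n = scenario.n_events
    prev = scenario.prevalence
    if not 0 < prev < 1:
        raise ValueError("prevalence must lie strictly in (0, 1)")
    for _ in range(_MAX_REDRAWS):
        X = draw_covariates(n, rng)
        Z = (rng.random(n) < prev).astype(np.int8)
        if 2 <= Z.sum() <= n - 2:
            return _finish_cohort(X, Z, oparams, rng, "rct")
        warnings.warn(
            f"degenerate cohort (n={n}, treated={int(Z.sum())}); redrawing",
            DegenerateSampleWarning,
            stacklevel=2,
        )
    raise RuntimeError("could not draw a non-degenerate cohort; check scenario parameters")
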