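"""Monte Carlo power, type-I error, and bias estimation.

Statistical power is estimated as the proportion of simulated replicates
in which the treatment-effect Wald test rejects at level alpha; a
binomial Monte Carlo standard error accompanies every estimate.
Replicates whose model fits fail (non-convergence, separation) are
excluded from the denominator and reported, never silently redrawn.

For the randomized design a closed-form benchmark exists
(:func:`schoenfeld_power`); the Monte Carlo machinery is cross-checked
against it.  No closed form exists for the IPTW analysis — that is the
reason the study is a simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.stats import norm

from .calibrate import Scenario
from .dgp import (
    OutcomeModelParams,
    TreatmentModelParams,
    simulate_observational_cohort,
    simulate_rct_cohort,
)
from .estimate import CoxFit, EstimationError, analyze_crude, analyze_iptw, analyze_rct

__all__ = [
    "PowerResult",
    "BiasResult",
    "run_replicates",
    "estimate_power",
    "estimate_type1_error",
    "estimate_relative_bias",
    "summarize_bias",
    "schoenfeld_power",
]

Analysis = Literal["iptw", "crude", "rct"]


@dataclass(frozen=True)
class PowerResult:
    """Monte Carlo power (or size) estimate for one scenario."""

    scenario: Scenario
    analysis: Analysis
    n_reps: int
    n_significant: int
    n_failed: int
    mean_log_hr: float

    @property
    def n_effective(self) -> int:
        return self.n_reps - self.n_failed

    @property
    def power(self) -> float:
        return self.n_significant / self.n_effective

    @property
    def mc_se(self) -> float:
        p = self.power
        return float(np.sqrt(p * (1 - p) / self.n_effective))


@dataclass(frozen=True)
class BiasResult:
    """Relative bias of an estimated marginal hazard ratio for one scenario.

    The replicate log-hazard-ratio estimates are averaged on the log
    scale and exponentiated; the relative bias is quoted in percent
    against the scenario's true marginal hazard ratio.
    """

    scenario: Scenario
    analysis: Analysis
    n_reps: int
    n_failed: int
    mean_log_hr: float

    @property
    def relative_bias_pct(self) -> float:
        hr_true = self.scenario.marginal_hr
        return float(100.0 * (np.exp(self.mean_log_hr) - hr_true) / hr_true)


_ANALYZERS = {"iptw": analyze_iptw, "crude": analyze_crude, "rct": analyze_rct}


def run_replicates(
    scenario: Scenario,
    tparams: TreatmentModelParams | None,
    oparams: OutcomeModelParams,
    n_reps: int,
    rng: np.random.Generator,
    analyses: Sequence[Analysis] | None = None,
) -> tuple[dict[Analysis, list[CoxFit]], int]:
    """Simulate ``n_reps`` cohorts and run the requested analyses on each.

    For an observational scenario the default analysis is IPTW; for an
    RCT scenario, the univariate randomized analysis.  Several analyses
    (e.g. IPTW and crude) may share the same simulated cohorts.  Returns
    ``(fits_by_analysis, n_failed)``; a replicate on which any requested
    analysis fails is dropped from all of them, keeping denominators
    aligned.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if analyses is None:
        analyses = ("iptw",) if scenario.design == "observational" else ("rct",)
    fits: dict[Analysis, list[CoxFit]] = {a: [] for a in analyses}
    n_failed = 0
    for _ in range(n_reps):
        if scenario.design == "observational":
            if tparams is None:
                raise ValueError("observational scenarios need treatment-model parameters")
            cohort = simulate_observational_cohort(scenario, tparams, oparams, rng)
        else:
            cohort = simulate_rct_cohort(scenario, oparams, rng)
        try:
            rep_fits = {a: _ANALYZERS[a](cohort) for a in analyses}
        except EstimationError:
            n_failed += 1
            continue
        for a, f in rep_fits.items():
            fits[a].append(f)
    if n_failed == n_reps:
        raise EstimationError(f"all {n_reps} replicates failed for scenario {scenario}")
    return fits, n_failed


def _power_from_fits(scenario, analysis, fits, n_reps, n_failed) -> PowerResult:
    n_sig = sum(f.p_value <= scenario.alpha for f in fits)
    mean_log_hr = float(np.mean([f.log_hr for f in fits]))
    return PowerResult(
        scenario=scenario,
        analysis=analysis,
        n_reps=n_reps,
        n_significant=int(n_sig),
        n_failed=n_failed,
        mean_log_hr=mean_log_hr,
    )


def estimate_power(
    scenario: Scenario,
    tparams: TreatmentModelParams | None,
    oparams: OutcomeModelParams,
    n_reps: int,
    rng: np.random.Generator,
    analysis: Analysis | None = None,
) -> PowerResult:
    """Monte Carlo power: proportion of replicates with p <= alpha.

    The p <= alpha convention is applied uniformly to both designs; with
    continuous test statistics the boundary event has probability zero.
    """
    if analysis is None:
        analysis = "iptw" if scenario.design == "observational" else "rct"
    fits, n_failed = run_replicates(scenario, tparams, oparams, n_reps, rng, (analysis,))
    return _power_from_fits(scenario, analysis, fits[analysis], n_reps, n_failed)


def estimate_type1_error(
    scenario: Scenario,
    tparams: TreatmentModelParams | None,
    oparams: OutcomeModelParams,
    n_reps: int,
    rng: np.random.Generator,
    analysis: Analysis | None = None,
) -> PowerResult:
    """Empirical size: same machinery as power, under a true null effect.

    Requires a null scenario (marginal hazard ratio 1, hence a zero
    conditional treatment coefficient).
    """
    if scenario.marginal_hr != 1.0:
        raise ValueError("type-I error requires a scenario with marginal_hr = 1")
    if oparams.beta_treat != 0.0:
        raise ValueError("type-I error requires beta_treat = 0 (null effect is collapsible)")
    return estimate_power(scenario, tparams, oparams, n_reps, rng, analysis)


def estimate_relative_bias(
    scenario: Scenario,
    tparams: TreatmentModelParams | None,
    oparams: OutcomeModelParams,
    n_reps: int,
    rng: np.random.Generator,
    analysis: Analysis = "crude",
) -> BiasResult:
    """Relative bias of one analysis's marginal hazard-ratio estimate."""
    fits, n_failed = run_replicates(scenario, tparams, oparams, n_reps, rng, (analysis,))
    mean_log_hr = float(np.mean([f.log_hr for f in fits[analysis]]))
    return BiasResult(
        scenario=scenario,
        analysis=analysis,
        n_reps=n_reps,
        n_failed=n_failed,
        mean_log_hr=mean_log_hr,
    )


def summarize_bias(results: Iterable[BiasResult]) -> dict[str, float]:
    """Min / median / max relative bias (percent) over a set of scenario cells."""
    biases = [r.relative_bias_pct for r in results]
    if not biases:
        raise ValueError("no bias results to summarize")
    return {
        "min": float(np.min(biases)),
        "median": float(np.median(biases)),
        "max": float(np.max(biases)),
    }


def schoenfeld_power(
    n_events: int,
    prevalence: float,
    log_hr: float,
    alpha: float = 0.05,
) -> float:
    """Closed-form power of the Cox test in a randomized trial.

    ``Phi( sqrt(D * p * (1-p)) * |log HR| - z_{1-alpha/2} )`` with ``D``
    the number of events and ``p`` the allocation probability.  Valid for
    the randomized design only; no analogue exists for IPTW.
    """
    if n_events < 1:
        raise ValueError("n_events must be at least 1")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    z_crit = norm.ppf(1 - alpha / 2)
    return float(
        norm.cdf(np.sqrt(n_events * prevalence * (1 - prevalence)) * abs(log_hr) - z_crit)
    )
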