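# Methods

## Data-generating process

Subjects are exchangeable draws from a ten-dimensional standard normal.
Treatment selection (observational design) is logistic in x₁…x₇ with
the fixed slope pattern (+α_W, +α_M, +α_S, −α_W, +α_M, −α_S, +α_AUC);
event times are Weibull, generated by inverting the survival function:
u ~ U(0,1), T = (−log u / (λ e^LP))^{1/η}. The outcome linear predictor
LP involves treatment and x₄…x₁₀, so x₄…x₇ are confounders, x₁…x₃ are
instruments, and x₈…x₁₀ are pure risk factors. x₄ and x₆ enter
selection negatively and outcome positively (treatment-risk paradox).
There is no censoring: the event count equals the sample size, which is
why scenarios are indexed by number of events.

Fixed parameters: λ = 2·10⁻⁵, η = 2, outcome hazard ratios
(1.25, 1.5, 1.75, 2) for weak/moderate/strong/very-strong covariates,
selection odds ratios (1.05, 1.10, 1.25) whenever the target
c-statistic exceeds 0.5. The uniform sampler is open at 0 (zero draws
are mapped to the smallest positive float) so log u is always finite.

Degenerate cohorts — fewer than two subjects in either arm, relevant
only at 200 events and 10% prevalence where the probability is ~10⁻⁶ —
are redrawn from the continuing random stream with a
`DegenerateSampleWarning`, because a Cox fit on them is undefined.
Covariates are generated for randomized cohorts too, both because they
drive event times and to support balance diagnostics.

## Calibration

**Discrimination.** α_AUC = √(2Φ⁻¹(AUC)² − 2α_W² − 2α_M² − 2α_S²),
i.e. the total slope variance of the selection linear predictor is set
to 2Φ⁻¹(AUC)². This is the classical relation between a normally
distributed score and its concordance statistic; it is exact when the
score distributions within each class are normal with a shifted mean
(the discriminant-analysis direction), but for a logistic selection
model on a marginally normal predictor it overstates discrimination.
The realized empirical c-statistics are 0.599 / 0.690 / 0.771 / 0.846
at nominal 0.6 / 0.7 / 0.8 / 0.9 (confirmed both by numerical double
integration and by 10⁶-subject simulation). The formula is kept as the
package's calibration definition because every downstream quantity
(intercept range, bias table) is defined in terms of it; scenario
labels should be read as nominal discrimination levels. A target of
exactly 0.5 zeroes the whole coefficient set instead of evaluating the
formula.

**Prevalence.** With iid normal covariates the slope part of the
selection linear predictor is N(0, σ²), so the expected treated
fraction is a one-dimensional integral; it is evaluated with 201-node
Gauss–Hermite quadrature and inverted by Brent root-finding to 10⁻⁹.
Targeting the expectation (rather than the per-sample fraction) is the
only well-defined choice when treatment is then drawn Bernoulli; the
solver is fully deterministic. Across the 15 (prevalence × nominal
c-statistic) design cells the intercepts range from −3.236 to 0 with
median −1.224.

**Marginal effect.** The conditional log-HR β_treat exceeds the
marginal log-HR whenever prognostic covariates are marginalized out of
a Cox model (non-collapsibility), and no closed-form map exists. The
solver draws a counterfactual population (default 10⁶ subjects),
generates each subject's event time under control and under treatment
with independent uniforms, stacks the 2N potential outcomes, and fits a
univariate Cox model whose coefficient estimates the marginal log-HR;
Brent root-finding over [0, 3·log(target)] drives it to the target
within 10⁻³. Under proportional hazards a candidate β only rescales the
treated potential times by e^{−β/η}, so the population is simulated
once. Stacked-counterfactual and single-outcome-randomized formulations
were verified to agree (the probability limit depends only on the two
arms' marginal hazards); independent uniforms for the two potential
outcomes are used because coupling does not change that limit. One
solve has a sampling SE of ≈0.003 on β at 10⁶ subjects.

Two subtleties of the marginal estimand worth knowing:

* It is mildly **prevalence-dependent**: the marginal hazard ratio is
  time-varying, and the Cox coefficient is a risk-set-weighted average
  of it, so the estimand at 10% treated differs from the 50/50
  calibration target by up to ≈ +1 percentage point on the hazard-ratio
  scale at target HR 1.5. Calibration fixes the 50/50 estimand.
* IPTW with estimated propensity scores has a small positive
  **finite-sample bias** under strong selection: ≈ +0.011 on the log-HR
  scale at 5000 events and nominal c-statistic 0.8–0.9, vanishing by
  20000 events. This is estimator behavior (large stabilized weights),
  not a defect of the fit, and matches R `coxph` exactly.

## Estimation arms

The propensity model is an unpenalized ML logistic regression of
treatment on the seven outcome predictors x₄…x₁₀ (outcome predictors
make better propensity covariates than the true selection variables).
Stabilized weights w = Z·Pr(Z=1)/ê + (1−Z)·Pr(Z=0)/(1−ê) use the
sample treated fraction and are never trimmed or truncated. The
treatment effect is a univariate Cox fit: case-weighted with the
weighted score-residual (dfbeta) sandwich variance for the IPTW arm,
unweighted with inverse-information variance for the randomized/crude
arm. Significance is the two-sided normal tail of the Wald statistic;
p ≤ α (inclusive) counts as rejection in both designs — with
continuous statistics the boundary has probability zero.

The Cox solver is a clamped Newton iteration on the partial likelihood,
which is globally concave for a single covariate; event times are
continuous so ties have probability zero, and in the measure-zero case
of floating-point ties the fit falls back to lifelines' Efron handling.
Validation: brute-force grid-search maximization of the hand-written
partial likelihood on ≤8-subject fixtures (10⁻³ agreement, randomized
via hypothesis), frozen R `survival::coxph` values on a 30-subject
weighted, censored fixture (10⁻⁸ agreement on coefficient, model SE and
robust SE), and lifelines on a 2000-subject weighted IPTW fit (10⁻⁵).
Fits that fail (separation, monotone likelihood, non-convergence) raise
a typed error; Monte Carlo loops count such replicates and exclude them
from the denominator rather than redrawing them.

## Monte Carlo machinery

Power is the proportion of replicates with p ≤ α, reported with the
binomial standard error √(p̂(1−p̂)/n_eff). Type-I error uses the same
machinery at marginal HR 1 (the null is collapsible, so β_treat = 0).
Relative bias averages replicate log-HRs, exponentiates, and reports
100·(exp(mean) − HR_true)/HR_true; averaging on the log scale treats
over- and under-estimation symmetrically. Note the sign convention: a
crude analysis under this DGP's confounding structure *over*estimates
the hazard ratio, so the package's bias table has positive entries at
high discrimination whose magnitudes mirror the classical presentation
of this confounding table with the opposite sign.

The factorial grid (13 event counts × 3 hazard ratios × 3 prevalences
× 5 c-statistics = 585 observational cells plus matched randomized
cells) is orchestrated by `run_grid`. The conditional-effect
calibration is cached per hazard-ratio level (3 solves for the full
grid); treatment-model calibration is deterministic and cached per
(c-statistic, prevalence). Randomized cells do not depend on the
c-statistic and are simulated once per (events, HR, prevalence), their
rows replicated across c-statistic levels. Seeds derive from a single
base seed through SHA-256-keyed `SeedSequence` spawn keys built from
the cell's factor levels, never from execution order, so cells are
individually reproducible, the grid is resumable, and subsets agree
with full runs. Results go to a flat CSV with a commented metadata
header (config hash, package version, base seed).

Default problem sizes: desk mode uses events ∈ {200, 500, 1000, 5000}
and 200 replicates per cell; the full design at 1000 replicates is
behind `paper_mode=True` / `--paper-mode` and is hours-scale. The
acceptance script uses 10⁶-subject calibrations, 200 replicates per
bias cell, and 1000 replicates for the type-I error — sizes at which
every reported quantity's Monte Carlo error is well below the
differences of interest.

## What the simulations do and do not show

The generator reproduces the study conditions exactly: iid normal
covariates, a correctly specified logistic selection model, Weibull
outcomes, no censoring, no unmeasured confounding. Passing tests
therefore demonstrate properties of the *methods* under ideal
measurement, not robustness to real-data features: correlated or
non-normal covariates, propensity-model misspecification, censoring
(power would track the event count, but the no-censoring shortcut of
equating events with sample size would no longer hold), competing
risks, and time-varying treatment are all out of scope. The power
comparison is also design-matched — both designs see the same number of
events — which is the planning question, not a statement about the
relative credibility of the two designs.
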