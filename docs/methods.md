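# Methods

This note records the statistical model, the choices made where the design
was genuinely open, and what the synthetic-data tests do and do not
establish.

## Scope and estimands

The package estimates, for a single cancer in a female population, the
stratum-level incidence and mortality rates on a province × 5-year
age-group × calendar-year grid (age groups 15–19 … 85+, A = 15 by
default), and derives from them: all-ages counts, directly age-standardized
rates (ASIR/ASDR), years of life lost (YLL) and its standardized rate
(ASYR), the mortality-to-incidence ratio (MIR), log-linear annual percent
change (APC), a growth/aging/rate decomposition of the change in case
counts, and age-period-cohort effects under the Intrinsic Estimator.

## Synthetic registry generator

Real registry inputs of this kind are confidential, so the generator is a
first-class module, not a test fixture.  It emulates:

- a latent log-linear truth: log incidence = age profile + province
  intercept (iid normal, SD 0.25) + spatially correlated province effect
  (white noise through a one-step smoothed-adjacency kernel, standardized
  to a configurable marginal SD) + per-province log-linear time trend.
  The default trend is +4.5%/year, in the range national breast-cancer
  studies report; the default age profile rises log-linearly from 4 to
  roughly 300 per 100,000 across the 15 groups.  Mortality is a fixed
  fraction (default 0.35) of incidence, which enforces mortality ≤
  incidence by construction.
- observation: true stratum counts are Poisson(rate × population / 10⁵);
  each true case enters the cancer registry with probability π_CRS and the
  reference capture source independently with π_SSOCR; deaths enter the
  death registry with π_DRS.  Duplicates re-draw a record id but share a
  hidden truth link; per-field missingness (age, sex, province) is applied
  after registration.
- demography: lognormal province sizes, a geometrically decaying age
  pyramid, constant annual growth (1.3%/year); a strictly decreasing
  Gompertz-like remaining-life-expectancy table (≈66 years at 15–19 down
  to ≈4.5 at 85+); province–year covariates (wealth, schooling years,
  urbanization) with mild secular trends.

What the generator does **not** emulate: migration, male cases, cause
misclassification/garbage codes, age heaping, reporting delays, and
source-dependent capture (CRS and reference captures are conditionally
independent given the case — the assumption under which two-source
capture–recapture is unbiased).  Passing tests therefore show the
estimators are correct *under their stated assumptions*, not that those
assumptions hold in any particular country's registries.

## Registry preparation

Deduplication is deterministic key matching: rows equal on normalized
record id, and rows identical on (source, cause, age, sex, province,
year).  The demographic-key rule can collapse distinct events that share
all fields; it is intended for registries where the matched fields are
close to identifying.  No probabilistic linkage is attempted.

Imputation is hot-deck: each missing age/sex/province cell is drawn from
complete records in the same source × year, falling back to the same
source across all years; m = 5 completed tables by default.  Downstream
point estimates average the m completed analyses (Rubin's rule for
means); between-imputation variance is not propagated into the headline
uncertainty intervals.  Hot-deck was chosen over a multivariate-normal
EM imputer because the missing fields are categorical/discrete and the
downstream estimand only needs completed counts.

Completeness: with the reference source treated as an enumeration
standard, primary completeness per province × year is m / n2.  Strata with
no reference captures are flagged and left uncorrected, never silently set
to one.  The symmetric Chandra Sekar–Deming total is available behind a
flag (it implies the same primary-coverage estimate).  Correction is
multiplicative (observed / completeness), producing fractional counts.
The stratum level (province × year) is a package choice; an annual-only
level is available.

## Two-stage rate model

Stage 1 is a Poisson GLM with offset log(person-years/10⁵), fixed effects
for the three covariates and age-group indicators, and province
intercepts estimated from province-level observed/fitted count ratios and
shrunk by an empirical-Bayes factor τ²/(τ² + v_p) (τ² by method of
moments, overridable).  The GLM is refit once with the shrunken
intercepts as an offset.  Zero-event strata get a 0.5-event continuity
correction when forming log-scale residuals; strata with zero
person-years are excluded from the likelihood by zero weight.

Stage 2 smooths residuals with a separable kernel: raw space weight 1 on
self and λ_space/degree on adjacent provinces; age weight exp(−ω·|Δage
group|); time weight ζ^|Δyear|.  Each axis factor is row-normalized, so
the induced product kernel is a proper weighted average (rows sum to 1 to
1e-10) and smoothing is three small matrix contractions.  Defaults
λ_space = 0.3, ω = 0.7, ζ = 0.8 keep all three axes active; they are
declared choices, not estimates, and a cross-validated search is out of
scope.  ζ = 1 (uniform time weights) is accepted as the degenerate limit.

Uncertainty: 1,000 Monte-Carlo draws by default.  Each draw re-samples
stratum-level observation noise with the delta-method Poisson SD
(1/√fitted count), derives the fixed-effect perturbation from that same
noise field through the GLM influence operator (X'WX)⁻¹X'W — which leaves
the perturbation exactly MVN(0, fitted covariance) marginally while
preserving its cross-covariance with the noise — re-forms and re-smooths
the residual surface, and exponentiates.  Dropping the cross-term, or
perturbing only the fixed effects, understates the spread of the final
estimates and makes the 95% intervals undercover on data simulated from
the model itself (empirical coverage ≈ 90% instead of ≈ 93–95% at the
test problem sizes); this motivated the coupled scheme.  Random-effect
province intercepts are held fixed across draws; their estimation error
is negligible at the count totals involved.  Intervals are empirical
2.5th/97.5th percentiles, widened if necessary to bracket the point
estimate.

## Cause fractions

A multinomial logit of per-stratum cause counts (reference cause last;
default predictors: age-group indicators, centered year, province
indicators) is fitted by weighted maximum likelihood; separation or
non-convergence falls back to a weak ridge with a warning.  Standard
errors come from the analytic Fisher information.  Applying the model to
an all-cause envelope multiplies predicted fractions by envelope counts,
so cause totals conserve the envelope exactly (softmax rows sum to one).
Fractions are not themselves smoothed over space-time.

## Burden metrics

ASR = Σ_a w_a r_a with w the age distribution of the chosen standard
population (the final-year national population by default).  APC is
100(e^β − 1) from OLS of ln(value) on year, requiring ≥3 positive points;
on an exact geometric series it equals the endpoint growth rate, which is
what makes endpoint-anchored reproduction of published APCs exact.  YLL
multiplies deaths by remaining life expectancy at the age group, with no
discounting or age weighting.  MIR divides the age-standardized death
rate by the age-standardized incidence rate (same standard population); a
crude-count variant is deliberately not the default.  Incidence APCs are
computed over the full span, death/YLL APCs over the span ending one year
earlier, matching the reporting convention of the endpoint tables used in
the acceptance checks.

## Decomposition

With base-year age-specific rates r_a and populations P⁰_a, final-year
populations P¹_a and observed final cases C¹: base cases C⁰ = Σ r_a P⁰_a /
10⁵; H1 applies base rates and base age structure to the final total
population; H2 = Σ r_a P¹_a / 10⁵.  Growth = H1 − C⁰, aging = H2 − H1,
rate change = C¹ − H2.  The identity (sum of components = C¹ − C⁰) is
algebraic and holds to machine precision; C¹ is taken from observed or
estimated final-year counts, not recomputed from final rates.  Sex is
collapsed (single-sex analysis).

## Intrinsic Estimator

The Lexis grid uses cohort index k = (A − 1 − i) + j, giving A + P − 1
cohorts; the 85+ group is treated as a regular 5-year block for cohort
assignment.  Note that with 15 age groups and 4 periods this yields 18
cohorts — the count is always derived from the grid, never hard-coded.
The design uses sum-to-zero effect coding (intercept + (A−1) + (P−1) +
(C−1) columns) and has a one-dimensional null space B0.  The fit is
Poisson IRLS with offset log(exposure) in which each step is solved by
minimum-norm least squares; since the weighted design's kernel equals the
design's kernel, iterates remain orthogonal to B0 and converge to the IE
(Moore–Penrose) solution.  Fitted cell means and deviance coincide with
any drop-one-level constrained GLM; only the split of the common linear
trend across the three factors is fixed by the orthogonality choice — RR
curves should be read with that identification in mind.  Poisson with log
link is the default family; bootstrap CIs are percentile, 200 parametric
(Poisson-around-observed) resamples, seeded.

## Numerical choices and degenerate inputs

- Age-similarity exponent capped at 700 before exponentiation so ω → ∞
  degenerates cleanly to self-only weights.
- Coefficient covariance is symmetrized and eigenvalue-clipped to the
  nearest PSD matrix (with a warning) before draws.
- Uncertainty intervals refuse fewer than 100 draws.
- Completeness m > min(n1, n2) raises a data-integrity error; unmapped
  province codes and missing life expectancy for ages with deaths are hard
  errors listing the offending values.
- A disconnected adjacency graph warns rather than errors; smoothing then
  never crosses components.

## Problem sizes in the shipped checks

Tests and the acceptance script run on deliberately small worlds chosen
so all mechanisms (spatial sharing, age/time smoothing, shrinkage,
capture overlap) are active at informative signal-to-noise: typically 4–6
provinces, 6–10 age groups, 10–14 years, populations of a few hundred
thousand to two million per province, 1,000 draws, 100 capture–recapture
replicates, and 95%-interval coverage pooled over six replicate worlds
(per-world coverage fluctuates several points because fixed-effect
estimation error is shared across strata).  The default full-size
configuration (31 provinces, 15 age groups, 1990–2016) runs the same code
paths.

## Known limitations

- Completeness correction inherits the two-source independence
  assumption; dependent capture biases it upward.
- The hot-deck imputer assumes missingness at random within source × year.
- Stage-1 covariance is model-based (no overdispersion adjustment); with
  strongly extra-Poisson counts the intervals will be too narrow.
- The demographic-key deduplication rule can over-merge in very large
  registries with coarse fields.
- Between-imputation variance is not in the uncertainty intervals.
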