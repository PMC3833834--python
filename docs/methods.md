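# Methods

`artstart` implements a parametric g-formula (g-computation) analysis of
when to start antiretroviral therapy (ART) in HIV-infected children aged
2–5 years, together with everything the analysis needs around it:
a synthetic cohort generator with exact counterfactual ground truth,
interval discretisation of irregular visit data, last-observation-carried-
forward (LOCF), EM-bootstrap multiple imputation, penalized-spline additive
models selected by generalized cross-validation (GCV), forward Monte-Carlo
simulation under dynamic treatment regimes, percentile bootstrap inference,
and pre-ART time-to-threshold survival estimators.

## The estimation problem

CD4 count, CD4% and weight-for-age z-score (WAZ) are time-dependent
confounders: they predict both imminent ART initiation (sicker children are
treated sooner — confounding by indication) and death, and they evolve over
time. A regression of death on time-varying ART status adjusted only for
baseline covariates is biased upward, because on-ART person-time is
contributed disproportionately by children whose *current* state has
deteriorated. The g-formula resolves this by (1) modelling the joint
evolution of confounders and death given history, and (2) simulating the
cohort forward under each hypothetical initiation rule, with treatment set
by the rule rather than by the observed assignment process.

## Discrete time structure

Follow-up is discretised to the grid t = 0, 1, 3, 6, …, 36 months after
the first clinic visit. Observation windows sit at the midpoints of
adjacent nominal times, half-open on the left, so "closest to the middle of
the interval" coincides with closest to the nominal time; the earlier
observation wins ties (deterministic, and it prefers less post-hoc
information). t = 0's window is exactly {0}; the final window extends 1.5
months past the horizon. A death between grid times is assigned to the next
grid time (Y_t means "died in the interval ending at t"), and ART started
between grid times counts from the next grid time ("on ART by t"), an
intention-to-treat encoding under which treatment is absorbing.

Children enter if aged 24–60 months at enrolment, ART-naive, and seen at
least once after the enrolment visit. Children with no clinic contact for
more than 9 months before database closure are censored as lost to
follow-up (LTFU) at the first grid time after their last contact.
Survivors who are not LTFU are administratively censored only when closure
precedes the horizon: their horizon row is genuinely observed follow-up,
and dropping it from the risk set would roughly double the apparent final-
interval hazard.

## Missing data

Missing confounder values are first filled by LOCF for at most 9 months.
Cells still missing after that window — and missing baseline CD4, CD4%,
WAZ, HAZ — are multiply imputed under a joint multivariate normal model
estimated by expectation-maximisation on child-level bootstrap resamples,
with the original data's missing cells drawn from the estimated
conditionals (m = 10 by default). The imputation matrix is child-level
wide: one row per child with time-indexed columns for sqrt CD4, CD4% and
WAZ, plus age, sex, region contrasts, baseline HAZ, the death indicator,
follow-up duration and the carried-forward fraction. In this layout the
temporal neighbours of each column *are* its lag and lead, so no separate
lag/lead columns are added (literal duplicates would make the covariance
singular); an optional long layout (one row per child-time) carries
explicit lag-1/lead-1 columns and polynomial time trends.

Cells after a child's death or censoring row are structurally absent: they
participate in EM as missing cells but are never written back to a panel.
CD4 is modelled on the square-root scale and back-transformed with
truncation at zero; CD4% is clamped to [0, 100]. The EM ridge
(10⁻⁴·trace(Σ)/p on the diagonal, pinned to the initial covariance scale so
the fixed point is stationary) stabilises near-singular steps; convergence
is declared at 10⁻⁴ relative parameter change, with a 1500-iteration cap —
late-time columns carry a large missing-information fraction (LTFU plus
deaths), and EM's geometric rate genuinely needs several hundred iterations
there. Estimates are pooled across imputations by Rubin's rules
(T = W̄ + (1 + 1/m)·B), with the Barnard–Rubin small-m degrees of freedom
for interval estimates in the imputation benchmark.

## The per-time models

At every fit time t ∈ {1, 3, …, 36}, four models are fitted to the
children still at risk at t:

* Gaussian additive models for sqrt CD4, CD4% and WAZ at t, and
* a logistic additive model for death in the interval ending at t,

all on the same covariate recipe: confounder history at t−1 (CD4 on the
sqrt scale on both sides), baseline CD4/CD4%/WAZ/HAZ, age, sex, region, and
ART at t−1. The history covariates at t = 1 *are* the baseline values, so
the duplicated baseline terms are dropped there. Death is modelled on
history at t−1 rather than on the concurrent confounders: a child who dies
in an interval has no visit at its end, so a concurrent-L_t death model can
only ever be fitted to carried-forward copies of L_{t−1} while being
simulated with fresh draws — an inconsistency the history-only recipe
avoids entirely.

Continuous covariates enter as P-splines: cubic B-splines (8 basis
functions) on uniform knots extended beyond the data range — uniform
(Eilers–Marx) knots matter, because they make the second-order difference
penalty's null space exactly the linear functions, so λ → ∞ recovers the
least-squares line — with a sum-to-zero constraint for identifiability next
to the intercept, and linear extrapolation beyond the fitted range. Each
smooth's λ is chosen by coordinate-wise golden-section search on log λ
against GCV = n·RSS/(n − edf)² (deviance analogue for the logistic model,
profiled by performance iteration: pilot IRLS, λ search on the frozen
working problem, final IRLS refit). The three confounder targets at a time
point share one design matrix and its cross-products.

Model-building candidates (smooth × baseline-CD4-tertile or × region
varying-coefficient terms) are compared by `gcv_select`, which requires a
0.5% relative GCV improvement before a later candidate displaces an earlier
one: raw GCV minimisation, like AIC, admits a spurious interaction roughly
30% of the time in our null simulations, while a real category-specific
slope improves GCV by ≥4%, so the margin separates the two regimes cleanly.
Interaction exploration is off by default in the pipeline recipe and
exercised through `gcv_select` directly.

Sparsity fallback: a time point with fewer than 25 usable rows — or, for
the death model, fewer than 25 deaths — falls back to a single pooled
model across time with a smooth time main effect. The death floor is
deliberately high: with the ~10–20 deaths per interval these cohorts
produce, a per-time penalized logistic with ~60 coefficients is badly
overfit even under GCV (we measured +0.5–0.8 pp bias in simulated
mortality against the oracle), while the pooled fit is unbiased. In
practice the confounder models are per-time and the death model is pooled.

## Forward simulation and inference

Each child starts from their observed (post-imputation) baseline state. At
every grid time the regime decides treatment from the *simulated* CD4 and
CD4% at the previous time (absorbing; thresholds are strict "falls below"
disjunctions, e.g. CD4 < 750 cells/mm³ or CD4% < 25%); sqrt CD4, CD4% and
WAZ are drawn from normal(model prediction, σ̂_t), squared/clamped; death is
drawn from the logistic model; a dead child has no further follow-up, and
no censoring exists in the simulated world. Cumulative mortality is the
fraction dead by each grid time. `k_rep` simulates each child k times to
shrink simulation Monte-Carlo noise (the studies use k = 2).

Inference: B bootstrap replicates resample *children* (whole trajectories),
refit all models (λ re-selected, candidate set frozen) and rerun the
simulation; the point estimate is the Rubin mean of the per-imputation
full-data curves, and the 95% interval takes the 2.5th/97.5th percentiles
of the pooled B×m bootstrap draws (widened, if necessary, to bracket the
point estimate). Random streams are keyed so that every regime within a
(imputation, bootstrap) cell sees identical draws — regimes are compared on
common random numbers, which removes most simulation noise from regime
contrasts — and identical inputs give bit-identical output for a given
seed.

## The synthetic cohort generator

The generator is an explicit structural causal model, not a fixture. Its
defaults are calibrated so that the *observable* cohort resembles the
published source-cohort description:

* Baseline: sqrt CD4 ~ N(24.33, 8.19) (median 592 cells/mm³, quartiles
  356–895), CD4% lognormal(ln 16, 0.595), WAZ ~ N(−1.4, 1.33),
  HAZ ~ N(−2.6, 1.41), age uniform on 2–5 years, sex 51.2% male, four
  region categories, coupled by a Gaussian copula (ρ = 0.55 CD4–CD4%,
  0.25 CD4–WAZ, 0.50 WAZ–HAZ).
* Transitions: first-order autoregression on (sqrt CD4, CD4%, WAZ) with
  independent Gaussian innovations, ρ = 0.72 per interval, stationary
  means (20, 12, −1.85) and innovation SDs (3.4, 2.5, 0.60). The modest
  persistence is a deliberate design point: it makes the *current* state
  diverge from baseline quickly, so confounding by indication cannot be
  removed by baseline adjustment — the phenomenon the analysis exists to
  handle. A consequence is that untreated immune decline is front-loaded
  compared with the real cohort's gentler trajectories.
* Treatment: per-visit logistic start probability with logit
  4.4 − 0.30·sqrtCD4 − 0.10·CD4% − 0.80·WAZ (absorbing). Roughly 80% of
  children start ART within 3 years, the sickest almost immediately.
* Death: per-interval logistic hazard on the interval-start state,
  logit −4.9 − 0.15·sqrtCD4 − 0.04·CD4% − 1.15·WAZ + ln(art_effect)·A.
  `art_effect` multiplies the death odds (default 0.4, protective);
  3-year counterfactual mortality is ≈2% under immediate ART and ≈5%
  under no ART. By default ART has *no* effect on the confounder
  transitions — the treatment acts directly on mortality — so a null
  `art_effect` is a null total effect; transition ART terms exist and are
  used in parameter-recovery tests.
* Observation: visit-time jitter (±1 month, ±0.4 at t = 1), per-cell
  missingness 0.15 (MAR — independent of the unobserved values), per-
  interval LTFU hazard 0.02 (≈20% LTFU by 3 years). All observation noise
  is applied after outcomes are generated, so ground truth is untouched;
  a child's death is recorded only if they had not already dropped out.

Per-child random streams derive from (master seed, child index), so
trajectories are reproducible under cohort subsetting.

`true_regime_mortality` computes exact counterfactual mortality for any
regime by brute force on the same SCM, with treatment forced and no
observation process, sharing one stream across regimes (common random
numbers). Because threshold sets are nested and treatment is absorbing,
the oracle curves are monotone in the regimes by construction.

What the generator does **not** emulate: staggered calendar enrolment,
between-cohort heterogeneity, measurement error in CD4/WAZ, informative
(MNAR) missingness, ART regimen composition, and the real cohort's slower
immune decline. Passing tests therefore demonstrate that the pipeline's
estimators are correct *under the stated model class and MAR observation*,
not that the model class fits any particular real cohort.

## Validation studies and problem sizes

The standard studies (module `artstart.experiments`, driven by the
`analysis/` scripts and `scripts/acceptance.py`) use n = 5,000 children,
m = 2 imputations and B = 20 bootstrap replicates where a bootstrap is
exercised, a 50,000-trajectory oracle, and 10 independent cohorts for the
regime-ordering check; the imputation benchmark uses the bivariate-normal
fixture (ρ = 0.8, n = 2,000, 20% missing, m = 10, 200 coverage
replications). These sizes keep each study in the minutes range while
leaving Monte-Carlo error well below the effects of interest, except for
one quantity discussed below.

A variance caveat worth stating explicitly: contrasts between regimes are
driven by the fitted ART coefficient in the death model. With ~100–250
deaths and genuine confounding by indication, its standard error is
0.2–0.3 on the log-odds scale, so even under a null treatment effect the
between-regime spread of point estimates, ≈ p·|e^â − 1|, is typically
0.5–2 percentage points at these sample sizes. Shrinking it materially
would need either far larger cohorts or weaker confounding. The same
sampling noise makes the naive hazard ratio's sign at a mean of ~1.3
unstable from seed to seed. These are properties of the data-generating
conditions, not of the estimator: both disappear as n grows.

## Numerical choices and degenerate inputs

* Linear solves carry a 10⁻⁸ ridge; quasi-separated logistic fits are
  detected (|β| > 30) and refitted with an explicit ridge.
* A constant smooth covariate demotes the term to linear with a warning;
  a constant binomial response is a fitting error (callers fall back to
  the pooled model).
* Empty cohorts, empty simulated panels, missing simulated state under a
  threshold regime, and incomplete model sets raise contract errors
  rather than propagating NaN.
* λ search range is log₁₀ λ ∈ [−4, 8]; ties in `gcv_select` keep the
  earliest candidate.
* The Kaplan–Meier estimator and Aalen–Johansen cumulative incidences come
  from lifelines; the competing-risks crossing probability divides the
  crossing incidence by one minus the competing incidence, capped at 1,
  and is undefined (NaN, with a warning) once the competing incidence
  reaches 1. Its intervals are child-level bootstrap percentiles (200
  resamples by default). The naive pooled logistic hazard model uses
  statsmodels GLM with an unpenalized quadratic-spline time trend; its
  exponentiated ART coefficient approximates a hazard ratio at these
  event rates.
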