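# artstart

**When should young children with HIV start antiretroviral therapy?**
`artstart` estimates counterfactual cumulative mortality over three years of
follow-up for children aged 2–5 years under dynamic ART-initiation rules —
treat immediately; defer until CD4 count < 750 cells/mm³ or CD4% < 25%
(likewise 500/20% and 250/15%); never treat — from longitudinal cohort data
in which treatment assignment is confounded by evolving disease severity.

It is built for biostatisticians and epidemiologists who want a tested,
self-validating implementation of the parametric g-formula for dynamic
regimes, including all the machinery such an analysis needs: interval
discretisation of irregular visit data, last-observation-carried-forward,
EM-bootstrap longitudinal multiple imputation with Rubin's-rules pooling,
penalized-spline (P-spline) additive models selected by generalized
cross-validation, child-level percentile bootstrap, Kaplan–Meier and
competing-risks time-to-threshold estimators, and a synthetic cohort
generator with exact counterfactual ground truth for end-to-end validation.

## The method

CD4 count, CD4% and weight-for-age z-score (WAZ) are time-dependent
confounders: they predict both ART initiation and death, and they change
over time. Writing L_t for the confounders at grid time
t ∈ {0, 1, 3, …, 36} months, A_t for the on-ART indicator (absorbing,
intention to treat) and Y_t for death in the interval ending at t, the
g-computation algorithm is:

1. **Fit** — for each t: Gaussian additive models for each component of
   L_t and a logistic additive model for Y_t, both on (L_{t−1}, baseline
   covariates V, demographics, A_{t−1}), with continuous covariates as
   P-splines whose smoothness is chosen by GCV.
2. **Simulate forward** — start every child from their observed L_0; at
   each t set A_{t−1} by the regime applied to the *simulated* state, draw
   L_t from normal(model mean, σ̂_t), draw Y_t from the logistic model;
   stop follow-up at a simulated death.
3. **Estimate** — cumulative mortality per regime = fraction dead by t.
4. **Repeat** over regimes, over B bootstrap resamples of children
   (percentile 95% intervals), and over m multiply imputed datasets
   (Rubin's-rules pooling).

The package's validation studies compare the whole pipeline against a
brute-force oracle that simulates the known structural causal model with
treatment forced by each regime.

## Worked example

```bash
python analysis/01_simulate_cohort.py     # synthetic cohort of 2,934 children
python analysis/02_prepare_panel.py       # eligibility, discretisation, LOCF, LTFU
python analysis/03_impute.py              # EM-bootstrap multiple imputation (m=5)
python analysis/04_gcomputation.py        # five regimes, B=30 bootstrap samples
python analysis/05_threshold_survival.py  # pre-ART time below 750/25, naive HR
python analysis/06_validate_against_oracle.py
```

With seed 1, `01` prints a baseline table whose medians match the cohort
the generator is calibrated to (CD4 597 cells/mm³ [358; 888], CD4% 16.1,
WAZ −1.37, HAZ −2.54; 83.6% start ART during follow-up). `02` reports the
analysis panel (2,882 children after exclusions, 49 recorded deaths,
497 LTFU censorings). `04` prints the counterfactual mortality table
(per cent, 95% bootstrap intervals; 36-month rows shown):

```
                regime  months  estimate  lower  upper
             immediate    36.0      1.40   0.83   2.05
<750 cells/mm3 or <25%    36.0      1.40   0.85   2.05
<500 cells/mm3 or <20%    36.0      1.40   0.87   2.09
<250 cells/mm3 or <15%    36.0      1.58   1.06   2.35
                 never    36.0      6.03   2.57  10.71
```

— immediate treatment and the 750/25% deferral rule are indistinguishable
(most children are already below the threshold at presentation, and the
rest cross it quickly), later thresholds carry slightly higher mortality,
and never treating carries much higher mortality. `05` reports that 322
children (11%) present above both thresholds and that essentially all of
them fall below within the first year of pre-ART follow-up under the
generator's disease-progression dynamics, and fits the naive
baseline-adjusted hazard model for time-varying ART — at this seed it
prints 0.56 (95% CI 0.27–1.14), biased upward from the true odds
multiplier of 0.40; across cohorts this naive estimate averages roughly
twice the truth and frequently lands above 1, the signature of confounding
by indication. `06` confirms that on an unconfounded cohort the pipeline
reproduces the brute-force counterfactual closely (immediate: estimated
1.94% vs true 1.89%; never: 4.06% vs 4.69%).

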