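# Methods

`misscase` studies *nonignorable missing-case mechanisms* in longitudinal
treatment data: covariates that predict both the probability that a
participant provides no posttreatment assessment and the participant's rate
of symptom change. When such a covariate exists, replacement strategies
that ignore it (completer-only analysis, unconditional imputation)
systematically understate the missing cases' symptom burden and overstate
the treatment effect. The package implements the full chain — cohort
simulation, dropout modelling, proportional-change modelling, replacement
comparison, power analysis and cross-validation — against a synthetic
cohort whose defaults emulate a large routine-care internet-CBT service
sample (n = 6701, three symptom scales, five treatment modules, ~36%
posttreatment missingness).

## The synthetic cohort generator

The generator is first-class, tested code; its defaults *are* the study
conditions every acceptance band refers to.

**Baselines.** Each participant receives integer baseline scores on PHQ-9
(0–27), GAD-7 (0–21) and K-10 (10–50, analysed on 0–40 after subtracting
its constant offset of 10). Scores are negative-binomial draws on the
offset scale (PHQ-9 mean 12.5, GAD-7 11.0, K-10 18.8; dispersion r = 8–9,
giving the positive skew typical of clinic intake data), coupled across
scales by a Gaussian copula with correlation 0.6 and clipped to the scale
range. Demographics use the cohort's observed proportions (mean age 37.6,
SD 10.9; 72.6% female — the published count, whose printed percentage is
internally inconsistent; 66.5% in a relationship; 73.2% employed; 48.3%
tertiary-educated). Module completion (1–5) is multinomial with
proportions 513/715/718/653/4102 out of 6701. Comorbidity is derived:
GAD-7 ≥ 8 and PHQ-9 ≥ 10 at baseline.

**Trajectories.** All modelling happens on the shifted analysis scale
`offset score + 1`, so the log link is defined at zero; the shift is
removed before storage and reporting. The expected shifted posttreatment
score is multiplicative:

    E[post] = pre * r_i,   r_i = r0 * m_completion * m_severity^(b_i - b̄)

where `r0` is the reference pre→post ratio of full completers (0.51 for
PHQ-9/GAD-7, 0.62 for K-10), `m_completion` attenuates change for partial
completers (e.g. PHQ-9: 1.392/1.314/1.275/1.137/1.0 for 1–5 modules,
derived from the published per-level change rates), and `m_severity` is a
per-point multiplier on the centred offset baseline (0.988/0.976/0.994).
The mid (week 4) score sits at the geometric midpoint `pre * r_i^0.5`,
keeping it consistent with the log-linear model and making LOCF genuinely
intermediate. Mid and post scores are multiplied by independent mean-one
gamma noise; the noise variance is solved in closed form from the target
pre-vs-later Pearson correlation (default 0.72, the scale's published
test–retest stability) given the realised baseline and expected-score
moments, so the generated correlation hits the target without tuning.
Scores are rounded and clipped to the scale range (both can be disabled
for closed-form checks).

**Dropout.** Missingness is a participant-level event (all scales lost
together) with

    logit(p) = logit(0.098) + log OR_completion + log(1.037)·(PHQ-9_b - b̄)
               + log(0.967)·(age - ā)

using the published per-stratum completion odds ratios (162.104, 106.01,
33.715, 9.104 for 1–4 of 5 modules vs full completers). Demographic odds
ratios default to 1, mirroring their near-null published effects. These
defaults reproduce the published marginal structure arithmetically:
0.0766·0.946 + 0.1067·0.921 + 0.1071·0.789 + 0.0974·0.502 + 0.6121·0.098
≈ 0.363 overall missingness. Pre and mid assessments are never deleted.

**What the generator does not emulate.** Item-level responses (hence no
internal-consistency statistics), time-varying adherence, therapist
effects, a week-20 follow-up, and any dependence of completion on baseline
severity (completion and baselines are drawn independently, matching the
additive published dropout effects). Passing tests therefore demonstrate
that the *methods* behave correctly under the study's statistical
structure, not that real attrition follows this model.

## Dropout models

Missing-case status is modelled by maximum-likelihood logistic regression
(statsmodels). Completion is categorical with full completers as
reference; baseline scores enter per offset point; comorbidity supports
both reference codings, since the published direction of its odds ratio
conflicts with its subgroup percentages. Reported per-term statistics are
Wald chi-squares with Wald (log-symmetric) CIs. Predictive strength is
summarised by:

- **Nagelkerke R²** — Cox–Snell rescaled by its maximum,
  `[1 − exp(2(L0−L1)/n)] / [1 − exp(2L0/n)]`;
- **classification metrics** at a threshold. No usable fixed threshold
  exists for weak predictors (their predicted probabilities never cross
  0.5), so the default rule classifies "missing" when the predicted
  probability reaches the sample missingness rate; fixed 0.5 is available;
- **AUROC** by the rank (Mann–Whitney) formulation with a DeLong
  placement-value CI. scikit-learn's trapezoidal implementation serves as
  an independent cross-check in the tests, never as the implementation.

Quasi-separation (possible in small completion strata) is detected and
falls back to a Firth-penalized fit, flagged on the results object.

Variable selection is Wald-based stepwise with entry = removal = P .01
(the conservative threshold the replication design prescribes), candidates
scanned in their given order; forward and backward variants are available
and reported side by side. The per-unit relative risk increment of a
continuous predictor is `100·(p(x̄+1) − p(x̄))/p(x̄)` from the fitted model;
categorical predictors report subgroup probabilities directly.

## Proportional-change models

Symptom change is modelled population-averaged by GEE with a log link,
gamma variance function, robust (sandwich) standard errors and an
unstructured working correlation. The default model uses pre and post
only (mid is consumed by LOCF and MI); with two timepoints the
unstructured working correlation has a single free off-diagonal parameter,
identical to exchangeable, and the implementation substitutes the
exchangeable structure internally for speed (parameter differences at
n=6701 are ~1e-3). A three-timepoint option codes time as the week
fraction (0, 0.5, 1).

`exp(β_time)` is the pre→post ratio of expected scores for the reference
group; the percent change rate is `100·(1 − ratio)`. Moderation is the
time×covariate interaction; per-level rates and their CIs come from the
delta method on the log scale, and marginal means are evaluated at the
observed covariate distribution. For continuous moderators the per-unit
row reports `100·(exp(β_interaction) − 1)`, matching how published
per-point moderation is displayed. Only observed rows enter the fit;
missing posttreatment rows are simply absent. Stability between observed
timepoints is the two-way consistency ICC (pingouin), cross-checked
against the generator's target.

## Replacement comparison

Each method yields the mean replacement score assigned to the missing
subset, a 95% CI, the percent difference from the completer-only (MCAR)
estimate, and a verdict. The missing-subset mean is the default reported
quantity because the published tables' own arithmetic requires it (their
BOCF row equals the missing subset's pretreatment mean); a cohort-level
mean (observed completers plus replacements) is carried on every estimate.

- **MCAR** — time-only GEE; every missing case receives the marginal
  posttreatment mean, so the estimate equals the completer marginal mean
  identically.
- **MAR(covariates)** — GEE with time×covariate terms; each missing case
  is predicted at its own covariate values. An empty covariate set reduces
  exactly to MCAR. Covariate levels unobserved among completers flag the
  estimate as extrapolated.
- **MI** — m = 20 (configurable, seedable) stochastic imputations on the
  log shifted scale: a Bayesian linear model of log post on the configured
  covariates plus log pre (and log mid) among completers; σ² and β drawn
  from their posterior, posterior-predictive draws for the missing, Rubin
  pooling with Barnard–Rubin degrees of freedom.
- **MLM** — linear mixed model on log shifted scores over all three
  timepoints with random intercepts and slopes; missing cases predicted at
  week 8 from fixed effects plus their own BLUPs (identified by their pre
  and mid assessments). On noise-free data this reproduces the generator's
  deterministic posttreatment values.
- **LOCF / BOCF** — mid-if-present-else-pre, and pre, carried forward.

**Confidence intervals.** The MCAR row uses the delta-method SE of the
marginal mean. Adjusted model rows use the delta-method SE of the
*adjustment* — the difference between the missing-subset prediction mean
and the same model's whole-cohort marginal mean — in which the shared
intercept/time uncertainty cancels; this expresses how far the covariate
moves the replacement away from the marginal estimate and is what makes
the published containment rule discriminating (a null covariate's CI
collapses onto the marginal mean instead of inheriting the marginal
mean's own width). LOCF/BOCF use a seeded percentile bootstrap (B=1000).
The relative-to-MCAR CI is a seeded parametric Monte Carlo over the two
means' normal approximations, with independence assumed.

**Verdict.** *Equivalent* if the adjusted CI lies within the MCAR CI;
*above*/*below* if the adjusted CI excludes the MCAR point mean on one
side; *inconclusive* otherwise (partial overlap — an explicit category
this package adds rather than silently calling it equivalence).

## Power analysis

Both curves are self-contained Monte-Carlo simulations anchored to pilot
parameters extracted from a fitted change model (rate of change, baseline
mean and dispersion, residual noise dispersion, within-subject
correlation). The two published minimal-detectable-effect figures imply
different designs, and the package implements each accordingly:

- **Missingness** — a one-sample design: n Bernoulli draws at the shifted
  probability, tested against the known whole-sample reference via the
  Wald test of a logistic intercept with the reference log-odds as offset.
  At n = 1341 and a 36% reference this is 80%-powered near a 3.6-point
  absolute shift. (A two-group split at that n would need roughly twice
  the shift, inconsistent with the published figure.)
- **Change** — a moderation design: half the sample changes at the pilot
  ratio, half at a ratio shifted by the effect (in percentage points of
  change); the test is the Wald test of the time×group interaction in the
  gamma/log GEE with exchangeable working correlation.

Rejection rates carry Wilson Monte-Carlo CIs; the minimal detectable
effect at the target power (default 80%, α = .05) is linearly interpolated
on the evaluated grid and flagged when out of range. Everything is
reproducible bit-for-bit from (config, seed).

## Cross-validation

`split_cohort` permutes participants and deals round-robin, guaranteeing
the 1341/1340×4 size pattern at n = 6701 and determinism given the seed.
Randomization balance uses k-way contingency chi-squares (continuous
variables quantile-binned); sparse expected cells flag the row.
`replicate_univariate` refits the univariate dropout models per subsample,
producing the replication sheet.

## Numerical choices and problem sizes

- Logistic fits: Newton MLE, Firth fallback on separation (|coef| > 15 or
  non-convergence).
- GEE: statsmodels defaults (60 iterations); non-convergence raises with
  the iteration state rather than returning silently.
- Degenerate inputs raise typed errors: constant predictors, single-class
  outcomes, constant scores, out-of-bounds scores, < 3 ICC pairs.
- Report tables round percentages to integers, means to one decimal,
  coefficients/odds ratios to three decimals; `results.json` keeps full
  precision and every output file carries the configuration hash.
- Test problem sizes are chosen per check: identity and definitional
  checks run on hand-built cohorts of 2–60 participants; band checks run
  at the study scale n = 6701; multi-seed recovery suites use 10–20 seeds;
  Monte-Carlo power checks use 150–400 replications (200 for the
  minimal-detectable-effect bands), sizes the package's own defaults
  document as adequate for the tolerances asserted.

## Known limitations

- The generator's dropout and change processes share no latent individual
  effect beyond baseline severity; real attrition is likely messier.
- Replacement CIs for model rows condition on the overall level (see
  above); users wanting full marginal uncertainty can combine the MCAR
  row's CI with the adjustment CI.
- The MLM replacement reports a dispersion-based SE of its predictions,
  not a full mixed-model prediction variance.
- Published per-unit "relative risk" columns for continuous predictors do
  not follow from any single reproducible transform; the package reports
  its own model-based definition and does not attempt to match those
  printed values.
- The K-10 floor (10 raw points) plus rounding makes very low distress
  scores slightly sticky near the boundary.
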