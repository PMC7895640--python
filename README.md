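# misscase

Missing-case mechanisms in longitudinal treatment data: who drops out of
posttreatment assessment, what their outcomes were likely to be, and which
statistical replacement models are defensible.

In routine-care psychotherapy cohorts a third or more of participants
provide no posttreatment symptom assessment. If a covariate predicts both
the probability of going missing *and* the rate of symptom change — a
**nonignorable missing-case mechanism** — then completer-only estimates and
unconditional imputation understate the missing cases' symptom burden and
inflate the apparent treatment effect. `misscase` is built for
biostatisticians and treatment-outcome researchers who want to detect such
mechanisms and compare replacement strategies side by side, with a
synthetic cohort generator so the entire pipeline is testable end to end
without access to clinical data.

## The models

**Dropout.** Posttreatment missing-case status is a binary outcome,
modelled by logistic regression. Predictive strength per covariate is
summarised by Nagelkerke's

&nbsp;&nbsp;&nbsp;&nbsp;R²_N = [1 − exp(2(L₀−L₁)/n)] / [1 − exp(2L₀/n)],

classification sensitivity/specificity/accuracy, and the AUROC computed by
the rank (Mann–Whitney) formulation with a DeLong CI. Multivariate models
are built by Wald-based stepwise selection at the conservative P = .01,
with forward and backward variants for replication.

**Symptom change.** Scores (PHQ-9, GAD-7, K-10; the K-10 analysed on its
0–40 offset range, all scores shifted by +1 for the log link) follow a
population-averaged GEE with log link, gamma variance and unstructured
working correlation. exp(β_time) is the pre→post ratio of expected
scores; the change rate is 100·(1 − exp(β_time)); moderation is the
time×covariate interaction.

**Replacement.** Missing posttreatment scores are approximated under
competing assumptions — MCAR (time-only marginal mean), covariate-adjusted
MAR, multiple imputation with Rubin pooling, a random-intercept/slope mixed
model, LOCF and BOCF — and each estimate is compared with the MCAR estimate
by percent difference and a CI-containment equivalence verdict.

**Power.** Monte-Carlo curves give the minimal detectable shift of the
missingness probability (one-sample, against the known whole-sample rate)
and of the change rate (time×group moderation) at 80% power.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

```python
from misscase import SimConfig, simulate, MissingnessModel, fit_change_model
from misscase.replacement import ReplacementAnalysis

cohort = simulate(SimConfig(), seed=1)      # n=6701, ~36% missing post
fit = MissingnessModel(cohort, ["completion"]).fit()
print(fit.summary())

change = fit_change_model(cohort, "phq9", "completion")
print(change.summary())

ra = ReplacementAnalysis(cohort, "phq9", seed=1)
for est in (ra.mcar(), ra.mar(["completion"]), ra.locf(), ra.bocf()):
    print(f"{est.method:16s} {est.mean:5.1f}  {est.relative_pct:+6.1f}%  {est.verdict}")
```

prints (abridged):

```
Posttreatment missing-case logistic model
  formula: missing ~ C(modules_completed, Treatment(reference=5))
  n=6701  method=mle
  Nagelkerke R2 = 58.1%
  completed 1 of 5 ... OR 137.430 (94.329, 200.226)
AUROC 0.874 (0.865, 0.883)

Proportional symptom change model — PHQ-9
  exp(beta_time) = 0.496  -> sample change rate 50.4%
  completed all modules   ratio 0.496   rate 50.4  (49.9, 50.9)
  completed 1 of 5        ratio 0.697   rate 30.3  (24.4, 35.7)

MCAR               5.9    +0.0%  equivalent
MAR:completion     7.1   +20.6%  above
LOCF               9.8   +66.3%  above
BOCF              12.9  +119.1%  above
```

Read: module completion alone explains ~58% of the missingness variance
and discriminates missing from observed cases with AUROC 0.87; minimal
completers both drop out far more often (odds ratio ≈ 137 vs full
completers) and improve ~20 percentage points more slowly. Replacement
models that ignore adherence (MCAR) assign missing cases the completers'
mean of 5.9 points; adjusting for adherence raises it by ~21%, while
carried-forward methods sit far above every model-based estimate.

## Command line

```bash
misscase simulate --n 6701 --seed 1 --out cohort/
misscase all --seed 1 --out run/          # full pipeline on simulated data
misscase analyze --input cohort/ --out run/   # same schema, your own files
```

A run directory contains the table analogues
(`missingness_univariate.csv`, `change_<scale>.csv`,
`replacement_<scale>.csv`, `replication.csv`, …), plot-ready figure data,
a `run.log`, and `results.json` with everything at full precision; every
file carries the configuration hash.

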