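# Methods

## Setting

Women with stage I–III HER2+ breast cancer treated with trastuzumab
(with or without prior anthracycline) are monitored with serial LVEF
studies (MUGA or 2D echocardiography).  A clinically meaningful decline
— cancer-therapeutics-related cardiac dysfunction (CTRCD) — interrupts
therapy and predicts later heart failure.  Several pre-treatment risk
models claim to stratify that risk; this package implements the
machinery needed to validate them externally: risk-score assignment,
rule-based CTRCD adjudication from the LVEF series, and
discrimination/calibration evaluation, plus a synthetic cohort
generator so the whole pipeline is testable without patient data.

## CTRCD adjudication

Three definitions are implemented as data (`CtrcdDefinition`):

| definition | drop rule | floor |
|---|---|---|
| CREC | ≥ 10 points asymptomatic, or ≥ 5 points with HF symptoms | < 55% |
| ESC  | > 10 points (strict) | < 50% |
| ASE  | > 10 points (strict) | < 53% |

Drops are absolute percentage points.  The inclusive "≥ 10" of CREC
versus the strict "> 10" of ESC/ASE is honored literally, because the
source wording differs and the difference is observable at exact
10-point drops.  When the baseline LVEF is below the lower limit of
normal (LLN), all definitions switch to a pure "> 10 point additional
drop" rule; this branch takes precedence whenever baseline < LLN, even
for symptomatic drops (the source wording does not order the branches;
we flag this choice here).  The LLN defaults to each definition's floor
(55/50/53) — the only numeric normality bounds in scope — and is
overridable.

MUGA and echo LVEF values are not interchangeable, so the default
`same_modality_only` policy compares each follow-up to the earliest
measurement of its own modality; a follow-up that is itself the
earliest study of its modality has no reference and is skipped and
logged.  A `pooled` policy (single time-0 baseline for everything) is
provided for sensitivity analyses.  A missing symptom flag is treated
as "no symptoms", which reduces CREC to its asymptomatic branch — the
realistic behaviour for retrospective cohorts without systematic
symptom capture.  All measurements in a series are eligible ("during or
immediately post therapy"); any windowing is the caller's responsibility.

## Risk models

The scoring engine is declarative: a model is a YAML config of factor
predicates and a combination mode, so the three shipped models are data,
not code.

* **Points model (Ezaz)** — comorbidity/treatment factors contribute
  integer points (0–12); totals 0–3/4–5/6–9 map to low/medium/high.
  The exact point allocation is not public in the text we model it
  after; the shipped points are clearly marked placeholders, while the
  category boundaries are the published ones and are what the tests
  pin down.
* **Formula model (NSABP-31 CRS)** — a closed form in age and baseline
  LVEF.  The shipped expression `age + (70 − baseline_lvef)` is a
  placeholder with the published structure (increasing in age,
  decreasing in LVEF, tertile boundaries at 50 and 64 in the validation
  cohort); formulas are parsed to an AST and evaluated over a whitelist
  of arithmetic operations, never executed as code.  A restricted cubic
  spline fitted through (score, risk) anchor points supplies predicted
  risks; anchors are likewise placeholder transcriptions.
* **Level-combination model (HFA-ICOS trastuzumab proforma)** — factors
  trigger at medium/high/very-high levels.  The consensus source does
  not give a complete combination algorithm, so the default rule is:
  any very-high factor → very high; any high factor or ≥ 5 medium
  factors → high; 2–4 medium → medium; else low.  It is monotone by
  construction (adding a factor never lowers the category) and
  config-overridable.  Optional biomarker factors use hsTnI > 16 ng/L
  and BNP > 100 pg/mL.  Predicted per-category risks default to band
  representatives 1%, 5.5%, 14.5%, and 30% (the very-high value being
  the published choice for an open-ended "> 20%" band).

A patient missing a covariate needed by a points or formula model
yields an explicit *unscorable* assignment naming the covariate; such
patients are excluded from that model's evaluation and counted in the
report rather than imputed.  Quantile stratification (tertiles,
quintiles) uses inverted-CDF order statistics, with scores equal to a
cutpoint going to the lower group to match "score ≤ cutpoint"
labelling conventions.

## Validation statistics

* **Association**: Pearson chi-square *without* continuity correction
  (df = k − 1) is the default, because it reproduces the published
  between-category p-values exactly at their printed rounding; an exact
  2×k conditional test (multivariate-hypergeometric enumeration,
  summing tables no more probable than observed) is available, and
  `auto` switches to it when any expected cell is below 5.  Caveat from
  our own property testing: the exact and asymptotic p-values can
  differ by more than 0.02 even with expected cells well above 20; they
  come within 0.02 only for cell counts in the thousands.
* **Discrimination**: AUC by the Mann–Whitney estimator
  P(case > control) + ½P(tie); ordered categories enter through their
  ranks, and for formula models the raw score is also evaluated.  The
  95% CI uses the DeLong structural-component variance by default, with
  a seeded percentile bootstrap (2,000 resamples) as the alternative;
  intervals are clipped to [0, 1].
* **Calibration**: observed risk per category is the empirical
  proportion (identically the intercept-only logistic MLE); its 95% CI
  is the Wald interval on the logit scale transformed back,
  se = (n·p̂(1−p̂))^−1/2.  Categories with 0% or 100% events fall back
  to an exact Clopper–Pearson interval and are flagged.
* **One-way ANOVA** (continuous covariates across categories) and
  relative risks (ratios of category proportions) round out the
  report.

## Synthetic cohorts

The generator's defaults reproduce the reference cohort's baseline
table marginals (age 52.4 ± 10.9 y truncated to ≥ 18; LVEF 64 ± 7%
truncated to 45–80; hypertension 18%; diabetes 7%; anthracycline 90%
with dose 272 ± 76 mg/m²; MUGA 70%; biomarkers measured in 29% with
log-normal levels placing ~7%/~9% above the troponin/BNP thresholds;
and so on).  Covariates are drawn independently — the source reports
marginals only — with a hook for a user-supplied dependence structure
on the flag draws.

Events follow a logistic model on standardized covariates.  The default
intercept is logit(0.24), the reference cohort's CREC incidence; the
default coefficients are modest positive effects for age, low baseline
LVEF, anthracycline exposure, hypertension and diabetes.  An event
patient receives one uniformly chosen follow-up whose drop is drawn
uniformly between "just breaches the target definition's floor and
drop rule (with a 0.5-point margin)" and a configured maximum
(30 points); an infeasible breach (baseline too high for the maximum
drop) raises rather than silently under-delivering events.  Non-event
visits fluctuate around baseline with measurement noise of SD 2.5 LVEF
points truncated at ±3 SD — physiological test–retest noise is not
heavy-tailed, and the bound (7.5 points) guarantees noise alone can
never reach a 10-point diagnostic drop, so adjudicated incidence equals
the latent event rate exactly.  Everything is driven by one
`numpy.random.default_rng(seed)` stream: runs are bit-reproducible.

What the generator does **not** emulate: covariate correlations,
modality switching within a patient, LVEF recovery/rechallenge
dynamics, informative visit schedules, and measurement-modality bias.
Passing pipeline tests on synthetic cohorts therefore demonstrates
correctness of the machinery and recoverability of configured effects,
not real-world model performance.

## Problem sizes and numerical choices

Published-table statistics are exact and instantaneous.  Simulation
sizes were chosen to make Monte-Carlo error small relative to the
effects checked: 5,000 patients for marginal fidelity (SE of the age
mean ≈ 0.15 y), 10,000 for the intercept-only incidence loop
(SE ≈ 0.43 pct points, checked within 3 SE), and 20,000 for gradient
recovery (smallest category ≈ 150–200 patients).  Spline fits use
least squares on the truncated-power natural-spline basis normalized
by (t_k − t_1)²; evaluation clips to [0, 1].  Quantile ties go to the
lower group; p-values are reported at full precision in JSON and
rounded only for display.

## Known limitations

The three shipped model configs carry placeholder numbers where the
original publications keep the values in appendices or figures
(Ezaz points, CRS closed form, CRS→risk anchors); validating a real
cohort requires transcribing those into the YAML files first.  The
real validation cohort is private, so its AUC and calibration figures
are not recomputable here — the package reproduces the published
between-category statistics from printed counts and demonstrates the
full pipeline on synthetic cohorts only.
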