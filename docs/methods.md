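# Methods

## The scoring model

The pipeline is a deterministic points-accumulation scheme wrapped around
standard statistics. Per probeset:

* **Internal discovery points** (0/2/4/6). Every eligible within-subject
  low/high visit pair contributes a vote in {−1, 0, +1} per method.
  DE votes compare de-logged intensities: +1 when 2^(high−low) ≥ 1.2,
  −1 when 2^(low−high) ≥ 1.2. AP votes are detection-call transitions
  (absent→present = +1). Raw score = Σ votes across all pairs and
  subjects. Points follow the percentage of the method's maximum
  absolute raw score: ≥ 33.3% → 2, > 50% → 4, > 80% → 6. The 33.3%
  boundary is inclusive so scores at exactly one third of the maximum
  are admitted; the 50/80 boundaries are strict. When both methods score
  a probeset, the higher-scoring method supplies the points and
  direction; directional conflicts are kept but flagged.
* **External CFG points** (0–12). Six evidence cells, {human, nonhuman} ×
  {genetic, brain_expression, peripheral_expression}; a cell contributes
  its full weight when ≥ 1 significant finding exists (binary, so the
  score stays bounded regardless of literature volume). Default weights
  2/4/2 (human) and 1/2/1 (non-human), summing to 12; human and brain
  evidence deliberately outweigh animal and peripheral evidence. Weights
  are config-overridable since only their sum is anchored. Evidence
  direction is recorded and surfaced in reports but does not affect the
  score.
* **Validation points** (0/2/4/6). Groups: LOW and HIGH from
  discovery-eligible visits (HIGH excluding clinically severe trait
  stress, PCL-C ≥ 50) and SEVERE (PCL-C ≥ 50 with VAS Life ≥ 67).
  Expression is de-logged then Z-scored per gender × diagnosis stratum
  using the sample (n−1) standard deviation — a documented choice, as
  strata are small; single-sample and zero-variance strata yield z = 0
  with a warning. Stepwise means strictly monotone group means in the
  discovery direction; ties count as failure. One-way fixed-effects
  ANOVA (scipy `f_oneway`) on the pooled Z-values supplies p; the
  Bonferroni family is the number of probesets tested in this run.
* **Testing points** (0/4/6/8 per outcome). Outcomes: state (high-stress
  visit, VAS Life ≥ 67), first-year hospitalization with stress (event
  within 365 days, else censored at 365) and all-future hospitalization
  (censored at the last medical-record note date). The primary
  significance metric is the one-sided ROC p for state and first-year,
  and the Cox Wald p for all-future, mirroring the scorecard's column
  conventions. The best significant stratum sets the points: all
  subjects 8, any gender 6, any gender × diagnosis 4 (schizophrenia and
  schizoaffective are additionally pooled as PSYCHOSIS). Both
  cross-sectional and longitudinal modes count.
* **CFE total** (≤ 54) = discovery + external + validation + three
  testing outcomes + cross-disorder (3) + opposite-direction drug
  evidence (3). Own-data subtotal (≤ 36) vs literature subtotal (≤ 18)
  weights the pipeline's own data twice as much as the literature.

Scores are keyed by probeset and annotated with gene symbol, because a
gene may carry several probesets with different behavior; evidence is
keyed by gene.

## Statistical components

* **ROC AUC** is the Mann-Whitney statistic normalized by
  n⁺·n⁻ — exactly the pairwise win-plus-half-tie probability — with a
  one-sided rank-sum p (exact for small tie-free samples, normal
  approximation with tie correction otherwise). Tests verify equality
  with a brute-force pair-enumeration oracle on all instances n ≤ 30.
* **Cox proportional hazards** fits are delegated to
  `lifelines.CoxPHFitter` (Newton iterations, Efron tie handling) behind
  the `cox_hr` surface; an independent grid-search maximizer of the
  partial likelihood serves as the test oracle. The hazard ratio is
  reported as exp(β̂) for increased markers and exp(−β̂) for decreased
  markers, so HR > 1 always reads "increased hospitalization risk".
  Consistently, decreased-marker scores are sign-flipped before
  ROC/t/Pearson, so AUC > 0.5 always reads "predicts the outcome".
* **Longitudinal features**: level at the most recent visit, slope into
  it, extreme level and extreme slope over the visits so far (minimum
  instead of maximum for decreased markers). Slope is the level ratio
  divided by inter-visit days, taken verbatim despite its instability
  near zero; previous levels within ε = 0.01 of zero are replaced by
  ±ε and slopes are capped at ±10 to keep extreme-slope features
  finite. The four features are Z-scored over the evaluable cohort and
  summed. Subjects with fewer than two visits are excluded from
  longitudinal analyses.
* **Multiple testing** in the prediction step is reported nominally
  (p < 0.05, the primary presentation) with a Bonferroni-over-candidates
  flag stored alongside. Each testing visit is an observation;
  within-subject correlation is acknowledged, not modeled.
* **Subtype clustering** uses Ward-linkage agglomerative clustering on
  per-scale standardized anxiety/mood/psychosis ratings (distance and
  linkage are config-overridable, as neither is canonical), cut at k = 3
  and labelled post hoc from centroids: highest anxiety → anxious,
  highest psychosis among the rest → psychotic, remainder →
  non-comorbid.
* **T/S ratio** assumes 100% qPCR efficiency: 2^(mean ALB Ct − mean TEL
  Ct); triplicate spreads over 0.5 cycles and missing replicates are
  flagged, not fatal.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, and its
defaults are the study conditions:

* 36 discovery subjects with 2–4 visits in proportions 22:9:5, ≈ 78%
  male, diagnosis mix BP 14 : MDD 7 : PTSD 6 : SZ 6 : SZA 2 : PSYCH 1 of
  36; visits 3–6 months apart. Every discovery subject has at least one
  low (VAS Life ≤ 33) and one high (≥ 67) visit, each with one
  concordant second VAS item; extra visits are high with probability
  `p_high_stress_visit` (default 0.5). A severe arm (default 48
  subjects, 1–2 visits) has PCL-C ≥ 50 and VAS ≥ 67.
* Expression is Gaussian on the log2 scale (RMA-like): per-probeset
  baseline U(4, 10) + subject random intercept (sd 0.3) + planted state
  effect + noise (sd 0.3). Planted DE probesets shift by
  `effect_log2fc` (default 0.5 ≈ 1.41-fold, above the 1.2-fold vote
  threshold) in high-stress visits and by 1.5× that in the severe arm,
  making them stepwise-changed by construction. Planted AP probesets
  flip their detection call with stress state; background calls are
  present with probability 0.95. Within-subject correlation across
  visits is exchangeable via the subject intercept — real longitudinal
  autocorrelation structure is not modeled.
* Hospitalizations use exponential waiting times from the last visit
  with log-hazard linear in the subject's exposure to a designated
  planted marker, oriented along the marker's stress direction — this
  makes the Cox coefficient analytically recoverable and keeps the
  HR-orientation rule meaningful. 15% of subjects get an unrelated
  (non-stress) admission. Follow-up ends `followup_days` (default
  2000) after the last visit.

What passing tests on this generator do **not** show: robustness to
probe-level artifacts, batch effects beyond gender × diagnosis
normalization groups, non-Gaussian expression noise, informative
dropout, or medication confounding in real cohorts.

## Problem sizes used in the test suite

The acceptance-style end-to-end check runs 20 seeds of 36 subjects ×
5,000 probesets with planted log2 fold change 1.0 and noise sd 0.2,
asking that ≥ 90% of planted DE probesets clear the 33.3% discovery
threshold, survive CFG prioritization under saturated evidence, and are
flagged stepwise against the simulated severe arm. Estimator
calibrations use 1,000 null simulations (ANOVA type-I error), n = 1000
(Cox coefficient recovery of a planted β = 0.5 ± 0.1) and 300 random
instances with n ≤ 30 (ROC oracle equality). These sizes were chosen so
the whole suite completes in about a minute while keeping Monte-Carlo
error well inside the asserted tolerances.

## Known limitations and open choices

* The pairing rule enumerates **all** low × high pairs within a subject,
  so subjects with more visits contribute proportionally more
  comparisons — consistent with across-subject raw-score summation.
* Expression values are assumed log2; the de-log step (2^x) is wrong if
  matrices are supplied on another scale.
* A missing presence matrix disables AP scoring with a warning rather
  than failing.
* The CFE scheme is additive bookkeeping; it deliberately does not model
  correlations between evidence lines.
* `hosp_frequency`'s Pearson correlate treats hospitalization counts per
  follow-up day as a rate without overdispersion modeling.
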