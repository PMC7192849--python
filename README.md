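# stressmark

Blood gene-expression biomarker discovery, prioritization, validation and
predictive testing for **psychological stress**, implemented as a reusable
Python library with a thin command-line pipeline.

Psychological stress is a subjective sensation with biological roots.
Psychiatric patients followed longitudinally report diametrically different
stress states across visits — a low-stress visit (visual-analog-scale Life
Stress ≤ 33/100) followed by a high-stress one (≥ 67/100), or vice versa —
which makes a powerful *within-subject* design possible: each subject is
their own control, factoring out genetic background and most medication
effects. `stressmark` implements the full multi-step workflow that turns
such a cohort, an expression matrix and a curated literature database into
a ranked scorecard of candidate blood biomarkers:

1. **Discovery** — within each subject, every low/high visit pair votes
   ±1 per probeset by two methods: DE (≥ 1.2-fold intensity change on
   the de-logged scale) and AP (absent→present detection-call flips).
   Votes are summed across subjects into a signed raw score; probesets
   at ≥ 33.3% / > 50% / > 80% of the method maximum earn 2 / 4 / 6
   internal points.
2. **Prioritization (CFG)** — each gene gains external points for prior
   literature evidence in six cells ({human, non-human} × {genetic,
   brain, peripheral}), maximum 12; internal + external ≥ 6 (one third
   of the 18-point maximum) carries forward, keeping novel genes with a
   maximal internal score and no literature.
3. **Validation** — expression is de-logged (2^x) and Z-scored by gender
   and diagnosis; a marker validates when its group means progress
   stepwise from Low Stress to High Stress to a Clinically Severe cohort
   (PCL-C ≥ 50 with state stress ≥ 67) in its discovery direction, with
   one-way ANOVA significance (Bonferroni 6 pts / nominal 4 / stepwise
   only 2).
4. **Testing** — the candidate union (top discovery ≥ 90%, top CFG ≥ 13,
   nominally validated) is evaluated in an independent cohort for
   *state* (ROC AUC against high-stress visits, one-sided rank-sum p)
   and *trait* (Cox proportional hazards on days to future
   hospitalization with stress, first-year and all-follow-up), in all
   subjects, by gender, and by gender × diagnosis, cross-sectionally and
   longitudinally (level + slope + extreme level + extreme slope).
5–7. **Convergent Functional Evidence** — everything is tabulated into a
   CFE score out of 54 (36 from the pipeline's own data, 18 from
   literature: external CFG, cross-disorder evidence, opposite-direction
   drug evidence) and ranked.

A first-class synthetic-cohort generator (`stressmark.synthetic_data`)
emulates the assumed data structure — diametric visit pairs with
concordant VAS items, planted fold changes and on/off markers, a severe
arm, and hospitalizations drawn from an exponential model whose
log-hazard is linear in a planted marker — so every stage is testable
without patient data.

## Worked example

`examples/` contains one narrative script per capability. For instance,
`python examples/05_cfe_scorecard.py` tabulates and ranks CFE scorecards:

```
marker        own data  literature   total
maximum             36          18      54
marker_a            22          18      40
marker_b            20          15      35
reference           12          13      25

own data (max 36) = discovery + validation + testing;
literature (max 18) = external CFG + other disorders + drugs.
```

`marker_a` (discovery 4, external 12, validation 4, testing 6+4+4,
disorder 3, drug 3) totals 40 of the attainable 54; the `reference` row
shows a marker with no discovery or validation data of its own (such as
a literature comparator like telomere length) still accumulating
literature and testing points.

`python examples/01_simulate_and_discover.py` simulates a 36-subject
cohort with planted 1.41-fold markers and shows all of them clearing the
33.3% discovery threshold; `04_predict_state_and_trait.py` demonstrates a
planted marker predicting both high-stress state (AUC 0.88, p < 1e-4 in
all subjects) and future stress hospitalization (HR 1.8, p < 1e-3).

The same workflow runs from the shell:

```bash
stressmark simulate --out sim --seed 1
stressmark run-all --out results --seed 1
```

which writes `discovery_scores.tsv`, `cfg_scores.tsv`,
`validation_results.tsv`, `candidates.tsv`, `predictions.tsv`,
`cfe_scores.tsv`, up/down `.grp` signature tag lists, and a
`manifest.json` with input/output digests and per-step fold enrichments.

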