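# Methods

## Problem setting

Serum biomarkers for ovarian cancer are noisy across women but comparatively
stable within a woman. The algorithm implemented here therefore scores each
serum sample against the subject's *own* pre-disease baseline rather than a
population cut-off, converts the deviation to an ordinal specificity-based
score per marker, and combines the four scores in a logistic risk model whose
output is mapped to clinically interpretable positive predictive values.

## Temporal frame and alignment

All times are years-to-diagnosis (tDx), larger = earlier; "< k years tDx" is
strict everywhere. Controls have no diagnosis date, so each control is
matched to a case and her sample times are offset so that her last draw's tDx
equals the matched case's smallest tDx; inter-draw spacing is preserved. The
operation is idempotent and leaves case samples untouched. Calendar-date
matching is abstracted to this offset rule; control inputs may carry either
tDx directly or relative draw times (`draw_time_years`).

## Baseline and scoring

The baseline per subject and marker is the arithmetic mean of the up-to-three
samples with the largest tDx among those with tDx > 2 years. Subjects with no
qualifying sample are flagged (`usable=False`) and excluded from training and
threshold derivation rather than given a fabricated baseline; in screening
output they surface as unscored.

Deviation is absolute (|value − baseline|): up- and down-regulation count
symmetrically through one two-sided threshold set. A per-direction variant
would be a straightforward extension but is not the default reading adopted
here.

Thresholds at specificity level s among N control deviations use the ceiling
order statistic: the ⌈sN⌉-th smallest deviation, i.e. the smallest attained
value whose empirical CDF reaches s. Ties and the threshold comparison are
inclusive (deviation ≥ threshold crosses the bin), so a sample exactly as
extreme as the s-quantile is treated as having specificity ≥ s and empirical
specificity guarantees are conservative (fraction of controls scoring ≥ k is
at most 1 − s_k + 1/N). With fewer than 20 control deviations per marker a
warning flags unstable upper quantiles. Threshold derivation pools the
deviations of **all** samples of eligible controls (controls flagged as later
developing cancer are excluded from training and thresholds but still
screened).

Bins: CA125/PROZ/LCAT at (0.80, 0.90, 0.95, 0.975, 0.98, 0.99) → scores 0–6;
CRP at (0.70, 0.80, 0.90, 0.95, 0.99, 0.995, 0.999) → scores 0–7, exposing
CRP's wider usable specificity range to the model.

## Risk model

Scores enter as numeric covariates (one slope per marker — consistent with a
single odds ratio "per score increment"), fitted by Newton maximum likelihood
(log-likelihood tolerance 1e−8), standard errors from the observed
information, Wald p-values against the normal reference. Perfect separation
and non-convergence raise errors instead of returning divergent coefficients;
a singular information matrix (e.g. a constant score column) falls back to
BFGS, which leaves the flat directions at zero. The published model
(intercept −3.5270; CA125 0.8217; PROZ 0.5345; LCAT 0.3595; CRP 0.3419) is
loaded from `src/ovascreen/data/published_model.yaml` and never refitted.
Probabilities compared against printed two-decimal values use round-half-even.

The training design is asymmetric by protocol: case rows are aggressive
(Type II) histotype samples with tDx < 2; control rows are *all* samples of
eligible controls. Rows are unweighted even though women contribute unequal
sample counts.

## Cross-validation

Leave-one-out removes one *subject* (all her samples) per refit; k-fold
(default 10) partitions *sample rows*, label-stratified with a recorded seed
— the asymmetry mirrors the protocol being implemented. Coefficient
stability is the per-term sample SD (ddof = 1) across refits. Held-out
predictions from each k-fold split are scored by ROC within terminal strata
(cases tDx < 1, tDx < 2, 1 ≤ tDx < 2, each versus all held-out controls);
the reported AUC is the arithmetic mean of per-fold AUCs over folds where the
stratum contains both classes. When k exceeds the smaller class count
(e.g. k = n, leave-one-sample-out) stratification is infeasible and a plain
shuffled partition is used. Degenerate partitions are redrawn up to 10 times
with incremented seeds before erroring.

## Screening simulation

PPV = se·π / (se·π + (1−sp)(1−π)) per ROC row, with prevalence π a required
input: the example configuration uses 0.004 as a **placeholder** for an
unscreened-population EOC prevalence, and every PPV output records the
prevalence used. The ROC feeding the PPV table pools cases of both
histotypes at tDx < 2 versus all controls, scored by the final model on its
training predictions. A sample's PPV is that of the largest tabulated
threshold ≤ its probability; empirical PPV may be non-monotone in the
threshold, and the row-selection rule is applied as stated (an isotonic
smoothing switch would be a natural extension but is off by design).
Classes: S at PPV ≥ 0.30, E ≥ 0.05, I ≥ 0.025, else N.

The annual programme screens at years 4, 3, 2, 1 tDx; the year-y screen sees
samples with tDx ≥ y and uses the latest (smallest such tDx). Subject-years
without an eligible sample are reported as "no sample". Outputs are
per-subject trajectories, per-group class counts and severe fractions per
year, and year-to-year transition counts suitable for any Sankey/river
renderer.

## Synthetic cohort generator

The generator emulates the study design the algorithm assumes, not its
measured data:

- **Sizes**: 31 controls, 30 Type II, 19 Type I (10 borderline) by default;
  per-subject follow-up span U(5, 7) years with draws every 1.0 ± 0.2 years
  and the last draw 0.2–0.8 years before diagnosis, giving ≈ 6 draws/subject
  and ≈ 480 samples for the 80-subject default.
- **Control model**: per-subject log-normal baselines (between-subject log-SD
  0.4 around literature-typical serum levels) with mean-one multiplicative
  log-normal noise (CV 0.15; 0.30 for CRP, which is the most labile marker).
- **Case model**: identical to controls for tDx > 2; thereafter the expected
  level ramps log-linearly from the baseline to baseline × effect (or
  ÷ effect) at tDx = 0, with terminal fold-changes CA125 4.0, PROZ 2.0,
  LCAT 1.8, CRP 2.0 and upward-direction probabilities 0.9/0.3/0.3/0.8
  (CA125 and CRP mostly rise; PROZ and LCAT mostly fall). The mean-one noise
  makes the ramp exact in expectation, so continuity at onset holds exactly.
- **Matching**: controls are assigned to Type II cases round-robin and
  generated already aligned; age/centre/date covariates are not simulated.
- **Determinism**: one seed spawns per-subject child streams; fixed seed ⇒
  byte-identical cohorts, and CSV output uses repr-exact floats so the
  write/read round trip is lossless.

The per-marker effect sizes and control variances are free parameters of the
emulation — the source study reports none — so synthetic results demonstrate
that the pipeline's machinery behaves correctly (signal in → discrimination
out; no signal in → chance-level AUC and overwhelmingly normal control
trajectories), not that real-data performance figures are reproduced. The
generator also omits assay drift, age/centre structure and confounding
conditions (endometriosis, inflammation), so passing tests say nothing about
robustness to those.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on the default 80-subject cohort, toy fixtures,
and an exhaustive N ≤ 50 sweep for the quantile oracle; parameter recovery
uses 2 000 simulated score rows; the PPV confusion-matrix check simulates
10⁶ women; the null-behaviour check uses a 240-subject cohort. The
acceptance script evaluates the published model on the worked score vectors
and exercises the full pipeline once on the default-size cohort. These sizes
were chosen so the whole suite completes in well under a minute while keeping
Monte-Carlo error far inside the asserted tolerances.

## Known limitations

- Real-data performance (AUCs, severe-classification fractions, the 482/168
  sample accounting) cannot be recomputed without the original measurements.
- The quantile convention, tie handling, row weighting and k-fold seed policy
  of the original analysis are unstated; the choices above are assumptions,
  recorded here.
- Empirical PPV non-monotonicity is passed through, not smoothed.
- Prevalence is user-supplied; all PPV-dependent outputs scale with it.
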