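# ovascreen

A reusable implementation of a four-protein serum biomarker algorithm for the
early detection of epithelial ovarian cancer (EOC), aimed at biostatisticians
and screening-programme modellers. The panel — CA125, vitamin K-dependent
protein Z (PROZ), phosphatidylcholine-sterol acyltransferase (LCAT) and
C-reactive protein (CRP) — is read longitudinally: what matters is not a
marker's absolute level but its departure from the woman's own pre-disease
baseline, in either direction.

## The algorithm

1. **Baseline.** For each subject, the per-marker baseline is the mean of the
   earliest up to three samples drawn more than 2 years before diagnosis
   (tDx > 2), the interval in which cases behave like controls. Controls are
   assigned tDx by aligning each control's last draw to her matched case's
   last draw.
2. **Dysregulation scores.** Each sample's absolute deviation from baseline
   is binned against deviation thresholds placed at fixed specificity levels
   of the control deviation distribution — 80/90/95/97.5/98/99% for CA125,
   PROZ and LCAT (ordinal scores 0–6) and 70/80/90/95/99/99.5/99.9% for CRP
   (scores 0–7).
3. **Risk model.** A logistic regression on the four scores as numeric
   covariates:

   logit p(EOC) = β₀ + β₁·s_CA125 + β₂·s_PROZ + β₃·s_LCAT + β₄·s_CRP

   with published coefficients β = (−3.5270, 0.8217, 0.5345, 0.3595, 0.3419),
   shipped as a versioned constants file. exp(βᵢ) is the odds ratio per score
   increment. Refitting on new data, with leave-one-subject-out and k-fold
   cross-validation of coefficient stability and held-out ROC, is provided.
4. **Screening classification.** Every probability threshold has a
   sensitivity/specificity pair from ROC analysis; combined with disease
   prevalence it yields a positive predictive value
   PPV = se·π / (se·π + (1−sp)(1−π)). Samples are classed severe (S),
   elevated (E) or intermediate (I) at PPV ≥ 30%, 5%, 2.5%, else normal (N).
   An annual screening programme over years 4→1 before diagnosis classifies
   each subject's latest sample before each year's cut-off and tabulates
   trajectories and class transitions (river-plot data).

Because the original serum measurements are not publicly deposited, the
package includes a seedable synthetic cohort generator
(`ovascreen.cohort.generate_cohort`) that emulates the study design: ~31
controls and ~49 cases (30 aggressive Type II, 19 Type I of which 10
borderline), ~480 roughly annual serial draws spanning up to 7 years tDx,
stable control baselines with multiplicative assay noise, and case
dysregulation ramping log-linearly from 2 years tDx to a terminal
fold-change at diagnosis.

## Worked example

```python
from ovascreen import predict_risk, published_model

model = published_model()
for scores in ({"CA125": 6, "PROZ": 0, "LCAT": 0, "CRP": 0},
               {"CA125": 6, "PROZ": 1, "LCAT": 0, "CRP": 0},
               {"CA125": 0, "PROZ": 0, "LCAT": 0, "CRP": 7}):
    print(scores, round(predict_risk(scores, model), 2))
```

prints

```
{'CA125': 6, 'PROZ': 0, 'LCAT': 0, 'CRP': 0} 0.8
{'CA125': 6, 'PROZ': 1, 'LCAT': 0, 'CRP': 0} 0.87
{'CA125': 0, 'PROZ': 0, 'LCAT': 0, 'CRP': 7} 0.24
```

Maximal CA125 dysregulation alone reaches only p = 0.80 (elevated); a severe
classification needs a contribution from at least one further marker — the
panel's guard against single-marker confounders such as CA125 elevation in
endometriosis or CRP elevation in inflammation.

The `examples/` directory holds narrative scripts for each capability:
generating and scoring a synthetic cohort, fitting and cross-validating the
model, and running the screening simulation. A thin CLI wraps the same
library calls:

```bash
ovascreen simulate --seed 1 --out cohort/
ovascreen classify --subjects cohort/subjects.csv --samples cohort/samples.csv \
    --prevalence 0.004 --out classified/
ovascreen train    --subjects cohort/subjects.csv --samples cohort/samples.csv --out model.yaml
ovascreen validate --subjects cohort/subjects.csv --samples cohort/samples.csv --out cv/
```

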