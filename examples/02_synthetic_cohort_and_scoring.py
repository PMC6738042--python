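"""Generate a synthetic longitudinal cohort and score dysregulation.

The generator emulates a nested case-control serum series: stable control
baselines with multiplicative assay noise, and cases departing from baseline
(up or down, per marker) only within two years of diagnosis.  Scoring bins
each sample's absolute deviation from the subject's own baseline against
specificity thresholds derived from the controls.
"""

from ovascreen import Cohort, CohortConfig, generate_cohort, score_cohort
from ovascreen.scoring import scores_frame

subjects, samples = generate_cohort(CohortConfig(rng_seed=1))
cohort = Cohort(subjects, samples, aligned=True)
print(f"{len(subjects)} subjects, {len(samples)} serum samples")

scores, thresholds, baselines = score_cohort(cohort)
print(f"scored {len(scores)} samples; "
      f"{sum(not b.usable for b in baselines.values())} subjects lacked a usable baseline")

print("\nderived control specificity thresholds (deviation units):")
print(thresholds.to_frame().pivot(index="specificity", columns="marker", values="threshold"))

frame = scores_frame(scores)
near_dx = frame[frame.tdx_years < 1].drop(columns=["subject_id", "tdx_years"])
print("\nmean scores within 1 year of diagnosis (cases pull these up):")
print(near_dx.mean().round(2))
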