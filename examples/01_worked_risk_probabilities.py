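"""Evaluate the published four-marker risk model on example score vectors.

Each vector lists ordinal dysregulation scores {CA125, PROZ, LCAT, CRP};
the model returns the probability of epithelial ovarian cancer.  High risk
requires contributions from several markers: a maximal CA125 score alone
gives 0.80, while maximal CRP alone yields only 0.24.
"""

from ovascreen import odds_ratio, predict_risk, published_model

model = published_model()
print(f"intercept {model.intercept}, coefficients {model.coefficients}\n")

examples = [
    {"CA125": 6, "PROZ": 0, "LCAT": 0, "CRP": 0},
    {"CA125": 6, "PROZ": 1, "LCAT": 0, "CRP": 0},
    {"CA125": 2, "PROZ": 3, "LCAT": 3, "CRP": 3},
    {"CA125": 0, "PROZ": 0, "LCAT": 0, "CRP": 7},
]
for s in examples:
    p = predict_risk(s, model)
    vec = "{" + ",".join(str(s[m]) for m in ("CA125", "PROZ", "LCAT", "CRP")) + "}"
    print(f"scores {vec:>12} -> p(EOC) = {p:.2f}")

print("\nodds ratios per score increment:")
for term, v in odds_ratio(model).items():
    print(f"  {term:>9}: {v:.4g}")
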