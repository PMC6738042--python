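# Published four-marker logit risk model (versioned constants; do not edit).
# Risk of epithelial ovarian cancer as a function of the four dysregulation
# scores: logit(p) = intercept + sum_m coefficient[m] * score[m].
version: 1
intercept: -3.5270
coefficients:
  CA125: 0.8217
  PROZ: 0.5345
  LCAT: 0.3595
  CRP: 0.3419
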