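# Calibrated so the exact class distribution approximates the published
# six-class percentages (7.5 / 3.2 / 76.9 / 2.4 / 5.4 / 4.7; achieved squared
# percentage-point distance 2.17).  The error rates are illustrative values
# consistent with that table, not estimates of the real cohort's rates.
prev_ever: 0.1898571
onset_probs: [0.8964400, 0.0, 0.0339450, 0.0254588, 0.0190941, 0.0143206, 0.0107415]
fp: 0.0123259
fn: 0.0848335
answer_margins: [0.0681, 0.0857, 0.1258, 0.5214]
ineligible_or: 1.6
monotone_weight: 0.55
effects:
  beta_fn: 2.5
  beta_fp: 1.5
  beta_dropout: 0.1
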