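# Error-free reporting: every answer reflects the latent lifetime state,
# so no record can be classified inconsistent and cross-sectional bias is zero.
prev_ever: 0.231
onset_probs: [0.65, 0.0, 0.10, 0.08, 0.07, 0.06, 0.04]
fp: 0.0
fn: 0.0
answer_margins: [0.0681, 0.0857, 0.1258, 0.5214]
ineligible_or: 1.0
monotone_weight: 0.55
effects:
  beta_fn: 0.0
  beta_fp: 0.0
  beta_dropout: 0.0
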