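# Literature-derived tissue-stiffness priors for a transperineal prostate
# biopsy path: pelvic muscle (proxied by published gastrocnemius tangent
# modulus) followed by prostate (average of published benign and cancerous
# moduli). Standard deviations are deliberately wide to cover the spread of
# reported measurements; the truncation at zero is implicit in the prior
# model. Layer geometry here is a generic placeholder — patient-specific
# boundaries must come from imaging.
layers:
  - to_depth_mm: 60
    mu_mpa: 0.0103   # muscle
    sigma_mpa: 0.08
  - to_depth_mm: 125
    mu_mpa: 0.043    # prostate
    sigma_mpa: 0.08
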