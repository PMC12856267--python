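# SF-36 -> EQ-5D utility mapping: published linear regression algorithm
# (Ara & Brazier style). Domain scores on the 0-100 scale.
# Coefficients are data, not code, so alternative mapping algorithms can be
# plugged in via a file with the same layout.
name: sf36-to-eq5d-linear
intercept: 0.03256
slopes:
  pf: 0.00370   # physical functioning
  sf: 0.00111   # social functioning
  rp: -0.00024  # role physical
  re: 0.00024   # role emotional
  mh: 0.00256   # mental health
  vt: -0.00063  # vitality
  bp: 0.00286   # bodily pain
  gh: 0.00052   # general health
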