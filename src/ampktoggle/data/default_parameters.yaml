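# Calibrated default parameters for the extended AMPK-mTORC1-ULK1-ATG model.
# Produced by ampktoggle.calibration (qualitative-constraint calibration:
# full main-text phenotype matrix at zero violations plus a non-empty
# bistable window in the stress input S).
# Fixed by convention, not searched: kamtor = 0.025 (half the 0.05
# hyper-activated value), totals AT = MT = UT = GT = 1, and the absence of
# a basal ULK1 activation term.
# provenance:
#   calibration_seed: 1
#   search: latin-hypercube screening + coordinate refinement
#   constraint_digest: main-text-matrix-v1 + bistable-window
parameters:
  kaA: 0.06
  S: 1.0
  kiA: 0.012
  kiAU: 0.156
  kiAM: 0.18
  kamtor: 0.025
  kiM: 0.022
  kiMA: 0.01
  kiMU: 0.07
  kaUA: 0.03
  kiU: 0.0003
  kiUM: 0.12
  kaG0: 0.005
  kaGU: 0.05
  kiG: 0.01
  kiGM: 0.2
  JaA: 0.01
  JiA: 0.005
  JaM: 0.1
  JiM: 0.1
  JaU: 0.05
  JiU: 0.2
  JaG: 0.01
  JiG: 0.01
  AT: 1.0
  MT: 1.0
  UT: 1.0
  GT: 1.0
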