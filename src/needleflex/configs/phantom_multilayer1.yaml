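# Example layered PVC-phantom stiffness profile (manually fitted moduli for
# a three-layer phantom). Layer boundaries are illustrative: equal thirds of
# the tissue column; the physical phantom geometry is not reproduced here.
layers:
  - to_depth_mm: 42
    modulus_mpa: 0.028
  - to_depth_mm: 84
    modulus_mpa: 0.014
  - to_depth_mm: 125
    modulus_mpa: 0.028
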