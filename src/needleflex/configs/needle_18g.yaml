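# 18-gauge nitinol biopsy needle (the package defaults, spelled out).
length: 140.0            # mm
outer_diameter: 1.27     # mm
inner_diameter: 0.838    # mm
elastic_modulus: 35000.0 # MPa
bevel_angle: 30.0        # degrees
n_elements: 47
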