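# 43-caudal tail with the length/height crossing planted at Ca25,
# light measurement noise, and four interior vertebrae deleted.
n_vertebrae: 43
ca1_height_cm: 25.0
ca1_length_cm: 6.0
height_taper: 0.93
tp_true: 25
noise_sd_cm: 0.1
missing_positions: [4, 9, 27, 37]
seed: 42
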