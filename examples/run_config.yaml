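# One synthetic tail processed through the full pipeline, plus the
# Diplodocus direct-parameter preset for the comparative table.
velocity_preset: as_implied   # or as_stated (2 m/s)
transfer_efficiency: 0.85
density: 0.8
tissue:
  muscle_fraction: 0.359
  skin_fraction: 0.057
specimens:
  - id: synthetic
    taxon: synthetic cone tail
    synthetic:
      n_vertebrae: 43
      ca1_height_cm: 25.0
      ca1_length_cm: 6.0
      height_taper: 0.93
      tp_true: 25
      noise_sd_cm: 0.1
      missing_positions: [4, 9, 27, 37]
      seed: 42
  - id: NHMW-1904-0004-0003
    taxon: Diplodocus carnegii
    direct:
      n_caudals: 70
      total_length_m: 13.26
      whip_length_m: 7.28
      mass_kg: 33.2
      velocity_m_s: 104.0
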