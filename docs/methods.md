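# Methods

## The model

The tail is treated as a serial chain of measured caudal vertebrae
(Ca1 = first caudal, increasing toward the tip). Two measurements per
vertebra drive everything: centrum length *l*ᵢ (cranio-caudal extent of the
centrum, cm) and total height *h*ᵢ (dorso-ventral extent including the neural
spine, cm).

**Length.** Total tail length is *l* = Σ *l*ᵢ with no allowance for
intervertebral space; range-of-motion work on articulated material shows
essentially no room for soft tissue between centra, so adding disc thickness
would bias the length upward with nothing to calibrate it against.

**Segmentation.** Tapering reptilian tails show a morphological inflection
where vertebrae become distinctly longer than tall; distal to it the elements
are elongate and gracile, and the segment behaves as a flexible whip. The
transition point (TP) is the first position with *l*ᵢ > *h*ᵢ — strictly:
"longer than tall" is read as a strict inequality, so an exactly square
vertebra is not yet whip. By default the condition must also hold at every
measured position caudal of the TP (`persistence=True`); fossil measurement
series contain single-vertebra irregularities from taphonomic compression,
and a one-element crossing that immediately reverses is noise, not anatomy.
The whip segment is [TP, tip] inclusive and the whip fraction is its length
share of the tail.

**Mass.** The tail is idealised as an elongate cone,
Vol = ⅓ π r² l, with r = ½ *h*₁ (half the height of Ca1) and l the summed
length; volume converts to mass at 0.8 kg per 1000 cm³, the bulk density used
in volumetric whole-body reconstructions of large sauropodomorphs. The whip
segment gets its own cone with r = ½ *h*(TP). The choice of the TP vertebra as
the whip cone's reference is a reconstruction of an under-specified published
calculation: inverting the published whiplash mass (0.3 kg over ~0.6 m at
density 0.8) gives a radius ≈ 2.4 cm, i.e. a vertebral height ≈ 4.9 cm —
anatomically a mid-tail element, consistent with the TP vertebra. This is
documented as reverse-engineered, not stated by the source.

**Soft tissue.** With muscle occupying fraction f_m = 0.359 and skin
f_s = 0.057 of the fleshed-out volume, bone and remaining tissue fill
1 − f_m − f_s = 0.584 of it, so the fleshed radius is the bone-defined radius
× k = 1/0.584 ≈ 1.7123. The factor scales the radius, hence mass by k²
(≈ 2.93). `TissueModel` uses the exact value by default; the
`published`/`--published-rounding` mode substitutes the conventional 1.7
(k² = 2.89) to reproduce published numbers at their printed precision.

**Energy.** E = ½ m v², in J (rendered as kJ to 3 decimals in the
single-specimen grid and 2 decimals in the comparative table). Scenarios:
whole tail swung horizontally; energy transferred through the whiplash
(whole-tail energy × 0.85); and a quick whiplash strike of the whip cone
alone. The 0.85 is not stated anywhere in the source text — it is implied,
to within 5×10⁻⁴, by all four published transferred/total ratios — and is
therefore an explicit, configurable constant labelled reverse-engineered.

**Velocities are always explicit inputs.** The source states an upper-bound
strike velocity of 2 m s⁻¹ but prints energies that require ~65.1 m s⁻¹
(whole tail) and ~59.8 m s⁻¹ (whiplash), obtained here by v = √(2E/m). The
pipeline ships both presets (`as_stated`, `as_implied`) and the audit reports
the conflict; the package deliberately refuses to decide which is "correct".

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| density | 0.8 | kg/litre | published volumetric-reconstruction value |
| muscle_fraction | 0.359 | — | published body-composition model |
| skin_fraction | 0.057 | — | published body-composition model |
| radius_scaling_factor | 1/0.584 ≈ 1.712 | — | derived; 1.7 in published-rounding mode |
| transfer_efficiency | 0.85 | — | reverse-engineered from published ratios |
| whole-tail / whiplash velocity | preset | m/s | `as_stated` = 2; `as_implied` ≈ 65.1 / 59.8 |
| persistence | True | — | suppresses single-vertebra spurious crossings |

## Imputation

Interior missing vertebrae are estimated from their neighbours: a single gap
takes the arithmetic mean of the flanking elements' length and height; runs
of consecutive gaps are linearly interpolated between the flanking preserved
elements (which reduces to the mean for single gaps). Heights are imputed by
the same rule as lengths so downstream cone radii stay computable — a minimal
consistent extension of the published mean-length rule. Terminal gaps are
never extrapolated and raise an error: no neighbour constrains them. Because
a geometric taper is convex, linear imputation systematically overestimates
by at most the local second difference of the profile; a test asserts that
bound.

## Synthetic data

`SyntheticSeriesSpec` emulates the serial structure of a real tail: heights
decay geometrically (default taper 0.93 per vertebra, Ca1 height 25 cm,
43 vertebrae — a tail of roughly 2 m total length and 26 kg bone-cone mass,
i.e. the regime of a mid-sized sauropodomorph), lengths decay more slowly so
the length/height ratio rises monotonically and crosses 1 exactly at the
planted position `tp_true` (the length taper is solved analytically from the
height taper and `tp_true`). Noise is an independent zero-truncated normal
per measurement — the simplest non-negative perturbation, since published
accounts attribute the irregularities to taphonomic distortion and individual
variation without offering a distributional model. One seed controls all
randomness.

`ground_truth` recomputes every downstream quantity from the spec parameters
alone (geometric-series sums, the cone formula inline), sharing no code with
the pipeline, so parameter-recovery tests have an independent oracle.

What the generator does **not** emulate: directional diagenetic deformation
(medio-lateral flattening grows caudally in real specimens), correlated
measurement error along the column, non-monotone mid-tail elongation maxima,
or allometric differences between taxa. Passing recovery tests therefore show
the pipeline is correct on idealised tapering tails with independent noise,
not that the cone model is an accurate volumetric description of any real
animal.

## Numerical choices and test problem sizes

- Measurements are written with `%.17g` and parsed with round-trip float
  precision, so write→read cycles are bit-exact.
- Ties (*l* = *h*) never trigger the TP; equality is "not yet whip".
- Detection requires ≥ 2 measured vertebrae; un-imputed gaps within one
  position of a detected crossing raise an error rather than silently
  shifting the TP.
- Published-precision comparisons use one unit in the last printed digit as
  the band, because at least one published energy (½·33.2·104² = 179.5456 kJ
  vs the printed 179.54) is truncated rather than rounded.
- The transition-point recovery study uses 120 series (40 seeds × 3 planted
  crossings on a 43-vertebra tail) with noise sd set to 5% of the smallest
  noiseless vertebral height, so the sd is at most 5% of every local height;
  the noiseless sweep covers every interior crossing position of a
  20-vertebra tail. Both sizes keep the whole suite in the seconds range
  while giving the recovery rate a resolution of under 1%.

## Known limitations

- The cone is a deliberately crude volume model: no frustum, elliptical
  section, or CT-derived geometry; whole-body mass is never recomputed.
- Extant-taxon tail masses are free config parameters; the allometric
  regressions behind the published comparative rows are cited constants, not
  re-derived, so those rows carry their published energies unchanged.
- The audit can only test internal consistency of printed values; where the
  underlying measurement appendix is required (e.g. the exact Ca1 height
  behind the 26.5 kg bone mass), the package substitutes property-based
  checks on synthetic tails of matching geometry.
- Published bookkeeping left unreconciled on purpose: 43 preserved + 4
  missing ≠ ~45 expected caudals (both counts are stored, their sum is not
  enforced); the whip share of the historical Trossingen specimen (~40% in
  the text vs 18.7% in the comparative table); which total length (195.8 vs
  196 cm) produced the published bone mass.
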