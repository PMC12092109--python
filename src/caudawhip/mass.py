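"""Elongate-cone tail mass model with optional soft-tissue scaling.

The tail is idealised as a cone of radius r = half the total height of the
cranial-most caudal vertebra (Ca1) and length l = the summed centrum
lengths, so Vol = (1/3)·π·r²·l.  Volume converts to mass at a bulk density
of 0.8 kg per 1000 cm³ (0.8 kg/litre), the value used in volumetric
whole-body reconstructions of large-bodied sauropodomorphs.

Soft tissue is added radially: with muscle and skin occupying fractions
f_m and f_s of the fleshed-out volume, bone plus the remaining tissue fill
1 − f_m − f_s of it, so the fleshed radius is the bone-defined radius
times k = 1/(1 − f_m − f_s) and the mass scales by k² (radius enters the
cone volume quadratically).  For f_m = 0.359 and f_s = 0.057, k ≈ 1.71,
conventionally rounded to 1.7.

The whip segment gets its own, smaller cone: radius = half the height of
the transition-point vertebra, length = the whip-segment length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError
from .segmentation import WhipSegmentation
from .series import VertebralSeries, total_length

__all__ = [
    "TissueModel",
    "TailMassModel",
    "cone_volume",
    "volume_to_mass",
    "soft_tissue_scaling_factor",
    "apply_soft_tissue",
    "tail_mass",
]

#: bulk density, kg per litre (= kg per 1000 cm³)
DEFAULT_DENSITY_KG_PER_LITRE = 0.8


def cone_volume(radius_cm: float, length_cm: float) -> float:
    """Volume of a cone, (1/3)·π·r²·l, in cm³. Zero inputs give zero."""
    if radius_cm < 0 or length_cm < 0:
        raise ValidationError(
            f"cone dimensions must be non-negative, got r={radius_cm}, l={length_cm}"
        )
    return (math.pi / 3.0) * radius_cm**2 * length_cm


def volume_to_mass(volume_cm3: float, density_kg_per_litre: float) -> float:
    """Mass in kg of a volume in cm³ at the given density (kg per 1000 cm³)."""
    if volume_cm3 < 0:
        raise ValidationError(f"volume must be non-negative, got {volume_cm3}")
    if density_kg_per_litre <= 0:
        raise ValidationError(f"density must be positive, got {density_kg_per_litre}")
    return volume_cm3 * density_kg_per_litre / 1000.0


def soft_tissue_scaling_factor(muscle_fraction: float, skin_fraction: float) -> float:
    """Radial scaling factor 1/(1 − muscle − skin) inflating the bone cone.

    For the standard fractions (0.359 muscle, 0.057 skin) this is
    1/0.584 ≈ 1.712, reported at 2 significant figures as 1.7.
    """
    for name, f in (("muscle", muscle_fraction), ("skin", skin_fraction)):
        if not (0 <= f < 1):
            raise ValidationError(f"{name} fraction must be in [0, 1), got {f}")
    remainder = 1.0 - muscle_fraction - skin_fraction
    if remainder <= 0:
        raise ValidationError(
            f"tissue fractions sum to {muscle_fraction + skin_fraction}, must be < 1"
        )
    return 1.0 / remainder


def apply_soft_tissue(bone_mass_kg: float, factor: float) -> float:
    """Soft-tissue-inclusive mass: bone mass × factor².

    The factor scales the cone *radius*, so it enters the mass quadratically.
    """
    if bone_mass_kg <= 0:
        raise ValidationError(f"bone mass must be positive, got {bone_mass_kg}")
    if factor <= 0:
        raise ValidationError(f"scaling factor must be positive, got {factor}")
    return bone_mass_kg * factor**2


@dataclass(frozen=True)
class TissueModel:
    """Muscle and skin volume fractions plus the derived radial factor.

    ``radius_scaling_factor`` defaults to the exact 1/(1 − muscle − skin);
    pass an explicit value (e.g. the conventionally rounded 1.7) to
    reproduce published numbers at their printed precision.
    """

    muscle_fraction: float = 0.359
    skin_fraction: float = 0.057
    radius_scaling_factor: float | None = None

    def __post_init__(self) -> None:
        derived = soft_tissue_scaling_factor(self.muscle_fraction, self.skin_fraction)
        if self.radius_scaling_factor is None:
            object.__setattr__(self, "radius_scaling_factor", derived)
        elif self.radius_scaling_factor <= 0:
            raise ValidationError("radius_scaling_factor must be positive")

    @property
    def factor(self) -> float:
        return self.radius_scaling_factor  # type: ignore[return-value]


@dataclass(frozen=True)
class TailMassModel:
    """Cone geometry and the resulting mass for a tail or tail segment.

    ``radius_cm`` is the bone-defined radius (half a vertebral height);
    ``volume_cm3`` is the effective cone volume — with a tissue model the
    radius is inflated by its factor before cubing up, so
    ``mass_kg = volume_cm3 · density / 1000`` always holds, and with
    tissue applied the mass equals the bone-only mass × factor².
    """

    radius_cm: float
    length_cm: float
    density_kg_per_litre: float = DEFAULT_DENSITY_KG_PER_LITRE
    tissue: TissueModel | None = None

    def __post_init__(self) -> None:
        if self.radius_cm <= 0 or self.length_cm <= 0:
            raise ValidationError(
                f"cone dimensions must be positive, got r={self.radius_cm}, "
                f"l={self.length_cm}"
            )
        if self.density_kg_per_litre <= 0:
            raise ValidationError("density must be positive")

    @property
    def bone_volume_cm3(self) -> float:
        return cone_volume(self.radius_cm, self.length_cm)

    @property
    def volume_cm3(self) -> float:
        f = self.tissue.factor if self.tissue is not None else 1.0
        return cone_volume(self.radius_cm * f, self.length_cm)

    @property
    def bone_mass_kg(self) -> float:
        return volume_to_mass(self.bone_volume_cm3, self.density_kg_per_litre)

    @property
    def mass_kg(self) -> float:
        return volume_to_mass(self.volume_cm3, self.density_kg_per_litre)


def tail_mass(
    series: VertebralSeries,
    segmentation: WhipSegmentation | None = None,
    tissue: TissueModel | None = None,
    density: float = DEFAULT_DENSITY_KG_PER_LITRE,
    include_imputed: bool = True,
) -> tuple[TailMassModel, TailMassModel | None]:
    """Cone mass models for the whole tail and (optionally) the whip segment.

    The whole-tail cone uses r = height(Ca1)/2 and l = total length; the
    whip cone uses r = height(TP vertebra)/2 and l = whip length.  Raises
    :class:`ValidationError` naming the position when a required height is
    absent.
    """
    ca1 = series.get(1)
    if ca1 is None:
        raise ValidationError(
            f"{series.specimen_id}: Ca1 height required for the whole-tail cone "
            "but no record exists at position 1"
        )
    whole = TailMassModel(
        radius_cm=ca1.total_height_cm / 2.0,
        length_cm=total_length(series, include_imputed=include_imputed),
        density_kg_per_litre=density,
        tissue=tissue,
    )
    whip_model: TailMassModel | None = None
    if segmentation is not None:
        tp = series.get(segmentation.tp_position)
        if tp is None:
            raise ValidationError(
                f"{series.specimen_id}: TP vertebra height required but no record "
                f"exists at position {segmentation.tp_position}"
            )
        whip_model = TailMassModel(
            radius_cm=tp.total_height_cm / 2.0,
            length_cm=segmentation.whip_length_cm,
            density_kg_per_litre=density,
            tissue=tissue,
        )
    return whole, whip_model
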