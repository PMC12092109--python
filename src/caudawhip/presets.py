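"""Ready-made specimen configs for the published comparative taxa.

The Diplodocus preset carries the published tail mass (33.2 kg, bone
only) and strike velocity (104 m s⁻¹), so its comparative-table energy is
recomputed; the extant taxa and the historical Trossingen skeleton carry
their published summary values directly (their masses were derived
allometrically in the original sources and are not recomputed here).
"""

from __future__ import annotations

from . import reference as ref
from .pipeline import DirectParams, SpecimenConfig

__all__ = ["diplodocus_preset", "comparative_presets"]


def diplodocus_preset() -> SpecimenConfig:
    row = next(r for r in ref.TABLE2 if "Diplodocus" in r["taxon"])
    return SpecimenConfig(
        specimen_id=row["specimen_id"],
        taxon=row["taxon"],
        direct=DirectParams(
            n_caudals=row["n_caudals"],
            total_length_m=row["total_length_m"],
            whip_length_m=row["whip_length_m"],
            mass_kg=ref.DIPLODOCUS_TAIL_MASS_KG,
            velocity_m_s=ref.DIPLODOCUS_STRIKE_VELOCITY_M_S,
        ),
    )


def comparative_presets() -> tuple[SpecimenConfig, ...]:
    """All published comparative rows as direct-parameter specimens."""
    out = []
    for row in ref.TABLE2:
        if "Diplodocus" in row["taxon"]:
            out.append(diplodocus_preset())
            continue
        out.append(
            SpecimenConfig(
                specimen_id=row["specimen_id"],
                taxon=row["taxon"],
                direct=DirectParams(
                    n_caudals=row["n_caudals"],
                    total_length_m=row["total_length_m"],
                    whip_length_m=row["whip_length_m"],
                    energy_kj=row["energy_kJ"],
                ),
            )
        )
    return tuple(out)
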