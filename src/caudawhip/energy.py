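"""Kinetic-energy scenarios for defensive tail strikes.

All scenarios use E = ½·m·v² with the mass from the cone model and an
explicit strike velocity.  Three scenarios are distinguished:

``whole_tail``
    the whole tail swung horizontally (mass = whole-tail cone mass);
``whip_transferred``
    the fraction of whole-tail energy delivered through the whiplash,
    whole-tail energy × a transfer efficiency (default 0.85 — not stated
    in the source text but implied by every published transferred/total
    ratio; treat it as a reverse-engineered, configurable constant);
``quick_whiplash``
    a rapid, focused strike of the whip segment alone
    (mass = whip-segment cone mass).

Velocities are always explicit inputs.  The published tables are
internally inconsistent on this point: the stated strike velocity of
2 m s⁻¹ cannot generate the printed kilojoule values, which instead imply
velocities near 65 m s⁻¹ (whole tail) and 60 m s⁻¹ (whiplash).
:func:`back_solve_velocity` exposes the implied values, and the audit
stage reports the conflict rather than resolving it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .mass import TailMassModel

__all__ = [
    "StrikeScenario",
    "EnergyReport",
    "kinetic_energy",
    "transferred_energy",
    "back_solve_velocity",
    "evaluate_scenarios",
    "comparative_table",
    "ComparativeRow",
    "DEFAULT_TRANSFER_EFFICIENCY",
]

#: transferred/total ratio implied by published tables; not stated in text
DEFAULT_TRANSFER_EFFICIENCY = 0.85


def kinetic_energy(mass_kg: float, velocity_m_s: float) -> float:
    """E = ½·m·v², in joules."""
    if mass_kg <= 0:
        raise ValidationError(f"mass must be positive, got {mass_kg}")
    if velocity_m_s < 0:
        raise ValidationError(f"velocity must be non-negative, got {velocity_m_s}")
    return 0.5 * mass_kg * velocity_m_s**2


def transferred_energy(total_energy_j: float, efficiency: float) -> float:
    """Energy delivered through the whiplash: total × efficiency."""
    if total_energy_j < 0:
        raise ValidationError(f"energy must be non-negative, got {total_energy_j}")
    if not (0 < efficiency <= 1):
        raise ValidationError(f"efficiency must be in (0, 1], got {efficiency}")
    return total_energy_j * efficiency


def back_solve_velocity(energy_j: float, mass_kg: float) -> float:
    """Velocity implied by an (E, m) pair: sqrt(2E/m). Exact inverse of ½mv²."""
    if energy_j <= 0:
        raise ValidationError(f"energy must be positive, got {energy_j}")
    if mass_kg <= 0:
        raise ValidationError(f"mass must be positive, got {mass_kg}")
    return math.sqrt(2.0 * energy_j / mass_kg)


@dataclass(frozen=True)
class StrikeScenario:
    """A (mass, velocity, efficiency) triple defining one energy estimate."""

    label: str
    mass_kg: float
    velocity_m_s: float
    transfer_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValidationError("mass must be positive")
        if self.velocity_m_s <= 0:
            raise ValidationError("velocity must be positive")
        if not (0 < self.transfer_efficiency <= 1):
            raise ValidationError("transfer efficiency must be in (0, 1]")

    @property
    def energy_j(self) -> float:
        return kinetic_energy(self.mass_kg, self.velocity_m_s) * self.transfer_efficiency

    @property
    def energy_kj(self) -> float:
        return self.energy_j / 1000.0


@dataclass
class EnergyReport:
    """Per-scenario strike energies for one specimen/mass variant."""

    specimen_id: str
    energies_j: dict[str, float] = field(default_factory=dict)
    implied_velocities: dict[str, float] = field(default_factory=dict)

    @property
    def energies_kj(self) -> dict[str, float]:
        return {k: v / 1000.0 for k, v in self.energies_j.items()}


def evaluate_scenarios(
    whole: TailMassModel,
    whip: TailMassModel,
    *,
    specimen_id: str = "",
    whole_tail_velocity_m_s: float,
    whiplash_velocity_m_s: float,
    transfer_efficiency: float = DEFAULT_TRANSFER_EFFICIENCY,
) -> EnergyReport:
    """Evaluate the three strike scenarios for one (whole, whip) mass pair.

    whole_tail = ½·m_tail·v_tail²; whip_transferred = whole_tail ×
    efficiency; quick_whiplash = ½·m_whip·v_whip².
    """
    whole_j = kinetic_energy(whole.mass_kg, whole_tail_velocity_m_s)
    report = EnergyReport(specimen_id=specimen_id)
    report.energies_j = {
        "whole_tail": whole_j,
        "whip_transferred": transferred_energy(whole_j, transfer_efficiency),
        "quick_whiplash": kinetic_energy(whip.mass_kg, whiplash_velocity_m_s),
    }
    return report


@dataclass(frozen=True)
class ComparativeRow:
    """One taxon/specimen row of the multi-taxon comparison."""

    specimen_id: str
    taxon: str
    n_caudals: float
    total_length_m: float | None
    whip_length_m: float | None
    energy_kj: float | None

    @property
    def whip_pct(self) -> float | None:
        if self.total_length_m and self.whip_length_m is not None:
            return 100.0 * self.whip_length_m / self.total_length_m
        return None


def comparative_table(rows: list[ComparativeRow]) -> pd.DataFrame:
    """Assemble the comparative table (one row per specimen).

    Lengths rounded to 2 decimals, whip percentage and energy to 2
    decimals, matching the conventional presentation; missing whip data
    (no transition detected) leaves the whip columns blank.
    """
    if not rows:
        raise ValidationError("comparative table needs at least one specimen")
    records = []
    for r in rows:
        records.append(
            {
                "specimen_id": r.specimen_id,
                "taxon": r.taxon,
                "n_caudals": round(r.n_caudals, 2),
                "total_tail_length_m": None
                if r.total_length_m is None
                else round(r.total_length_m, 2),
                "whip_length_m": None
                if r.whip_length_m is None
                else round(r.whip_length_m, 2),
                "whip_pct": None if r.whip_pct is None else round(r.whip_pct, 2),
                "energy_kJ": None if r.energy_kj is None else round(r.energy_kj, 2),
            }
        )
    return pd.DataFrame.from_records(records)
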