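"""Synthetic vertebral series with closed-form ground truth.

The generator emulates the serial structure of a tapering reptilian tail:
total vertebral height decays geometrically toward the tip while centrum
length decays more slowly, so the length/height ratio grows monotonically
and crosses 1 at a configurable position — the planted transition point.
Measurement noise is an independent zero-truncated normal perturbation per
measurement (heights and lengths never go non-positive), and arbitrary
interior positions can be deleted to exercise the imputation machinery.

Given height taper d_h and a planted crossing at position t, the length
taper is d_l = g·d_h with g = ρ^(−1/(t−1.5)) and ρ = l₁/h₁ < 1, which puts
the noiseless ratio ρ·g^(i−1) exactly at 1 at fractional position t−0.5:
strictly below 1 at t−1, strictly above at t.

:func:`ground_truth` recomputes every downstream quantity (lengths,
segmentation, cone masses, strike energies) directly from the spec's
parameters using geometric-series sums — no code shared with the pipeline
— so parameter-recovery tests have an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .errors import ValidationError
from .mass import TissueModel
from .series import VertebraRecord, VertebralSeries

__all__ = ["SyntheticSeriesSpec", "GroundTruth", "generate_series", "ground_truth"]


@dataclass(frozen=True)
class SyntheticSeriesSpec:
    """Parameters of one synthetic tail.

    ``tp_true`` is the planted crossing position (first vertebra longer
    than tall, noiselessly); it must be interior, i.e. in
    [2, n_vertebrae − 1].  ``noise_sd_cm`` is the standard deviation, in
    cm, of the zero-truncated normal measurement noise.
    """

    n_vertebrae: int = 43
    ca1_height_cm: float = 25.0
    ca1_length_cm: float = 6.0
    height_taper: float = 0.93
    tp_true: int = 25
    noise_sd_cm: float = 0.0
    missing_positions: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertebrae < 3:
            raise ValidationError(f"need >= 3 vertebrae, got {self.n_vertebrae}")
        if not (0 < self.height_taper < 1):
            raise ValidationError(
                f"height_taper must be in (0, 1), got {self.height_taper}"
            )
        if self.ca1_height_cm <= 0 or self.ca1_length_cm <= 0:
            raise ValidationError("Ca1 dimensions must be positive")
        if self.ca1_length_cm >= self.ca1_height_cm:
            raise ValidationError(
                "Ca1 must be taller than long so the ratio starts below 1"
            )
        if not (2 <= self.tp_true <= self.n_vertebrae - 1):
            raise ValidationError(
                f"tp_true must be interior, in [2, {self.n_vertebrae - 1}], "
                f"got {self.tp_true}"
            )
        if self.noise_sd_cm < 0:
            raise ValidationError("noise_sd_cm must be non-negative")
        bad = [
            p
            for p in self.missing_positions
            if not (1 < p < self.n_vertebrae)
        ]
        if bad:
            raise ValidationError(
                f"missing_positions must be interior (2..{self.n_vertebrae - 1}), "
                f"got {bad}"
            )
        object.__setattr__(
            self, "missing_positions", tuple(sorted(set(self.missing_positions)))
        )

    # --- noiseless profile, shared by the generator and the oracle ---------

    @property
    def length_taper(self) -> float:
        rho = self.ca1_length_cm / self.ca1_height_cm
        g = rho ** (-1.0 / (self.tp_true - 1.5))
        return g * self.height_taper

    def noiseless_height(self, position: int) -> float:
        return self.ca1_height_cm * self.height_taper ** (position - 1)

    def noiseless_length(self, position: int) -> float:
        return self.ca1_length_cm * self.length_taper ** (position - 1)


def generate_series(spec: SyntheticSeriesSpec) -> VertebralSeries:
    """Generate a vertebral series from a spec; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for pos in range(1, spec.n_vertebrae + 1):
        length = spec.noiseless_length(pos)
        height = spec.noiseless_height(pos)
        if spec.noise_sd_cm > 0:
            length = _truncated_normal(rng, length, spec.noise_sd_cm)
            height = _truncated_normal(rng, height, spec.noise_sd_cm)
        if pos in spec.missing_positions:
            continue
        records.append(
            VertebraRecord(
                position=pos,
                centrum_length_cm=float(length),
                total_height_cm=float(height),
                preserved=True,
            )
        )
    return VertebralSeries(
        specimen_id=f"synthetic-seed{spec.seed}",
        taxon="synthetic",
        records=tuple(records),
        expected_count=spec.n_vertebrae,
        missing_positions=spec.missing_positions,
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    # normal(mean, sd) truncated at zero so measurements stay positive
    a = (0.0 - mean) / sd
    return float(truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form expectations for a noiseless synthetic series."""

    tp_position: int
    total_length_cm: float
    whip_length_cm: float
    whip_fraction: float
    whole_radius_cm: float
    whip_radius_cm: float
    whole_bone_mass_kg: float
    whip_bone_mass_kg: float
    whole_soft_mass_kg: float | None
    whip_soft_mass_kg: float | None
    energies_j: dict[str, float] = field(default_factory=dict)


def ground_truth(
    spec: SyntheticSeriesSpec,
    density: float = 0.8,
    tissue: TissueModel | None = None,
    *,
    whole_tail_velocity_m_s: float = 2.0,
    whiplash_velocity_m_s: float = 2.0,
    transfer_efficiency: float = 0.85,
) -> GroundTruth:
    """Expected pipeline outputs computed directly from the spec parameters.

    Uses geometric-series sums and the cone formula inline; shares no code
    with the pipeline stages it is used to check.
    """
    n, tp = spec.n_vertebrae, spec.tp_true
    l1, dl = spec.ca1_length_cm, spec.length_taper
    # sum_{i=1}^{n} l1*dl^(i-1) and the suffix from tp
    total = l1 * (1 - dl**n) / (1 - dl) if dl != 1 else l1 * n
    whip = l1 * dl ** (tp - 1) * (1 - dl ** (n - tp + 1)) / (1 - dl)

    r_whole = spec.ca1_height_cm / 2.0
    r_whip = spec.noiseless_height(tp) / 2.0
    bone_whole = (math.pi / 3.0) * r_whole**2 * total * density / 1000.0
    bone_whip = (math.pi / 3.0) * r_whip**2 * whip * density / 1000.0

    soft_whole = soft_whip = None
    if tissue is not None:
        f2 = tissue.factor**2
        soft_whole, soft_whip = bone_whole * f2, bone_whip * f2

    m_whole = soft_whole if soft_whole is not None else bone_whole
    m_whip = soft_whip if soft_whip is not None else bone_whip
    whole_j = 0.5 * m_whole * whole_tail_velocity_m_s**2
    energies = {
        "whole_tail": whole_j,
        "whip_transferred": whole_j * transfer_efficiency,
        "quick_whiplash": 0.5 * m_whip * whiplash_velocity_m_s**2,
    }
    return GroundTruth(
        tp_position=tp,
        total_length_cm=total,
        whip_length_cm=whip,
        whip_fraction=whip / total,
        whole_radius_cm=r_whole,
        whip_radius_cm=r_whip,
        whole_bone_mass_kg=bone_whole,
        whip_bone_mass_kg=bone_whip,
        whole_soft_mass_kg=soft_whole,
        whip_soft_mass_kg=soft_whip,
        energies_j=energies,
    )
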