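"""Config-driven orchestration: read → impute → segment → mass → energy →
comparative report across multiple specimens, plus the audit mode.

A run config lists specimens of three kinds:

* ``measurements`` — a per-vertebra CSV/TSV table, fully processed through
  imputation, segmentation and the cone model;
* ``synthetic`` — a generator spec, materialised at run time and then
  processed identically;
* ``direct`` — summary parameters (caudal count, lengths, mass, velocity)
  for taxa without per-vertebra data, which contribute a comparative-table
  row only.

For each measured specimen the pipeline emits a four-column mass/energy
grid (bone / bone+imputed / soft / soft+imputed), a per-vertebra profile,
and a comparative-table row; the bundle also carries the audit report when
requested.  Velocity presets: ``as_stated`` uses the stated 2 m s⁻¹ strike
velocity; ``as_implied`` back-solves velocities from the published Vienna
energies (≈65 and ≈60 m s⁻¹) — the two presets disagree by design, and the
audit flags the conflict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import reference as ref
from .audit import AuditCheck, audit_frame, audit_published_tables
from .energy import (
    DEFAULT_TRANSFER_EFFICIENCY,
    ComparativeRow,
    back_solve_velocity,
    comparative_table,
    evaluate_scenarios,
    kinetic_energy,
)
from .errors import CaudawhipError, ConfigError
from .mass import TissueModel, tail_mass
from .segmentation import find_transition_point, segment
from .series import (
    VertebralSeries,
    impute_missing,
    profile,
    read_measurements,
    total_length,
)
from .synthetic import SyntheticSeriesSpec, generate_series

__all__ = [
    "DirectParams",
    "SpecimenConfig",
    "RunConfig",
    "ReportBundle",
    "run_pipeline",
    "implied_velocities",
    "load_config",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DirectParams:
    """Summary parameters for a taxon without per-vertebra measurements."""

    n_caudals: float
    total_length_m: float | None = None
    whip_length_m: float | None = None
    mass_kg: float | None = None
    velocity_m_s: float | None = None
    energy_kj: float | None = None


@dataclass(frozen=True)
class SpecimenConfig:
    specimen_id: str
    taxon: str = ""
    measurements: Path | None = None
    synthetic: SyntheticSeriesSpec | None = None
    direct: DirectParams | None = None

    def __post_init__(self) -> None:
        sources = [
            s for s in (self.measurements, self.synthetic, self.direct) if s is not None
        ]
        if len(sources) != 1:
            raise ConfigError(
                f"specimen '{self.specimen_id}' must supply exactly one of "
                "measurements / synthetic / direct, got "
                f"{len(sources)}"
            )


@dataclass(frozen=True)
class RunConfig:
    specimens: tuple[SpecimenConfig, ...]
    density: float = ref.DENSITY_KG_PER_LITRE
    tissue: TissueModel = field(default_factory=TissueModel)
    velocity_preset: str = "as_stated"  # or "as_implied"
    whole_tail_velocity_m_s: float | None = None
    whiplash_velocity_m_s: float | None = None
    transfer_efficiency: float = DEFAULT_TRANSFER_EFFICIENCY
    rounding: str = "full"  # "full" | "published"

    def __post_init__(self) -> None:
        if not self.specimens:
            raise ConfigError("config lists no specimens")
        if self.velocity_preset not in ("as_stated", "as_implied"):
            raise ConfigError(
                f"unknown velocity preset '{self.velocity_preset}' "
                "(expected 'as_stated' or 'as_implied')"
            )
        if self.rounding not in ("full", "published"):
            raise ConfigError(f"unknown rounding mode '{self.rounding}'")

    def resolved_velocities(self) -> tuple[float, float]:
        """(whole-tail, whiplash) strike velocities in m/s."""
        if self.whole_tail_velocity_m_s is not None and self.whiplash_velocity_m_s is not None:
            return self.whole_tail_velocity_m_s, self.whiplash_velocity_m_s
        if self.velocity_preset == "as_stated":
            v = ref.STATED_STRIKE_VELOCITY_M_S
            return (
                self.whole_tail_velocity_m_s or v,
                self.whiplash_velocity_m_s or v,
            )
        v_whole, v_whip = implied_velocities()
        return (
            self.whole_tail_velocity_m_s or v_whole,
            self.whiplash_velocity_m_s or v_whip,
        )

    def tissue_model(self) -> TissueModel:
        """Tissue model honouring the rounding mode (published factor = 1.7)."""
        if self.rounding == "published":
            return TissueModel(
                muscle_fraction=self.tissue.muscle_fraction,
                skin_fraction=self.tissue.skin_fraction,
                radius_scaling_factor=ref.ROUNDED_SCALING_FACTOR,
            )
        return self.tissue


def implied_velocities() -> tuple[float, float]:
    """Velocities back-solved from the published bone-only Vienna energies.

    Returns (whole-tail, whiplash) ≈ (65.1, 59.8) m/s — the values the
    printed energy grid actually implies, in conflict with the stated
    2 m/s.
    """
    v_whole = back_solve_velocity(
        ref.table1_value("whole_tail_energy_kJ", "bone") * 1000.0,
        ref.table1_value("tail_mass_kg", "bone"),
    )
    v_whip = back_solve_velocity(
        ref.table1_value("quick_whiplash_energy_kJ", "bone") * 1000.0,
        ref.table1_value("whiplash_mass_kg", "bone"),
    )
    return v_whole, v_whip


@dataclass
class ReportBundle:
    """Everything one pipeline run produces."""

    energy_grids: dict[str, pd.DataFrame] = field(default_factory=dict)
    comparative: pd.DataFrame | None = None
    profiles: dict[str, pd.DataFrame] = field(default_factory=dict)
    audit: pd.DataFrame | None = None
    audit_checks: list[AuditCheck] = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sid, grid in self.energy_grids.items():
            grid.to_csv(out / f"{_slug(sid)}_energy_grid.csv")
        for sid, prof in self.profiles.items():
            prof.to_csv(out / f"{_slug(sid)}_profile.csv", index=False)
        if self.comparative is not None:
            self.comparative.to_csv(out / "comparative_table.csv", index=False)
        if self.audit is not None:
            self.audit.to_csv(out / "audit_report.csv", index=False)


def _slug(s: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in s)


def _measured_specimen(
    series: VertebralSeries, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, ComparativeRow]:
    """Energy grid, profile frame and comparative row for one measured tail."""
    imputed = impute_missing(series)
    tp = find_transition_point(imputed)
    v_whole, v_whip = config.resolved_velocities()
    tissue = config.tissue_model()

    # four mass/energy variants: bone vs soft tissue × without vs with imputation
    grid: dict[str, dict[str, float]] = {}
    variants = {
        "bone": (False, None),
        "bone_imputed": (True, None),
        "soft": (False, tissue),
        "soft_imputed": (True, tissue),
    }
    for col, (use_imputed, tiss) in variants.items():
        seg = segment(imputed, tp, include_imputed=use_imputed)
        whole, whip = tail_mass(
            imputed,
            segmentation=seg,
            tissue=tiss,
            density=config.density,
            include_imputed=use_imputed,
        )
        assert whip is not None
        report = evaluate_scenarios(
            whole,
            whip,
            specimen_id=series.specimen_id,
            whole_tail_velocity_m_s=v_whole,
            whiplash_velocity_m_s=v_whip,
            transfer_efficiency=config.transfer_efficiency,
        )
        ndig = 1 if config.rounding == "published" else 6
        grid[col] = {
            "tail_mass_kg": round(whole.mass_kg, ndig),
            "tail_length_m": round(whole.length_cm / 100.0, 3),
            "whiplash_mass_kg": round(whip.mass_kg, ndig),
            "whiplash_length_m": round(whip.length_cm / 100.0, 3),
            "whole_tail_energy_kJ": round(report.energies_kj["whole_tail"], 3),
            "transferred_energy_kJ": round(report.energies_kj["whip_transferred"], 3),
            "quick_whiplash_energy_kJ": round(report.energies_kj["quick_whiplash"], 3),
        }
    grid_df = pd.DataFrame(grid)[list(variants)]

    prof_df = pd.DataFrame(
        profile(imputed),
        columns=["position", "length_cm", "height_cm", "length_to_height_ratio"],
    )

    seg_bone = segment(imputed, tp, include_imputed=False)
    whole_bone, _ = tail_mass(
        imputed, segmentation=None, tissue=None, density=config.density,
        include_imputed=False,
    )
    row = ComparativeRow(
        specimen_id=series.specimen_id,
        taxon=series.taxon,
        n_caudals=len([r for r in series.records if r.preserved]),
        total_length_m=seg_bone.total_length_cm / 100.0,
        whip_length_m=seg_bone.whip_length_cm / 100.0,
        energy_kj=kinetic_energy(whole_bone.mass_kg, v_whole) / 1000.0,
    )
    return grid_df, prof_df, row


def run_pipeline(config: RunConfig, audit: bool = False) -> ReportBundle:
    """Process every specimen in the config; collect per-specimen failures.

    A stage error for one specimen is recorded in ``bundle.errors`` and
    the remaining specimens still run; config-level problems raise
    :class:`ConfigError` before any computation.
    """
    bundle = ReportBundle()
    rows: list[ComparativeRow] = []
    for spec in config.specimens:
        try:
            if spec.direct is not None:
                d = spec.direct
                energy = d.energy_kj
                if energy is None and d.mass_kg is not None and d.velocity_m_s is not None:
                    energy = kinetic_energy(d.mass_kg, d.velocity_m_s) / 1000.0
                if d.whip_length_m is None:
                    log.warning(
                        "%s: no whip segment parameters; whip columns left blank",
                        spec.specimen_id,
                    )
                rows.append(
                    ComparativeRow(
                        specimen_id=spec.specimen_id,
                        taxon=spec.taxon,
                        n_caudals=d.n_caudals,
                        total_length_m=d.total_length_m,
                        whip_length_m=d.whip_length_m,
                        energy_kj=energy,
                    )
                )
                continue
            if spec.synthetic is not None:
                series = generate_series(spec.synthetic)
                series = VertebralSeries(
                    specimen_id=spec.specimen_id,
                    taxon=spec.taxon or series.taxon,
                    records=series.records,
                    expected_count=series.expected_count,
                    missing_positions=series.missing_positions,
                )
            else:
                assert spec.measurements is not None
                series = read_measurements(
                    spec.measurements, specimen_id=spec.specimen_id, taxon=spec.taxon
                )
            grid, prof, row = _measured_specimen(series, config)
            bundle.energy_grids[spec.specimen_id] = grid
            bundle.profiles[spec.specimen_id] = prof
            rows.append(row)
            log.info("%s: processed (%d records)", spec.specimen_id, len(series))
        except CaudawhipError as exc:
            log.error("%s: %s", spec.specimen_id, exc)
            bundle.errors[spec.specimen_id] = str(exc)
    if rows:
        bundle.comparative = comparative_table(rows)
    if audit:
        bundle.audit_checks = audit_published_tables()
        bundle.audit = audit_frame(bundle.audit_checks)
    return bundle


# --- config file loading ----------------------------------------------------


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config.

    Schema (defaults in parentheses)::

        density: 0.8
        tissue: {muscle_fraction: 0.359, skin_fraction: 0.057}
        velocity_preset: as_stated | as_implied   (as_stated)
        whole_tail_velocity_m_s: ...              (from preset)
        whiplash_velocity_m_s: ...                (from preset)
        transfer_efficiency: 0.85
        rounding: full | published                (full)
        specimens:
          - id: ...
            taxon: ...
            measurements: path/to/table.csv      # exactly one of these
            synthetic: {n_vertebrae: ..., seed: ...}
            direct: {n_caudals: ..., mass_kg: ..., velocity_m_s: ...}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return config_from_dict(raw, base_dir=Path(path).parent)


def config_from_dict(raw: dict[str, Any], base_dir: Path | None = None) -> RunConfig:
    base_dir = base_dir or Path(".")
    specs: list[SpecimenConfig] = []
    for entry in raw.get("specimens", []):
        if "id" not in entry:
            raise ConfigError("every specimen needs an 'id'")
        measurements = entry.get("measurements")
        synthetic = entry.get("synthetic")
        direct = entry.get("direct")
        specs.append(
            SpecimenConfig(
                specimen_id=str(entry["id"]),
                taxon=str(entry.get("taxon", "")),
                measurements=None if measurements is None else base_dir / measurements,
                synthetic=None
                if synthetic is None
                else SyntheticSeriesSpec(
                    **{
                        **synthetic,
                        "missing_positions": tuple(
                            synthetic.get("missing_positions", ())
                        ),
                    }
                ),
                direct=None if direct is None else DirectParams(**direct),
            )
        )
    tissue_raw = raw.get("tissue", {})
    tissue = TissueModel(
        muscle_fraction=tissue_raw.get("muscle_fraction", ref.MUSCLE_FRACTION),
        skin_fraction=tissue_raw.get("skin_fraction", ref.SKIN_FRACTION),
        radius_scaling_factor=tissue_raw.get("radius_scaling_factor"),
    )
    try:
        return RunConfig(
            specimens=tuple(specs),
            density=raw.get("density", ref.DENSITY_KG_PER_LITRE),
            tissue=tissue,
            velocity_preset=raw.get("velocity_preset", "as_stated"),
            whole_tail_velocity_m_s=raw.get("whole_tail_velocity_m_s"),
            whiplash_velocity_m_s=raw.get("whiplash_velocity_m_s"),
            transfer_efficiency=raw.get("transfer_efficiency", DEFAULT_TRANSFER_EFFICIENCY),
            rounding=raw.get("rounding", "full"),
        )
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
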