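"""Serial caudal-vertebra measurements: data model, delimited-text I/O,
missing-element imputation and length summation.

A tail skeleton is represented as an ordered series of per-vertebra
measurements (centrum length and total height, both in cm), indexed by
caudal position (Ca1 = first caudal behind the sacrum, increasing toward
the tail tip).  Vertebrae lost to taphonomy appear as *missing positions*
and can be filled in by interpolation between their preserved neighbours:
a single interior gap takes the arithmetic mean of the two flanking
vertebrae; a run of consecutive gaps is interpolated linearly between the
flanking preserved elements (which reduces to the mean for a single gap).
Terminal gaps are never extrapolated.

Total tail length is the plain sum of centrum lengths with no allowance
for intervertebral space, since articulated material shows essentially no
room for soft tissue between centra.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ImputationError, SchemaError, ValidationError

__all__ = [
    "VertebraRecord",
    "VertebralSeries",
    "read_measurements",
    "write_measurements",
    "impute_missing",
    "total_length",
    "profile",
]

#: logical field -> default column name in measurement files
DEFAULT_SCHEMA: Mapping[str, str] = {
    "position": "position",
    "length": "length_cm",
    "height": "height_cm",
    "preserved": "preserved",
    "note": "note",
}


@dataclass(frozen=True)
class VertebraRecord:
    """One caudal vertebra's measurements.

    Parameters
    ----------
    position
        1-based caudal index (Ca1 = 1, increasing caudally).
    centrum_length_cm
        Cranio-caudal extent of the centrum, cm.
    total_height_cm
        Dorso-ventral extent including the neural spine, cm.
    preserved
        True for vertebrae physically present in the specimen.
    imputed
        True for values estimated from neighbours; implies not preserved.
    """

    position: int
    centrum_length_cm: float
    total_height_cm: float
    preserved: bool = True
    imputed: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if self.imputed and self.preserved:
            raise ValidationError(f"Ca{self.position}: imputed implies not preserved")
        if self.preserved or self.imputed:
            if not (self.centrum_length_cm > 0):
                raise ValidationError(
                    f"Ca{self.position}: centrum length must be positive, "
                    f"got {self.centrum_length_cm}"
                )
            if not (self.total_height_cm > 0):
                raise ValidationError(
                    f"Ca{self.position}: total height must be positive, "
                    f"got {self.total_height_cm}"
                )

    @property
    def length_to_height_ratio(self) -> float:
        if self.total_height_cm == 0:
            raise ValidationError(f"Ca{self.position}: zero height")
        return self.centrum_length_cm / self.total_height_cm


@dataclass(frozen=True)
class VertebralSeries:
    """Ordered specimen-level collection of vertebra records.

    ``expected_count`` carries the anatomical expectation for the taxon
    (e.g. ~45 caudals) independently of how many elements are preserved;
    the two counts are stored side by side and deliberately not forced to
    reconcile, since published counts for the same specimen can disagree.
    """

    specimen_id: str
    taxon: str = ""
    records: tuple[VertebraRecord, ...] = ()
    expected_count: int | None = None
    missing_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        positions = [r.position for r in self.records]
        if positions != sorted(positions):
            object.__setattr__(
                self, "records", tuple(sorted(self.records, key=lambda r: r.position))
            )
            positions = sorted(positions)
        dupes = {p for p in positions if positions.count(p) > 1}
        if dupes:
            raise ValidationError(
                f"{self.specimen_id}: duplicate positions {sorted(dupes)}"
            )
        preserved = {r.position for r in self.records if r.preserved}
        clash = preserved & set(self.missing_positions)
        if clash:
            raise ValidationError(
                f"{self.specimen_id}: positions {sorted(clash)} are both "
                "preserved and listed as missing"
            )
        object.__setattr__(
            self, "missing_positions", tuple(sorted(self.missing_positions))
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def max_position(self) -> int:
        if not self.records:
            raise ValidationError(f"{self.specimen_id}: empty series")
        return self.records[-1].position

    def get(self, position: int) -> VertebraRecord | None:
        for r in self.records:
            if r.position == position:
                return r
        return None

    def require(self, position: int) -> VertebraRecord:
        rec = self.get(position)
        if rec is None:
            raise ValidationError(
                f"{self.specimen_id}: no record at position Ca{position}"
            )
        return rec


def _resolve_schema(
    columns: Sequence[str], schema: Mapping[str, str] | None
) -> Mapping[str, str]:
    merged = dict(DEFAULT_SCHEMA)
    if schema:
        merged.update(schema)
    for key in ("position", "length", "height"):
        if merged[key] not in columns:
            raise SchemaError(
                f"required column '{merged[key]}' (for {key}) not found; "
                f"file has columns {list(columns)}"
            )
    return merged


def read_measurements(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    specimen_id: str | None = None,
    taxon: str = "",
    expected_count: int | None = None,
) -> VertebralSeries:
    """Read a per-vertebra measurement table (CSV or TSV, auto-detected).

    Rows with a blank length or height become entries of
    ``missing_positions``; all measurements are in cm with a dot decimal
    separator regardless of locale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # comma vs tab auto-detected from the header line; round_trip parsing keeps
    # measurements bit-exact through a write/read cycle
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    cols = _resolve_schema(df.columns.tolist(), schema)

    records: list[VertebraRecord] = []
    missing: list[int] = []
    seen: set[int] = set()
    for i, row in df.iterrows():
        rownum = int(i) + 2  # header is line 1
        pos_raw = row[cols["position"]]
        if pd.isna(pos_raw):
            raise ValidationError(f"{path.name} row {rownum}: blank position")
        pos = int(pos_raw)
        if pos in seen:
            raise ValidationError(f"{path.name} row {rownum}: duplicate position {pos}")
        seen.add(pos)

        length = row[cols["length"]]
        height = row[cols["height"]]
        if pd.isna(length) or pd.isna(height):
            missing.append(pos)
            continue
        length = float(length)
        height = float(height)
        if length <= 0 or height <= 0:
            raise ValidationError(
                f"{path.name} row {rownum}: non-positive measurement "
                f"(length={length}, height={height})"
            )
        preserved = True
        if cols["preserved"] in df.columns and not pd.isna(row[cols["preserved"]]):
            preserved = _parse_bool(row[cols["preserved"]])
        imputed = False
        if "imputed" in df.columns and not pd.isna(row["imputed"]):
            imputed = _parse_bool(row["imputed"])
            if imputed:
                preserved = False
        note = ""
        if cols["note"] in df.columns and not pd.isna(row[cols["note"]]):
            note = str(row[cols["note"]])
        records.append(
            VertebraRecord(
                position=pos,
                centrum_length_cm=length,
                total_height_cm=height,
                preserved=preserved,
                imputed=imputed,
                note=note,
            )
        )

    return VertebralSeries(
        specimen_id=specimen_id or path.stem,
        taxon=taxon,
        records=tuple(records),
        expected_count=expected_count,
        missing_positions=tuple(missing),
    )


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    raise ValidationError(f"cannot parse boolean value {value!r}")


def write_measurements(series: VertebralSeries, path: str | Path) -> Path:
    """Write a series back to CSV with the standard schema plus ``imputed``.

    Missing positions are written as rows with blank length/height so a
    read→write→read roundtrip is lossless.
    """
    path = Path(path)
    rows: list[dict] = []
    by_pos = {r.position: r for r in series.records}
    all_positions = sorted(set(by_pos) | set(series.missing_positions))
    for pos in all_positions:
        rec = by_pos.get(pos)
        if rec is None:
            rows.append(
                {
                    "position": pos,
                    "length_cm": None,
                    "height_cm": None,
                    "preserved": False,
                    "imputed": False,
                    "note": "",
                }
            )
        else:
            rows.append(
                {
                    "position": rec.position,
                    "length_cm": rec.centrum_length_cm,
                    "height_cm": rec.total_height_cm,
                    "preserved": rec.preserved,
                    "imputed": rec.imputed,
                    "note": rec.note,
                }
            )
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return path


def impute_missing(series: VertebralSeries) -> VertebralSeries:
    """Fill interior missing positions by interpolation between neighbours.

    Each missing vertebra gets centrum length *and* total height estimated
    from the nearest available records on either side: the arithmetic mean
    for a single gap, linear interpolation across runs of consecutive gaps.
    Terminal gaps (no neighbour on one side) raise :class:`ImputationError`.
    The input series is returned unchanged (same object) when nothing is
    missing; otherwise a new series is built and the original untouched.
    """
    if not series.missing_positions:
        return series
    by_pos = {r.position: r for r in series.records}
    available = sorted(by_pos)
    if not available:
        raise ImputationError(f"{series.specimen_id}: no records to impute from")

    new_records = list(series.records)
    for pos in series.missing_positions:
        left = max((p for p in available if p < pos), default=None)
        right = min((p for p in available if p > pos), default=None)
        if left is None or right is None:
            side = "cranial" if left is None else "caudal"
            raise ImputationError(
                f"{series.specimen_id}: Ca{pos} has no {side} neighbour; "
                "terminal missing vertebrae are not extrapolated"
            )
        lo, hi = by_pos[left], by_pos[right]
        t = (pos - left) / (right - left)
        length = lo.centrum_length_cm + t * (hi.centrum_length_cm - lo.centrum_length_cm)
        height = lo.total_height_cm + t * (hi.total_height_cm - lo.total_height_cm)
        new_records.append(
            VertebraRecord(
                position=pos,
                centrum_length_cm=length,
                total_height_cm=height,
                preserved=False,
                imputed=True,
                note=f"interpolated between Ca{left} and Ca{right}",
            )
        )
    return replace(
        series,
        records=tuple(sorted(new_records, key=lambda r: r.position)),
        missing_positions=(),
    )


def total_length(series: VertebralSeries, include_imputed: bool = True) -> float:
    """Total tail length in cm: sum of centrum lengths, no intervertebral space.

    With ``include_imputed=False`` only preserved elements contribute
    (the bone-only sum).
    """
    if not series.records:
        raise ValidationError(f"{series.specimen_id}: empty series")
    return sum(
        r.centrum_length_cm
        for r in series.records
        if r.preserved or (r.imputed and include_imputed)
    )


def profile(series: VertebralSeries) -> list[tuple[int, float, float, float]]:
    """Per-vertebra (position, length, height, length/height ratio) tuples.

    This is the data behind the length-versus-height profile plot used to
    locate the whip-tail transition.
    """
    out = []
    for r in series.records:
        if r.total_height_cm == 0:
            raise ValidationError(f"Ca{r.position}: zero height")
        out.append(
            (r.position, r.centrum_length_cm, r.total_height_cm, r.length_to_height_ratio)
        )
    return out
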