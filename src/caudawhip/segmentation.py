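"""Whip-tail transition-point detection and segment bookkeeping.

Along a tapering reptilian tail there is a morphological inflection where
the caudal vertebrae become distinctly longer than tall; distal to it the
elements are elongate and gracile, consistent with a flexible, whip-like
segment.  The first vertebra whose centrum length strictly exceeds its
total height is taken as the transition point (TP); the whip segment runs
from the TP vertebra (inclusive) to the tail tip.

The crossing test uses a strict inequality — a vertebra exactly as long as
tall is not yet whip.  With ``persistence=True`` (the default) the
condition must hold at every available position from the TP caudally,
which guards against spurious single-vertebra crossings caused by
taphonomic distortion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import SegmentationError, ValidationError
from .series import VertebralSeries, total_length

__all__ = ["WhipSegmentation", "find_transition_point", "segment"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WhipSegmentation:
    """Detected whip segment of a tail.

    ``whip_fraction`` is whip length over total length, in (0, 1].
    """

    tp_position: int
    whip_length_cm: float
    total_length_cm: float

    def __post_init__(self) -> None:
        if self.tp_position < 1:
            raise ValidationError(f"tp_position must be >= 1, got {self.tp_position}")
        if self.whip_length_cm > self.total_length_cm + 1e-9:
            raise ValidationError(
                f"whip length {self.whip_length_cm} exceeds total {self.total_length_cm}"
            )

    @property
    def whip_fraction(self) -> float:
        return self.whip_length_cm / self.total_length_cm


def find_transition_point(series: VertebralSeries, persistence: bool = True) -> int:
    """Position of the first vertebra with centrum length > total height.

    With ``persistence=True``, the smallest position from which the
    condition holds at *every* available position caudally.  Raises
    :class:`SegmentationError` when no crossing exists, or when un-imputed
    missing positions sit immediately around the detected crossing (the
    measurements needed to trust it are absent).
    """
    usable = [r for r in series.records if r.preserved or r.imputed]
    if len(usable) < 2:
        raise SegmentationError(
            f"{series.specimen_id}: need at least 2 measured vertebrae, have {len(usable)}"
        )

    tp: int | None = None
    if persistence:
        # walk tail-tip -> head, tracking the longest suffix where l > h
        for rec in reversed(usable):
            if rec.centrum_length_cm > rec.total_height_cm:
                tp = rec.position
            else:
                break
    else:
        for rec in usable:
            if rec.centrum_length_cm > rec.total_height_cm:
                tp = rec.position
                break
    if tp is None:
        raise SegmentationError(
            f"{series.specimen_id}: no whip segment detected "
            "(centrum length never exceeds total height)"
        )

    gaps = [p for p in series.missing_positions if tp - 1 <= p <= tp + 1]
    if gaps:
        raise SegmentationError(
            f"{series.specimen_id}: measurements absent near the crossing at "
            f"positions {gaps}; impute before segmenting"
        )
    imputed_near = [r.position for r in usable if r.imputed and abs(r.position - tp) <= 1]
    if imputed_near:
        log.warning(
            "%s: imputed vertebrae %s participate in TP detection near Ca%d",
            series.specimen_id,
            imputed_near,
            tp,
        )
    return tp


def segment(
    series: VertebralSeries, tp_position: int, include_imputed: bool = True
) -> WhipSegmentation:
    """Whip/total lengths and fraction for a given transition point.

    The whip segment includes the TP vertebra itself: whip length is the
    sum of centrum lengths at positions >= ``tp_position``.
    """
    if not series.records:
        raise ValidationError(f"{series.specimen_id}: empty series")
    if not (1 <= tp_position <= series.max_position):
        raise ValidationError(
            f"{series.specimen_id}: tp_position {tp_position} outside "
            f"[1, {series.max_position}]"
        )
    whip = sum(
        r.centrum_length_cm
        for r in series.records
        if r.position >= tp_position and (r.preserved or (r.imputed and include_imputed))
    )
    total = total_length(series, include_imputed=include_imputed)
    return WhipSegmentation(
        tp_position=tp_position, whip_length_cm=whip, total_length_cm=total
    )
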