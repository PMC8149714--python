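"""Replichore-balance terminus prediction and deletion-overlap analysis.

Bacterial replicons replicate bidirectionally from a single origin; under
replichore balance the two forks meet near the coordinate antipodal to the
origin.  Given an origin position (an input -- origin prediction is out of
scope) and the replicon length, the predicted terminus is simply the
half-length offset from the origin, modulo the circle.  The module also
intersects a set of deletion intervals (the recurrently deleted region)
and asks whether each deletion removes the predicted terminus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .genome_io import Interval

__all__ = [
    "ReplichoreModel",
    "predict_terminus",
    "common_region",
    "spans_terminus",
    "round_to",
]


def predict_terminus(ori_pos: int, length: int) -> int:
    """Antipodal (half-length) terminus coordinate, 1-based, wrapping."""
    if not 1 <= ori_pos <= length:
        raise ValueError(f"ori_pos must be in [1, {length}], got {ori_pos}")
    return ((ori_pos - 1 + length // 2) % length) + 1


def round_to(value: int, nearest: int = 1000) -> int:
    """Round to the nearest multiple, for human-readable reports."""
    return int(round(value / nearest)) * nearest


@dataclass(frozen=True)
class ReplichoreModel:
    """A replicon with its origin and the implied terminus."""

    element_id: str
    ori_pos: int  # 1-based
    length: int

    @property
    def ter_pos(self) -> int:
        return predict_terminus(self.ori_pos, self.length)


def common_region(intervals: Sequence[Interval]) -> Interval | None:
    """Intersection of deletion intervals: [max(starts), min(ends)), or
    None when the intersection is empty.  All intervals must lie on one
    element."""
    if not intervals:
        return None
    eids = {iv.element_id for iv in intervals}
    if len(eids) > 1:
        raise ValueError(f"intervals span multiple elements: {sorted(eids)}")
    start = max(iv.start for iv in intervals)
    end = min(iv.end for iv in intervals)
    if start >= end:
        return None
    return Interval(eids.pop(), start, end)


def spans_terminus(interval: Interval, model: ReplichoreModel, wraps: bool = False) -> bool:
    """Whether the predicted terminus falls inside the interval.

    ``wraps=True`` supports intervals crossing the end of a circular
    replicon, represented half-open with ``end > length`` (positions
    start..length-1 plus 0..end-length-1).
    """
    if interval.element_id != model.element_id:
        raise ValueError(
            f"interval on {interval.element_id!r} does not match model "
            f"element {model.element_id!r}"
        )
    t = model.ter_pos - 1  # 0-based
    if wraps:
        return interval.start <= t < interval.end or (
            interval.start <= t + model.length < interval.end
        )
    return interval.start <= t < interval.end
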