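"""Genome coverage by exact repeat pairs of a fixed length.

An L-bp window is *repeated* when its exact sequence occurs at two or more
distinct start positions anywhere in the genome (all elements pooled); a
genome position is *covered* when it lies inside at least one repeated
window.  The percent of covered positions measures how much of the genome
could, in principle, serve as a substrate for repair between direct
repeats of that length.  For short L in a genome of megabase scale the
statistic saturates at 100%; it decays as L grows past the uniqueness
scale ~log4(genome size).

Windows containing N are excluded from both the numerator and the
denominator (an ambiguous window cannot attest a repeat pair).  By default
only direct (same-strand) repeats count; ``include_revcomp`` also counts
occurrences on the reverse complement.  Circular elements contribute
wrap-around windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._seq import encode, kmer_codes
from .genome_io import GenomeElement

__all__ = ["RepeatCoverage", "repeat_coverage", "repeat_coverage_per_element"]


@dataclass(frozen=True)
class RepeatCoverage:
    """Coverage of a genome by repeated L-windows."""

    L: int
    covered_positions: int
    total_positions: int
    element_id: str | None = None  # None = whole genome, pooled

    @property
    def percent(self) -> float:
        if self.total_positions == 0:
            return 0.0
        return 100.0 * self.covered_positions / self.total_positions


def _element_windows(el: GenomeElement, L: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(codes, start positions, revcomp codes) of valid windows of one element."""
    arr = encode(el.seq)
    if el.topology == "circular" and el.length >= L:
        arr = np.concatenate([arr, arr[: L - 1]])
    codes, valid = kmer_codes(arr, L)
    rc_arr = np.where(arr == 4, np.uint8(4), (np.uint8(3) - arr).astype(np.uint8))
    rc_codes, _ = kmer_codes(rc_arr[::-1], L)
    rc_codes = rc_codes[::-1]  # rc_codes[i] = code of revcomp(window i)
    pos = np.nonzero(valid)[0]
    return codes[valid], pos, rc_codes[valid]


def repeat_coverage(
    genome: Sequence[GenomeElement] | GenomeElement,
    L: int,
    include_revcomp: bool = False,
) -> RepeatCoverage:
    """Compute the repeat-pair coverage statistic over a pooled genome."""
    elements = [genome] if isinstance(genome, GenomeElement) else list(genome)
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if all(el.length < L for el in elements):
        raise ValueError(f"L={L} is longer than every element")

    per_el = [_element_windows(el, L) for el in elements]
    all_codes = np.concatenate([c for c, _, _ in per_el]) if per_el else np.empty(0, np.uint64)
    sorted_codes = np.sort(all_codes)

    covered = 0
    total = 0
    for el, (codes, pos, rc_codes) in zip(elements, per_el):
        count = _multiplicity(sorted_codes, codes)
        repeated = count >= 2
        if include_revcomp:
            rc_count = _multiplicity(sorted_codes, rc_codes)
            repeated |= (rc_codes != codes) & (rc_count >= 1)
        n = el.length
        cov = _mark_covered(pos[repeated], L, n, el.topology == "circular")
        non_n = np.frombuffer(el.seq.encode("ascii"), dtype=np.uint8) != ord("N")
        covered += int(np.count_nonzero(cov & non_n))
        total += int(np.count_nonzero(non_n))
    return RepeatCoverage(L=L, covered_positions=covered, total_positions=total)


def _multiplicity(sorted_codes: np.ndarray, query: np.ndarray) -> np.ndarray:
    lo = np.searchsorted(sorted_codes, query, side="left")
    hi = np.searchsorted(sorted_codes, query, side="right")
    return hi - lo


def _mark_covered(starts: np.ndarray, L: int, n: int, circular: bool) -> np.ndarray:
    """Boolean mask of positions inside >= 1 repeated window."""
    diff = np.zeros(n + L + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, starts + L, -1)
    depth = np.cumsum(diff[: n + L])
    cov = depth[:n] > 0
    if circular:
        # windows starting near the end wrap onto the element head
        overflow = depth[n : n + L] > 0
        if overflow.size:
            cov[: overflow.size] |= overflow
    return cov


def repeat_coverage_per_element(
    genome: Sequence[GenomeElement], L: int, include_revcomp: bool = False
) -> list[RepeatCoverage]:
    """Diagnostic mode: coverage computed within each element separately
    (window multiplicity restricted to that element)."""
    out = []
    for el in genome:
        if el.length < L:
            out.append(RepeatCoverage(L=L, covered_positions=0, total_positions=el.length, element_id=el.id))
            continue
        rc = repeat_coverage([el], L, include_revcomp)
        out.append(RepeatCoverage(L=L, covered_positions=rc.covered_positions, total_positions=rc.total_positions, element_id=el.id))
    return out
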