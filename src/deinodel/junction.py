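"""Breakpoint characterization: microhomology, canonical placement,
in-silico re-enactment, junction verification, and repair-mechanism
classification.

A deletion between two copies of a direct repeat is ambiguous: it can be
placed anywhere the repeat lets it slide.  We normalize to the *leftmost*
equivalent placement (the standard left-alignment convention for indels)
and report the deletion as starting at the beginning of the breakpoint
repeat, so ``interval.start`` and ``interval.end`` are the start
coordinates of the two repeat copies and ``end - start`` is the number of
bases lost.

The maximal exact repeat shared by the two breakpoints is the junction
microhomology; its length is the main feature separating candidate repair
mechanisms (see :func:`classify_mechanism`).  N never matches anything, so
assembly gaps cannot inflate microhomology.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import match
from .genome_io import GenomeElement, Interval

__all__ = [
    "DeletionCall",
    "MechanismCall",
    "characterize_breakpoint",
    "reenact_deletion",
    "reconstruct_junction",
    "verify_junction",
    "classify_mechanism",
]

DEFAULT_FLANK = 60


@dataclass
class DeletionCall:
    """A canonicalized deletion with its breakpoint repeat.

    Invariants: ``ref[start:start+mh] == ref[end:end+mh]`` exactly; the
    repeat cannot be extended on either side; ``start`` is the leftmost
    equivalent placement; excising ``[start, end)`` yields the same derived
    sequence for every placement in ``slide_window``.
    """

    interval: Interval
    repeat: str
    slide_window: tuple[int, int]  # (leftmost_start, rightmost_start), 0-based
    junction_context: str
    degenerate: bool = False

    @property
    def mh_length(self) -> int:
        return len(self.repeat)

    @property
    def deleted_segment_length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class MechanismCall:
    """Repair-mechanism compatibility of a junction, from its features."""

    label: str
    mh_length: int
    junction_exact: bool
    inserted_bases: int


def characterize_breakpoint(
    ref: GenomeElement, raw: Interval, flank: int = DEFAULT_FLANK
) -> DeletionCall:
    """Canonicalize a raw deletion interval and extract its breakpoint repeat.

    Slides the placement leftward while the base before the deletion start
    equals the base before the deletion end, then takes the repeat as the
    longest common prefix of the suffixes at ``start`` and ``end``.  The
    deleted-segment length (``end - start``) is invariant under sliding.
    """
    if raw.element_id != ref.id:
        raise ValueError(f"interval on {raw.element_id!r} does not match element {ref.id!r}")
    if raw.end > ref.length:
        raise ValueError(f"interval end {raw.end} beyond element length {ref.length}")
    seq = ref.seq
    s, e = raw.start, raw.end
    if s == e:
        iv = Interval(ref.id, s, e)
        return DeletionCall(
            interval=iv,
            repeat="",
            slide_window=(s, s),
            junction_context=_context(seq, s, e, 0, flank),
            degenerate=True,
        )
    # canonical (leftmost) placement
    while s > 0 and match(seq[s - 1], seq[e - 1]):
        s -= 1
        e -= 1
    # maximal forward repeat at the canonical placement
    mh = 0
    n = len(seq)
    while s + mh < n and e + mh < n and match(seq[s + mh], seq[e + mh]):
        mh += 1
    rightmost = s + min(mh, n - e)
    return DeletionCall(
        interval=Interval(ref.id, s, e),
        repeat=seq[s : s + mh],
        slide_window=(s, rightmost),
        junction_context=_context(seq, s, e, mh, flank),
    )


def _context(seq: str, s: int, e: int, mh: int, flank: int) -> str:
    return seq[max(0, s - flank) : s] + seq[s : s + mh] + seq[e + mh : e + mh + flank]


def reenact_deletion(ref: GenomeElement, call: DeletionCall) -> GenomeElement:
    """Excise the deleted segment in silico.

    Removes ``ref[start:end)``: everything between the two repeat copies
    plus one copy, so exactly one copy survives at the junction.
    """
    s, e = call.interval.start, call.interval.end
    return GenomeElement(id=ref.id, seq=ref.seq[:s] + ref.seq[e:], topology=ref.topology)


def reconstruct_junction(
    ref: GenomeElement, call: DeletionCall, flank: int = DEFAULT_FLANK
) -> str:
    """Reconstruct the expected junction: upstream flank + surviving repeat
    copy + downstream flank (truncated at element ends)."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    s, e = call.interval.start, call.interval.end
    return _context(ref.seq, s, e, call.mh_length, flank)


def verify_junction(derived: GenomeElement, junction: str) -> str:
    """Exact search for the reconstructed junction in the derived genome.

    Returns "verified" iff the junction occurs exactly once (overlapping
    occurrences counted), "not_found" if absent, "multiple" otherwise.
    """
    if not junction:
        raise ValueError("junction string must be non-empty")
    count = 0
    pos = derived.seq.find(junction)
    while pos != -1 and count < 2:
        count += 1
        pos = derived.seq.find(junction, pos + 1)
    return ("not_found", "verified", "multiple")[min(count, 2)]


def classify_mechanism(
    mh_length: int, junction_exact: bool = True, inserted_bases: int = 0
) -> MechanismCall:
    """Classify a junction into repair-mechanism-compatible categories.

    Rule table (thresholds from the repair literature): inserted bases or
    an inexact junction are the error-prone end-joining signature
    (NHEJ-like); precise junctions split by microhomology length --
    >= 25 bp is the classical single-strand-annealing substrate range,
    2-20 bp the alternative end-joining range, 21-24 bp falls between the
    two cited thresholds and stays ambiguous, and 0-1 bp carries no
    homology signal (unclassified).
    """
    if mh_length < 0 or inserted_bases < 0:
        raise ValueError("mh_length and inserted_bases must be non-negative")
    if inserted_bases > 0 or not junction_exact:
        label = "NHEJ-like"
    elif mh_length >= 25:
        label = "SSA-compatible"
    elif 21 <= mh_length <= 24:
        label = "ambiguous"
    elif 2 <= mh_length <= 20:
        label = "AEJ-compatible"
    else:
        label = "unclassified"
    return MechanismCall(
        label=label,
        mh_length=mh_length,
        junction_exact=junction_exact,
        inserted_bases=inserted_bases,
    )
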