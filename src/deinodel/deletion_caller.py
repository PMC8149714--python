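"""Assembly-to-assembly deletion calling via unique k-mer anchor chaining.

Two collinear assemblies of the same replicon are compared by matching
k-mers that occur exactly once in each sequence (anchors), chaining the
longest subset that is strictly increasing in both coordinates, and
refining every chain gap where the reference advances further than the
derived sequence.  Refinement extends exact matches inward from the two
bounding anchors; when the extensions meet or overlap, the gap is a clean
excision and a deletion is emitted at its leftmost placement (downstream
canonicalization in :mod:`deinodel.junction` re-derives the breakpoint
repeat).  When they do not meet, the unexplained derived bases are
reported as junction-inserted sequence, so every emitted call -- exact or
not -- reproduces the derived sequence over the anchored neighborhood
(asserted on every call).

Only forward-strand, collinear comparison is supported; a derived sequence
sharing no unique k-mers with the reference raises :class:`UnalignableError`.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from ._seq import encode, kmer_codes
from .genome_io import GenomeElement, Interval

__all__ = [
    "AnchorMatch",
    "AnchorSet",
    "RawDeletion",
    "UnalignableError",
    "find_anchors",
    "call_deletions",
    "DEFAULT_K",
    "DEFAULT_MIN_LEN",
]

#: Default anchor length: a 31-mer is unique in a random few-Mb genome with
#: overwhelming probability, long enough to step over short repeat families.
DEFAULT_K = 31
#: Deletions below this size are left to small-indel machinery.
DEFAULT_MIN_LEN = 1000


class UnalignableError(ValueError):
    """The two sequences share no unique k-mer anchors."""


@dataclass(frozen=True)
class AnchorMatch:
    ref_pos: int
    der_pos: int
    k: int


class AnchorSet:
    """Sequence of anchors backed by numpy arrays, sorted by ``ref_pos``."""

    def __init__(self, ref_pos: np.ndarray, der_pos: np.ndarray, k: int):
        order = np.argsort(ref_pos, kind="stable")
        self.ref_pos = ref_pos[order]
        self.der_pos = der_pos[order]
        self.k = k

    def __len__(self) -> int:
        return int(self.ref_pos.size)

    def __getitem__(self, i: int) -> AnchorMatch:
        return AnchorMatch(int(self.ref_pos[i]), int(self.der_pos[i]), self.k)

    def __iter__(self) -> Iterator[AnchorMatch]:
        for i in range(len(self)):
            yield self[i]


def _unique_kmer_positions(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes and start positions of k-mers occurring exactly once (no N)."""
    codes, valid = kmer_codes(encode(seq), k)
    pos = np.nonzero(valid)[0]
    codes = codes[valid]
    uniq, first, counts = np.unique(codes, return_index=True, return_counts=True)
    single = counts == 1
    return uniq[single], pos[first[single]]


def find_anchors(ref: GenomeElement, der: GenomeElement, k: int = DEFAULT_K) -> AnchorSet:
    """Match k-mers unique in both sequences; sorted by reference position."""
    if k < 2:
        raise ValueError(f"anchor length k must be >= 2, got {k}")
    if ref.length == 0 or der.length == 0:
        raise ValueError("sequences must be non-empty")
    rcodes, rpos = _unique_kmer_positions(ref.seq, k)
    dcodes, dpos = _unique_kmer_positions(der.seq, k)
    _, ri, di = np.intersect1d(rcodes, dcodes, assume_unique=True, return_indices=True)
    if ri.size == 0:
        raise UnalignableError(
            f"no shared unique {k}-mers between {ref.id!r} and {der.id!r} "
            "(reversed orientation, or sequences too divergent)"
        )
    return AnchorSet(rpos[ri], dpos[di], k)


@dataclass
class RawDeletion:
    """A called deletion: reference interval, derived breakpoint, and any
    derived bases not explained by a clean excision (junction insertion)."""

    ref_interval: Interval
    der_breakpoint: int
    inserted: str = ""

    @property
    def junction_exact(self) -> bool:
        return self.inserted == ""


def _longest_chain(der_pos: np.ndarray) -> list[int]:
    """Longest strictly-increasing subsequence of der_pos (anchors already
    sorted by ref_pos).  Patience algorithm; deterministic tie-break: the
    reconstruction naturally prefers earlier (smaller ref_pos) anchors."""
    d = der_pos.tolist()
    tails: list[int] = []  # smallest tail value per chain length
    tails_i: list[int] = []
    prev = [-1] * len(d)
    for i, v in enumerate(d):
        j = bisect.bisect_left(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_i.append(i)
        else:
            tails[j] = v
            tails_i[j] = i
        prev[i] = tails_i[j - 1] if j > 0 else -1
    chain = []
    i = tails_i[-1]
    while i != -1:
        chain.append(i)
        i = prev[i]
    return chain[::-1]


def _match_forward(ref: str, der: str, r: int, d: int, limit: int) -> int:
    i = 0
    while i < limit and ref[r + i] == der[d + i] and ref[r + i] != "N":
        i += 1
    return i


def _match_backward(ref: str, der: str, r: int, d: int, limit: int) -> int:
    """Matching bases ending just before ref[r] / der[d]."""
    i = 0
    while i < limit and ref[r - 1 - i] == der[d - 1 - i] and ref[r - 1 - i] != "N":
        i += 1
    return i


def call_deletions(
    ref: GenomeElement,
    der: GenomeElement,
    k: int = DEFAULT_K,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[RawDeletion]:
    """Call deletions >= ``min_len`` bp between a reference and a derived
    assembly of the same replicon.  Gaps where the derived sequence advances
    more than the reference (insertions) are skipped with a warning."""
    anchors = find_anchors(ref, der, k)
    chain = _longest_chain(anchors.der_pos)
    rp = anchors.ref_pos
    dp = anchors.der_pos
    calls: list[RawDeletion] = []
    for a, b in zip(chain, chain[1:]):
        r1, d1 = int(rp[a]), int(dp[a])
        r2, d2 = int(rp[b]), int(dp[b])
        diag_jump = (r2 - d2) - (r1 - d1)
        if diag_jump == 0:
            continue
        if diag_jump < 0:
            warnings.warn(
                f"{ref.id}: insertion of {-diag_jump} bp near reference "
                f"position {r1 + k} skipped (not a deletion)",
                stacklevel=2,
            )
            continue
        if diag_jump < min_len:
            continue
        call = _refine_gap(ref.seq, der.seq, r1, d1, r2, d2, k, diag_jump, ref.id)
        calls.append(call)
    return calls


def _refine_gap(
    rseq: str, dseq: str, r1: int, d1: int, r2: int, d2: int, k: int, jump: int, eid: str
) -> RawDeletion:
    span = d2 + k - d1  # derived bases between anchor1 start and anchor2 end
    p = _match_forward(rseq, dseq, r1, d1, span)  # >= k by anchor identity
    q = _match_backward(rseq, dseq, r2 + k, d2 + k, span)
    if p + q >= span:
        # clean excision; leftmost feasible cut
        cut = max(d1, d2 + k - q)
        s_ref = r1 + (cut - d1)
        call = RawDeletion(
            ref_interval=Interval(eid, s_ref, s_ref + jump),
            der_breakpoint=cut,
        )
    else:
        call = RawDeletion(
            ref_interval=Interval(eid, r1 + p, r2 + k - q),
            der_breakpoint=d1 + p,
            inserted=dseq[d1 + p : d2 + k - q],
        )
    # soundness over the full anchored neighborhood: excising the called
    # interval (and re-inserting any junction bases) reproduces the derived
    # sequence between the two bounding anchors
    s, e = call.ref_interval.start, call.ref_interval.end
    assert rseq[r1:s] + call.inserted + rseq[e : r2 + k] == dseq[d1 : d2 + k], (
        f"unsound deletion call at {call.ref_interval}"
    )
    return call
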