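"""Low-level nucleotide encoding and k-mer machinery shared across modules.

Sequences are plain Python strings over {A,C,G,T,N} at the API surface;
internally they are encoded as uint8 arrays (A=0, C=1, G=2, T=3, N=4) for
vectorized k-mer work.  N is deliberately outside the 2-bit alphabet: any
window containing N is marked invalid, so ambiguity can never attest a
repeat or a homology match.
"""

from __future__ import annotations

import numpy as np

VALID_CHARS = frozenset("ACGTN")

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
_ENCODE[ord("N")] = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# index -> letter, N last
ALPHABET = "ACGTN"


def encode(seq: str) -> np.ndarray:
    """Encode an upper-case A/C/G/T/N string as a uint8 array (N = 4)."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        pos = int(np.argmax(arr == 255))
        raise ValueError(f"invalid nucleotide {seq[pos]!r} at position {pos + 1}")
    return arr


def decode(arr: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in arr)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit pack every k-window of an encoded sequence.

    Returns ``(codes, valid)`` where ``codes[i]`` is the base-4 integer code
    of the window starting at i and ``valid[i]`` is False when the window
    contains an N.  Requires 1 <= k <= 31 so codes fit in uint64 exactly
    (4**31 == 2**62).
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    n = arr.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    a = (arr & np.uint8(3)).astype(np.uint64)
    codes = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | a[j : j + m]
    is_n = (arr == 4).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(is_n)))
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid


def match(a: str, b: str) -> bool:
    """Base equality with the N-never-matches rule."""
    return a == b and a != "N"
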