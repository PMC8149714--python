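"""Synthetic genomes with planted repeats and deletion events of known truth.

The generator emulates the composition regime of a GC-rich multi-replicon
bacterial genome (~3.3 Mb over four elements at ~67% GC by default) and
plants deletion events under three double-strand-break repair models:

* ``AEJ``  -- alternative end-joining: an exact direct repeat of 2-20 bp at
  the two breakpoints, precise junction (no extra sequence change).
* ``SSA``  -- single-strand annealing: same junction structure but with a
  long repeat (>= 25 bp).
* ``NHEJ`` -- non-homologous end-joining: 0-4 bp of junction homology,
  optionally with bases inserted at the junction.

Planting uses rejection sampling on the bases immediately flanking the
repeat copies so that the maximal exact repeat at the planted junction
equals the requested microhomology length *exactly* and the planted start
is already the canonical leftmost placement.  Downstream parameter-recovery
tests are therefore exact, not probabilistic.

All randomness flows from a single ``numpy`` Generator seeded by
``SimConfig.seed`` and consumed in a fixed order (element sequences, then
standalone repeat pairs, then events in listed order), so a config fully
determines the output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_io import GenomeElement, Interval, write_fasta

__all__ = [
    "EventSpec",
    "SimConfig",
    "PlantedEvent",
    "SimTruth",
    "generate_genome",
    "plant_deletion",
    "simulate",
    "DEFAULT_ELEMENT_LENGTHS",
    "DEFAULT_GC",
]

#: Element lengths of the default emulation profile: a GC-rich bacterial
#: genome with one main chromosome, a secondary chromosome and two plasmids
#: (total 3,284,156 bp).
DEFAULT_ELEMENT_LENGTHS = (2_648_638, 412_348, 177_466, 45_704)
DEFAULT_ELEMENT_IDS = ("chrI", "chrII", "MP1", "CP1")
DEFAULT_GC = 0.67

_MECHANISMS = ("AEJ", "SSA", "NHEJ")


@dataclass(frozen=True)
class EventSpec:
    """A deletion event to plant: mechanism, microhomology, size, indel."""

    mechanism: str
    mh_length: int
    deletion_length: int
    junction_insert: str = ""
    element_index: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in _MECHANISMS:
            raise ValueError(f"mechanism must be one of {_MECHANISMS}, got {self.mechanism!r}")
        mh = self.mh_length
        if self.mechanism == "AEJ" and not 2 <= mh <= 20:
            raise ValueError(f"AEJ microhomology must be 2-20 bp, got {mh}")
        if self.mechanism == "SSA" and mh < 25:
            raise ValueError(f"SSA repeat must be >= 25 bp, got {mh}")
        if self.mechanism == "NHEJ" and not 0 <= mh <= 4:
            raise ValueError(f"NHEJ junction homology must be 0-4 bp, got {mh}")
        if self.junction_insert and self.mechanism != "NHEJ":
            raise ValueError("only NHEJ events may insert bases at the junction")
        if self.deletion_length < self.mh_length + 2:
            # the flanking bases that guarantee repeat maximality must lie
            # outside both repeat copies
            raise ValueError(
                f"deletion_length must be >= mh_length + 2 "
                f"({self.deletion_length} < {self.mh_length + 2})"
            )


@dataclass
class SimConfig:
    """Full description of one simulated dataset."""

    element_lengths: Sequence[int] = DEFAULT_ELEMENT_LENGTHS
    gc: float = DEFAULT_GC
    seed: int = 0
    markov_order: int = 0
    gc_clustering: float = 0.0  # order-1 persistence of the G+C state
    planted_repeats: Sequence[tuple[int, int, int]] = ()  # (length, separation, count)
    events: Sequence[EventSpec] = ()
    element_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"gc must be in [0, 1], got {self.gc}")
        if any(n <= 0 for n in self.element_lengths):
            raise ValueError("element lengths must be positive")
        if self.markov_order not in (0, 1):
            raise ValueError("markov_order must be 0 or 1")
        if not 0.0 <= self.gc_clustering < 1.0:
            raise ValueError("gc_clustering must be in [0, 1)")
        if self.element_ids is not None and len(self.element_ids) != len(self.element_lengths):
            raise ValueError("element_ids must match element_lengths")

    def ids(self) -> list[str]:
        if self.element_ids is not None:
            return list(self.element_ids)
        if len(self.element_lengths) <= len(DEFAULT_ELEMENT_IDS):
            return list(DEFAULT_ELEMENT_IDS[: len(self.element_lengths)])
        return [f"elem{i + 1}" for i in range(len(self.element_lengths))]


@dataclass
class PlantedEvent:
    """Ground truth for one planted deletion (coordinates on the reference)."""

    spec: EventSpec
    interval: Interval  # canonical leftmost placement, 0-based half-open
    repeat: str
    inserted: str = ""


@dataclass
class SimTruth:
    reference: list[GenomeElement]
    derived: list[GenomeElement]
    events: list[PlantedEvent]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.reference, outdir / "reference.fasta")
        write_fasta(self.derived, outdir / "derived.fasta")
        records = []
        for ev in self.events:
            s1, e1 = ev.interval.to_1based()
            records.append(
                {
                    "mechanism": ev.spec.mechanism,
                    "element": ev.interval.element_id,
                    "start": s1,
                    "end": e1,
                    "deletion_length": ev.interval.length,
                    "mh_length": ev.spec.mh_length,
                    "repeat": ev.repeat,
                    "inserted": ev.inserted,
                }
            )
        (outdir / "truth.json").write_text(json.dumps(records, indent=1) + "\n")


def _letter_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T


def _random_seq(rng: np.random.Generator, n: int, gc: float, order: int, clustering: float) -> str:
    if order == 0 or clustering == 0.0:
        idx = rng.choice(4, size=n, p=_letter_probs(gc))
    else:
        idx = _markov_seq(rng, n, gc, clustering)
    return "".join("ACGT"[i] for i in idx) if n < 1024 else _idx_to_str(idx)


def _idx_to_str(idx: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[idx].tobytes().decode("ascii")


def _markov_seq(rng: np.random.Generator, n: int, gc: float, c: float) -> np.ndarray:
    """Two-state (S=G/C, W=A/T) order-1 chain with stationary GC fraction.

    Transition matrix T = c*I + (1-c)*stationary, so the stationary
    distribution is (gc, 1-gc) for any persistence c; c=0 reduces to iid.
    Sampled via geometric run lengths, then letters uniform within state.
    """
    stay = {1: c + (1 - c) * gc, 0: c + (1 - c) * (1 - gc)}  # 1 = S state
    state = 1 if rng.random() < gc else 0
    states = []
    total = 0
    while total < n:
        p_leave = 1.0 - stay[state]
        if p_leave <= 0.0:
            run = n - total
        else:
            run = int(rng.geometric(p_leave))
        run = min(run, n - total)
        states.append((state, run))
        total += run
        state = 1 - state
    out = np.empty(n, dtype=np.int64)
    pos = 0
    for st, run in states:
        coin = rng.integers(0, 2, size=run)
        # S -> C(1)/G(2); W -> A(0)/T(3)
        out[pos : pos + run] = np.where(coin == 0, 1, 2) if st == 1 else np.where(coin == 0, 0, 3)
        pos += run
    return out


def generate_genome(config: SimConfig) -> list[GenomeElement]:
    """Generate the reference elements of a config (no repeats/events planted)."""
    rng = np.random.default_rng(config.seed)
    return _generate_elements(config, rng)


def _generate_elements(config: SimConfig, rng: np.random.Generator) -> list[GenomeElement]:
    elements = []
    for eid, n in zip(config.ids(), config.element_lengths):
        seq = _random_seq(rng, n, config.gc, config.markov_order, config.gc_clustering)
        elements.append(GenomeElement(id=eid, seq=seq))
    return elements


def _draw_base(rng: np.random.Generator, gc: float, exclude: str = "") -> str:
    bases = [b for b in "ACGT" if b not in exclude]
    probs = np.array([_letter_probs(gc)["ACGT".index(b)] for b in bases])
    probs = probs / probs.sum()
    return bases[int(rng.choice(len(bases), p=probs))]


def _place(
    rng: np.random.Generator,
    n: int,
    span: int,
    margin: int,
    occupied: list[tuple[int, int]],
    max_tries: int = 100,
) -> int:
    """Pick a start for a feature of ``span`` bp avoiding occupied regions."""
    lo, hi = margin, n - span - margin
    if hi < lo:
        raise ValueError(f"element too short ({n} bp) for a {span} bp feature")
    for _ in range(max_tries):
        s = int(rng.integers(lo, hi + 1))
        region = (s - margin, s + span + margin)
        if all(region[1] <= a or b <= region[0] for a, b in occupied):
            occupied.append(region)
            return s
    raise RuntimeError(f"could not place a {span} bp feature after {max_tries} tries")


def _write_exact_pair(
    seq: bytearray, rng: np.random.Generator, gc: float, s: int, e: int, mh: int
) -> str:
    """Write an exact ``mh``-bp repeat at ``s`` and ``e`` and randomize the
    four flanking bases so the repeat is maximal and leftmost-canonical:
    seq[s-1] != seq[e-1] (no left slide) and seq[s+mh] != seq[e+mh]
    (no right extension).  Returns the repeat string."""
    rep = "".join(_draw_base(rng, gc) for _ in range(mh))
    seq[s : s + mh] = rep.encode("ascii")
    seq[e : e + mh] = rep.encode("ascii")
    seq[e - 1 : e] = _draw_base(rng, gc, exclude=chr(seq[s - 1])).encode("ascii")
    seq[e + mh : e + mh + 1] = _draw_base(rng, gc, exclude=chr(seq[s + mh])).encode("ascii")
    return rep


def plant_deletion(
    ref: GenomeElement,
    spec: EventSpec,
    seed: int | np.random.Generator,
    occupied: list[tuple[int, int]] | None = None,
) -> tuple[GenomeElement, GenomeElement, PlantedEvent]:
    """Plant one deletion event into ``ref``.

    Returns ``(reference, derived, truth)``: the reference with the repeat
    pair written in, the derived genome with the segment (and one repeat
    copy) excised, and the planted truth.  For AEJ/SSA (and NHEJ without
    insertion) the junction is precise: excising ``truth.interval`` from
    the returned reference reproduces the derived sequence byte-for-byte.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    occupied = occupied if occupied is not None else []
    mh, dlen = spec.mh_length, spec.deletion_length
    margin = mh + 2
    seq = bytearray(ref.seq.encode("ascii"))
    s = _place(rng, len(seq), dlen + mh, margin, occupied)
    e = s + dlen
    gc = _observed_gc(ref.seq)
    rep = _write_exact_pair(seq, rng, gc, s, e, mh)
    new_ref = GenomeElement(id=ref.id, seq=seq.decode("ascii"), topology=ref.topology)
    derived_seq = seq[:s].decode("ascii") + spec.junction_insert + seq[e:].decode("ascii")
    derived = GenomeElement(id=ref.id, seq=derived_seq, topology=ref.topology)
    truth = PlantedEvent(
        spec=spec,
        interval=Interval(ref.id, s, e),
        repeat=rep,
        inserted=spec.junction_insert,
    )
    return new_ref, derived, truth


def _observed_gc(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.5
    return (seq.count("G") + seq.count("C")) / acgt


def simulate(config: SimConfig) -> SimTruth:
    """Generate reference + derived genomes with all configured features.

    Standalone repeat pairs are planted on the first element; events go to
    the element named by their ``element_index``.  Events on one element
    must not collide (bounded retries, then error).
    """
    rng = np.random.default_rng(config.seed)
    reference = _generate_elements(config, rng)
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(reference))}

    for length, separation, count in config.planted_repeats:
        el = reference[0]
        for _ in range(count):
            seq = bytearray(el.seq.encode("ascii"))
            s = _place(rng, len(seq), separation + length, length + 2, occupied[0])
            _write_exact_pair(seq, rng, config.gc, s, s + separation, length)
            el = GenomeElement(id=el.id, seq=seq.decode("ascii"), topology=el.topology)
        reference[0] = el

    events: list[PlantedEvent] = []
    for spec in config.events:
        idx = spec.element_index
        if not 0 <= idx < len(reference):
            raise ValueError(f"event element_index {idx} out of range")
        new_ref, _, truth = plant_deletion(reference[idx], spec, rng, occupied[idx])
        reference[idx] = new_ref
        events.append(truth)

    # derive: excise planted intervals right-to-left so coordinates hold
    derived = []
    for idx, el in enumerate(reference):
        dseq = el.seq
        for ev in sorted(
            (e for e in events if e.interval.element_id == el.id),
            key=lambda e: e.interval.start,
            reverse=True,
        ):
            s, e = ev.interval.start, ev.interval.end
            dseq = dseq[:s] + ev.inserted + dseq[e:]
        derived.append(GenomeElement(id=el.id, seq=dseq, topology=el.topology))
    return SimTruth(reference=reference, derived=derived, events=events)
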