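"""Genome and table I/O plus the coordinate conventions used package-wide.

Internally every interval is 0-based, half-open ``[start, end)``.  All
user-facing I/O (TSV tables, reports, truth files) is 1-based inclusive,
the convention of GenBank feature tables and of published deletion
coordinates.  :meth:`Interval.from_1based` / :meth:`Interval.to_1based`
are the only conversion points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from ._seq import VALID_CHARS

__all__ = [
    "GenomeElement",
    "Interval",
    "GeneRecord",
    "read_fasta",
    "write_fasta",
    "read_deletion_table",
    "write_deletion_table",
    "read_gene_table",
]


@dataclass
class GenomeElement:
    """One replicon: a chromosome or plasmid sequence.

    ``topology`` is "linear" or "circular"; circular treatment is opt-in
    because the deletions this package targets do not span the origin.
    """

    id: str
    seq: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")
        bad = set(self.seq) - VALID_CHARS
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(
                f"element {self.id!r}: invalid nucleotide {self.seq[pos]!r} at position {pos + 1}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """Half-open 0-based interval on a named element."""

    element_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start <= self.end:
            raise ValueError(
                f"invalid interval on {self.element_id!r}: start={self.start}, end={self.end}"
            )

    @classmethod
    def from_1based(cls, element_id: str, start1: int, end1: int) -> "Interval":
        """Build from 1-based inclusive coordinates (table/GenBank style)."""
        if start1 < 1:
            raise ValueError(f"1-based start must be >= 1, got {start1}")
        return cls(element_id, start1 - 1, end1)

    def to_1based(self) -> tuple[int, int]:
        return self.start + 1, self.end

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "Interval") -> bool:
        return (
            self.element_id == other.element_id
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.element_id == other.element_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneRecord:
    """A gene row: coordinates, strand, product, and COG class letters."""

    gene_id: str
    interval: Interval
    strand: str = "+"
    product: str = ""
    cog_classes: frozenset = field(default_factory=frozenset)
    complete_cds: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.complete_cds and self.interval.length % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id!r} flagged as complete CDS but length "
                f"{self.interval.length} is not a multiple of 3"
            )


def read_fasta(path, circular_ids: Iterable[str] = ()) -> list[GenomeElement]:
    """Read a (multi-)FASTA file into GenomeElements, order preserved.

    Topology defaults to linear; records whose id is in ``circular_ids``
    or whose description contains the token "circular" are circular.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    circular = set(circular_ids)
    with open(path) as fh:
        first = ""
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                first = line
                break
        if not first:
            raise ValueError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise ValueError(f"{path}: line {lineno}: expected '>' header, got {first[:30]!r}")
    elements = []
    for rec in SeqIO.parse(str(path), "fasta"):
        topo = "circular" if (rec.id in circular or "circular" in rec.description.lower()) else "linear"
        elements.append(GenomeElement(id=rec.id, seq=str(rec.seq), topology=topo))
    if not elements:
        raise ValueError(f"{path}: no FASTA records found")
    return elements


def write_fasta(elements: Sequence[GenomeElement], path, width: int = 70) -> None:
    """Write elements as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for el in elements:
            fh.write(f">{el.id}\n")
            for i in range(0, len(el.seq), width):
                fh.write(el.seq[i : i + width] + "\n")


_DELETION_COLUMNS = ["isolate", "element", "start", "end"]


def read_deletion_table(
    path,
    elements: Sequence[GenomeElement] | None = None,
    convention: str = "inclusive",
) -> list[tuple[str, Interval]]:
    """Read a deletion TSV (isolate, element, start, end; 1-based).

    Coordinates are converted to the internal 0-based half-open convention.
    Two published conventions are supported:

    * ``"inclusive"`` (default): start/end delimit the deleted bases
      1-based inclusively -- the rendering this package writes, so
      write/read round-trips.  Internal interval: ``[start-1, end)``.
    * ``"repeat_anchored"``: start *and* end are the 1-based start
      positions of the two breakpoint repeat copies, so the bases lost are
      ``end - start``.  Internal interval: ``[start-1, end-1)``.

    When ``elements`` is given, coordinates are validated against element
    lengths.  ``start > end`` is rejected (circular-spanning deletions are
    not representable in this table); ``start == end`` is flagged with a
    warning.
    """
    if convention not in ("inclusive", "repeat_anchored"):
        raise ValueError(f"unknown convention {convention!r}")
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _DELETION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: deletion table missing columns {missing}")
    lengths = {el.id: el.length for el in elements} if elements else None
    out = []
    for row in df.itertuples(index=False):
        start1, end1 = int(row.start), int(row.end)
        if start1 > end1:
            raise ValueError(
                f"{path}: isolate {row.isolate}: start {start1} > end {end1} on linear element"
            )
        if start1 == end1:
            # under "inclusive" a single base; under "repeat_anchored" a
            # zero-length deletion -- both unusual, both accepted
            warnings.warn(
                f"isolate {row.isolate}: degenerate interval {start1}..{end1}",
                stacklevel=2,
            )
        end_internal = end1 if convention == "inclusive" else end1 - 1
        iv = Interval(str(row.element), start1 - 1, end_internal)
        if lengths is not None:
            if row.element not in lengths:
                raise ValueError(f"{path}: unknown element {row.element!r}")
            if iv.end > lengths[row.element]:
                raise ValueError(
                    f"{path}: isolate {row.isolate}: end {end1} beyond element "
                    f"length {lengths[row.element]}"
                )
        out.append((str(row.isolate), iv))
    return out


def write_deletion_table(calls: Sequence[tuple[str, Interval]], path) -> None:
    rows = []
    for isolate, iv in calls:
        s1, e1 = iv.to_1based()
        rows.append({"isolate": isolate, "element": iv.element_id, "start": s1, "end": e1})
    pd.DataFrame(rows, columns=_DELETION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> list[GeneRecord]:
    """Read a gene TSV: gene_id, element, start, end, strand, product, cog.

    ``cog`` holds concatenated single-letter COG classes ("IQR"); "-" or
    empty means unassigned.  Coordinates are 1-based inclusive.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["gene_id", "element", "start", "end", "strand", "product", "cog"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gene table missing columns {missing}")
    genes = []
    for row in df.itertuples(index=False):
        iv = Interval.from_1based(row.element, int(row.start), int(row.end))
        cog = row.cog if isinstance(row.cog, str) else ""
        cogs = frozenset(c for c in cog if c.isalpha())
        genes.append(
            GeneRecord(
                gene_id=row.gene_id,
                interval=iv,
                strand=row.strand,
                product=row.product if isinstance(row.product, str) else "",
                cog_classes=cogs,
                complete_cds=iv.length % 3 == 0,
            )
        )
    return genes
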