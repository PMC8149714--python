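"""Region dispensability statistics: GC%, GC3s, SCUO, and COG tabulation.

SCUO (synonymous codon usage order) is the entropy-based per-gene codon
bias statistic of Wan et al. (2004): for each amino acid *a* with
``n_a >= 2`` synonymous codons present in the gene,

    p_aj = c_aj / sum_j c_aj
    H_a  = -sum_j p_aj log2 p_aj
    O_a  = (log2 n_a - H_a) / log2 n_a

and SCUO is the codon-frequency-weighted mean of O_a.  It is 0 when every
synonymous codon of every used amino acid is equally frequent and 1 when
each amino acid uses a single codon; higher means stronger bias.

GC3s here is the GC percent at third positions of codons in the eight
fourfold-degenerate codon boxes of the bacterial translation table
(table 11): GCN, CGN, GGN, CTN, CCN, TCN, ACN, GTN.  Third positions of
those boxes are silent, so their composition reflects mutational bias
rather than protein constraint.  The Leu/Arg/Ser sextets contribute only
their quartet boxes.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Data import CodonTable

from ._seq import revcomp
from .genome_io import GeneRecord, GenomeElement, Interval

__all__ = [
    "CodonProfile",
    "RegionReport",
    "count_codons",
    "gc_percent",
    "scuo",
    "gc3s",
    "gene_profile",
    "genes_in_region",
    "region_report",
    "lower_median",
    "SYNONYM_FAMILIES",
    "FOURFOLD_BOXES",
]

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

#: amino acid -> tuple of synonymous codons (stops excluded), table 11
SYNONYM_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _TABLE11.forward_table.items():
    SYNONYM_FAMILIES.setdefault(_aa, ())
    SYNONYM_FAMILIES[_aa] += (_codon,)

_CODON_TO_AA = dict(_TABLE11.forward_table)
_STOPS = frozenset(_TABLE11.stop_codons)

#: the eight fourfold-degenerate codon boxes (first two bases)
FOURFOLD_BOXES = frozenset({"GC", "CG", "GG", "CT", "CC", "TC", "AC", "GT"})


def count_codons(cds: str) -> Counter:
    """Codon counts of an in-frame CDS (length must be a multiple of 3).

    Stop codons are counted (they belong to the CDS length) but are
    ignored by :func:`scuo` and :func:`gc3s`.  Codons containing N are
    skipped.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    counts: Counter = Counter()
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if "N" not in codon:
            counts[codon] += 1
    return counts


def gc_percent(seq: str) -> float:
    """(G+C) / (A+C+G+T) * 100; N excluded from the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return 100.0 * gc / (gc + at)


def scuo(codon_counts: Mapping[str, int]) -> float:
    """Synonymous codon usage order of a codon-count table, in [0, 1]."""
    families: dict[str, list[int]] = {}
    for codon, count in codon_counts.items():
        if count <= 0 or codon in _STOPS or codon not in _CODON_TO_AA:
            continue
        aa = _CODON_TO_AA[codon]
        if len(SYNONYM_FAMILIES[aa]) < 2:
            continue  # Met/Trp carry no synonymous choice
        families.setdefault(aa, []).append(count)
    if not families:
        raise ValueError("no amino acid with >= 2 synonymous codons present")
    total = sum(sum(c) for c in families.values())
    out = 0.0
    for aa, counts in families.items():
        n_a = len(SYNONYM_FAMILIES[aa])
        tot_a = sum(counts)
        h = -sum((c / tot_a) * math.log2(c / tot_a) for c in counts)
        o = (math.log2(n_a) - h) / math.log2(n_a)
        out += (tot_a / total) * o
    return out


def gc3s(codon_counts: Mapping[str, int]) -> float:
    """GC percent at third positions of fourfold-degenerate codon boxes."""
    gc = 0
    tot = 0
    for codon, count in codon_counts.items():
        if count <= 0 or len(codon) != 3 or codon[:2] not in FOURFOLD_BOXES:
            continue
        tot += count
        if codon[2] in "GC":
            gc += count
    if tot == 0:
        raise ValueError("no fourfold-degenerate-box codons present")
    return 100.0 * gc / tot


@dataclass
class CodonProfile:
    """Per-gene codon counts with the derived bias statistics."""

    gene_id: str
    codon_counts: Counter
    scuo: float
    gc3s_percent: float | None


def gene_profile(genome: GenomeElement, gene: GeneRecord) -> CodonProfile:
    """Extract a gene's CDS (reverse-complemented for minus-strand genes)
    and compute its codon profile."""
    iv = gene.interval
    if iv.element_id != genome.id:
        raise ValueError(f"gene {gene.gene_id} is on {iv.element_id!r}, not {genome.id!r}")
    cds = genome.seq[iv.start : iv.end]
    if gene.strand == "-":
        cds = revcomp(cds)
    counts = count_codons(cds)
    try:
        g3 = gc3s(counts)
    except ValueError:
        g3 = None
    return CodonProfile(gene_id=gene.gene_id, codon_counts=counts, scuo=scuo(counts), gc3s_percent=g3)


def lower_median(values: Sequence[float]) -> float:
    """Order-statistic median; the lower of the two middle values for even
    counts (deterministic, always an observed value)."""
    if not values:
        raise ValueError("median of empty sequence")
    s = sorted(values)
    return s[(len(s) - 1) // 2]


@dataclass
class RegionReport:
    """Composition and gene statistics of one genomic region."""

    interval: Interval
    gc_percent: float
    gene_count: int
    median_scuo: float | None
    gc3s_percent: float | None  # pooled over contained genes
    cog_histogram: Counter = field(default_factory=Counter)
    contained_genes: list[str] = field(default_factory=list)
    overlapping_genes: list[str] = field(default_factory=list)


def genes_in_region(
    genes: Sequence[GeneRecord], interval: Interval
) -> tuple[list[GeneRecord], list[GeneRecord]]:
    """Split genes into (fully contained, overlapping-but-not-contained).

    Usable without the genome sequence, e.g. for COG tabulation from a
    coordinate table alone.
    """
    contained = [g for g in genes if interval.contains(g.interval)]
    touching = [
        g for g in genes if interval.overlaps(g.interval) and not interval.contains(g.interval)
    ]
    return contained, touching


def region_report(
    genome: GenomeElement,
    genes: Sequence[GeneRecord],
    interval: Interval,
    containment: str = "full",
) -> RegionReport:
    """Aggregate GC over the interval and codon statistics over its genes.

    A gene counts toward the region iff fully contained in it
    (``containment="full"``, the default) or merely overlapping it
    (``containment="overlap"``).  Genes that overlap without being
    contained are always listed separately so border cases are visible.
    """
    if containment not in ("full", "overlap"):
        raise ValueError("containment must be 'full' or 'overlap'")
    if interval.element_id != genome.id:
        raise ValueError(f"interval on {interval.element_id!r} does not match {genome.id!r}")
    gc = gc_percent(genome.seq[interval.start : interval.end])
    contained = [g for g in genes if interval.contains(g.interval)]
    touching = [
        g for g in genes if interval.overlaps(g.interval) and not interval.contains(g.interval)
    ]
    counted = contained + touching if containment == "overlap" else contained
    if not counted:
        return RegionReport(
            interval=interval,
            gc_percent=gc,
            gene_count=0,
            median_scuo=None,
            gc3s_percent=None,
            overlapping_genes=[g.gene_id for g in touching],
        )
    profiles = [gene_profile(genome, g) for g in counted]
    pooled: Counter = Counter()
    for p in profiles:
        pooled.update(p.codon_counts)
    cogs: Counter = Counter()
    for g in counted:
        cogs.update(g.cog_classes)
    try:
        pooled_gc3s = gc3s(pooled)
    except ValueError:
        pooled_gc3s = None
    return RegionReport(
        interval=interval,
        gc_percent=gc,
        gene_count=len(counted),
        median_scuo=lower_median([p.scuo for p in profiles]),
        gc3s_percent=pooled_gc3s,
        cog_histogram=cogs,
        contained_genes=[g.gene_id for g in contained],
        overlapping_genes=[g.gene_id for g in touching],
    )
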