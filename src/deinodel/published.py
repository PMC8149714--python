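"""Published coordinates and genome constants for the *D. radiodurans*
*recA* deletion study, shipped as package data.

These tables are analysis *inputs*: the five chromosome II deletions with
their breakpoint repeats (in both the study's reference-wild-type and the
1999 wild-type coordinate systems), the gene annotation of the recurrently
deleted region, and replicon lengths.  Two published conventions are
deliberately surfaced rather than reconciled:

* for four of five isolates the printed deletion length differs by a few
  bp from ``end - start`` of the printed coordinates
  (:func:`consistency_report` warns about each);
* the running-text coordinates of the union and common deleted regions
  differ by a few bp from those derived from the deletion table
  (``TEXT_UNION_REGION`` / ``TEXT_COMMON_REGION`` vs the table-derived
  values).
"""

from __future__ import annotations

import warnings
from importlib import resources

import pandas as pd

from .genome_io import GeneRecord, Interval, read_gene_table

__all__ = [
    "REF_WT_LENGTHS",
    "WT1999_LENGTHS",
    "CHRII_ORI_POS",
    "TEXT_UNION_REGION",
    "TEXT_COMMON_REGION",
    "load_deletion_table",
    "deletion_intervals",
    "load_gene_table",
    "consistency_report",
    "deleted_fractions",
]

#: Replicon lengths (bp) of the study's own reference wild-type assembly.
REF_WT_LENGTHS = {"chrI": 2_644_543, "chrII": 412_189, "MP1": 177_363, "CP1": 45_503}

#: Replicon lengths (bp) of the 1999 wild-type assembly.
WT1999_LENGTHS = {"chrI": 2_648_638, "chrII": 412_348, "MP1": 177_466, "CP1": 45_704}

#: Database-predicted origin of replication of chromosome II (1-based).
CHRII_ORI_POS = 1

#: Union / common deleted region as printed in the study's running text
#: (1-based inclusive); the table-derived values differ by a few bp.
TEXT_UNION_REGION = (160_030, 247_789)
TEXT_COMMON_REGION = (187_425, 222_947)


def _data(name: str):
    return resources.files("deinodel.data") / name


def load_deletion_table() -> pd.DataFrame:
    """The five published deletions: coordinates, printed length, repeat."""
    with resources.as_file(_data("recA_deletions.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def deletion_intervals(coords: str = "ref_wt") -> list[tuple[str, Interval]]:
    """Deletions as internal intervals, in "ref_wt" or "wt1999" coordinates.

    The published start/end are repeat-anchored (both are repeat start
    positions), so the internal half-open interval of excised bases is
    ``[start-1, end-1)`` and its length equals ``end - start``.
    """
    df = load_deletion_table()
    cols = {"ref_wt": ("start", "end"), "wt1999": ("wt1999_start", "wt1999_end")}
    if coords not in cols:
        raise ValueError(f"coords must be 'ref_wt' or 'wt1999', got {coords!r}")
    s, e = cols[coords]
    return [
        (row.isolate, Interval(row.element, int(getattr(row, s)) - 1, int(getattr(row, e)) - 1))
        for row in df.itertuples(index=False)
    ]


def load_gene_table() -> list[GeneRecord]:
    """Gene annotation of the recurrently deleted chromosome II region."""
    with resources.as_file(_data("chrII_genes.tsv")) as p:
        return read_gene_table(p)


def consistency_report(warn: bool = True) -> pd.DataFrame:
    """Printed deletion length vs length computed from printed coordinates.

    The deletion coordinates are repeat-anchored, so the number of bases
    lost is ``end - start``.  Where the printed length disagrees, a
    warning is emitted and both values are reported; the discrepancy is a
    property of the source table and is not reconciled here.
    """
    df = load_deletion_table().copy()
    df["computed_length"] = df["end"] - df["start"]
    df["repeat_length"] = df["repeat"].str.len()
    df["consistent"] = df["computed_length"] == df["printed_length"]
    if warn:
        for row in df[~df["consistent"]].itertuples(index=False):
            warnings.warn(
                f"isolate {row.isolate}: printed deletion length "
                f"{row.printed_length} != end - start = {row.computed_length}",
                stacklevel=2,
            )
    return df


def deleted_fractions(chromosome_length: int = REF_WT_LENGTHS["chrII"]) -> pd.Series:
    """Percent of chromosome II removed by each deletion (printed lengths)."""
    df = load_deletion_table()
    return (100.0 * df["printed_length"] / chromosome_length).set_axis(df["isolate"])
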