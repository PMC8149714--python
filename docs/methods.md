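# Methods

## Scope and model

`deinodel` analyzes large deletions between two collinear assemblies of
the same bacterial replicon.  The underlying biological model is
double-strand-break (DSB) repair by annealing at pre-existing sequence
repeats: a break (or two) is resected, complementary single strands
anneal at a direct repeat, and ligation deletes one repeat copy plus the
intervening DNA.  The observable is therefore a deletion whose two
breakpoints share an exact direct repeat, one copy of which survives at
the junction.  Three mechanism classes are distinguished purely by
junction features:

| label | rule |
|---|---|
| `NHEJ-like` | bases inserted at the junction, or junction not exact |
| `SSA-compatible` | exact junction, microhomology ≥ 25 bp |
| `AEJ-compatible` | exact junction, microhomology 2–20 bp |
| `ambiguous` | exact junction, microhomology 21–24 bp |
| `unclassified` | exact junction, microhomology ≤ 1 bp |

The 21–24 bp band is deliberately not forced into either class: the two
literature thresholds (A-EJ up to 20 bp, SSA above 25 bp) leave a gap,
and the classifier reports what the data cannot decide.  The label is a
pure function of `(mh_length, junction_exact, inserted_bases)`.

## Coordinates and canonicalization

Internally every interval is 0-based half-open; all I/O is 1-based.  A
deletion between repeat copies is ambiguous under sliding, so calls are
normalized to the **leftmost** equivalent placement (the standard
left-alignment convention for indels).  The breakpoint repeat is the
longest common prefix of the suffixes at the canonical start and end;
maximality (no one-base extension on either side) is an invariant that
is brute-force-checkable on short sequences.  `N` matches nothing,
anywhere homology is measured.

Deletion tables are read under two conventions because both occur in
practice: `inclusive` (start/end delimit the deleted bases 1-based
inclusively — the rendering this package writes, so tables round-trip)
and `repeat_anchored` (start and end are the 1-based start positions of
the two repeat copies, so bases lost = end − start — the convention of
published deletion tables anchored "at the beginning of the repeat").
The shipped published table is repeat-anchored.  Published printed
lengths disagree with end − start by 4–27 bp for four of five isolates;
the package reports end − start, carries the printed value alongside,
and warns — it does not guess which the original authors meant.

## Deletion calling

Assemblies are compared via k-mer anchors: k-mers occurring exactly once
in each sequence, matched by content (default k = 31; 4³¹ ≫ genome size,
so unique 31-mers are effectively unambiguous and step over short repeat
families).  The longest chain strictly increasing in both coordinates is
selected (patience algorithm, deterministic reconstruction preferring
earlier reference anchors).  A chain gap where the reference diagonal
jumps by ≥ `min_len` (default 1,000 bp — this tool targets gross
deletions; smaller indels belong to SNP/indel callers) is refined by
exact match extension inward from the bounding anchors.  If the
extensions close the gap, the call is a clean excision placed leftmost;
otherwise the unexplained derived bases are reported as junction-inserted
sequence.  Either way the module asserts, for every call, that excision
(+ insertion) reproduces the derived sequence over the full anchored
neighborhood.  Gaps where the derived sequence advances more than the
reference are insertions and are skipped with a warning; inversions and
translocations are out of scope (forward-strand collinear comparison
only).

## Synthetic data

The generator emulates a GC-rich multi-replicon bacterial genome.
Defaults define the emulation profile used by the acceptance analysis:
four elements of 2,648,638 / 412,348 / 177,466 / 45,704 bp (3,284,156 bp
total) at GC 0.67, iid nucleotides (a two-state order-1 chain with a
`gc_clustering` persistence knob is available; its stationary GC equals
the configured GC for any persistence).  A single `numpy` generator
seeded by `SimConfig.seed` is consumed in a fixed order (element
sequences → standalone repeat pairs → events), so a config fully
determines every output byte.

Planting an exact-junction event writes the repeat at the two breakpoint
sites and then rejection-samples the four flanking bases so that
`ref[s-1] ≠ ref[e-1]` (the planted start is already leftmost-canonical)
and `ref[s+mh] ≠ ref[e+mh]` (the repeat is maximal).  This makes
parameter recovery a deterministic contract rather than a probabilistic
one, which is why the recovery tests can demand 100%.  Two consequences
are documented as deliberate design:

* `plant_deletion` returns the *modified reference* together with the
  derived genome and the truth record — planting necessarily edits the
  reference, and returning it keeps the truth self-consistent
  (excising the truth interval from the returned reference reproduces
  the derived sequence byte-for-byte).
* `deletion_length ≥ mh_length + 2` is required: for shorter deletions
  the flank positions that guarantee maximality fall inside the repeat
  copies themselves, so an exactly-maximal planting does not exist.

What the simulator does **not** emulate: real repeat families (insertion
sequences, rRNA operons), compositional heterogeneity along the replicon,
SNPs between assemblies, and sequencing/assembly error.  Passing
round-trip tests therefore demonstrates the correctness of the
algorithms under the stated model, not robustness to misassembly.

## Repeat-pair coverage

An L-window is repeated iff its exact sequence occurs at ≥ 2 distinct
start positions across all elements pooled; a position is covered iff it
lies in ≥ 1 repeated window; the statistic is covered / total non-N
positions × 100.  Windows containing N are excluded from both sides of
the ratio.  Implementation packs windows into 62-bit integers and uses
sorted-array lookups; it is cross-checked against a dictionary-based
oracle and a quadratic all-pairs scan on small inputs.

Orientation: the five characterized deletions all involve *direct*
repeats, so the library default counts direct pairs only
(`include_revcomp=False`).  For the whole-genome abundance statistic,
however, the package follows the convention of whole-genome repeat
finders and counts a pair when either the sequence or its reverse
complement recurs (a palindromic window does not pair with itself).  The
distinction matters quantitatively at the saturation edge: on the
3.28 Mb iid emulation genome at GC 0.67, direct-only coverage at L = 11
is ≈ 99.3% while either-strand coverage is ≈ 99.9%, which rounds to the
published-scale figure of 100%.  Real genomes sit above the iid regime
because repeat families add long identical pairs.

## Region statistics

GC% is (G+C)/(A+C+G+T)×100 with N excluded.  GC3s is the GC percent at
third positions of codons in the eight fourfold-degenerate boxes of
bacterial translation table 11 (GCN, CGN, GGN, CTN, CCN, TCN, ACN, GTN);
sextet amino acids contribute only their quartet boxes.  SCUO follows
the entropy formulation of Wan et al. (2004) with `n_a` taken from the
genetic code (amino acids absent from the gene are skipped; Met/Trp and
stop codons carry no synonymous information; log base cancels in the
normalized difference).  Gene-level statistics aggregate over genes
fully contained in the region (the containment rule); genes that
straddle the region border are always listed separately, and an
`overlap` mode counts them too.  The region median is the lower median
(deterministic, always an observed value).

The published per-gene and per-region values for the real secondary
chromosome (GC ≈ 66.7/67.4%, SCUO medians 0.3831/0.3543) depend on the
external genome accession and on the exact SCUO variant of the original
codon-usage software, which is not fully specified; they are a
qualitative comparison surface for this module, not a bit-exact target.
The conventions themselves are exercised on synthetic genes with
hand-computable codon counts.

## Terminus analysis

Origin position is an input (database lookup is out of scope; the
default for a secondary chromosome is coordinate 1).  The terminus is
the antipodal coordinate `((ori − 1 + ⌊len/2⌋) mod len) + 1`; reports
round it to the nearest 1,000 bp alongside the exact value.  The common
deleted region is the interval intersection `[max(starts), min(ends))`.
Both the table-derived common region and the slightly different
running-text coordinates of the source tables are surfaced
(`deinodel.published.TEXT_COMMON_REGION`), not reconciled.

## Problem sizes and determinism

The test suite simulates at reduced scale chosen to exercise every code
path densely: parameter recovery uses 500 events on 6–12 kb elements;
caller round-trips use ~85 genomes of 100–220 kb with 1–4 events each
(≥ 200 events checked, ≥ 95% exact recovery demanded; the slack covers
anchor-sparsity cases, not interval errors); the coverage regime check
runs once at the full 3,284,156 bp emulation profile.  All randomness is
`numpy.random.default_rng` seeded explicitly; hypothesis profiles are
derandomized.  Pipeline outputs are byte-deterministic: fixed column
orders, fixed float formatting (percents 1 decimal, SCUO 4 decimals).

## Known limitations

* Only collinear, same-strand assembly pairs; no inversion/translocation
  or duplication detection.
* Junction verification is exact substring search; a single polishing
  error inside the ±60 bp junction context yields `not_found`.
* Circular topology is opt-in and used for wrap-around repeat windows
  and terminus containment; the deletion caller treats elements as
  linear (the targeted events do not span the origin).
* Mechanism labels state compatibility, not proof: a 4 bp exact junction
  is consistent with A-EJ and with precise NHEJ; the classifier encodes
  the literature thresholds, and the `ambiguous` band makes the
  undecidable zone explicit.
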