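import math
from collections import Counter

import pytest
from hypothesis import given
from hypothesis import strategies as st

from deinodel._seq import revcomp
from deinodel.genome_io import GeneRecord, GenomeElement, Interval
from deinodel.region_stats import (
    SYNONYM_FAMILIES,
    count_codons,
    gc3s,
    gc_percent,
    gene_profile,
    genes_in_region,
    lower_median,
    region_report,
    scuo,
)


class TestGCPercent:
    @pytest.mark.parametrize(
        "seq,expected", [("GGCC", 100.0), ("ACGT", 50.0), ("ACGGGT", 200 / 3)]
    )
    def test_values(self, seq, expected):
        assert gc_percent(seq) == pytest.approx(expected)

    def test_n_excluded_from_denominator(self):
        assert gc_percent("GCNN") == 100.0

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            gc_percent("NNN")
        with pytest.raises(ValueError):
            gc_percent("")


class TestSCUO:
    def test_uniform_usage_is_zero(self):
        counts = {c: 5 for aa in SYNONYM_FAMILIES.values() if len(aa) >= 2 for c in aa}
        assert scuo(counts) == pytest.approx(0.0, abs=1e-12)

    def test_single_codon_per_amino_acid_is_one(self):
        counts = {fam[0]: 7 for fam in SYNONYM_FAMILIES.values() if len(fam) >= 2}
        assert scuo(counts) == pytest.approx(1.0)

    def test_hand_computed_alanine_example(self):
        # Ala box (4 synonyms), counts 3:1 -> H = 0.8113, O = (2-H)/2
        h = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        expected = (2 - h) / 2
        assert scuo({"GCA": 3, "GCC": 1}) == pytest.approx(expected)
        assert round(scuo({"GCA": 3, "GCC": 1}), 4) == 0.5944

    def test_met_trp_only_undefined(self):
        with pytest.raises(ValueError):
            scuo({"ATG": 3, "TGG": 2})

    def test_stop_codons_ignored(self):
        assert scuo({"GCA": 3, "GCC": 1, "TAA": 1}) == scuo({"GCA": 3, "GCC": 1})

    @given(
        counts=st.dictionaries(
            st.sampled_from(sorted(c for f in SYNONYM_FAMILIES.values() for c in f)),
            st.integers(1, 50),
            min_size=2,
            max_size=30,
        )
    )
    def test_bounded_in_unit_interval(self, counts):
        try:
            val = scuo(counts)
        except ValueError:
            return  # only single-synonym amino acids drawn
        assert 0.0 <= val <= 1.0 + 1e-12


class TestGC3s:
    def test_single_fourfold_codon(self):
        assert gc3s({"GTG": 5}) == 100.0

    def test_symmetric_pair(self):
        assert gc3s({"ACA": 1, "ACG": 1}) == 50.0

    def test_non_fourfold_codons_ignored(self):
        assert round(gc3s({"GCC": 2, "GCT": 1, "ATG": 7}), 1) == 66.7

    def test_twofold_boxes_excluded(self):
        # AAG (Lys, twofold) is not a fourfold box
        with pytest.raises(ValueError):
            gc3s({"AAG": 10, "ATG": 2})


class TestGeneProfileAndRegion:
    def _genome_with_genes(self):
        # two hand-built CDSs embedded in a small element
        cds1 = "ATG" + "GCA" * 6 + "GCC" * 2 + "TAA"  # Ala-biased
        cds2 = "ATG" + "CTG" * 4 + "CTA" * 4 + "TGA"  # Leu, uniform in 2 codons
        pad = "T" * 30
        seq = pad + cds1 + pad + cds2 + pad
        el = GenomeElement(id="e", seq=seq)
        g1 = GeneRecord("g1", Interval("e", 30, 30 + len(cds1)), "+", complete_cds=True)
        s2 = 60 + len(cds1)
        g2 = GeneRecord("g2", Interval("e", s2, s2 + len(cds2)), "+", complete_cds=True)
        return el, [g1, g2], cds1, cds2

    def test_codon_counts_match_cds(self):
        el, genes, cds1, _ = self._genome_with_genes()
        prof = gene_profile(el, genes[0])
        assert prof.codon_counts == Counter(
            {"ATG": 1, "GCA": 6, "GCC": 2, "TAA": 1}
        )
        assert sum(prof.codon_counts.values()) * 3 == len(cds1)

    def test_strand_invariance(self):
        el, genes, _, _ = self._genome_with_genes()
        plus = gene_profile(el, genes[0])
        flipped_seq = revcomp(el.seq)
        n = el.length
        iv = genes[0].interval
        flipped_gene = GeneRecord("g1", Interval("e", n - iv.end, n - iv.start), "-")
        minus = gene_profile(GenomeElement(id="e", seq=flipped_seq), flipped_gene)
        assert plus.codon_counts == minus.codon_counts
        assert plus.scuo == pytest.approx(minus.scuo)

    def test_region_report_median_over_genes(self):
        el, genes, _, _ = self._genome_with_genes()
        rep = region_report(el, genes, Interval("e", 0, el.length))
        assert rep.gene_count == 2
        expected = lower_median([gene_profile(el, g).scuo for g in genes])
        assert rep.median_scuo == pytest.approx(expected)

    def test_region_without_genes_reports_gc_only(self):
        el, genes, _, _ = self._genome_with_genes()
        rep = region_report(el, genes, Interval("e", 0, 10))
        assert rep.gene_count == 0
        assert rep.median_scuo is None
        assert rep.gc_percent == pytest.approx(0.0)  # leading T pad

    def test_containment_vs_overlap_rule(self):
        el, genes, _, _ = self._genome_with_genes()
        # cut through the middle of g2: it overlaps but is not contained
        cut = genes[1].interval.start + 3
        full = region_report(el, genes, Interval("e", 0, cut))
        assert full.gene_count == 1
        assert full.overlapping_genes == ["g2"]
        both = region_report(el, genes, Interval("e", 0, cut), containment="overlap")
        assert both.gene_count == 2

    def test_cog_histogram_counts_each_letter(self):
        el, genes, _, _ = self._genome_with_genes()
        genes[0].cog_classes = frozenset("IQ")
        genes[1].cog_classes = frozenset("I")
        rep = region_report(el, genes, Interval("e", 0, el.length))
        assert rep.cog_histogram == {"I": 2, "Q": 1}

    def test_genes_in_region_without_genome(self):
        genes = [
            GeneRecord("a", Interval("e", 10, 20)),
            GeneRecord("b", Interval("e", 18, 30)),
            GeneRecord("c", Interval("e", 40, 50)),
        ]
        contained, touching = genes_in_region(genes, Interval("e", 9, 31))
        assert [g.gene_id for g in contained] == ["a", "b"]
        assert touching == []


class TestMedian:
    def test_lower_median_even_count(self):
        assert lower_median([4.0, 1.0, 3.0, 2.0]) == 2.0

    def test_permutation_invariant(self):
        assert lower_median([3.0, 1.0, 2.0]) == lower_median([1.0, 2.0, 3.0]) == 2.0


def test_count_codons_requires_frame():
    with pytest.raises(ValueError):
        count_codons("ACGTA")
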