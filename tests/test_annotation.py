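"""Region classification, CDS coordinate mapping and coding consequences."""

import pytest
from Bio.Seq import Seq

from somaticfunnel.annotation import (
    TranscriptIndex,
    TranscriptModel,
    annotate_variant,
    classify_region,
    coding_consequence,
)
from somaticfunnel.errors import ReferenceMismatchError
from somaticfunnel.simulate import generate_reference_and_transcripts
from somaticfunnel.variants import Variant


def _toy_transcript(strand="+"):
    """Two-exon model: 5'UTR 10 bp, CDS 30 bp split 18+12, 3'UTR 10 bp.

    Plus strand: exon1 = 101..128 (UTR 101-110, CDS 111-128),
    intron 129-228, exon2 = 229-250 (CDS 229-240, UTR 241-250).
    """
    cds = "ATGGCCAAAGGATACTTAGCAGCCGGGTAA"  # M A K G Y L A A G *
    assert len(cds) == 30
    if strand == "+":
        return TranscriptModel(
            transcript_id="TOY+", gene_symbol="TOY", chrom="t", strand="+",
            exons=((101, 128), (229, 250)), cds_start=111, cds_end=240,
            cds_sequence=cds,
        )
    # mirrored layout on the minus strand: same CDS in mRNA orientation
    return TranscriptModel(
        transcript_id="TOY-", gene_symbol="TOYM", chrom="m", strand="-",
        exons=((101, 122), (223, 250)), cds_start=111, cds_end=240,
        cds_sequence=cds,
    )


class TestRegionClassification:
    @pytest.fixture()
    def index(self):
        return TranscriptIndex([_toy_transcript("+")])

    @pytest.mark.parametrize("pos,expected", [
        (115, "exonic"),      # inside CDS
        (105, "UTR5"),        # exon, upstream of CDS
        (245, "UTR3"),        # exon, downstream of CDS
        (130, "splicing"),    # 2 bp into the intron (donor side)
        (227, "splicing"),    # 2 bp into the intron (acceptor side)
        (131, "intronic"),    # 3 bp into the intron
        (180, "intronic"),
        (60, "upstream"),     # < 1 kb left of tx start
        (800, "downstream"),
    ])
    def test_classes(self, index, pos, expected):
        region, genes = classify_region(
            Variant(chrom="t", pos=pos, ref="A", alt="G"), index)
        assert region == expected
        assert genes == ("TOY",)

    def test_far_away_is_intergenic_without_genes(self, index):
        region, genes = classify_region(
            Variant(chrom="t", pos=5000, ref="A", alt="G"), index)
        assert (region, genes) == ("intergenic", ())

    def test_exonic_beats_intronic_across_transcripts(self):
        """A variant exonic in one transcript and intronic in another
        reports exonic with only the exonic transcript's gene, independent
        of transcript input order."""
        a = _toy_transcript("+")
        b = TranscriptModel(
            transcript_id="WIDE", gene_symbol="WIDEG", chrom="t", strand="+",
            exons=((50, 60), (300, 329)), cds_start=300, cds_end=329,
            cds_sequence="ATGGCCAAAGGATACTTAGCAGCCGGGTAA",
        )
        v = Variant(chrom="t", pos=115, ref="A", alt="G")
        for order in ([a, b], [b, a]):
            region, genes = classify_region(v, TranscriptIndex(order))
            assert (region, genes) == ("exonic", ("TOY",))


class TestCodingConsequence:
    def test_nonsynonymous_with_compact_and_hgvs_strings(self):
        t = _toy_transcript("+")
        # CDS pos 5 (codon 2 GCC, middle base) C>T -> GTC: A2V
        v = Variant(chrom="t", pos=115, ref="C", alt="T")
        c = coding_consequence(v, t)
        assert c.kind == "nonsynonymous SNV"
        assert c.cdna_change == "c.C5T"
        assert c.cdna_change_hgvs == "c.5C>T"
        assert c.protein_change == "p.A2V"
        assert c.exon_number == 1

    def test_synonymous_wobble(self):
        t = _toy_transcript("+")
        # codon 7 GCA -> GCG (both Ala), CDS pos 21 in exon 2 (229 + 2)
        assert t.cds_sequence[18:21] == "GCA"
        v = Variant(chrom="t", pos=231, ref="A", alt="G")
        c = coding_consequence(v, t)
        assert c.kind == "synonymous SNV"
        assert c.protein_change == "p.A7A"
        # full-CDS translations agree for every synonymous call
        mutated = t.cds_sequence[:20] + "G" + t.cds_sequence[21:]
        assert str(Seq(mutated).translate()) == str(Seq(t.cds_sequence).translate())

    def test_stopgain_and_stoploss(self):
        t = _toy_transcript("+")
        # codon 5 TAC: pos 15 C>A gives TAA (stopgain); CDS 13..15 = 123..125
        v = coding_consequence(Variant(chrom="t", pos=125, ref="C", alt="A"), t)
        assert v.kind == "stopgain"
        assert v.protein_change.endswith("X")
        # final codon TAA: CDS 28..30 = 238..240; A>C gives TCA (stoploss)
        w = coding_consequence(Variant(chrom="t", pos=239, ref="A", alt="C"), t)
        assert w.kind == "stoploss"

    def test_minus_strand_mirror_matches_plus(self):
        """A minus-strand model with the same spliced CDS yields the same
        consequence for the equivalent (reverse-complemented) genomic SNV."""
        plus, minus = _toy_transcript("+"), _toy_transcript("-")
        cds_pos, alt_cds = 5, "T"
        gp = plus.cds_to_genomic(cds_pos)
        gm = minus.cds_to_genomic(cds_pos)
        v_plus = Variant(chrom="t", pos=gp, ref=plus.cds_sequence[4], alt=alt_cds)
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        v_minus = Variant(chrom="m", pos=gm,
                          ref=comp[minus.cds_sequence[4]], alt=comp[alt_cds])
        c_plus = coding_consequence(v_plus, plus)
        c_minus = coding_consequence(v_minus, minus)
        assert c_plus.kind == c_minus.kind
        assert c_plus.cdna_change == c_minus.cdna_change
        assert c_plus.protein_change == c_minus.protein_change

    def test_frameshift_and_nonframeshift_indels(self):
        t = _toy_transcript("+")
        # single-base deletion inside CDS (anchor 114 deletes CDS pos 5)
        d = coding_consequence(
            Variant(chrom="t", pos=114, ref="CC", alt="C"), t)
        assert d.kind == "frameshift deletion"
        assert d.cdna_change == "c.5del"
        # 3-base deletion: CDS 5..7
        d3 = coding_consequence(
            Variant(chrom="t", pos=114, ref="CCAA", alt="C"), t)
        assert d3.kind == "nonframeshift deletion"
        assert d3.cdna_change == "c.5_7del"
        i = coding_consequence(
            Variant(chrom="t", pos=114, ref="C", alt="CTG"), t)
        assert i.kind == "frameshift insertion"

    def test_cds_reference_mismatch_rejected(self):
        t = _toy_transcript("+")
        with pytest.raises(ReferenceMismatchError):
            coding_consequence(Variant(chrom="t", pos=115, ref="G", alt="T"), t)


class TestCoordinateMapping:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_cds_genomic_roundtrip(self, strand):
        t = _toy_transcript(strand)
        for cds_pos in range(1, t.cds_length + 1):
            g = t.cds_to_genomic(cds_pos)
            assert t.genomic_to_cds(g) == cds_pos


class TestGeneratedTranscripts:
    def test_generated_models_are_well_formed(self):
        reference, transcripts = generate_reference_and_transcripts(seed=3, n_genes=12)
        for t in transcripts:
            assert len(t.cds_sequence) % 3 == 0
            assert t.cds_sequence.startswith("ATG")
            protein = t.protein()
            assert protein.endswith("X") and "X" not in protein[:-1]
            # the genome carries the CDS at the modeled coordinates
            for cds_pos in (1, t.cds_length):
                g = t.cds_to_genomic(cds_pos)
                base = reference.base(t.chrom, g)
                expected = t.cds_sequence[cds_pos - 1]
                if t.strand == "-":
                    expected = str(Seq(expected).reverse_complement())
                assert base == expected

    def test_worked_example_codon_layout(self):
        _, transcripts = generate_reference_and_transcripts(seed=3, n_genes=4)
        csf2rb = next(t for t in transcripts if t.gene_symbol == "CSF2RB")
        assert csf2rb.cds_sequence[687:690] == "AGC"
        assert csf2rb.protein()[229] == "S"

    def test_database_membership_flags(self):
        t = _toy_transcript("+")
        index = TranscriptIndex([t])
        v = Variant(chrom="t", pos=115, ref="C", alt="T")
        databases = {"avsnp150": {("t", 115, "C", "T")}, "COSMIC": set()}
        av = annotate_variant(v, index, databases)
        assert av.memberships == {"avsnp150": True, "COSMIC": False}
        assert av.region == "exonic" and av.genes == ("TOY",)
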