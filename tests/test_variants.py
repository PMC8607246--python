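"""VCF I/O, multi-allelic decomposition, left-normalization and variant keys."""

import subprocess

import numpy as np
import pytest

from somaticfunnel.errors import (
    BoundaryError,
    NormalizationError,
    RecordError,
    ReferenceMismatchError,
    VcfFormatError,
)
from somaticfunnel.variants import (
    CallFilter,
    RawRecord,
    ReferenceSequence,
    Variant,
    left_normalize,
    load_variants,
    read_vcf,
    split_multiallelic,
    variant_key,
    write_vcf,
    write_vcf_records,
)

from conftest import apply_variant, oracle_normalize


class TestReadVcf:
    def test_one_record_per_data_line(self, tmp_path):
        path = tmp_path / "two.vcf"
        records = [
            RawRecord(chrom="1", pos=10, ref="A", alts=("G",)),
            RawRecord(chrom="1", pos=20, ref="C", alts=("A", "T")),
        ]
        write_vcf_records(records, path, {"1": 100})
        back = read_vcf(path, "s")
        assert len(back) == 2
        assert back[1].alts == ("A", "T")

    def test_missing_header_is_format_error(self, tmp_path):
        path = tmp_path / "nohdr.vcf"
        path.write_text("1\t5\t.\tA\tG\t.\t.\t.\n")
        with pytest.raises(VcfFormatError):
            read_vcf(path, "s")

    def test_bad_position_is_record_error(self, tmp_path):
        path = tmp_path / "badpos.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\tXX\t.\tA\tG\t.\t.\t.\n"
        )
        with pytest.raises(RecordError):
            read_vcf(path, "s")

    def test_roundtrip_preserves_alleles_and_qual(self, tmp_path):
        reference = ReferenceSequence({"1": "ACGTACGTACGTACGTACGT"})
        variants = [
            Variant(chrom="1", pos=3, ref="G", alt="A", qual=99.25,
                    total_depth=80, variant_depth=20, call_p=0.001),
            Variant(chrom="1", pos=8, ref="T", alt="C", qual=12.5,
                    total_depth=70, variant_depth=25, call_p=0.005),
        ]
        path = tmp_path / "rt.vcf"
        write_vcf(variants, path, {"1": 20})
        back = load_variants(path, "s", reference, normalize=False)
        assert [(v.chrom, v.pos, v.ref, v.alt) for v in back] == [
            (v.chrom, v.pos, v.ref, v.alt) for v in variants
        ]
        assert back[0].qual == pytest.approx(99.25)
        assert back[1].qual == pytest.approx(12.5)


class TestSplitMultiallelic:
    @pytest.mark.parametrize("alts", [("A",), ("A", "T"), ("A", "AT", "ATT")])
    def test_one_variant_per_alt_order_preserved(self, alts):
        record = RawRecord(chrom="1", pos=100, ref="G", alts=alts,
                           qual=50.0, total_depth=120,
                           variant_depths=tuple(range(20, 20 + len(alts))),
                           call_ps=(0.001,) * len(alts))
        out = split_multiallelic(record)
        assert [v.alt for v in out] == list(alts)
        assert all(v.pos == 100 and v.ref == "G" and v.qual == 50.0 for v in out)
        assert [v.variant_depth for v in out] == list(range(20, 20 + len(alts)))

    def test_allele_count_conserved_over_records(self):
        records = [
            RawRecord(chrom="1", pos=10 * i, ref="G", alts=("A", "T")[: 1 + i % 2])
            for i in range(1, 20)
        ]
        total = sum(len(r.alts) for r in records)
        assert sum(len(split_multiallelic(r)) for r in records) == total

    def test_empty_alts_rejected(self):
        with pytest.raises(RecordError):
            RawRecord(chrom="1", pos=5, ref="A", alts=())


class TestLeftNormalize:
    def test_worked_homopolymer_example(self):
        # deletion of one T from the run in ATTTTC shifts to the anchor A
        reference = ReferenceSequence({"c": "ATTTTC"})
        v = Variant(chrom="c", pos=4, ref="TT", alt="T")
        n = left_normalize(v, reference)
        assert (n.pos, n.ref, n.alt) == (1, "AT", "A")

    def test_snv_is_fixed_point(self, homopolymer_reference):
        v = Variant(chrom="H", pos=10, ref="A", alt="T")
        assert left_normalize(v, homopolymer_reference) is v

    def test_boundary_error_at_position_one(self):
        reference = ReferenceSequence({"c": "TTTTC"})
        with pytest.raises(BoundaryError):
            left_normalize(Variant(chrom="c", pos=1, ref="TT", alt="T"), reference)

    def test_reference_mismatch_rejected(self):
        reference = ReferenceSequence({"c": "ATTTTC"})
        with pytest.raises(ReferenceMismatchError):
            left_normalize(Variant(chrom="c", pos=2, ref="GG", alt="G"), reference)

    def test_agrees_with_string_diff_oracle_on_random_indels(self):
        """>= 1000 random homopolymer indels: the production algorithm and
        the sequence-diff oracle give the identical representation, and
        normalization is idempotent."""
        rng = np.random.default_rng(230)
        n_checked = 0
        while n_checked < 1000:
            # random sequence with an embedded homopolymer run
            length = 60
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
            run_start = int(rng.integers(10, 30))
            run_len = int(rng.integers(3, 9))
            base = "ACGT"[int(rng.integers(0, 4))]
            seq = seq[:run_start] + base * run_len + seq[run_start + run_len :]
            reference = ReferenceSequence({"r": seq})
            # spell an indel somewhere inside/around the run
            pos = int(rng.integers(run_start - 2, run_start + run_len - 1)) + 1
            if pos < 2:
                continue
            size = int(rng.integers(1, 4))
            if pos + size >= length:
                continue
            ref_allele = seq[pos - 1 : pos + size]
            if rng.random() < 0.5:  # deletion spelled with leading context
                ref, alt = ref_allele, ref_allele[0]
            else:  # insertion duplicating downstream bases
                ref, alt = ref_allele[0], ref_allele[0] + seq[pos : pos + size]
            if ref == alt:
                continue
            v = Variant(chrom="r", pos=pos, ref=ref, alt=alt)
            n = left_normalize(v, reference)
            assert apply_variant(seq, n.pos, n.ref, n.alt) == \
                apply_variant(seq, v.pos, v.ref, v.alt)
            assert (n.pos, n.ref, n.alt) == oracle_normalize(seq, v.pos, v.ref, v.alt)
            n2 = left_normalize(n, reference)
            assert (n2.pos, n2.ref, n2.alt) == (n.pos, n.ref, n.alt)
            n_checked += 1

    def test_agrees_with_bcftools_norm(self, tmp_path):
        """Independent oracle: bcftools norm left-aligns a shifted-indel VCF
        to the same representations."""
        seq = "GATTTTTCAAAAGGGGCCTTAGCAGGATCCA" * 3
        reference = ReferenceSequence({"b": seq})
        fasta = tmp_path / "ref.fa"
        reference.to_fasta(fasta)
        variants = [
            Variant(chrom="b", pos=5, ref="TT", alt="T"),
            Variant(chrom="b", pos=10, ref="AA", alt="A"),
            Variant(chrom="b", pos=11, ref="A", alt="AA"),
            Variant(chrom="b", pos=14, ref="GG", alt="G"),
            Variant(chrom="b", pos=36, ref="TT", alt="T"),
            Variant(chrom="b", pos=42, ref="A", alt="AA"),
        ]
        vcf = tmp_path / "in.vcf"
        write_vcf(variants, vcf, {"b": len(seq)})
        out = subprocess.run(
            ["bcftools", "norm", "-f", str(fasta), str(vcf)],
            capture_output=True, text=True, check=True,
        )
        normalized_by_tool = []
        for line in out.stdout.splitlines():
            if line.startswith("#"):
                continue
            chrom, pos, _, ref, alt = line.split("\t")[:5]
            normalized_by_tool.append((chrom, int(pos), ref, alt))
        ours = sorted(
            variant_key(left_normalize(v, reference)) for v in variants
        )
        assert sorted(normalized_by_tool) == ours


class TestVariantKey:
    def test_equivalent_spellings_share_key(self, homopolymer_reference):
        a = Variant(chrom="H", pos=3, ref="TT", alt="T")
        b = Variant(chrom="H", pos=5, ref="TT", alt="T")
        ka = variant_key(left_normalize(a, homopolymer_reference))
        kb = variant_key(left_normalize(b, homopolymer_reference))
        assert ka == kb

    def test_different_alt_different_key(self):
        a = Variant(chrom="1", pos=10, ref="G", alt="A")
        b = Variant(chrom="1", pos=10, ref="G", alt="T")
        assert variant_key(a) != variant_key(b)

    def test_sample_independent(self):
        a = Variant(chrom="1", pos=10, ref="G", alt="A", sample_id="tumor")
        b = Variant(chrom="1", pos=10, ref="G", alt="A", sample_id="normal")
        assert variant_key(a) == variant_key(b)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(NormalizationError):
            variant_key(Variant(chrom="1", pos=10, ref="AT", alt="CT"))


class TestCallFilter:
    def test_gate_thresholds(self):
        gate = CallFilter()
        ok = Variant(chrom="1", pos=1, ref="A", alt="G",
                     total_depth=60, variant_depth=20, call_p=0.001)
        assert gate.passes(ok)
        for field, value in (("total_depth", 50), ("variant_depth", 15),
                             ("call_p", 0.01)):
            bad = Variant(**{**ok.__dict__, field: value})
            assert not gate.passes(bad)

    def test_missing_fields_pass_with_warning(self, caplog):
        gate = CallFilter()
        v = Variant(chrom="1", pos=1, ref="A", alt="G")
        with caplog.at_level("WARNING"):
            assert gate.passes(v)
        assert "missing" in caplog.text

    def test_disabled_gate_passes_everything(self):
        gate = CallFilter(enabled=False)
        v = Variant(chrom="1", pos=1, ref="A", alt="G",
                    total_depth=1, variant_depth=1, call_p=0.5)
        assert gate.passes(v)
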