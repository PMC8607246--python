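"""Germline subtraction, novelty cascade, functional filter, gene
extraction and Cancer Gene Census comparison."""

import pytest

from somaticfunnel.annotation import AnnotatedVariant
from somaticfunnel.errors import ConfigurationError, SomaticFunnelError
from somaticfunnel.funnel import (
    DEFAULT_DB_ORDER,
    FunnelConfig,
    apply_filter_cascade,
    cgc_compare,
    extract_genes,
    subtract_germline,
)
from somaticfunnel.variants import ReferenceSequence, Variant, left_normalize, variant_key


def _snv(pos, ref="A", alt="G", sample="s", chrom="f"):
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, sample_id=sample)


class TestSubtractGermline:
    def test_shared_variant_removed(self):
        tumor = [_snv(10, sample="t"), _snv(20, sample="t")]
        normal = [_snv(20, sample="n")]
        exclusive, n_shared, n_exclusive = subtract_germline(tumor, normal)
        assert [v.pos for v in exclusive] == [10]
        assert (n_shared, n_exclusive) == (1, 1)

    def test_swapped_inputs_detected(self):
        tumor = [_snv(10, sample="x")]
        normal = [_snv(20, sample="x")]
        with pytest.raises(ConfigurationError):
            subtract_germline(tumor, normal)

    def test_differently_spelled_indel_still_subtracts(self):
        """The same deletion spelled right-shifted in the tumor and
        left-aligned in the normal is recognized as shared once both are
        normalized."""
        reference = ReferenceSequence({"f": "GATTTTTCAAAA"})
        tumor_raw = Variant(chrom="f", pos=5, ref="TT", alt="T", sample_id="t")
        normal = Variant(chrom="f", pos=2, ref="AT", alt="A", sample_id="n")
        tumor = left_normalize(tumor_raw, reference)
        assert variant_key(tumor) == variant_key(normal)
        exclusive, n_shared, _ = subtract_germline([tumor], [normal])
        assert exclusive == [] and n_shared == 1


class TestFilterCascade:
    def _dbs(self, **overrides):
        dbs = {name: set() for name in DEFAULT_DB_ORDER}
        dbs.update(overrides)
        return dbs

    def test_empty_databases_are_identity(self):
        variants = [_snv(i * 10) for i in range(1, 6)]
        survivors, counts = apply_filter_cascade(variants, self._dbs())
        assert survivors == variants
        assert all(c == 5 for c in counts.values())

    def test_survivor_counts_monotone_nonincreasing(self):
        variants = [_snv(i * 10) for i in range(1, 8)]
        dbs = self._dbs(
            avsnp150={variant_key(variants[0])},
            COSMIC={variant_key(variants[1]), variant_key(variants[2])},
            gnomAD={variant_key(variants[3])},
        )
        _, counts = apply_filter_cascade(variants, dbs)
        series = [counts[db] for db in DEFAULT_DB_ORDER]
        assert series == sorted(series, reverse=True)
        assert series[0] == 6 and series[-1] == 3

    def test_final_set_independent_of_database_order(self):
        variants = [_snv(i * 10) for i in range(1, 10)]
        dbs = self._dbs(
            avsnp150={variant_key(variants[0])},
            ICGC={variant_key(variants[4])},
            Nci60={variant_key(variants[4]), variant_key(variants[8])},
        )
        base, _ = apply_filter_cascade(variants, dbs)
        reordered = FunnelConfig(novelty_db_order=tuple(reversed(DEFAULT_DB_ORDER)))
        flipped, _ = apply_filter_cascade(variants, dbs, reordered)
        assert {variant_key(v) for v in base} == {variant_key(v) for v in flipped}

    def test_missing_database_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            apply_filter_cascade([_snv(10)], {"avsnp150": set()})


class TestExtractGenes:
    def _annotated(self, pos, genes):
        return AnnotatedVariant(variant=_snv(pos), region="exonic",
                                genes=tuple(genes))

    def test_two_variants_one_gene(self):
        assert extract_genes([self._annotated(1, ["TP53"]),
                              self._annotated(5, ["TP53"])]) == ["TP53"]

    def test_multi_gene_variant_contributes_all_symbols(self):
        assert extract_genes([self._annotated(1, ["A1", "B2"])]) == ["A1", "B2"]

    def test_unannotated_variant_rejected(self):
        with pytest.raises(SomaticFunnelError):
            extract_genes([self._annotated(1, [])])


class TestCgcCompare:
    def test_tier_breakdown_and_percentage(self):
        cgc = {"TP53": 1, "KRAS": 1, "FOO": 2}
        common, n_tier1, n_tier2, pct = cgc_compare(["tp53", "FOO", "OTHER"], cgc)
        assert common == ["FOO", "TP53"]
        assert (n_tier1, n_tier2) == (1, 1)
        assert pct == 50.0

    def test_disjoint_sets_percentage_undefined(self):
        common, n_tier1, _, pct = cgc_compare(["NOPE"], {"TP53": 1})
        assert common == [] and n_tier1 == 0 and pct is None

    def test_all_common_all_tier2(self):
        _, _, _, pct = cgc_compare(["A", "B"], {"A": 2, "B": 2})
        assert pct == 0.0

    def test_empty_cgc_rejected(self):
        with pytest.raises(ConfigurationError):
            cgc_compare(["A"], {})


class TestEndToEndSmallCohort:
    def test_report_matches_planted_profile(self, small_cohort):
        p, r = small_cohort.fixture.profile, small_cohort.report
        assert r.n_tumor_total == p.n_tumor_total
        assert r.n_normal_total == p.n_normal_total
        assert r.n_exclusive == p.n_exclusive
        assert r.n_after_first_db == p.n_in_other_dbs + p.n_novel
        assert r.n_novel == p.n_novel
        assert r.n_exonic == p.n_exonic
        assert r.n_nonsyn_plus == p.n_functional
        assert (r.n_snv, r.n_other) == (p.n_functional_snv, p.n_functional_other)
        assert r.n_genes == p.n_genes
        assert (r.n_cgc_common, r.n_cgc_tier1) == (p.n_cgc_common, p.n_cgc_tier1)
        r.validate()

    def test_tumor_equals_normal_empties_downstream(self, small_cohort, tmp_path):
        from somaticfunnel.funnel import run_funnel

        paths = small_cohort.paths
        report, functional = run_funnel(
            paths["normal_vcf"], paths["normal_vcf"], small_cohort.reference,
            small_cohort.transcripts, small_cohort.databases,
            small_cohort.fixture.cgc,
            tumor_sample="copyA", normal_sample="copyB",
        )
        assert report.n_exclusive == 0
        assert report.n_novel == 0 and functional == []

    def test_planted_functional_set_recovered_exactly(self, small_cohort):
        assert small_cohort.recovered_keys == \
            small_cohort.fixture.planted["novel_functional"]
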