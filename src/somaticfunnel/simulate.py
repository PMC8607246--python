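"""Seeded generators for every input the pipeline consumes.

The central object is the :class:`FunnelProfile`: the stage-by-stage
composition of a tumor/normal exome variant cohort (shared germline calls,
dbSNP-catalogued calls, catalogue-known calls, novel calls split into
non-coding / synonymous / functional SNV / functional indel).  The default
profile realizes the study conditions of the KAIMRC1 breast-cancer
tumor/PBMC pair — 32,917 tumor and 30,939 normal calls funneling down to
983 novel, 491 functional variants in 423 genes — so that running the full
pipeline on a generated cohort must reproduce every printed funnel count
exactly.  All generators are deterministic in their seed.

Fixture genes include a CSF2RB-like transcript (synthetic sequence, real
codon layout: codon 230 = AGC at CDS 688-690 on a 240-codon CDS split over
6 exons) carrying the c.G689T / p.S230I worked example, plus KCNQ3-, NRCAM-
and SCN11A-like transcripts carrying their published coding changes.  Indel
planting is biased into constructed homopolymer runs, with some spellings
deliberately right-shifted, to exercise left-normalization nontrivially.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotation import TranscriptModel, TranscriptIndex, write_transcripts
from .dose_response import _four_pl
from .errors import ProfileError, SomaticFunnelError
from .funnel import DEFAULT_DB_ORDER
from .variants import (
    RawRecord,
    ReferenceSequence,
    Variant,
    VariantKey,
    left_normalize,
    variant_key,
    write_key_table,
    write_vcf_records,
)

log = logging.getLogger(__name__)

#: master seed default; every generator accepts an override
DEFAULT_SEED = 230

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# Profile
# ---------------------------------------------------------------------------

@dataclass
class FunnelProfile:
    """Planted composition of the synthetic tumor/normal cohort."""

    n_tumor_total: int = 32917
    n_normal_total: int = 30939
    n_shared: int = 16700
    n_in_avsnp150: int = 15119
    n_in_other_dbs: int = 115
    n_novel: int = 983
    n_exonic: int = 582
    n_synonymous: int = 91
    n_functional_snv: int = 325
    n_functional_other: int = 166
    n_genes: int = 423
    multi_hit_extra: int = 68
    n_cgc_common: int = 21
    n_cgc_tier1: int = 19
    cgc_total: int = 723

    @property
    def n_exclusive(self) -> int:
        return self.n_tumor_total - self.n_shared

    @property
    def n_normal_exclusive(self) -> int:
        return self.n_normal_total - self.n_shared

    @property
    def n_nonexonic(self) -> int:
        return self.n_novel - self.n_exonic

    @property
    def n_functional(self) -> int:
        return self.n_functional_snv + self.n_functional_other

    def validate(self) -> None:
        checks = [
            ("n_shared <= min(n_tumor_total, n_normal_total)",
             self.n_shared <= min(self.n_tumor_total, self.n_normal_total)),
            ("n_exclusive = n_in_avsnp150 + n_in_other_dbs + n_novel",
             self.n_exclusive == self.n_in_avsnp150 + self.n_in_other_dbs + self.n_novel),
            ("n_exonic <= n_novel", self.n_exonic <= self.n_novel),
            ("n_synonymous + n_functional_snv + n_functional_other = n_exonic",
             self.n_synonymous + self.n_functional_snv + self.n_functional_other
             == self.n_exonic),
            ("n_genes + multi_hit_extra = functional count",
             self.n_genes + self.multi_hit_extra == self.n_functional),
            ("n_functional_snv >= 4 (named fixture variants)",
             self.n_functional_snv >= 4),
            ("n_genes >= 4 + n_cgc_common (named genes excluded from CGC overlap)",
             self.n_genes >= 4 + self.n_cgc_common),
            ("n_cgc_tier1 <= n_cgc_common <= min(n_genes, cgc_total)",
             self.n_cgc_tier1 <= self.n_cgc_common
             <= min(self.n_genes, self.cgc_total)),
            ("all counts nonnegative",
             min(asdict(self).values()) >= 0 and self.n_exclusive >= 0
             and self.n_normal_exclusive >= 0 and self.n_nonexonic >= 0),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ProfileError("profile violates: " + "; ".join(bad))


#: a proportionally scaled-down profile preserving every funnel identity,
#: used where many independent cohorts must be generated quickly
SMALL_PROFILE = FunnelProfile(
    n_tumor_total=1578, n_normal_total=1400, n_shared=800,
    n_in_avsnp150=700, n_in_other_dbs=18, n_novel=60,
    n_exonic=40, n_synonymous=6, n_functional_snv=22, n_functional_other=12,
    n_genes=28, multi_hit_extra=6,
    n_cgc_common=6, n_cgc_tier1=5, cgc_total=80,
)


# ---------------------------------------------------------------------------
# Gene fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _NamedVariant:
    cds_pos: int
    alt: str  # CDS-strand alternate base


@dataclass(frozen=True)
class _NamedGene:
    gene: str
    transcript_id: str
    chrom: str
    n_codons: int
    special_codons: Dict[int, str]
    exon_cds_lens: Tuple[int, ...]
    variant: _NamedVariant


# codon layouts reproduce the published coding changes:
# CSF2RB c.G689T -> AGC(S230) to ATC(I); KCNQ3 c.A293G -> CAA(Q98) to CGA(R);
# NRCAM c.C4G -> CAA(Q2) to GAA(E); SCN11A c.A3253C -> AAA(K1085) to CAA(Q)
NAMED_GENES = (
    _NamedGene("CSF2RB", "NM_000395", "22", 240, {230: "AGC"},
               (120, 120, 120, 120, 120, 120), _NamedVariant(689, "T")),
    _NamedGene("KCNQ3", "NM_001204824", "8", 150, {98: "CAA"},
               (113, 113, 112, 112), _NamedVariant(293, "G")),
    _NamedGene("NRCAM", "NM_005010", "7", 200, {2: "CAA"},
               (150, 150, 150, 150), _NamedVariant(4, "G")),
    _NamedGene("SCN11A", "NM_014139", "3", 1086, {1085: "AAA"},
               (543, 543, 543, 543, 543, 543), _NamedVariant(3253, "C")),
)

_UTR5, _UTR3, _INTRON, _GENE_GAP, _CHROM_PAD = 80, 80, 240, 2400, 2000


def _random_cds(rng: np.random.Generator, n_codons: int,
                special: Dict[int, str]) -> str:
    codons = ["ATG"]
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
    codons += [_SENSE_CODONS[i] for i in idx]
    codons.append("TAA")
    for pos, codon in special.items():
        if not 1 < pos < n_codons:
            raise SomaticFunnelError(f"special codon {pos} out of range")
        codons[pos - 1] = codon
    return "".join(codons)


def _layout_transcript(tid: str, gene: str, chrom: str, strand: str,
                       start: int, cds: str,
                       exon_cds_lens: Sequence[int]) -> TranscriptModel:
    """Place a transcript on the genome at 1-based ``start`` (leftmost base)."""
    assert sum(exon_cds_lens) == len(cds)
    # exon lengths in genomic (left-to-right) order; UTRs sit in terminal exons
    lens = list(exon_cds_lens)
    if strand == "+":
        lens[0] += _UTR5
        lens[-1] += _UTR3
    else:
        lens = lens[::-1]
        lens[0] += _UTR3
        lens[-1] += _UTR5
    exons = []
    cursor = start
    for length in lens:
        exons.append((cursor, cursor + length - 1))
        cursor += length + _INTRON
    tx_start, tx_end = exons[0][0], exons[-1][1]
    if strand == "+":
        cds_start, cds_end = tx_start + _UTR5, tx_end - _UTR3
    else:
        cds_start, cds_end = tx_start + _UTR3, tx_end - _UTR5
    return TranscriptModel(
        transcript_id=tid, gene_symbol=gene, chrom=chrom, strand=strand,
        exons=tuple(exons), cds_start=cds_start, cds_end=cds_end,
        cds_sequence=cds,
    )


def _split_cds(total: int, n_exons: int) -> Tuple[int, ...]:
    base, extra = divmod(total, n_exons)
    return tuple(base + (1 if i < extra else 0) for i in range(n_exons))


def _make_transcripts(n_genes: int, rng: np.random.Generator
                      ) -> Tuple[List[TranscriptModel], Dict[str, int]]:
    """Named fixture genes on their own contigs plus generic genes on "1"."""
    if n_genes < 4:
        raise ProfileError("at least 4 genes required (named fixture genes)")
    transcripts: List[TranscriptModel] = []
    chrom_end: Dict[str, int] = {}
    for ng in NAMED_GENES:
        cds = _random_cds(rng, ng.n_codons, ng.special_codons)
        t = _layout_transcript(ng.transcript_id, ng.gene, ng.chrom, "+",
                               _CHROM_PAD + 1, cds, ng.exon_cds_lens)
        transcripts.append(t)
        chrom_end[ng.chrom] = t.tx_end + _CHROM_PAD
    cursor = _CHROM_PAD + 1
    for i in range(n_genes - 4):
        n_codons = 120 + (i % 7) * 10
        strand = "-" if i % 7 == 3 else "+"
        cds = _random_cds(rng, n_codons, {})
        t = _layout_transcript(f"NM_9{i:05d}", f"GENE{i:04d}", "1", strand,
                               cursor, cds, _split_cds(len(cds), 3))
        transcripts.append(t)
        cursor = t.tx_end + _GENE_GAP
    chrom_end["1"] = cursor + _CHROM_PAD
    return transcripts, chrom_end


class _GenomeBuilder:
    """Mutable per-chromosome byte arrays, 1-based addressing."""

    _BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

    def __init__(self, lengths: Dict[str, int], rng: np.random.Generator):
        self.arrays = {
            chrom: self._BASES[rng.integers(0, 4, size=length)]
            for chrom, length in lengths.items()
        }

    def write(self, chrom: str, pos: int, seq: str) -> None:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        self.arrays[chrom][pos - 1 : pos - 1 + len(arr)] = arr

    def base(self, chrom: str, pos: int) -> str:
        return chr(self.arrays[chrom][pos - 1])

    def carve_homopolymer(self, chrom: str, anchor: int, run: int = 6) -> Tuple[str, str]:
        """Write X Y*run Z at anchor-1..anchor+run with X != Y != Z; returns (X, Y)."""
        y = self.base(chrom, anchor)
        x = _TRANSITION[y]
        z = _TRANSITION[y]
        self.write(chrom, anchor - 1, x + y * run + z if z != y else x + y * run + x)
        return x, y

    def freeze(self) -> ReferenceSequence:
        return ReferenceSequence(
            {chrom: arr.tobytes().decode() for chrom, arr in self.arrays.items()}
        )


def _write_cds_to_genome(builder: _GenomeBuilder, t: TranscriptModel) -> None:
    seq = t.cds_sequence if t.strand == "+" else str(Seq(t.cds_sequence).reverse_complement())
    offset = 0
    for s, e in t._cds_segments:
        builder.write(t.chrom, s, seq[offset : offset + e - s + 1])
        offset += e - s + 1


def generate_reference_and_transcripts(
    seed: int = DEFAULT_SEED, n_genes: int = 423, chrom_length: Optional[int] = None
) -> Tuple[ReferenceSequence, List[TranscriptModel]]:
    """Random reference plus non-overlapping multi-exon transcripts with
    valid ATG..stop CDS, including the CSF2RB-like worked-example model."""
    rng = np.random.default_rng([int(seed), 1])
    transcripts, chrom_end = _make_transcripts(n_genes, rng)
    if chrom_length is not None and chrom_length < max(chrom_end.values()):
        raise SomaticFunnelError(
            f"chrom_length {chrom_length} too short for {n_genes} genes "
            f"(need {max(chrom_end.values())})"
        )
    builder = _GenomeBuilder(chrom_end, np.random.default_rng([int(seed), 2]))
    for t in transcripts:
        _write_cds_to_genome(builder, t)
    return builder.freeze(), transcripts


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortFixture:
    """A complete generated input set plus the planted ground truth."""

    profile: FunnelProfile
    seed: int
    reference: ReferenceSequence
    transcripts: List[TranscriptModel]
    tumor_records: List[RawRecord]
    normal_records: List[RawRecord]
    databases: Dict[str, Set[VariantKey]]
    cgc: Dict[str, int]
    targets: List[Tuple[str, int, int]]  # BED-style 0-based half-open
    contigs: Dict[str, int]
    planted: Dict[str, Set[VariantKey]] = field(default_factory=dict)
    functional_genes: List[str] = field(default_factory=list)
    predictor_calls: List[dict] = field(default_factory=list)

    def transcript_index(self) -> TranscriptIndex:
        return TranscriptIndex(self.transcripts)

    def write(self, out_dir) -> Dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "db").mkdir(exist_ok=True)
        paths = {
            "reference": str(out / "reference.fa"),
            "targets": str(out / "targets.bed"),
            "transcripts_tsv": str(out / "transcripts.tsv"),
            "transcripts_fasta": str(out / "cds.fa"),
            "tumor_vcf": str(out / "tumor.vcf"),
            "normal_vcf": str(out / "normal.vcf"),
            "db_dir": str(out / "db"),
            "cgc": str(out / "cgc.tsv"),
            "predictor_calls": str(out / "predictor_calls.tsv"),
            "manifest": str(out / "manifest.json"),
        }
        self.reference.to_fasta(paths["reference"])
        with open(paths["targets"], "w") as fh:
            for chrom, start, end in self.targets:
                fh.write(f"{chrom}\t{start}\t{end}\n")
        write_transcripts(self.transcripts, paths["transcripts_tsv"],
                          paths["transcripts_fasta"])
        write_vcf_records(self.tumor_records, paths["tumor_vcf"], self.contigs)
        write_vcf_records(self.normal_records, paths["normal_vcf"], self.contigs)
        for name, keys in self.databases.items():
            write_key_table(keys, Path(paths["db_dir"]) / f"{name}.tsv")
        pd.DataFrame(
            [{"gene_symbol": g, "tier": t} for g, t in sorted(self.cgc.items())]
        ).to_csv(paths["cgc"], sep="\t", index=False)
        pd.DataFrame(self.predictor_calls).to_csv(
            paths["predictor_calls"], sep="\t", index=False)
        manifest = {
            "seed": self.seed,
            "profile": asdict(self.profile),
            "paths": {k: str(Path(v).name) for k, v in paths.items()},
            "planted_counts": {k: len(v) for k, v in self.planted.items()},
        }
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return paths


def _passing_metrics(rng: np.random.Generator) -> dict:
    """Caller metrics that pass the default depth/coverage/p gate."""
    return {
        "qual": float(np.round(rng.uniform(50, 3000), 2)),
        "total_depth": int(rng.integers(60, 200)),
        "variant_depth": int(rng.integers(16, 50)),
        "call_p": float(np.round(rng.uniform(1e-6, 9e-3), 8)),
    }


def _snv_alt(ref: str, rng: np.random.Generator) -> str:
    """Alternate base, transition-biased (2:1) as in real exome calls."""
    if rng.random() < 0.66:
        return _TRANSITION[ref]
    choices = [b for b in "ACGT" if b != ref and b != _TRANSITION[ref]]
    return choices[int(rng.integers(0, 2))]


class _CodonAllocator:
    """Hands out non-colliding codon indices per gene for variant planting."""

    def __init__(self, transcripts: Sequence[TranscriptModel],
                 reserved: Dict[str, Set[int]]):
        self._next = {t.transcript_id: 5 for t in transcripts}
        self._max = {t.transcript_id: t.cds_length // 3 - 2 for t in transcripts}
        self._reserved = reserved

    def take(self, t: TranscriptModel) -> int:
        reserved = self._reserved.get(t.transcript_id, set())
        codon = self._next[t.transcript_id]
        while any(abs(codon - r) < 3 for r in reserved):
            codon += 4
        if codon > self._max[t.transcript_id]:
            raise ProfileError(f"{t.transcript_id}: CDS too short for planted variants")
        self._next[t.transcript_id] = codon + 4
        return codon


def generate_cohort(profile: FunnelProfile = None, seed: int = DEFAULT_SEED
                    ) -> CohortFixture:
    """Plant a full cohort so the pipeline reproduces every profile count.

    Tumor calls = shared germline + dbSNP-known + catalogue-known + novel;
    novel calls split into non-coding and exonic with the profile's
    synonymous / functional-SNV / functional-indel composition; functional
    variants cover exactly ``n_genes`` unique genes with ``multi_hit_extra``
    repeat hits; the mock CGC overlaps the gene set in exactly
    ``n_cgc_common`` genes, ``n_cgc_tier1`` of them Tier 1.
    """
    profile = profile or FunnelProfile()
    profile.validate()
    seed = int(seed)

    rng_cds = np.random.default_rng([seed, 1])
    rng_genome = np.random.default_rng([seed, 2])
    rng_alleles = np.random.default_rng([seed, 3])
    rng_metrics = np.random.default_rng([seed, 4])

    transcripts, chrom_end = _make_transcripts(profile.n_genes, rng_cds)
    named_index = {t.gene_symbol: t for t in transcripts[:4]}

    # ---- farm layout on contig "2": one 24-bp slot per background variant
    W = 24
    n_ma = min(150, profile.n_shared // 20)        # multi-allelic shared records
    n_shared_single = profile.n_shared - 2 * n_ma
    n_avsnp_decoys, n_other_decoys = 2000, 100
    slot_counts = [
        ("shared_single", n_shared_single),
        ("shared_multi", n_ma),
        ("avsnp_member", profile.n_in_avsnp150),
        ("otherdb_member", profile.n_in_other_dbs),
        ("normal_excl", profile.n_normal_exclusive),
        ("avsnp_decoy", n_avsnp_decoys),
        ("otherdb_decoy", n_other_decoys * (len(DEFAULT_DB_ORDER) - 1)),
    ]
    farm_start = 101
    slots: Dict[str, List[int]] = {}
    cursor = farm_start
    for name, count in slot_counts:
        slots[name] = [cursor + W * i + 10 for i in range(count)]
        cursor += W * count
    chrom_end["2"] = cursor + W + 100
    contigs = {c: chrom_end[c] for c in ("1", "2", "3", "7", "8", "22")}

    # indel slots (carved homopolymers) among the background categories
    def _is_indel(category: str, i: int) -> bool:
        return {"shared_single": 17, "avsnp_member": 19, "normal_excl": 23}.get(
            category, 0) not in (0,) and i % {"shared_single": 17,
                                              "avsnp_member": 19,
                                              "normal_excl": 23}[category] == 0

    # ---- genome assembly
    builder = _GenomeBuilder(contigs, rng_genome)
    for t in transcripts:
        _write_cds_to_genome(builder, t)
    carved: Dict[Tuple[str, int], Tuple[str, str]] = {}
    for category in ("shared_single", "avsnp_member", "normal_excl"):
        for i, anchor in enumerate(slots[category]):
            if _is_indel(category, i):
                carved[("2", anchor)] = builder.carve_homopolymer("2", anchor)

    # non-exonic novel variants: geometry-driven positions inside gene models
    nonexonic_plan = _plan_nonexonic(profile, transcripts)
    for entry in nonexonic_plan:
        if entry["indel"]:
            carved[(entry["chrom"], entry["pos"])] = builder.carve_homopolymer(
                entry["chrom"], entry["pos"])
    reference = builder.freeze()

    # ---- background (farm) variants
    tumor_records: List[RawRecord] = []
    normal_records: List[RawRecord] = []
    planted: Dict[str, Set[VariantKey]] = {
        "shared": set(), "avsnp150_members": set(), "otherdb_members": set(),
        "normal_exclusive": set(), "novel": set(), "novel_functional": set(),
        "novel_synonymous": set(), "novel_nonexonic": set(),
    }

    def _farm_snv(anchor: int) -> Tuple[Variant, VariantKey]:
        ref = reference.base("2", anchor)
        v = Variant(chrom="2", pos=anchor, ref=ref, alt=_snv_alt(ref, rng_alleles),
                    **_passing_metrics(rng_metrics))
        return v, variant_key(v)

    def _farm_indel(anchor: int, deletion: bool, shifted: bool
                    ) -> Tuple[Variant, VariantKey]:
        """Homopolymer indel at a carved slot; optionally right-shifted."""
        x, y = carved[("2", anchor)]
        canonical = Variant(
            chrom="2", pos=anchor - 1,
            ref=x + y if deletion else x,
            alt=x if deletion else x + y,
            **_passing_metrics(rng_metrics),
        )
        key = variant_key(canonical)
        if not shifted:
            return canonical, key
        shift = 2
        spelled = Variant(
            chrom="2", pos=anchor + shift,
            ref=y + y if deletion else y,
            alt=y if deletion else y + y,
            qual=canonical.qual, total_depth=canonical.total_depth,
            variant_depth=canonical.variant_depth, call_p=canonical.call_p,
        )
        assert variant_key(left_normalize(spelled, reference)) == key
        return spelled, key

    def _to_record(v: Variant, sample: str) -> RawRecord:
        return RawRecord(
            chrom=v.chrom, pos=v.pos, ref=v.ref, alts=(v.alt,), qual=v.qual,
            total_depth=v.total_depth, variant_depths=(v.variant_depth,),
            call_ps=(v.call_p,), sample_id=sample,
        )

    # shared germline: identical keys in both samples; indels sometimes
    # spelled right-shifted in the tumor VCF only
    for i, anchor in enumerate(slots["shared_single"]):
        if _is_indel("shared_single", i):
            deletion = (i // 17) % 2 == 0
            tumor_v, key = _farm_indel(anchor, deletion, shifted=(i % 3 == 0))
            normal_v, _ = _farm_indel(anchor, deletion, shifted=False)
            normal_v = Variant(**{**asdict(normal_v), **_passing_metrics(rng_metrics)})
        else:
            tumor_v, key = _farm_snv(anchor)
            normal_v = Variant(**{**asdict(tumor_v), **_passing_metrics(rng_metrics)})
        planted["shared"].add(key)
        tumor_records.append(_to_record(tumor_v, "tumor"))
        normal_records.append(_to_record(normal_v, "normal"))

    for anchor in slots["shared_multi"]:
        ref = reference.base("2", anchor)
        alts = tuple(b for b in "ACGT" if b != ref)[:2]
        for sample, recs in (("tumor", tumor_records), ("normal", normal_records)):
            m = _passing_metrics(rng_metrics)
            recs.append(RawRecord(
                chrom="2", pos=anchor, ref=ref, alts=alts, qual=m["qual"],
                total_depth=m["total_depth"],
                variant_depths=(m["variant_depth"], m["variant_depth"]),
                call_ps=(m["call_p"], m["call_p"]), sample_id=sample,
            ))
        for alt in alts:
            planted["shared"].add(("2", anchor, ref, alt))

    for i, anchor in enumerate(slots["avsnp_member"]):
        if _is_indel("avsnp_member", i):
            v, key = _farm_indel(anchor, deletion=(i // 19) % 2 == 0,
                                 shifted=(i % 2 == 0))
        else:
            v, key = _farm_snv(anchor)
        planted["avsnp150_members"].add(key)
        tumor_records.append(_to_record(v, "tumor"))

    other_db_names = DEFAULT_DB_ORDER[1:]
    other_members: Dict[str, Set[VariantKey]] = {n: set() for n in other_db_names}
    for j, anchor in enumerate(slots["otherdb_member"]):
        v, key = _farm_snv(anchor)
        planted["otherdb_members"].add(key)
        other_members[other_db_names[j % len(other_db_names)]].add(key)
        tumor_records.append(_to_record(v, "tumor"))

    for i, anchor in enumerate(slots["normal_excl"]):
        if _is_indel("normal_excl", i):
            v, key = _farm_indel(anchor, deletion=True, shifted=False)
        else:
            v, key = _farm_snv(anchor)
        planted["normal_exclusive"].add(key)
        normal_records.append(_to_record(v, "normal"))

    # ---- novel non-exonic variants
    for entry in nonexonic_plan:
        chrom, pos = entry["chrom"], entry["pos"]
        if entry["indel"]:
            x, y = carved[(chrom, pos)]
            raw = Variant(chrom=chrom, pos=pos + 2, ref=y + y, alt=y,
                          **_passing_metrics(rng_metrics))
            v = left_normalize(raw, reference)
            emitted = raw  # right-shifted spelling goes into the VCF
        else:
            ref = reference.base(chrom, pos)
            v = emitted = Variant(chrom=chrom, pos=pos, ref=ref,
                                  alt=_snv_alt(ref, rng_alleles),
                                  **_passing_metrics(rng_metrics))
        key = variant_key(v)
        planted["novel"].add(key)
        planted["novel_nonexonic"].add(key)
        tumor_records.append(_to_record(emitted, "tumor"))

    # ---- novel exonic variants
    allocator = _CodonAllocator(
        transcripts,
        reserved={t.transcript_id: set(ng.special_codons)
                  for t, ng in zip(transcripts[:4], NAMED_GENES)},
    )
    functional_slots = _plan_functional_slots(profile, transcripts)
    named_keys: Dict[str, VariantKey] = {}
    for t, kind in functional_slots:
        if kind == "named":
            ng = next(g for g in NAMED_GENES if g.gene == t.gene_symbol)
            v = _plant_cds_snv(t, ng.variant.cds_pos, ng.variant.alt,
                               reference, rng_metrics)
            named_keys[t.gene_symbol] = variant_key(v)
        elif kind == "snv":
            v = _plant_nonsyn_snv(t, allocator.take(t), reference, rng_metrics)
        else:
            v = _plant_cds_indel(t, allocator.take(t), kind, reference,
                                 rng_alleles, rng_metrics)
        key = variant_key(v)
        planted["novel"].add(key)
        planted["novel_functional"].add(key)
        tumor_records.append(_to_record(v, "tumor"))

    for i in range(profile.n_synonymous):
        t = transcripts[i % profile.n_genes]
        v = _plant_synonymous_snv(t, allocator, reference, rng_metrics)
        key = variant_key(v)
        planted["novel"].add(key)
        planted["novel_synonymous"].add(key)
        tumor_records.append(_to_record(v, "tumor"))

    # ---- databases, CGC, targets, predictor calls
    databases = generate_databases(
        planted, other_members, slots, reference, profile)
    generic = transcripts[4:]
    cgc_common = [t.gene_symbol for t in generic[: profile.n_cgc_common]]
    cgc = {g: (1 if i < profile.n_cgc_tier1 else 2)
           for i, g in enumerate(cgc_common)}
    for i in range(profile.cgc_total - profile.n_cgc_common):
        cgc[f"CGCX{i:04d}"] = 1 if i % 4 else 2
    targets = [(chrom, 0, length) for chrom, length in sorted(contigs.items())]
    predictor_calls = _named_predictor_calls(named_keys)

    fixture = CohortFixture(
        profile=profile, seed=seed, reference=reference, transcripts=transcripts,
        tumor_records=tumor_records, normal_records=normal_records,
        databases=databases, cgc=cgc, targets=targets, contigs=contigs,
        planted=planted,
        functional_genes=sorted({t.gene_symbol for t, _ in functional_slots}),
        predictor_calls=predictor_calls,
    )
    _check_fixture(fixture)
    return fixture


def _plan_nonexonic(profile: FunnelProfile, transcripts: Sequence[TranscriptModel]
                    ) -> List[dict]:
    """Deterministic intronic/splicing/UTR positions, cycled over genes and
    classes; every 6th intronic one becomes a homopolymer indel."""
    classes = ("intronic", "splicing", "UTR5", "UTR3")
    plan = []
    for i in range(profile.n_nonexonic):
        t = transcripts[i % len(transcripts)]
        occ = i // len(transcripts)
        cls = classes[i % 4]
        intron = (t.exons[0][1], t.exons[1][0])  # (prev exon end, next exon start)
        if cls == "intronic":
            pos = (intron[0] + intron[1]) // 2 + occ * 3
            indel = i % 6 == 0
        elif cls == "splicing":
            pos = intron[0] + 2 if occ % 2 == 0 else intron[1] - 2
            pos += 0 if occ < 2 else 0  # one splice slot per intron side
            indel = False
        elif cls == "UTR5":
            pos = (t.cds_start - 10 - occ * 2 if t.strand == "+"
                   else t.cds_end + 10 + occ * 2)
            indel = False
        else:  # UTR3
            pos = (t.cds_end + 10 + occ * 2 if t.strand == "+"
                   else t.cds_start - 10 - occ * 2)
            indel = False
        plan.append({"chrom": t.chrom, "pos": pos, "class": cls, "indel": indel})
    positions = {(p["chrom"], p["pos"]) for p in plan}
    if len(positions) != len(plan):
        raise ProfileError("non-exonic plan produced colliding positions")
    return plan


def _plan_functional_slots(profile: FunnelProfile,
                           transcripts: Sequence[TranscriptModel]
                           ) -> List[Tuple[TranscriptModel, str]]:
    """Assign each functional variant a (gene, kind) slot.

    Every gene gets one variant; ``multi_hit_extra`` genes (generic only)
    get a second (or third).  Indels go to plus-strand generic genes;
    minus-strand genes take SNVs, exercising strand-aware consequences.
    """
    genes = list(transcripts[: profile.n_genes])
    slot_gene_idx = list(range(profile.n_genes))
    for j in range(profile.multi_hit_extra):
        slot_gene_idx.append(4 + j % (profile.n_genes - 4))
    slots: List[Tuple[TranscriptModel, str]] = []
    indel_kinds = itertools.cycle(
        ("frameshift deletion", "nonframeshift deletion",
         "frameshift insertion", "nonframeshift insertion"))
    n_generic_snv = profile.n_functional_snv - 4
    minus_slots = sum(1 for g in slot_gene_idx[4:] if genes[g].strand == "-")
    if minus_slots > n_generic_snv:
        raise ProfileError("not enough SNV slots for minus-strand genes")
    snv_budget = n_generic_snv - minus_slots
    for rank, g in enumerate(slot_gene_idx):
        t = genes[g]
        if rank < 4:
            slots.append((t, "named"))
        elif t.strand == "-":
            slots.append((t, "snv"))
        elif snv_budget > 0:
            slots.append((t, "snv"))
            snv_budget -= 1
        else:
            slots.append((t, next(indel_kinds)))
    n_indels = sum(1 for _, k in slots if k not in ("named", "snv"))
    if n_indels != profile.n_functional_other:
        raise ProfileError(
            f"slot plan yields {n_indels} indels, profile wants "
            f"{profile.n_functional_other}")
    return slots


def _plant_cds_snv(t: TranscriptModel, cds_pos: int, calt: str,
                   reference: ReferenceSequence, rng_metrics) -> Variant:
    gpos = t.cds_to_genomic(cds_pos)
    gref = reference.base(t.chrom, gpos)
    galt = calt if t.strand == "+" else _COMPLEMENT[calt]
    return Variant(chrom=t.chrom, pos=gpos, ref=gref, alt=galt,
                   **_passing_metrics(rng_metrics))


def _plant_nonsyn_snv(t: TranscriptModel, codon_idx: int,
                      reference: ReferenceSequence, rng_metrics) -> Variant:
    codon = t.cds_sequence[3 * (codon_idx - 1) : 3 * codon_idx]
    aa = str(Seq(codon).translate())
    for alt in "ACGT":
        if alt == codon[0]:
            continue
        if str(Seq(alt + codon[1:]).translate()) != aa:
            return _plant_cds_snv(t, 3 * codon_idx - 2, alt, reference, rng_metrics)
    raise SomaticFunnelError(f"no nonsynonymous change at codon {codon_idx} of "
                             f"{t.transcript_id}")


def _plant_synonymous_snv(t: TranscriptModel, allocator: _CodonAllocator,
                          reference: ReferenceSequence, rng_metrics) -> Variant:
    for _ in range(40):
        codon_idx = allocator.take(t)
        codon = t.cds_sequence[3 * (codon_idx - 1) : 3 * codon_idx]
        aa = str(Seq(codon).translate())
        for alt in "ACGT":
            if alt != codon[2] and str(Seq(codon[:2] + alt).translate()) == aa:
                return _plant_cds_snv(t, 3 * codon_idx, alt, reference, rng_metrics)
    raise SomaticFunnelError(f"no synonymous site found in {t.transcript_id}")


def _plant_cds_indel(t: TranscriptModel, codon_idx: int, kind: str,
                     reference: ReferenceSequence, rng_alleles, rng_metrics
                     ) -> Variant:
    assert t.strand == "+", "exonic indels are planted on plus-strand genes"
    anchor = t.cds_to_genomic(3 * codon_idx - 2)
    length = 1 if kind.startswith("frameshift") else 3
    if "deletion" in kind:
        ref = reference.slice(t.chrom, anchor, anchor + length)
        raw = Variant(chrom=t.chrom, pos=anchor, ref=ref, alt=ref[0],
                      **_passing_metrics(rng_metrics))
    else:
        ref = reference.base(t.chrom, anchor)
        ins = "".join("ACGT"[i] for i in rng_alleles.integers(0, 4, size=length))
        raw = Variant(chrom=t.chrom, pos=anchor, ref=ref, alt=ref + ins,
                      **_passing_metrics(rng_metrics))
    return left_normalize(raw, reference)


def generate_databases(
    planted: Dict[str, Set[VariantKey]],
    other_members: Dict[str, Set[VariantKey]],
    slots: Dict[str, List[int]],
    reference: ReferenceSequence,
    profile: FunnelProfile,
) -> Dict[str, Set[VariantKey]]:
    """avsnp150 = planted members + decoys absent from the cohort; the nine
    other catalogues partition the catalogue-known members round-robin."""
    def _decoy(anchor: int) -> VariantKey:
        ref = reference.base("2", anchor)
        return ("2", anchor, ref, _TRANSITION[ref])

    databases = {"avsnp150": set(planted["avsnp150_members"])}
    databases["avsnp150"].update(_decoy(a) for a in slots["avsnp_decoy"])
    decoy_iter = iter(slots["otherdb_decoy"])
    n_decoys_each = len(slots["otherdb_decoy"]) // max(1, len(other_members))
    for name, members in other_members.items():
        keys = set(members)
        keys.update(_decoy(next(decoy_iter)) for _ in range(n_decoys_each))
        databases[name] = keys
    return databases


def _named_predictor_calls(named_keys: Dict[str, VariantKey]) -> List[dict]:
    """Predictor verdicts for the four named variants; the CSF2RB change is
    damaging by all five methods."""
    verdicts = {
        "CSF2RB": ("deleterious", "probably_damaging", "probably_damaging",
                   "disease_causing", "deleterious"),
        "KCNQ3": ("deleterious", "possibly_damaging", "benign",
                  "disease_causing", "neutral"),
        "NRCAM": ("tolerated", "benign", "benign",
                  "polymorphism", "neutral"),
        "SCN11A": ("deleterious", "probably_damaging", "possibly_damaging",
                   "disease_causing", "unknown_call"),
    }
    methods = ("SIFT", "PolyPhen2_HDIV", "PolyPhen2_HVAR",
               "MutationTaster", "PROVEAN")
    rows = []
    for gene, key in sorted(named_keys.items()):
        chrom, pos, ref, alt = key
        for method, verdict in zip(methods, verdicts[gene]):
            rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                         "gene": gene, "method": method, "verdict": verdict,
                         "score": ""})
    return rows


def _check_fixture(fx: CohortFixture) -> None:
    p = fx.profile
    n_tumor = sum(len(r.alts) for r in fx.tumor_records)
    n_normal = sum(len(r.alts) for r in fx.normal_records)
    identities = [
        ("tumor total", n_tumor, p.n_tumor_total),
        ("normal total", n_normal, p.n_normal_total),
        ("shared", len(fx.planted["shared"]), p.n_shared),
        ("novel", len(fx.planted["novel"]), p.n_novel),
        ("functional", len(fx.planted["novel_functional"]), p.n_functional),
        ("unique genes", len(fx.functional_genes), p.n_genes),
    ]
    bad = [f"{name}: built {got}, profile {want}"
           for name, got, want in identities if got != want]
    if bad:
        raise ProfileError("fixture inconsistent with profile: " + "; ".join(bad))


# ---------------------------------------------------------------------------
# QC fixtures
# ---------------------------------------------------------------------------

def titv_fixture() -> List[Variant]:
    """Substitution set with Ti/Tv exactly 2.7: transitions A>G 700, G>A 650,
    C>T 720, T>C 630; 125 of each of the eight transversion types."""
    composition = [("A", "G", 700), ("G", "A", 650), ("C", "T", 720), ("T", "C", 630)]
    composition += [(r, a, 125) for r in "ACGT" for a in "ACGT"
                    if a != r and a != _TRANSITION[r]]
    variants = []
    pos = 1
    for ref, alt, count in composition:
        for _ in range(count):
            variants.append(Variant(chrom="QT", pos=pos, ref=ref, alt=alt))
            pos += 2
    return variants


def dbsnp_conc_fixture(seed: int = DEFAULT_SEED) -> Tuple[List[Variant], Set[VariantKey]]:
    """1,000 SNVs of which exactly 962 are planted in the mock dbSNP
    (plus decoys), giving 96.2% concordance."""
    rng = np.random.default_rng([int(seed), 7])
    variants = []
    for i in range(1000):
        ref = "ACGT"[int(rng.integers(0, 4))]
        variants.append(Variant(chrom="QD", pos=10 * i + 1, ref=ref,
                                alt=_snv_alt(ref, rng)))
    dbsnp = {variant_key(v) for v in variants[:962]}
    for i in range(500):  # decoys at positions no fixture variant occupies
        ref = "ACGT"[int(rng.integers(0, 4))]
        dbsnp.add(("QD", 20001 + 10 * i, ref, _TRANSITION[ref]))
    return variants, dbsnp


# ---------------------------------------------------------------------------
# Pathway (ORA) fixture
# ---------------------------------------------------------------------------

def generate_pathway_db(seed: int = DEFAULT_SEED):
    """ORA fixture: a 13,870-gene universe, a 309-gene query with exactly
    178 in the universe, and a pathway collection in which exactly 695
    pathways are hit by at least one query gene.  Includes small named
    pathways mirroring the study's top hits (sizes 33, 8, 8, 9, 52, 13, 53,
    32, 2, 2)."""
    from .enrichment import Pathway

    rng = np.random.default_rng([int(seed), 8])
    named_query = ["CSF2RB", "KCNQ3", "NRCAM", "SCN11A", "SFTPC"]
    n_in_universe, n_query, n_universe, n_hit = 178, 309, 13870, 695
    query_in = named_query + [f"QGENE{i:04d}" for i in range(n_in_universe - len(named_query))]
    query_out = [f"NOVELG{i:04d}" for i in range(n_query - n_in_universe)]
    query = query_in + query_out
    fillers = [f"RGN{i:05d}" for i in range(n_universe - n_in_universe)]
    universe = set(query_in) | set(fillers)

    named_pathways = [
        ("R-FIX-0001", "Interaction between L1 and ankyrins", 33,
         ["SCN11A", "KCNQ3", "NRCAM"]),
        ("R-FIX-0002", "Defective CSF2RB causes SMDP5", 8, ["SFTPC", "CSF2RB"]),
        ("R-FIX-0003", "Defective CSF2RA causes SMDP4", 8, ["SFTPC", "CSF2RB"]),
        ("R-FIX-0004", "Signaling by FGFR1 amplification mutants", 9, ["QGENE0000"]),
        ("R-FIX-0005", "DAP12 interactions", 52, ["QGENE0001", "QGENE0002"]),
        ("R-FIX-0006", "Folding of actin by CCT/TriC", 13, ["QGENE0003"]),
        ("R-FIX-0007", "Surfactant metabolism", 53, ["SFTPC", "CSF2RB"]),
        ("R-FIX-0008", "HDMs demethylate histones", 32, ["QGENE0004"]),
        ("R-FIX-0009", "Regulation of PAK-2p34 activity", 2, ["QGENE0005"]),
        ("R-FIX-0010", "Defective pro-SFTPC causes SMDP2 and RDS", 2, ["QGENE0006"]),
    ]
    pathways = []
    filler_cursor = 0

    def _fill(n: int) -> List[str]:
        nonlocal filler_cursor
        out = fillers[filler_cursor : filler_cursor + n]
        filler_cursor = (filler_cursor + n) % (len(fillers) - 300)
        return out

    for pid, name, size, members in named_pathways:
        pathways.append(Pathway(pid, name, frozenset(members + _fill(size - len(members)))))
    for i in range(n_hit - len(named_pathways)):
        size = int(rng.integers(5, 120))
        members = [query_in[i % n_in_universe]] + _fill(size - 1)
        pathways.append(Pathway(f"R-HIT-{i:04d}", f"Synthetic pathway {i}",
                                frozenset(members)))
    for i in range(205):  # pathways no query gene touches
        size = int(rng.integers(5, 120))
        pathways.append(Pathway(f"R-MISS-{i:04d}", f"Unhit synthetic pathway {i}",
                                frozenset(_fill(size))))
    return pathways, universe, query


# ---------------------------------------------------------------------------
# Dose-response fixture
# ---------------------------------------------------------------------------

#: half-maximal inhibitory concentration truths, micromolar; the ruxolitinib
#: entry mirrors the screen's strongest kinase-inhibitor hit
RUXOLITINIB_TRUTH = {"ic50_um": 0.94, "hill": -1.0, "top": 100.0, "bottom": 5.0}

# 20 uM -> 6.3 nM: half-log series roughly centered on the fixture IC50,
# which minimizes var(log IC50) among half-log anchors
_HALF_LOG_SERIES = tuple(20.0 / (10 ** (0.5 * i)) for i in range(8))


def generate_dose_response(
    compound_params: Dict[str, Dict[str, float]] = None,
    noise_sd: float = 0.05,
    seed: int = DEFAULT_SEED,
    n_replicates: int = 3,
    n_dmso_wells: int = 6,
    baseline_luminescence: float = 1.0e6,
) -> pd.DataFrame:
    """Long-format plate: 8-point half-log dilution series in triplicate
    with multiplicative Gaussian noise, plus DMSO wells averaging 100%."""
    if noise_sd < 0:
        raise SomaticFunnelError("noise_sd must be nonnegative")
    compound_params = compound_params or {"ruxolitinib": RUXOLITINIB_TRUTH}
    rng = np.random.default_rng([int(seed), 9])
    rows = []
    for compound, pars in sorted(compound_params.items()):
        log_ic50 = np.log10(pars["ic50_um"])
        for conc in _HALF_LOG_SERIES:
            y = _four_pl(np.log10(conc), pars["top"], pars["bottom"],
                         pars["hill"], log_ic50)
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(1.0, noise_sd) if noise_sd > 0 else 1.0
                rows.append({
                    "compound": compound, "concentration_um": conc,
                    "replicate": rep,
                    "luminescence": baseline_luminescence * (y / 100.0) * noise,
                })
    for rep in range(1, n_dmso_wells + 1):
        noise = rng.normal(1.0, noise_sd) if noise_sd > 0 else 1.0
        rows.append({"compound": "DMSO", "concentration_um": 0.0,
                     "replicate": rep,
                     "luminescence": baseline_luminescence * noise})
    return pd.DataFrame(rows)
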