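"""Gene-model annotation: region classification, coding consequences and
database memberships.

Variants are classified against transcript models (exon structure plus a
spliced CDS sequence) with the precedence

    exonic = splicing > UTR5 = UTR3 > intronic > upstream = downstream > intergenic

where "splicing" means within ``SPLICE_WINDOW`` (default 2) bp of an
exon/intron boundary on the intron side and upstream/downstream means
within ``FLANK`` (default 1000) bp of the transcript ends.  Coding
consequences carry c./p. strings in the compact annotator dialect
("c.G689T", "p.S230I"); strict HGVS spellings ("c.689G>T") are emitted
alongside.  Stop codons are written as "X".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .errors import ConfigurationError, RecordError, ReferenceMismatchError, SomaticFunnelError
from .variants import Variant, variant_key

SPLICE_WINDOW = 2  # bp into the intron still called "splicing"
FLANK = 1000       # bp up/downstream of transcript ends

REGION_PRECEDENCE = (
    "exonic", "splicing", "UTR5", "UTR3", "intronic",
    "upstream", "downstream", "intergenic",
)
_REGION_RANK = {
    "exonic": 0, "splicing": 0,
    "UTR5": 1, "UTR3": 1,
    "intronic": 2,
    "upstream": 3, "downstream": 3,
    "intergenic": 4,
}

FUNCTIONAL_KINDS = frozenset({
    "nonsynonymous SNV", "stopgain", "stoploss",
    "frameshift insertion", "frameshift deletion",
    "nonframeshift insertion", "nonframeshift deletion",
})
SNV_KINDS = frozenset({"nonsynonymous SNV", "stopgain", "stoploss", "synonymous SNV"})


class OutsideCdsError(SomaticFunnelError):
    """Variant does not fall inside the transcript's CDS."""


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _translate_codon(codon: str) -> str:
    aa = str(Seq(codon).translate())
    return "X" if aa == "*" else aa


@dataclass
class TranscriptModel:
    """One transcript: genomic exon structure plus its spliced CDS.

    ``exons`` are 1-based inclusive genomic intervals in ascending genomic
    order; ``cds_start``/``cds_end`` are genomic bounds of the coding
    region; ``cds_sequence`` is the spliced CDS 5'->3' in mRNA orientation
    (reverse-complemented relative to the genome for minus-strand models).
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    cds_start: int
    cds_end: int
    cds_sequence: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise RecordError(f"{self.transcript_id}: strand must be + or -")
        prev_end = 0
        for start, end in self.exons:
            if start > end or start <= prev_end:
                raise RecordError(f"{self.transcript_id}: exons must be ordered, non-overlapping")
            prev_end = end
        # genomic CDS segments, ascending
        segs = []
        for start, end in self.exons:
            s, e = max(start, self.cds_start), min(end, self.cds_end)
            if s <= e:
                segs.append((s, e))
        self._cds_segments = segs
        self._cds_len = sum(e - s + 1 for s, e in segs)
        if self._cds_len != len(self.cds_sequence):
            raise RecordError(
                f"{self.transcript_id}: CDS segments span {self._cds_len} bp but "
                f"cds_sequence has {len(self.cds_sequence)}"
            )
        # cumulative plus-strand offsets for fast position mapping
        self._cum = []
        total = 0
        for s, e in segs:
            self._cum.append(total)
            total += e - s + 1

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return self._cds_len

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self._cds_segments)

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """1-based CDS coordinate (mRNA orientation) of genomic ``pos``."""
        for (s, e), cum in zip(self._cds_segments, self._cum):
            if s <= pos <= e:
                plus = cum + (pos - s) + 1
                return plus if self.strand == "+" else self._cds_len - plus + 1
        return None

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Genomic position of 1-based CDS coordinate ``cds_pos``."""
        if not 1 <= cds_pos <= self._cds_len:
            raise OutsideCdsError(f"{self.transcript_id}: CDS position {cds_pos} out of range")
        plus = cds_pos if self.strand == "+" else self._cds_len - cds_pos + 1
        for (s, e), cum in zip(self._cds_segments, self._cum):
            if cum < plus <= cum + (e - s + 1):
                return s + (plus - cum) - 1
        raise AssertionError("unreachable")

    def exon_number(self, pos: int) -> Optional[int]:
        """1-based exon index in transcript (5'->3') orientation."""
        for i, (s, e) in enumerate(self.exons):
            if s <= pos <= e:
                return i + 1 if self.strand == "+" else len(self.exons) - i
        return None

    def protein(self) -> str:
        return "".join(
            _translate_codon(self.cds_sequence[i : i + 3])
            for i in range(0, len(self.cds_sequence) - 2, 3)
        )


@dataclass(frozen=True)
class CodingConsequence:
    kind: str
    cdna_change: str       # compact dialect, e.g. c.G689T
    cdna_change_hgvs: str  # strict spelling, e.g. c.689G>T
    protein_change: str    # e.g. p.S230I
    exon_number: Optional[int]


@dataclass
class AnnotatedVariant:
    variant: Variant
    region: str
    genes: Tuple[str, ...]
    consequences: Tuple[Tuple[str, CodingConsequence], ...] = ()
    memberships: Dict[str, bool] = field(default_factory=dict)

    @property
    def primary_consequence(self) -> Optional[CodingConsequence]:
        return self.consequences[0][1] if self.consequences else None

    @property
    def is_synonymous(self) -> bool:
        """Synonymous only if every overlapping-transcript call is synonymous."""
        return bool(self.consequences) and all(
            c.kind == "synonymous SNV" for _, c in self.consequences
        )


class TranscriptIndex:
    """Chromosome-indexed transcript collection with flank-padded lookup."""

    def __init__(self, transcripts: Iterable[TranscriptModel], flank: int = FLANK):
        self.transcripts = list(transcripts)
        self.flank = flank
        self._trees: Dict[str, IntervalTree] = {}
        for t in self.transcripts:
            tree = self._trees.setdefault(t.chrom, IntervalTree())
            tree.addi(max(0, t.tx_start - flank - 1), t.tx_end + flank, t)

    def overlapping(self, chrom: str, pos: int) -> List[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos - 1)]
        return sorted(hits, key=lambda t: t.transcript_id)

    def by_id(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise ConfigurationError(f"unknown transcript {transcript_id}")

    def __len__(self):
        return len(self.transcripts)


def _region_for_transcript(
    t: TranscriptModel, pos: int, splice_window: int, flank: int
) -> Optional[str]:
    if t.tx_start <= pos <= t.tx_end:
        in_exon = any(s <= pos <= e for s, e in t.exons)
        if in_exon:
            if t.cds_start <= pos <= t.cds_end:
                return "exonic"
            before_cds = pos < t.cds_start
            if t.strand == "+":
                return "UTR5" if before_cds else "UTR3"
            return "UTR3" if before_cds else "UTR5"
        # intronic: distance to nearest exon boundary on the intron side
        dist = min(
            min(abs(pos - e - 1), abs(s - 1 - pos)) + 1
            for (_, e), (s, _) in zip(t.exons, t.exons[1:])
            if e < pos < s
        )
        return "splicing" if dist <= splice_window else "intronic"
    if t.tx_start - flank <= pos < t.tx_start:
        return "upstream" if t.strand == "+" else "downstream"
    if t.tx_end < pos <= t.tx_end + flank:
        return "downstream" if t.strand == "+" else "upstream"
    return None


def classify_region(
    v: Variant,
    transcripts: TranscriptIndex,
    splice_window: int = SPLICE_WINDOW,
    flank: int = FLANK,
) -> Tuple[str, Tuple[str, ...]]:
    """Resolve the region class across all overlapping transcripts.

    The most severe per-transcript class wins; the reported genes are the
    symbols of every transcript achieving the winning class.  Intergenic
    variants report an empty gene tuple.
    """
    per_class: Dict[str, Set[str]] = {}
    for t in transcripts.overlapping(v.chrom, v.pos):
        cls = _region_for_transcript(t, v.pos, splice_window, flank)
        if cls is not None:
            per_class.setdefault(cls, set()).add(t.gene_symbol)
    if not per_class:
        return "intergenic", ()
    best_rank = min(_REGION_RANK[c] for c in per_class)
    for cls in REGION_PRECEDENCE:
        if cls in per_class and _REGION_RANK[cls] == best_rank:
            genes = set().union(
                *(per_class[c] for c in per_class if _REGION_RANK[c] == best_rank)
            )
            return cls, tuple(sorted(genes))
    raise AssertionError("unreachable")


def coding_consequence(v: Variant, t: TranscriptModel) -> CodingConsequence:
    """Consequence of ``v`` on transcript ``t``; requires the variant inside
    the CDS.  Minus-strand alleles are reverse-complemented before mapping."""
    if len(v.ref) == 1 and len(v.alt) == 1:
        return _snv_consequence(v, t)
    if len(v.ref) != len(v.alt) and (v.ref[0] == v.alt[0] or min(len(v.ref), len(v.alt)) == 1):
        return _indel_consequence(v, t)
    raise RecordError(
        f"{v.chrom}:{v.pos} {v.ref}>{v.alt}: unsupported allele shape for consequence calling"
    )


def _snv_consequence(v: Variant, t: TranscriptModel) -> CodingConsequence:
    cds_pos = t.genomic_to_cds(v.pos)
    if cds_pos is None:
        raise OutsideCdsError(f"{v.chrom}:{v.pos} not in CDS of {t.transcript_id}")
    cref = v.ref if t.strand == "+" else _revcomp(v.ref)
    calt = v.alt if t.strand == "+" else _revcomp(v.alt)
    if t.cds_sequence[cds_pos - 1] != cref:
        raise ReferenceMismatchError(
            f"{t.transcript_id} CDS pos {cds_pos}: expected {cref}, "
            f"found {t.cds_sequence[cds_pos - 1]}"
        )
    codon_idx = (cds_pos + 2) // 3
    offset = (cds_pos - 1) % 3
    codon = t.cds_sequence[3 * (codon_idx - 1) : 3 * codon_idx]
    mutated = codon[:offset] + calt + codon[offset + 1 :]
    ref_aa, alt_aa = _translate_codon(codon), _translate_codon(mutated)
    if ref_aa == alt_aa:
        kind = "synonymous SNV"
    elif ref_aa == "X":
        kind = "stoploss"
    elif alt_aa == "X":
        kind = "stopgain"
    else:
        kind = "nonsynonymous SNV"
    return CodingConsequence(
        kind=kind,
        cdna_change=f"c.{cref}{cds_pos}{calt}",
        cdna_change_hgvs=f"c.{cds_pos}{cref}>{calt}",
        protein_change=f"p.{ref_aa}{codon_idx}{alt_aa}",
        exon_number=t.exon_number(v.pos),
    )


def _indel_consequence(v: Variant, t: TranscriptModel) -> CodingConsequence:
    diff = len(v.alt) - len(v.ref)
    frameshift = diff % 3 != 0
    if diff < 0:  # deletion of ref[1:] after the anchor base
        del_start_g, del_end_g = v.pos + len(v.alt), v.pos + len(v.ref) - 1
        c1, c2 = t.genomic_to_cds(del_start_g), t.genomic_to_cds(del_end_g)
        if c1 is None or c2 is None:
            raise OutsideCdsError(
                f"{v.chrom}:{v.pos} deletion not fully in CDS of {t.transcript_id}"
            )
        cstart, cend = min(c1, c2), max(c1, c2)
        kind = "frameshift deletion" if frameshift else "nonframeshift deletion"
        cdna = f"c.{cstart}del" if cstart == cend else f"c.{cstart}_{cend}del"
        aa_start, aa_end = (cstart + 2) // 3, (cend + 2) // 3
        if frameshift:
            ref_aa = _translate_codon(t.cds_sequence[3 * (aa_start - 1) : 3 * aa_start])
            protein = f"p.{ref_aa}{aa_start}fs"
        else:
            protein = f"p.{aa_start}_{aa_end}del"
    else:  # insertion after the anchor base
        c_anchor = t.genomic_to_cds(v.pos)
        if c_anchor is None:
            raise OutsideCdsError(
                f"{v.chrom}:{v.pos} insertion anchor not in CDS of {t.transcript_id}"
            )
        ins = v.alt[len(v.ref):] if v.alt.startswith(v.ref) else v.alt[1:]
        if t.strand == "-":
            ins = _revcomp(ins)
            c_anchor -= 1  # insertion lands 5' of the anchor in mRNA coordinates
        kind = "frameshift insertion" if frameshift else "nonframeshift insertion"
        cdna = f"c.{c_anchor}_{c_anchor + 1}ins{ins}"
        aa_idx = (c_anchor + 2) // 3
        if frameshift:
            ref_aa = _translate_codon(t.cds_sequence[3 * (aa_idx - 1) : 3 * aa_idx])
            protein = f"p.{ref_aa}{aa_idx}fs"
        else:
            protein = f"p.{aa_idx}ins{_translate_codon(ins) if len(ins) == 3 else ''}"
    return CodingConsequence(
        kind=kind,
        cdna_change=cdna,
        cdna_change_hgvs=cdna,
        protein_change=protein,
        exon_number=t.exon_number(v.pos),
    )


def annotate_variant(
    v: Variant,
    transcripts: TranscriptIndex,
    databases: Optional[Dict[str, Set]] = None,
) -> AnnotatedVariant:
    """Full annotation: region + genes + per-transcript consequences + one
    membership flag per configured database (exact normalized-key lookup).

    When a variant is exonic in one transcript and non-coding in another,
    the exonic call wins and only exonic transcripts contribute
    consequences, so multi-transcript loci report a single region class.
    """
    region, genes = classify_region(v, transcripts)
    consequences = []
    if region == "exonic":
        for t in transcripts.overlapping(v.chrom, v.pos):
            if _region_for_transcript(t, v.pos, SPLICE_WINDOW, FLANK) == "exonic":
                try:
                    consequences.append((t.transcript_id, coding_consequence(v, t)))
                except OutsideCdsError:
                    continue
    key = variant_key(v)
    memberships = {name: key in keys for name, keys in (databases or {}).items()}
    return AnnotatedVariant(
        variant=v,
        region=region,
        genes=genes,
        consequences=tuple(consequences),
        memberships=memberships,
    )


# ---------------------------------------------------------------------------
# Transcript model I/O (TSV for structure + FASTA for CDS sequences)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "transcript_id", "gene_symbol", "chrom", "strand",
    "tx_start", "tx_end", "cds_start", "cds_end", "exon_starts", "exon_ends",
]


def write_transcripts(transcripts: Sequence[TranscriptModel], tsv_path, fasta_path) -> None:
    rows = []
    for t in transcripts:
        rows.append({
            "transcript_id": t.transcript_id,
            "gene_symbol": t.gene_symbol,
            "chrom": t.chrom,
            "strand": t.strand,
            "tx_start": t.tx_start,
            "tx_end": t.tx_end,
            "cds_start": t.cds_start,
            "cds_end": t.cds_end,
            "exon_starts": ",".join(str(s) for s, _ in t.exons),
            "exon_ends": ",".join(str(e) for _, e in t.exons),
        })
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(tsv_path, sep="\t", index=False)
    with open(fasta_path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id}\n")
            for i in range(0, len(t.cds_sequence), 70):
                fh.write(t.cds_sequence[i : i + 70] + "\n")


def read_transcripts(tsv_path, fasta_path) -> TranscriptIndex:
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    cds = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    transcripts = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).split(",")]
        ends = [int(x) for x in str(row.exon_ends).split(",")]
        if row.transcript_id not in cds:
            raise ConfigurationError(f"no CDS sequence for {row.transcript_id} in {fasta_path}")
        transcripts.append(
            TranscriptModel(
                transcript_id=row.transcript_id,
                gene_symbol=str(row.gene_symbol).upper(),
                chrom=str(row.chrom),
                strand=row.strand,
                exons=tuple(zip(starts, ends)),
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
                cds_sequence=cds[row.transcript_id],
            )
        )
    return TranscriptIndex(transcripts)


def write_annotated_tsv(annotated: Sequence[AnnotatedVariant], path) -> None:
    """One row per (variant, transcript); membership flags as 0/1 columns."""
    db_names = sorted({name for av in annotated for name in av.memberships})
    rows = []
    for av in annotated:
        v = av.variant
        base = {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "region": av.region, "genes": ",".join(av.genes),
        }
        for name in db_names:
            base[f"in_{name}"] = int(av.memberships.get(name, False))
        if av.consequences:
            for tid, c in av.consequences:
                rows.append({
                    **base, "transcript_id": tid, "kind": c.kind,
                    "cdna_change": c.cdna_change, "protein_change": c.protein_change,
                    "exon_number": c.exon_number,
                })
        else:
            rows.append({**base, "transcript_id": "", "kind": "",
                         "cdna_change": "", "protein_change": "", "exon_number": ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
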