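"""VCF/BED I/O, multi-allelic decomposition, indel left-normalization and
the canonical variant identity key.

The internal coordinate model is VCF-style: 1-based, inclusive, with the
first REF base at ``pos``.  BED input (0-based half-open) is converted on
read.  Every downstream set operation — germline subtraction, database
novelty filtering, dbSNP concordance — compares variants through
:func:`variant_key`, which is only defined on left-normalized alleles, so
two spellings of the same indel always collapse to one identity.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pysam
from Bio import SeqIO
from intervaltree import IntervalTree

from .errors import (
    BoundaryError,
    NormalizationError,
    RecordError,
    ReferenceMismatchError,
    VcfFormatError,
)

log = logging.getLogger(__name__)

VariantKey = Tuple[str, int, str, str]


def _is_plain_allele(allele: str) -> bool:
    """True for simple A/C/G/T strings; symbolic (<DEL>), breakend or
    N-containing alleles are passed through un-normalized and flagged."""
    return bool(allele) and not set(allele) - set("ACGT")


@dataclass(frozen=True)
class Variant:
    """One allele substitution or indel from one sample.

    ``pos`` is the 1-based reference position of the first REF base;
    ``total_depth``/``variant_depth``/``call_p`` carry the caller metrics
    used by the depth/coverage/p quality gate.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: Optional[float] = None
    total_depth: Optional[int] = None
    variant_depth: Optional[int] = None
    call_p: Optional[float] = None
    sample_id: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise RecordError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise RecordError("ref and alt must be nonempty")
        if self.ref == self.alt:
            raise RecordError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.ref != self.ref.upper() or self.alt != self.alt.upper():
            raise RecordError("alleles must be uppercase")
        if self.qual is not None and self.qual < 0:
            raise RecordError("qual must be nonnegative")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and self.is_plain

    @property
    def is_plain(self) -> bool:
        return _is_plain_allele(self.ref) and _is_plain_allele(self.alt)

    @property
    def variant_type(self) -> str:
        """One of SNV / insertion / deletion / MNV / other."""
        if not self.is_plain:
            return "other"
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.ref) < len(self.alt):
            return "insertion"
        if len(self.ref) > len(self.alt):
            return "deletion"
        return "MNV"


@dataclass(frozen=True)
class RawRecord:
    """One VCF data line, possibly multi-allelic."""

    chrom: str
    pos: int
    ref: str
    alts: Tuple[str, ...]
    qual: Optional[float] = None
    total_depth: Optional[int] = None
    variant_depths: Tuple[Optional[int], ...] = ()
    call_ps: Tuple[Optional[float], ...] = ()
    sample_id: str = ""

    def __post_init__(self):
        if not self.alts:
            raise RecordError(f"record at {self.chrom}:{self.pos} has no ALT alleles")


class ReferenceSequence:
    """Per-chromosome base strings with 1-based addressing."""

    def __init__(self, sequences: Dict[str, str]):
        self._seqs = {c: s.upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "ReferenceSequence":
        with _maybe_gzip(path) as handle:
            return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")})

    def chroms(self) -> List[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def base(self, chrom: str, pos: int) -> str:
        """Single base at 1-based ``pos``."""
        return self._seqs[chrom][pos - 1]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Bases ``start..end`` inclusive, 1-based."""
        return self._seqs[chrom][start - 1 : end]

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self._seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


class TargetRegions:
    """Capture-target intervals; built from BED (0-based half-open)."""

    def __init__(self, intervals: Iterable[Tuple[str, int, int]]):
        self._trees: Dict[str, IntervalTree] = {}
        self.n_intervals = 0
        for chrom, start, end in intervals:
            if start >= end:
                raise RecordError(f"BED interval {chrom}:{start}-{end} has start >= end")
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
            self.n_intervals += 1

    @classmethod
    def from_bed(cls, path) -> "TargetRegions":
        intervals = []
        with _maybe_gzip(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                intervals.append((parts[0], int(parts[1]), int(parts[2])))
        return cls(intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        """True if 1-based ``pos`` falls inside any interval."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps(pos - 1))

    def __len__(self) -> int:
        return self.n_intervals


@dataclass(frozen=True)
class CallFilter:
    """Quality gate on caller metrics applied at load time.

    Defaults keep calls with average total coverage > 50, variant-supporting
    coverage > 15 and caller p < 0.01; records missing any field pass with a
    logged warning (synthetic fixtures may omit them).
    """

    min_total_depth: int = 50
    min_variant_depth: int = 15
    max_call_p: float = 0.01
    enabled: bool = True

    def passes(self, v: Variant) -> bool:
        if not self.enabled:
            return True
        missing = [
            name
            for name, val in (
                ("total_depth", v.total_depth),
                ("variant_depth", v.variant_depth),
                ("call_p", v.call_p),
            )
            if val is None
        ]
        if missing:
            log.warning(
                "variant %s:%d %s>%s missing %s; passing gate",
                v.chrom, v.pos, v.ref, v.alt, ",".join(missing),
            )
            return True
        return (
            v.total_depth > self.min_total_depth
            and v.variant_depth > self.min_variant_depth
            and v.call_p < self.max_call_p
        )


DEFAULT_CALL_FILTER = CallFilter()


def _maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path, sample_id: str) -> List[RawRecord]:
    """Read a VCF (plain or gzipped) into :class:`RawRecord` objects.

    Depth metrics are taken from INFO fields ``DP`` (total depth), ``VD``
    (per-alt supporting depth, Number=A) and ``PV`` (per-alt caller
    p-value, Number=A) when present.
    """
    _require_vcf_header(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:  # malformed header etc.
        raise VcfFormatError(f"{path}: {exc}") from exc
    records = []
    with vf:
        iterator = iter(vf)
        i = 0
        while True:
            i += 1
            try:
                rec = next(iterator)
            except StopIteration:
                break
            except (ValueError, OSError) as exc:  # htslib parse failure
                raise RecordError(f"{path}: record {i}: {exc}") from exc
            try:
                records.append(_to_raw_record(rec, sample_id))
            except (ValueError, TypeError) as exc:
                raise RecordError(f"{path}: record {i}: {exc}") from exc
    return records


def _require_vcf_header(path) -> None:
    with _maybe_gzip(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                return
            raise VcfFormatError(f"{path}: no #CHROM header line before data")
    raise VcfFormatError(f"{path}: empty file, no #CHROM header")


def _to_raw_record(rec, sample_id: str) -> RawRecord:
    alts = tuple(a for a in (rec.alts or ()))
    if not alts:
        raise ValueError("record has no ALT")
    n = len(alts)
    dp = rec.info.get("DP")
    vd = rec.info.get("VD")
    pv = rec.info.get("PV")
    vd = tuple(vd) if vd is not None else (None,) * n
    pv = tuple(pv) if pv is not None else (None,) * n
    return RawRecord(
        chrom=rec.chrom,
        pos=rec.pos,
        ref=rec.ref.upper(),
        alts=tuple(a.upper() for a in alts),
        qual=rec.qual,
        total_depth=int(dp) if dp is not None else None,
        variant_depths=tuple(int(x) if x is not None else None for x in vd),
        call_ps=tuple(float(x) if x is not None else None for x in pv),
        sample_id=sample_id,
    )


def _vcf_header(contigs: Dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##source=somaticfunnel')
    for chrom, length in contigs.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">')
    header.add_line('##INFO=<ID=VD,Number=A,Type=Integer,Description="Reads supporting ALT">')
    header.add_line('##INFO=<ID=PV,Number=A,Type=Float,Description="Caller p-value per ALT">')
    return header


def write_vcf_records(records: Sequence[RawRecord], path, contigs: Dict[str, int]) -> None:
    """Write records (sorted by chrom order given in ``contigs``, then pos)."""
    header = _vcf_header(contigs)
    order = {c: i for i, c in enumerate(contigs)}
    recs = sorted(records, key=lambda r: (order.get(r.chrom, len(order)), r.pos, r.ref, r.alts))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in recs:
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                stop=r.pos - 1 + len(r.ref),
                alleles=(r.ref,) + r.alts,
            )
            if r.qual is not None:
                rec.qual = r.qual
            if r.total_depth is not None:
                rec.info["DP"] = r.total_depth
            if any(x is not None for x in r.variant_depths):
                rec.info["VD"] = tuple(int(x) for x in r.variant_depths)
            if any(x is not None for x in r.call_ps):
                rec.info["PV"] = tuple(float(x) for x in r.call_ps)
            out.write(rec)


def variants_to_records(variants: Iterable[Variant]) -> List[RawRecord]:
    return [
        RawRecord(
            chrom=v.chrom, pos=v.pos, ref=v.ref, alts=(v.alt,), qual=v.qual,
            total_depth=v.total_depth,
            variant_depths=(v.variant_depth,),
            call_ps=(v.call_p,),
            sample_id=v.sample_id,
        )
        for v in variants
    ]


def write_vcf(variants: Sequence[Variant], path, contigs: Dict[str, int]) -> None:
    """Write one Variant per line (already-split representation)."""
    write_vcf_records(variants_to_records(variants), path, contigs)


# ---------------------------------------------------------------------------
# Decomposition and normalization
# ---------------------------------------------------------------------------

def split_multiallelic(record: RawRecord) -> List[Variant]:
    """Decompose a multi-allelic record into one :class:`Variant` per ALT,
    preserving ALT order; shared fields are copied to every output."""
    out = []
    for i, alt in enumerate(record.alts):
        vd = record.variant_depths[i] if i < len(record.variant_depths) else None
        pv = record.call_ps[i] if i < len(record.call_ps) else None
        out.append(
            Variant(
                chrom=record.chrom, pos=record.pos, ref=record.ref, alt=alt,
                qual=record.qual, total_depth=record.total_depth,
                variant_depth=vd, call_p=pv, sample_id=record.sample_id,
            )
        )
    return out


def left_normalize(v: Variant, ref_seq: ReferenceSequence) -> Variant:
    """Return the unique left-aligned, parsimonious representation of ``v``.

    Trailing bases shared by REF and ALT are truncated; when either allele
    empties, both are extended one reference base to the left.  Then shared
    leading bases are trimmed while both alleles keep length >= 2.  SNVs are
    fixed points; the operation is idempotent.  Symbolic or N-containing
    alleles are returned unchanged.
    """
    if not v.is_plain:
        log.warning("not normalizing symbolic/N allele %s:%d %s>%s",
                    v.chrom, v.pos, v.ref, v.alt)
        return v
    observed = ref_seq.slice(v.chrom, v.pos, v.pos + len(v.ref) - 1)
    if observed != v.ref:
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos} REF {v.ref!r} does not match reference {observed!r}"
        )
    pos, ref, alt = v.pos, v.ref, v.alt
    # (a) truncate shared trailing bases, extending left on emptying
    while len(ref) >= 1 and len(alt) >= 1 and ref[-1] == alt[-1] \
            and not (len(ref) == 1 and len(alt) == 1):
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos == 1:
                raise BoundaryError(
                    f"{v.chrom}:{v.pos} {v.ref}>{v.alt}: left extension past position 1"
                )
            pad = ref_seq.base(v.chrom, pos - 1)
            ref, alt, pos = pad + ref, pad + alt, pos - 1
    # (b) trim shared leading bases while both alleles stay nonempty after
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    if (pos, ref, alt) == (v.pos, v.ref, v.alt):
        return v
    return replace(v, pos=pos, ref=ref, alt=alt)


def is_normalized(v: Variant) -> bool:
    """Cheap necessary check: no shared trailing base unless both are len-1,
    and no shared leading base when both have length >= 2."""
    if not v.is_plain:
        return True
    if v.ref[-1] == v.alt[-1] and not (len(v.ref) == 1 and len(v.alt) == 1):
        return False
    if len(v.ref) >= 2 and len(v.alt) >= 2 and v.ref[0] == v.alt[0]:
        return False
    return True


def variant_key(v: Variant) -> VariantKey:
    """Canonical identity ``(chrom, pos, ref, alt)``; sample and genotype
    fields are deliberately excluded.  Requires a left-normalized input."""
    if not is_normalized(v):
        raise NormalizationError(
            f"{v.chrom}:{v.pos} {v.ref}>{v.alt} is not left-normalized"
        )
    return (v.chrom, v.pos, v.ref, v.alt)


def load_variants(
    path,
    sample_id: str,
    reference: ReferenceSequence,
    gate: CallFilter = DEFAULT_CALL_FILTER,
    normalize: bool = True,
) -> List[Variant]:
    """Read, decompose, quality-gate and left-normalize a VCF in one step."""
    variants: List[Variant] = []
    for record in read_vcf(path, sample_id):
        for v in split_multiallelic(record):
            if not gate.passes(v):
                continue
            variants.append(left_normalize(v, reference) if normalize else v)
    return variants


def key_set(variants: Iterable[Variant]) -> set:
    return {variant_key(v) for v in variants}


# ---------------------------------------------------------------------------
# Database key tables (TSV of chrom/pos/ref/alt)
# ---------------------------------------------------------------------------

def read_key_table(path) -> set:
    """Read a variant-key membership table (TSV with header chrom pos ref alt)."""
    keys = set()
    with _maybe_gzip(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom"):
            raise VcfFormatError(f"{path}: expected 'chrom pos ref alt' header")
        for line in fh:
            if not line.strip():
                continue
            chrom, pos, ref, alt = line.rstrip("\n").split("\t")[:4]
            keys.add((chrom, int(pos), ref, alt))
    return keys


def write_key_table(keys: Iterable[VariantKey], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in sorted(keys):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")
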