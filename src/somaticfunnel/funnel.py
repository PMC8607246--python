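"""The somatic-novel-variant funnel: germline subtraction, ordered
database-novelty filtering, functional classification, gene extraction and
Cancer Gene Census comparison, with the count after every stage recorded.

Germline subtraction is set-algebraic (no allele-frequency model): tumor
calls whose normalized key also appears in the matched-normal call set are
treated as inherited and removed.  "Passing" a novelty database means being
absent from it, so the cascade retains only variants found in none of the
configured catalogues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .annotation import (
    FUNCTIONAL_KINDS,
    SNV_KINDS,
    AnnotatedVariant,
    TranscriptIndex,
    annotate_variant,
)
from .errors import ConfigurationError, SomaticFunnelError, StageError
from .qc import QCReport, compute_qc
from .variants import (
    CallFilter,
    ReferenceSequence,
    TargetRegions,
    Variant,
    load_variants,
    read_key_table,
    variant_key,
)

log = logging.getLogger(__name__)

DEFAULT_DB_ORDER = (
    "avsnp150", "COSMIC", "ExAC_ALL", "GME", "esp",
    "gnomAD", "clinvar", "ICGC", "Nci60", "1000g",
)


@dataclass
class FunnelConfig:
    novelty_db_order: Tuple[str, ...] = DEFAULT_DB_ORDER
    functional_kinds_kept: frozenset = FUNCTIONAL_KINDS
    call_filter: CallFilter = field(default_factory=CallFilter)

    def __post_init__(self):
        if "synonymous SNV" in self.functional_kinds_kept:
            raise ConfigurationError("synonymous SNV cannot be a kept functional kind")


@dataclass
class FunnelReport:
    n_tumor_total: int = 0
    n_normal_total: int = 0
    n_shared: int = 0
    n_exclusive: int = 0
    per_database_survivors: Dict[str, int] = field(default_factory=dict)
    n_after_first_db: int = 0
    n_novel: int = 0
    n_exonic: int = 0
    n_synonymous: int = 0
    n_nonsyn_plus: int = 0
    n_snv: int = 0
    n_other: int = 0
    n_genes: int = 0
    n_cgc_common: int = 0
    n_cgc_tier1: int = 0
    cgc_tier1_pct: Optional[float] = None
    qc_tumor: Optional[QCReport] = None
    qc_normal: Optional[QCReport] = None

    def validate(self) -> None:
        checks = [
            ("n_exclusive = n_tumor_total - n_shared",
             self.n_exclusive == self.n_tumor_total - self.n_shared),
            ("n_nonsyn_plus = n_exonic - n_synonymous",
             self.n_nonsyn_plus == self.n_exonic - self.n_synonymous),
            ("n_snv + n_other = n_nonsyn_plus",
             self.n_snv + self.n_other == self.n_nonsyn_plus),
            ("n_cgc_tier1 <= n_cgc_common <= n_genes",
             self.n_cgc_tier1 <= self.n_cgc_common <= self.n_genes),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise SomaticFunnelError("FunnelReport inconsistent: " + "; ".join(bad))

    def to_tsv(self) -> str:
        rows = [
            ("n_tumor_total", self.n_tumor_total),
            ("n_normal_total", self.n_normal_total),
            ("n_shared", self.n_shared),
            ("n_exclusive", self.n_exclusive),
        ]
        rows += [(f"survivors_after_{db}", n) for db, n in self.per_database_survivors.items()]
        rows += [
            ("n_novel", self.n_novel),
            ("n_exonic", self.n_exonic),
            ("n_synonymous", self.n_synonymous),
            ("n_functional", self.n_nonsyn_plus),
            ("n_functional_snv", self.n_snv),
            ("n_functional_other", self.n_other),
            ("n_genes", self.n_genes),
            ("n_cgc_common", self.n_cgc_common),
            ("n_cgc_tier1", self.n_cgc_tier1),
            ("cgc_tier1_pct", "NA" if self.cgc_tier1_pct is None else self.cgc_tier1_pct),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"

    def summary(self) -> str:
        lines = [
            "Somatic novel-variant funnel",
            f"  tumor calls               {self.n_tumor_total:>8}",
            f"  normal calls              {self.n_normal_total:>8}",
            f"  shared (germline, removed){self.n_shared:>8}",
            f"  tumor-exclusive           {self.n_exclusive:>8}",
        ]
        for db, n in self.per_database_survivors.items():
            lines.append(f"  after {db:<19} {n:>8}")
        lines += [
            f"  novel                     {self.n_novel:>8}",
            f"  exonic                    {self.n_exonic:>8}",
            f"  synonymous (dropped)      {self.n_synonymous:>8}",
            f"  functional                {self.n_nonsyn_plus:>8}"
            f"  ({self.n_snv} SNVs + {self.n_other} others)",
            f"  unique genes              {self.n_genes:>8}",
            f"  in Cancer Gene Census     {self.n_cgc_common:>8}"
            f"  ({self.n_cgc_tier1} Tier 1"
            + (f" = {self.cgc_tier1_pct}%" if self.cgc_tier1_pct is not None else "")
            + ")",
        ]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def subtract_germline(
    tumor_variants: Sequence[Variant], normal_variants: Sequence[Variant]
) -> Tuple[List[Variant], int, int]:
    """Remove tumor calls whose key occurs in the matched normal.

    Returns (tumor-exclusive variants, n_shared, n_exclusive).  Refuses to
    run when the two inputs carry the same sample label on both sides, a
    symptom of swapped arguments.
    """
    tumor_samples = {v.sample_id for v in tumor_variants if v.sample_id}
    normal_samples = {v.sample_id for v in normal_variants if v.sample_id}
    if tumor_samples and tumor_samples == normal_samples:
        raise ConfigurationError(
            f"tumor and normal inputs carry identical sample ids {tumor_samples}; "
            "inputs swapped or mislabeled?"
        )
    normal_keys = {variant_key(v) for v in normal_variants}
    exclusive = [v for v in tumor_variants if variant_key(v) not in normal_keys]
    n_shared = len(tumor_variants) - len(exclusive)
    return exclusive, n_shared, len(exclusive)


def apply_filter_cascade(
    variants: Sequence[Variant],
    databases: Dict[str, Set],
    config: FunnelConfig = None,
) -> Tuple[List[Variant], Dict[str, int]]:
    """Sequentially remove variants present in each catalogue, in the
    configured order, recording the survivor count after every stage."""
    config = config or FunnelConfig()
    missing = [db for db in config.novelty_db_order if db not in databases]
    if missing:
        raise ConfigurationError(f"missing novelty databases: {missing}")
    survivors = list(variants)
    counts: Dict[str, int] = {}
    for db in config.novelty_db_order:
        keys = databases[db]
        survivors = [v for v in survivors if variant_key(v) not in keys]
        counts[db] = len(survivors)
    return survivors, counts


def classify_and_filter_functional(
    novel_variants: Sequence[Variant],
    transcripts: TranscriptIndex,
    config: FunnelConfig = None,
    databases: Optional[Dict[str, Set]] = None,
) -> Tuple[List[AnnotatedVariant], Dict[str, int]]:
    """Annotate regions, keep exonic variants, drop synonymous SNVs and
    split the retained functional set into SNVs vs indels."""
    config = config or FunnelConfig()
    annotated = [annotate_variant(v, transcripts, databases) for v in novel_variants]
    exonic = [av for av in annotated if av.region == "exonic"]
    synonymous = [av for av in exonic if av.is_synonymous]
    functional = [av for av in exonic if not av.is_synonymous]
    n_snv = sum(
        1 for av in functional
        if av.primary_consequence and av.primary_consequence.kind in SNV_KINDS
    )
    counts = {
        "n_exonic": len(exonic),
        "n_synonymous": len(synonymous),
        "n_functional": len(functional),
        "n_snv": n_snv,
        "n_other": len(functional) - n_snv,
    }
    return functional, counts


def extract_genes(functional_variants: Sequence[AnnotatedVariant]) -> List[str]:
    """Union of gene symbols over annotated variants (multi-gene variants
    contribute every symbol), sorted for determinism."""
    genes: Set[str] = set()
    for av in functional_variants:
        if not av.genes:
            raise SomaticFunnelError(
                f"variant {av.variant.chrom}:{av.variant.pos} has no gene annotation"
            )
        genes.update(av.genes)
    return sorted(genes)


def read_cgc(path) -> Dict[str, int]:
    """Cancer Gene Census table: gene_symbol TAB tier (1 or 2)."""
    df = pd.read_csv(path, sep="\t")
    cgc: Dict[str, int] = {}
    for row in df.itertuples(index=False):
        tier = int(row.tier)
        if tier not in (1, 2):
            raise ConfigurationError(f"CGC tier must be 1 or 2, got {tier}")
        cgc[str(row.gene_symbol).upper()] = tier
    return cgc


def cgc_compare(
    genes: Iterable[str], cgc: Dict[str, int]
) -> Tuple[List[str], int, int, Optional[float]]:
    """Intersect a gene list with the CGC; returns (common genes sorted,
    n_tier1, n_tier2, tier-1 percentage rounded to 1 decimal)."""
    if not cgc:
        raise ConfigurationError("empty CGC table")
    common = sorted({g.upper() for g in genes} & set(cgc))
    n_tier1 = sum(1 for g in common if cgc[g] == 1)
    n_tier2 = len(common) - n_tier1
    pct = round(100.0 * n_tier1 / len(common), 1) if common else None
    return common, n_tier1, n_tier2, pct


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def load_databases(db_dir, names: Iterable[str]) -> Dict[str, Set]:
    db_dir = Path(db_dir)
    databases = {}
    for name in names:
        path = db_dir / f"{name}.tsv"
        if not path.exists():
            raise ConfigurationError(f"database table not found: {path}")
        databases[name] = read_key_table(path)
    return databases


def run_funnel(
    tumor_vcf,
    normal_vcf,
    reference: ReferenceSequence,
    transcripts: TranscriptIndex,
    databases: Dict[str, Set],
    cgc: Dict[str, int],
    targets: Optional[TargetRegions] = None,
    dbsnp_keys: Optional[Set] = None,
    config: FunnelConfig = None,
    tumor_sample: str = "tumor",
    normal_sample: str = "normal",
) -> Tuple[FunnelReport, List[AnnotatedVariant]]:
    """Run the whole cascade and return the report plus the annotated novel
    functional variants.  Any stage failure is re-raised tagged with the
    stage name."""
    config = config or FunnelConfig()
    dbsnp = dbsnp_keys if dbsnp_keys is not None else databases.get(
        config.novelty_db_order[0], set()
    )

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except SomaticFunnelError as exc:
            raise StageError(name, str(exc)) from exc

    tumor = stage("load-tumor", load_variants, tumor_vcf, tumor_sample,
                  reference, gate=config.call_filter)
    normal = stage("load-normal", load_variants, normal_vcf, normal_sample,
                   reference, gate=config.call_filter)
    report = FunnelReport(n_tumor_total=len(tumor), n_normal_total=len(normal))
    report.qc_tumor = stage("qc", compute_qc, tumor, dbsnp, targets)
    report.qc_normal = stage("qc", compute_qc, normal, dbsnp, targets)

    exclusive, report.n_shared, report.n_exclusive = stage(
        "subtract-germline", subtract_germline, tumor, normal)
    novel, per_db = stage("novelty-cascade", apply_filter_cascade,
                          exclusive, databases, config)
    report.per_database_survivors = per_db
    report.n_after_first_db = per_db[config.novelty_db_order[0]]
    report.n_novel = len(novel)

    functional, counts = stage("functional-filter", classify_and_filter_functional,
                               novel, transcripts, config, databases)
    report.n_exonic = counts["n_exonic"]
    report.n_synonymous = counts["n_synonymous"]
    report.n_nonsyn_plus = counts["n_functional"]
    report.n_snv = counts["n_snv"]
    report.n_other = counts["n_other"]

    genes = stage("extract-genes", extract_genes, functional)
    report.n_genes = len(genes)
    common, n_tier1, _, pct = stage("cgc-compare", cgc_compare, genes, cgc)
    report.n_cgc_common = len(common)
    report.n_cgc_tier1 = n_tier1
    report.cgc_tier1_pct = pct
    report.validate()
    return report, functional
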