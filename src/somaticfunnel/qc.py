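"""Exome call-set QC: off-target counting, Ti/Tv, dbSNP concordance and
variant-type proportions.

Ti/Tv is computed over SNVs only (transitions A<->G and C<->T; the eight
other substitutions are transversions); in capture exomes a ratio near
2.5-3 indicates a clean call set.  Concordance is the percentage of all
loaded variants (not only SNVs) whose normalized key is present in a
known-polymorphism catalogue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Set

from .variants import TargetRegions, Variant, variant_key

log = logging.getLogger(__name__)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

_TYPE_CLASSES = ("SNV", "insertion", "deletion", "MNV")


@dataclass
class QCReport:
    n_variants: int
    n_off_target: int
    n_transitions: int
    n_transversions: int
    titv: Optional[float]  # None when transversions == 0 (undefined, not inf)
    dbsnp_concordance: Optional[float]  # percent 0-100; None when no variants
    type_counts: Dict[str, int] = field(default_factory=dict)

    def to_tsv(self) -> str:
        rows = [
            ("n_variants", self.n_variants),
            ("n_off_target", self.n_off_target),
            ("n_transitions", self.n_transitions),
            ("n_transversions", self.n_transversions),
            ("titv", "NA" if self.titv is None else f"{self.titv:.6g}"),
            ("dbsnp_concordance_pct",
             "NA" if self.dbsnp_concordance is None else f"{self.dbsnp_concordance:.6g}"),
        ]
        rows += [(f"n_{cls}", self.type_counts.get(cls, 0)) for cls in _TYPE_CLASSES]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"

    def summary(self) -> str:
        titv = "undefined" if self.titv is None else f"{self.titv:.3g}"
        conc = "undefined" if self.dbsnp_concordance is None else f"{self.dbsnp_concordance:.1f}%"
        lines = [
            f"Variants loaded        : {self.n_variants}",
            f"Off-target variants    : {self.n_off_target}",
            f"Ti/Tv ratio            : {titv} "
            f"({self.n_transitions} Ti / {self.n_transversions} Tv)",
            f"dbSNP concordance      : {conc}",
            "Variant types          : "
            + ", ".join(f"{cls}={self.type_counts.get(cls, 0)}" for cls in _TYPE_CLASSES),
        ]
        return "\n".join(lines) + "\n"


def off_target_count(variants: Sequence[Variant], targets: TargetRegions) -> int:
    """Number of variants whose first REF base lies in no target interval."""
    if len(targets) == 0 and variants:
        log.warning("empty target set: all %d variants counted off-target", len(variants))
    return sum(1 for v in variants if not targets.contains(v.chrom, v.pos))


def compute_qc(
    variants: Sequence[Variant],
    dbsnp_keys: Set,
    targets: Optional[TargetRegions] = None,
) -> QCReport:
    """Ti/Tv, dbSNP concordance and type proportions; optionally off-target."""
    n = len(variants)
    ti = tv = 0
    type_counts = {cls: 0 for cls in _TYPE_CLASSES}
    n_in_dbsnp = 0
    for v in variants:
        vt = v.variant_type
        if vt in type_counts:
            type_counts[vt] += 1
        if vt == "SNV":
            if (v.ref, v.alt) in TRANSITIONS:
                ti += 1
            else:
                tv += 1
        if variant_key(v) in dbsnp_keys:
            n_in_dbsnp += 1
    titv = (ti / tv) if tv > 0 else None
    if titv is None and ti > 0:
        log.warning("zero transversions among %d transitions: Ti/Tv undefined", ti)
    concordance = (100.0 * n_in_dbsnp / n) if n > 0 else None
    n_off = off_target_count(variants, targets) if targets is not None else 0
    return QCReport(
        n_variants=n,
        n_off_target=n_off,
        n_transitions=ti,
        n_transversions=tv,
        titv=titv,
        dbsnp_concordance=concordance,
        type_counts=type_counts,
    )
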