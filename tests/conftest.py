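"""Shared fixtures: generated cohorts, tiny references, and the string-diff
oracle for left-normalization."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Set

import pytest

from somaticfunnel.annotation import read_transcripts
from somaticfunnel.funnel import DEFAULT_DB_ORDER, load_databases, read_cgc, run_funnel
from somaticfunnel.simulate import SMALL_PROFILE, FunnelProfile, generate_cohort
from somaticfunnel.variants import (
    ReferenceSequence,
    TargetRegions,
    Variant,
    variant_key,
)


@dataclass
class CohortRun:
    fixture: object
    paths: Dict[str, str]
    reference: ReferenceSequence
    transcripts: object
    databases: Dict[str, Set]
    report: object
    functional: List
    recovered_keys: Set


def _run_cohort(profile: FunnelProfile, seed: int, out_dir) -> CohortRun:
    fixture = generate_cohort(profile, seed)
    paths = fixture.write(out_dir)
    reference = ReferenceSequence.from_fasta(paths["reference"])
    transcripts = read_transcripts(paths["transcripts_tsv"], paths["transcripts_fasta"])
    databases = load_databases(paths["db_dir"], DEFAULT_DB_ORDER)
    cgc = read_cgc(paths["cgc"])
    targets = TargetRegions.from_bed(paths["targets"])
    report, functional = run_funnel(
        paths["tumor_vcf"], paths["normal_vcf"], reference, transcripts,
        databases, cgc, targets=targets,
    )
    return CohortRun(
        fixture=fixture, paths=paths, reference=reference,
        transcripts=transcripts, databases=databases, report=report,
        functional=functional,
        recovered_keys={variant_key(av.variant) for av in functional},
    )


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory) -> CohortRun:
    """The full-size cohort (default profile, seed 230), run end to end."""
    return _run_cohort(FunnelProfile(), 230, tmp_path_factory.mktemp("cohort-default"))


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory) -> CohortRun:
    """A proportionally scaled cohort for cheap per-module tests."""
    return _run_cohort(SMALL_PROFILE, 230, tmp_path_factory.mktemp("cohort-small"))


# ---------------------------------------------------------------------------
# Left-normalization oracle: string-diff canonicalization
# ---------------------------------------------------------------------------

def apply_variant(window: str, pos: int, ref: str, alt: str) -> str:
    """Apply a variant to a 1-based sequence window; sanity-checks REF."""
    assert window[pos - 1 : pos - 1 + len(ref)] == ref
    return window[: pos - 1] + alt + window[pos - 1 + len(ref) :]


def oracle_normalize(window: str, pos: int, ref: str, alt: str):
    """Canonical left-aligned parsimonious representation via sequence diff.

    Independent of the production algorithm: build the full alternate
    haplotype, strip the longest common suffix then the longest common
    prefix of (reference window, alternate haplotype), re-anchoring
    one base left when an allele would empty.
    """
    alt_window = apply_variant(window, pos, ref, alt)
    r, a = window, alt_window
    end_r, end_a = len(r), len(a)
    while end_r > 1 and end_a > 1 and r[end_r - 1] == a[end_a - 1]:
        end_r -= 1
        end_a -= 1
    start = 0
    while start < min(end_r, end_a) - 1 and r[start] == a[start]:
        start += 1
    new_ref, new_alt = r[start:end_r], a[start:end_a]
    # parsimony: if both still share a leading base and either would not
    # empty on trimming, trim; re-anchor only when one side would empty
    while len(new_ref) > 1 and len(new_alt) > 1 and new_ref[0] == new_alt[0]:
        new_ref, new_alt, start = new_ref[1:], new_alt[1:], start + 1
    return start + 1, new_ref, new_alt


@pytest.fixture
def homopolymer_reference() -> ReferenceSequence:
    return ReferenceSequence({"H": "GATTTTTCAAAAGGGGCCTTAGCA" * 4})


def make_variant(chrom: str, pos: int, ref: str, alt: str, **kw) -> Variant:
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)
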