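"""End-to-end orchestration: simulate -> funnel -> ORA -> consensus ->
dose-response, with a run directory, manifest and machine+human reports."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import __version__
from .annotation import read_transcripts, write_annotated_tsv
from .dose_response import fit_plate
from .enrichment import run_ora, write_ora_tsv
from .errors import ConfigurationError, SomaticFunnelError, StageError
from .funnel import FunnelConfig, load_databases, read_cgc, run_funnel
from .pathogenicity import consensus_verdict, read_predictor_calls, write_consensus_tsv
from .simulate import FunnelProfile, generate_cohort, generate_pathway_db
from .variants import ReferenceSequence, TargetRegions

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated inputs for a full pipeline run."""

    tumor_vcf: str
    normal_vcf: str
    reference: str
    targets_bed: Optional[str]
    transcripts_tsv: str
    transcripts_fasta: str
    db_dir: str
    cgc: str
    out_dir: str
    predictor_calls: Optional[str] = None
    plate_csv: Optional[str] = None
    ora_query: Optional[str] = None  # optional explicit gene subset for ORA
    seed: int = 230
    funnel: FunnelConfig = field(default_factory=FunnelConfig)

    def validate(self) -> None:
        required = {
            "tumor_vcf": self.tumor_vcf, "normal_vcf": self.normal_vcf,
            "reference": self.reference, "transcripts_tsv": self.transcripts_tsv,
            "transcripts_fasta": self.transcripts_fasta, "cgc": self.cgc,
        }
        missing = [name for name, p in required.items() if not Path(p).exists()]
        if not Path(self.db_dir).is_dir():
            missing.append("db_dir")
        if missing:
            raise ConfigurationError(f"missing inputs: {', '.join(sorted(missing))}")

    def content_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items() if isinstance(v, (str, int))},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute every configured stage; returns the run directory.

    Stage failures raise :class:`StageError` after writing a FAILED marker;
    partial outputs are retained for inspection.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        reference = ReferenceSequence.from_fasta(config.reference)
        transcripts = read_transcripts(config.transcripts_tsv, config.transcripts_fasta)
        databases = load_databases(config.db_dir, config.funnel.novelty_db_order)
        cgc = read_cgc(config.cgc)
        targets = (TargetRegions.from_bed(config.targets_bed)
                   if config.targets_bed else None)

        report, functional = run_funnel(
            config.tumor_vcf, config.normal_vcf, reference, transcripts,
            databases, cgc, targets=targets, config=config.funnel,
        )
        (out / "funnel_report.tsv").write_text(report.to_tsv())
        (out / "funnel_report.txt").write_text(report.summary())
        if report.qc_tumor:
            (out / "qc_tumor.tsv").write_text(report.qc_tumor.to_tsv())
            (out / "qc_normal.tsv").write_text(report.qc_normal.to_tsv())
        write_annotated_tsv(functional, out / "novel_functional_variants.tsv")

        # ORA on the functional gene set, or on an explicit query subset
        if config.ora_query:
            query = [g.strip().upper() for g in
                     Path(config.ora_query).read_text().split() if g.strip()]
        else:
            query = sorted({g for av in functional for g in av.genes})
        pathways, universe, _ = generate_pathway_db(config.seed)
        results, ora_summary = run_ora(query, pathways, universe)
        write_ora_tsv(results, out / "ora_results.tsv")
        (out / "ora_summary.json").write_text(json.dumps(ora_summary, indent=2))

        if config.predictor_calls:
            calls = read_predictor_calls(config.predictor_calls)
            verdicts = {key: consensus_verdict(cs) for key, cs in calls.items()}
            write_consensus_tsv(verdicts, out / "consensus_pathogenicity.tsv")

        if config.plate_csv:
            plate = pd.read_csv(config.plate_csv)
            fit_plate(plate).to_csv(out / "ic50_fits.tsv", sep="\t", index=False)

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.content_hash(),
            "stages": ["funnel", "ora"]
            + (["consensus"] if config.predictor_calls else [])
            + (["ic50"] if config.plate_csv else []),
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    except SomaticFunnelError as exc:
        (out / "FAILED").write_text(str(exc) + "\n")
        raise
    return out


def simulate_to_dir(profile: Optional[FunnelProfile], seed: int, out_dir) -> Dict[str, str]:
    """Generate a cohort fixture and write every artifact to ``out_dir``."""
    fixture = generate_cohort(profile or FunnelProfile(), seed)
    return fixture.write(out_dir)


def load_profile_yaml(path) -> FunnelProfile:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return FunnelProfile(**data)
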