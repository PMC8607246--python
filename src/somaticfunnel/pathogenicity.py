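"""Consensus of heterogeneous functional-effect predictors.

Each predictor (SIFT, PolyPhen-2 HDIV/HVAR, MutationTaster, PROVEAN) emits
verdicts in its own vocabulary; these are normalized onto
{damaging, benign, unknown} via a fixed, extensible table, and a variant is
called unanimously damaging only when every supplied method says damaging
with no unknowns.  PolyPhen "possibly_damaging" counts as damaging (a
documented, configurable choice).  Predictor scoring itself is consumed as
data, never re-computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError
from .variants import VariantKey

DAMAGING, BENIGN, UNKNOWN = "damaging", "benign", "unknown"

#: raw-verdict -> normalized verdict, per method (keys lowercase)
DEFAULT_VOCABULARY: Dict[str, Dict[str, str]] = {
    "SIFT": {"deleterious": DAMAGING, "damaging": DAMAGING, "tolerated": BENIGN},
    "PolyPhen2_HDIV": {
        "probably_damaging": DAMAGING, "possibly_damaging": DAMAGING, "benign": BENIGN,
    },
    "PolyPhen2_HVAR": {
        "probably_damaging": DAMAGING, "possibly_damaging": DAMAGING, "benign": BENIGN,
    },
    "MutationTaster": {
        "disease_causing": DAMAGING, "disease_causing_automatic": DAMAGING,
        "polymorphism": BENIGN, "polymorphism_automatic": BENIGN,
    },
    "PROVEAN": {"deleterious": DAMAGING, "neutral": BENIGN},
}


@dataclass(frozen=True)
class PredictorCall:
    method: str
    raw_verdict: str
    score: Optional[float] = None


@dataclass
class ConsensusVerdict:
    n_methods: int
    n_damaging: int
    n_benign: int
    n_unknown: int
    unanimous_damaging: bool
    per_method: Dict[str, str] = field(default_factory=dict)


def normalize_call(
    call: PredictorCall, vocabulary: Dict[str, Dict[str, str]] = None
) -> str:
    """Map a raw verdict into {damaging, benign, unknown}."""
    vocab = vocabulary or DEFAULT_VOCABULARY
    if call.method not in vocab:
        raise ConfigurationError(f"unregistered predictor method: {call.method}")
    return vocab[call.method].get(call.raw_verdict.strip().lower(), UNKNOWN)


def consensus_verdict(
    calls: Sequence[PredictorCall], vocabulary: Dict[str, Dict[str, str]] = None
) -> ConsensusVerdict:
    """Tally normalized verdicts for one variant.

    Duplicate method entries are rejected; the unanimous flag requires every
    method damaging with no unknowns.
    """
    if not calls:
        raise ConfigurationError("consensus requires at least one predictor call")
    methods = [c.method for c in calls]
    if len(set(methods)) != len(methods):
        dupes = sorted({m for m in methods if methods.count(m) > 1})
        raise ConfigurationError(f"duplicate predictor entries: {dupes}")
    per_method = {c.method: normalize_call(c, vocabulary) for c in calls}
    n_damaging = sum(1 for v in per_method.values() if v == DAMAGING)
    n_benign = sum(1 for v in per_method.values() if v == BENIGN)
    n_unknown = len(calls) - n_damaging - n_benign
    return ConsensusVerdict(
        n_methods=len(calls),
        n_damaging=n_damaging,
        n_benign=n_benign,
        n_unknown=n_unknown,
        unanimous_damaging=(n_damaging == len(calls) and len(calls) >= 1),
        per_method=per_method,
    )


# ---------------------------------------------------------------------------
# Predictor-call table I/O (TSV keyed by variant key + method)
# ---------------------------------------------------------------------------

def read_predictor_calls(path) -> Dict[VariantKey, List[PredictorCall]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    calls: Dict[VariantKey, List[PredictorCall]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.chrom), int(row.pos), row.ref, row.alt)
        score = float(row.score) if "score" in df.columns and pd.notna(row.score) else None
        calls.setdefault(key, []).append(
            PredictorCall(method=row.method, raw_verdict=row.verdict, score=score)
        )
    return calls


def write_consensus_tsv(
    verdicts: Dict[VariantKey, ConsensusVerdict], path
) -> None:
    rows = []
    for (chrom, pos, ref, alt), cv in sorted(verdicts.items()):
        rows.append({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "n_methods": cv.n_methods, "n_damaging": cv.n_damaging,
            "n_benign": cv.n_benign, "n_unknown": cv.n_unknown,
            "unanimous_damaging": int(cv.unanimous_damaging),
            **{f"verdict_{m}": v for m, v in sorted(cv.per_method.items())},
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
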