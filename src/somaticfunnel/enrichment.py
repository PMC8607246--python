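"""Pathway over-representation analysis (ORA).

For a query gene list of size n (after restriction to the annotation
universe of N genes) and a pathway with K member genes, the enrichment
p-value is the binomial upper tail P(X >= k) with X ~ Binomial(n, K/N),
where k is the number of query genes in the pathway.  p-values over all
pathways hit by at least one query gene are adjusted with the
Benjamini-Hochberg step-up procedure.  Counting is gene-level throughout
(entity-level expansion as done by pathway servers is out of scope).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class Pathway:
    pathway_id: str
    name: str
    members: frozenset

    def __post_init__(self):
        if not isinstance(self.members, frozenset):
            object.__setattr__(self, "members", frozenset(self.members))


@dataclass
class EnrichmentResult:
    pathway_id: str
    name: str
    k: int           # query genes in pathway (and universe)
    K: int           # pathway size within the universe
    n: int           # query genes found in universe
    N: int           # universe size
    entities_ratio: float  # K / N
    p_value: float
    fdr: Optional[float] = None
    found_genes: Tuple[str, ...] = ()


def binomial_overrepresentation(
    query_genes: Iterable[str], pathway: Pathway, universe: Set[str]
) -> EnrichmentResult:
    """Upper-tail binomial test for one pathway.

    K=0 yields p=1 with a warning; n=0 (no query gene in the universe) is
    flagged with p = NaN.
    """
    if not universe:
        raise ConfigurationError("empty universe")
    query = set(query_genes) & universe
    members = pathway.members & universe
    n, N, K = len(query), len(universe), len(members)
    found = sorted(query & members)
    k = len(found)
    if n == 0:
        log.warning("no query gene found in universe; result undefined")
        p = float("nan")
    elif K == 0:
        log.warning("pathway %s has no member in universe; p = 1", pathway.pathway_id)
        p = 1.0
    else:
        # survival function at k-1 gives P(X >= k); numerically stable tail
        p = float(binom.sf(k - 1, n, K / N))
    return EnrichmentResult(
        pathway_id=pathway.pathway_id, name=pathway.name,
        k=k, K=K, n=n, N=N,
        entities_ratio=K / N, p_value=p, found_genes=tuple(found),
    )


def bh_adjust(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adjusted]


def run_ora(
    query_genes: Iterable[str],
    pathway_db: Sequence[Pathway],
    universe: Set[str],
) -> Tuple[List[EnrichmentResult], Dict[str, int]]:
    """Test every pathway hit by at least one query gene.

    Returns results sorted by (p, pathway_id) with BH FDR attached over the
    tested set, plus a summary with ``n_query``, ``n_found`` (query genes in
    the universe) and ``n_pathways_hit``.
    """
    if not pathway_db:
        raise ConfigurationError("empty pathway database")
    query = set(query_genes)
    results = [
        r for p in pathway_db
        if (r := binomial_overrepresentation(query, p, universe)).k >= 1
    ]
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    for r, fdr in zip(results, bh_adjust([r.p_value for r in results]) if results else []):
        r.fdr = fdr
    summary = {
        "n_query": len(query),
        "n_found": len(query & universe),
        "n_pathways_hit": len(results),
    }
    return results, summary


# ---------------------------------------------------------------------------
# GMT and result I/O
# ---------------------------------------------------------------------------

def read_gmt(path) -> List[Pathway]:
    """GMT: pathway_id TAB name TAB gene1 TAB gene2 ..."""
    pathways = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pathways.append(Pathway(parts[0], parts[1], frozenset(parts[2:])))
    return pathways


def write_gmt(pathways: Sequence[Pathway], path) -> None:
    with open(path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.pathway_id, p.name] + sorted(p.members)) + "\n")


def write_ora_tsv(results: Sequence[EnrichmentResult], path) -> None:
    rows = [
        {
            "pathway_id": r.pathway_id, "pathway_name": r.name,
            "entities_found": f"{r.k}/{r.K}",
            "entities_ratio": r.entities_ratio,
            "p_value": r.p_value, "fdr": r.fdr,
            "found_genes": ",".join(r.found_genes),
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
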