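"""Hypergeometric over-representation of gene sets with BH correction.

The background (universe) is the giant component of the network resource in
use.  Terms are taken as flat sets from the supplied GMT; no ontology-graph
propagation is performed.  The test is one-sided (over-representation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    term_id: str
    term_size: int  # |term ∩ background|
    query_size: int
    overlap: int
    pvalue: float
    qvalue: float
    enriched: bool


def hypergeometric_enrich(query: set[str], collection: dict[str, set[str]],
                          background: set[str],
                          q_threshold: float = 0.05) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test per term, BH-corrected across the collection.

    Query genes outside the background are dropped (count logged).
    """
    if not background:
        raise ValueError("empty background universe")
    q = query & background
    if len(q) < len(query):
        log.warning("%d query genes outside the background dropped",
                    len(query) - len(q))
    M, N = len(background), len(q)
    terms, pvals, metas = [], [], []
    for term in sorted(collection):
        genes = collection[term] & background
        n = len(genes)
        k = len(genes & q)
        # P(X >= k) with X ~ Hypergeom(M, n, N)
        p = float(hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        p = min(max(p, 5e-324), 1.0)
        terms.append(term)
        pvals.append(p)
        metas.append((n, k))
    if not terms:
        return []
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = []
    for term, p, qv, (n, k) in zip(terms, pvals, qvals, metas):
        out.append(EnrichmentResult(term_id=term, term_size=n, query_size=N,
                                    overlap=k, pvalue=p, qvalue=float(qv),
                                    enriched=bool(qv < q_threshold)))
    out.sort(key=lambda r: (r.pvalue, r.term_id))
    return out


def enriched_terms(results: list[EnrichmentResult]) -> set[str]:
    return {r.term_id for r in results if r.enriched}


def term_set_overlap(enriched_a: set[str], enriched_b: set[str]) -> dict[str, float]:
    """Overlap of two enriched-term sets.

    Returns the asymmetric fraction of A's terms found in B (and the reverse),
    plus the symmetric Jaccard index.  Empty sets give NaN fractions.
    """
    inter = len(enriched_a & enriched_b)
    union = len(enriched_a | enriched_b)
    return {
        "fraction_a_in_b": inter / len(enriched_a) if enriched_a else float("nan"),
        "fraction_b_in_a": inter / len(enriched_b) if enriched_b else float("nan"),
        "jaccard": inter / union if union else float("nan"),
    }
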