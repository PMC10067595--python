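"""Hypergeometric gene-set enrichment with BH correction, plus class tallies.

For a term of size M inside a background of N genes, and n candidate
genes of which m hit the term, the enrichment p-value is the upper tail

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N - M, n - i) / C(N, n) = P(X >= m)

Q-values are Benjamini-Hochberg adjusted over the family of terms with at
least one candidate hit; terms with q <= 0.05 (configurable) are called
significantly enriched.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from bsaed.pool_io import AnnotationRecord

__all__ = [
    "EnrichmentResult",
    "GeneSetDatabase",
    "bh_adjust",
    "enrich",
    "hypergeom_p",
    "tally_annotation_classes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetDatabase:
    """term_id -> gene membership, with the annotated-background size N."""

    terms: Mapping[str, frozenset[str]]
    background: int

    def __post_init__(self) -> None:
        if self.terms and self.background < max(len(g) for g in self.terms.values()):
            raise ValueError("background smaller than the largest term")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset().union(*self.terms.values()) if self.terms else frozenset()


def hypergeom_p(N: int, M: int, n: int, m: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= m)."""
    if not (0 <= M <= N and 0 <= n <= N and 0 <= m <= min(n, M)):
        raise ValueError(f"invalid hypergeometric parameters N={N} M={M} n={n} m={m}")
    if m == 0:
        return 1.0
    # sf(m-1) = P(X >= m); scipy works in log space internally
    return float(min(1.0, hypergeom.sf(m - 1, N, M, n)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    N: int
    M: int
    n: int
    m: int
    p_value: float
    q_value: float
    significant: bool

    @property
    def rich_factor(self) -> float:
        return self.m / self.M


def enrich(
    candidate_genes: Iterable[str],
    db: GeneSetDatabase,
    q_cutoff: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every term with >= 1 candidate hit; sorted by p ascending."""
    candidates = set(candidate_genes)
    known = candidates & db.genes
    dropped = len(candidates) - len(known)
    if dropped:
        logger.info("dropped %d candidate genes outside the background", dropped)
    n = len(known)
    tested: list[tuple[str, int, int, float]] = []
    for term_id, genes in db.terms.items():
        m = len(known & genes)
        if m == 0:
            continue
        p = hypergeom_p(db.background, len(genes), n, m)
        tested.append((term_id, len(genes), m, p))
    if not tested:
        return []
    qs = bh_adjust([t[3] for t in tested])
    results = [
        EnrichmentResult(
            term_id=term_id,
            N=db.background,
            M=M,
            n=n,
            m=m,
            p_value=p,
            q_value=float(q),
            significant=bool(q <= q_cutoff),
        )
        for (term_id, M, m, p), q in zip(tested, qs)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def tally_annotation_classes(
    annotations: Iterable[AnnotationRecord],
) -> tuple[Counter, Counter]:
    """Counts per region_class and per mutation_class; each sums to the input size."""
    region: Counter = Counter()
    mutation: Counter = Counter()
    for ann in annotations:
        region[ann.region_class] += 1
        mutation[ann.mutation_class] += 1
    return region, mutation


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path) -> None:
    import pandas as pd

    rows = [
        {
            "term_id": r.term_id,
            "N": r.N,
            "M": r.M,
            "n": r.n,
            "m": r.m,
            "p": r.p_value,
            "q": r.q_value,
            "rich_factor": r.rich_factor,
            "significant": r.significant,
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=["term_id", "N", "M", "n", "m", "p", "q", "rich_factor", "significant"],
    ).to_csv(path, sep="\t", index=False)
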