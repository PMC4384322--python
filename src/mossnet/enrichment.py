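"""GO term over/under-representation by hypergeometric test with BH-FDR.

For each term with at least one annotated gene in the background, the study
set of size n drawn from a universe of N annotated genes (K of which carry
the term, k of them in the study set) is tested one-sided:

    over:  P(X >= k),   under: P(X <= k),   X ~ Hypergeometric(N, K, n)

Raw p-values across all tested terms are adjusted by the Benjamini-Hochberg
step-up procedure and flagged significant at adjusted p <= alpha (default
0.05).  The background universe defaults to all genes in the annotation map
("against the whole annotation"); pass a custom universe to test against the
network's node set instead.

GO-graph propagation (the true-path rule) is not performed: annotations are
tested as given, and a slim projection, if used, is assumed pre-propagated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import AnnotationMap

log = logging.getLogger(__name__)


def hypergeometric_tail(k: int, n: int, K: int, N: int, direction: str = "over") -> float:
    """One-sided hypergeometric tail probability.

    ``over`` → P(X >= k); ``under`` → P(X <= k) for X ~ Hypergeometric(N, K, n).
    """
    if direction not in ("over", "under"):
        raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    if direction == "over":
        return float(hypergeom.sf(k - 1, N, K, n))
    return float(hypergeom.cdf(k, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(q) for q in adjusted]


@dataclass
class EnrichmentResult:
    term: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_adj: float
    direction: str
    significant: bool


def go_enrichment(
    study_genes: Iterable[str],
    annotations: AnnotationMap,
    alpha: float = 0.05,
    direction: str = "over",
    universe: Optional[set[str]] = None,
) -> list[EnrichmentResult]:
    """Test every annotated term for over/under-representation in the study set.

    Study genes outside the universe are dropped with a warning; an empty
    study set (after filtering) is an error.  Results are sorted by adjusted
    then raw p-value.
    """
    uni = set(universe) if universe is not None else set(annotations)
    study = set(study_genes)
    outside = study - uni
    if outside:
        log.warning("%d study genes outside the universe dropped", len(outside))
        study &= uni
    if not study:
        raise ValueError("empty study set")
    N, n = len(uni), len(study)
    term_genes: dict[str, set[str]] = {}
    for gene in uni:
        for term in annotations.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    terms = sorted(term_genes)
    results: list[EnrichmentResult] = []
    for term in terms:
        K = len(term_genes[term])
        k = len(term_genes[term] & study)
        p = hypergeometric_tail(k, n, K, N, direction)
        results.append(EnrichmentResult(term, k, n, K, N, p, 1.0, direction, False))
    adjusted = bh_adjust([r.p_raw for r in results])
    for r, q in zip(results, adjusted):
        r.p_adj = q
        r.significant = q <= alpha
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.term))
    return results


def write_enrichment_results(results: Iterable[EnrichmentResult], path) -> None:
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["term", "k", "n", "K", "N", "p_raw", "p_adj", "direction", "significant"])
        for r in results:
            w.writerow([r.term, r.k, r.n, r.K, r.N, f"{r.p_raw:.6g}", f"{r.p_adj:.6g}",
                        r.direction, int(r.significant)])
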