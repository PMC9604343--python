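"""Pathway overrepresentation of the pooled DEG set.

The statistic is the one-sided hypergeometric upper tail: with a universe of
``N`` genes of which ``K`` lie in the pathway, and a query (DEG) set of size
``n``, the p-value is P(X >= k) for the observed overlap ``k`` under
X ~ Hypergeom(N, K, n) — the classic Fisher-exact overrepresentation model.

The default universe is the intersection of the expression matrix with the
union of all pathway sets, so unmeasured genes never inflate significance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, PathwaySet


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    uploaded_count: int     # |DEGs ∩ pathway ∩ universe|
    pathway_size: int       # |pathway ∩ universe|
    universe_size: int
    deg_count: int          # |DEGs ∩ universe|
    p_value: float


def overrepresentation_p(
    deg_count: int, pathway_size: int, overlap: int, universe_size: int
) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    Raises on inconsistent counts (overlap exceeding either margin, or any
    count exceeding the universe).
    """
    counts = dict(deg_count=deg_count, pathway_size=pathway_size,
                  overlap=overlap, universe_size=universe_size)
    for name, v in counts.items():
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if overlap > min(deg_count, pathway_size):
        raise ValueError(
            f"overlap {overlap} exceeds min(deg_count={deg_count}, pathway_size={pathway_size})"
        )
    if max(deg_count, pathway_size) > universe_size:
        raise ValueError("deg_count and pathway_size must not exceed universe_size")
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, pathway_size, deg_count))
    return min(p, 1.0)


def build_universe(
    matrix: ExpressionMatrix, pathway_sets: Iterable[PathwaySet], scope: str = "intersection"
) -> set[str]:
    """Gene universe for the test.

    ``intersection`` (default): matrix genes that appear in at least one
    pathway set. ``matrix``: all matrix genes.
    """
    matrix_genes = set(matrix.gene_ids)
    if scope == "matrix":
        return matrix_genes
    if scope == "intersection":
        in_sets: set[str] = set()
        for ps in pathway_sets:
            in_sets |= ps.genes
        return matrix_genes & in_sets
    raise ValueError(f"unknown universe scope {scope!r}")


def enrich(
    deg_genes: Iterable[str],
    pathway_sets: Sequence[PathwaySet],
    universe: set[str],
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Score every pathway set against the pooled DEG query set."""
    degs = set(deg_genes) & universe
    results = []
    for ps in pathway_sets:
        members = ps.genes & universe
        overlap = len(degs & members)
        p = overrepresentation_p(len(degs), len(members), overlap, len(universe))
        results.append(EnrichmentResult(
            pathway=ps.name, uploaded_count=overlap, pathway_size=len(members),
            universe_size=len(universe), deg_count=len(degs), p_value=p,
        ))
    if bh_correct:
        adj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        results = [
            EnrichmentResult(r.pathway, r.uploaded_count, r.pathway_size,
                             r.universe_size, r.deg_count, float(q))
            for r, q in zip(results, adj)
        ]
    return results


def rank_pathways(results: Iterable[EnrichmentResult], top_k: int = 10) -> list[EnrichmentResult]:
    """Order by ascending p; ties by larger uploaded count, then name; keep top_k."""
    ranked = sorted(results, key=lambda r: (r.p_value, -r.uploaded_count, r.pathway))
    return ranked[:top_k]
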