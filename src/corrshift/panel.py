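"""Assembly of the diagnostic gene panel.

Correlation-shifted pairs from all pathways are deduplicated (a pair kept
once, its pathway provenance merged), the genes they involve are extracted,
and the final panel is the exact set union of the top-N upregulated genes,
top-N downregulated genes, and the correlation-shift genes — each gene once,
tagged with every source it came from.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .deg import DegRecord
from .diffcorr import DeltaCCRecord

logger = logging.getLogger("corrshift")

TOP_UP = "top_up"
TOP_DOWN = "top_down"
CORR_SHIFT = "corr_shift"


@dataclass(frozen=True)
class PanelGene:
    gene_id: str
    sources: frozenset[str]
    log2fc: float | None
    p_value: float | None
    # (partner gene, delta_cc, pathway names) per surviving deduped pair
    pair_evidence: tuple[tuple[str, float, frozenset[str]], ...] = ()

    def __post_init__(self):
        if not self.sources:
            raise ValueError(f"panel gene {self.gene_id!r} has no sources")
        unknown = set(self.sources) - {TOP_UP, TOP_DOWN, CORR_SHIFT}
        if unknown:
            raise ValueError(f"unknown source tag(s) {unknown} for {self.gene_id!r}")


def dedupe_pairs(records: Iterable[DeltaCCRecord]) -> list[DeltaCCRecord]:
    """One record per unordered pair; pathway sets merged across duplicates.

    When duplicates carry different ΔCC values (possible when masking differs
    between pathway contexts), the maximum-|ΔCC| value is kept and the range
    is logged. Idempotent, and output order is deterministic (sorted by pair).
    """
    by_key: dict[tuple[str, str], list[DeltaCCRecord]] = defaultdict(list)
    for rec in records:
        by_key[rec.key].append(rec)
    out = []
    for key in sorted(by_key):
        group = by_key[key]
        deltas = sorted({r.delta_cc for r in group})
        if len(deltas) > 1:
            logger.warning(
                "pair %s-%s has differing delta_cc across pathways "
                "(range %.4f .. %.4f); keeping max |delta_cc|",
                key[0], key[1], deltas[0], deltas[-1],
            )
        best = max(group, key=lambda r: (abs(r.delta_cc), r.delta_cc))
        pathways = frozenset().union(*(r.pathways for r in group))
        out.append(DeltaCCRecord(
            gene_a=best.gene_a, gene_b=best.gene_b,
            cc_control=best.cc_control, cc_cancer=best.cc_cancer,
            delta_cc=best.delta_cc, pathways=pathways,
        ))
    return out


def genes_from_pairs(records: Iterable[DeltaCCRecord]) -> set[str]:
    """Union of both members over all pair records."""
    genes: set[str] = set()
    for rec in records:
        genes.add(rec.gene_a)
        genes.add(rec.gene_b)
    return genes


def assemble_panel(
    top_up: Sequence[str],
    top_down: Sequence[str],
    pair_genes: Iterable[str],
    deg_records: Iterable[DegRecord] = (),
    pair_records: Iterable[DeltaCCRecord] = (),
) -> list[PanelGene]:
    """Union of the three source lists with per-gene merged source tags.

    The panel size equals |top_up ∪ top_down ∪ pair_genes| exactly. Output is
    sorted by (number of sources desc, |log2FC| desc, symbol asc); genes
    without a fold-change estimate sort after those with one. An overlap
    between top_up and top_down is a hard error — impossible under valid
    direction calls.
    """
    up_set, down_set, shift_set = set(top_up), set(top_down), set(pair_genes)
    clash = up_set & down_set
    if clash:
        raise ValueError(f"genes in both top-up and top-down lists: {sorted(clash)}")

    deg_by_gene: Mapping[str, DegRecord] = {r.gene_id: r for r in deg_records}
    evidence: dict[str, list[tuple[str, float, frozenset[str]]]] = defaultdict(list)
    for rec in pair_records:
        evidence[rec.gene_a].append((rec.gene_b, rec.delta_cc, rec.pathways))
        evidence[rec.gene_b].append((rec.gene_a, rec.delta_cc, rec.pathways))

    panel = []
    for gene in up_set | down_set | shift_set:
        sources = set()
        if gene in up_set:
            sources.add(TOP_UP)
        if gene in down_set:
            sources.add(TOP_DOWN)
        if gene in shift_set:
            sources.add(CORR_SHIFT)
        deg = deg_by_gene.get(gene)
        panel.append(PanelGene(
            gene_id=gene,
            sources=frozenset(sources),
            log2fc=None if deg is None else deg.log2fc,
            p_value=None if deg is None else deg.p_value,
            pair_evidence=tuple(sorted(evidence.get(gene, []), key=lambda e: e[0])),
        ))
    panel.sort(key=lambda g: (
        -len(g.sources),
        -(abs(g.log2fc) if g.log2fc is not None else float("-inf")),
        g.gene_id,
    ))
    return panel


def panel_frame(panel: Iterable[PanelGene]) -> pd.DataFrame:
    """Tabular view of the panel for panel.tsv."""
    rows = []
    for g in panel:
        rows.append({
            "gene_id": g.gene_id,
            "sources": ",".join(sorted(g.sources)),
            "log2fc": "" if g.log2fc is None else g.log2fc,
            "p_value": "" if g.p_value is None else g.p_value,
            "partners": ";".join(p for p, _, _ in g.pair_evidence),
            "delta_cc_values": ";".join(repr(d) for _, d, _ in g.pair_evidence),
            "pathways": ";".join(sorted(set().union(*(pw for _, _, pw in g.pair_evidence)) if g.pair_evidence else set())),
        })
    return pd.DataFrame(rows, columns=[
        "gene_id", "sources", "log2fc", "p_value", "partners", "delta_cc_values", "pathways",
    ])


def pairs_frame(records: Iterable[DeltaCCRecord]) -> pd.DataFrame:
    """Tabular view of deduplicated pair records for pairs.tsv."""
    rows = [{
        "gene_a": r.gene_a, "gene_b": r.gene_b,
        "cc_control": r.cc_control, "cc_cancer": r.cc_cancer,
        "delta_cc": r.delta_cc, "pathways": ";".join(sorted(r.pathways)),
    } for r in records]
    return pd.DataFrame(rows, columns=[
        "gene_a", "gene_b", "cc_control", "cc_cancer", "delta_cc", "pathways",
    ])
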