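"""End-to-end pipeline: DEG calls → pathway overrepresentation → per-pathway
ΔCC matrices → shifted-pair selection → panel assembly → heatmaps.

:func:`run_pipeline` operates on in-memory objects and returns every
intermediate result; :func:`run_all` wraps it with file I/O and writes the
standard output set (deg_table.tsv, enrichment.tsv, pairs.tsv, panel.tsv,
diagnostics.tsv, run_summary.json, heatmaps/). Reruns with identical inputs
and configuration produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import deg as deg_mod
from . import diffcorr as dc_mod
from . import enrichment as enr_mod
from . import panel as panel_mod
from . import viz as viz_mod
from .io_formats import (
    ExpressionMatrix, PathwaySet, SampleGroups,
    read_expression_matrix, read_gmt, read_sample_sheet, write_table,
)

logger = logging.getLogger("corrshift")


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds and method switches, defaulting to the study settings."""

    log2fc_cutoff: float = 2.50
    pval_cutoff: float = 0.001
    top_n: int = 20
    top_pathways: int = 10
    delta_cc_cutoff: float = 0.70
    correlation: str = "pearson"      # or "spearman"
    corr_space: str = "raw"           # or "log2"
    pseudocount: float = 1.0
    bh_correct: bool = False
    universe: str = "intersection"    # or "matrix"
    seed: int = 0
    make_plots: bool = True

    def deg_config(self) -> deg_mod.DegConfig:
        return deg_mod.DegConfig(
            fc_cutoff=self.log2fc_cutoff, p_cutoff=self.pval_cutoff,
            top_n=self.top_n, pseudocount=self.pseudocount, bh_correct=self.bh_correct,
        )


@dataclass
class PipelineResult:
    deg_records: list[deg_mod.DegRecord]
    up_genes: set[str]
    down_genes: set[str]
    top_up: list[str]
    top_down: list[str]
    enrichment: list[enr_mod.EnrichmentResult]
    corr_pairs: dict[str, dc_mod.CorrelationMatrixPair]
    shifted_records: list[dc_mod.DeltaCCRecord]       # per-pathway, pre-dedup
    deduped_pairs: list[dc_mod.DeltaCCRecord]
    pair_genes: set[str]
    panel: list[panel_mod.PanelGene]
    skipped_pathways: list[str] = field(default_factory=list)
    diagnostics: list[tuple[str, str, str, str]] = field(default_factory=list)


def run_pipeline(
    matrix: ExpressionMatrix,
    groups: SampleGroups,
    pathway_sets: list[PathwaySet],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every analysis stage in order on in-memory inputs."""
    config = config or PipelineConfig()
    groups.validate_against(matrix)

    logger.info("stage deg: %d genes, %d control / %d cancer samples",
                matrix.shape[0], len(groups.control_samples), len(groups.cancer_samples))
    deg_cfg = config.deg_config()
    records = deg_mod.compute_deg_records(matrix, groups, deg_cfg)
    up, down = deg_mod.filter_degs(records, deg_cfg)
    top_up = deg_mod.top_n_by_fold(records, config.top_n, "up")
    top_down = deg_mod.top_n_by_fold(records, config.top_n, "down")
    logger.info("stage deg: %d up, %d down at |log2FC| >= %g, p < %g",
                len(up), len(down), config.log2fc_cutoff, config.pval_cutoff)

    universe = enr_mod.build_universe(matrix, pathway_sets, config.universe)
    results = enr_mod.enrich(up | down, pathway_sets, universe, config.bh_correct)
    ranked = enr_mod.rank_pathways(results, config.top_pathways)
    logger.info("stage enrichment: %d pathways scored, top %d kept (universe %d genes)",
                len(results), len(ranked), len(universe))

    set_by_name = {ps.name: ps for ps in pathway_sets}
    corr_pairs: dict[str, dc_mod.CorrelationMatrixPair] = {}
    shifted: list[dc_mod.DeltaCCRecord] = []
    skipped: list[str] = []
    diagnostics: list[tuple[str, str, str, str]] = []
    for res in ranked:
        ps = set_by_name[res.pathway]
        subset = dc_mod.pathway_gene_subset(ps, up | down, matrix)
        if len(subset) < 2:
            skipped.append(ps.name)
            continue
        pair = dc_mod.compute_pathway_correlations(
            matrix, groups, ps.name, subset,
            space=config.corr_space, method=config.correlation,
            pseudocount=config.pseudocount,
        )
        corr_pairs[ps.name] = pair
        shifted.extend(dc_mod.select_shifted_pairs(pair, config.delta_cc_cutoff))
        diagnostics.extend((ps.name, a, b, grp) for a, b, grp in dc_mod.masked_pair_diagnostics(pair))
    logger.info("stage diffcorr: %d pathway(s) analyzed, %d skipped, %d shifted pair selections",
                len(corr_pairs), len(skipped), len(shifted))

    deduped = panel_mod.dedupe_pairs(shifted)
    pair_genes = panel_mod.genes_from_pairs(deduped)
    panel = panel_mod.assemble_panel(top_up, top_down, pair_genes, records, deduped)
    logger.info("stage panel: %d unique pairs, %d shift genes, panel size %d",
                len(deduped), len(pair_genes), len(panel))

    return PipelineResult(
        deg_records=records, up_genes=up, down_genes=down,
        top_up=top_up, top_down=top_down,
        enrichment=ranked, corr_pairs=corr_pairs,
        shifted_records=shifted, deduped_pairs=deduped,
        pair_genes=pair_genes, panel=panel,
        skipped_pathways=skipped, diagnostics=diagnostics,
    )


def enrichment_frame(results: list[enr_mod.EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in results],
        columns=["pathway", "uploaded_count", "pathway_size", "universe_size", "deg_count", "p_value"],
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(
    result: PipelineResult,
    out_dir: str | Path,
    config: PipelineConfig,
    input_checksums: dict[str, str] | None = None,
) -> Path:
    """Write the standard output set under ``out_dir`` and return it."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    write_table(deg_mod.deg_frame(result.deg_records), out_dir / "deg_table.tsv")
    write_table(enrichment_frame(result.enrichment), out_dir / "enrichment.tsv")
    write_table(panel_mod.pairs_frame(result.deduped_pairs), out_dir / "pairs.tsv")
    write_table(panel_mod.panel_frame(result.panel), out_dir / "panel.tsv")
    write_table(
        pd.DataFrame(result.diagnostics, columns=["pathway", "gene_a", "gene_b", "zero_variance_group"]),
        out_dir / "diagnostics.tsv",
    )

    if config.make_plots:
        heatmap_dir = out_dir / "heatmaps"
        for name, pair in result.corr_pairs.items():
            safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in name)
            viz_mod.plot_correlation_pair(pair, heatmap_dir / safe)

    summary = {
        "config": dataclasses.asdict(config),
        "inputs": input_checksums or {},
        "counts": {
            "genes": len(result.deg_records),
            "upregulated_degs": len(result.up_genes),
            "downregulated_degs": len(result.down_genes),
            "pathways_reported": len(result.enrichment),
            "pathways_analyzed": len(result.corr_pairs),
            "pathways_skipped": len(result.skipped_pathways),
            "shifted_pair_selections": len(result.shifted_records),
            "unique_shifted_pairs": len(result.deduped_pairs),
            "correlation_shift_genes": len(result.pair_genes),
            "panel_size": len(result.panel),
        },
    }
    with open(out_dir / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_dir


def run_all(
    matrix_path: str | Path,
    sample_sheet_path: str | Path,
    gmt_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> Path:
    """File-to-file pipeline run. Raises on any stage failure after logging
    the failing stage; partial outputs already written are preserved."""
    config = config or PipelineConfig()
    checksums = {
        str(Path(p)): _sha256(Path(p))
        for p in (matrix_path, sample_sheet_path, gmt_path)
    }
    for p, digest in checksums.items():
        logger.info("input %s sha256=%s", p, digest)

    stage = "read inputs"
    try:
        matrix = read_expression_matrix(matrix_path)
        groups = read_sample_sheet(sample_sheet_path, matrix)
        pathway_sets = read_gmt(gmt_path)
        stage = "pipeline"
        result = run_pipeline(matrix, groups, pathway_sets, config)
        stage = "write outputs"
        return write_outputs(result, out_dir, config, checksums)
    except Exception:
        logger.exception("pipeline failed during stage: %s", stage)
        raise
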