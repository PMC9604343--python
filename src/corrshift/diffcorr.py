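"""Per-pathway differential gene-pair correlation (ΔCC).

For each pathway the genes of interest are the pathway members that are also
DEGs and present in the matrix. Pairwise correlation matrices are computed
separately over the control and cancer samples; the ΔCC matrix is their
elementwise difference (cancer − control), and gene pairs with
|ΔCC| >= 0.70 (boundary inclusive) are called correlation-shifted.

Pearson on raw abundances is the default; Spearman and a log2(x+1) value
space are available. Pairs involving a zero-variance gene in either group
are masked invalid rather than reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_formats import ExpressionMatrix, PathwaySet, SampleGroups

logger = logging.getLogger("corrshift")

DELTA_CC_CUTOFF = 0.70


@dataclass
class CorrelationMatrixPair:
    """Control and cancer correlation matrices over one pathway's gene subset.

    ``mask_control`` / ``mask_cancer`` flag entries whose genes both have
    non-zero variance in that group; ``mask`` is their conjunction (where a
    ΔCC value is defined). Invalid entries are NaN in the matrices.
    """

    pathway: str
    genes: list[str]
    cc_control: np.ndarray
    cc_cancer: np.ndarray
    mask_control: np.ndarray
    mask_cancer: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        return self.mask_control & self.mask_cancer


@dataclass(frozen=True)
class DeltaCCRecord:
    """One unordered gene pair with its per-group correlations and shift."""

    gene_a: str
    gene_b: str
    cc_control: float
    cc_cancer: float
    delta_cc: float
    pathways: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError(f"pair members must differ, got {self.gene_a!r} twice")
        if not self.gene_a < self.gene_b:
            raise ValueError("gene_a must sort before gene_b; use make_record()")
        if abs(self.delta_cc - (self.cc_cancer - self.cc_control)) > 1e-12:
            raise ValueError("delta_cc must equal cc_cancer - cc_control")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def make_record(
    gene_a: str, gene_b: str, cc_control: float, cc_cancer: float,
    pathways: Iterable[str] = (),
) -> DeltaCCRecord:
    """Build a DeltaCCRecord with members in canonical (lexical) order."""
    a, b = sorted((gene_a, gene_b))
    return DeltaCCRecord(
        gene_a=a, gene_b=b, cc_control=float(cc_control), cc_cancer=float(cc_cancer),
        delta_cc=float(cc_cancer) - float(cc_control), pathways=frozenset(pathways),
    )


def pathway_gene_subset(
    pathway: PathwaySet, degs: Iterable[str], matrix: ExpressionMatrix
) -> list[str]:
    """Pathway ∩ DEGs ∩ matrix genes, sorted lexically.

    A subset with fewer than 2 genes admits no pairs; a warning is logged and
    the caller is expected to skip the pathway.
    """
    subset = sorted(pathway.genes & set(degs) & set(matrix.gene_ids))
    if len(subset) < 2:
        logger.warning(
            "pathway %r has %d DEG(s) in the matrix; skipped (no pairs possible)",
            pathway.name, len(subset),
        )
    return subset


def correlation_matrix(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    samples: Sequence[str],
    space: str = "raw",
    method: str = "pearson",
    pseudocount: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gene–gene correlation over one group's samples.

    Returns ``(C, mask)``: C is symmetric with exact unit diagonal where
    defined and NaN where masked; mask[i, j] is True iff both genes have
    non-zero variance in this group. ``space='log2'`` correlates
    log2(value + pseudocount) instead of raw abundances.
    """
    if len(samples) < 3:
        raise ValueError(f"correlation needs >= 3 samples, got {len(samples)}")
    if space not in ("raw", "log2"):
        raise ValueError(f"unknown value space {space!r}")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    X = matrix.values_for(genes, samples)
    if space == "log2":
        X = np.log2(X + pseudocount)
    if method == "spearman":
        X = stats.rankdata(X, axis=1)  # Pearson of ranks = Spearman (ties averaged)
    valid = X.var(axis=1) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.corrcoef(X)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    mask = np.outer(valid, valid)
    C[~mask] = np.nan
    C = np.clip(C, -1.0, 1.0)
    di = np.arange(len(genes))
    C[di, di] = np.where(valid, 1.0, np.nan)
    return C, mask


def compute_pathway_correlations(
    matrix: ExpressionMatrix,
    groups: SampleGroups,
    pathway_name: str,
    genes: Sequence[str],
    space: str = "raw",
    method: str = "pearson",
    pseudocount: float = 1.0,
) -> CorrelationMatrixPair:
    """Control and cancer correlation matrices for one pathway gene subset."""
    order = {s: i for i, s in enumerate(matrix.sample_ids)}
    ctrl = sorted(groups.control_samples, key=order.__getitem__)
    canc = sorted(groups.cancer_samples, key=order.__getitem__)
    cc0, m0 = correlation_matrix(matrix, genes, ctrl, space, method, pseudocount)
    cc1, m1 = correlation_matrix(matrix, genes, canc, space, method, pseudocount)
    return CorrelationMatrixPair(
        pathway=pathway_name, genes=list(genes),
        cc_control=cc0, cc_cancer=cc1, mask_control=m0, mask_cancer=m1,
    )


def delta_cc_matrix(pair: CorrelationMatrixPair) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise cc_cancer − cc_control with the combined validity mask."""
    if pair.cc_control.shape != pair.cc_cancer.shape:
        raise ValueError(
            f"shape mismatch: control {pair.cc_control.shape} vs cancer {pair.cc_cancer.shape}"
        )
    mask = pair.mask
    delta = pair.cc_cancer - pair.cc_control
    delta[~mask] = np.nan
    return delta, mask


def select_shifted_pairs(
    pair: CorrelationMatrixPair, cutoff: float = DELTA_CC_CUTOFF
) -> list[DeltaCCRecord]:
    """All valid unordered pairs with |ΔCC| >= cutoff (boundary inclusive).

    Records carry the source pathway; the same pair may be re-selected under
    other pathways and is deduplicated downstream.
    """
    delta, mask = delta_cc_matrix(pair)
    records = []
    n = len(pair.genes)
    for i in range(n):
        for j in range(i + 1, n):
            if mask[i, j] and abs(delta[i, j]) >= cutoff:
                records.append(make_record(
                    pair.genes[i], pair.genes[j],
                    pair.cc_control[i, j], pair.cc_cancer[i, j],
                    pathways=[pair.pathway],
                ))
    return records


def masked_pair_diagnostics(pair: CorrelationMatrixPair) -> list[tuple[str, str, str]]:
    """(gene_a, gene_b, group) for every pair masked by zero variance."""
    out = []
    n = len(pair.genes)
    for i in range(n):
        for j in range(i + 1, n):
            if not pair.mask_control[i, j]:
                out.append((pair.genes[i], pair.genes[j], "control"))
            if not pair.mask_cancer[i, j]:
                out.append((pair.genes[i], pair.genes[j], "cancer"))
    return out
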