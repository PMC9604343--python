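"""Differential expression between cancer and control groups.

Per gene, the stage computes a log2 fold change of group means (with a
pseudocount guarding zero FPKM) and a two-sided Welch t-test p-value on
log2-transformed abundances. A gene is called differentially expressed when
|log2FC| >= ``fc_cutoff`` (boundary inclusive) and p < ``p_cutoff`` (strict),
and the top-N lists are ranked by fold-change magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, SampleGroups

Direction = Literal["up", "down", "none"]

UP = "up"
DOWN = "down"
NONE = "none"


@dataclass(frozen=True)
class DegConfig:
    """Thresholds for differential-expression calls.

    fc_cutoff
        Minimum |log2 fold change| for a call (inclusive). Default 2.50,
        i.e. a ~5.7-fold change on the linear scale.
    p_cutoff
        Strict upper bound on the p-value. Default 0.001.
    top_n
        Length of the ranked up/down lists. Default 20.
    pseudocount
        Added to abundances before ratios and log transforms; guards
        against zero FPKM. Default 1.0.
    bh_correct
        If True, apply Benjamini–Hochberg correction to the p-values
        before thresholding. Default False (raw p-values).
    """

    fc_cutoff: float = 2.50
    p_cutoff: float = 0.001
    top_n: int = 20
    pseudocount: float = 1.0
    bh_correct: bool = False

    def __post_init__(self):
        if not self.fc_cutoff > 0:
            raise ValueError("fc_cutoff must be > 0")
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must be in (0, 1)")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not self.pseudocount > 0:
            raise ValueError("pseudocount must be > 0")


@dataclass(frozen=True)
class DegRecord:
    gene_id: str
    log2fc: float
    p_value: float
    direction: Direction


def _group_arrays(matrix: ExpressionMatrix, groups: SampleGroups) -> tuple[np.ndarray, np.ndarray]:
    """Split the matrix into (control, cancer) value arrays, genes × samples."""
    groups.validate_against(matrix)
    sample_set = set(matrix.sample_ids)
    ctrl = [s for s in matrix.sample_ids if groups.assignment[s] == "control"]
    canc = [s for s in matrix.sample_ids if groups.assignment[s] == "cancer"]
    if not ctrl or not canc:
        raise ValueError("both groups must be non-empty")
    assert set(ctrl) | set(canc) <= sample_set
    genes = matrix.gene_ids
    return matrix.values_for(genes, ctrl), matrix.values_for(genes, canc)


def compute_log2fc(
    matrix: ExpressionMatrix, groups: SampleGroups, pseudocount: float = 1.0
) -> pd.Series:
    """Per-gene log2((mean_cancer + c) / (mean_control + c)) with pseudocount c.

    Finite for every gene because the pseudocount is strictly positive.
    """
    if not pseudocount > 0:
        raise ValueError("pseudocount must be > 0")
    ctrl, canc = _group_arrays(matrix, groups)
    lfc = np.log2(canc.mean(axis=1) + pseudocount) - np.log2(ctrl.mean(axis=1) + pseudocount)
    return pd.Series(lfc, index=matrix.gene_ids, name="log2fc")


def compute_pvalues(
    matrix: ExpressionMatrix,
    groups: SampleGroups,
    pseudocount: float = 1.0,
    bh_correct: bool = False,
) -> pd.Series:
    """Two-sided Welch (unequal-variance) t-test per gene on log2(value + c).

    Genes with zero variance in both groups get p = 1 when the group means
    are equal (no evidence of change) and p = 0 when they differ (a constant
    offset is detected with certainty under this degenerate model).
    """
    ctrl, canc = _group_arrays(matrix, groups)
    if ctrl.shape[1] < 2 or canc.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples for the p-value test")
    la = np.log2(canc + pseudocount)
    lb = np.log2(ctrl + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    var_a = la.var(axis=1, ddof=1)
    var_b = lb.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    equal_means = np.isclose(la.mean(axis=1), lb.mean(axis=1))
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, 0.0, p)
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
    if bh_correct:
        p = multipletests(p, method="fdr_bh")[1]
    return pd.Series(p, index=matrix.gene_ids, name="p_value")


def classify(log2fc: float, p_value: float, config: DegConfig) -> Direction:
    if p_value < config.p_cutoff and log2fc >= config.fc_cutoff:
        return UP
    if p_value < config.p_cutoff and log2fc <= -config.fc_cutoff:
        return DOWN
    return NONE


def compute_deg_records(
    matrix: ExpressionMatrix, groups: SampleGroups, config: DegConfig | None = None
) -> list[DegRecord]:
    """Full per-gene table: fold change, p-value, and direction call."""
    config = config or DegConfig()
    lfc = compute_log2fc(matrix, groups, config.pseudocount)
    pvals = compute_pvalues(matrix, groups, config.pseudocount, config.bh_correct)
    return [
        DegRecord(gene_id=g, log2fc=float(lfc[g]), p_value=float(pvals[g]),
                  direction=classify(float(lfc[g]), float(pvals[g]), config))
        for g in matrix.gene_ids
    ]


def filter_degs(records: Iterable[DegRecord], config: DegConfig | None = None) -> tuple[set[str], set[str]]:
    """Split records into (upregulated, downregulated) gene-ID sets.

    Boundary inclusive on |log2FC| (>= cutoff passes), strict on p; the two
    sets are disjoint by construction since fc_cutoff > 0.
    """
    config = config or DegConfig()
    up = {r.gene_id for r in records if classify(r.log2fc, r.p_value, config) == UP}
    down = {r.gene_id for r in records if classify(r.log2fc, r.p_value, config) == DOWN}
    return up, down


def top_n_by_fold(records: Iterable[DegRecord], n: int, direction: Direction) -> list[str]:
    """Rank gene IDs of the requested direction by |log2FC| descending.

    Ties are broken by gene symbol ascending; returns min(n, available).
    """
    if direction not in (UP, DOWN):
        raise ValueError("direction must be 'up' or 'down'")
    pool = [r for r in records if r.direction == direction]
    pool.sort(key=lambda r: (-abs(r.log2fc), r.gene_id))
    return [r.gene_id for r in pool[:n]]


def fold_change(log2fc: float) -> float:
    """Linear fold change 2**log2fc."""
    return float(2.0 ** log2fc)


def deg_frame(records: Iterable[DegRecord]) -> pd.DataFrame:
    """Tabular view (gene_id, log2fc, p_value, direction) in record order."""
    return pd.DataFrame(
        [(r.gene_id, r.log2fc, r.p_value, r.direction) for r in records],
        columns=["gene_id", "log2fc", "p_value", "direction"],
    )
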