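import numpy as np
import pandas as pd
import pytest

from corrshift import (
    ExpressionMatrix, PlantedPair, SampleGroups, SimulationConfig, simulate_dataset,
)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 6 samples with simple hand-checkable values."""
    data = pd.DataFrame(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [2.0, 4.0, 6.0, 8.0, 10.0, 12.0],
            [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
        ],
        index=["GA", "GB", "GC"],
        columns=[f"S{i}" for i in range(6)],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def tiny_groups(tiny_matrix) -> SampleGroups:
    return SampleGroups({
        "S0": "control", "S1": "control", "S2": "control",
        "S3": "cancer", "S4": "cancer", "S5": "cancer",
    })


@pytest.fixture
def small_cohort():
    """A compact simulated cohort: 40 genes, 20/30 samples, two pathways,
    two planted DEGs and one planted correlation-shift pair."""
    genes = [f"G{i:03d}" for i in range(40)]
    config = SimulationConfig(
        n_genes=40,
        n_control=20,
        n_cancer=30,
        planted_degs={"G000": 3.0, "G001": -3.0, "G002": 4.0, "G003": -4.0},
        planted_pairs=(PlantedPair("G000", "G002", 0.8, -0.2),),
        pathways=[
            ("pathway_alpha", ["G000", "G001", "G002", "G003", "G010", "G011"]),
            ("pathway_beta", ["G002", "G003", "G012", "G013", "G014"]),
        ],
        noise_sd=0.4,
        seed=7,
        gene_ids=genes,
    )
    return simulate_dataset(config)


@pytest.fixture
def small_cohort_files(small_cohort, tmp_path):
    """The small cohort written to disk (matrix.tsv, samples.tsv, pathways.gmt)."""
    from corrshift import write_expression_matrix, write_gmt, write_sample_sheet

    matrix, groups, sets, _ = small_cohort
    paths = {
        "matrix": write_expression_matrix(matrix, tmp_path / "matrix.tsv"),
        "sheet": write_sample_sheet(groups, tmp_path / "samples.tsv"),
        "gmt": write_gmt(sets, tmp_path / "pathways.gmt"),
    }
    return paths
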