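"""Shared fixtures: all data is generated in-process, nothing is downloaded."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scregnet.synthetic import SimulationConfig, simulate_grn, simulate_multiome
from scregnet.types import (
    AccessibilityMatrix,
    CellAnnotation,
    ExpressionMatrix,
    GeneAnnotation,
    RegionSet,
)


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Small, fast study: 4 TFs, 10 genes, 30 REs, 2 cell types."""
    return SimulationConfig(
        n_tf=4,
        n_gene=10,
        n_re=30,
        n_celltypes=2,
        cells_per_type=30,
        n_bulk=40,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_network(tiny_config):
    return simulate_grn(tiny_config)


@pytest.fixture(scope="session")
def tiny_multiome(tiny_network, tiny_config):
    return simulate_multiome(tiny_network, tiny_config)


@pytest.fixture(scope="session")
def tiny_pipeline(tiny_config):
    """End-to-end run at toy scale for integration-level assertions."""
    from scregnet.pipeline import run_synthetic_pipeline

    return run_synthetic_pipeline(tiny_config, epochs=200, n_perm=50, k_neighbors=10)


@pytest.fixture(scope="session")
def ablation_study():
    """Default-scale study over 5 seeds, consolidated vs single-cell-only."""
    from scregnet.pipeline import gamma_aupr_ratio, run_synthetic_pipeline

    runs = []
    for seed in range(1, 6):
        cfg = SimulationConfig(seed=seed)
        consolidated = run_synthetic_pipeline(cfg, method="consolidated")
        single_cell = run_synthetic_pipeline(cfg, method="single_cell")
        runs.append(
            {
                "seed": seed,
                "consolidated": consolidated,
                "ratio_consolidated": gamma_aupr_ratio(consolidated.population, consolidated.network),
                "ratio_single_cell": gamma_aupr_ratio(single_cell.population, single_cell.network),
            }
        )
    return runs


@pytest.fixture
def gene_table() -> GeneAnnotation:
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3"],
                "chrom": ["chr1", "chr1", "chr2"],
                "tss": [1_000_000, 3_000_000, 500_000],
                "strand": ["+", "-", "+"],
            }
        )
    )


@pytest.fixture
def region_table() -> RegionSet:
    return RegionSet(
        pd.DataFrame(
            {
                "re_id": ["r1", "r2", "r3", "r4"],
                "chrom": ["chr1", "chr1", "chr1", "chr2"],
                "start": [1_009_900, 1_989_900, 2_200_100, 400_000],
                "end": [1_010_100, 1_990_100, 2_200_300, 400_200],
            }
        )
    )


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]), ["g1", "g2", "g3"], ["c1", "c2"]
    )
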