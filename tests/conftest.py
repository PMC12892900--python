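"""Shared fixtures: small constructed matrices and simulated datasets.

Expensive simulated fixtures are session-scoped so the property and
acceptance tests share a single draw of each study condition.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import germkit as gk
from germkit.cli import _subset_cells

RECEPTIVE_CONTRAST = gk.ContrastSpec("stage", "mid_secretory", "early_secretory")


def subset_cells(cells: gk.CellMatrix, mask: np.ndarray) -> gk.CellMatrix:
    return _subset_cells(cells, mask)


def target_cells(cells: gk.CellMatrix, target: str = "secretory_glandular_epithelium"):
    meta = cells.cell_meta
    mask = (
        meta["stage"].isin(["early_secretory", "mid_secretory"]).to_numpy()
        & (meta["cluster"] == target).to_numpy()
    )
    return _subset_cells(cells, mask)


@pytest.fixture
def tiny_matrix() -> gk.CellMatrix:
    """4 genes x 4 cells with hand-set counts and full metadata."""
    counts = np.array(
        [
            [5, 0, 2, 1],
            [0, 3, 0, 0],
            [1, 1, 1, 1],
            [0, 0, 4, 2],
        ]
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s2", "s2"],
            "stage": ["early_secretory"] * 2 + ["mid_secretory"] * 2,
            "cluster": ["epi", "stroma", "epi", "stroma"],
        },
        index=pd.Index([f"c{i}" for i in range(4)], name="cell_id"),
    )
    return gk.CellMatrix(sparse.csr_matrix(counts), [f"g{i}" for i in range(4)],
                         [f"c{i}" for i in range(4)], meta)


@pytest.fixture(scope="session")
def planted_sim():
    """The reference planted fixture: default study conditions, fixed seed."""
    cfg = gk.SimConfig(seed=101)
    cells, truth = gk.simulate_cells(cfg)
    return cfg, cells, truth


@pytest.fixture(scope="session")
def planted_de(planted_sim):
    """Single-cell and cohort DE tables for the planted fixture."""
    cfg, cells, truth = planted_sim
    sc = target_cells(cells, cfg.target_type)
    sc_de = gk.wilcoxon_de(gk.lognormalize(sc), RECEPTIVE_CONTRAST)
    cohort, stage_of = gk.simulate_cohort(cfg, cells=cells)
    bulk_de = gk.ttest_de(cohort, stage_of, RECEPTIVE_CONTRAST)
    return sc_de, bulk_de


@pytest.fixture(scope="session")
def planted_signature(planted_de):
    sc_de, bulk_de = planted_de
    return gk.derive_germ(bulk_de, sc_de)


@pytest.fixture(scope="session")
def planted_ranked(planted_de):
    sc_de, _ = planted_de
    return gk.rank_genes(sc_de)


@pytest.fixture(scope="session")
def null_sim():
    """Null fixture: same generative family, no planted program."""
    cfg = gk.SimConfig(
        seed=303,
        n_genes=4000,
        cells_per_stage=400,
        stages=("early_secretory", "mid_secretory"),
        n_up=0,
        n_down=0,
    )
    cells, truth = gk.simulate_cells(cfg)
    return cfg, cells, truth


@pytest.fixture(scope="session")
def null_ranked(null_sim):
    cfg, cells, _ = null_sim
    de = gk.wilcoxon_de(gk.lognormalize(target_cells(cells, cfg.target_type)),
                        RECEPTIVE_CONTRAST)
    return gk.rank_genes(de)


@pytest.fixture(scope="session")
def null_matrix():
    """Single-stage null expression matrix for module-score calibration."""
    cfg = gk.SimConfig(
        seed=55,
        n_genes=2000,
        cells_per_stage=300,
        stages=("mid_secretory",),
        target_stages=(),
        n_up=0,
        n_down=0,
        libsize_log_mean=math.log(5000),
    )
    cells, _ = gk.simulate_cells(cfg)
    return gk.lognormalize(cells)
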