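import numpy as np
import pandas as pd
import pytest

from slscreen import SimulationConfig, generate_library, simulate_counts
from slscreen.io import LibraryDesign


@pytest.fixture
def tiny_design() -> LibraryDesign:
    """Two genes x two constructs plus one Luciferase control, one module."""
    return LibraryDesign(
        pd.DataFrame(
            {
                "barcode": ["AAAA", "AAAC", "AAAG", "AAAT", "AACA"],
                "construct_id": ["g1_c1", "g1_c2", "g2_c1", "g2_c2", "luc_1"],
                "gene": ["GENE1", "GENE1", "GENE2", "GENE2", ""],
                "module": [1, 1, 1, 1, 1],
                "is_control": [False, False, False, False, True],
            }
        )
    )


@pytest.fixture(scope="session")
def small_screen():
    """A 100-gene simulated screen with planted effects (session-shared)."""
    cfg = SimulationConfig(
        n_genes=100,
        frac_sl_genes=0.05,
        frac_rescue_genes=0.03,
        reads_per_lane=200_000,
        seed=7,
    )
    design, truth = generate_library(cfg)
    ctrl, treat = simulate_counts(design, truth, cfg)
    return cfg, design, truth, ctrl, treat


def ratio_frame(rows):
    """Hand-build a ratio-table DataFrame from (cid, gene, module, is_control,
    count_ctrl, count_treat, passes, log2_ratio) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "construct_id",
            "gene",
            "module",
            "is_control",
            "count_ctrl",
            "count_treat",
            "passes_filter",
            "log2_ratio",
        ],
    )
    df["norm_ctrl"] = np.nan
    df["norm_treat"] = np.nan
    return df
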