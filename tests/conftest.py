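import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

import celldrs
from celldrs import (
    SimulationConfig,
    compute_gene_stats,
    load_primary_genes,
    normalize_counts,
    sample_matched_controls,
    score_cells,
    simulate_atlas,
)


def run_pipeline(cfg: SimulationConfig, n_ctrl: int = 100,
                 ctrl_seed: int = 42, n_mean_bins: int = 20,
                 n_sd_bins: int = 5):
    """Simulate an atlas and push it through the full scoring pipeline."""
    adata, truth = simulate_atlas(cfg)
    normalize_counts(adata)
    stats = compute_gene_stats(adata, n_mean_bins, n_sd_bins)
    target = load_primary_genes({"planted": truth.target_genes},
                                name="planted")
    ctrl = sample_matched_controls(stats, target, n_ctrl=n_ctrl,
                                   seed=ctrl_seed)
    scores = score_cells(adata, target, ctrl, stats)
    return {"adata": adata, "truth": truth, "stats": stats,
            "target": target, "ctrl": ctrl, "scores": scores}


def make_adata(counts: np.ndarray, obs: pd.DataFrame | None = None,
               genes: list[str] | None = None) -> AnnData:
    """Small dense-count AnnData for hand-built examples."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    if genes is None:
        genes = [f"G{i:03d}" for i in range(1, n_genes + 1)]
    if obs is None:
        obs = pd.DataFrame(index=[f"C{i:03d}" for i in range(1, n_cells + 1)])
    obs.index.name = "cell_id"
    return AnnData(X=sp.csr_matrix(counts.astype(float)), obs=obs,
                   var=pd.DataFrame(index=pd.Index(genes, name="symbol")))


@pytest.fixture(scope="session")
def small_null():
    """Null atlas pipeline at desk scale (no planted effect)."""
    cfg = SimulationConfig(n_cells=500, n_genes=800, target_size=30, seed=11)
    return run_pipeline(cfg, n_ctrl=100, ctrl_seed=7, n_mean_bins=10,
                        n_sd_bins=4)


@pytest.fixture(scope="session")
def small_planted():
    """Atlas with a 2x planted effect on the target set in cluster ct2."""
    cfg = SimulationConfig(n_cells=600, n_genes=800, target_size=30,
                           effect=2.0, affected_groups=("ct2",), seed=12)
    return run_pipeline(cfg, n_ctrl=100, ctrl_seed=8, n_mean_bins=10,
                        n_sd_bins=4)
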