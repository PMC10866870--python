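"""Comparative analyses over computed cell scores.

Covers the analyses that sit downstream of per-cell scoring: rank-sum
contrasts of scores between annotation groups (developmental time points,
anterior vs posterior regions), gene prioritization by Pearson correlation of
expression with scores, comparison of two correlation profiles through
Fisher's z-transformation, and the HOX-panel anterior/posterior contrast that
labels cells along the body axis from the expression of anterior
(HOXA1-HOXA6) versus posterior (HOXA9-HOXA13) HOX genes.

All operations here are deterministic given their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats as sps

from .geneset import GeneSet
from .scoring import LOGNORM_LAYER, CellScores

__all__ = [
    "ContrastResult",
    "GenePriority",
    "CorrelationComparison",
    "contrast_scores",
    "prioritize_genes",
    "compare_correlation_profiles",
    "fisher_z",
    "hox_region_contrast",
    "HOX_ANTERIOR_PANEL",
    "HOX_POSTERIOR_PANEL",
]

# Anterior/posterior positional identity panels along the HOXA cluster.
HOX_ANTERIOR_PANEL = ("HOXA1", "HOXA2", "HOXA3", "HOXA4", "HOXA5", "HOXA6")
HOX_POSTERIOR_PANEL = ("HOXA9", "HOXA10", "HOXA11", "HOXA13")


@dataclass
class ContrastResult:
    """Two-sided Wilcoxon rank-sum contrast of scores between two groups."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    direction: str  # which group has the larger median score

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def contrast_scores(scores: CellScores, ann: pd.DataFrame | pd.Series,
                    key: str | None, a: str, b: str) -> ContrastResult:
    """Compare normalized scores between annotation groups ``a`` and ``b``.

    ``ann`` is either a per-cell Series of labels or a DataFrame with column
    ``key``, aligned with the scored cells.  The test is a two-sided Wilcoxon
    rank-sum with tie-corrected normal approximation, so identical score
    multisets give p = 1 exactly.
    """
    labels = ann[key] if isinstance(ann, pd.DataFrame) else ann
    labels = pd.Series(np.asarray(labels).astype(str), index=scores.cell_ids)
    norm = pd.Series(scores.norm, index=scores.cell_ids)
    x = norm[(labels == str(a)) & np.isfinite(norm)]
    y = norm[(labels == str(b)) & np.isfinite(norm)]
    for name, vals in ((a, x), (b, y)):
        if len(vals) == 0:
            raise ValueError(f"group {name!r} has no scored cells")
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=False)
    med_x, med_y = np.median(x), np.median(y)
    direction = str(a) if med_x > med_y else str(b) if med_y > med_x else "tie"
    return ContrastResult(group_a=str(a), group_b=str(b), n_a=len(x),
                          n_b=len(y), statistic=float(res.statistic),
                          p_value=float(res.pvalue), direction=direction)


@dataclass
class GenePriority:
    """Genes ranked by Pearson correlation of expression with cell scores.

    ``frame`` is indexed by gene symbol with columns ``r`` (NaN for
    zero-variance genes), ``n_cells``, ``rank`` (1 = most positively
    correlated; NaN correlations rank last) and ``in_set``.
    """

    frame: pd.DataFrame
    n_cells: int

    def to_frame(self) -> pd.DataFrame:
        return self.frame.rename_axis("symbol").reset_index()


def prioritize_genes(adata: AnnData, scores: CellScores,
                     mask: np.ndarray | None = None,
                     flag_set: GeneSet | None = None,
                     layer: str = LOGNORM_LAYER) -> GenePriority:
    """Rank genes by Pearson correlation of expression with normalized scores.

    ``mask`` optionally restricts the cells used (e.g. one developmental
    stage); cells with missing scores are always dropped.  Ranks are a
    permutation of 1..n_genes, ties broken by matrix column order and missing
    correlations placed last.
    """
    if not scores.cell_ids.equals(adata.obs_names):
        raise ValueError("scores were computed on different cells than adata")
    use = np.isfinite(scores.norm)
    if mask is not None:
        use &= np.asarray(mask, dtype=bool)
    n = int(use.sum())
    if n < 3:
        raise ValueError(f"need >= 3 cells with scores, got {n}")

    y = scores.norm[use]
    sy = y.std()
    X = adata.layers[layer][use]
    if sp.issparse(X):
        mx = np.asarray(X.mean(axis=0)).ravel()
        ex2 = np.asarray(X.multiply(X).mean(axis=0)).ravel()
        xy = np.asarray(X.T @ (y - y.mean())).ravel() / n
    else:
        X = np.asarray(X)
        mx = X.mean(axis=0)
        ex2 = (X ** 2).mean(axis=0)
        xy = (X.T @ (y - y.mean())) / n
    sx = np.sqrt(np.maximum(ex2 - mx ** 2, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip(xy / (sx * sy), -1.0, 1.0)
    r[sx == 0] = np.nan
    if sy == 0 or np.isnan(r).all():
        raise ValueError("no gene has a defined correlation with the scores")

    frame = pd.DataFrame({"r": r, "n_cells": n}, index=adata.var_names)
    frame["rank"] = frame["r"].rank(ascending=False, method="first",
                                    na_option="bottom").astype(int)
    frame["in_set"] = [g in flag_set for g in frame.index] if flag_set \
        else False
    return GenePriority(frame=frame, n_cells=n)


def fisher_z(r_a, r_b, n_a: int, n_b: int):
    """Fisher z statistic for the difference of two Pearson correlations.

    ``z = (atanh(r_a) - atanh(r_b)) / sqrt(1/(n_a - 3) + 1/(n_b - 3))``;
    undefined (NaN) when either sample has fewer than 4 observations or a
    correlation of magnitude 1.
    """
    if n_a < 4 or n_b < 4:
        raise ValueError("Fisher z requires n >= 4 in both samples")
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.arctanh(r_a) - np.arctanh(r_b)) / \
            np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    z = np.where(np.isfinite(z), z, np.nan)
    p = 2.0 * sps.norm.sf(np.abs(z))
    return z, p


@dataclass
class CorrelationComparison:
    """Per-gene Fisher z comparison of two correlation profiles.

    ``frame`` covers the shared genes with defined correlations (columns
    ``r_a``, ``r_b``, ``z``, ``p``); ``summary_r`` is the correlation of
    correlations over those genes, the alignment measure used to compare
    atlases or developmental stages.
    """

    frame: pd.DataFrame
    summary_r: float
    n_shared: int
    n_a: int
    n_b: int

    def to_frame(self) -> pd.DataFrame:
        return self.frame.rename_axis("symbol").reset_index()


def compare_correlation_profiles(pa: GenePriority,
                                 pb: GenePriority) -> CorrelationComparison:
    """Compare two gene-prioritization profiles gene-by-gene via Fisher z."""
    shared = pa.frame.index.intersection(pb.frame.index)
    if shared.empty:
        raise ValueError("the two profiles share no genes")
    r_a = pa.frame.loc[shared, "r"]
    r_b = pb.frame.loc[shared, "r"]
    defined = r_a.notna() & r_b.notna()
    shared = shared[defined]
    if shared.empty:
        raise ValueError("no shared gene has a defined correlation in both "
                         "profiles")
    r_a, r_b = r_a[defined], r_b[defined]
    z, p = fisher_z(r_a.to_numpy(), r_b.to_numpy(), pa.n_cells, pb.n_cells)
    frame = pd.DataFrame({"r_a": r_a, "r_b": r_b, "z": z, "p": p},
                         index=shared)
    summary_r = float(np.corrcoef(r_a, r_b)[0, 1])
    return CorrelationComparison(frame=frame, summary_r=summary_r,
                                 n_shared=len(shared), n_a=pa.n_cells,
                                 n_b=pb.n_cells)


def _panel_mean(adata: AnnData, panel: Sequence[str],
                layer: str) -> np.ndarray:
    idx = [i for i, g in enumerate(adata.var_names) if g in set(panel)]
    if not idx:
        raise ValueError(f"none of the panel genes {list(panel)} are in the "
                         "matrix")
    X = adata.layers[layer][:, idx]
    return np.asarray(X.mean(axis=1)).ravel()


def hox_region_contrast(adata: AnnData, scores: CellScores,
                        anterior_panel: Sequence[str] = HOX_ANTERIOR_PANEL,
                        posterior_panel: Sequence[str] = HOX_POSTERIOR_PANEL,
                        min_expr: float = 0.0,
                        layer: str = LOGNORM_LAYER) -> ContrastResult:
    """Contrast scores between cells of anterior vs posterior HOX identity.

    A cell is labeled anterior when its mean log-normalized expression over
    the anterior panel exceeds ``min_expr`` and the posterior-panel mean;
    posterior symmetrically.  Unlabeled cells are dropped before the rank-sum
    contrast.
    """
    if min_expr < 0:
        raise ValueError("min_expr must be >= 0")
    a_mean = _panel_mean(adata, anterior_panel, layer)
    p_mean = _panel_mean(adata, posterior_panel, layer)
    labels = np.full(adata.n_obs, "unlabeled", dtype=object)
    labels[(a_mean > min_expr) & (a_mean > p_mean)] = "anterior"
    labels[(p_mean > min_expr) & (p_mean > a_mean)] = "posterior"
    for name in ("anterior", "posterior"):
        if not (labels == name).any():
            raise ValueError(f"no cell labeled {name!r} by the HOX panels")
    return contrast_scores(scores, pd.Series(labels, index=scores.cell_ids),
                           None, "anterior", "posterior")
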