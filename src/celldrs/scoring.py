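"""Per-cell disease-relevance scores with matched-control Monte-Carlo nulls.

The central quantity is a per-cell score for a target gene set (here the
esophageal-malformation genes) measured against control gene sets matched on
per-gene mean and standard deviation of log-normalized expression:

1.  counts are log-normalized, ``log1p(count / cell_total * scale)``;
2.  genes are partitioned into equal-frequency (mean, sd) bins;
3.  each control replicate replaces every target gene by a random gene from
    the same bin, so control sets share the target set's expression profile;
4.  the raw cell score is an (inverse-sd weighted) mean of the set's
    normalized expression; the normalized score is a z-score of the target's
    raw score against that cell's control raw scores, and the Monte-Carlo
    p-value is ``(1 + #{controls >= target}) / (1 + n_ctrl)``.

Cluster-level statistics reuse the control replicates: the association
statistic is the within-group mean of normalized scores and the heterogeneity
statistic the within-group variance, each compared against the same statistic
recomputed on every control replicate (z-scored leave-one-out against the
remaining replicates).

Expression matrices are :class:`anndata.AnnData` objects in the canonical
cells x genes orientation; counts live in ``.X`` and the log-normalized layer
in ``.layers["lognorm"]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .geneset import GeneSet

__all__ = [
    "GeneStats",
    "ControlSets",
    "CellScores",
    "GroupStats",
    "normalize_counts",
    "compute_gene_stats",
    "sample_matched_controls",
    "score_cells",
    "group_association",
    "mc_p_floor",
]

LOGNORM_LAYER = "lognorm"
CONSTANT_BIN = "constant"


def mc_p_floor(n_ctrl: int) -> float:
    """Smallest attainable Monte-Carlo p-value, (0 + 1) / (n_ctrl + 1)."""
    return 1.0 / (n_ctrl + 1)


def _dense_rows(x) -> np.ndarray:
    return x.toarray() if sp.issparse(x) else np.asarray(x)


def normalize_counts(adata: AnnData, scale: float = 10_000.0,
                     layer: str = LOGNORM_LAYER) -> AnnData:
    """Add the log-normalized layer ``log1p(count / cell_total * scale)`` in place.

    Cells with zero total counts keep an all-zero row and are flagged in
    ``adata.obs["degenerate"]``; negative counts are a hard error.  Returns
    ``adata`` for chaining.
    """
    X = adata.X
    if sp.issparse(X):
        if X.data.size and X.data.min() < 0:
            raise ValueError("count matrix contains negative values")
        totals = np.asarray(X.sum(axis=1)).ravel()
        degenerate = totals == 0
        inv = np.divide(scale, totals, out=np.zeros_like(totals, dtype=float),
                        where=~degenerate)
        norm = sp.diags(inv) @ X.tocsr().astype(float)
        norm.data = np.log1p(norm.data)
        adata.layers[layer] = norm.tocsr()
    else:
        X = np.asarray(X, dtype=float)
        if X.size and X.min() < 0:
            raise ValueError("count matrix contains negative values")
        totals = X.sum(axis=1)
        degenerate = totals == 0
        inv = np.divide(scale, totals, out=np.zeros_like(totals), where=~degenerate)
        adata.layers[layer] = np.log1p(X * inv[:, None])
    adata.obs["degenerate"] = degenerate
    adata.uns["lognorm_scale"] = float(scale)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} cell(s) with zero total counts "
                      "flagged as degenerate", stacklevel=2)
    return adata


@dataclass
class GeneStats:
    """Per-gene mean/sd of log-normalized expression and the (mean, sd) bin id.

    ``frame`` is indexed by gene symbol with columns ``mean``, ``sd``,
    ``bin``; zero-variance genes share the reserved ``"constant"`` bin.
    """

    frame: pd.DataFrame
    n_mean_bins: int
    n_sd_bins: int

    @property
    def bins(self) -> dict[str, list[str]]:
        """Bin id -> lexicographically sorted member symbols."""
        out: dict[str, list[str]] = {}
        for sym, b in self.frame["bin"].items():
            out.setdefault(b, []).append(sym)
        for members in out.values():
            members.sort()
        return out


def compute_gene_stats(adata: AnnData, n_mean_bins: int = 20,
                       n_sd_bins: int = 5, layer: str = LOGNORM_LAYER) -> GeneStats:
    """Partition genes into equal-frequency mean bins sub-split by sd bins.

    Means and sds are taken over non-degenerate cells of the log-normalized
    layer.  Genes are sorted by (mean, symbol), cut into ``n_mean_bins``
    near-equal chunks, and each chunk is sorted by (sd, symbol) and cut into
    ``n_sd_bins`` chunks, which makes the binning invariant to the column
    order of the input matrix.  Zero-variance genes go to a reserved bin.
    """
    if layer not in adata.layers:
        raise ValueError(f"layer {layer!r} missing; run normalize_counts first")
    keep = ~adata.obs["degenerate"].to_numpy() if "degenerate" in adata.obs \
        else np.ones(adata.n_obs, bool)
    X = adata.layers[layer][keep]
    n = int(keep.sum())
    if sp.issparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        ex2 = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    else:
        X = np.asarray(X)
        mean = X.mean(axis=0)
        ex2 = (X ** 2).mean(axis=0)
    var = np.maximum(ex2 - mean ** 2, 0.0)
    sd = np.sqrt(var)

    symbols = np.asarray(adata.var_names)
    frame = pd.DataFrame({"mean": mean, "sd": sd}, index=symbols)
    constant = sd == 0
    variable = frame.index[~constant]
    if 0 < len(variable) < n_mean_bins * n_sd_bins:
        raise ValueError(
            f"{len(variable)} variable genes cannot fill "
            f"{n_mean_bins} x {n_sd_bins} bins"
        )

    bin_id = pd.Series(CONSTANT_BIN, index=frame.index, dtype=object)
    if len(variable) == 0:  # fully degenerate matrix: one reserved bin
        frame["bin"] = bin_id
        frame.attrs["n_cells"] = n
        return GeneStats(frame=frame, n_mean_bins=n_mean_bins,
                         n_sd_bins=n_sd_bins)
    # (mean, symbol) sort keeps the partition invariant to column order
    order = frame.loc[variable].reset_index(names="symbol") \
        .sort_values(["mean", "symbol"], kind="stable")
    for i, mean_chunk in enumerate(np.array_split(order["symbol"].to_numpy(),
                                                  n_mean_bins)):
        sub = frame.loc[mean_chunk].reset_index(names="symbol") \
            .sort_values(["sd", "symbol"], kind="stable")
        for j, sd_chunk in enumerate(np.array_split(sub["symbol"].to_numpy(),
                                                    n_sd_bins)):
            bin_id.loc[sd_chunk] = f"m{i}.s{j}"
    frame["bin"] = bin_id
    frame.attrs["n_cells"] = n
    return GeneStats(frame=frame, n_mean_bins=n_mean_bins, n_sd_bins=n_sd_bins)


@dataclass
class ControlSets:
    """Replicate control gene lists matched to a target set bin-by-bin."""

    sets: list[list[str]]
    target_name: str
    seed: int

    @property
    def n_ctrl(self) -> int:
        return len(self.sets)


def sample_matched_controls(stats: GeneStats, target: GeneSet,
                            n_ctrl: int = 1000, seed: int = 0,
                            ctrl_size: int | None = None) -> ControlSets:
    """Draw ``n_ctrl`` control gene sets matched on the (mean, sd) bins.

    Each replicate replaces every target gene by a gene sampled uniformly from
    that gene's own bin, excluding the gene itself; duplicates within a
    replicate are rejected and redrawn.  ``ctrl_size`` overrides the default
    equivalent-cardinality matching by sampling that many genes (cycling
    through the target genes' bins) instead.
    """
    bins = stats.bins
    bin_of = stats.frame["bin"]
    missing = [g for g in target.symbols if g not in bin_of.index]
    if missing:
        raise ValueError(f"target genes absent from gene stats: {missing}")
    if set(stats.frame.index) == target.members:
        raise ValueError("target set covers the whole gene universe; "
                         "no control genes available")

    slots = list(target.symbols)
    if ctrl_size is not None:
        reps = -(-ctrl_size // len(slots))
        slots = (slots * reps)[:ctrl_size]

    pools: dict[str, np.ndarray] = {}
    for g in set(slots):
        pool = [s for s in bins[bin_of[g]] if s != g]
        if not pool:
            raise ValueError(f"no eligible control gene in the bin of {g!r} "
                             f"(bin {bin_of[g]!r})")
        pools[g] = np.asarray(pool, dtype=object)

    rng = np.random.default_rng(seed)
    target_set = target.members
    sets: list[list[str]] = []
    for _ in range(n_ctrl):
        for _attempt in range(100):
            used: set[str] = set()
            chosen: list[str] = []
            ok = True
            for g in slots:
                pool = pools[g]
                if len(used) > 0:
                    pool = pool[~np.isin(pool, list(used))]
                if pool.size == 0:
                    ok = False
                    break
                pick = pool[int(rng.integers(pool.size))]
                chosen.append(pick)
                used.add(pick)
            if ok and set(chosen) != target_set:
                sets.append(chosen)
                break
        else:
            raise RuntimeError("could not draw a valid control replicate; "
                               "bins are too small for the target set")
    return ControlSets(sets=sets, target_name=target.name, seed=seed)


@dataclass
class CellScores:
    """Per-cell raw score, normalized z-score and Monte-Carlo p-value.

    ``ctrl_raw`` (cells x n_ctrl) keeps the control raw scores so that
    cluster-level statistics can be tested against the same replicates.
    Degenerate cells carry NaN in all three score columns.
    """

    cell_ids: pd.Index
    raw: np.ndarray
    norm: np.ndarray
    mc_p: np.ndarray
    n_ctrl: int
    seed: int
    weighting: str
    ctrl_raw: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_ids, "raw_score": self.raw,
             "norm_score": self.norm, "mc_p": self.mc_p},
        )


def _raw_score(X, idx: np.ndarray, w: np.ndarray) -> np.ndarray:
    v = np.zeros(X.shape[1])
    v[idx] = w / w.sum()
    return np.asarray(X @ v).ravel()


def score_cells(adata: AnnData, target: GeneSet, ctrl: ControlSets,
                stats: GeneStats, weighting: str = "inverse_sd",
                eps: float = 1e-3, layer: str = LOGNORM_LAYER) -> CellScores:
    """Score every cell for the target set against its matched controls.

    The raw score is ``sum_g w_g x_cg / sum_g w_g`` over the set's genes with
    ``w_g = 1 / (sd_g + eps)`` (or 1 under ``weighting="uniform"``).  The
    normalized score is the z-score of the target raw score against the cell's
    control raw scores and ``mc_p = (1 + #{ctrl >= target}) / (1 + n_ctrl)``.
    Cells whose control scores have zero spread get ``norm = 0`` and
    ``mc_p = 1``; degenerate cells get NaN throughout.
    """
    if weighting not in ("inverse_sd", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if layer not in adata.layers:
        raise ValueError(f"layer {layer!r} missing; run normalize_counts first")

    sym_to_idx = {s: i for i, s in enumerate(adata.var_names)}
    present = [g for g in target.symbols if g in sym_to_idx]
    if not present:
        raise ValueError(f"no gene of target set {target.name!r} is present "
                         "in the expression matrix")
    if len(present) < len(target.symbols):
        warnings.warn(f"{len(target.symbols) - len(present)} target gene(s) "
                      "absent from the matrix; scoring the rest", stacklevel=2)

    sd = stats.frame["sd"]
    if weighting == "inverse_sd":
        weight_of = (1.0 / (sd + eps)).to_dict()
    else:
        weight_of = {g: 1.0 for g in sd.index}

    X = adata.layers[layer]
    idx_t = np.asarray([sym_to_idx[g] for g in present])
    w_t = np.asarray([weight_of[g] for g in present])
    raw_t = _raw_score(X, idx_t, w_t)

    n_ctrl = ctrl.n_ctrl
    W = np.zeros((adata.n_vars, n_ctrl))
    for k, genes in enumerate(ctrl.sets):
        idx = np.asarray([sym_to_idx[g] for g in genes])
        w = np.asarray([weight_of[g] for g in genes])
        W[idx, k] = w / w.sum()
    ctrl_raw = np.asarray(X @ W)

    mu = ctrl_raw.mean(axis=1)
    sd_c = ctrl_raw.std(axis=1, ddof=1)
    ok = sd_c > 0
    norm = np.zeros(adata.n_obs)
    norm[ok] = (raw_t[ok] - mu[ok]) / sd_c[ok]
    mc_p = (1.0 + (ctrl_raw >= raw_t[:, None]).sum(axis=1)) / (1.0 + n_ctrl)
    mc_p[~ok] = 1.0

    degenerate = adata.obs["degenerate"].to_numpy() if "degenerate" in adata.obs \
        else np.zeros(adata.n_obs, bool)
    raw_t = raw_t.copy()
    for arr in (raw_t, norm, mc_p):
        arr[degenerate] = np.nan
    ctrl_raw[degenerate] = np.nan

    return CellScores(cell_ids=adata.obs_names.copy(), raw=raw_t, norm=norm,
                      mc_p=mc_p, n_ctrl=n_ctrl, seed=ctrl.seed,
                      weighting=weighting, ctrl_raw=ctrl_raw)


@dataclass
class GroupStats:
    """Per-group association and heterogeneity statistics.

    ``frame`` is indexed by group label with columns ``n_cells``, ``assoc_z``,
    ``assoc_p``, ``hetero_z``, ``hetero_p``; groups with fewer than
    ``min_cells`` scored cells are listed in ``excluded``.
    """

    frame: pd.DataFrame
    group_key: str
    n_ctrl: int
    excluded: list[tuple[str, int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.frame.rename_axis("group").reset_index()


def _loo_zscores(ctrl_raw: np.ndarray) -> np.ndarray:
    """Z-score each control replicate against the remaining replicates, per cell."""
    n = ctrl_raw.shape[1]
    if n < 3:
        raise ValueError("need at least 3 control replicates for the null")
    S = ctrl_raw.sum(axis=1, keepdims=True)
    Q = (ctrl_raw ** 2).sum(axis=1, keepdims=True)
    m = (S - ctrl_raw) / (n - 1)
    # unbiased variance of the n-1 left-out values
    var = (Q - ctrl_raw ** 2 - (n - 1) * m ** 2) / (n - 2)
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (ctrl_raw - m) / sd
    z[~np.isfinite(z)] = 0.0
    return z


def group_association(scores: CellScores, adata: AnnData, group_key: str,
                      min_cells: int = 20) -> GroupStats:
    """Association (mean) and heterogeneity (variance) of scores per cell group.

    The observed statistics on normalized scores are compared against the same
    statistics recomputed on each control replicate's leave-one-out z-scores;
    Monte-Carlo p-values are ``(1 + #{null >= obs}) / (1 + n_ctrl)`` and z
    statistics are the observed value standardized against the null draws.
    """
    if group_key not in adata.obs:
        raise ValueError(f"annotation {group_key!r} not found in adata.obs")
    if not scores.cell_ids.equals(adata.obs_names):
        raise ValueError("scores were computed on different cells than adata")
    if scores.ctrl_raw is None:
        raise ValueError("CellScores lacks control raw scores; "
                         "rerun score_cells")

    valid = np.isfinite(scores.norm)
    Z = _loo_zscores(scores.ctrl_raw[valid])
    norm = scores.norm[valid]
    labels = adata.obs[group_key].astype(str).to_numpy()[valid]
    n_ctrl = scores.n_ctrl

    rows = {}
    excluded: list[tuple[str, int]] = []
    for group in sorted(set(labels)):
        mask = labels == group
        n = int(mask.sum())
        if n < min_cells:
            excluded.append((group, n))
            continue
        obs_assoc = norm[mask].mean()
        obs_hetero = norm[mask].var(ddof=1)
        null_assoc = Z[mask].mean(axis=0)
        null_hetero = Z[mask].var(axis=0, ddof=1)
        assoc_p = (1.0 + (null_assoc >= obs_assoc).sum()) / (1.0 + n_ctrl)
        hetero_p = (1.0 + (null_hetero >= obs_hetero).sum()) / (1.0 + n_ctrl)
        sd_a = null_assoc.std(ddof=1)
        sd_h = null_hetero.std(ddof=1)
        rows[group] = {
            "n_cells": n,
            "assoc_z": (obs_assoc - null_assoc.mean()) / sd_a if sd_a > 0 else 0.0,
            "assoc_p": assoc_p,
            "hetero_z": (obs_hetero - null_hetero.mean()) / sd_h if sd_h > 0 else 0.0,
            "hetero_p": hetero_p,
        }
    if excluded:
        warnings.warn(
            "excluded groups with fewer than "
            f"{min_cells} scored cells: {excluded}", stacklevel=2)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    return GroupStats(frame=frame, group_key=group_key, n_ctrl=n_ctrl,
                      excluded=excluded)
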