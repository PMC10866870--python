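"""Synthetic single-cell atlas generator with planted disease signals.

Emulates the structure the scoring pipeline assumes in real embryonic
atlases: cells organised into clusters crossed with developmental time points
and anterior/posterior regions, sparse overdispersed counts, and a target
gene set that can be made preferentially expressed in chosen groups (in all
of a group's cells, or in a fraction of them for heterogeneity scenarios).

Counts follow a negative-binomial (gamma-Poisson) model:

    counts[c, g] ~ NB(mean = lib_c * pi_g * fold(c, g), size = r_g)

with log-normal library sizes ``lib_c``, log-normal relative gene abundances
``pi_g`` (normalized to sum to 1), per-gene inverse-dispersion ``r_g``, and
``fold(c, g) = effect`` for target genes in affected cells, 1 otherwise.
An optional HOX coupling ties small anterior/posterior marker panels to the
region labels so the axis-labeling analysis can be exercised end to end.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from anndata import AnnData

from .downstream import HOX_ANTERIOR_PANEL, HOX_POSTERIOR_PANEL
from .geneset import GeneSet

__all__ = [
    "GroupSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_atlas",
    "make_fixture_suite",
    "default_groups",
    "toy_interaction_frame",
]


@dataclass(frozen=True)
class GroupSpec:
    """One cell group: cluster label, developmental stage, axial region, share."""

    cell_type: str
    time_point: str
    region: str  # "anterior" | "posterior"
    proportion: float


def default_groups(n_cell_types: int = 5,
                   time_points: Sequence[str] = ("E8.5", "E9.0", "E9.5"),
                   ) -> list[GroupSpec]:
    """Equal-share groups: cell types cycled over time points and regions."""
    regions = ("anterior", "posterior")
    groups = []
    for i in range(n_cell_types):
        groups.append(GroupSpec(
            cell_type=f"ct{i + 1}",
            time_point=time_points[i % len(time_points)],
            region=regions[i % 2],
            proportion=1.0 / n_cell_types,
        ))
    return groups


@dataclass
class SimulationConfig:
    """Full generative recipe for a synthetic atlas.

    Defaults give a desk-scale atlas (2,000 cells x 3,000 genes, five
    clusters, 50-gene target set) on which the whole pipeline runs in
    seconds.  ``effect`` is the multiplicative fold-change applied to target
    genes in affected cells; ``affected_fraction < 1`` plants the effect in
    only part of each affected group, the heterogeneity scenario.
    """

    n_cells: int = 2000
    n_genes: int = 3000
    groups: list[GroupSpec] = field(default_factory=default_groups)
    baseline_loc: float = 0.0     # log-normal location of relative abundances
    baseline_scale: float = 1.0   # log-normal scale of relative abundances
    dispersion_loc: float = 0.0   # log-normal location of NB size r_g
    dispersion_scale: float = 0.7
    lib_loc: float = math.log(5000.0)  # log-normal library-size parameters
    lib_scale: float = 0.3
    target_size: int = 50
    target_genes: list[str] | None = None  # explicit symbols override sampling
    effect: float = 1.0
    affected_groups: tuple[str, ...] = ()  # cell_type labels
    affected_fraction: float = 1.0
    hox_coupling: bool = False
    hox_fold: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be >= 1")
        total = sum(g.proportion for g in self.groups)
        if not math.isclose(total, 1.0, abs_tol=1e-8):
            raise ValueError(f"group proportions sum to {total}, not 1")
        if any(g.proportion <= 0 for g in self.groups):
            raise ValueError("group proportions must be positive")
        if self.effect <= 0:
            raise ValueError("effect must be > 0")
        cell_types = {g.cell_type for g in self.groups}
        unknown = set(self.affected_groups) - cell_types
        if unknown:
            raise ValueError(f"affected_groups not among simulated cell "
                             f"types: {sorted(unknown)}")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must lie in [0, 1]")
        for p in (self.baseline_scale, self.dispersion_scale, self.lib_scale):
            if p < 0:
                raise ValueError("scale parameters must be >= 0")
        if self.target_size < 1 and self.target_genes is None:
            raise ValueError("target_size must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = [asdict(g) for g in self.groups]
        return d


@dataclass
class GroundTruth:
    """What was planted: per-cell labels/flags and realized fold-changes."""

    cells: pd.DataFrame          # cell_type, time_point, region, affected
    target_genes: list[str]
    fold: pd.DataFrame           # genes x cell types, realized fold-change
    config: SimulationConfig


def _gene_symbols(cfg: SimulationConfig) -> list[str]:
    hox = list(HOX_ANTERIOR_PANEL) + list(HOX_POSTERIOR_PANEL)
    n_plain = cfg.n_genes - (len(hox) if cfg.hox_coupling else 0)
    plain = [f"G{i:05d}" for i in range(1, n_plain + 1)]
    return (hox + plain) if cfg.hox_coupling else plain


def _cells_per_group(cfg: SimulationConfig) -> list[int]:
    # largest-remainder apportionment so counts sum exactly to n_cells
    raw = [g.proportion * cfg.n_cells for g in cfg.groups]
    base = [int(math.floor(x)) for x in raw]
    short = cfg.n_cells - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i],
                   reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def simulate_atlas(cfg: SimulationConfig) -> tuple[AnnData, GroundTruth]:
    """Draw one atlas from the configured generative model.

    Returns the counts as an AnnData (cells x genes, sparse ``X``, cluster /
    time-point / region annotations in ``obs``) plus the ground truth.  Fully
    reproducible: the same config (including seed) gives identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    symbols = _gene_symbols(cfg)
    if cfg.hox_coupling and cfg.n_genes <= len(HOX_ANTERIOR_PANEL) + \
            len(HOX_POSTERIOR_PANEL):
        raise ValueError("n_genes too small for HOX coupling")

    pi = rng.lognormal(cfg.baseline_loc, cfg.baseline_scale, cfg.n_genes)
    pi /= pi.sum()
    size_r = rng.lognormal(cfg.dispersion_loc, cfg.dispersion_scale,
                           cfg.n_genes)
    lib = rng.lognormal(cfg.lib_loc, cfg.lib_scale, cfg.n_cells)

    hox_syms = set(HOX_ANTERIOR_PANEL) | set(HOX_POSTERIOR_PANEL) \
        if cfg.hox_coupling else set()
    if cfg.target_genes is not None:
        target = [s.upper() for s in cfg.target_genes]
        missing = sorted(set(target) - set(symbols))
        if missing:
            raise ValueError(f"target_genes not simulated: {missing}")
    else:
        eligible = [s for s in symbols if s not in hox_syms]
        target = sorted(str(g) for g in
                        rng.choice(eligible, size=cfg.target_size,
                                   replace=False))
    target_idx = np.asarray([symbols.index(g) for g in target])

    counts_group = _cells_per_group(cfg)
    cell_type = np.concatenate([[g.cell_type] * n for g, n in
                                zip(cfg.groups, counts_group)])
    time_point = np.concatenate([[g.time_point] * n for g, n in
                                 zip(cfg.groups, counts_group)])
    region = np.concatenate([[g.region] * n for g, n in
                             zip(cfg.groups, counts_group)])

    affected = np.zeros(cfg.n_cells, dtype=bool)
    for g in cfg.affected_groups:
        idx = np.flatnonzero(cell_type == g)
        if cfg.affected_fraction >= 1.0:
            affected[idx] = True
        else:
            k = int(round(cfg.affected_fraction * idx.size))
            affected[rng.choice(idx, size=k, replace=False)] = True

    mean = np.outer(lib, pi)
    if affected.any():
        mean[np.ix_(affected, target_idx)] *= cfg.effect
    if cfg.hox_coupling:
        for panel, reg in ((HOX_ANTERIOR_PANEL, "anterior"),
                           (HOX_POSTERIOR_PANEL, "posterior")):
            idx = np.asarray([symbols.index(g) for g in panel])
            match = region == reg
            mean[np.ix_(match, idx)] *= cfg.hox_fold
            mean[np.ix_(~match, idx)] *= 0.05

    lam = rng.gamma(shape=size_r[None, :], scale=mean / size_r[None, :])
    counts = rng.poisson(lam).astype(np.int32)

    obs = pd.DataFrame(
        {"cell_type": cell_type, "time_point": time_point, "region": region,
         "affected": affected},
        index=pd.Index([f"C{i:06d}" for i in range(1, cfg.n_cells + 1)],
                       name="cell_id"),
    )
    adata = AnnData(X=sp.csr_matrix(counts), obs=obs,
                    var=pd.DataFrame(index=pd.Index(symbols, name="symbol")))
    adata.uns["simulation_seed"] = cfg.seed

    fold = pd.DataFrame(1.0, index=symbols,
                        columns=[g.cell_type for g in cfg.groups])
    for g in cfg.affected_groups:
        fold.loc[target, g] = cfg.effect if cfg.affected_fraction >= 1.0 \
            else 1.0 + cfg.affected_fraction * (cfg.effect - 1.0)
    truth = GroundTruth(cells=obs.copy(), target_genes=list(target),
                        fold=fold, config=cfg)
    return adata, truth


def toy_interaction_frame(seed_set: GeneSet, n_shell1: int = 20,
                          n_shell2: int = 18, score: float = 0.9
                          ) -> pd.DataFrame:
    """Synthetic STRING-dialect edge table wired to a seed gene set.

    Connects ``n_shell1`` invented interactors (``INT1_*``) directly to seed
    genes and ``n_shell2`` more (``INT2_*``) to the first shell only, all at
    the same high confidence, so a two-shell expansion with a cap of 20 adds
    exactly ``n_shell1 + n_shell2`` disjoint genes.  Purely synthetic plumbing
    for tests and demos; not a real interactome.
    """
    rows = []
    seeds = list(seed_set.symbols)
    shell1 = [f"INT1_{i:02d}" for i in range(1, n_shell1 + 1)]
    shell2 = [f"INT2_{i:02d}" for i in range(1, n_shell2 + 1)]
    for i, g in enumerate(shell1):
        rows.append((seeds[i % len(seeds)], g, score))
    for i, g in enumerate(shell2):
        rows.append((shell1[i % len(shell1)], g, score))
    # a few low-confidence distractors that must never be picked up
    for i in range(5):
        rows.append((seeds[i % len(seeds)], f"LOW_{i:02d}", 0.2))
    return pd.DataFrame(rows, columns=["protein1", "protein2",
                                       "combined_score"])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture_suite(out_dir: str | Path, seed: int = 0,
                       n_cells: int = 2000, n_genes: int = 3000) -> dict:
    """Write the canonical synthetic fixtures and a YAML manifest.

    Produces (a) a null atlas, (b) a one-group planted atlas, (c) a
    heterogeneous atlas with the effect in half of one group's cells,
    (d) a pair of atlases sharing a planted signal plus one with an
    independent signal, and (e) a toy interaction table with the curated
    gene lists.  Returns the manifest dictionary.
    """
    from .io import write_mtx_dir
    from .geneset import em_primary_geneset

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    shared_target = [f"G{i:05d}" for i in range(101, 151)]
    configs = {
        "null": SimulationConfig(n_cells=n_cells, n_genes=n_genes, seed=seed),
        "planted": SimulationConfig(n_cells=n_cells, n_genes=n_genes,
                                    effect=1.5, affected_groups=("ct2",),
                                    seed=seed + 1),
        "heterogeneous": SimulationConfig(n_cells=n_cells, n_genes=n_genes,
                                          effect=2.0,
                                          affected_groups=("ct2",),
                                          affected_fraction=0.5,
                                          seed=seed + 2),
        "species_a": SimulationConfig(n_cells=n_cells, n_genes=n_genes,
                                      effect=2.0, affected_groups=("ct3",),
                                      target_genes=shared_target,
                                      seed=seed + 3),
        "species_b": SimulationConfig(n_cells=n_cells, n_genes=n_genes,
                                      effect=2.0, affected_groups=("ct3",),
                                      target_genes=shared_target,
                                      seed=seed + 4),
        "species_c": SimulationConfig(n_cells=n_cells, n_genes=n_genes,
                                      effect=2.0, affected_groups=("ct5",),
                                      seed=seed + 5),
    }

    manifest: dict = {"seed": seed, "atlases": {}, "files": {}}
    for name, cfg in configs.items():
        adata, truth = simulate_atlas(cfg)
        atlas_dir = out / name
        write_mtx_dir(adata, atlas_dir)
        pd.Series(truth.target_genes).to_csv(
            atlas_dir / "target_genes.txt", index=False, header=False)
        manifest["atlases"][name] = {
            "config": cfg.to_dict(),
            "target_genes": truth.target_genes,
        }
        for f in sorted(atlas_dir.iterdir()):
            manifest["files"][str(f.relative_to(out))] = _sha256(f)

    primary = em_primary_geneset()
    primary.to_frame().to_csv(out / "em_primary_genes.tsv", sep="\t",
                              index=False)
    toy_interaction_frame(primary).to_csv(out / "toy_interactions.tsv",
                                          sep="\t", index=False)
    for fname in ("em_primary_genes.tsv", "toy_interactions.tsv"):
        manifest["files"][fname] = _sha256(out / fname)

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
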