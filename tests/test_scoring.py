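"""Normalization, control matching, per-cell scoring and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from celldrs import (
    SimulationConfig,
    compute_gene_stats,
    group_association,
    load_primary_genes,
    mc_p_floor,
    normalize_counts,
    sample_matched_controls,
    score_cells,
)
from conftest import make_adata, run_pipeline


class TestNormalizeCounts:
    def test_matches_the_log1p_scaling_formula(self):
        adata = make_adata(np.array([[2, 0, 8]]))
        normalize_counts(adata, scale=1e4)
        row = adata.layers["lognorm"].toarray()[0]
        np.testing.assert_allclose(
            row, [np.log1p(2000.0), 0.0, np.log1p(8000.0)])

    def test_invariant_to_doubling_every_count_in_a_cell(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(5, 12))
        a = make_adata(counts)
        b = make_adata(counts * 2)
        normalize_counts(a)
        normalize_counts(b)
        np.testing.assert_allclose(a.layers["lognorm"].toarray(),
                                   b.layers["lognorm"].toarray())

    def test_zero_total_cell_is_flagged_and_all_zero(self):
        counts = np.array([[1, 2], [0, 0]])
        with pytest.warns(UserWarning, match="degenerate"):
            adata = normalize_counts(make_adata(counts))
        assert adata.obs["degenerate"].tolist() == [False, True]
        assert adata.layers["lognorm"].toarray()[1].sum() == 0

    def test_negative_counts_rejected(self):
        adata = make_adata(np.array([[1, 2]]))
        adata.X = np.array([[-1.0, 2.0]])
        with pytest.raises(ValueError, match="negative"):
            normalize_counts(adata)


class TestGeneStats:
    def test_equal_frequency_partition_100_genes_10_bins(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(rng.uniform(0.5, 30, size=100), size=(50, 100))
        adata = normalize_counts(make_adata(counts))
        stats = compute_gene_stats(adata, n_mean_bins=10, n_sd_bins=1)
        sizes = stats.frame["bin"].value_counts()
        assert (sizes == 10).all() and len(sizes) == 10

    def test_largest_mean_gene_lands_in_top_mean_bin(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(rng.uniform(0.5, 5, size=60), size=(40, 60))
        counts[:, 7] += 50  # make gene 7 by far the highest expressed
        adata = normalize_counts(make_adata(counts))
        stats = compute_gene_stats(adata, n_mean_bins=6, n_sd_bins=2)
        top = stats.frame["bin"].loc[stats.frame["mean"].idxmax()]
        assert top.startswith("m5.")

    def test_bin_mean_summaries_are_non_decreasing(self, small_null):
        stats = small_null["stats"]
        frame = stats.frame[stats.frame["bin"] != "constant"]
        mean_bin = frame["bin"].str.extract(r"m(\d+)")[0].astype(int)
        # recompute per-bin summaries independently of the binning code
        summary = frame.groupby(mean_bin)["mean"].mean()
        assert (summary.sort_index().diff().dropna() >= 0).all()

    def test_fewer_genes_than_bins_is_an_error(self):
        rng = np.random.default_rng(3)
        adata = normalize_counts(
            make_adata(rng.poisson(2, size=(20, 8))))
        with pytest.raises(ValueError, match="bins"):
            compute_gene_stats(adata, n_mean_bins=5, n_sd_bins=3)


class TestMatchedControls:
    def test_same_seed_gives_identical_replicates(self, small_null):
        a = sample_matched_controls(small_null["stats"],
                                    small_null["target"], n_ctrl=20, seed=3)
        b = sample_matched_controls(small_null["stats"],
                                    small_null["target"], n_ctrl=20, seed=3)
        assert a.sets == b.sets

    def test_controls_confined_to_the_target_gene_bins(self, small_null):
        stats = small_null["stats"]
        target = small_null["target"]
        ctrl = sample_matched_controls(stats, target, n_ctrl=25, seed=4)
        bin_of = stats.frame["bin"]
        for rep in ctrl.sets:
            assert len(rep) == len(target.symbols)
            for tg, cg in zip(target.symbols, rep):
                assert bin_of[cg] == bin_of[tg]
                assert cg != tg

    def test_control_means_match_target_mean_within_bin_width(self,
                                                              small_null):
        stats, target = small_null["stats"], small_null["target"]
        ctrl = sample_matched_controls(stats, target, n_ctrl=200, seed=5)
        means = stats.frame["mean"]
        target_mean = means[target.symbols].mean()
        ctrl_mean = np.mean([means[rep].mean() for rep in ctrl.sets])
        frame = stats.frame[stats.frame["bin"] != "constant"]
        mean_bin = frame["bin"].str.extract(r"m(\d+)")[0].astype(int)
        widths = frame.groupby(mean_bin)["mean"].agg(np.ptp)
        assert abs(ctrl_mean - target_mean) < widths.max()

    def test_bin_without_replacement_raises_naming_the_gene(self):
        counts = np.array([[3, 1, 1, 5], [0, 2, 2, 4], [1, 1, 3, 2]])
        adata = normalize_counts(make_adata(counts))
        stats = compute_gene_stats(adata, n_mean_bins=4, n_sd_bins=1)
        lone = stats.frame.index[0]
        target = load_primary_genes({"t": [lone]})
        with pytest.raises(ValueError, match=lone):
            sample_matched_controls(stats, target, n_ctrl=5, seed=1)

    def test_target_equal_to_universe_is_an_error(self):
        rng = np.random.default_rng(6)
        adata = normalize_counts(make_adata(rng.poisson(3, size=(30, 12))))
        stats = compute_gene_stats(adata, n_mean_bins=3, n_sd_bins=2)
        target = load_primary_genes({"t": list(adata.var_names)})
        with pytest.raises(ValueError, match="universe"):
            sample_matched_controls(stats, target, n_ctrl=5, seed=1)

    def test_ctrl_size_option_changes_replicate_cardinality(self, small_null):
        ctrl = sample_matched_controls(small_null["stats"],
                                       small_null["target"], n_ctrl=5,
                                       seed=6, ctrl_size=100)
        assert all(len(rep) == 100 for rep in ctrl.sets)


class TestScoreCells:
    def test_constant_matrix_gives_zero_norm_and_p_one(self):
        counts = np.tile([[4], [7], [2]], (1, 12))  # equal within each cell
        adata = normalize_counts(make_adata(counts))
        stats = compute_gene_stats(adata, n_mean_bins=3, n_sd_bins=1)
        target = load_primary_genes({"t": list(adata.var_names[:4])})
        ctrl = sample_matched_controls(stats, target, n_ctrl=20, seed=1)
        sc = score_cells(adata, target, ctrl, stats)
        np.testing.assert_allclose(sc.norm, 0.0)
        np.testing.assert_allclose(sc.mc_p, 1.0)

    def test_uniform_weighting_single_gene_equals_its_expression(self,
                                                                 small_null):
        adata, stats = small_null["adata"], small_null["stats"]
        gene = small_null["target"].symbols[0]
        single = load_primary_genes({"t": [gene]})
        ctrl = sample_matched_controls(stats, single, n_ctrl=10, seed=2)
        sc = score_cells(adata, single, ctrl, stats, weighting="uniform")
        col = adata.layers["lognorm"][:, list(adata.var_names).index(gene)]
        np.testing.assert_allclose(sc.raw, np.asarray(col.todense()).ravel())

    def test_mc_p_respects_the_monte_carlo_floor(self, small_planted):
        sc = small_planted["scores"]
        p = sc.mc_p[np.isfinite(sc.mc_p)]
        assert p.min() >= mc_p_floor(sc.n_ctrl) - 1e-12
        assert p.max() <= 1.0

    def test_scores_invariant_to_gene_and_cell_permutation(self):
        cfg = SimulationConfig(n_cells=120, n_genes=200, target_size=15,
                               seed=21)
        base = run_pipeline(cfg, n_ctrl=30, ctrl_seed=9, n_mean_bins=5,
                            n_sd_bins=2)
        adata = base["adata"]
        rng = np.random.default_rng(0)
        gperm = rng.permutation(adata.n_vars)
        cperm = rng.permutation(adata.n_obs)
        shuffled = adata[cperm, gperm].copy()
        stats2 = compute_gene_stats(shuffled, 5, 2)
        ctrl2 = sample_matched_controls(stats2, base["target"], n_ctrl=30,
                                        seed=9)
        sc2 = score_cells(shuffled, base["target"], ctrl2, stats2)
        ref = pd.Series(base["scores"].norm, index=base["scores"].cell_ids)
        got = pd.Series(sc2.norm, index=sc2.cell_ids)
        np.testing.assert_allclose(got[ref.index], ref, rtol=1e-10)

    def test_missing_target_genes_is_an_error(self, small_null):
        ghost = load_primary_genes({"t": ["NOT_A_GENE"]})
        with pytest.raises(ValueError, match="no gene"):
            score_cells(small_null["adata"], ghost, small_null["ctrl"],
                        small_null["stats"])

    def test_degenerate_cells_get_missing_scores(self):
        rng = np.random.default_rng(31)
        counts = rng.poisson(3, size=(40, 30))
        counts[5] = 0
        with pytest.warns(UserWarning):
            adata = normalize_counts(make_adata(counts))
        stats = compute_gene_stats(adata, n_mean_bins=3, n_sd_bins=2)
        target = load_primary_genes({"t": list(adata.var_names[:5])})
        ctrl = sample_matched_controls(stats, target, n_ctrl=15, seed=3)
        sc = score_cells(adata, target, ctrl, stats)
        assert np.isnan(sc.norm[5]) and np.isnan(sc.mc_p[5])
        assert np.isfinite(np.delete(sc.norm, 5)).all()


class TestGroupAssociation:
    def test_planted_group_attains_min_assoc_p(self, small_planted):
        gstats = group_association(small_planted["scores"],
                                   small_planted["adata"], "cell_type")
        frame = gstats.frame
        assert frame["assoc_p"].idxmin() == "ct2"
        assert frame.loc["ct2", "assoc_p"] <= 0.05
        assert frame.loc["ct2", "assoc_z"] == frame["assoc_z"].max()

    def test_planted_group_mean_norm_score_exceeds_rest(self, small_planted):
        sc, adata = small_planted["scores"], small_planted["adata"]
        inside = adata.obs["cell_type"].to_numpy() == "ct2"
        assert np.nanmean(sc.norm[inside]) > np.nanmean(sc.norm[~inside])

    def test_group_p_values_respect_floor_and_ceiling(self, small_planted):
        gstats = group_association(small_planted["scores"],
                                   small_planted["adata"], "cell_type")
        floor = mc_p_floor(small_planted["scores"].n_ctrl)
        for col in ("assoc_p", "hetero_p"):
            assert (gstats.frame[col] >= floor - 1e-12).all()
            assert (gstats.frame[col] <= 1.0).all()

    def test_small_groups_are_excluded_with_warning(self, small_null):
        adata = small_null["adata"]
        labels = adata.obs["cell_type"].astype(str).copy()
        labels.iloc[:5] = "tiny"
        adata.obs["with_tiny"] = labels
        with pytest.warns(UserWarning, match="tiny"):
            gstats = group_association(small_null["scores"], adata,
                                       "with_tiny", min_cells=20)
        assert "tiny" not in gstats.frame.index
        assert ("tiny", 5) in gstats.excluded

    def test_effect_size_monotonically_raises_planted_group_score(self):
        means = []
        for effect in (1.0, 1.5, 2.5):
            vals = []
            for rep in range(3):
                cfg = SimulationConfig(n_cells=300, n_genes=400,
                                       target_size=20, effect=effect,
                                       affected_groups=("ct2",),
                                       seed=50 + rep)
                out = run_pipeline(cfg, n_ctrl=40, ctrl_seed=60 + rep,
                                   n_mean_bins=8, n_sd_bins=2)
                inside = out["adata"].obs["cell_type"].to_numpy() == "ct2"
                vals.append(np.nanmean(out["scores"].norm[inside]))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


def test_null_mc_p_uniform_across_replicate_runs():
    """Calibration is a property over random target sets: aggregate cells
    from several independent null realizations before testing uniformity."""
    rng = np.random.default_rng(77)
    pooled = []
    for rep in range(10):
        cfg = SimulationConfig(n_cells=300, n_genes=800, target_size=30,
                               seed=300 + rep)
        out = run_pipeline(cfg, n_ctrl=100, ctrl_seed=1400 + rep,
                           n_mean_bins=16, n_sd_bins=4)
        p = out["scores"].mc_p
        pooled.append(rng.choice(p[np.isfinite(p)], size=100, replace=False))
    ks = sps.kstest(np.concatenate(pooled), "uniform")
    assert ks.pvalue > 0.01
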