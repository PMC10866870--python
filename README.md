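# celldrs

Single-cell disease-relevance scoring for congenital-malformation gene sets.

Congenital anomalies such as esophageal atresia and tracheoesophageal fistula
arise in narrow developmental windows and in specific progenitor cell
populations, which makes it hard to say *where* and *when* the implicated
genes act. `celldrs` answers that question on single-cell atlases: given a
curated disease gene set — by default 29 genes implicated in esophageal
malformations through GWAS, animal models and patient exomes, optionally
expanded to 67 genes through their high-confidence protein-interaction
neighbourhood — it scores every cell for preferential expression of the set
and tests which cell clusters, developmental stages and axial regions carry
the signal.

## The method

For a target gene set *D* and a log-normalized expression matrix
*x* (cells × genes, `log1p(count / total × 10⁴)`):

1. **Matched controls.** Genes are partitioned into equal-frequency bins by
   mean and standard deviation of expression. Each of *N* control replicates
   replaces every target gene with a random gene from the same bin, so the
   control sets share the target set's expression profile.
2. **Per-cell scores.** The raw score of cell *c* is the inverse-sd weighted
   mean `Σ_g w_g x_cg / Σ_g w_g` over the set, with `w_g = 1/(sd_g + ε)`.
   The normalized score is the z-score of the target raw score against the
   cell's *N* control raw scores, and the Monte-Carlo p-value is
   `(1 + #{controls ≥ target}) / (1 + N)` — floored at `1/(N+1)`
   (0.00099 at N = 1000).
3. **Cluster statistics.** Per cell cluster, the association statistic is the
   mean normalized score and the heterogeneity statistic the within-cluster
   variance; both are tested against the same statistics recomputed on every
   control replicate (leave-one-out z-scored against the remaining
   replicates).
4. **Downstream.** Wilcoxon rank-sum contrasts between time points or
   regions; gene prioritization by Pearson correlation of expression with
   scores; Fisher-z comparison of two correlation profiles across atlases;
   and an anterior/posterior contrast that labels cells from HOXA1–HOXA6
   (anterior) versus HOXA9–HOXA13 (posterior) expression.

A negative-binomial synthetic-atlas generator with planted cell-type-,
stage- and region-specific effects is included, so every statistical
guarantee is testable end to end without external data.

## Worked example

```python
import celldrs

# a synthetic atlas with a 1.5x planted effect in cluster ct2
cfg = celldrs.SimulationConfig(effect=1.5, affected_groups=("ct2",), seed=1)
adata, truth = celldrs.simulate_atlas(cfg)

celldrs.normalize_counts(adata)                      # log1p CPM-10k layer
stats = celldrs.compute_gene_stats(adata)            # 20 x 5 (mean, sd) bins
target = celldrs.load_primary_genes({"planted": truth.target_genes})
ctrl = celldrs.sample_matched_controls(stats, target, n_ctrl=200, seed=2)
scores = celldrs.score_cells(adata, target, ctrl, stats)
groups = celldrs.group_association(scores, adata, "cell_type")
print(groups.frame.round(4))
```

```
     n_cells  assoc_z  assoc_p  hetero_z  hetero_p
ct1      400  -3.8095    1.000   -0.0905    0.5274
ct2      400  14.3300    0.005    3.7173    0.0050
ct3      400  -3.1064    1.000    0.1265    0.4527
ct4      400  -4.6344    1.000   -0.5591    0.7214
ct5      400  -3.0299    0.995    0.7958    0.2239
```

The planted cluster `ct2` is the only one whose association p-value reaches
the Monte-Carlo floor `1/(200+1) ≈ 0.005`; every other cluster is null.
With the paper-scale 1,000 replicates the floor becomes 0.00099.

The same pipeline is available from the shell:

```bash
celldrs simulate --seed 1 --out atlas/
celldrs geneset --primary gwas.txt --primary animal_model.txt \
    --primary exome.txt --net string_export.tsv --out em_genes.tsv
celldrs score --matrix atlas/ --geneset em_genes.tsv --n-ctrl 1000 \
    --seed 1 --out results/
celldrs hox-contrast --matrix atlas/ --scores results/cell_scores.tsv \
    --out hox.tsv
```

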