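# Methods

## Scope and model

`celldrs` quantifies the preferential expression of a disease gene set in
single cells and aggregates the evidence to cell clusters, developmental
stages and axial regions. The statistical core is a matched-control
Monte-Carlo design: the target set's expression is compared, cell by cell,
with control gene sets that share its per-gene mean and standard deviation
of expression, so that library-size, detection-rate and expression-level
artifacts cancel rather than masquerade as disease relevance.

### Normalization

Counts are transformed as `log1p(count / cell_total × scale)` with
`scale = 10,000` by default. Cells with zero total counts are flagged
degenerate, keep all-zero rows, and receive missing scores downstream;
they are excluded from the per-gene statistics.

### Control matching

Per-gene mean and standard deviation (population sd, over non-degenerate
cells) are computed on the normalized layer. Genes are sorted by
(mean, symbol) and cut into `n_mean_bins` equal-frequency chunks; each chunk
is sorted by (sd, symbol) and cut into `n_sd_bins` chunks. The secondary
symbol key makes the partition invariant to the column order of the input
matrix. Zero-variance genes live in a reserved `constant` bin: they are
matched only with one another, which keeps them out of ordinary control
pools while still letting fully degenerate matrices flow through the
degenerate-contract path (all scores 0, all p-values 1).

Defaults are 20 mean-bins × 5 sd-bins — fine enough that a bin spans a
narrow slice of expression space, coarse enough to leave ≥ 2 genes per bin
on 2–20k-gene matrices. Both counts are arguments.

Each control replicate replaces every target gene with a gene drawn
uniformly from the target gene's own bin, excluding that gene itself;
duplicates within a replicate are rejected and redrawn, and a replicate
identical to the target set is redrawn entirely. Bin members are sorted
lexicographically before sampling, so a fixed seed yields the same control
sets regardless of matrix layout. Control sets match the target set's
cardinality by default — required for raw scores to be directly
comparable — with `ctrl_size` available when a fixed larger control
cardinality is wanted.

### Per-cell scores

The raw score of a cell is the weighted mean of the set's normalized
expression, with inverse-sd weights `w_g = 1/(sd_g + ε)`, `ε = 1e-3`
(uniform weights available). Inverse-sd weighting downweights noisy
high-variance genes; with a single-gene set and uniform weights the raw
score is exactly that gene's normalized expression.

The normalized score is `(raw − mean_k raw_ctrl_k) / sd_k raw_ctrl_k`
(sd with one delta degree of freedom over the N control replicates), and
`mc_p = (1 + #{k : raw_ctrl_k ≥ raw}) / (1 + N)`, floored at `1/(N+1)`
(0.00099 at N = 1,000, printed after five-decimal truncation). Cells whose
control scores have zero spread get a normalized score of 0 and p = 1.

### Cluster association and heterogeneity

For each cell cluster (or any per-cell annotation), the association
statistic is the mean of normalized scores and the heterogeneity statistic
their within-cluster variance — the latter flags clusters that mix strongly
scored and unscored cells, the signature of a disease-relevant
subpopulation. The null distribution reuses the control replicates: each
replicate's raw scores are z-scored per cell against the remaining
replicates (leave-one-out, so the replicate being tested never contaminates
its own null), and the group statistic is recomputed on each replicate's
z-scores. P-values use the same `(1 + #{null ≥ obs}) / (1 + N)` counting
rule; z-statistics standardize the observed value against the null draws.
Groups with fewer than `min_cells` (default 20) scored cells are excluded
and reported.

### Downstream analyses

* **Contrasts** between annotation groups (time points, regions) use the
  two-sided Wilcoxon rank-sum test with tie-corrected normal approximation
  and *no* continuity correction, so identical score multisets give p = 1
  exactly; at the group sizes involved (hundreds of cells) the continuity
  term is negligible.
* **Gene prioritization** computes the Pearson correlation of each gene's
  normalized expression with the normalized scores over any cell subset,
  and ranks genes by descending correlation (missing correlations — zero
  variance genes — rank last; ties break by column order). Ranks are
  invariant to positive affine rescaling of the scores, and only to that,
  as Pearson correlation dictates.
* **Correlation-profile comparison** across two atlases or stages uses
  Fisher's z-transformation per shared gene,
  `z = (atanh r_A − atanh r_B) / sqrt(1/(n_A−3) + 1/(n_B−3))`, with a
  two-sided normal p-value, plus the correlation-of-correlations over the
  shared gene universe (whose size is always reported, since gene-universe
  intersection is where cross-atlas comparisons silently shrink).
  Cross-species gene matching defaults to uppercase symbol identity; an
  ortholog table can be applied upstream.
* **Axial contrast**: cells are labeled anterior when their mean normalized
  expression over HOXA1–HOXA6 exceeds both a threshold (default 0: any
  positive panel expression) and the HOXA9/10/11/13 panel mean, posterior
  symmetrically; unlabeled cells are dropped and the groups contrasted as
  above.

### Gene-set construction

The curated set concatenates three evidence tracks (GWAS, animal-model,
exome; 29 genes), keeping first-occurrence order and the first source for a
symbol listed twice. Interactome expansion reads a STRING-export TSV
(integer 0–1000 or fractional scores, auto-detected), keeps edges with
combined score ≥ 0.7, and adds up to 20 interactors per shell for two
shells. Shell k candidates are the qualifying neighbours of shell k−1's
additions — the convention STRING itself uses — ranked by best edge score
into the whole current set with lexicographic tie-breaks, which makes the
expansion deterministic. A gene passed over by an earlier shell's cap is
reconsidered only if a later addition links to it.

## Synthetic atlas generator

The generator emulates the structure the analysis assumes in embryonic
atlases: clusters crossed with developmental time points and
anterior/posterior regions, sparse overdispersed counts, and a target set
preferentially expressed where the scenario plants it. Counts are
gamma-Poisson: `counts ~ NB(mean = lib_c × π_g × fold, size = r_g)` with
log-normal library sizes (median 5,000 counts), log-normal relative
abundances π (normalized to 1), and per-gene log-normal inverse-dispersion.
`fold = effect` for target genes in affected cells and 1 otherwise;
`affected_fraction < 1` plants the effect in a random subset of a group's
cells (the heterogeneity scenario). Optional HOX coupling ties synthetic
anterior (6-gene) and posterior (4-gene) marker panels to the region labels
at a 20× fold, mirroring the panel sizes used for axial labeling.

Canonical fixture scale is 2,000 cells × 3,000 genes, five equal clusters,
a 50-gene target set and 200 control replicates — sized so a full pipeline
run takes a few seconds on one CPU and the complete test suite a couple of
minutes. What the generator deliberately does *not* emulate: lineage or
trajectory structure, batch effects, doublets, ambient RNA, or the
gene-level statistics of any real atlas. Passing tests therefore
demonstrate the statistical machinery (calibration, recovery, determinism),
not biological fidelity of any particular atlas.

## Calibration: what is (and is not) guaranteed

Conditional on a *single* random target set, per-cell Monte-Carlo p-values
are only approximately uniform: a specific 50-gene draw carries a coherent
set-level offset relative to its bin-matched controls (it persists when the
control sets are redrawn), which a Kolmogorov–Smirnov test over thousands
of cells can detect. This is intrinsic to matched-control designs, not an
implementation artifact. Calibration is therefore validated the way the
design warrants it — over independent realizations of atlas *and* target
set: the calibration tests aggregate cells and cluster p-values across ten
independent null runs, where KS uniformity and the 5%-rejection band hold
robustly. Single-run results should be read accordingly: cluster-level
p-values compare clusters *within* a run against a common null and are the
quantity the pipeline is designed to rank.

## Numerical choices and degenerate inputs

* One integer seed drives each sampling step (simulation, control draws)
  via `numpy.random.default_rng`; seeds are recorded in outputs, and every
  operation is deterministic given its inputs.
* Leave-one-out null z-scores use unbiased variance over the N−1 remaining
  replicates and need N ≥ 3; zero null spread yields z = 0.
* Fisher z is undefined (NaN) at |r| = 1 and requires n ≥ 4 per sample.
* Monte-Carlo p-values can never be 0 by construction; tables serialize
  floats at six significant digits and missing values as `NA`.
* MTX input orientation is auto-detected from the label files; duplicate
  gene symbols or barcodes are rejected outright rather than uniquified.

## Known limitations

* Group statistics (mean/variance with control-replicate nulls) are one
  reasonable formalization of cluster association and heterogeneity; other
  statistics (e.g. rank-based) would need their own calibration study.
* Raw Monte-Carlo p-values are reported without multiple-testing
  correction, matching the upstream convention; apply Benjamini–Hochberg
  downstream if desired.
* No alias/ortholog resolution is built in; symbol hygiene is the caller's
  responsibility.
* The resolution of Monte-Carlo p-values is bounded by the replicate count;
  ranking clusters at the floor requires raising `n_ctrl`.
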