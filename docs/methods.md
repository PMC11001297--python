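# Methods

`dopavuln` quantifies differential survival of cell populations in a
two-condition (intact vs lesioned hemisphere) single-nucleus RNA-seq design,
the setting of unilateral 6-OHDA lesions of midbrain dopamine (mDA) neurons.
This note records the models, the defaults and why they were chosen, what
the synthetic data does and does not emulate, and the numerical decisions a
maintainer would want written down.

## The normalized cell-loss estimator

Nuclei are sorted per hemisphere (FANS), sequenced, QC-filtered, restricted
to dopaminergic nuclei (`Th` or `Slc6a3` detected), clustered, and each
cluster is subdivided into subclusters (Louvain, resolution 0.5). For a
subcluster with `s_i` intact and `s_l` lesioned nuclei,

    L = 1 - (beta * s_l) / s_i

where `beta` is the *yield normalization coefficient*: the ratio of intact
to lesioned QC-passing totals over **all** nuclei (before dopaminergic
selection). It absorbs the asymmetry in per-hemisphere sorting throughput;
because the non-dopaminergic majority of the sorted pool is unaffected by
the lesion, the all-nuclei ratio estimates the capture asymmetry rather
than the biology. `L = 1` is total loss, `L = 0` no loss; negative values
(apparent gain, reachable by sampling noise) are set to NA.

Cluster-level loss `A` is the unweighted mean of non-NA subcluster losses.
The protocol's formula divides by the number of subclusters `N` while also
NA-ing negative terms; since averaging with NA contributions is undefined,
we take `N` = the non-NA count and report both `N_total` and `N_used`. The
prose "considering the subcluster size" conflicts with the printed
unweighted sum; we implement the printed formula, with a size-weighted mean
behind `weighted=True`. Territory/neighborhood losses aggregate the same
subcluster values through a cluster-to-unit map, again as unweighted means,
following the statement that subcluster values feed every aggregation level.

Known property (visible in validation runs): the NA rule truncates the
sampling distribution of low-loss subclusters, so territories with true
loss near zero are estimated with a small upward bias — at the bundled
granularity (clusters of a few hundred nuclei) up to roughly +0.05, and
occasionally slightly more at unlucky seeds. This is a property of the
printed estimator, not of this implementation; the size-weighted option and
coarser clustering both reduce it.

## Statistics battery

Group comparisons (subcluster losses across clusters/territories, module
scores across groups) follow a recorded decision tree: Shapiro-Wilk
normality per group (the D'Agostino skewness/kurtosis omnibus for groups
above 5000 observations), Levene (normal) or Fligner-Killeen (otherwise)
for variance homogeneity, then for two groups a t-test or Wilcoxon
rank-sum, and for more than two groups Kruskal-Wallis plus Welch's ANOVA
followed by Conover-Iman pairwise post hocs with Benjamini-Hochberg
adjustment. The Conover-Iman convention is one-sided `p = P(T >= |t|)` on
`n - k` degrees of freedom with rejection at adjusted `p <= alpha/2`
(0.025), i.e. a nominal two-sided 0.05 per comparison before adjustment.
The implementation uses the tie-corrected Kruskal-Wallis `H` and the
`S^2 (n-1-H)/(n-k)` variance scaling; the test suite verifies it against an
algebraically independent route (pairwise pooled-variance t-tests on
midranks, whose MSE equals that scaling) and checks null calibration by
Monte Carlo (2000 null replicates; the observed per-comparison rejection
rate must not exceed nominal by more than two binomial SEs — BH makes it
conservative, ~0.02 observed).

Composition homogeneity across animals uses Pearson's chi-square of
independence without continuity correction; zero-margin rows/columns are
dropped with a warning.

## Vulnerability and resilience modules

Differential expression is a two-sided Wilcoxon rank-sum (normal
approximation, tie-corrected) on intact nuclei of a cluster versus all
other intact dopaminergic nuclei, with the conventional prefilters
(`min.pct = 0.1`, `|log2FC| >= 0.25`); `avg_log2FC` compares expm1-back-
transformed means with pseudocount 1; Bonferroni adjustment is over the
full post-QC gene universe, not only the tested genes. The reference set
("all other intact nuclei") is a choice — the protocol does not name one —
and is the convention of the toolkit family this follows.

A gene enters the vulnerability (resilience) module only if it passes
adjusted `p < 0.05` AND `log2FC > 0.5` in **every** cluster with loss > 0.9
(< 0.5); genes are ranked by mean log2FC with a lexicographic tie-break and
truncated to 20 (8). An `exclude_gene` flag reproduces the
transporter-excluded sensitivity variant (the toxin enters via the dopamine
transporter, so `Slc6a3` membership is partly mechanistic).

Module scores: genes are binned into 24 equal-frequency bins of mean
normalized expression; per module gene, 100 control genes are drawn from
its bin (module genes excluded; with replacement plus a warning when the
bin is smaller, which is routine on the 2000-gene simulations); the score
is mean(module) − mean(pooled controls). The 24/100 values are the cited
scoring function's defaults. Scores are seeded and translation-invariant
per nucleus.

The validating regression is OLS of per-cluster loss on the square root of
the per-cluster **mean** nucleus score (mean, not median — a choice),
excluding the module's input clusters. Negative scores are shifted by
`-min + 1e-6` before the square root and the shift is recorded in the
transform tag.

## Normalization and clustering stand-ins

Regularized negative-binomial Pearson residuals (SCTransform-style) are
deliberately not reimplemented: every downstream statistic in scope is
rank-based, count-based or contrast-based, so depth-scaled log1p
(`log1p(count / total * 1e4)`) plus dispersion-z-scored HVG selection
(~100-gene mean bins, top 1000) is an adequate variance-stabilization
stand-in. PCA (top 30 PCs of the z-scored HVG matrix) fixes each
component's sign by making its largest-magnitude loading positive, for
backend-independent reproducibility. The SNN graph uses 20 nearest
neighbors, Jaccard edge weights over self-inclusive neighbor sets, pruning
at 1/15 (the convention of the common single-cell toolkits; the protocol
states none). Louvain runs on that graph via igraph's multilevel algorithm
with a resolution parameter, seeded. K-means uses MacQueen online updates
(random distinct-point initialization, incremental centroid updates,
reseeding policy for empty clusters) because that variant is not in
scikit-learn; `k` defaults to `ceil(n/500)` with floor 8, matching the
granularity of the original analysis (71 clusters on ~33k nuclei). The
centroid dendrogram is Ward on Euclidean distances (scipy's `ward` equals
ward.D2 on raw distances). Singleton subclusters are retained.

## The synthetic-data generator

The generator emulates the study conditions, not the dataset: hierarchical
territories with subpopulations ("neighborhoods") and private marker
programs; negative-binomial counts (dispersion 2) with lognormal library
sizes (sigma 0.35, ~6000 UMIs/nucleus over 2000 genes); 13 `mt-` genes
carrying 2% of UMIs, ribosomal genes, and a `Malat1` analogue at 7% so the
QC filters act; per-territory survival under lesioning; FANS capture rates
0.9 (intact) vs 0.82 (lesioned), i.e. a true yield ratio of ~1.098, the
magnitude observed in the study; a "mostly lesion" stress state (fraction
0.4 of surviving nuclei of the most vulnerable territory) with 30 stress
genes up 2 log2 units and `Th`/`Slc6a3` down 1.5; and six animals per
condition assigned round-robin.

Two structural choices matter:

* **Backfilled sorting pool.** The sorter draws from a per-hemisphere
  tissue pool of constant size: dopaminergic nuclei killed by the lesion
  are replaced by non-dopaminergic background nuclei (in the study,
  background counts more than doubled on the lesioned side while totals
  stayed near-equal). This makes the yield ratio identifiable from
  QC-passing totals under any survival configuration — without it, the
  all-nuclei ratio would absorb the average dopaminergic loss.
* **Graded vulnerability/resilience programs.** A 30-gene vulnerability
  program is expressed in territory `t` at `log2FC * loss_t / max(loss)`
  (resilience mirrored on survival), and `Slc6a3` itself is
  vulnerability-graded. The most vulnerable territory carries the program
  at full strength as its signature (its module genes ARE its markers, as
  in the original analysis). The gradient is what lets module scores carry
  information about loss outside the module's input clusters; with flat
  per-territory programs the held-out correlation would be undefined.

Bundled conditions: `recovery_config()` (3 territories x 2000 nuclei,
survival 0.05/0.5/0.9, 1500 background) for loss recovery, and
`module_config()` (6 territories x 900, survival 0.05–0.95, 30
vulnerability genes at log2FC 1.0, subpopulation markers at 0.5 —
neighborhood heterogeneity is subtler than territory programs) for module
recovery. These sizes keep a full validation run around twenty seconds on
one CPU while leaving binomial noise well inside the recovery bands.

Not emulated: ambient RNA, doublets beyond the gene-ceiling filter,
batch/animal effects, gene–gene correlation beyond the planted programs,
and any spatial structure. Passing recovery tests therefore show that the
estimators invert the generative model they were designed for — they do not
certify behavior under real-data artifacts the generator omits.

## Degenerate inputs and numerical conventions

Zero-total nuclei are flagged in QC (NaN percentages) and rejected by
normalization; `s_i = 0` subclusters are NA with reason `no_intact`;
all-identical groups make the rank statistics undefined and return a
no-rejection result with a diagnostic; duplicate centroids merge at height
0; PCA raises when the requested dimension exceeds the data rank; BH
monotonicity comes from the standard step-up construction; all randomness
(simulation, clustering, control-gene draws) flows from explicit seeds, and
the pipeline expands one root seed into per-stage child seeds so stages are
independently reproducible.
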