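# Methods

## Differential expression

The model is the two-group special case of the standard linear-model
approach for microarray-scale data. Per gene g, with groups of sizes n_a
(treated) and n_b (control) on a log2-scale matrix:

- log2 fold change: `log2fc_g = mean_a - mean_b`;
- pooled (equal-variance) residual variance `s2_g` on `d = n_a + n_b - 2`
  degrees of freedom. Pooled rather than Welch variance is used because the
  statistic re-implements the linear-model formulation, which assumes a
  common within-group variance.
- empirical-Bayes shrinkage: the prior `(d0, s0^2)` is estimated by moment
  matching on `log s2_g` under the scaled-F model `s2_g ~ s0^2 F(d, d0)`
  (mean and variance of log s2 give two equations; the trigamma equation is
  inverted by Newton iteration). If the observed dispersion of `log s2`
  does not exceed what `d` alone implies, `d0` is infinite and every gene
  shares `s0^2`. Exactly constant variances short-circuit to
  `d0 = inf, s0^2 = the common value` (the estimator's bias correction
  assumes random draws and would be wrong for a degenerate input).
  Zero variances are excluded from estimation; with `d0 > 0` such genes
  still get a positive posterior variance, while `d0 = 0` (moderation
  disabled) raises an error for them.
- moderated t: `t_g = log2fc_g / (s~_g sqrt(1/n_a + 1/n_b))` with
  `s~2_g = (d0 s0^2 + d s2_g)/(d0 + d)`; two-sided p-values from a
  t-distribution on `d0 + d` df (standard normal when `d0 = inf`).
  `d0 = 0` reproduces the classical pooled t exactly, which the tests use
  as a degeneracy check, and the whole path is cross-validated against
  limma's `lmFit + eBayes` on a small heteroscedastic fixture.

Benjamini–Hochberg adjustment is implemented directly (step-up
`q_(i) = min_{j>=i} p_(j) m/j`, capped at 1, ties preserved, order
invariant) because it is contractually part of both the DE and the GSEA
modules; tests compare it against a literal brute-force implementation and
against statsmodels. Genes are selected at `|log2FC| >= 1` (inclusive) and
`FDR < 0.05` (strict), both exposed as parameters.

Scope: only two-group contrasts are supported — the design under study has
no other contrasts. Technical replicates are treated as independent
samples; with triplicates this overstates the effective sample size on real
data, and the moderated t partially compensates by borrowing variance
information across genes.

## Preranked GSEA

Genes are ranked by the moderated t, descending; ties break by ascending
gene id so the ranking is reproducible. For a set S of size n_s in a
universe of N genes, walking the ranking accumulates
`+|t|^w / sum_S |t|^w` at members and `-1/(N - n_s)` elsewhere (default
weight w = 1; w = 0 gives the unweighted Kolmogorov–Smirnov form). The
enrichment score is the extremal deviation from zero, signed; at an exact
magnitude tie the positive extreme is taken. The implementation evaluates
only hit positions (the extrema can occur only immediately after or before
a hit) and matches both a literal running-sum oracle and
`fgsea::calcGseaStat` in tests.

The null model draws random same-size gene subsets of the universe — the
only permutation scheme available to preranked input. p-value and NES use
the same-sign permutation population:
`p = (1 + #{perm same sign, |ES_perm| >= |ES|}) / (1 + #{perm same sign})`,
`NES = ES / mean |ES_perm same sign|`; whether the original analyses
normalized within the same-sign population is not documented, so this
classic convention is adopted and frozen. FDR across sets is BH on the
permutation p-values (consistent with the fgsea-style workflow; the
original NES-binned FDR is deliberately not implemented). Defaults are
10,000 permutations and a [15, 500] post-intersection size filter.

## Signature scores

All scores operate on log2 expression. The matrix is median-centered per
gene across **all** analyzed samples (not per condition): the scores are
comparative by construction, and centering within condition would erase the
very contrast being measured. The across-sample median uses the midpoint
rule for even counts.

- MAPK output and TDS: per-sample mean of centered expression over the
  signature genes.
- BRS: mean over RAS-ward (up) genes minus mean over BRAF-ward (down)
  genes. The exact weighting used by the original cohort-derived score is
  not recoverable from the published description, so this equal-weight
  difference convention (positive = RAS-ward, matching the TCGA sign
  convention where negative = BRAF-like) is frozen and isolated in a single
  function for easy substitution.
- Rank-based single-sample score: per sample, genes are ranked ascending
  with average ranks on ties; a direction class's mean rank is min-max
  normalized to [0, 1] and centered to [-0.5, 0.5]; directional sets add an
  up and a down component (down on reversed ranks), giving a [-1, 1] range.
  The score depends only on within-sample ranks, hence is invariant to any
  strictly monotone transform of one sample's values.

Missing signature genes: scoring proceeds with a coverage warning when at
least 50% of members are present and errors below that; platform dropout
behavior is otherwise undocumented, and 50% keeps directional sets from
collapsing to one class silently.

Subtype call: sign of BRS (negative BRAF-like, positive RAS-like). The
measure-zero BRS = 0 tie is assigned RAS-like purely for determinism and
flagged in the output.

## Cross-dataset integration

Datasets are joined on their common genes (sorted lexicographically for
determinism), then each gene is standardized within each dataset to mean 0
and unit standard deviation with the n-1 divisor (a convention frozen here
and asserted by tests). Genes with zero variance in any batch are dropped
before z-scoring rather than set to 0, to avoid spurious distances; the
dropped list is logged.

Clustering is agglomerative on Euclidean distances with Ward's
minimum-variance criterion in its Ward.D2 form (scipy's `linkage(...,
"ward")`); heights differ from the legacy Ward.D variant, which is why the
variant is documented. Restriction to a signature (the 71-gene BRAF-RAS set
reproduces the subtype co-clustering analysis) is applied after
standardization, i.e. the order is standardize → merge → cluster on the
signature genes. PCA mean-centers genes without rescaling (the input is
already z-scored per dataset); signature-restricted PCA is the default
analysis for subtype geometry, with all-gene PCA also supported. Agreement
between a cut and known classes is the adjusted Rand index.

## Synthetic data generator

The generator emulates the study design the pipeline targets, not any real
dataset:

- Cell-line experiment: 3 conditions (vehicle DMSO + 2 BRAF inhibitors) x
  3 technical replicates, simulated as independent samples.
- Tissue cohort: 29 samples, 15 BRAF-like / 14 RAS-like, in a separate
  batch.
- Gene universe 5,000 genes by default; per-gene baselines drawn once from
  Normal(8, 2^2) log2 units, a typical microarray intensity range.
- Planted signatures of sizes 52/16/71 mirroring the packaged ones, drawn
  disjointly from the universe via a seed substream separate from the
  noise stream (so changing sigma never changes membership).
- Effects on the log2 scale in non-control samples: MAPK-like genes -delta,
  TD-like +delta, BRAF-RAS up(RAS) genes +delta and down(BRAF) genes
  -delta; cohort groups are shifted in opposite directions along the
  BRAF-RAS signature only. Default delta = 2 log2 units for all three
  effects and noise sigma = 0.25 — a strong, cleanly separable effect
  regime chosen to represent the pronounced treatment-induced shifts the
  design is meant to exhibit; the true effect sizes in real treated cells
  are not published as numbers and these defaults are free parameters, not
  a calibration.
- Noise is i.i.d. Gaussian on the log2 scale. No gene-gene correlation
  beyond the planted mean shifts, no probe-level structure, no
  batch-intensity artifacts, no dose-response. Consequently, passing tests
  demonstrate correctness of the statistical machinery under the assumed
  model, not robustness to correlated noise, outliers or platform effects
  found in real arrays.

Determinism: each dataset uses a single seeded RNG stream; the same
configuration and seed reproduce every matrix bit for bit (asserted by
re-running simulation and GSEA twice in the tests).

## Packaged signatures

The three thyroid signature gene lists ship as a GMT file with a
directional dialect (`GENE|up` / `GENE|down`; plain tokens undirected —
standard GMT remains readable). Sizes are exact (52 MAPK output, 16 TD, 71
BRAF-RAS with 36 RAS-ward / 35 BRAF-ward members); membership was
transcribed from the published signature literature with symbols harmonized
to current HGNC usage. Probe-level inputs are collapsed to genes by the
MaxMean rule (keep the probe with the largest mean across samples) with
ties broken by lexicographically smallest probe id; array normalization
itself (RMA and relatives) is out of scope — the pipeline starts from a
normalized log2 matrix.

## Problem sizes in the shipped checks

Tests and the acceptance script exercise the defaults end to end: 5,000
genes, 3 vs 3 replicates, the 29-sample cohort, and 1,000–2,000
permutations for GSEA (the 10,000-permutation default remains available at
the API level). The empirical-Bayes recovery check uses 10,000 simulated
variances; the BH and ES oracle comparisons use exhaustive small instances
plus 1,000 random cases each.
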