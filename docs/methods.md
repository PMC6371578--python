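# Methods

## Problem setting

`methexpr` implements an integration analysis for case/control blood
studies profiled on two platforms: a gene-expression microarray (log2
scale, quantile-normalized upstream) and the Illumina 450K methylation
array (beta values in [0, 1]). The goal is a ranked panel of candidate
blood biomarkers — genes that are simultaneously hypo-methylated and
upregulated in cases (hypo-up genes) — together with the gene regions that
carry the methylation change, and a cross-validated classifier built from
the panel.

The two cohorts need not contain the same individuals for the differential
and integration stages; only the correlation analysis requires matched
samples (see Deviations).

## Differential models

Both platforms use the same two-group linear model per feature. The effect
is the case-minus-control mean (log2 fold change for expression, M-value
difference for methylation). By default the per-feature variances are
moderated: an empirical-Bayes prior (d0, s0²) is estimated by method of
moments on log s² across features (with a Newton inversion of the trigamma
function), and the posterior variance (d0·s0² + d·s²)/(d0 + d) with
df = d0 + d replaces the raw one. When the moment estimate implies no
excess spread of variances, the estimator degenerates to complete pooling
(a normal reference distribution); the ordinary pooled-variance t-test
(`moderated=False`) is retained and serves as an oracle in tests.
Zero-variance features with equal group means report t = 0, p = 1; under
moderation the prior variance takes over and avoids division by zero.

Multiple testing uses the Benjamini-Hochberg step-up adjustment computed
across all features of the analysis at hand. A gene is a DEG when
adj-p < 0.05 **and** |log2FC| > 0.1, both strict, mirroring the thresholds
this analysis style prescribes.

## Methylation scales and region summarization

Statistics run on M-values, m = log2(b/(1−b)), which are unbounded and
closer to homoscedastic; effects are reported as delta-beta (case mean −
control mean beta), the interpretable scale. Betas are clamped to
[1e−6, 1−1e−6] before the logit because background-normalized arrays touch
0/1. P-values that underflow double precision are floored at the smallest
positive normal float so bounds like "p < 2.2e−16" stay decidable.

A gene's methylation level at a region selector (TSS1500, TSS200, 5′UTR,
1stExon, Body, 3′UTR) is the arithmetic mean beta over the CpGs assigned
to that gene with that label; the pooled `ALL` selector averages each
distinct CpG of the gene once. A probe annotated to several genes
contributes to each of them. Probes missing in more than 20% of samples
are dropped at load time; otherwise a missing beta is skipped only for the
affected sample.

A feature is differentially methylated when **both** criteria hold: its
delta-beta lies below the 0.1 quantile or above the 0.8 quantile of the
delta-beta distribution over all features of the analysis, and its
BH-adjusted M-value p is < 0.05. Quantiles use linear interpolation of
order statistics (h = (n−1)q); the 0.8 cut is taken literally as the 0.8
quantile. All inequalities are strict.

Enhancer enrichment of differential intergenic CpGs uses the Pearson
chi-square test (df = 1) on the 2×2 table differential/non-differential ×
enhancer/non-enhancer, without continuity correction by default (a Yates
flag exists; at the magnitudes involved it cannot change conclusions).

## Integration

Genes significant in both analyses are crossed into four classes: hypo-up,
hyper-down, hyper-up, hypo-down. The DMG side of the default overlap is the
`ALL`-region caller; per-region overlaps come from the same operation with
each selector. For a gene of interest, the dominant methylation-altered
regions are those whose delta-beta is strictly within 0.005 of the gene's
minimum delta-beta; the argmin region is always dominant, regions without
probes never are, and a gap exactly equal to 0.005 is excluded (strict
inequality, as the rule is stated).

Expression–methylation correlation draws a fixed random subsample (without
replacement, n per group) of matched samples and reports Pearson r with the
two-sided t-based p per gene × region. For hypo-up genes the expected
signature is predominantly negative r.

## Classifier

One random forest per LOOCV fold (500 trees by default, sqrt(p) candidate
features per split, impurity-decrease importance — the conventional
defaults of the forest implementation this analysis style relies on; all
configurable). Feature importances are averaged over folds and ranked
descending (ties break by feature identifier). Panels grow one feature at
a time in rank order; each size k is scored by LOOCV out-of-fold case
probabilities, AUC is the Mann-Whitney concordance (ties = 1/2), and the
panel p-value is the two-sided normal-approximation rank-sum test with tie
correction. The best panel is the smallest k attaining the maximal AUC.
Cross-cohort validation fits once on the full training cohort and scores
the other cohort unchanged; missing panel features are an error, never
silently imputed.

Determinism: each fold's forest seed derives from the master seed plus a
CRC32 hash of the held-out sample identifier (and k where relevant), and
training rows are sorted by sample identifier before fitting — results are
therefore invariant to sample and fold order, and every `auc_by_k` entry is
independently reproducible.

An optional gender feature (male = 1) can be appended to any feature
table; it enters only the classifier, never the differential models.

## Synthetic cohorts

The generator emulates the structure the analysis assumes rather than any
particular dataset: two-group log2 expression with per-gene Gaussian noise;
450K-style betas produced by planting all effects and noise on the M scale
and back-transforming, which keeps betas strictly inside (0, 1); probes of
one gene-region share a baseline drawn from `baseline_beta_range` plus a
small per-probe jitter (sd 0.15 on the M scale) so region averaging acts on
correlated CpGs; intergenic CpGs with enhancer flags whose planted
differential subset has its enhancer odds multiplied by a configurable
factor; and 1:1 random gender with an optional shift applied to 5% of
genes. The M-scale shift of a planted probe is calibrated per probe so the
noiseless beta difference equals `meth_effect`; the realized group
difference after noise stays within a few percent of the target for
mid-range baselines (verified in tests at 20% tolerance). Planted
differential intergenic CpGs are 80% hypo / 20% hyper, matching the
direction balance blood studies of this design report.

Default study conditions: 200 cases vs 200 controls, 2000 genes, two CpGs
per gene region, 1000 intergenic CpGs (32% enhancer baseline, odds
multiplier 2.2 — the magnitudes implied by published intergenic enhancer
tables), 85 planted hypo-up genes with `expr_effect` = 0.3 (log2) and
`meth_effect` = 0.05 (beta scale). Noise defaults were fixed once by a
power analysis before any tests were written: `expr_noise_sd` = 0.5 —
typical within-group variability for log2 microarray data, and a level at
which the 0.3 log2FC planted effect is reliably detectable under BH at
n = 200/200 (~99% power; at sd 1.0 the same effect is undetectable at
~30% power, which would make recovery experiments meaningless) — and
`meth_noise_sd` = 0.5 on the M scale (~0.09 beta-scale sd per probe at
mid-range baselines). By default a planted gene's methylation shift is
gene-wide (all six regions "dominant"), so the `ALL` aggregate carries the
full effect; region-specific patterns are configured per gene via
`dominant_regions`, with `meth_offregion_effect` controlling non-dominant
regions (default 0).

What the generator does **not** emulate: probe cross-hybridization, batch
effects, cell-type composition shifts, correlated gene networks, or raw
intensity artifacts. Passing recovery tests therefore demonstrates that
the pipeline's logic and calibration are correct under its stated
assumptions, not that real cohorts of a given size yield the same power.

## Problem sizes used in automated checks

The test suite and the acceptance script run at desk scale, chosen as the
smallest sizes at which each property is statistically decidable: null
calibration on 100 zero-effect cohorts of 2000 genes at 40 vs 40;
planted-signal recovery on one 200/200 cohort at generator defaults;
dominant-region recovery on 60 planted genes at 200/200; classifier
experiments at 50 vs 50 with 85 planted features, 150 trees, and panels
capped at 12 features (the AUC curve plateaus well before that under the
default effect sizes).

## Deviations and design choices

* The source analysis style drew its correlation subsample from two
  cohorts of different individuals; per-gene correlation across unmatched
  individuals is not well defined, so this package requires matched
  samples (synthetic cohorts are matched by construction) and documents
  the difference here.
* The conditional-inference-tree forest variant is not reimplemented; the
  gender-feature comparison runs with the standard forest.
* GEO series-matrix files: only the value table is extracted; sample
  metadata travels in a sidecar TSV (sample_id, group, gender), which
  keeps fixtures plain and readable.
* BH with NaN p-values: NaNs pass through as NaN and do not count toward m.
* A 2×2 table with a zero marginal is an error ("degenerate table") rather
  than a silent p = 1.

## Known limitations

* The moderated-t prior estimator uses the standard method-of-moments fit;
  for very small feature counts (< ~20) the prior is unstable and the
  estimator falls back to complete pooling.
* Incremental panel selection reuses the full-cohort importance ranking in
  every fold (as the source style does); the LOOCV AUC of the selected
  panel therefore carries a mild selection optimism. The permutation and
  cross-cohort checks bound its practical size.
* Region aggregation weights every CpG equally; no probe-type (I/II)
  normalization is applied, as inputs are assumed preprocessed.
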