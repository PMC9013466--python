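# Methods

This note documents the statistical models, parameter defaults and design
choices behind `stimskew`, and what the synthetic-data experiments do and
do not establish about real data.

## Count model and normalization

Gene-level counts are treated as negative binomial (NB) with mean μ and
variance μ + φμ², the standard RNA-seq parameterization in which φ = 0
recovers the Poisson and φ quantifies biological replicate-to-replicate
variability (typical bulk values 0.01–0.4; the simulators default to 0.1).

**Low-count filter.** "Primarily zero" genes are removed before any
modelling: a gene is kept when its library-size CPM is ≥ `min_cpm`
(default 1) in at least `min_samples` samples (default: the smallest group
size).  The filter uses plain library-size CPM, not TMM-adjusted CPM, so
that filtering does not depend on the normalization it precedes.

**TMM.** Per-sample scale factors are weighted trimmed means of per-gene
log₂ expression ratios (M-values) to a reference sample, excluding genes
with a zero in either sample, trimming the extreme 30 % of M-values and
5 % of A-values on each side (rank-based, the conventional defaults), and
rescaled so the factors' geometric mean is exactly 1.  The reference is
the sample whose upper-quartile count fraction is closest to the mean
upper quartile.  Precision weights follow the binomial (delta-method)
variance of a log count ratio but are expressed through the count
*proportions* only, `w = (1−p)/p + (1−p_ref)/p_ref`; this departs from
formulations that divide by library size and makes the factors — and hence
every CPM value — exactly invariant under rescaling any single sample's
counts, which is also the property the unit tests assert.  Samples with no
positive genes shared with the reference get factor 1 with a warning.

**CPM / FPKM.** CPM = count / (library size × factor) × 10⁶; FPKM
additionally divides by gene length in kb.  Log expression is
log₂(CPM + 0.125) throughout: the pseudocount 0.125 keeps ratios of
zero-count groups finite and is the same constant used for fold-changes.

## Dispersion estimation

A common φ maximizes the NB likelihood conditional on per-group totals
(which removes the group means from the likelihood), pooled over genes.
Because conditioning requires exchangeable samples, counts are first
quantile-adjusted to a common (geometric-mean) effective library size:
each count is mapped through the midpoint-corrected CDF of its fitted NB
to the matching continuous quantile at the common size.  Adjustment and
estimation are alternated twice; with equal effective sizes the adjustment
is the identity.  The optimizer is bounded on log φ ∈ [10⁻⁶, 10], so
Poisson-like data yield estimates at the lower bound rather than exactly 0.

Tagwise (per-gene) dispersions maximize the per-gene conditional
likelihood plus `prior_weight` (default 10) times the genewise-average
likelihood, evaluated on a log-spaced grid that includes the common
estimate; as the prior weight grows every tagwise value collapses onto the
common φ.  The default weight gives mild shrinkage appropriate for the
small replicate numbers (n = 3–6) these designs have.

## Exact two-group test

With equalized library sizes, the sum of n i.i.d. NB(μ, φ) counts is
NB with size n/φ, so conditional on the two-group total *t* the case-group
sum follows Beta-Binomial(*t*, n₁/φ_g, n₂/φ_g) — Binomial(*t*, n₁/(n₁+n₂))
in the Poisson limit (φ_g < 10⁻⁸).  The two-sided p-value sums the
probabilities of all splits whose probability does not exceed the observed
one; ties are included with a 10⁻¹⁰ log-probability tolerance, so a
perfectly symmetric observation returns p = 1 and the (0, 10) split at
φ = 0, n₁ = n₂ = 1 returns 2/1024 exactly.  Group sums of the adjusted
(generally non-integer) pseudo-counts are rounded to the nearest integer
before conditioning.  The tail computation is canonicalized in the group
order so that swapping case and control labels reproduces the identical
floating-point p-value while negating the fold-change.

The table's `log2fc` is not the model-based estimate but the pseudocount
fold-change of TMM-normalized group-mean CPM, the same quantity used for
plotting and classification.  BH step-up adjustment (delegated to
statsmodels) controls FDR; `significant` means FDR ≤ α (default 0.05).

## Outlier screening

Samples are projected by PCA of the gene-centered log-expression matrix.
A sample is *flagged* when its Euclidean distance to its group centroid in
the first two components exceeds median + 3×MAD of all within-group
distances (raw MAD, not normal-consistent).  The rule is deliberately
report-only: replicate numbers are too small to justify automatic
exclusion, so flags are surfaced for the analyst to act on.

## Two-way classification

The classified universe defaults to genes significantly regulated at
least twofold (|log₂FC| ≥ 1, pseudocount fold-change) versus control under
either stimulus (`restrict_to_universe=True`); both the threshold and the
restriction are configurable, since one may prefer to classify every
tested gene.  The decision table, applied to the significance flags of the
three contrasts:

| stim1 vs ctrl | stim2 vs ctrl | directions | stim1 vs stim2 | category |
|---|---|---|---|---|
| – | – | · | · | NOT_REGULATED |
| sig | – | · | · | STIM1_SKEWED |
| – | sig | · | · | STIM2_SKEWED |
| sig | sig | opposite | · | skewed toward the **up** stimulus |
| sig | sig | same | – | CORE |
| sig | sig | same | sig | skewed toward the larger \|log₂FC\| |

Two resolutions are our own where the verbal rules are ambiguous: (i) a
gene significant in both vs-control contrasts *and* between the stimuli
matches both skew definitions; it is assigned to the stimulus with the
larger fold-change magnitude, matching the visual interpretation of the
two-way fold-change plot, and an exact magnitude tie (measure-zero on real
data) falls back to CORE with a warning; (ii) discordant-direction genes
are never CORE regardless of the between-stimulus flag.  Category shares
(core as a percentage of each stimulus' regulated genes) are reported to
one decimal.

## Cross-study meta-analysis

Each study is processed fully independently — filter, TMM, dispersion, one
exact test per comparison — mirroring how heterogeneous public data must
be handled.  Genes significant in ≥ `min_comparisons` comparisons
(default 4; every supplied comparison counts) form the recurrent set.
Their log₂(CPM + 0.125) expression — the "normalized reads" scale; a
linear scale is configurable — is standardized per gene *within each
study* (ddof = 1; constant genes map to 0), which removes any per-study
additive offset of the log-expression exactly; this Z-score harmonization
is the batch correction, and the tests assert bitwise invariance of the
Z-matrix and the clustering under injected per-study offsets.  The
combined matrix is clustered by agglomerative hierarchical clustering,
complete linkage on Euclidean distances (the defaults of the common
heatmap tools), cut into exactly *k* flat clusters; *k* is a user
parameter (22 in the motivating application) with no automatic selection.
Cluster summaries are median (midpoint-interpolated) pseudocount log₂
fold-changes per comparison, and set-overlap shares are
100·|cluster ∩ reference|/|cluster|.

The gene universe across studies is the intersection of the studies' gene
sets (warned about when it drops genes); genes filtered out of an
individual study but recurrent overall enter that study's block of the
Z-matrix at the log-pseudocount floor.

## Purity QC

A preparation passes when every signature marker exceeds the detection
threshold (default 1 FPKM/CPM — "not detectable" has no published numeric
cutoff, so a 1-unit floor is used) in at least `frac_samples` of samples
(default all) and every contaminant-class marker stays below it.  Markers
absent from the matrix are reported as not quantified and excluded from
the verdict.  A default panel (microglia signature genes; astrocyte,
oligodendrocyte and neuron contaminant classes) ships as a GMT file.

## Simulators and study conditions

`simulate_three_group` draws per-gene baseline abundances log-normally
(natural-log mean 3.0, sd 1.5 on the CPM scale, normalized to
proportions), per-sample library sizes uniformly in [0.8, 1.2]×10⁶, and NB
counts at φ = 0.1 with 5 replicates/group by default — sizes typical of
sorted-cell bulk RNA-seq.  Planted categories (default 3 % of genes each
for core-up/down and the four skewed classes, |log₂FC| = 2) multiply the
mean of the affected case group only, so controls are identical across
categories; the induced mild composition shift is what TMM exists to
absorb.  `simulate_multistudy` shares one gene universe across studies,
plants co-regulation clusters as genes sharing a log₂FC vector across
comparisons, and adds per-study-per-gene Gaussian offsets (sd 1 natural-log
unit by default) to the log-mean of *all* samples of a study — a batch
effect that leaves within-study contrasts unbiased.  A study-wide scalar
offset would cancel in CPM; gene-wise offsets are what Z-scoring is
actually needed for.

What passing synthetic tests shows: correct arithmetic, calibrated type-I
error under the generating model, and recovery of effects the model can
express.  What they do not show: robustness to features the generator
omits — gene–gene correlation, outlier samples, GC/length biases,
count-level technical artifacts, or dispersion varying with expression.

## Evaluation experiment sizes

The packaged experiments (`stimskew.evaluation`) use 2,000 genes with
20 seeds for null calibration (n = 5/group), 2,000 genes with 10 seeds for
category recovery (n = 3/group, planted |log₂FC| = 2), and 1,000 genes /
3 studies / 5 planted 40-gene clusters with 10 seeds for meta-analysis
recovery — large enough for stable Monte-Carlo summaries while keeping a
full run in minutes on one CPU.

## Known limitations

* The exact test assumes a single dispersion per gene shared by both
  groups and no covariates; GLM designs are out of scope.
* Quantile library-size equalization uses the pooled two-group abundance
  for the tested contrast; under very strong DE with very unequal library
  sizes the adjustment is slightly misspecified (the classical behaviour
  of this test family).
* Printed gene counts from the motivating study (e.g. 445/439, 869/680
  DEGs, the 22-cluster partition) depend on the deposited datasets and are
  not reproduced here; only their defining rules and arithmetic are.
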