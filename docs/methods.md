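# Methods

This note documents the statistical models, the synthetic-data generators,
the numerical choices and the known limitations of `glycocode`. Everything
stated here is computed by the test suite or by `scripts/acceptance.py`;
nothing is quoted from elsewhere.

## Moderated differential expression

For each gene the two supported designs give an effect estimate β̂_g, a
residual variance s²_g with d_g degrees of freedom, and a standard-error
scale u_g:

* unpaired: β̂ = mean difference, s² the pooled variance,
  d = n₁ + n₂ − 2, u = √(1/n₁ + 1/n₂);
* paired: a one-sample analysis of within-pair differences,
  d = n_pairs − 1, u = √(1/n_pairs).

The prior (d₀, s₀²) is estimated by moment matching on
e_g = log s²_g − ψ(d/2) + log(d/2): the mean of e identifies s₀² and the
excess of var(e) over ψ′(d/2) identifies d₀ via Newton inversion of the
trigamma function. When the excess is non-positive there is no evidence of
variance heterogeneity: d₀ = ∞ and every gene is shrunk completely to
s₀² = mean(s²) (the arithmetic mean, matching the reference empirical-Bayes
implementation, against which the finite-d₀ path agrees to 1e-15 — see
`tests/test_diffexp.py`). The moderated statistic
t̃ = β̂ / (u · s̃), s̃² = (d₀s₀² + d s²)/(d₀ + d), is referred to a t
distribution on d₀ + d df (normal when d₀ = ∞). Zero-variance genes are
excluded from prior estimation; under moderation they get finite t̃, and in
the degenerate d₀ = 0 case a zero-variance gene with non-zero effect is
reported with p = 0 plus a warning. Only these two designs are
implemented — no arbitrary design matrices, voom weights or batch
covariates.

**Panel rule.** A gene enters the clustering panel when its raw p ≤ 0.01
in at least two cohorts (counting only cohorts that measured it). The
cut-off is applied to raw p by default because the rule is a screening
heuristic whose downstream consumer is clustering, not inference; a config
switch applies it to BH-adjusted p instead.

## Consensus clustering

Expression is median-centred per gene (a config switch disables this),
distances are 1 − Pearson correlation between sample columns, and the
inner algorithm is PAM: greedy BUILD (first medoid minimises total
distance, later medoids maximise cost reduction) followed by
best-improvement SWAP until no single medoid exchange lowers the cost, all
ties broken toward the lowest index, so the algorithm is fully
deterministic. Note that single-swap descent terminates at local optima;
on small random instances it reaches the exhaustive-search optimum on most
but not all draws (the unit suite asserts local optimality everywhere and
global optimality on cluster-structured instances).

Each of H iterations draws ⌈f·n⌉ samples without replacement (defaults
H = 2000, f = 0.9) with an RNG stream keyed by (seed, k, iteration), so
extending H never reshuffles earlier iterations. Consensus
C(i,j) = co-clustering count / co-draw count (0/0 → 0, diagonal 1). The
final partition cuts the average-linkage tree of 1 − C into k clusters.
A(k) is the area under the empirical CDF of the upper-triangular consensus
entries (step sum); Δ(2) = A(2) and Δ(k) = (A(k) − A(k−1))/A(k−1)
otherwise; the selected k is the largest with Δ(k) ≥ 0.1 (threshold in
config — the delta-area rule automates what is usually a visual call, and
Δ(4) sits near 0.09 on the default synthetic design, so occasional k = 4
selections at unlucky seeds are expected and visible in the acceptance
report). Subsampling is over samples only; gene resampling is off.

## Single-sample enrichment and derived scores

The per-gene statistic is the Gaussian-kernel cumulative
z_gi = (1/n) Σ_j Φ((x_gi − x_gj)/h_g) with bandwidth h_g = s_g/4 (floored
at 1e-8 for constant genes), which makes scores invariant to per-gene
affine transforms. Per sample, genes are ranked by z (descending, stable
ties by input order), weighted d_g = |p/2 − rank_g|^τ (τ = 1), and walked:
inside-set steps up by d_g normalised by the in-set total, outside-set
steps down by 1/(p − |S|). The score is the magnitude difference
max(0, max ν) + min(0, min ν). Kernel, τ and the ES mode are exposed.

EMT score = mesenchymal − epithelial score, so mesenchymal-high (Basal)
samples score high. The two obvious sign conventions both circulate; this
package fixes the one under which the Basal subtype has the higher score,
and this is the convention every downstream comparison assumes.

Kruskal–Wallis (tie-corrected, χ² reference) compares any score across
clusters; all-identical inputs return H = 0, p = 1 rather than an error.
Two-class GSEA ranks genes by signal-to-noise (μ₁−μ₂)/(σ₁+σ₂) with each σ
floored at 0.2·|μ| (0.2 when μ = 0), walks the |metric|-weighted KS sum,
and builds the null by phenotype permutation: NES = ES / mean|same-sign
null ES|, p = (1 + #{|same-sign null| ≥ |ES|})/(1 + #same-sign), BH across
sets; p is therefore bounded below by 1/(n_perm + 1). Module scores for
single cells follow the binned-control recipe: genes cut into 24
equal-frequency bins of mean expression, 100 control genes per set gene
drawn with replacement from the matching bin, score = set mean − control
mean. These defaults emulate the widely used implementations; no
bit-for-bit equality with them is claimed.

## Concordance network

Each classification scheme is applied by consensus-clustering the samples
on the union of the scheme's classifier genes with k = number of subtypes;
clusters are named after the subtype whose signature score has the highest
cluster mean, collisions resolved greedily in descending score-gap order.
At least 50% of each classifier set must be present in the matrix.
Cross-scheme subtype pairs become candidate edges: Jaccard coefficient as
weight, upper-tail hypergeometric p over the common sample universe
(per-dataset, not pooled), BH across all candidate edges, significance on
the adjusted p at α = 0.05 by default (raw-p switch available). The
significant-edge graph is clustered with MCL: self-loops of weight 1,
column normalisation, expansion power 2, inflation 2.0, pruning at 1e-8,
iterated to a 1e-6 fixed point; clusters are read off attractor-row
supports and merged into a partition. The shipped schemes
(`pipeline.default_schemes`) are synthetic stand-ins built from the
package's own gene sets; real published classifiers are supplied as GMTs.

## Survival

Kaplan–Meier product-limit curves and the multi-group log-rank test
(χ² on g − 1 df) are delegated to lifelines behind the package's record
types; hand-tabulated fixtures in the test suite pin the conventions:
events precede censorings at tied times, censored subjects count as at
risk at their censoring time, plain (unweighted, unstratified) log-rank.
For three clusters both the global test and unadjusted pairwise tests are
emitted; the pairwise p-values are explicitly flagged as unadjusted.

## Single-cell pipeline

Counts are normalised as log(1 + 10⁴·c/total); the mitochondrial fraction
is removed by per-gene OLS (residuals keep the gene mean; a constant
covariate passes through with a warning). This log-CP10k + covariate
regression is a deliberate simplification of variance-stabilising
transforms: the contract downstream stages rely on is "normalised,
covariate-decorrelated expression", not a specific VST. Highly variable
genes are ranked by within-mean-bin z-scored variance (20 bins; constant
genes never selected); PCA is exact SVD on centred genes with the sign of
each component fixed by its largest-|loading| gene; clustering builds a
k = 20 nearest-neighbour graph, weights edges by neighbour-set Jaccard
pruned below 1/15, and maximises resolution-scaled modularity with
seeded Louvain (resolution 1).

The circuit readout computes, per patient with both compartments, the mean
tumour-cell module score of each fucosylation programme (GDP-fucose
synthesis, fucosyltransferases, and their union) and the mean normalised
cytokine expression over that patient's macrophages, then Spearman
correlation across patients (Pearson by config; Spearman is the default
because patient-level summaries are few and the coupling need only be
monotone). Patients missing a compartment are dropped with a warning;
fewer than three usable patients is an error. Cytokine averages use all
cells carrying the macrophage label.

## Synthetic-data generators

The generators define the study conditions the acceptance experiments run
under; their defaults are fixed and are not claims about PDAC effect
sizes.

**Bulk.** Four cohorts (two paired, two unpaired), each with 30/30/20
tumours of the fucosylated/basal/low-purity subtypes and 30 normals, on
log2 scale:

    x_gi = μ_g + purity_i · (a_g + Σ_p L_gp · s_p(subtype_i)) · 1[tumour_i]
           + (1 − purity_i) · S_g · 1[tumour_i] + ε_gi,   ε ~ N(0, 0.5²)

with per-cohort baselines μ_g ~ N(7, 1) (so the ≥2-cohorts panel rule is a
real constraint), tumour shift a_g = 1 on all tumour programme genes,
programme loadings L = 2 (fucosylated loads fucosylation + O-glycan +
epithelial; basal loads basal + mesenchymal; low-purity loads nothing),
purity ~ Beta(8,2) for the tumour-cell subtypes and Beta(2,8) for the
low-purity subtype, and a stromal programme S = 2 on eight stromal genes
scaling with 1 − purity. Two modelling choices deserve emphasis because
the naive alternative fails: purity multiplies the *entire* tumour signal
(as bulk tumour/stroma mixing does), and the stromal programme gives
low-purity samples a shared positive profile. Without these, low-purity
samples are mutually uncorrelated noise under the 1 − Pearson distance and
no clustering algorithm can group them — with them, the generator
reproduces the reported phenomenology (low-purity samples co-cluster while
showing no glycan signature of their own). Paired cohorts link their 30
normals to tumours round-robin across subtype blocks, so pairs span all
subtypes. 300 background genes carry no effect; all catalogue genes ride
along so every glyco pathway is scorable (null pathways stay null).

**Survival.** Exponential times at baseline rate 1/600 per day with
hazard ratios 1.0 / 2.0 / 1.4 for fucosylated / basal / low-purity and
administrative censoring at 1825 days (about 95% event rate at baseline).

**Single cell.** 12 patients × 400 cells (50% tumour, 20% macrophage, 30%
other/stromal). Each tumour cell has a latent EMT position u ∈ [0,1]
(patient mean ~ Uniform(0.1, 0.9), cells ~ Beta around it with
concentration 10); four archetype profiles anchored at u = 0, 1/3, 2/3, 1
are interpolated by tent functions, fucosylation/O-glycan/epithelial
programmes load on 1 − u and mesenchymal/basal on u (log-amplitude 2).
Macrophage cytokines are coupled to the patient-level latent fucosylation
f_p = 1 − mean(u): log-mean shift = sign · c · 2(f_p − 0.5) with c = 1 and
signs IL6 −, CXCL8 −, TGFB1 +. Counts are negative-binomial
(gamma-Poisson, dispersion 0.3) over softmax-composed rates at log-normal
library sizes (median 2000); dispersion 0 with a fixed library degenerates
to rounded means, which the tests use as the noise-free limit.

What the generators do *not* emulate: probe-level microarray artefacts,
doublets and ambient RNA, realistic gene–gene correlation beyond the
planted programmes, non-exponential hazards, or informative censoring.
Passing tests therefore demonstrate that the pipeline recovers the
structure it is designed for when that structure is present — not that
real cohorts contain it.

## Problem sizes and determinism

The acceptance experiments run at desk scale as the package's own choice
of problem size: consensus recovery uses 250 subsample iterations
(10 seeds), calibration experiments use 100 seeds at n = 100 per arm
(log-rank) and 2000 null genes (moderated t), and the single-cell circuit
uses the default 12 patients × 400 cells over 10 seeds. All randomness
flows from explicit seeds through `numpy.random.SeedSequence` (per-(k,
iteration) children in consensus clustering); rerunning any pipeline with
the same config and seed reproduces byte-identical output files, which the
test suite asserts by hashing two complete run directories.

## Known limitations

* The moderated-t module covers exactly the two designs used here.
* PAM is a local-descent heuristic; global optimality is not guaranteed
  (see above) and is not required by any downstream stage, which consume
  consensus frequencies rather than single partitions.
* GSVA-style scores use the Gaussian kernel appropriate for log-scale
  data; a count-model kernel for raw counts is not implemented.
* Scheme classification assumes classifier gene sets discriminate on the
  provided matrix; it does not re-derive published centroids.
* The log-rank pairwise comparisons are unadjusted by design; users
  comparing many clusters should adjust externally.
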