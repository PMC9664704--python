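# Methods

## Scope and model

`sspatk` transforms a samples × metabolites abundance matrix
X<sub>n×m</sub> into a samples × pathways score matrix A<sub>n×P</sub>:
one enrichment score per sample and pathway ("single-sample pathway
analysis", ssPA).  A pathway is identified with the set of metabolite
identifiers annotated to it; all scoring operates on the *measured*
member subset (members present as matrix columns), with the convention
that a pathway enters the analysis only if at least `min_coverage = 2`
of its members are measured.  Full member sets are retained for
reporting (`CoverageView`).

## Post-processing chain

The expected input to scoring is a post-processed matrix produced by,
in order: iterative-SVD imputation of missing intensities, probabilistic
quotient normalisation (PQN) against the per-metabolite median spectrum,
log2 transformation, and per-metabolite standardisation to mean 0 and
sd 1 (sample sd, ddof = 1 — stated explicitly because the z-score
scorer inherits it).  Each step is independently callable.  The
imputation rank defaults to `min(10, min(n, m) − 1)` and convergence is
declared when the relative Frobenius change of the imputed entries
falls below `1e-4` (both exposed; the literature on this pipeline does
not pin either value).  Non-convergence is recorded in the provenance
as a warning rather than an error, since the partially converged fill
is still a valid imputation.

## The six scorers

All six share the contract (standardized matrix, coverage-filtered
collection) → score matrix and are deterministic given their inputs and
seed.

* **z-score** — score(i, k) = Σ<sub>j∈p_k</sub> z<sub>ij</sub> / √M_k.
  On independent standardized members the scores are again approximately
  standard normal.
* **SVD (PLAGE)** — the unit-norm left singular vector of the pathway
  submatrix Z_k (n × M_k) for its largest singular value, computed via
  the M_k × M_k Gram matrix (M_k ≪ n in practice).
* **ssGSEA** — per sample, metabolites are ranked by abundance
  (descending; average ranks at ties, stable order for the walk); the
  enrichment score is the *integrated* running sum of the weighted
  in-set ECDF (weights = rank<sup>α</sup>, α = 0.25) minus the
  unweighted out-set ECDF.  The integrated form (rather than the max
  deviation) follows the ssGSEA lineage and is what distinguishes it
  from GSVA here.  Optional normalisation by the score-matrix range is
  off by default.
* **GSVA** — per metabolite, a Gaussian-kernel CDF estimate across
  samples (bandwidth = sd/4); per sample, the kernel statistics are
  ranked across metabolites with *ordinal* tie-breaking in stable
  column order and converted to the symmetric statistic |m/2 − rank|;
  the enrichment score is the max-diff statistic (largest positive plus
  largest negative deviation) of the KS-like walk with in-set weights
  |r|<sup>τ</sup>, τ = 1.  Ordinal rather than midrank tie handling is
  used because midranks can make the symmetric statistic vanish for an
  entire tied group, leaving a pathway with zero total walk weight.
  Because both the kernel CDF and the ranks are invariant to
  per-metabolite affine rescaling, GSVA scores are identical whether or
  not the matrix is re-standardized after spiking.
* **ssClustPA** — per pathway, k-means with k = 2 (k-means++
  initialisation, 10 restarts from a seeded stream, relative tolerance
  1e-6) on Z_k; scores are the projection A_k = Z_k u onto the unit
  vector u between the two centroids.
* **kPCA** — per pathway, an RBF kernel K<sub>ij</sub> =
  exp(−γ‖x_i − x_j‖²) on the rows of Z_k with γ = 1/n by default
  (n = number of *samples*; library defaults elsewhere often use the
  number of features, so γ is exposed); the double-centered kernel's
  leading eigenvector scaled by √eigenvalue is the PC1 score vector.

SVD, ssClustPA and kPCA scores have an intrinsically arbitrary sign.
The `mean-correlation` sign policy flips each column so it covaries
non-negatively with the per-sample mean of its pathway submatrix; this
makes output deterministic without asserting that positive scores mean
up-regulation (no such claim is possible for these methods).

## Comparators

ORA: one-sided Fisher's exact test on the 2×2 membership table of
differentially abundant (DA) metabolites per pathway, where the DA set
comes from per-metabolite two-sided t-tests at BH q ≤ 0.05 and the
background is the measured metabolites annotated to at least one
pathway (configurable to all measured).  Only pathways with ≥ 1 DA
member receive a p-value; BH runs over those.  GSEA: metabolites ranked
by the signed equal-variance t statistic, max-deviation weighted KS
enrichment score (weight 1), sample-label permutation p-values with the
plus-one correction, BH over all tested pathways.

## Permute-and-spike benchmark

Each iteration permutes the group labels (erasing real signal), draws
k = 3 enriched pathways E, and adds a constant α on the log2 scale to a
`signal_fraction` percent of the pooled measured members M_k, in the
permuted second group only — so α = 1 is exactly a raw-scale fold
change of 2.  By default the spiked matrix is re-standardized per
metabolite before scoring (`restandardize=True`): the spike is read as
acting on the log2 scale *before* the standardisation step of the
post-processing chain.  The alternative reading (spiking the already
standardized matrix, α in sd units) is available by flag; per-metabolite
t-tests are identical between the modes, pathway scores differ only
mildly, and GSVA is provably identical.

Per-pathway significance is a two-sided equal-variance t-test on score
columns (Welch optional) with BH correction; a pathway is *truly
positive* if it is in E or its measured member set has overlap
coefficient ≥ θ with M_k (θ ∈ {0.25, 0.5} are the conventional
choices).  Recall = TP/(TP+FN); precision = TP/(TP+FP), recorded as 0
with a flag when nothing is called significant; AUC is the rank-based
ROC AUC of −log10 p against the positive-class labels with midrank tie
handling, recorded as undefined (and excluded from aggregation) if only
one class is present.  Normalized ranking performance is the mean over
E of rank(p)/n_tested (midranks at ties; an enriched pathway a method
does not test — possible for ORA — is charged the worst rank).

Per-iteration RNG streams are spawned from the master seed, and all
methods see the identical spike design within an iteration, so method
comparisons are paired and reruns are bit-identical.  Scorer failures
are recorded per iteration with the reason and do not abort the run.

## Synthetic data

The generator emulates a post-processed untargeted MS plasma dataset:
260 samples × 335 standardized log-scale Gaussian metabolites with
block-equicorrelated structure (block sizes 5–20, within-block ρ = 0.3,
realised by a shared factor per block, hence positive semi-definite for
any ρ ∈ [0, 1)).  It reproduces the *shape* of such data — marginal
scale, block covariance, two-group design — but not heavy tails,
metabolite-specific noise, batch structure, or the alignment of pathway
membership with correlation blocks; passing benchmarks on it therefore
demonstrate the machinery and the methods' relative behaviour under
controlled conditions, not performance guarantees on any particular
real dataset.  Pathway collections come as fully disjoint sets
(pairwise overlap coefficient 0, the "non-redundant" scenario) or from
a shared-pool model in which each pathway re-draws a controlled
fraction (default 0.5) of its members from metabolites already used,
giving a spread of pairwise overlaps on both sides of the conventional
θ thresholds.

## Downstream analyses

Sample clustering uses Ward linkage on Euclidean distances of
per-pathway standardized scores, cut at 2 branches, evaluated with the
adjusted Rand index against known labels; the cumulative-threshold
curve re-clusters on growing prefixes of features ordered by BH
q-value (q ≤ 0.05).  The correlation network takes the top 50 pathways
by two-group t-test p (ties broken by pathway id), computes pairwise
Spearman ρ of the score columns, and keeps edges with *signed* ρ ≥ 0.4
(the absolute-value rule is available but off by default, since the
signed reading matches the stated convention); nodes carry a 2-branch
Ward cluster id and the mean standardized score per sample group, which
supports more than two groups.

## Numerical choices and degenerate inputs

Zero-variance metabolites are an error for standardisation and for the
GSVA bandwidth; constant score columns get t-test p = 1 by convention
with a warning; all-zero pathway submatrices, coincident k-means
centroids and non-positive leading kernel eigenvalues are errors.
p-values are clipped at 1e-300 before −log10 for AUC.  BH q-values are
computed by the step-up procedure with monotonicity enforcement, capped
at 1.

## Problem sizes used in the shipped checks

The simulation-scale checks run 100 iterations (18-pathway disjoint and
200-pathway redundant collections) and 200 iterations for null
calibration, on the 260 × 335 synthetic base matrix — sizes chosen so a
full check runs in minutes on a single core while keeping the Monte
Carlo standard error of the aggregated metrics near 0.01.  Stochastic
claims are asserted in the usual Monte-Carlo form (observed mean within
two standard errors of the claimed level).

## Known limitations

No identifier mapping between metabolite namespaces; no topology-aware
scoring; the benchmark simulates a two-group design only; ssClustPA
assumes two clusters and is not recommended for multi-group designs
(kPCA is the multi-group option); competitive scorers (ssGSEA, GSVA)
show mild false-positive inflation for non-enriched pathways under
strong spikes, because a spike perturbs every sample's within-sample
ranking — visible as a precision penalty in benchmarks and documented
behaviour of this method family rather than an artefact of this
implementation.
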