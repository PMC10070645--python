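# Methods

`snfcc` stratifies a cohort described by several data-type blocks into
subgroups by fusing per-block patient-similarity networks and
consensus-clustering the fused network, then profiles the subgroups with a
nonparametric test battery. This note records the model, the defaults and
the numerical choices, and what the synthetic cohorts do and do not emulate.

## Preprocessing

Subjects with any in-model numeric value outside the per-variable Tukey
fences `[Q1 − k·IQR, Q3 + k·IQR]` (default `k = 3`, quartiles by linear
interpolation) are excluded before anything else; fence equality is inside.
An alternative median-anchored mode (`mode="median"`) is available because
"k times the IQR" rules are stated ambiguously across the literature; Tukey
fences are the default. Exclusion uses raw values; all standardization
statistics are computed on the retained subjects only.

Zero-inflated count variables are recoded to 3-level ordinals: level 0 for
zero, level 2 at or above the top-quintile cutpoint (80th percentile, linear
interpolation, computed over all subjects including zeros by default —
`include_zeros_in_quintile=False` restricts to positive values), level 1
otherwise. Recoding is monotone by construction.

Mixed blocks are range-standardized (Gower): each numeric column is mapped
to `[0, 1]` by its observed range and ordinals enter as rank scores 0, 1, 2
likewise range-normalized, so the Gower distance is the equal-weight mean of
absolute per-variable differences and lies in `[0, 1]`. Numeric-only blocks
are z-scored with the sample SD (`n − 1`). Zero-range / zero-variance
columns are hard errors naming the variable.

## Similarity networks and fusion

Per block: Gower distance (mixed) or Euclidean distance (numeric). The
affinity is the locally scaled exponential kernel

    W(i,j) = exp( −d²(i,j) / (α · ε(i,j)) ),
    ε(i,j) = ( mean_K(i) + mean_K(j) + d(i,j) ) / 3,

with `K` the neighborhood size and `α` the edge-weighting parameter. Pairs
with `ε = 0` (identical subjects) get `W = 1`. A Gaussian-density variant
(`kernel="gaussian_density"`, scale `α·ε`) is provided because similarity-
fusion tools differ in which form they use; the two are strongly rank-
concordant but not identical, and the exponential kernel is the default.

From `W`, the full kernel `P(i,j) = W(i,j) / (2 Σ_{k≠i} W(i,k))` with
diagonal 1/2 (row-stochastic; exact symmetry is necessarily lost by row
normalization) and the sparse kernel `S` restricted to each subject's `K`
nearest neighbors (row-normalized, zero diagonal; ties at the K-th neighbor
break by subject index).

Fusion iterates `P(v) ← S(v) (Σ_{k≠v} P(k)/(m−1)) S(v)ᵀ` for `T = 20`
iterations (the common convention for this update; the per-step relative
Frobenius change is returned so convergence below the default tolerance
`1e-6` can be verified). Each step ends with the full-kernel renormalization
(diagonal restored to 1/2) and symmetrization `P ← (P + Pᵀ)/2`; the output
is the elementwise mean of the views, row-normalized and symmetrized once
more. The chosen normalization order is covered by invariance tests
(block-order permutation invariance, subject-permutation equivariance,
preservation of exact block structure) rather than bit-parity with any
external implementation. The final symmetrization perturbs exact row sums
by a small amount; exact row-stochasticity holds at the kernel stage.

## Cluster number, clustering, consensus

Candidate cluster counts are ranked by two heuristics on the fused network:
the eigengap of the normalized graph Laplacian `L = I − D^{−1/2} A D^{−1/2}`
(gap between consecutive ascending eigenvalues), and a rotation cost — the
top-C row-normalized eigenvectors are rotated toward an indicator-like basis
by alternating discretization (deterministic initialization at the middle
row, then least-aligned rows) and scored by the mean excess spread
`Σ_j Z²_ij / max_j Z²_ij − 1`; rows orthogonal to the embedding (possible in
degenerate spectra) are scored maximally misaligned. Both heuristics report
their top-2 candidates; ties break toward smaller C.

Spectral clustering is the normalized-cut embedding (top-C eigenvectors of
`D^{−1/2} A D^{−1/2}`, rows renormalized) partitioned by k-means with
k-means++ seeding and 10 restarts. The k-means is a compact seeded numpy
implementation because the consensus loops invoke it tens of thousands of
times on C-dimensional embeddings, where per-call overhead dominates; an
emptied cluster is re-seeded with the farthest point, and a fit that still
returns an empty cluster is retried with a fresh derived seed (error after
10 failures). Labels are 1..C.

Consensus clustering of one network draws `reps` subsamples of
`⌈p_item·n⌉` subjects (default `p_item = 0.8`), spectral-clusters each
submatrix, and accumulates co-clustering and co-inclusion counts; the
consensus frequency is their ratio where defined. Final labels come from
average-linkage hierarchical clustering on `1 − frequency` cut to exactly C
clusters (linkage configurable: average/complete/ward). A subject never
included in any run is a hard error — negligible at realistic `reps`, and
deliberate so partial coverage can never silently distort the labeling.

The hyperparameter grid is the Cartesian product of
`K ∈ {10, 15, 20, 25, 30}` and `α ∈ {0.3, 0.4, 0.5, 0.6, 0.7, 0.8}`
(30 cells). Each cell builds affinities with its (K, α), fuses, and
consensus-clusters; the cell with the highest average silhouette width is
retained, ties toward smaller K then smaller α. Failed cells (e.g. K ≥ n)
are recorded and skipped. Silhouettes are computed on the dissimilarity
`1 − A/max_offdiag(A)` — invariant to positive rescaling of the fused
similarity; singleton clusters score 0.

The outer bootstrap repeats the grid search on `⌈boot_frac·n⌉`-subject
subsamples (default 0.8, `B = 1000` at full scale), re-running the
standardizations (and ordinal quintile cutpoints) on each subsample; outlier
screening happens once on the full sample. Retained labelings accumulate in
a global consensus matrix with co-inclusion accounting, so subjects absent
from an iteration are handled exactly, never imputed. Final labels are the
hierarchical cut of the global `1 − frequency` at C. The C=2 and C=3
solutions are compared by cross-tabulation.

Randomness discipline: a single master seed feeds a `numpy SeedSequence`
spawning tree (sampling and clustering streams separated at every level), so
reruns are byte-identical and changing `B` or `reps` does not correlate
streams.

## Subgroup profiling

Numeric variables: per-group Shapiro-Wilk at α = 0.05; if any group is
non-normal (groups of < 3 count as non-normal), Mann-Whitney for two groups
(exact p when the smaller group has ≤ 8 subjects and there are no ties, else
tie-corrected normal approximation) or tie-corrected Kruskal-Wallis for
three or more; if all normal, a one-way linear model. The gate can be forced
(`gate="nonparametric"|"parametric"`) since which variables took which path
is generally not recoverable from a published analysis. Effect sizes:
rank-biserial `gr = 1 − 2U₁/(n₁n₂)` (positive when group 1 tends lower —
the convention fixed by the U-statistic orientation), epsilon-squared
`H/(n−1)`, Cohen's F `√(η²/(1−η²))`.

Categorical tables: chi-squared without continuity correction when every
cell exceeds 5, otherwise Fisher's exact test (scipy hypergeometric for 2×2;
for larger tables, fixed-margin enumeration under the probability-ordering
two-sided rule, with a Monte-Carlo fallback above 200,000 enumerated tables
that reports its standard error). Cramér's V from the uncorrected
chi-squared in every branch.

Ordinal 3-level variables vs unordered groups: extended Cochran-Armitage
trend test. The statistic is the maximum over groups of the standardized
one-vs-rest mean-score contrast (reducing to the classical trend statistic
for two groups); p by Monte-Carlo permutation of group labels (default
10,000, seeded), so `p ≥ 1/(n_perm+1)` always.

Multiplicity: Benjamini-Hochberg step-up within the in-model and
out-of-model families separately (pooling available), and separately for
the covariate-adjusted battery. Covariate adjustment is a Freedman-Lane
permutation GLM: `outcome ~ group + age + sex`, group F-statistic referenced
to permutations of reduced-model residuals added back to the reduced fit,
`p = (1 + #{F* ≥ F}) / (1 + n_perm)` (default 5000 permutations).
Rank-deficient designs error naming the collinear columns.

## Synthetic cohorts

The generator plants C clusters (deterministic largest-remainder
allocation). In-model numeric variables are cluster-specific Gaussians whose
adjacent-cluster centroids are `effect_size` SDs apart, sign alternating
across variables; nominal per-variable offsets/scales make the raw tables
look like plausible instrument scores without affecting any standardized
quantity. Zero-inflated counts are a cluster-specific point mass at zero
(the ordinal profile's level-0 probability, exactly) plus a shifted Poisson
whose rate grows with the profile's level-2 share — profiles therefore
control the zero mass exactly and the upper tail monotonically, which is the
property the downstream quintile recoding consumes. Default profiles are
flat at `effect_size = 0` and spread with the effect (capped at 2), so a
zero-effect cohort carries no in-model signal at all. Out-of-model outcomes
get their own standardized separation; age is uniform on 4–7 years and sex
Bernoulli(1/2), independent of cluster unless `covariate_confounding`
shifts age by cluster. Optional equicorrelation induces within-block noise
correlation (default independent — within-block covariance of real
instruments is not identifiable from published summaries). Injected
outliers sit ~12 SD out, far outside any 3×IQR fence.

What the cohorts do not emulate: missingness (absent by design — loading
rejects missing in-model data), floor/ceiling effects and discreteness of
real questionnaire scores, sibling clustering, and any imaging modality.
Passing tests therefore demonstrate the pipeline's statistical behavior
under clean planted structure, not performance on real cohort data.

## Problem sizes

Tests and the acceptance script run the pipeline at reduced scale chosen to
keep full recomputation cheap while leaving the statistical conclusions
unambiguous: recovery uses n = 120, a 3×3 (K, α) grid, B = 50 bootstrap
iterations and 100 consensus subsamples; determinism uses n = 90, a 2×2
grid, B = 20; calibration uses 500 null cohorts at 299 permutations.
Full-scale defaults (5×6 grid, B = 1000, reps = 1000, 5000 GLM
permutations) are plain configuration.

## Known limitations

- The fused network's final symmetrization leaves row sums ≈ 1 but not
  exact; downstream spectral steps renormalize and are unaffected.
- The r×c Fisher enumeration is exponential in table size; beyond the cap it
  degrades gracefully to Monte-Carlo with a reported standard error.
- The rotation-cost heuristic depends on a discretization with a
  deterministic but heuristic initialization; eigengap is the primary
  criterion and both are advisory — the pipeline never picks C silently.
- Consensus with very small `reps` can leave subjects uncovered, which is a
  hard error rather than an imputation.
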