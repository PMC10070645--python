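# snfcc

Similarity-network-fusion consensus clustering for mixed-type cohort
stratification, with nonparametric subgroup profiling.

## What it is for

Cohort studies often measure the same subjects across several *data types* —
e.g. neonatal clinical/socio-demographic variables, questionnaire batteries
on socio-emotional outcomes, executive-function ratings. No single block
tells the whole story, and the blocks mix numeric, ordinal and zero-inflated
variables. `snfcc` integrates such blocks into a single patient-similarity
network and derives data-driven subgroups from it:

1. **Preprocess** — exclude subjects beyond 3×IQR Tukey fences on in-model
   numeric variables, recode zero-inflated counts to 3-level ordinals
   (zero / below / within the top quintile), Gower range-standardize mixed
   blocks, z-score numeric blocks.
2. **Per-block networks** — Gower or Euclidean distances, then the locally
   scaled exponential affinity
   `W(i,j) = exp(−d²(i,j) / (α·ε(i,j)))` with
   `ε(i,j) = (mean_K(i) + mean_K(j) + d(i,j))/3`,
   and the row-stochastic full kernel `P` and K-nearest-neighbor sparse
   kernel `S`.
3. **SNF** — iterative cross-diffusion
   `P(v) ← S(v) (Σ_{k≠v} P(k)/(m−1)) S(v)ᵀ` fuses the blocks into one
   network.
4. **Consensus clustering** — for each cell of the
   `K ∈ {10..30} × α ∈ {0.3..0.8}` grid, spectral clustering on repeated 80%
   subject subsamples aggregated into a co-clustering frequency matrix; the
   cell with the highest average silhouette width is retained; an outer 80%
   bootstrap (with per-subsample re-standardization) combines the retained
   labelings into the final consensus subgrouping. Eigengap and
   rotation-cost heuristics on the fused network rank candidate cluster
   numbers.
5. **Profiling** — subgroups are compared on in-model and held-out
   (out-of-model) variables: Shapiro-gated Mann-Whitney / Kruskal-Wallis,
   chi-squared / Fisher exact, extended Cochran-Armitage trend tests,
   Benjamini-Hochberg FDR, and Freedman-Lane permutation GLMs adjusting for
   age and sex. Effect sizes: rank-biserial gr, epsilon-squared, Cohen's F,
   Cramér's V.

Everything is seeded end-to-end: one master seed makes the whole pipeline
byte-reproducible. A synthetic-cohort generator with planted cluster
structure makes every stage testable without access to real cohort data.

See `docs/methods.md` for the full model description and numerical choices.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from snfcc import (BootstrapConsensusClusterer, CohortSpec, generate_cohort,
                   profile_clusters, results_to_frame)

cohort = generate_cohort(CohortSpec(
    n_subjects=120, cluster_proportions=(1/3, 1/3, 1/3),
    effect_size=2.0, seed=7,
))

est = BootstrapConsensusClusterer(
    n_clusters=3, k_values=(10, 20, 30), alpha_values=(0.3, 0.5, 0.8),
    n_bootstrap=50, reps=100, random_state=1,
).fit(cohort.blocks)

truth = cohort.true_labels.loc[est.subject_ids_]
print("ARI vs planted labels:", round(adjusted_rand_score(truth, est.labels_), 3))

results = profile_clusters(est.labels_,
                           [b.subset(est.subject_ids_) for b in cohort.blocks],
                           cohort.out_of_model.loc[est.subject_ids_])
print(results_to_frame(results).head(3)[["variable", "test", "p_raw", "q_fdr"]])
```

Output:

```
ARI vs planted labels: 0.975
              variable                  test         p_raw         q_fdr
0                   ga  one_way_linear_model  1.313322e-38  1.838651e-37
1  prosocial_behaviors  one_way_linear_model  1.800172e-37  1.260121e-36
2                  imd  one_way_linear_model  1.589309e-36  6.037850e-36
```

An adjusted Rand index of 0.975 means the bootstrap consensus recovered the
three planted subgroups almost exactly; the profiling table ranks variables
by FDR-adjusted evidence of between-subgroup differences (here the strong
planted effects on gestational age, deprivation index and the behavioral
subscales dominate, and the Gaussian draws pass the normality gate, so the
parametric one-way model is used).

The same pipeline is available from the shell:

```bash
snfcc simulate --out cohort/ --seed 7
snfcc cluster --blocks cohort/ --clusters 2,3 --boot 50 --reps 100 \
      --k-grid 10,20,30 --alpha-grid 0.3,0.5,0.8 --seed 1 --out run/
snfcc profile --assignment run/assignment_C3.csv --blocks cohort/ \
      --out-of-model cohort/out_of_model.csv --covariates cohort/covariates.csv \
      --seed 1 --out profile_C3.csv
```

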