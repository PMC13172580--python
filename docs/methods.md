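# Methods

## The model

Each bulk sample `j` is treated as a convex mixture of two reference tissue
profiles. On the log2 scale, gene `g` has mean

```
log2 μ_gj = (1 − w_j)·mu_gm_g + w_j·mu_wm_g + batch_gj + disease effect
```

where `w_j ∈ [0, 1]` is the sample's (latent) white-matter fraction.
Counts are negative binomial around `libsize_j · 2^{log2 μ}` with a common
dispersion (`Var = μ + φ μ²`). Mixing on the log2 scale is a deliberate
modeling choice: it keeps every planted effect interpretable as a log2 fold
change, at the cost of physical exactness (real tissue mixes linearly in
transcript space; see *Cross-modality projection* below for where this
matters).

The discovery algorithm never sees `w`. It splits the expression matrix
additively into `X = U + B`: per gene, expression is regressed on any
supplied biological covariates (intercept always included) and each
non-intercept coefficient is soft-thresholded at `λ × SE`; `U` is rebuilt
from the shrunken fit and `B = X − U` keeps everything the covariates do
not explain. With no covariates — the default discovery configuration —
`U` is the matrix of row means and `B` is the row-centered data. `B` is
then factorized by semi-NMF (`B ≈ F Gᵀ`, `G ≥ 0`, multiplicative updates
with the positive/negative-part rule, k-means-derived initialization
`indicator + 0.2`), and each sample is labeled by the argmax row of `G`.

**Numerical note.** All semi-NMF iterations are computed in the Gram domain:
with `S = BᵀB` and `F` the least-squares solution given `G`, every quantity
in the `G` update and the objective is a function of `S` and `G`, so the
gene dimension never enters the restart loop. This is algebraically
identical to the direct updates and makes 500-restart consensus over
`k = 2…8` run in seconds at the default study scale. Singular `GᵀG` gets a
`1e-10` ridge (logged); the objective trace is recorded and is
non-increasing by construction of the update.

## Rank selection

For each candidate rank, the consensus matrix is the mean connectivity over
restarts with distinct sub-seeds. Final labels cut the average-linkage
dendrogram of `1 − consensus`; stability is summarized by the cophenetic
coefficient of that dendrogram and by the mean silhouette width under the
same `1 − consensus` distance.

Because the latent factor is a one-dimensional continuum, consensus
matrices are nearly block-perfect at *every* rank and cophenetic
coefficients crowd into 0.96–0.99; their float argmax is dominated by
restart noise (rerun variability of the coefficient is about 0.01).
`choose_k` therefore treats cophenetic values within 0.01 of the maximum
as tied and resolves ties by larger mean silhouette, then smaller k. The
silhouette drops sharply beyond the true rank, so this rule selects the
planted rank across the generator configurations we tested; occasionally
(at some cohort draws) the metrics genuinely prefer a neighboring rank —
that residual variability is a property of the method, not a bug, and the
reproduction script reports whatever the rule selects.

## The synthetic study conditions

Defaults of `SimulationConfig` (the values every test and the reproduction
script use):

| parameter | default | meaning / rationale |
|---|---|---|
| `n_genes` | 1500 | desk-scale cohort; 10 % WM markers, 10 % GM markers with `|Δ| ≥ 2` log2 |
| `n_per_subgroup` | (40, 40, 40) | 120 samples |
| `w_beta` | Beta(25.5, 124.5), Beta(124.5, 25.5), Beta(75, 75) | subgroup WM-fraction laws with means 0.17 / 0.83 / 0.5 and common concentration 150: three dissection practices whose within-practice spread (sd ≈ 0.03–0.04) is small against their separation, with tails that still overlap |
| `nb_dispersion` | 0.2 | bulk RNA-seq-like overdispersion |
| `n_batches`, `batch_sd` | 3, 0.2 log2 | real but subordinate batch structure: the sampling axis, not batch, dominates per-gene variance, which is the regime the variance-partition analysis demonstrates |
| `n_degs`, `deg_effect_range` | 100, (0.3, 1.0) log2 | planted disease effects at case-control cortex magnitudes (FC 1.2–2). Larger defaults would plant a literal fourth transcriptional group (subgroup 2 × diagnosis) and change the correct rank to 4 |
| `frac_subgroup_specific` | 0.5 | half the disease effects act only in the WM-enriched subgroup, enabling the stratified-gain analysis |
| `confound_diagnosis` | 0 | `P(AD)` independent of `w` by default; positive values couple them for confounding experiments |

RIN and PMI are drawn independently of `w`, so the expected absence of
correlation between the factor and tissue-quality covariates is
reproducible.

Single cells: each sample's cell-type proportions target the convex blend
`(1 − w)·GM_composition + w·WM_composition` (Dirichlet noise, concentration
200). Neurons dominate the GM endpoint (55 % excitatory) and collapse
toward zero in WM, while the oligodendrocyte share rises linearly from
0.08 to 0.72 — moving only the oligodendrocyte share would floor neuronal
signal at the non-oligo remainder, which no classifier could separate, and
would misrepresent WM, which contains almost no neuronal somata. Spatial
spots draw from the pure GM profile (L2–L6), the pure WM profile (WM), or
a 50/50 blend (L1); spot depth ≈ 5,000 counts. Omics matrices are Gaussian
in log abundance with WM-like/GM-like/neutral feature classes and
per-feature missing-at-random rates spanning the 70 % filtering threshold.

**What the generator does not emulate:** real gene-gene correlation beyond
the mixture axis, spatial autocorrelation within layers, cell-type
substructure, library-preparation chemistry, or realistic gene identities.
Passing the recovery tests therefore shows the chain is correct and
well-calibrated under the stated mixture model — not that it would find a
factor of any particular strength in a given real cohort.

## Preprocessing and scale conventions

Discovery and signature derivation run on median-of-ratios size-factor
normalization, `log2(count/sf + 1)`, followed by per-gene OLS removal of
batch, RIN and PMI (the fitted intercept is added back so values stay on
the original scale). Feature selection keeps the top genes by median
absolute deviation — 500 of 1,500 by default, matching the fraction of the
genome a full-scale analysis would keep — with ties broken
lexicographically.

The subgroup classifier uses a different convention: per-gene z-scores of
CPM-log values, identically for the training cohort and every projection
target. The reason is structural: bulk mixtures are built on the log2
scale while cells and spots mix linearly, so absolute per-gene levels can
never agree across modalities; location/scale standardization within each
matrix removes exactly that mismatch while preserving the between-sample
ordering the forest actually uses. Targets missing some signature genes
are median-imputed from the training matrix when at least half the
features are present, and rejected below that.

## Differential expression

One-vs-rest signature tests use Welch's *t* on the log2-normalized values
(zero-variance genes get `p = 1` so the BH input stays well-defined);
signatures keep up-regulated genes at FDR ≤ 1 % and fold change ≥ 1.5.
Disease contrasts use a moderated *t*: per-gene OLS, residual variances
shrunk toward a scaled-F prior whose hyperparameters `(d0, s0²)` come from
moment-matching `log s²` (Newton inversion of the trigamma equation);
`d0 = 0` recovers the ordinary *t* and `d0 = ∞` the pooled-variance *t*,
both of which are asserted in tests. DEG calls need `q ≤ 0.05` and
`FC ≥ 1.2`.

The stratified-gain experiment merges clusters 1 and 3 (the two GM-like
groups) and compares the joint contrast against the per-stratum union. It
plants fixed 1-log2 effects — the same magnitude the moderated-*t*
calibration experiment uses — because with the cohort default U(0.3, 1)
effects most subgroup-specific signals are undetectable at stratum size
n ≈ 40 by *any* method, which would measure power rather than the gain
from stratification.

The WM-score adjustment (`~ diagnosis + wm_score`) is evaluated in two
regimes. When `w` varies independently of diagnosis — the regime the
discovery cohorts are in, where the factor adds residual variance —
adjustment raises true-DEG recall. When `w` is forced to confound the
diagnosis labels, the *joint* model's apparent yield inflates with
hundreds of false, composition-driven calls while the adjusted model stays
controlled; raw recall comparisons are meaningless there, so the test
asserts false-call control instead.

The moderated-*t* calibration simulation draws gene variances from a
scaled inverse-chi-square law (`d0 = 4, s0 = 0.3`), the canonical
heteroscedastic design for evaluating empirical-Bayes moderation, since
the spec of the simulation fixes genes, effects, sample size and
replicates but not the variance law.

## Gene-set statistics

Preranked GSEA uses the weighted running-sum statistic (hit increments
`|stat|`, normalized; uniform miss decrements) with a gene-label
permutation null; when the number of distinct set placements `C(N, n)` is
within the permutation budget the null is enumerated exhaustively and the
p-value is exact — this is also what makes the small-universe oracle tests
exact rather than approximate. ssGSEA is the rank-weighted ECDF difference
with `α = 0.25` and no final range normalization; ties get average ranks
and ordering is made deterministic by gene id. Both are pinned by
brute-force re-implementations in the test-suite; results are
self-consistent but not bit-compatible with any external tool. The
hypergeometric module-overlap tail is computed in exact integer
arithmetic.

## Variance partitioning

Genes are restricted to the most variable, z-scored, and fitted jointly
with additive fixed effects for the latent labels and each clinical
covariate (categoricals one-hot and centered). Each factor's share is the
variance of its fitted component, renormalized over components only
(residual excluded). With correlated factors the components share variance
— a documented limitation of the fixed-effect decomposition; the
orthogonal-design recovery test defines its accuracy contract
(50/30/20 within ±5 points at n = 500).

## Known limitations

- Rank selection on continuum-valued latent factors is intrinsically less
  stable than on discrete mixtures; at some cohort draws the
  cophenetic/silhouette rule picks 2 or 4.
- The final consensus labels come from a hierarchical cut and can lag the
  classifier trained on them (the forest's out-of-bag voting denoises
  boundary samples).
- Semi-NMF of row-centered data represents the middle subgroup only by its
  displacement from the grand mean; in perfectly balanced symmetric
  designs that displacement vanishes and the middle group's assignment
  degrades. Real cohorts (and the default generator) are not in that
  degenerate configuration.
- The WM proxy score is a relative ranking, not an absolute WM fraction.
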