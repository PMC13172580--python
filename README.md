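# latentmix

Latent tissue-composition factor discovery and adjustment for brain bulk
transcriptomes.

Bulk RNA-seq samples dissected from cortex are rarely pure gray matter (GM):
depending on where the block was cut, each sample carries a variable
admixture of white matter (WM). Because WM is dominated by oligodendrocytes
and nearly devoid of neuronal somata, this sampling variation is a major —
and usually unmodeled — axis of transcriptomic variation. It can masquerade
as disease subtypes, dilute case–control contrasts, and confound molecular
subtyping.

`latentmix` implements an analysis chain that

1. **discovers** the latent composition factor in a cohort's expression
   matrix: the data are split as `X = U + B`, where `U` holds what known
   biological covariates explain (per-gene least squares with coefficients
   soft-thresholded at λ·SE; with no covariates, `U` is the matrix of gene
   means) and the factor matrix `B = X − U` is clustered by
   semi-nonnegative matrix factorization, `B ≈ F·Gᵀ` with `G ≥ 0`, labels
   from `argmax_k G[j, k]`;
2. **selects the number of clusters** by consensus over restarts: the
   consensus matrix of co-clustering frequencies is cut hierarchically, and
   the rank is chosen by cophenetic coefficient with mean silhouette width
   as tie-break;
3. **derives subgroup signature genes** (one-vs-rest differential
   expression, BH FDR ≤ 1 %, fold change ≥ 1.5, up-regulated only) and
   trains a 200-tree random-forest subgroup classifier with out-of-bag
   validation;
4. **projects** the classifier across modalities — held-out bulk cohorts,
   pseudo-bulk aggregates of single cells, spatial transcriptomics spots —
   and exposes the predicted probability of the WM-enriched subgroup as a
   continuous **WM proxy score**;
5. **quantifies the payoff**: subgroup-stratified and WM-score-adjusted
   moderated-*t* differential expression (empirical-Bayes variance
   shrinkage), per-gene variance partitioning, hypergeometric module
   overlap, intra-module coexpression, and WM/GM marker calling for paired
   metabolome data.

A first-class synthetic-data module (`latentmix.synthio`) generates bulk
cohorts as convex GM/WM mixtures on the log2 scale with known WM fraction
`w` per sample, plus matching single-cell, spatial-spot and
metabolome/proteome-like datasets — with complete ground truth, so every
stage of the chain is testable end to end without any external data.

## Worked example

```python
from latentmix import workflow, synthio, subgroup_model as sm
from latentmix.dasc import adjusted_rand_index

# simulate a 120-sample cohort and run the full discovery chain
study = workflow.run_discovery_study(seed=1)
print("chosen k:", study.consensus.chosen_k)
print("recovery ARI:", round(study.recovery_ari, 3))
print("signature genes:", len(study.signature.combined))
print("OOB accuracy:", study.model.oob_accuracy)

# project onto an independently simulated cohort
counts2, meta2, truth2 = synthio.simulate_bulk(
    study.profiles, synthio.SimulationConfig(seed=1001))
pred = sm.predict_subgroups(study.model, workflow.classifier_input(counts2))
print("transfer ARI:", round(
    adjusted_rand_index(pred.labels, truth2.subgroup), 3))
```

prints

```
chosen k: 3
recovery ARI: 1.0
signature genes: 336
OOB accuracy: 1.0
transfer ARI: 1.0
```

Three clusters are selected because the consensus matrix is most stable at
rank 3; an adjusted Rand index of 1 against the planted subgroups means
the clustering recovered the simulated GM-heavy / mixed / WM-heavy
dissection groups exactly at this seed (typical values across seeds are
0.9–1.0); and the classifier trained on one
cohort's discovered labels reproduces the planted subgroups of a second,
independently simulated cohort perfectly.

The same pipeline is available from the shell:

```bash
latentmix run-all demo.config     # simulate → discover → signature → train
latentmix discover --matrix counts.tsv --meta meta.tsv --out out/
```

where `demo.config` is a flat `key = value` file (see
`latentmix.cli.DEFAULT_CONFIG` for the recognized keys and defaults).

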