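"""Gene-set statistics and spatial projection of the latent factor.

Implements preranked GSEA (weighted Kolmogorov-Smirnov running sum with a
gene-label permutation null), single-sample GSEA (rank-weighted ECDF
difference), derivation of cortical layer markers from spot-level data,
layer-enrichment profiles of subgroup signatures, spot-level subgroup
classification, and the correlation check that validates the classifier's
WM score against an independent ssGSEA WM-marker score.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .prep import cpm_log, zscore_genes
from .signatures import SignatureSet, bh_adjust, _welch_t
from .subgroup_model import SubgroupModel, predict_subgroups

logger = logging.getLogger(__name__)

__all__ = ["preranked_gsea", "ssgsea", "derive_layer_markers",
           "layer_profile", "classify_spots", "validate_wm_score",
           "EnrichmentResult"]


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p: float
    q: float
    leading_edge: list


# --------------------------------------------------------------------------- #
# Preranked GSEA
# --------------------------------------------------------------------------- #

def _running_es(stat_sorted: np.ndarray, hit_mask: np.ndarray
                ) -> tuple[float, np.ndarray]:
    """ES for hits at given positions of a descending-sorted stat vector.

    Hit increments are |stat| normalized to sum 1 within the set; misses
    decrement uniformly by 1/(N - n). ES is the running-sum value of maximal
    absolute deviation from zero.
    """
    n_tot = stat_sorted.size
    n_hit = int(hit_mask.sum())
    weights = np.abs(stat_sorted) * hit_mask
    wsum = weights.sum()
    if wsum <= 0:  # all-zero stats within the set: uniform hit increments
        weights = hit_mask / n_hit
    else:
        weights = weights / wsum
    steps = weights - (~hit_mask) / (n_tot - n_hit)
    running = np.cumsum(steps)
    peak = np.argmax(np.abs(running))
    return float(running[peak]), running


def preranked_gsea(ranked_stats: pd.Series, sets: dict, n_perm: int = 10000,
                   min_size: int = 10, max_size: int = 500,
                   seed: int = 0) -> list[EnrichmentResult]:
    """Preranked GSEA with a gene-label permutation null.

    The null permutes which genes carry the set labels (equivalently, places
    the set at random positions of the fixed ranked list). When the number
    of distinct placements C(N, n) does not exceed ``n_perm`` the null is
    enumerated exhaustively and p is exact; otherwise p is the fraction of
    same-sign null ES at least as extreme (with a +1 continuity correction).
    NES divides ES by the mean |same-sign null ES|; q is BH across the
    reported sets.
    """
    stats_ = ranked_stats.dropna()
    if stats_.index.has_duplicates:
        raise ValueError("ranked stats must have unique gene ids")
    order = np.argsort(-stats_.to_numpy(), kind="mergesort")
    genes = stats_.index.to_numpy()[order]
    stat_sorted = stats_.to_numpy()[order]
    universe = set(genes)
    n_tot = genes.size
    rng = np.random.default_rng(seed)

    results = []
    for name, members in sets.items():
        members_in = [g for g in members if g in universe]
        size = len(members_in)
        if size < min_size or size > max_size or size == 0 or size == n_tot:
            warnings.warn(f"set {name!r} skipped (size {size} outside bounds)")
            continue
        hit = np.isin(genes, members_in)
        es, running = _running_es(stat_sorted, hit)
        positions = np.arange(n_tot)
        exact = math.comb(n_tot, size) <= n_perm
        if exact:
            placements = itertools.combinations(positions, size)
            null_list = []
            for pos in placements:
                perm_hit = np.zeros(n_tot, dtype=bool)
                perm_hit[list(pos)] = True
                null_list.append(_running_es(stat_sorted, perm_hit)[0])
            null_es = np.array(null_list)
        else:
            null_es = np.empty(n_perm)
            for b in range(n_perm):
                perm_hit = np.zeros(n_tot, dtype=bool)
                perm_hit[rng.choice(positions, size=size,
                                    replace=False)] = True
                null_es[b], _ = _running_es(stat_sorted, perm_hit)
        same_sign = null_es * np.sign(es) > 0 if es != 0 else np.ones(
            null_es.size, dtype=bool)
        n_ss = int(same_sign.sum())
        if n_ss == 0:
            warnings.warn(f"set {name!r}: empty same-sign null; NES undefined")
            p = 1.0 / (null_es.size + 1)
            nes = float("nan")
        else:
            extreme = np.abs(null_es[same_sign]) >= abs(es)
            if exact:
                p = int(extreme.sum()) / n_ss
            else:
                p = (1 + int(extreme.sum())) / (1 + n_ss)
            nes = es / float(np.mean(np.abs(null_es[same_sign])))
        peak = int(np.argmax(np.abs(running)))
        if es >= 0:
            leading = [g for g, h in zip(genes[:peak + 1], hit[:peak + 1]) if h]
        else:
            leading = [g for g, h in zip(genes[peak:], hit[peak:]) if h]
        results.append(EnrichmentResult(name, es, nes, p, float("nan"),
                                        leading))
    if results:
        qs = bh_adjust([r.p for r in results])
        for r, q in zip(results, qs):
            r.q = float(q)
    return results


# --------------------------------------------------------------------------- #
# ssGSEA
# --------------------------------------------------------------------------- #

def _ssgsea_sample(expr: pd.Series, in_set: np.ndarray,
                   alpha: float) -> float:
    """Rank-weighted ECDF difference for one sample.

    Genes are walked in descending expression order (ties get average ranks
    for weighting, deterministic order by gene id); the score sums, over all
    positions, the difference between the weighted in-set ECDF (weights
    rank**alpha, normalized) and the uniform out-of-set ECDF.
    """
    n = expr.size
    ranks = stats.rankdata(expr.to_numpy())  # ascending, average ties
    order = np.lexsort((expr.index.to_numpy(), -expr.to_numpy()))
    r = ranks[order]
    hits = in_set[order]
    w = np.where(hits, r ** alpha, 0.0)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("gene set carries zero total rank weight")
    ecdf_in = np.cumsum(w) / wsum
    n_out = n - hits.sum()
    ecdf_out = np.cumsum(~hits) / n_out if n_out > 0 else np.zeros(n)
    return float(np.sum(ecdf_in - ecdf_out))


def ssgsea(X: ExpressionMatrix, gene_set, alpha: float = 0.25) -> pd.Series:
    """Single-sample gene-set enrichment score per sample (deterministic)."""
    members = [g for g in gene_set if g in X.gene_ids]
    if len(members) < 2:
        raise ValueError("gene set shares fewer than 2 genes with the matrix")
    in_set = np.asarray(X.gene_ids.isin(members))
    scores = {s: _ssgsea_sample(X.data[s], in_set, alpha)
              for s in X.sample_ids}
    return pd.Series(scores, name="ssgsea")


# --------------------------------------------------------------------------- #
# Layer markers and profiles
# --------------------------------------------------------------------------- #

def derive_layer_markers(spatial: ExpressionMatrix, layer_labels,
                         t_min: float = 5.0, p_max: float = 0.01,
                         wm_strict_t: float = 10.0) -> dict:
    """One-vs-rest layer markers from spot-level data.

    Per layer, Welch t of layer spots vs the rest per gene; markers satisfy
    t > t_min and p < p_max. An additional strict WM set requires
    t > wm_strict_t. Layers with fewer than 3 spots are excluded.
    """
    labels = pd.Series(layer_labels, index=spatial.sample_ids
                       ) if not isinstance(layer_labels, pd.Series
                                           ) else layer_labels
    labels = labels.reindex(spatial.sample_ids)
    layers = [l for l in pd.unique(labels)]
    usable = []
    for lay in layers:
        if (labels == lay).sum() < 3:
            warnings.warn(f"layer {lay!r} has < 3 spots; excluded")
        else:
            usable.append(lay)
    if len(usable) < 2:
        raise ValueError("need >= 2 usable layers")
    sets: dict = {}
    values = spatial.values
    for lay in usable:
        mask = (labels == lay).to_numpy()
        t, p = _welch_t(values[:, mask], values[:, ~mask])
        sets[lay] = list(spatial.gene_ids[(t > t_min) & (p < p_max)])
        if lay == "WM":
            sets["WM_strict"] = list(spatial.gene_ids[t > wm_strict_t])
    return sets


def layer_profile(spatial: ExpressionMatrix, layer_labels,
                  signatures: SignatureSet, top_n: int = 50,
                  min_avg_expr: float = 8.0) -> pd.DataFrame:
    """Z-scored median log-count layer profile of top signature genes.

    Per subgroup: among genes with average expression above ``min_avg_expr``
    take the ``top_n`` up-regulated signature genes by log2 fold change;
    compute each gene's median log-count per layer, z-score across layers,
    and average over genes. Returns layers x subgroups.
    """
    labels = pd.Series(layer_labels, index=spatial.sample_ids
                       ) if not isinstance(layer_labels, pd.Series
                                           ) else layer_labels
    labels = labels.reindex(spatial.sample_ids)
    layers = list(pd.unique(labels))
    if len(layers) < 2:
        raise ValueError("need >= 2 layers")
    avg = spatial.data.mean(axis=1)
    eligible = set(avg.index[avg > min_avg_expr])
    profiles = {}
    for group, table in signatures.per_subgroup.items():
        genes = [g for g in table.index
                 if g in eligible and g in spatial.gene_ids][:top_n]
        if len(genes) == 0:
            warnings.warn(f"subgroup {group!r}: no eligible signature genes")
            continue
        if len(genes) < top_n:
            warnings.warn(f"subgroup {group!r}: only {len(genes)} eligible "
                          f"genes (< {top_n}); using all")
        med = pd.DataFrame({
            lay: spatial.data.loc[genes, (labels == lay).to_numpy()].median(
                axis=1)
            for lay in layers})
        mu = med.mean(axis=1)
        sd = med.std(axis=1, ddof=0)
        z = med.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(
            0.0)
        profiles[group] = z.mean(axis=0)
    return pd.DataFrame(profiles)


def classify_spots(model: SubgroupModel, spatial_counts: ExpressionMatrix
                   ) -> pd.DataFrame:
    """Project the subgroup classifier onto spatial spots.

    CPM-log normalizes the raw spot counts (followed by per-gene
    standardization when the model was trained on z-scores), aligns
    features, predicts class probabilities, and z-scores each class's
    probabilities across spots. Labels come from the raw (pre-z-score)
    probabilities.
    """
    if spatial_counts.scale != "counts":
        raise ValueError("classify_spots expects raw spot counts")
    logged = cpm_log(spatial_counts)
    if model.scale == "zscore":
        logged = zscore_genes(logged)
    pred = predict_subgroups(model, logged)
    probs = pred.probabilities
    if probs.shape[0] < 2:
        warnings.warn("single spot: z-normalization skipped")
        z = probs.copy()
    else:
        sd = probs.std(axis=0, ddof=0)
        z = (probs - probs.mean(axis=0)) / sd.replace(0.0, np.nan)
        z = z.fillna(0.0)
    out = z.add_prefix("z_score_")
    out["label"] = pred.labels
    return out


def validate_wm_score(wm_scores: pd.Series, X: ExpressionMatrix,
                      wm_marker_set, alpha: float = 0.25) -> dict:
    """Correlate the classifier WM score with an ssGSEA WM-marker score."""
    scores = ssgsea(X, wm_marker_set, alpha=alpha)
    common = wm_scores.index.intersection(scores.index)
    if len(common) < 3:
        raise ValueError("need >= 3 shared samples")
    a = wm_scores.loc[common]
    b = scores.loc[common]
    rho, rho_p = stats.spearmanr(a, b)
    r, r_p = stats.pearsonr(a, b)
    return {"spearman": float(rho), "spearman_p": float(rho_p),
            "pearson": float(r), "pearson_p": float(r_p),
            "ssgsea_scores": b}
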