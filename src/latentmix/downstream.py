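"""Heterogeneity analyses that exploit or adjust for the latent factor.

Covers moderated (empirical-Bayes) differential expression; the comparison
of joint vs subgroup-stratified vs WM-score-adjusted disease contrasts;
per-gene variance partitioning across the latent factor and clinical
covariates; hypergeometric module overlap (exact integer tail); intra-module
coexpression CDFs with random-set controls; and the paired-tissue
fold-change rule used to call WM/GM metabolite markers.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import ExpressionMatrix
from .signatures import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "moderated_deg", "make_design", "stratified_deg_compare",
    "covariate_adjusted_deg", "variance_partition", "hypergeom_overlap",
    "module_coexpression_cdf", "paired_tissue_markers",
]


# --------------------------------------------------------------------------- #
# Moderated differential expression (empirical-Bayes variance shrinkage)
# --------------------------------------------------------------------------- #

def _trigamma_inverse(x: float, tol: float = 1e-8,
                      max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return float("inf")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return y


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Hyperparameters (d0, s0^2) of the scaled-F prior for residual variances.

    Matches the moments of e = log s^2 - digamma(df/2) + log(df/2): the
    excess of var(e) over trigamma(df/2) identifies trigamma(d0/2); the mean
    then identifies s0^2. Non-positive excess means no evidence of variance
    heterogeneity, giving d0 = inf (complete pooling).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return float("inf"), float(np.mean(s2[ok])) if ok.any() else 1.0
    e = (np.log(s2[ok]) - float(special.digamma(df / 2.0))
         + math.log(df / 2.0))
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    excess = evar - float(special.polygamma(1, df / 2.0))
    if not np.isfinite(excess) or excess <= 0:
        return float("inf"), math.exp(emean)
    d0 = 2.0 * _trigamma_inverse(excess)
    if not np.isfinite(d0) or d0 <= 0:
        warnings.warn("trigamma solve failed; falling back to pooled variance")
        return float("inf"), math.exp(emean)
    s0_2 = math.exp(emean + float(special.digamma(d0 / 2.0))
                    - math.log(d0 / 2.0))
    return d0, s0_2


def moderated_deg(X: ExpressionMatrix, design: pd.DataFrame,
                  coefficient: str, q_max: float = 0.05,
                  min_fc: float = 1.2, d0_override: float | None = None,
                  model_tag: str = "joint") -> pd.DataFrame:
    """Moderated-t differential expression for one design coefficient.

    Per-gene OLS, then empirical-Bayes shrinkage of the residual variances
    toward a common prior fitted by moment matching on log s^2:
    ``s_tilde^2 = (d0 s0^2 + d s^2) / (d0 + d)``; the moderated t uses
    df = d0 + d. ``d0_override`` forces d0 (0 recovers the ordinary t,
    numpy.inf the pooled-variance t). DEG flag: q <= q_max and fold change
    2**|log2fc| >= min_fc.
    """
    design = design.loc[X.sample_ids]
    d = design.to_numpy(dtype=float)
    n, p = d.shape
    df_resid = n - p
    if df_resid < 2:
        raise ValueError("residual degrees of freedom < 2")
    if coefficient not in design.columns:
        raise ValueError(f"coefficient {coefficient!r} not in design")
    ci = design.columns.get_loc(coefficient)
    xtx = d.T @ d
    if np.linalg.matrix_rank(xtx) < p:
        raise ValueError("design is not full rank")
    xtx_inv = np.linalg.inv(xtx)
    y = X.values.T                       # samples x genes
    beta = xtx_inv @ d.T @ y             # p x genes
    resid = y - d @ beta
    s2 = (resid ** 2).sum(axis=0) / df_resid
    c = math.sqrt(xtx_inv[ci, ci])

    if d0_override is not None:
        d0 = float(d0_override)
        s0_2 = float(np.mean(s2[s2 > 0])) if np.isinf(d0) else 0.0
    else:
        d0, s0_2 = _fit_f_dist(s2, df_resid)
    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 == 0:
        s2_mod = s2
        df_total = df_resid
    else:
        s2_mod = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[ci] / (np.sqrt(s2_mod) * c)
    t = np.where(np.isfinite(t), t, 0.0)
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    pvals = np.where(s2_mod > 0, pvals, 1.0)
    q = bh_adjust(pvals)
    lfc = beta[ci]
    out = pd.DataFrame({
        "gene_id": X.gene_ids, "log2fc": lfc, "t": t, "p": pvals, "q": q,
        "deg": (q <= q_max) & (np.exp2(np.abs(lfc)) >= min_fc),
        "model": model_tag,
    }).set_index("gene_id")
    out.attrs["d0"] = d0
    out.attrs["df_resid"] = df_resid
    return out


def make_design(diagnosis, extra: pd.DataFrame | None = None,
                case_label: str = "AD") -> pd.DataFrame:
    """Design matrix [intercept, diagnosis indicator, extra columns]."""
    diag = pd.Series(diagnosis)
    design = pd.DataFrame({
        "intercept": 1.0,
        "diagnosis": (diag == case_label).astype(float),
    }, index=diag.index)
    if extra is not None:
        for col in extra.columns:
            design[col] = extra[col].astype(float)
    return design


# --------------------------------------------------------------------------- #
# Stratified and adjusted disease contrasts
# --------------------------------------------------------------------------- #

def stratified_deg_compare(X: ExpressionMatrix, diagnosis,
                           subgroup_labels, merge: dict | None = None,
                           q_max: float = 0.05, min_fc: float = 1.2) -> dict:
    """Joint vs subgroup-stratified disease contrasts and the yield ratio.

    Clusters are merged per ``merge`` (default {3: 1}: the two GM-like
    clusters pool into subgroup 1). Reports the joint DEG table, per-stratum
    tables, the union of stratified DEG calls, Venn-style overlap counts,
    and yield_ratio = |stratified union| / |joint|.
    """
    merge = {3: 1} if merge is None else merge
    diag = pd.Series(diagnosis).reindex(X.sample_ids)
    labels = pd.Series(subgroup_labels).reindex(X.sample_ids)
    labels = labels.map(lambda v: merge.get(v, v))

    design = make_design(diag)
    joint = moderated_deg(X, design, "diagnosis", q_max, min_fc,
                          model_tag="joint")
    per_stratum = {}
    for sg in sorted(pd.unique(labels)):
        mask = (labels == sg).to_numpy()
        sub_diag = diag[mask]
        if (sub_diag == "AD").sum() < 3 or (sub_diag != "AD").sum() < 3:
            warnings.warn(f"stratum {sg!r} lacks both diagnoses; skipped")
            continue
        sub_X = ExpressionMatrix(X.data.loc[:, mask], X.scale)
        per_stratum[sg] = moderated_deg(sub_X, make_design(sub_diag),
                                        "diagnosis", q_max, min_fc,
                                        model_tag=f"subgroup{sg}")
    joint_degs = set(joint.index[joint["deg"]])
    strat_degs: set = set()
    for table in per_stratum.values():
        strat_degs |= set(table.index[table["deg"]])
    yield_ratio = (len(strat_degs) / len(joint_degs)
                   if joint_degs else float("nan"))
    venn = {
        "joint_only": len(joint_degs - strat_degs),
        "stratified_only": len(strat_degs - joint_degs),
        "both": len(joint_degs & strat_degs),
        "joint": len(joint_degs),
        "stratified_union": len(strat_degs),
    }
    return {"joint": joint, "per_stratum": per_stratum,
            "venn": venn, "yield_ratio": yield_ratio}


def covariate_adjusted_deg(X: ExpressionMatrix, diagnosis,
                           wm_scores: pd.Series, q_max: float = 0.05,
                           min_fc: float = 1.2) -> pd.DataFrame:
    """Disease contrast adjusting for the continuous WM proxy score.

    Model per gene: expression ~ intercept + diagnosis + wm_score; the
    diagnosis coefficient is tested at the average WM composition. A
    constant wm_score reduces to the joint model (with a warning).
    """
    diag = pd.Series(diagnosis).reindex(X.sample_ids)
    scores = wm_scores.reindex(X.sample_ids)
    if scores.nunique() <= 1:
        warnings.warn("wm_score is constant; reducing to the joint model")
        design = make_design(diag)
    else:
        design = make_design(diag, extra=scores.to_frame("wm_score"))
    return moderated_deg(X, design, "diagnosis", q_max, min_fc,
                         model_tag="covariate-adjusted")


# --------------------------------------------------------------------------- #
# Variance partitioning
# --------------------------------------------------------------------------- #

def _factor_block(series: pd.Series, name: str) -> pd.DataFrame:
    """Centered design block for one factor (one-hot for categoricals)."""
    if pd.api.types.is_numeric_dtype(series):
        block = series.astype(float).to_frame(name)
    else:
        block = pd.get_dummies(series, prefix=name, dtype=float)
    return block - block.mean(axis=0)


def variance_partition(X: ExpressionMatrix, factor_table: pd.DataFrame,
                       latent_labels, top_n_hvg: int = 9000) -> pd.DataFrame:
    """Fraction of per-gene variance attributed to each factor.

    Genes are restricted to the ``top_n_hvg`` most variable, then z-scored.
    An additive fixed-effect linear model with all factors (categoricals
    one-hot encoded and centered) is fitted jointly per gene; each factor's
    explained variance is the variance of its fitted component, and
    fractions renormalize over the factor components only (residual
    excluded), so they sum to 1 per gene.
    """
    latent = pd.Series(latent_labels).reindex(X.sample_ids).astype(str)
    blocks = {"latent_factor": _factor_block(latent, "latent_factor")}
    for col in factor_table.columns:
        blocks[col] = _factor_block(factor_table[col].reindex(X.sample_ids),
                                    col)
    # aliasing check between factor pairs
    names = list(blocks)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            combined = pd.concat([blocks[a], blocks[b]], axis=1).to_numpy()
            ra = np.linalg.matrix_rank(blocks[a].to_numpy())
            rb = np.linalg.matrix_rank(blocks[b].to_numpy())
            if np.linalg.matrix_rank(combined) < max(ra, rb) + min(ra, rb):
                raise ValueError(f"aliased factors: {a!r} and {b!r}")

    variances = X.data.var(axis=1)
    top = variances.sort_values(ascending=False).index[:top_n_hvg]
    y = X.data.loc[top].to_numpy(dtype=float)
    y = (y - y.mean(axis=1, keepdims=True))
    sd = y.std(axis=1, ddof=0, keepdims=True)
    y = y / np.where(sd > 0, sd, 1.0)

    design = pd.concat(blocks.values(), axis=1)
    col_of = {}
    start = 0
    for name, block in blocks.items():
        col_of[name] = slice(start, start + block.shape[1])
        start += block.shape[1]
    d = design.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(d, y.T, rcond=None)   # p x genes
    comp_var = {}
    for name in names:
        sl = col_of[name]
        comp = d[:, sl] @ beta[sl]                   # samples x genes
        comp_var[name] = comp.var(axis=0, ddof=0)
    comp_df = pd.DataFrame(comp_var, index=top)
    total = comp_df.sum(axis=1)
    fractions = comp_df.div(total.replace(0.0, np.nan), axis=0).fillna(0.0)
    return fractions


# --------------------------------------------------------------------------- #
# Set overlap and coexpression
# --------------------------------------------------------------------------- #

def hypergeom_overlap(set_a, set_b, universe_size: int) -> dict:
    """Exact hypergeometric upper-tail p for the overlap of two gene sets.

    p = P(X >= observed overlap) for X ~ Hypergeometric(universe, |a|, |b|),
    computed as an exact integer-arithmetic tail sum.
    """
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than universe")
    overlap = len(a & b)
    K, n, M = len(a), len(b), universe_size
    denom = math.comb(M, n)
    tail = sum(math.comb(K, k) * math.comb(M - K, n - k)
               for k in range(overlap, min(K, n) + 1))
    return {"overlap": overlap, "p": tail / denom}


def module_coexpression_cdf(X: ExpressionMatrix, module_genes,
                            subgroup_labels, n_random: int = 100,
                            seed: int = 0) -> dict:
    """Pairwise |Pearson r| among module genes, stratified by subgroup.

    Returns the |r| value arrays (suitable for empirical CDFs) and mean |r|
    for all samples, each subgroup stratum, and ``n_random`` random gene
    sets of the same size (drawn from the analyzed universe excluding the
    module; all-samples stratum) as a control.
    """
    labels = pd.Series(subgroup_labels).reindex(X.sample_ids)
    present = [g for g in module_genes if g in X.gene_ids]
    dropped = len(list(module_genes)) - len(present)
    if dropped:
        warnings.warn(f"{dropped} module gene(s) absent; dropped")
    if len(present) < 3:
        raise ValueError("fewer than 3 module genes present")

    def pairwise_abs_r(genes, mask=None):
        data = X.data.loc[genes]
        if mask is not None:
            data = data.loc[:, mask]
        r = np.corrcoef(data.to_numpy())
        iu = np.triu_indices_from(r, k=1)
        vals = np.abs(r[iu])
        return vals[np.isfinite(vals)]

    out = {"all": pairwise_abs_r(present)}
    for sg in sorted(pd.unique(labels.dropna())):
        mask = (labels == sg).to_numpy()
        if mask.sum() < 5:
            warnings.warn(f"stratum {sg!r} has < 5 samples; skipped")
            continue
        out[f"subgroup{sg}"] = pairwise_abs_r(present, mask)
    if n_random > 0:
        rng = np.random.default_rng(seed)
        pool = np.array([g for g in X.gene_ids if g not in set(present)])
        rand_means = []
        rand_vals = []
        for _ in range(n_random):
            pick = rng.choice(pool, size=len(present), replace=False)
            vals = pairwise_abs_r(list(pick))
            rand_vals.append(vals)
            rand_means.append(vals.mean())
        out["random"] = np.concatenate(rand_vals)
        summary_random = float(np.mean(rand_means))
    else:
        warnings.warn("n_random=0: random-set control omitted")
        summary_random = float("nan")
    summary = {k: float(v.mean()) for k, v in out.items()}
    summary["random"] = summary_random
    return {"values": out, "mean_abs_r": summary}


def paired_tissue_markers(fold_changes: pd.DataFrame, fc_min: float = 2.0,
                          min_groups: int = 3) -> dict:
    """WM/GM marker calls from per-group WM-vs-GM fold changes.

    A feature is a WM marker when its fold change is >= ``fc_min`` in at
    least ``min_groups`` of the group columns, and a GM marker when the
    fold change is <= 1/``fc_min`` in at least that many groups.
    """
    if fold_changes.shape[1] < min_groups:
        raise ValueError(f"need at least {min_groups} group columns")
    fc = fold_changes.to_numpy(dtype=float)
    wm = (fc >= fc_min).sum(axis=1) >= min_groups
    gm = (fc <= 1.0 / fc_min).sum(axis=1) >= min_groups
    return {"wm_markers": list(fold_changes.index[wm]),
            "gm_markers": list(fold_changes.index[gm])}
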