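"""Latent factor discovery: adaptive shrinkage, semi-NMF, consensus clustering.

The discovery chain splits a log-scale expression matrix X into a signal part
U (what supplied biological covariates explain, with small coefficients
soft-thresholded away) and a factor part B = X - U that carries unexplained
structure. B is then factorized as B ~ F G^T with G >= 0 (semi-NMF); the
argmax row of G assigns each sample to a latent cluster. Stability is
assessed by consensus over many restarts, and the number of clusters is
chosen by the cophenetic coefficient of the consensus matrix with mean
silhouette width as tie-break.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .containers import ExpressionMatrix
from .prep import _build_design, _check_full_rank, select_features

logger = logging.getLogger(__name__)

__all__ = [
    "ShrinkageResult", "SemiNMFFactors", "ConsensusResult",
    "ConsensusClustering", "adaptive_shrink", "semi_nmf",
    "consensus_cluster", "choose_k", "adjusted_rand_index",
    "sensitivity_grid",
]


# --------------------------------------------------------------------------- #
# Adaptive shrinkage
# --------------------------------------------------------------------------- #

@dataclass
class ShrinkageResult:
    """Additive split X = U + B into signal and factor matrices."""

    U: pd.DataFrame
    B: pd.DataFrame
    lam: float


def adaptive_shrink(X: ExpressionMatrix,
                    biological_covariates: pd.DataFrame | None = None,
                    lam: float = 0.01) -> ShrinkageResult:
    """Split X into covariate-explained signal U and factor matrix B = X - U.

    Per gene, expression is regressed on the supplied covariates (intercept
    always included) and each non-intercept coefficient is soft-thresholded
    at ``lam`` times its standard error; U is rebuilt from the shrunken
    coefficients. With no covariates U is the matrix of per-gene means and B
    the row-centered data. U + B = X exactly by construction.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    y = X.values  # genes x samples
    if biological_covariates is None:
        means = y.mean(axis=1, keepdims=True)
        U = np.broadcast_to(means, y.shape).copy()
    else:
        cov = biological_covariates.loc[X.sample_ids]
        design = _build_design(cov)
        _check_full_rank(design)
        d = design.to_numpy(dtype=float)
        n, p = d.shape
        dtd_inv = np.linalg.inv(d.T @ d)
        beta = dtd_inv @ d.T @ y.T                      # p x genes
        resid = y.T - d @ beta                          # n x genes
        dof = max(n - p, 1)
        sigma2 = (resid ** 2).sum(axis=0) / dof         # per gene
        se = np.sqrt(np.outer(np.diag(dtd_inv), sigma2))  # p x genes
        shrunk = beta.copy()
        thresh = lam * se[1:]
        shrunk[1:] = np.sign(beta[1:]) * np.maximum(
            np.abs(beta[1:]) - thresh, 0.0)
        U = (d @ shrunk).T
    B = y - U
    idx, cols = X.gene_ids, X.sample_ids
    return ShrinkageResult(pd.DataFrame(U, index=idx, columns=cols),
                           pd.DataFrame(B, index=idx, columns=cols), lam)


# --------------------------------------------------------------------------- #
# Semi-NMF
# --------------------------------------------------------------------------- #

@dataclass
class SemiNMFFactors:
    """B ~ F G^T with G >= 0; labels are per-sample argmax over G columns."""

    F: np.ndarray          # genes x k (unconstrained)
    G: np.ndarray          # samples x k (non-negative)
    objective: list[float]  # ||B - F G^T||_F^2 per iteration
    labels: np.ndarray      # per-sample cluster index 0..k-1


def _pos(m: np.ndarray) -> np.ndarray:
    return (np.abs(m) + m) / 2.0


def _neg(m: np.ndarray) -> np.ndarray:
    return (np.abs(m) - m) / 2.0


def _semi_nmf_gram(S: np.ndarray, G0: np.ndarray, max_iter: int,
                   tol: float) -> tuple[np.ndarray, list[float]]:
    """Semi-NMF updates expressed through the Gram matrix S = B^T B.

    With F the least-squares solution F = B G (G^T G)^-1, every quantity in
    the multiplicative G update and the objective can be written in terms of
    S, so the gene dimension never enters the iteration:
      B^T F = S G W,  F^T F = W^T G^T S G W,  W = (G^T G)^-1
      ||B - F G^T||^2 = tr(S) - 2 tr(G^T B^T F) + tr((F^T F)(G^T G)).
    """
    G = G0.copy()
    trS = float(np.trace(S))
    eps = 1e-12
    obj_trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        gtg = G.T @ G
        try:
            W = np.linalg.inv(gtg)
        except np.linalg.LinAlgError:
            logger.warning("singular G^T G; adding ridge 1e-10")
            W = np.linalg.inv(gtg + 1e-10 * np.eye(gtg.shape[0]))
        SG = S @ G
        BtF = SG @ W                       # samples x k
        FtF = W.T @ (G.T @ SG) @ W         # k x k
        num = _pos(BtF) + G @ _neg(FtF)
        den = _neg(BtF) + G @ _pos(FtF)
        G = G * np.sqrt(num / np.maximum(den, eps))

        gtg = G.T @ G
        try:
            W = np.linalg.inv(gtg)
        except np.linalg.LinAlgError:
            logger.warning("singular G^T G; adding ridge 1e-10")
            W = np.linalg.inv(gtg + 1e-10 * np.eye(gtg.shape[0]))
        SG = S @ G
        BtF = SG @ W
        FtF = W.T @ (G.T @ SG) @ W
        obj = trS - 2.0 * float(np.sum(G * BtF)) + float(np.sum(FtF * gtg))
        obj_trace.append(obj)
        if prev - obj <= tol * max(abs(prev), 1.0):
            break
        prev = obj
    return G, obj_trace


def _init_G(Bt: np.ndarray, k: int, seed: int,
            kmeans_max_iter: int = 50) -> np.ndarray:
    """Indicator of a k-means partition of samples, offset by 0.2."""
    n = Bt.shape[0]
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=1, max_iter=kmeans_max_iter,
                    random_state=seed % 2**31)
        labels = km.fit_predict(Bt)
    G = np.full((n, k), 0.2)
    G[np.arange(n), labels] += 1.0
    return G


def semi_nmf(B, k: int, seed: int = 0, max_iter: int = 500,
             tol: float = 1e-6) -> SemiNMFFactors:
    """Semi-nonnegative factorization B ~ F G^T with alternating updates.

    F solves the least-squares problem given G; G is updated multiplicatively
    with the positive/negative-part rule, which keeps it non-negative and the
    objective non-increasing. G is initialized from a k-means partition of
    the samples (cluster indicator + 0.2). Labels are per-sample argmax of G
    (ties resolve to the lowest column index).
    """
    Bv = B.to_numpy(dtype=float) if hasattr(B, "to_numpy") else np.asarray(
        B, dtype=float)
    n = Bv.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples ({n})")
    Bt = Bv.T
    S = Bt @ Bv
    G0 = _init_G(Bt, k, seed)
    G, trace = _semi_nmf_gram(S, G0, max_iter, tol)
    gtg = G.T @ G
    W = np.linalg.pinv(gtg)
    F = Bv @ G @ W
    labels = np.argmax(G, axis=1)
    return SemiNMFFactors(F=F, G=G, objective=trace, labels=labels)


# --------------------------------------------------------------------------- #
# Consensus clustering and rank selection
# --------------------------------------------------------------------------- #

@dataclass
class ConsensusResult:
    """Consensus over restarts at a single rank k."""

    k: int
    consensus: np.ndarray       # samples x samples co-clustering frequency
    labels: np.ndarray          # final labels from hierarchical cut
    cophenetic: float
    silhouette: float


@dataclass
class ConsensusClustering:
    """Per-rank consensus results plus the selected rank."""

    results: dict[int, ConsensusResult]
    chosen_k: int
    sample_ids: pd.Index | None = None

    def metrics(self) -> pd.DataFrame:
        return pd.DataFrame({
            k: {"cophenetic": r.cophenetic, "silhouette": r.silhouette}
            for k, r in self.results.items()}).T.rename_axis("k")


def _consensus_metrics(consensus: np.ndarray, k: int
                       ) -> tuple[np.ndarray, float, float]:
    """Hierarchical cut of 1 - consensus, cophenetic corr, mean silhouette."""
    n = consensus.shape[0]
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = squareform(dist, checks=False)
    Z = average(condensed)
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    if np.allclose(condensed, condensed[0] if condensed.size else 0.0):
        warnings.warn("degenerate consensus; cophenetic undefined")
        coph = float("nan")
    else:
        coph, _ = cophenet(Z, condensed)
        coph = float(coph)
    if len(np.unique(labels)) < 2 or n <= len(np.unique(labels)):
        sil = float("nan")
    else:
        sil = float(silhouette_score(dist, labels, metric="precomputed"))
    return labels, coph, sil


def consensus_cluster(B, k_range=range(2, 9), n_iter: int = 500,
                      seed: int = 0, max_iter: int = 200,
                      tol: float = 1e-6) -> ConsensusClustering:
    """Consensus semi-NMF clustering over restarts for each candidate rank.

    Each restart uses a distinct sub-seed for its perturbed k-means
    initialization; the consensus matrix is the mean of run connectivity
    matrices (1 when two samples share a label). Final labels come from
    average-linkage hierarchical clustering of 1 - consensus cut at k.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    sample_ids = B.columns if hasattr(B, "columns") else None
    Bv = B.to_numpy(dtype=float) if hasattr(B, "to_numpy") else np.asarray(
        B, dtype=float)
    n = Bv.shape[1]
    Bt = np.ascontiguousarray(Bv.T)
    S = Bt @ Bv
    ss = np.random.SeedSequence(seed)
    results: dict[int, ConsensusResult] = {}
    for k in k_range:
        if k > n:
            raise ValueError(f"k={k} exceeds number of samples ({n})")
        sub = ss.spawn(1)[0]
        run_seeds = [int(s.generate_state(1)[0] % 2**31)
                     for s in sub.spawn(n_iter)]
        consensus = np.zeros((n, n))
        for rs in run_seeds:
            G0 = _init_G(Bt, k, rs)
            G, _ = _semi_nmf_gram(S, G0, max_iter, tol)
            labels = np.argmax(G, axis=1)
            consensus += (labels[:, None] == labels[None, :])
        consensus /= n_iter
        labels, coph, sil = _consensus_metrics(consensus, k)
        results[k] = ConsensusResult(k, consensus, labels, coph, sil)
    cc = ConsensusClustering(results, chosen_k=-1, sample_ids=sample_ids)
    try:
        cc.chosen_k = choose_k(cc)
    except ValueError:
        warnings.warn("rank-selection metrics all undefined; no k chosen")
        cc.chosen_k = -1
    return cc


def choose_k(cc: ConsensusClustering, coph_tol: float = 0.01) -> int:
    """Rank with maximal cophenetic coefficient.

    Cophenetic coefficients within ``coph_tol`` of the maximum are treated
    as tied: the coefficient's variability across restart seeds is of that
    order, so smaller differences carry no signal. Ties break by larger
    mean silhouette, then by smaller k (parsimony).
    """
    candidates = [(k, r.cophenetic, r.silhouette)
                  for k, r in cc.results.items()
                  if np.isfinite(r.cophenetic)]
    if not candidates:
        raise ValueError("all rank-selection metrics are NaN")
    top = max(c[1] for c in candidates)
    tied = [c for c in candidates if c[1] >= top - coph_tol]
    best = max(tied, key=lambda c: (
        c[2] if np.isfinite(c[2]) else -np.inf, -c[0]))
    return best[0]


# --------------------------------------------------------------------------- #
# Adjusted Rand index
# --------------------------------------------------------------------------- #

def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected Rand index from the contingency table.

    1 for identical partitions up to relabeling; expectation 0 under random
    labelings with the same marginals.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


# --------------------------------------------------------------------------- #
# Parameter sensitivity
# --------------------------------------------------------------------------- #

def sensitivity_grid(X: ExpressionMatrix,
                     covariates: pd.DataFrame | None = None,
                     feature_sizes=(2000, 3000, 4000),
                     lambdas=(0.001, 0.01, 0.1),
                     iter_counts=(10, 100, 500),
                     k_range=range(2, 9), seed: int = 0,
                     gene_annot: pd.DataFrame | None = None,
                     min_count: float = 0.0
                     ) -> dict[tuple[int, int], pd.DataFrame]:
    """Pairwise ARI of cluster assignments across parameter combinations.

    For each consensus iteration count and rank k, runs the full discovery
    chain (MAD feature selection -> shrinkage -> consensus clustering) for
    every (feature size, lambda) combination, then reports the matrix of
    pairwise adjusted Rand indices between the combinations' labelings.
    Note lambda only influences the split when covariates are supplied; the
    covariate-free chain row-centers X for every lambda.
    """
    combos = list(itertools.product(feature_sizes, lambdas))
    out: dict[tuple[int, int], pd.DataFrame] = {}
    names = [f"top{fs}_lam{lam}" for fs, lam in combos]
    for n_iter in iter_counts:
        labelings: dict[tuple, dict[int, np.ndarray]] = {}
        for fs, lam in combos:
            sub = select_features(X, gene_annot=gene_annot,
                                  min_count=min_count, top_n_mad=fs)
            shrink = adaptive_shrink(sub, covariates, lam=lam)
            cc = consensus_cluster(shrink.B, k_range=k_range,
                                   n_iter=n_iter, seed=seed)
            labelings[(fs, lam)] = {k: r.labels
                                    for k, r in cc.results.items()}
        for k in k_range:
            mat = np.ones((len(combos), len(combos)))
            for i, ci in enumerate(combos):
                for j, cj in enumerate(combos):
                    if j > i:
                        mat[i, j] = mat[j, i] = adjusted_rand_index(
                            labelings[ci][k], labelings[cj][k])
            out[(n_iter, k)] = pd.DataFrame(mat, index=names, columns=names)
    return out
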