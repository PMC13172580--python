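"""I/O and preprocessing applied before latent-factor discovery.

The preprocessing chain mirrors common bulk RNA-seq practice: median-of-ratios
size factors, log2 normalization with a pseudocount, removal of technical
covariates by per-gene least squares (keeping gene means so fold changes stay
interpretable), Y-chromosome/low-count/MAD feature selection, CPM-log scaling
for shallow (spot-level) libraries, and missForest-style imputation for
metabolite/protein matrices with block missingness.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from scipy.linalg import qr
from sklearn.ensemble import RandomForestRegressor

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix", "write_matrix", "size_factors", "normalize_log2",
    "residualize_covariates", "select_features", "cpm_log", "zscore_genes",
    "filter_and_impute", "read_sample_table",
]


# --------------------------------------------------------------------------- #
# I/O
# --------------------------------------------------------------------------- #

def read_matrix(path, fmt: str = "tsv", scale: str = "counts",
                allow_missing: bool = False) -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV or MatrixMarket.

    TSV: first column gene id, header row of sample ids. MTX: `path` points to
    the ``.mtx`` file with sibling ``features.tsv`` and ``barcodes.tsv`` files
    (1-based indices per the MatrixMarket standard, handled by scipy).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if fmt == "tsv":
        na_vals = ["NA", ""] if allow_missing else []
        try:
            df = pd.read_csv(path, sep="\t", index_col=0,
                             na_values=na_vals, keep_default_na=allow_missing)
        except pd.errors.ParserError as exc:
            raise ValueError(f"ragged or malformed TSV {path}: {exc}") from exc
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        return ExpressionMatrix(df.astype(float), scale, allow_missing)
    if fmt == "mtx":
        try:
            mat = scipy.io.mmread(str(path))
        except ValueError as exc:
            raise ValueError(f"malformed MTX header in {path}: {exc}") from exc
        genes = pd.read_csv(path.parent / "features.tsv", sep="\t",
                            header=None)[0]
        samples = pd.read_csv(path.parent / "barcodes.tsv", sep="\t",
                              header=None)[0]
        df = pd.DataFrame(np.asarray(mat.todense(), dtype=float),
                          index=genes, columns=samples)
        return ExpressionMatrix(df, scale, allow_missing)
    raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'mtx'")


def write_matrix(matrix: ExpressionMatrix, path, fmt: str = "tsv") -> None:
    """Write a matrix as TSV (dense) or MTX (+features.tsv/barcodes.tsv)."""
    path = Path(path)
    if fmt == "tsv":
        matrix.data.to_csv(path, sep="\t", index_label="gene_id",
                           na_rep="NA" if matrix.allow_missing else "")
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(matrix.values))
        pd.Series(matrix.gene_ids).to_csv(path.parent / "features.tsv",
                                          sep="\t", index=False, header=False)
        pd.Series(matrix.sample_ids).to_csv(path.parent / "barcodes.tsv",
                                            sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_sample_table(path) -> pd.DataFrame:
    """Read per-sample metadata (TSV, first column sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    return df


# --------------------------------------------------------------------------- #
# Normalization
# --------------------------------------------------------------------------- #

def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Per sample j: median over reference genes g (genes with strictly positive
    counts in all samples, hence positive geometric mean) of
    ``counts[g, j] / geomean(counts[g, :])``.
    """
    if counts.scale != "counts":
        raise ValueError("size_factors expects a counts-scale matrix")
    values = counts.values
    if np.any(values < 0):
        raise ValueError("negative counts")
    ref = np.all(values > 0, axis=1)
    if not ref.any():
        raise ValueError("no reference genes: no gene is positive in all samples")
    logv = np.log(values[ref])
    log_geomean = logv.mean(axis=1)
    ratios = np.exp(logv - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def normalize_log2(counts: ExpressionMatrix, factors: pd.Series,
                   pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(count / size_factor + pseudocount) on the full matrix."""
    f = factors.reindex(counts.sample_ids).to_numpy(dtype=float)
    if np.any(~np.isfinite(f)) or np.any(f <= 0):
        raise ValueError("size factors must be positive and finite")
    norm = np.log2(counts.values / f[None, :] + pseudocount)
    return ExpressionMatrix(
        pd.DataFrame(norm, index=counts.gene_ids, columns=counts.sample_ids),
        "log2norm")


def cpm_log(counts: ExpressionMatrix) -> ExpressionMatrix:
    """log2(1e6 * count / library_size + 1), the scale used for spot data."""
    values = counts.values
    colsums = values.sum(axis=0)
    bad = np.flatnonzero(colsums <= 0)
    if bad.size:
        raise ValueError(f"all-zero library for sample {counts.sample_ids[bad[0]]!r}")
    out = np.log2(1e6 * values / colsums[None, :] + 1.0)
    return ExpressionMatrix(
        pd.DataFrame(out, index=counts.gene_ids, columns=counts.sample_ids),
        "cpmlog")


def zscore_genes(X: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene standardization across samples (constant genes map to 0).

    The scale used for cross-modality classifier transfer: bulk cohorts mix
    tissue on the log scale while cells and spots mix linearly, so absolute
    per-gene levels never align across modalities; location/scale
    standardization within each matrix removes that mismatch.
    """
    d = X.data
    mu = d.mean(axis=1)
    sd = d.std(axis=1, ddof=0).replace(0.0, 1.0)
    return ExpressionMatrix(d.sub(mu, axis=0).div(sd, axis=0), "zscore")


# --------------------------------------------------------------------------- #
# Covariate removal and feature selection
# --------------------------------------------------------------------------- #

def _build_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Intercept + numeric columns + one-hot (drop-first) categoricals."""
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in covariates.columns:
        s = covariates[col]
        if s.isna().any():
            raise ValueError(f"missing values in covariate {col!r}")
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True,
                                     dtype=float)
            parts.extend(dummies[c] for c in dummies.columns)
    return pd.concat(parts, axis=1)


def _check_full_rank(design: pd.DataFrame) -> None:
    d = design.to_numpy(dtype=float)
    _, r, piv = qr(d, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(d.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < d.shape[1]:
        aliased = [design.columns[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


def residualize_covariates(X: ExpressionMatrix,
                           covariates: pd.DataFrame) -> ExpressionMatrix:
    """Remove covariate effects per gene by OLS, adding back the intercept.

    Output = residual + fitted intercept, so per-gene residuals are orthogonal
    to every covariate column while values stay on the original scale (the
    intercept equals the gene mean exactly when covariates are centered).
    Idempotent.
    """
    if X.scale not in ("log2norm", "cpmlog", "zscore"):
        raise ValueError("residualize_covariates expects log-scale data")
    covariates = covariates.loc[X.sample_ids]
    design = _build_design(covariates)
    _check_full_rank(design)
    d = design.to_numpy(dtype=float)
    y = X.values  # genes x samples
    beta, *_ = np.linalg.lstsq(d, y.T, rcond=None)  # p x genes
    fitted = d @ beta
    intercept = np.outer(np.ones(d.shape[0]), beta[0])
    out = (y.T - fitted + intercept).T
    return ExpressionMatrix(
        pd.DataFrame(out, index=X.gene_ids, columns=X.sample_ids), X.scale)


def select_features(X: ExpressionMatrix,
                    gene_annot: pd.DataFrame | None = None,
                    min_count: float = 10.0,
                    top_n_mad: int | None = None,
                    counts: ExpressionMatrix | None = None) -> ExpressionMatrix:
    """Drop Y-chromosome genes, low-count genes, then keep top genes by MAD.

    ``gene_annot`` needs a ``chromosome`` column to apply the Y filter. The
    total-count filter uses ``counts`` when supplied (the matrix X itself is
    usually on a log scale); otherwise it applies to X's own row sums. MAD is
    computed on X; ties broken by gene id lexicographic order.
    """
    keep = pd.Series(True, index=X.gene_ids)
    if gene_annot is not None and "chromosome" in gene_annot.columns:
        chrom = gene_annot["chromosome"].reindex(X.gene_ids)
        keep &= ~chrom.isin(["Y", "chrY"])
    totals_src = counts if counts is not None else X
    totals = totals_src.data.sum(axis=1).reindex(X.gene_ids)
    keep &= totals >= min_count
    sub = X.data.loc[keep[keep].index]
    if top_n_mad is None:
        return ExpressionMatrix(sub, X.scale)
    if top_n_mad <= 0:
        raise ValueError("top_n_mad must be positive")
    if top_n_mad > sub.shape[0]:
        raise ValueError("top_n_mad exceeds number of genes after filtering")
    med = sub.median(axis=1)
    mad = (sub.sub(med, axis=0)).abs().median(axis=1)
    order = mad.to_frame("mad")
    order["gene"] = order.index
    order = order.sort_values(["mad", "gene"], ascending=[False, True])
    chosen = order.index[:top_n_mad]
    chosen = sub.index[sub.index.isin(chosen)]  # preserve original row order
    return ExpressionMatrix(sub.loc[chosen], X.scale)


# --------------------------------------------------------------------------- #
# Omics missing-data handling
# --------------------------------------------------------------------------- #

def filter_and_impute(matrix: ExpressionMatrix, max_missing: float = 0.7,
                      seed: int = 0, max_rounds: int = 10,
                      tol: float = 1e-3,
                      n_estimators: int = 30) -> ExpressionMatrix:
    """Drop features with too much missingness, impute the rest.

    Features (rows) whose missing fraction exceeds ``max_missing`` are
    discarded. Remaining missing entries are filled by iterative tree-ensemble
    imputation: initialize with feature medians, then cycle features in order
    of increasing missingness, regressing each feature's missing entries on
    all other features with a random forest, until the relative change of the
    imputed values falls below ``tol`` or ``max_rounds`` is reached.
    """
    if not matrix.allow_missing:
        return matrix.copy()
    df = matrix.data.copy()
    frac = df.isna().mean(axis=1)
    kept = df.loc[frac <= max_missing]
    if kept.empty:
        raise ValueError("all features dropped by missingness filter")
    mask = kept.isna()
    if not mask.to_numpy().any():
        return ExpressionMatrix(kept, matrix.scale)

    filled = kept.apply(lambda row: row.fillna(row.median()), axis=1)
    order = mask.mean(axis=1)
    order = order[order > 0].sort_values(kind="mergesort").index
    rng = np.random.SeedSequence(seed)
    prev = filled.to_numpy().copy()
    for round_i in range(max_rounds):
        for feat in order:
            miss_cols = mask.loc[feat]
            others = filled.drop(index=feat)
            rf = RandomForestRegressor(
                n_estimators=n_estimators,
                random_state=int(rng.spawn(1)[0].generate_state(1)[0] % 2**31))
            rf.fit(others.loc[:, ~miss_cols].T, filled.loc[feat, ~miss_cols])
            filled.loc[feat, miss_cols] = rf.predict(others.loc[:, miss_cols].T)
        cur = filled.to_numpy()
        denom = np.linalg.norm(cur[mask.to_numpy()]) or 1.0
        delta = np.linalg.norm(cur[mask.to_numpy()] - prev[mask.to_numpy()])
        if delta / denom < tol:
            break
        prev = cur.copy()
    return ExpressionMatrix(filled, matrix.scale)
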