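"""Per-subgroup signature genes by one-vs-rest differential expression.

Signatures are the genes significantly up-regulated in a subgroup relative to
all remaining samples (Welch t on log2-normalized values, Benjamini-Hochberg
FDR <= 1%, fold change >= 1.5). The union over subgroups forms the feature
list for the subgroup classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = ["bh_adjust", "one_vs_rest_deg", "derive_signature",
           "SignatureSet", "read_gmt", "write_gmt"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, mapped back to input
    order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t statistic and two-sided p; zero-variance rows -> p=1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(t)
    t[bad] = 0.0
    p[bad] = 1.0
    return t, p


def one_vs_rest_deg(X: ExpressionMatrix, labels, group) -> pd.DataFrame:
    """Differential expression of one subgroup against all remaining samples.

    Per gene: log2 fold change = mean(group) - mean(rest) on the log2 scale,
    Welch two-sample t statistic, two-sided p, and BH-adjusted q. Genes with
    zero variance on both sides get t = 0, p = 1 by convention.
    """
    labels = pd.Series(labels, index=X.sample_ids
                       ) if not isinstance(labels, pd.Series) else labels
    labels = labels.reindex(X.sample_ids)
    mask = (labels == group).to_numpy()
    if mask.sum() == 0:
        raise ValueError(f"group {group!r} absent from labels")
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ValueError("need >= 3 samples on each side")
    a = X.values[:, mask]
    b = X.values[:, ~mask]
    t, p = _welch_t(a, b)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    return pd.DataFrame({
        "gene_id": X.gene_ids,
        "log2fc": lfc,
        "statistic": t,
        "p": p,
        "q": bh_adjust(p),
        "group": group,
    }).set_index("gene_id")


@dataclass
class SignatureSet:
    """Ordered up-regulated gene lists per subgroup plus their union."""

    per_subgroup: dict  # group -> DataFrame (log2fc, q), sorted by log2fc desc
    combined: list      # union of per-subgroup gene ids (first-seen order)

    def genes(self, group) -> list:
        return list(self.per_subgroup[group].index)


def derive_signature(deg_tables: dict, q_max: float = 0.01,
                     min_fc: float = 1.5) -> SignatureSet:
    """Select per-subgroup up-regulated signature genes at the thresholds.

    Keeps genes with q <= q_max, log2fc > 0 and fold change 2**log2fc >=
    min_fc. A gene may appear in more than one subgroup's list; the combined
    signature is the de-duplicated union.
    """
    per = {}
    combined: list = []
    seen = set()
    for group, table in deg_tables.items():
        keep = table[(table["q"] <= q_max) & (table["log2fc"] > 0)
                     & (np.exp2(table["log2fc"]) >= min_fc)]
        keep = keep.sort_values("log2fc", ascending=False)
        per[group] = keep[["log2fc", "q"]]
        for g in keep.index:
            if g not in seen:
                seen.add(g)
                combined.append(g)
    if not combined:
        raise ValueError("no signature genes at thresholds")
    return SignatureSet(per_subgroup=per, combined=combined)


# --------------------------------------------------------------------------- #
# GMT round trip
# --------------------------------------------------------------------------- #

def write_gmt(sets: dict, path) -> None:
    """Write named gene sets as GMT (name, description, genes...)."""
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([str(name), "latentmix"] +
                               [str(g) for g in genes]) + "\n")


def read_gmt(path) -> dict:
    """Read a GMT file into {set name: [gene ids]}."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[parts[0]] = parts[2:]
    return sets
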