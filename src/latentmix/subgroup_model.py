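"""Subgroup classifier: train on signature genes, project across modalities.

A 200-tree random forest trained on the signature-gene submatrix assigns
subgroup labels and class probabilities to new bulk samples, pseudo-bulk
single-cell samples and spatial spots. The predicted probability of the
WM-enriched subgroup (class 2) serves as a continuous proxy for white-matter
content - a relative score, not an absolute WM fraction.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["SubgroupModel", "SubgroupPrediction", "train_subgroup_classifier",
           "align_features", "predict_subgroups", "pseudo_bulk", "wm_score"]

SCHEMA_VERSION = 1


@dataclass
class SubgroupModel:
    """Trained tree ensemble bound to an ordered signature gene list."""

    features: list
    classifier: RandomForestClassifier
    classes: np.ndarray
    oob_accuracy: float
    oob_auc: dict            # class -> one-vs-rest AUC from OOB votes
    medians: pd.Series       # training per-gene medians, for imputation
    scale: str               # training scale tag
    schema_version: int = SCHEMA_VERSION

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "SubgroupModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if model.schema_version != SCHEMA_VERSION:
            raise ValueError("incompatible model schema version")
        return model


@dataclass
class SubgroupPrediction:
    """Per-sample labels, class probabilities and the WM proxy score."""

    labels: pd.Series
    probabilities: pd.DataFrame   # samples x classes
    missing_fraction: float = 0.0

    @property
    def subgroup_2_score(self) -> pd.Series:
        return wm_score(self)


def train_subgroup_classifier(X_signature: ExpressionMatrix, labels,
                              n_trees: int = 200, seed: int = 0
                              ) -> SubgroupModel:
    """Train the bagged-tree subgroup classifier with out-of-bag evaluation.

    OOB accuracy and per-class one-vs-rest AUC are computed from OOB votes
    only. The model stores training-set per-gene medians so that projection
    targets missing some signature genes can be median-imputed.
    """
    if X_signature.scale not in ("log2norm", "cpmlog", "zscore"):
        raise ValueError("classifier expects log-scale input "
                         f"(got scale={X_signature.scale!r})")
    labels = pd.Series(labels, index=X_signature.sample_ids
                       ) if not isinstance(labels, pd.Series) else labels
    labels = labels.reindex(X_signature.sample_ids)
    counts = labels.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with < 2 samples: {small}")
    y = labels.to_numpy()
    Xt = X_signature.values.T  # samples x genes
    clf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                 random_state=seed % 2**31)
    clf.fit(Xt, y)
    oob = clf.oob_decision_function_
    valid = ~np.isnan(oob).any(axis=1)
    oob_labels = clf.classes_[np.argmax(oob[valid], axis=1)]
    oob_acc = float(np.mean(oob_labels == y[valid]))
    aucs = {}
    for i, cls in enumerate(clf.classes_):
        aucs[cls] = float(roc_auc_score((y[valid] == cls).astype(int),
                                        oob[valid, i]))
    medians = X_signature.data.median(axis=1)
    return SubgroupModel(features=list(X_signature.gene_ids),
                         classifier=clf, classes=clf.classes_,
                         oob_accuracy=oob_acc, oob_auc=aucs,
                         medians=medians, scale=X_signature.scale)


def align_features(model: SubgroupModel, X_new: ExpressionMatrix
                   ) -> tuple[pd.DataFrame, float]:
    """Reorder a new matrix to the model's feature order.

    Missing features are filled with training medians; extra genes are
    dropped. Errors when fewer than half the training features are present
    (at that point a retrained model is warranted).
    """
    present = set(X_new.gene_ids)
    overlap = sum(g in present for g in model.features) / len(model.features)
    if overlap < 0.5:
        raise ValueError(
            f"feature overlap too low ({overlap:.2f}); retrain")
    aligned = X_new.data.reindex(model.features)
    for g in model.features:
        if g not in present:
            aligned.loc[g] = model.medians[g]
    missing_fraction = 1.0 - overlap
    if missing_fraction > 0:
        logger.info("align_features: %.1f%% of model features median-imputed",
                    100 * missing_fraction)
    return aligned, missing_fraction


def predict_subgroups(model: SubgroupModel, X_new: ExpressionMatrix
                      ) -> SubgroupPrediction:
    """Predict subgroup labels and class probabilities for new samples.

    Probabilities are tree vote fractions; labels are the argmax class (ties
    resolve to the lowest class index). Input must be on a log scale
    comparable to training (log2norm or cpmlog).
    """
    if X_new.scale not in ("log2norm", "cpmlog", "zscore"):
        raise ValueError("prediction expects log-scale input "
                         f"(got scale={X_new.scale!r})")
    aligned, missing_fraction = align_features(model, X_new)
    values = aligned.to_numpy(dtype=float).T
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in prediction input")
    probs = model.classifier.predict_proba(values)
    prob_df = pd.DataFrame(probs, index=X_new.sample_ids,
                           columns=model.classes)
    labels = pd.Series(model.classes[np.argmax(probs, axis=1)],
                       index=X_new.sample_ids, name="subgroup")
    return SubgroupPrediction(labels=labels, probabilities=prob_df,
                              missing_fraction=missing_fraction)


def pseudo_bulk(sc_counts, cell_to_sample: pd.Series, gene_ids,
                cell_types: pd.Series | None = None,
                subset_celltype: str | None = None) -> ExpressionMatrix:
    """Sum single-cell counts per sample into a pseudo-bulk counts matrix.

    Optionally restrict to one cell type before summing (the
    single-cell-type control). Samples left with zero cells after the
    restriction are dropped with a warning.
    """
    mat = scipy.sparse.csr_matrix(sc_counts)
    n_cells = mat.shape[1]
    if len(cell_to_sample) != n_cells:
        raise ValueError("every cell must map to a sample")
    keep = np.ones(n_cells, dtype=bool)
    if subset_celltype is not None:
        if cell_types is None:
            raise ValueError("cell_types required to subset by cell type")
        if subset_celltype not in set(cell_types):
            raise ValueError(f"unknown cell type {subset_celltype!r}")
        keep = (cell_types == subset_celltype).to_numpy()
    samples = pd.Index(pd.unique(cell_to_sample), name="sample_id")
    cell_sample_idx = samples.get_indexer(cell_to_sample)
    indicator = scipy.sparse.csr_matrix(
        (keep.astype(float), (np.arange(n_cells), cell_sample_idx)),
        shape=(n_cells, len(samples)))
    agg = np.asarray((mat @ indicator).todense(), dtype=float)
    cells_per_sample = np.asarray(indicator.sum(axis=0)).ravel()
    empty = cells_per_sample == 0
    if empty.any():
        logger.warning("dropping %d sample(s) with no cells after subsetting",
                       int(empty.sum()))
    df = pd.DataFrame(agg[:, ~empty], index=pd.Index(gene_ids,
                                                     name="gene_id"),
                      columns=samples[~empty])
    return ExpressionMatrix(df, "counts")


def wm_score(prediction: SubgroupPrediction) -> pd.Series:
    """Predicted probability of the WM-enriched subgroup (class 2).

    A relative proxy for white-matter content, not an absolute WM fraction.
    """
    cols = prediction.probabilities.columns
    if 2 in cols:
        col = 2
    elif "2" in cols:
        col = "2"
    else:
        raise ValueError("prediction carries no class 2")
    return prediction.probabilities[col].rename("wm_score")
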