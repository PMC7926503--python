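"""The two claudin-low calling procedures.

1. **Nearest-centroid classification** against a labeled reference panel:
   a centroid is the per-gene mean expression vector of each reference group
   (CL / other) over a fixed gene list; a profile is assigned to whichever
   centroid is closer in Euclidean distance. Exact distance ties go to
   "other" — conservative for a rare-subtype caller.

2. **Signature clustering**: Ward agglomerative clustering (Euclidean metric)
   of samples on the 17 signature genes, genes standardized across samples,
   followed by an explicit CL-cluster identification score. The score of a
   cluster is the mean over its samples of
   ``mean z(up-direction genes) - mean z(down-direction genes)`` with z-scores
   taken per gene across all samples of the cohort; the cluster maximizing
   the score is called CL only if the score reaches a threshold (default 1.0
   pooled-z units).

Ward merge heights follow the classic criterion on within-cluster
sum-of-squares increments; for two singletons the merge cost is
``||a - b||^2 / 2`` (the reported scipy height is its square root times
sqrt(2), so ``cost = height^2 / 2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClassifierMixin, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted
from sklearn.utils.multiclass import unique_labels

from .io import (
    CL_LABEL,
    OTHER_LABEL,
    ExpressionMatrix,
    LabeledReference,
    MarkerSignature,
    intersect_genes,
)

#: Hard-fail if fewer than this fraction of a centroid gene list is present.
DEFAULT_MIN_GENE_FRACTION = 0.5

#: Minimum CL-concordance score (pooled-z units) to call a cluster CL.
DEFAULT_CL_SCORE_THRESHOLD = 1.0


# ---------------------------------------------------------------------------
# Nearest-centroid classifier
# ---------------------------------------------------------------------------


class CentroidSubtypeClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-centroid two-class subtype classifier (Euclidean distance).

    sklearn conventions: X is (n_samples, n_features). ``fit`` stores the
    per-class mean vectors; ``decision_function`` returns the margin
    ``d(other) - d(positive)`` so positive margins mean the positive class
    (default ``"CL"``); exact ties predict the negative class.
    """

    def __init__(self, positive_label: str = CL_LABEL):
        self.positive_label = positive_label

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = unique_labels(y)
        if len(self.classes_) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(self.classes_)}")
        if self.positive_label not in self.classes_:
            raise ValueError(
                f"positive_label {self.positive_label!r} absent from y"
            )
        self.negative_label_ = next(
            c for c in self.classes_ if c != self.positive_label
        )
        pos_mask = y == self.positive_label
        if pos_mask.sum() == 0 or (~pos_mask).sum() == 0:
            raise ValueError("each class needs at least one training sample")
        self.centroid_pos_ = X[pos_mask].mean(axis=0)
        self.centroid_neg_ = X[~pos_mask].mean(axis=0)
        self.n_features_in_ = X.shape[1]
        self.group_sizes_ = {
            str(self.positive_label): int(pos_mask.sum()),
            str(self.negative_label_): int((~pos_mask).sum()),
        }
        return self

    def _distances(self, X):
        check_is_fitted(self, "centroid_pos_")
        X = check_array(X, dtype=float)
        d_pos = np.linalg.norm(X - self.centroid_pos_, axis=1)
        d_neg = np.linalg.norm(X - self.centroid_neg_, axis=1)
        return d_pos, d_neg

    def decision_function(self, X):
        d_pos, d_neg = self._distances(X)
        return d_neg - d_pos

    def predict(self, X):
        margin = self.decision_function(X)
        return np.where(margin > 0, self.positive_label, self.negative_label_)


@dataclass
class CentroidModel:
    """Trained centroid pair over a fixed gene list, with training metadata."""

    gene_list: list[str]
    centroid_cl: np.ndarray
    centroid_other: np.ndarray
    n_cl: int
    n_other: int
    missing_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.centroid_cl) != len(self.gene_list) or len(
            self.centroid_other
        ) != len(self.gene_list):
            raise ValueError("centroid length must equal gene list length")
        if not (
            np.isfinite(self.centroid_cl).all()
            and np.isfinite(self.centroid_other).all()
        ):
            raise ValueError("centroids must be finite")


def build_centroids(
    reference: LabeledReference,
    gene_list: list[str] | None = None,
    min_gene_fraction: float = DEFAULT_MIN_GENE_FRACTION,
) -> CentroidModel:
    """Train CL/other centroids from a labeled reference panel.

    The gene list (default: the reference's own) is intersected with the
    panel's genes; the model proceeds on the intersection and records the
    missing genes, failing only if fewer than ``min_gene_fraction`` remain.
    """
    if gene_list is None:
        gene_list = reference.gene_list
    sub, kept, missing = intersect_genes(reference.matrix, gene_list)
    if len(kept) / len(gene_list) < min_gene_fraction:
        raise ValueError(
            f"only {len(kept)}/{len(gene_list)} centroid genes present "
            f"(< {min_gene_fraction:.0%}); check gene symbol conventions"
        )
    clf = CentroidSubtypeClassifier().fit(
        sub.values.T, reference.labels.to_numpy()
    )
    return CentroidModel(
        gene_list=kept,
        centroid_cl=clf.centroid_pos_,
        centroid_other=clf.centroid_neg_,
        n_cl=clf.group_sizes_[CL_LABEL],
        n_other=clf.group_sizes_[OTHER_LABEL],
        missing_genes=missing,
    )


def assign_subtype(
    model: CentroidModel,
    matrix: ExpressionMatrix,
    min_gene_fraction: float = DEFAULT_MIN_GENE_FRACTION,
) -> pd.DataFrame:
    """Assign each sample to the nearest centroid.

    Genes missing from ``matrix`` are dropped from both the sample vectors
    and the centroids so distances stay comparable. Returns one row per
    sample: label, d_cl, d_other, margin (= d_other - d_cl; CL iff > 0).
    """
    present_mask = np.array([g in set(matrix.genes) for g in model.gene_list])
    present = [g for g, ok in zip(model.gene_list, present_mask) if ok]
    if len(present) / len(model.gene_list) < min_gene_fraction:
        raise ValueError(
            f"only {len(present)}/{len(model.gene_list)} model genes present in "
            f"the matrix (< {min_gene_fraction:.0%})"
        )
    clf = CentroidSubtypeClassifier()
    clf.classes_ = np.array([CL_LABEL, OTHER_LABEL], dtype=object)
    clf.negative_label_ = OTHER_LABEL
    clf.centroid_pos_ = model.centroid_cl[present_mask]
    clf.centroid_neg_ = model.centroid_other[present_mask]
    clf.n_features_in_ = len(present)
    X = matrix.data.loc[present].to_numpy(dtype=float).T
    d_cl, d_other = clf._distances(X)
    margin = d_other - d_cl
    return pd.DataFrame(
        {
            "sample_id": matrix.samples,
            "label": np.where(margin > 0, CL_LABEL, OTHER_LABEL),
            "d_cl": d_cl,
            "d_other": d_other,
            "margin": margin,
        }
    ).set_index("sample_id")


# ---------------------------------------------------------------------------
# Ward signature clustering + CL-cluster identification
# ---------------------------------------------------------------------------


class WardSubtypeClusterer(ClusterMixin, BaseEstimator):
    """Ward/Euclidean agglomerative clustering with a directed marker score.

    ``directions`` is a +1/-1 vector over features (up/down expected in the
    target subtype). ``fit`` standardizes features (optional), builds the
    Ward merge tree, cuts it into ``k`` clusters, scores every cluster by the
    mean directed z-score of its samples, and calls the top cluster the
    target subtype if its score reaches ``threshold``.

    Fitted attributes: ``linkage_`` (scipy linkage matrix), ``merge_costs_``
    (within-cluster SS increments, = height^2/2), ``labels_``,
    ``cluster_scores_``, ``cl_cluster_`` (id or None).
    """

    def __init__(
        self,
        k: int = 2,
        threshold: float = DEFAULT_CL_SCORE_THRESHOLD,
        standardize: bool = True,
        directions=None,
    ):
        self.k = k
        self.threshold = threshold
        self.standardize = standardize
        self.directions = directions

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        n_samples = X.shape[0]
        if n_samples < 2:
            raise ValueError("clustering needs at least 2 samples")
        if self.directions is None:
            raise ValueError("directions (+1/-1 per feature) are required")
        directions = np.asarray(self.directions, dtype=float)
        if directions.shape[0] != X.shape[1]:
            raise ValueError("directions length must match number of features")

        Xc = X
        if self.standardize:
            Xc = self._zscore(X)
        self.linkage_ = linkage(Xc, method="ward", metric="euclidean")
        self.merge_costs_ = self.linkage_[:, 2] ** 2 / 2.0
        k = min(self.k, n_samples)
        self.labels_ = fcluster(self.linkage_, t=k, criterion="maxclust")

        # directed concordance score on z-scores of the *raw* feature values
        z = self._zscore(X)
        n_up = int((directions > 0).sum())
        n_down = int((directions < 0).sum())
        up_part = z[:, directions > 0].mean(axis=1) if n_up else 0.0
        down_part = z[:, directions < 0].mean(axis=1) if n_down else 0.0
        self.sample_scores_ = up_part - down_part
        self.cluster_scores_ = {
            int(c): float(self.sample_scores_[self.labels_ == c].mean())
            for c in np.unique(self.labels_)
        }
        best = max(self.cluster_scores_, key=self.cluster_scores_.get)
        self.cl_cluster_ = (
            best if self.cluster_scores_[best] >= self.threshold else None
        )
        return self

    @staticmethod
    def _zscore(X: np.ndarray) -> np.ndarray:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)  # constant features contribute zero
        return (X - mean) / sd

    def predict_labels(self) -> np.ndarray:
        check_is_fitted(self, "labels_")
        if self.cl_cluster_ is None:
            return np.full(len(self.labels_), OTHER_LABEL, dtype=object)
        return np.where(self.labels_ == self.cl_cluster_, CL_LABEL, OTHER_LABEL)


@dataclass
class ClusterResult:
    """Ward merge tree, cut labels, and the CL-cluster call for one cohort."""

    linkage: np.ndarray
    merge_costs: np.ndarray
    labels: pd.Series
    cluster_scores: dict[int, float]
    cl_cluster: int | None
    k: int

    @property
    def calls(self) -> pd.Series:
        """Per-sample CL/other calls implied by the identified cluster."""
        if self.cl_cluster is None:
            return pd.Series(OTHER_LABEL, index=self.labels.index, name="label")
        return pd.Series(
            np.where(self.labels == self.cl_cluster, CL_LABEL, OTHER_LABEL),
            index=self.labels.index,
            name="label",
        )


def ward_cluster(
    matrix: ExpressionMatrix,
    signature: MarkerSignature,
    k: int = 2,
    threshold: float = DEFAULT_CL_SCORE_THRESHOLD,
    standardize: bool = True,
) -> ClusterResult:
    """Cluster cohort samples on the signature genes and identify a CL cluster."""
    if matrix.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    sub, kept, _ = intersect_genes(matrix, signature.genes)
    directions = np.array(
        [1.0 if signature.direction(g) == "up" else -1.0 for g in kept]
    )
    est = WardSubtypeClusterer(
        k=k, threshold=threshold, standardize=standardize, directions=directions
    ).fit(sub.values.T)
    return ClusterResult(
        linkage=est.linkage_,
        merge_costs=est.merge_costs_,
        labels=pd.Series(est.labels_, index=matrix.samples, name="cluster"),
        cluster_scores=est.cluster_scores_,
        cl_cluster=est.cl_cluster_,
        k=k,
    )


def identify_cl_cluster(
    result: ClusterResult,
    matrix: ExpressionMatrix,
    signature: MarkerSignature,
    threshold: float = DEFAULT_CL_SCORE_THRESHOLD,
) -> tuple[int | None, dict[int, float]]:
    """Re-score an existing clustering and identify the CL cluster.

    Scores are computed from scratch on ``matrix`` (z per gene across all
    cohort samples), so a clustering obtained elsewhere can be audited.
    """
    sub, kept, _ = intersect_genes(matrix, signature.genes)
    X = sub.values.T
    z = WardSubtypeClusterer._zscore(X)
    up = np.array([signature.direction(g) == "up" for g in kept])
    up_part = z[:, up].mean(axis=1) if up.any() else 0.0
    down_part = z[:, ~up].mean(axis=1) if (~up).any() else 0.0
    sample_scores = up_part - down_part
    labels = result.labels.to_numpy()
    scores = {
        int(c): float(sample_scores[labels == c].mean()) for c in np.unique(labels)
    }
    best = max(scores, key=scores.get)
    return (best if scores[best] >= threshold else None), scores
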