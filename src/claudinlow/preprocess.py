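"""Expression preprocessing: log2 transform and quantile normalization.

Normalization is applied per cohort, never across cohorts: each dataset is
analyzed separately and only unit-free summaries (subtype calls, log hazard
ratios) are pooled later.

Quantile normalization forces every sample (column) to share one reference
distribution: the vector of row means of the column-sorted matrix. Ties
within a column receive the mean of the reference values at their tied
ranks, so tied inputs stay tied.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import ExpressionMatrix


def _map_to_reference(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map one 1-D array onto ``reference`` by rank, averaging over ties."""
    n = values.shape[0]
    order = np.argsort(values, kind="stable")
    assigned = np.empty(n, dtype=float)
    assigned[order] = reference
    uniq, inverse, counts = np.unique(values, return_inverse=True, return_counts=True)
    if uniq.shape[0] < n:  # ties: mean of reference values at tied ranks
        sums = np.bincount(inverse, weights=assigned)
        assigned = (sums / counts)[inverse]
    return assigned


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Quantile-normalize each sample's value distribution to a reference.

    Follows the sklearn convention: X is (n_samples, n_features). ``fit``
    learns the reference distribution (the mean of the row-sorted training
    samples); ``transform`` maps each row onto it by rank. Fitting and
    transforming the same matrix reproduces classic within-cohort quantile
    normalization.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        out = np.empty_like(X, dtype=float)
        for i in range(X.shape[0]):
            out[i] = _map_to_reference(X[i], self.reference_)
        return out


def log2_transform(
    matrix: ExpressionMatrix, pseudocount: float = 1.0, already_log: bool = False
) -> ExpressionMatrix:
    """Apply x -> log2(x + pseudocount) to every value.

    Raises on negative input, which usually means the data are already on the
    log scale (pass ``already_log=True`` to skip the transform).
    """
    if already_log:
        return matrix
    values = matrix.values
    if (values < 0).any():
        raise ValueError(
            "negative expression values: data may already be log-transformed "
            "(use already_log=True)"
        )
    data = matrix.data.copy()
    data.loc[:, :] = np.log2(values + pseudocount)
    return ExpressionMatrix(data, cohort=matrix.cohort)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize the samples (columns) of one cohort's matrix.

    A single-sample matrix is returned unchanged.
    """
    if matrix.shape[1] < 2:
        return matrix
    normalizer = QuantileNormalizer()
    normalized = normalizer.fit_transform(matrix.values.T).T
    data = matrix.data.copy()
    data.loc[:, :] = normalized
    return ExpressionMatrix(data, cohort=matrix.cohort)
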