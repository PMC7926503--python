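"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: distances are looped,
the Ward agglomeration recomputes within-cluster sums of squares from the
cluster members at every step, the enrichment running sum is re-derived term
by term, and the Cox partial likelihood is written out directly and maximized
by 1-D numerical search.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar


# -- nearest centroid -------------------------------------------------------


def centroid_assign_brute(X, centroid_cl, centroid_other):
    """Per-sample label and distances by explicit loops."""
    labels, d_cl_all, d_other_all = [], [], []
    for row in X:
        d_cl = math.sqrt(sum((a - b) ** 2 for a, b in zip(row, centroid_cl)))
        d_other = math.sqrt(sum((a - b) ** 2 for a, b in zip(row, centroid_other)))
        labels.append("CL" if d_other - d_cl > 0 else "other")
        d_cl_all.append(d_cl)
        d_other_all.append(d_other)
    return labels, np.array(d_cl_all), np.array(d_other_all)


# -- Ward agglomeration -----------------------------------------------------


def _within_ss(points: np.ndarray) -> float:
    centroid = points.mean(axis=0)
    return float(((points - centroid) ** 2).sum())


def ward_agglomerate_brute(X: np.ndarray, k: int = 2):
    """Greedy Ward agglomeration with merge costs recomputed from scratch.

    At every step the pair of clusters whose union minimizes the increase in
    total within-cluster sum of squares is merged. Returns the sequence of
    merge costs and the partition (set of frozensets of sample indices) at
    ``k`` clusters.
    """
    clusters: list[list[int]] = [[i] for i in range(len(X))]
    costs: list[float] = []
    partition_at_k = None
    while len(clusters) > 1:
        if len(clusters) == k:
            partition_at_k = {frozenset(c) for c in clusters}
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                union = clusters[i] + clusters[j]
                cost = (
                    _within_ss(X[union])
                    - _within_ss(X[clusters[i]])
                    - _within_ss(X[clusters[j]])
                )
                if best is None or cost < best[0]:
                    best = (cost, i, j)
        cost, i, j = best
        costs.append(cost)
        merged = clusters[i] + clusters[j]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
    if partition_at_k is None:  # k >= n
        partition_at_k = {frozenset([i]) for i in range(len(X))}
    return costs, partition_at_k


# -- GSEA running sum -------------------------------------------------------


def enrichment_score_brute(stats: np.ndarray, hits: np.ndarray, weight: float = 1.0):
    """O(N * |S|) re-computation of the running sum and its extremum."""
    n = len(stats)
    n_hits = int(hits.sum())
    denom = sum(abs(stats[i]) ** weight for i in range(n) if hits[i])
    running = []
    for i in range(n):
        value = 0.0
        for j in range(i + 1):
            if hits[j]:
                value += (abs(stats[j]) ** weight / denom) if denom > 0 else 1.0 / n_hits
            else:
                value -= 1.0 / (n - n_hits)
        running.append(value)
    running = np.array(running)
    imax, imin = int(np.argmax(running)), int(np.argmin(running))
    es = running[imax] if running[imax] >= -running[imin] else running[imin]
    return float(es), running


# -- Cox partial likelihood -------------------------------------------------


def cox_partial_loglik(beta: float, times, events, x) -> float:
    """Tie-free Cox partial log-likelihood for one covariate, written out."""
    order = np.argsort(times)
    times, events, x = np.asarray(times)[order], np.asarray(events)[order], np.asarray(x)[order]
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            risk = [j for j in range(len(times)) if times[j] >= times[i]]
            ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


def cox_mle_brute(times, events, x) -> float:
    """Maximize the hand-written partial likelihood by bounded 1-D search."""
    res = minimize_scalar(
        lambda b: -cox_partial_loglik(b, times, events, x),
        bounds=(-8.0, 8.0),
        method="bounded",
        options={"xatol": 1e-7},
    )
    return float(res.x)
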