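"""Preranked gene-set enrichment on a moderated-t ranking.

The enrichment score (ES) of a set S in a ranked list of N genes is the
extremum of a weighted Kolmogorov-Smirnov running sum: walking down the
ranking, members of S increment the sum by ``|r_i|^p / sum_{hits} |r|^p``
(weight p = 1 by default) and non-members decrement it by ``1 / (N - |S|)``.
ES is the running-sum value of largest magnitude (ties go positive); the
leading edge is the members at or before (positive ES) / at or after
(negative ES) the extremum.

Significance uses a gene-label permutation null per set size: random sets of
the same size drawn from the ranked genes. NES divides ES by the mean
magnitude of same-sign null scores; the nominal p is the fraction of
same-sign null scores at least as extreme (with the +1 small-sample
correction); FDR q follows the sign-stratified pooled-NES procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import canonicalize_symbol


def rank_genes(results: pd.DataFrame, stat: str = "t") -> pd.Series:
    """Order genes by decreasing statistic; ties broken by gene symbol.

    ``results`` is a per-gene DataFrame (e.g. from :func:`moderated_t`)
    indexed by gene. Returns the ranking statistic as a Series in ranked
    order — the RankedList consumed by the enrichment functions.
    """
    if results.index.duplicated().any():
        raise ValueError("ranked list requires unique gene symbols")
    frame = results[[stat]].copy()
    frame["_gene"] = frame.index
    frame = frame.sort_values([stat, "_gene"], ascending=[False, True], kind="stable")
    return frame[stat].copy()


@dataclass
class EnrichmentScore:
    es: float
    running_sum: np.ndarray
    leading_edge: list[str]


def _running_sum(r: np.ndarray, hits: np.ndarray, weight: float) -> np.ndarray:
    n = r.shape[0]
    n_hits = int(hits.sum())
    w = np.where(hits, np.abs(r) ** weight, 0.0)
    total = w.sum()
    if total > 0:
        inc = w / total
    else:  # all hit statistics are zero: fall back to unweighted hits
        inc = hits / n_hits
    miss = 0.0 if n == n_hits else 1.0 / (n - n_hits)
    return np.cumsum(inc - np.where(hits, 0.0, miss))


def enrichment_score(
    ranked: pd.Series, gene_set: Iterable[str], weight: float = 1.0
) -> EnrichmentScore:
    """ES, full running sum and leading edge for one gene set."""
    members = {canonicalize_symbol(g) for g in gene_set}
    genes = np.array([canonicalize_symbol(g) for g in ranked.index])
    hits = np.isin(genes, list(members))
    if not hits.any():
        raise ValueError("gene set has no overlap with the ranked list")
    running = _running_sum(ranked.to_numpy(dtype=float), hits, weight)
    imax, imin = int(np.argmax(running)), int(np.argmin(running))
    if running[imax] >= -running[imin]:
        es = float(running[imax])
        leading = [g for g, h in zip(genes[: imax + 1], hits[: imax + 1]) if h]
    else:
        es = float(running[imin])
        leading = [g for g, h in zip(genes[imin:], hits[imin:]) if h]
    return EnrichmentScore(es=es, running_sum=running, leading_edge=leading)


def _batch_es(weights_by_rank: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """ES for many hit-position sets at once (positions sorted per row).

    Between hits the running sum decreases linearly, so its global maximum is
    attained immediately after a hit (or is 0) and its global minimum
    immediately before a hit (or 0); only those 2m candidate values are
    evaluated.
    """
    n = weights_by_rank.shape[0]
    m = positions.shape[1]
    w = weights_by_rank[positions]
    totals = w.sum(axis=1, keepdims=True)
    zero = (totals == 0).ravel()
    if zero.any():  # all-zero hit weights: unweighted hit increments
        w[zero] = 1.0
        totals = w.sum(axis=1, keepdims=True)
    cw = np.cumsum(w, axis=1) / totals
    step = 0.0 if n == m else 1.0 / (n - m)
    i = np.arange(1, m + 1)
    after = cw - (positions + 1 - i) * step
    before = np.concatenate(
        [np.zeros((positions.shape[0], 1)), cw[:, :-1]], axis=1
    ) - (positions - (i - 1)) * step
    mx = np.maximum(after.max(axis=1), 0.0)
    mn = np.minimum(before.min(axis=1), 0.0)
    return np.where(mx >= -mn, mx, mn)


def _observed_es(weights_by_rank: np.ndarray, hits: np.ndarray) -> float:
    positions = np.where(hits)[0][None, :]
    return float(_batch_es(weights_by_rank, positions)[0])


def _null_es(
    weights_by_rank: np.ndarray, size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    n = weights_by_rank.shape[0]
    keys = rng.random((n_perm, n))
    positions = np.argpartition(keys, size - 1, axis=1)[:, :size]
    positions.sort(axis=1)
    return _batch_es(weights_by_rank, positions)


def permutation_significance(
    ranked: pd.Series,
    gene_sets: Mapping[str, Iterable[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 1,
) -> pd.DataFrame:
    """Permutation-based NES, nominal p and FDR q for a gene-set collection.

    Sets with no overlap with the ranked list are skipped. Fully
    deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    genes = np.array([canonicalize_symbol(g) for g in ranked.index])
    r = ranked.to_numpy(dtype=float)
    weights_by_rank = np.abs(r) ** weight

    records: list[dict] = []
    null_nes_all: list[np.ndarray] = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in gene_sets.items():
        member_set = {canonicalize_symbol(g) for g in members}
        hits = np.isin(genes, list(member_set))
        size = int(hits.sum())
        if size < min_size:
            continue
        es = _observed_es(weights_by_rank, hits)
        if size not in null_cache:
            null_cache[size] = _null_es(weights_by_rank, size, n_perm, rng)
        null = null_cache[size]
        pos_null = null[null > 0]
        neg_null = null[null < 0]
        if es >= 0:
            same = pos_null
            denom = pos_null.mean() if pos_null.size else np.nan
        else:
            same = -neg_null
            denom = np.abs(neg_null).mean() if neg_null.size else np.nan
        nes = es / denom if np.isfinite(denom) and denom > 0 else 0.0
        p = (1.0 + float((same >= abs(es)).sum())) / (1.0 + same.size)
        with np.errstate(invalid="ignore", divide="ignore"):
            null_nes = np.where(
                null >= 0,
                null / (pos_null.mean() if pos_null.size else np.nan),
                null / (np.abs(neg_null).mean() if neg_null.size else np.nan),
            )
        null_nes_all.append(null_nes[np.isfinite(null_nes)])
        score = enrichment_score(ranked, member_set, weight=weight)
        records.append(
            {
                "name": name,
                "size": size,
                "es": es,
                "nes": float(nes),
                "p": float(p),
                "leading_edge": ",".join(score.leading_edge),
            }
        )

    if not records:
        return pd.DataFrame(
            columns=["name", "size", "es", "nes", "p", "q", "leading_edge"]
        )
    table = pd.DataFrame(records)
    pooled = np.concatenate(null_nes_all) if null_nes_all else np.array([])
    table["q"] = _sign_stratified_fdr(table["nes"].to_numpy(), pooled)
    return table[["name", "size", "es", "nes", "p", "q", "leading_edge"]]


def _sign_stratified_fdr(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """FDR q per observed NES from the pooled permutation NES distribution."""
    q = np.ones_like(obs_nes, dtype=float)
    null_pos = null_nes[null_nes >= 0]
    null_neg = null_nes[null_nes < 0]
    obs_pos = obs_nes[obs_nes >= 0]
    obs_neg = obs_nes[obs_nes < 0]
    for i, nes in enumerate(obs_nes):
        if nes >= 0:
            num = (null_pos >= nes).mean() if null_pos.size else 1.0
            den = (obs_pos >= nes).mean() if obs_pos.size else 1.0
        else:
            num = (null_neg <= nes).mean() if null_neg.size else 1.0
            den = (obs_neg <= nes).mean() if obs_neg.size else 1.0
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    return q
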