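"""Two-group differential expression with empirical-Bayes moderated t-statistics.

Per gene g with groups of sizes n1 (CL) and n2 (other):

* ``log2fc = mean(CL) - mean(other)`` (data already on the log2 scale);
* pooled residual variance ``s_g^2`` with ``d_g = n1 + n2 - 2`` df;
* the prior ``s_g^2 ~ s_0^2 * d_0 / chi^2_{d_0}`` is fitted across genes by
  method of moments on ``log s_g^2`` (digamma/trigamma matching, monotone
  root-finding for d_0);
* posterior variance ``s~_g^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g)``;
* moderated ``t~_g = log2fc / (s~_g * sqrt(1/n1 + 1/n2))`` with
  ``d_0 + d_g`` degrees of freedom, two-sided p, and BH-FDR q-values.

``d_0 = 0`` reproduces the ordinary pooled two-sample t exactly;
``d_0 = inf`` means full shrinkage to the common prior variance.

Two published DEG filters are exposed as named modes: ``"methods"``
(|log2FC| > 2 and raw p < 0.01) and ``"results"`` (q <= 0.01 and linear fold
change > 2 or < 0.5, i.e. |log2FC| > 1); ``"results"`` is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array
from statsmodels.stats.multitest import multipletests

from .io import CL_LABEL, ExpressionMatrix

_D0_MAX = 1e7  # treat larger prior df as infinite shrinkage


@dataclass
class EBPrior:
    """Empirical-Bayes prior on gene variances: d_0 df and scale s_0^2."""

    df_prior: float  # d_0 > 0; inf allowed (full shrinkage); 0 = no shrinkage
    var_prior: float  # s_0^2 > 0

    def __post_init__(self) -> None:
        if self.df_prior < 0:
            raise ValueError("df_prior must be >= 0")
        if self.var_prior <= 0:
            raise ValueError("var_prior must be > 0")


def fit_eb_prior(s2: np.ndarray, df: float | np.ndarray) -> EBPrior:
    """Fit (d_0, s_0^2) from per-gene sample variances by moment matching.

    On the scaled-F model, ``e_g = log s_g^2 - psi(d_g/2) + log(d_g/2)`` has
    mean ``log s_0^2 + psi(d_0/2) - log(d_0/2)`` and excess variance
    ``psi'(d_0/2)`` beyond ``psi'(d_g/2)``; d_0 is recovered by monotone
    root-finding on the trigamma equation. If the empirical variance does not
    exceed the d_0 = inf expectation, d_0 = inf is returned.
    """
    s2 = np.asarray(s2, dtype=float)
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if (s2 == 0).all():
        raise ValueError("all gene variances are zero: degenerate data")
    ok = (s2 > 0) & (df_arr >= 1)
    s2, df_arr = s2[ok], df_arr[ok]
    if s2.size < 2:
        raise ValueError("need at least 2 genes with positive variance and df >= 1")
    if np.all(s2 == s2[0]):
        # dispersion-free limit: the prior is a point mass at the common value
        return EBPrior(np.inf, float(s2[0]))
    e = np.log(s2) - special.digamma(df_arr / 2.0) + np.log(df_arr / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df_arr / 2.0).mean()
    if e_var <= special.polygamma(1, _D0_MAX / 2.0):
        return EBPrior(np.inf, float(np.exp(e_mean)))
    half_d0 = brentq(lambda x: special.polygamma(1, x) - e_var, 1e-8, _D0_MAX / 2.0)
    d0 = 2.0 * half_d0
    s0_sq = np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0))
    return EBPrior(float(d0), float(s0_sq))


class ModeratedTTest(BaseEstimator):
    """Empirical-Bayes moderated two-sample t-test, sklearn estimator style.

    X is (n_samples, n_features); y holds two group labels. The contrast is
    ``positive_label - other`` (default positive label ``"CL"``). Pass
    ``prior`` to override the fitted hyperparameters (e.g. ``EBPrior(0, 1)``
    for the ordinary pooled t).

    Fitted attributes: ``prior_`` and ``results_`` (one row per feature:
    log2fc, s, s_post, t, df_total, p, q, pass_methods, pass_results).
    """

    def __init__(self, positive_label: str = CL_LABEL, prior: EBPrior | None = None):
        self.positive_label = positive_label
        self.prior = prior

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 groups, got {list(classes)}")
        if self.positive_label in classes:
            pos = self.positive_label
        else:
            pos = classes[0]
        mask = y == pos
        n1, n2 = int(mask.sum()), int((~mask).sum())
        if n1 < 2 or n2 < 2:
            raise ValueError(f"each group needs >= 2 samples (got {n1} and {n2})")

        x1, x2 = X[mask], X[~mask]
        log2fc = x1.mean(axis=0) - x2.mean(axis=0)
        d_g = n1 + n2 - 2
        s2 = ((n1 - 1) * x1.var(axis=0, ddof=1) + (n2 - 1) * x2.var(axis=0, ddof=1)) / d_g

        prior = self.prior if self.prior is not None else fit_eb_prior(s2, d_g)
        d0 = prior.df_prior
        if np.isinf(d0):
            s2_post = np.full_like(s2, prior.var_prior)
            df_total = np.inf
        elif d0 == 0:
            s2_post = s2
            df_total = float(d_g)
        else:
            s2_post = (d0 * prior.var_prior + d_g * s2) / (d0 + d_g)
            df_total = float(d0 + d_g)

        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t = np.where(np.isnan(t), 0.0, t)  # 0/0: no change, no evidence
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        q = bh_fdr(p)

        results = pd.DataFrame(
            {
                "log2fc": log2fc,
                "s": np.sqrt(s2),
                "s_post": np.sqrt(s2_post),
                "t": t,
                "df_total": df_total,
                "p": p,
                "q": q,
            }
        )
        results["pass_methods"] = (np.abs(results["log2fc"]) > 2) & (results["p"] < 0.01)
        results["pass_results"] = (results["q"] <= 0.01) & (np.abs(results["log2fc"]) > 1)
        self.prior_ = prior
        self.results_ = results
        self.group_sizes_ = (n1, n2)
        return self


def moderated_t(
    matrix: ExpressionMatrix,
    groups: pd.Series,
    prior: EBPrior | None = None,
    positive_label: str = CL_LABEL,
) -> pd.DataFrame:
    """Moderated-t differential expression between two sample groups.

    ``groups`` maps sample id to one of two labels; the contrast is
    ``positive_label - other``. Returns one row per gene.
    """
    groups = groups.reindex(matrix.samples)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    est = ModeratedTTest(positive_label=positive_label, prior=prior).fit(
        matrix.values.T, groups.to_numpy()
    )
    results = est.results_.copy()
    results.index = pd.Index(matrix.genes, name="gene")
    return results


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_degs(results: pd.DataFrame, mode: str = "results") -> pd.DataFrame:
    """Apply one of the two published DEG filters and annotate direction.

    ``"methods"``: |log2FC| > 2 and raw p < 0.01.
    ``"results"``: q <= 0.01 and linear fold change > 2 or < 0.5.
    """
    if mode not in ("methods", "results"):
        raise ValueError(f"mode must be 'methods' or 'results', got {mode!r}")
    if results.empty:
        out = results.copy()
        out["direction"] = pd.Series(dtype=object)
        return out
    keep = results["pass_methods"] if mode == "methods" else results["pass_results"]
    out = results.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out
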