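"""Per-cohort Cox proportional-hazards fits and meta-analytic pooling.

Each cohort contributes one Cox fit of overall survival on the binary
claudin-low indicator (Newton-Raphson partial-likelihood maximization with
Efron tie handling, via lifelines); the per-cohort log hazard ratios are then
pooled by inverse-variance weighting, both fixed-effect and
DerSimonian-Laird random-effects, with Cochran Q, I^2 and tau^2 reported.
Cohorts whose fit is unidentifiable (no events in a group, separation) are
flagged and excluded from pooling rather than silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .io import CL_LABEL

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class CoxFit:
    """One cohort's Cox fit of the CL-vs-other contrast."""

    cohort: str
    beta: float = np.nan  # log hazard ratio, CL vs other
    se: float = np.nan
    n: int = 0
    n_events: int = 0
    n_cl: int = 0
    valid: bool = False
    message: str = ""

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta - Z_95 * self.se)),
            float(np.exp(self.beta + Z_95 * self.se)),
        )


def cox_fit(clinical: pd.DataFrame, calls: pd.Series, cohort: str | None = None) -> CoxFit:
    """Fit a univariate Cox model of survival on the CL indicator.

    ``clinical`` needs columns sample_id, time, event; ``calls`` maps sample
    id to 'CL'/'other'. Returns a flagged (``valid=False``) fit when the
    contrast is unidentifiable instead of raising.
    """
    cohort = cohort or (
        str(clinical["cohort"].iloc[0]) if "cohort" in clinical else "cohort"
    )
    df = clinical.set_index("sample_id")[["time", "event"]].copy()
    df["cl"] = (calls.reindex(df.index) == CL_LABEL).astype(float)
    if calls.reindex(df.index).isna().any():
        raise ValueError("every clinical sample needs a subtype call")
    fit = CoxFit(
        cohort=cohort,
        n=len(df),
        n_events=int(df["event"].sum()),
        n_cl=int(df["cl"].sum()),
    )
    events_cl = int(df.loc[df["cl"] == 1, "event"].sum())
    events_other = int(df.loc[df["cl"] == 0, "event"].sum())
    if fit.n_cl == 0 or fit.n_cl == fit.n:
        fit.message = "only one subtype present"
        return fit
    if events_cl == 0 or events_other == 0:
        fit.message = "no observed events in one group (monotone likelihood)"
        return fit
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(
                df,
                duration_col="time",
                event_col="event",
                fit_options={"precision": 1e-09, "max_steps": 500},
            )
        fit.beta = float(cph.params_["cl"])
        fit.se = float(cph.standard_errors_["cl"])
        if not np.isfinite(fit.beta) or not np.isfinite(fit.se) or fit.se <= 0:
            fit.message = "non-finite estimate (likely separation)"
            return fit
        fit.valid = True
    except (ConvergenceError, ValueError) as exc:
        fit.message = f"convergence failure: {exc}"
    return fit


@dataclass
class MetaResult:
    """Pooled log hazard ratio with heterogeneity statistics."""

    k: int
    beta_fixed: float
    se_fixed: float
    beta_random: float
    se_random: float
    tau2: float
    q_stat: float
    i2: float  # percent, in [0, 100]
    weights_fixed: pd.Series = field(default_factory=pd.Series)  # normalized
    model: str = "random"

    def _pair(self, which: str) -> tuple[float, float]:
        return (
            (self.beta_fixed, self.se_fixed)
            if which == "fixed"
            else (self.beta_random, self.se_random)
        )

    def hr(self, which: str | None = None) -> float:
        beta, _ = self._pair(which or self.model)
        return float(np.exp(beta))

    def ci(self, which: str | None = None) -> tuple[float, float]:
        beta, se = self._pair(which or self.model)
        return float(np.exp(beta - Z_95 * se)), float(np.exp(beta + Z_95 * se))


def meta_pool(fits: list[CoxFit], model: str = "random") -> MetaResult:
    """Inverse-variance pooling of per-cohort log hazard ratios.

    Computes the fixed-effect estimate, Cochran Q, I^2, the DerSimonian-Laird
    tau^2 and the random-effects estimate; ``model`` only selects which pair
    the result reports as headline. Invalid fits are excluded.
    """
    if model not in ("fixed", "random"):
        raise ValueError("model must be 'fixed' or 'random'")
    valid = [f for f in fits if f.valid]
    excluded = [f for f in fits if not f.valid]
    if excluded:
        warnings.warn(
            "excluded from pooling: "
            + "; ".join(f"{f.cohort} ({f.message})" for f in excluded)
        )
    k = len(valid)
    if k == 0:
        raise ValueError("no valid Cox fits to pool")
    beta = np.array([f.beta for f in valid])
    var = np.array([f.se**2 for f in valid])
    w = 1.0 / var
    beta_fixed = float((w * beta).sum() / w.sum())
    se_fixed = float(w.sum() ** -0.5)
    q_stat = float((w * (beta - beta_fixed) ** 2).sum())
    if k > 1 and q_stat > 0:
        i2 = max(0.0, (q_stat - (k - 1)) / q_stat) * 100.0
        tau2 = max(0.0, (q_stat - (k - 1)) / (w.sum() - (w**2).sum() / w.sum()))
    else:
        i2, tau2 = 0.0, 0.0
    wr = 1.0 / (var + tau2)
    beta_random = float((wr * beta).sum() / wr.sum())
    se_random = float(wr.sum() ** -0.5)
    return MetaResult(
        k=k,
        beta_fixed=beta_fixed,
        se_fixed=se_fixed,
        beta_random=beta_random,
        se_random=se_random,
        tau2=float(tau2),
        q_stat=q_stat,
        i2=float(i2),
        weights_fixed=pd.Series(w / w.sum(), index=[f.cohort for f in valid]),
        model=model,
    )


def forest_table(meta: MetaResult, fits: list[CoxFit]) -> pd.DataFrame:
    """One row per study (HR, CI, normalized fixed weight) plus pooled rows."""
    rows = []
    for f in fits:
        lo, hi = f.ci if f.valid else (np.nan, np.nan)
        rows.append(
            {
                "study": f.cohort,
                "hr": f.hr if f.valid else np.nan,
                "ci_low": lo,
                "ci_high": hi,
                "weight_fixed": float(meta.weights_fixed.get(f.cohort, 0.0)),
                "n": f.n,
                "n_events": f.n_events,
                "n_cl": f.n_cl,
                "note": f.message,
            }
        )
    for which in ("fixed", "random"):
        lo, hi = meta.ci(which)
        rows.append(
            {
                "study": f"pooled ({which})",
                "hr": meta.hr(which),
                "ci_low": lo,
                "ci_high": hi,
                "weight_fixed": 1.0 if which == "fixed" else np.nan,
                "n": sum(f.n for f in fits if f.valid),
                "n_events": sum(f.n_events for f in fits if f.valid),
                "n_cl": sum(f.n_cl for f in fits if f.valid),
                "note": "",
            }
        )
    return pd.DataFrame(rows)


def forest_plot(table: pd.DataFrame, path: str) -> None:
    """Minimal forest plot (log HR scale) saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plotted = table.dropna(subset=["hr"])
    y = np.arange(len(plotted))[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(plotted) + 1.5))
    ax.errorbar(
        plotted["hr"],
        y,
        xerr=[plotted["hr"] - plotted["ci_low"], plotted["ci_high"] - plotted["hr"]],
        fmt="s",
        color="black",
        capsize=3,
    )
    ax.axvline(1.0, color="grey", linestyle="--", linewidth=1)
    ax.set_xscale("log")
    ax.set_yticks(y)
    ax.set_yticklabels(plotted["study"])
    ax.set_xlabel("hazard ratio (CL vs other)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
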