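"""Survival analysis layer: KM/log-rank on expression splits, PC1 metagene,
and martingale-residual regression trees.

Overall survival is measured in months from surgery; subjects alive past the
five-year horizon are administratively censored at 60 months.  Expression is
dichotomized at the median (ties to the low group) or cut at tertiles.  The
metagene is the first principal component of z-scored probe expression, sign
fixed so the loading sum is positive, dichotomized at its median.  Survival
trees regress martingale residuals of a null (covariate-free) Cox model on
marker expression: each binary split maximizes the reduction in residual sum
of squares, reported with a one-degree-of-freedom chi-square approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "KMCurve",
    "MetageneModel",
    "CARTNode",
    "censor_at_horizon",
    "km_estimate",
    "survival_at",
    "logrank_test",
    "split_by_median",
    "split_by_tertiles",
    "metagene_pc1",
    "null_cox_martingale_residuals",
    "cart_fit",
    "two_marker_subgroups",
]

HORIZON_MONTHS = 60.0


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if t.size == 0:
        raise ValueError("need at least one record")
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return t, e


def censor_at_horizon(
    times: Sequence[float], events: Sequence[bool], horizon: float = HORIZON_MONTHS
) -> tuple[np.ndarray, np.ndarray]:
    """Administrative censoring: times beyond the horizon truncate to it with
    the event flag cleared; all other records are unchanged."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    t, e = _as_arrays(times, events)
    over = t > horizon
    t = np.where(over, horizon, t)
    e = e & ~over
    return t, e


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate on the observed time grid."""

    times: np.ndarray  # sorted unique observed times, starting at 0
    survival: np.ndarray  # S(t) at those times; S(0) = 1
    at_risk: np.ndarray  # number at risk just before each time


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan-Meier product-limit estimator (censoring at an event time is
    processed after the events at that time)."""
    t, e = _as_arrays(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return KMCurve(times=grid, survival=surv, at_risk=at_risk)


def survival_at(curve: KMCurve, t: float) -> float:
    """Step-function lookup S(t) on a KM curve."""
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


def logrank_test(
    times: Sequence[float], events: Sequence[bool], groups: Sequence
) -> tuple[float, float]:
    """k-sample log-rank test; returns (chi-square statistic, p-value)."""
    t, e = _as_arrays(times, events)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise ValueError("groups must align with times")
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if not e.any():
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def split_by_median(values: Sequence[float]) -> np.ndarray:
    """Dichotomize at the median: value > median -> ``high``, else ``low``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    if np.ptp(x) == 0:
        raise ValueError("all values identical: median split is degenerate")
    med = np.median(x)
    return np.where(x > med, "high", "low")


def split_by_tertiles(values: Sequence[float]) -> np.ndarray:
    """Cut at the 1/3 and 2/3 empirical quantiles into low/mid/high."""
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least three distinct values")
    q1, q2 = np.quantile(x, [1.0 / 3.0, 2.0 / 3.0])
    if q1 == q2:
        raise ValueError("degenerate tertile cutpoints (q1 == q2)")
    out = np.full(x.shape, "high", dtype=object)
    out[x <= q2] = "mid"
    out[x <= q1] = "low"
    return out.astype(str)


@dataclass
class MetageneModel:
    """First-principal-component summary of a probe panel."""

    probe_ids: list[str]
    means: np.ndarray
    sds: np.ndarray
    loading: np.ndarray  # unit-norm PC1 loading, sum > 0 by convention
    sign_flipped: bool
    median_cutpoint: float

    def transform(self, expression: pd.DataFrame) -> pd.Series:
        """Score new probe x sample expression with the fitted loadings."""
        x = expression.loc[self.probe_ids].to_numpy(dtype=float)
        z = (x - self.means[:, None]) / self.sds[:, None]
        return pd.Series(z.T @ self.loading, index=expression.columns, name="metagene")


def metagene_pc1(expression: pd.DataFrame) -> tuple[MetageneModel, pd.Series]:
    """Fit the PC1 metagene on a probe x sample expression sub-matrix.

    Probes are z-scored, PC1 is the leading right-singular vector of the
    sample x probe matrix, and the sign is fixed so the loading sum is
    positive (first nonzero loading positive if the sum is exactly zero), so
    the high/low dichotomization is reproducible regardless of solver sign.
    """
    if expression.shape[0] < 2 or expression.shape[1] < 3:
        raise ValueError("need >= 2 probes and >= 3 samples")
    x = expression.to_numpy(dtype=float)
    means = x.mean(axis=1)
    sds = x.std(axis=1, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise ValueError(f"zero-variance probe: {expression.index[zero[0]]!r}")
    z = ((x - means[:, None]) / sds[:, None]).T  # samples x probes
    _, _, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    loading = vt[0]
    s = loading.sum()
    flipped = s < 0 or (s == 0 and loading[np.flatnonzero(loading)[0]] < 0)
    if flipped:
        loading = -loading
    scores = pd.Series(z @ loading, index=expression.columns, name="metagene")
    model = MetageneModel(
        probe_ids=list(expression.index),
        means=means,
        sds=sds,
        loading=loading,
        sign_flipped=bool(flipped),
        median_cutpoint=float(scores.median()),
    )
    return model, scores


def null_cox_martingale_residuals(
    times: Sequence[float], events: Sequence[bool]
) -> np.ndarray:
    """Martingale residuals of the covariate-free Cox model.

    residual_i = event_i - H(t_i), with H the Nelson-Aalen cumulative hazard
    (ties aggregated, censorings at an event time at risk for that event).
    The residuals sum to zero exactly.
    """
    t, e = _as_arrays(times, events)
    if not e.any():
        raise ValueError("need at least one event")
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    uniq = np.unique(ts[es])
    n = t.size
    cumhaz_steps = []
    for u in uniq:
        d = np.count_nonzero(es & (ts == u))
        at_risk = np.count_nonzero(ts >= u)
        cumhaz_steps.append(d / at_risk)
    cum = np.cumsum(cumhaz_steps)
    # H(t_i): cumulative hazard at each subject's own (possibly censored) time
    idx = np.searchsorted(uniq, t, side="right") - 1
    h = np.where(idx >= 0, cum[np.clip(idx, 0, None)], 0.0)
    return e.astype(float) - h


@dataclass
class CARTNode:
    """A node of the martingale-residual survival tree."""

    n: int
    residual_mean: float
    depth: int
    split_var: str | None = None
    cutpoint: float | None = None
    chi_square: float | None = None
    left: "CARTNode | None" = None
    right: "CARTNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None

    def to_dict(self) -> dict:
        d = {"n": self.n, "residual_mean": self.residual_mean, "depth": self.depth}
        if not self.is_leaf:
            d.update(
                split_var=self.split_var,
                cutpoint=self.cutpoint,
                chi_square=self.chi_square,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d


def _best_split(
    resid: np.ndarray, covariates: pd.DataFrame, min_node: int
) -> tuple[str, float, float] | None:
    """Exhaustive search over covariate midpoints for the split with maximal
    reduction in residual sum of squares.  Ties keep the first covariate in
    column order and then the smallest cutpoint."""
    n = resid.size
    sse_parent = float(np.sum((resid - resid.mean()) ** 2))
    best = None
    for var in covariates.columns:
        x = covariates[var].to_numpy(dtype=float)
        u = np.unique(x)
        if u.size < 2:
            continue
        mids = (u[:-1] + u[1:]) / 2.0
        for cut in mids:
            left = x <= cut
            nl = int(left.sum())
            if nl < min_node or n - nl < min_node:
                continue
            rl, rr = resid[left], resid[~left]
            sse = float(np.sum((rl - rl.mean()) ** 2) + np.sum((rr - rr.mean()) ** 2))
            gain = sse_parent - sse
            if best is None or gain > best[0] + 1e-12:
                best = (gain, var, float(cut), sse_parent)
    if best is None:
        return None
    gain, var, cut, sse_parent = best
    if sse_parent <= 0 or gain <= 0:
        return None
    chi2 = gain / (sse_parent / (n - 1))
    return var, cut, chi2


def cart_fit(
    times: Sequence[float],
    events: Sequence[bool],
    covariates: pd.DataFrame,
    min_node: int = 20,
    max_depth: int = 2,
) -> CARTNode:
    """Fit a survival tree on martingale residuals of the null Cox model.

    Residuals are computed once on the full cohort; recursive binary splits
    on covariate midpoints maximize the reduction in residual sum of squares.
    Each chosen split carries chi_square = SSE reduction / (parent SSE /
    (n - 1)), a one-df chi-square approximation to the split's significance.
    Splitting stops at ``max_depth``, when a child would fall below
    ``min_node``, or when no split reduces the SSE.
    """
    t, e = _as_arrays(times, events)
    if len(covariates) != t.size:
        raise ValueError("covariates must align with times")
    if not np.all(np.isfinite(covariates.to_numpy(dtype=float))):
        raise ValueError("covariates must be finite numeric")
    resid = null_cox_martingale_residuals(t, e)
    cov = covariates.reset_index(drop=True)

    def build(mask: np.ndarray, depth: int) -> CARTNode:
        r = resid[mask]
        node = CARTNode(n=int(mask.sum()), residual_mean=float(r.mean()), depth=depth)
        if depth >= max_depth or node.n < 2 * min_node:
            return node
        found = _best_split(r, cov.loc[mask].reset_index(drop=True), min_node)
        if found is None:
            return node
        var, cut, chi2 = found
        node.split_var, node.cutpoint, node.chi_square = var, cut, chi2
        x = cov[var].to_numpy(dtype=float)
        node.left = build(mask & (x <= cut), depth + 1)
        node.right = build(mask & (x > cut), depth + 1)
        return node

    return build(np.ones(t.size, dtype=bool), 0)


def two_marker_subgroups(
    times: Sequence[float],
    events: Sequence[bool],
    marker_a_values: Sequence[float],
    marker_b_values: Sequence[float],
    cut_a: float,
    cut_b: float,
) -> tuple[np.ndarray, float, float]:
    """2x2 subgroups from two marker cutpoints, with a log-rank test across
    the nonempty groups.  Labels are ``{low,high}_{low,high}`` for marker A
    then marker B; values at or below a cut go low.  Returns (labels,
    chi-square, p)."""
    t, e = _as_arrays(times, events)
    a = np.asarray(marker_a_values, dtype=float)
    b = np.asarray(marker_b_values, dtype=float)
    if a.shape != t.shape or b.shape != t.shape:
        raise ValueError("marker values must align with times")
    labels = np.array(
        [
            f"{'high' if ai > cut_a else 'low'}_{'high' if bi > cut_b else 'low'}"
            for ai, bi in zip(a, b)
        ]
    )
    if len(np.unique(labels)) < 2:
        raise ValueError("fewer than two nonempty subgroups: cutpoints degenerate")
    stat, p = logrank_test(t, e, labels)
    return labels, stat, p
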