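"""Tumor-vs-normal elevation screen, filter battery and MarkerScore ranking.

The screen asks, probe by probe, whether a subpopulation of lung tumors
expresses the transcript well above the normal-lung distribution.  For each
probe the normal group defines an elevation cutoff ``avg_normal + 3*sd_normal``;
samples strictly above it count as elevated.  A probe passes the screen when
all five criteria hold:

* ``avg_tumor_elevated`` (mean of elevated tumor samples) > 5 log2 units,
* ``% elevated_tumor`` > 25%,
* ``log2_ratio_elevated`` = ``avg_tumor_elevated - avg_normal`` >= 2 (4-fold),
* Welch t-test and Mann-Whitney U-test p-values both below the Bonferroni
  threshold ``alpha / N`` with N the number of probes screened,
* Hellinger distance between Gaussian fits of the two groups > 1/3.

Passing probes are ranked in decreasing order of the MarkerScore

    (% elevated_tumor - % elevated_normal) * log2_ratio_elevated,

with percentages on the 0-100 scale.  Cross-tissue comparisons (Dunnett's
control-vs-groups and Tukey's all-pairs) support the tissue-panel reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .compendium import LUNG_NORMAL, LUNG_TUMOR, ExpressionCompendium

__all__ = [
    "GroupSummary",
    "ElevationStats",
    "FilterCriteria",
    "FilterResult",
    "ProbeScreenRecord",
    "group_summary",
    "elevation_cutoff",
    "elevation_stats",
    "two_sided_t_test",
    "mann_whitney_u",
    "hellinger_gaussian",
    "bonferroni_threshold",
    "marker_score",
    "apply_filters",
    "screen",
    "dunnett_control_comparisons",
    "tukey_pairwise",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean and standard deviation of log2 intensities."""

    group: str
    n: int
    avg: float
    sd: float | None  # None when n < 2 (sd undefined)


@dataclass(frozen=True)
class ElevationStats:
    """Elevation summary of one probe relative to the lung-normal cutoff."""

    cutoff: float
    pct_elevated_tumor: float
    pct_elevated_normal: float
    avg_tumor_elevated: float | None
    log2_ratio_elevated: float | None


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the five-criterion filter (defaults as used in the screen)."""

    min_avg_tumor_elevated: float = 5.0
    min_pct_elevated_tumor: float = 25.0
    min_log2_ratio: float = 2.0
    alpha: float = 0.05
    hellinger_min: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        for name in (
            "min_avg_tumor_elevated",
            "min_pct_elevated_tumor",
            "min_log2_ratio",
            "hellinger_min",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class FilterResult:
    pass_avg_elevated: bool
    pass_pct_elevated: bool
    pass_log2_ratio: bool
    pass_t_test: bool
    pass_u_test: bool
    pass_hellinger: bool

    @property
    def overall(self) -> bool:
        return (
            self.pass_avg_elevated
            and self.pass_pct_elevated
            and self.pass_log2_ratio
            and self.pass_t_test
            and self.pass_u_test
            and self.pass_hellinger
        )


@dataclass
class ProbeScreenRecord:
    """All per-probe statistics computed by the screen."""

    probe_id: str
    gene: str | None
    tumor: GroupSummary
    normal: GroupSummary
    elevation: ElevationStats
    t_p: float
    u_p: float
    hellinger: float | None
    filters: FilterResult | None = None
    marker_score: float | None = None


def group_summary(group: str, values: Sequence[float]) -> GroupSummary:
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError(f"group {group!r} is empty")
    sd = float(np.std(x, ddof=1)) if x.size >= 2 else None
    return GroupSummary(group=group, n=int(x.size), avg=float(np.mean(x)), sd=sd)


def elevation_cutoff(avg_normal: float, sd_normal: float) -> float:
    """Elevation cutoff: mean of the normal group plus three standard deviations."""
    if sd_normal is None or not math.isfinite(sd_normal):
        raise ValueError("sd_normal is undefined (need >= 2 normal samples)")
    if sd_normal < 0:
        raise ValueError("sd_normal must be non-negative")
    return avg_normal + 3.0 * sd_normal


def elevation_stats(
    tumor_values: Sequence[float], normal_values: Sequence[float]
) -> ElevationStats:
    """Percent-elevated and elevated-tumor mean relative to the +3 sd cutoff.

    A sample is elevated when its value is strictly above the cutoff; ties at
    the cutoff count as not elevated.  ``avg_tumor_elevated`` (and hence the
    log2 ratio) is undefined when no tumor sample is elevated.
    """
    t = np.asarray(tumor_values, dtype=float)
    n = np.asarray(normal_values, dtype=float)
    if t.size < 1:
        raise ValueError("need at least 1 tumor value")
    if n.size < 2:
        raise ValueError("need at least 2 normal values to define the cutoff")
    avg_n = float(np.mean(n))
    sd_n = float(np.std(n, ddof=1))
    cutoff = elevation_cutoff(avg_n, sd_n)
    elev_t = t[t > cutoff]
    pct_t = 100.0 * elev_t.size / t.size
    pct_n = 100.0 * np.count_nonzero(n > cutoff) / n.size
    if elev_t.size:
        avg_elev = float(np.mean(elev_t))
        ratio = avg_elev - avg_n
    else:
        avg_elev = None
        ratio = None
    return ElevationStats(
        cutoff=cutoff,
        pct_elevated_tumor=pct_t,
        pct_elevated_normal=pct_n,
        avg_tumor_elevated=avg_elev,
        log2_ratio_elevated=ratio,
    )


def two_sided_t_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value.

    When both groups have zero variance and equal means the statistic is
    0/0; p = 1 by convention (no evidence of a difference).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return 1.0 if x[0] == y[0] else 0.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value (normal approximation, tie and
    continuity corrected).  All values tied across both groups gives p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each group needs n >= 1")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def hellinger_gaussian(avg1: float, sd1: float, avg2: float, sd2: float) -> float:
    """Closed-form Hellinger distance between two Gaussians.

    H^2 = 1 - sqrt(2*s1*s2 / (s1^2 + s2^2)) * exp(-(m1 - m2)^2 / (4*(s1^2 + s2^2)))
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    s2 = sd1 * sd1 + sd2 * sd2
    bc = math.sqrt(2.0 * sd1 * sd2 / s2) * math.exp(-((avg1 - avg2) ** 2) / (4.0 * s2))
    return math.sqrt(max(0.0, 1.0 - bc))


def bonferroni_threshold(alpha: float, n_probes: int) -> float:
    """Familywise p-value threshold alpha / N over N screened probes."""
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_probes


def marker_score(
    pct_elevated_tumor: float,
    pct_elevated_normal: float,
    log2_ratio_elevated: float | None,
) -> float | None:
    """Composite ranking score (pct_tumor - pct_normal) * log2 ratio.

    Percentages are on the 0-100 scale.  Undefined (None) when the ratio is
    undefined, which makes the probe unrankable.
    """
    if log2_ratio_elevated is None:
        return None
    return (pct_elevated_tumor - pct_elevated_normal) * log2_ratio_elevated


def apply_filters(
    record: ProbeScreenRecord, criteria: FilterCriteria, n_probes: int
) -> FilterResult:
    """Evaluate the five filter criteria for one probe.

    Strict ``>`` for the elevated mean, percent-elevated and Hellinger
    criteria, strict ``<`` for both p-values against the Bonferroni
    threshold, and ``>=`` for the log2 ratio.  Undefined elevation statistics
    fail the corresponding criteria automatically.
    """
    p_thr = bonferroni_threshold(criteria.alpha, n_probes)
    ele = record.elevation
    return FilterResult(
        pass_avg_elevated=(
            ele.avg_tumor_elevated is not None
            and ele.avg_tumor_elevated > criteria.min_avg_tumor_elevated
        ),
        pass_pct_elevated=ele.pct_elevated_tumor > criteria.min_pct_elevated_tumor,
        pass_log2_ratio=(
            ele.log2_ratio_elevated is not None
            and ele.log2_ratio_elevated >= criteria.min_log2_ratio
        ),
        pass_t_test=record.t_p < p_thr,
        pass_u_test=record.u_p < p_thr,
        pass_hellinger=(
            record.hellinger is not None and record.hellinger > criteria.hellinger_min
        ),
    )


def _screen_probe(
    probe_id: str,
    gene: str | None,
    tumor: np.ndarray,
    normal: np.ndarray,
    criteria: FilterCriteria,
    n_probes: int,
) -> ProbeScreenRecord:
    rec = ProbeScreenRecord(
        probe_id=probe_id,
        gene=gene,
        tumor=group_summary(LUNG_TUMOR, tumor),
        normal=group_summary(LUNG_NORMAL, normal),
        elevation=elevation_stats(tumor, normal),
        t_p=two_sided_t_test(tumor, normal),
        u_p=mann_whitney_u(tumor, normal),
        hellinger=None,
    )
    sd_t, sd_n = rec.tumor.sd, rec.normal.sd
    if sd_t and sd_n and sd_t > 0 and sd_n > 0:
        rec.hellinger = hellinger_gaussian(rec.tumor.avg, sd_t, rec.normal.avg, sd_n)
    rec.filters = apply_filters(rec, criteria, n_probes)
    rec.marker_score = marker_score(
        rec.elevation.pct_elevated_tumor,
        rec.elevation.pct_elevated_normal,
        rec.elevation.log2_ratio_elevated,
    )
    return rec


def screen(
    comp: ExpressionCompendium, criteria: FilterCriteria | None = None
) -> pd.DataFrame:
    """Score, filter and rank every probe of a compendium.

    Returns one row per probe with all statistics, per-criterion pass flags,
    the overall pass flag, the MarkerScore and the rank.  Rows are ordered
    passing probes first, by descending MarkerScore; probes with an undefined
    score sort after all defined scores; ties break on probe id.  Additional
    sample groups (non-lung normal tissues) contribute an ``avg_<group>``
    column each so tissue expression can be inspected, but never enter the
    score.  The Bonferroni denominator is the number of probes screened.
    """
    criteria = criteria or FilterCriteria()
    groups = comp.groups
    for required in (LUNG_TUMOR, LUNG_NORMAL):
        if required not in groups:
            raise ValueError(f"compendium lacks required group {required!r}")
    tumor = comp.group_values(LUNG_TUMOR).to_numpy(dtype=float)
    normal = comp.group_values(LUNG_NORMAL).to_numpy(dtype=float)
    extra = [g for g in groups if g not in (LUNG_TUMOR, LUNG_NORMAL)]
    extra_means = {
        g: comp.group_values(g).to_numpy(dtype=float).mean(axis=1) for g in extra
    }
    n_probes = comp.n_probes

    rows = []
    for i, probe_id in enumerate(comp.probe_ids):
        rec = _screen_probe(
            probe_id, comp.gene_of(probe_id), tumor[i], normal[i], criteria, n_probes
        )
        f = rec.filters
        row = {
            "probe_id": rec.probe_id,
            "gene": rec.gene,
            "n_tumor": rec.tumor.n,
            "avg_tumor": rec.tumor.avg,
            "sd_tumor": rec.tumor.sd,
            "n_normal": rec.normal.n,
            "avg_normal": rec.normal.avg,
            "sd_normal": rec.normal.sd,
            "cutoff": rec.elevation.cutoff,
            "pct_elevated_tumor": rec.elevation.pct_elevated_tumor,
            "pct_elevated_normal": rec.elevation.pct_elevated_normal,
            "avg_tumor_elevated": rec.elevation.avg_tumor_elevated,
            "log2_ratio_elevated": rec.elevation.log2_ratio_elevated,
            "t_p": rec.t_p,
            "u_p": rec.u_p,
            "hellinger": rec.hellinger,
            "marker_score": rec.marker_score,
            "pass_avg_elevated": f.pass_avg_elevated,
            "pass_pct_elevated": f.pass_pct_elevated,
            "pass_log2_ratio": f.pass_log2_ratio,
            "pass_t_test": f.pass_t_test,
            "pass_u_test": f.pass_u_test,
            "pass_hellinger": f.pass_hellinger,
            "pass_overall": f.overall,
        }
        for g in extra:
            row[f"avg_{g}"] = float(extra_means[g][i])
        rows.append(row)

    df = pd.DataFrame(rows)
    score_key = df["marker_score"].astype(float).fillna(-np.inf)
    df = (
        df.assign(_score=score_key)
        .sort_values(
            ["pass_overall", "_score", "probe_id"],
            ascending=[False, False, True],
            kind="stable",
        )
        .drop(columns="_score")
        .reset_index(drop=True)
    )
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def dunnett_control_comparisons(
    control_values: Sequence[float],
    group_values_map: Mapping[str, Sequence[float]],
) -> dict[str, float]:
    """Dunnett-adjusted two-sided p-values for each group versus a control."""
    control = np.asarray(control_values, dtype=float)
    if control.size < 2:
        raise ValueError("control group needs n >= 2")
    if not group_values_map:
        raise ValueError("need at least one comparison group")
    names = list(group_values_map)
    samples = [np.asarray(group_values_map[g], dtype=float) for g in names]
    res = stats.dunnett(*samples, control=control, alternative="two-sided")
    return dict(zip(names, (float(p) for p in res.pvalue)))


def tukey_pairwise(
    group_values_map: Mapping[str, Sequence[float]],
) -> dict[tuple[str, str], float]:
    """Tukey HSD (studentized-range) adjusted p-values for all unordered pairs."""
    if len(group_values_map) < 2:
        raise ValueError("need at least two groups")
    names = list(group_values_map)
    samples = [np.asarray(group_values_map[g], dtype=float) for g in names]
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    res = stats.tukey_hsd(*samples)
    out: dict[tuple[str, str], float] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            out[(names[i], names[j])] = float(res.pvalue[i, j])
    return out
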