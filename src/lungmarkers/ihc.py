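"""Immunohistochemistry score summarization.

Each scored tissue core carries a pathologist intensity grade (0 = negative,
1 = weak, 2 = moderate, 3 = strong) and the percent of tumor cells stained
(independent of intensity; 0 whenever the intensity is 0).  Summaries mirror
the standard marker-characterization table: intensity counts, percent of
cores at or above a grade, a heterogeneity score, and the normalized value
intensity x percent (0-300).

The heterogeneity score is the mean +/- sd of percent-cells over the stained
cores only (intensity >= 1).  A group in which no core stained is reported as
100% +/- 0% — uniformly unstained is still uniform.  The 100% convention is
not mixed into groups that contain stained cores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

INTENSITY_LEVELS = (0, 1, 2, 3)

REQUIRED_COLUMNS = ("sample_id", "tissue_type", "intensity", "percent_cells")


@dataclass(frozen=True)
class IHCRecord:
    """One scored tissue core."""

    sample_id: str
    tissue_type: str
    intensity: int
    percent_cells: float
    histology: str | None = None

    def __post_init__(self) -> None:
        if self.intensity not in INTENSITY_LEVELS:
            raise ValueError(f"intensity must be one of {INTENSITY_LEVELS}, got {self.intensity}")
        if not 0.0 <= self.percent_cells <= 100.0:
            raise ValueError(f"percent_cells must lie in [0, 100], got {self.percent_cells}")
        if self.intensity == 0 and self.percent_cells != 0:
            raise ValueError("percent_cells must be 0 when intensity is 0")


@dataclass(frozen=True)
class IHCGroupSummary:
    """Summary of one tissue group: counts, positivity, heterogeneity."""

    n: int
    counts: tuple[int, int, int, int]  # cores at intensity 0, 1+, 2+, 3+
    pct_at_or_above: dict[int, float]  # threshold -> percent of cores
    heterogeneity_mean: float
    heterogeneity_sd: float | None  # None when < 2 stained cores


def _as_frame(records: Iterable[IHCRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([vars(r) for r in records])
    if df.empty:
        raise ValueError("no IHC records")
    missing = [c for c in ("intensity", "percent_cells") if c not in df.columns]
    if missing:
        raise ValueError(f"IHC table lacks columns: {missing}")
    return df


def validate_ihc(df: pd.DataFrame) -> None:
    df = _as_frame(df)
    if not df["intensity"].isin(INTENSITY_LEVELS).all():
        bad = df.loc[~df["intensity"].isin(INTENSITY_LEVELS), "intensity"].unique()
        raise ValueError(f"invalid intensity values: {bad.tolist()}")
    pct = df["percent_cells"].astype(float)
    if ((pct < 0) | (pct > 100)).any():
        raise ValueError("percent_cells outside [0, 100]")
    if ((df["intensity"] == 0) & (pct != 0)).any():
        raise ValueError("percent_cells must be 0 where intensity is 0")


def score_distribution(records: Iterable[IHCRecord] | pd.DataFrame) -> tuple[int, int, int, int]:
    """Counts of cores at intensity 0, 1+, 2+ and 3+."""
    df = _as_frame(records)
    validate_ihc(df)
    counts = df["intensity"].value_counts()
    return tuple(int(counts.get(k, 0)) for k in INTENSITY_LEVELS)


def percent_at_or_above(
    records: Iterable[IHCRecord] | pd.DataFrame, threshold: int
) -> float:
    """Percent of cores with intensity >= threshold (threshold in {1, 2, 3})."""
    if threshold not in (1, 2, 3):
        raise ValueError("threshold must be 1, 2 or 3")
    df = _as_frame(records)
    return 100.0 * (df["intensity"] >= threshold).sum() / len(df)


def heterogeneity_score(
    records: Iterable[IHCRecord] | pd.DataFrame,
) -> tuple[float, float | None]:
    """Mean and sd of percent-cells over stained cores.

    All-unstained groups return (100.0, 0.0): uniformly unstained.  A group
    with a single stained core has an undefined sd (None).
    """
    df = _as_frame(records)
    stained = df.loc[df["intensity"] >= 1, "percent_cells"].astype(float)
    if stained.empty:
        return 100.0, 0.0
    mean = float(stained.mean())
    sd = float(stained.std(ddof=1)) if len(stained) >= 2 else None
    return mean, sd


def normalized_score(record: IHCRecord | tuple[int, float]) -> float:
    """Normalized IHC value: intensity x percent cells stained (0-300)."""
    if isinstance(record, IHCRecord):
        intensity, pct = record.intensity, record.percent_cells
    else:
        intensity, pct = record
    if intensity not in INTENSITY_LEVELS:
        raise ValueError(f"intensity must be one of {INTENSITY_LEVELS}")
    if not 0.0 <= pct <= 100.0:
        raise ValueError("percent_cells must lie in [0, 100]")
    return float(intensity) * float(pct)


def group_summary(records: Iterable[IHCRecord] | pd.DataFrame) -> IHCGroupSummary:
    df = _as_frame(records)
    counts = score_distribution(df)
    het_mean, het_sd = heterogeneity_score(df)
    return IHCGroupSummary(
        n=len(df),
        counts=counts,
        pct_at_or_above={k: percent_at_or_above(df, k) for k in (1, 2, 3)},
        heterogeneity_mean=het_mean,
        heterogeneity_sd=het_sd,
    )


def summarize(df: pd.DataFrame, by: Sequence[str] = ("tissue_type",)) -> pd.DataFrame:
    """One summary row per group, mirroring the marker table layout."""
    df = _as_frame(df)
    validate_ihc(df)
    rows = []
    for keys, sub in df.groupby(list(by), sort=True, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        s = group_summary(sub)
        rows.append(
            {
                **dict(zip(by, keys)),
                "n": s.n,
                "score_0": s.counts[0],
                "score_1": s.counts[1],
                "score_2": s.counts[2],
                "score_3": s.counts[3],
                "pct_ge_1": s.pct_at_or_above[1],
                "pct_ge_2": s.pct_at_or_above[2],
                "pct_ge_3": s.pct_at_or_above[3],
                "heterogeneity_mean": s.heterogeneity_mean,
                "heterogeneity_sd": s.heterogeneity_sd,
            }
        )
    return pd.DataFrame(rows)


def printed_percent(value: float) -> float:
    """Render a percent the way summary tables print it.

    Half-up rounding to the nearest integer, except values exact at one
    decimal place (e.g. 12.5 from 1/8) which keep that decimal.
    """
    one_dp = round(value, 1)
    if math.isclose(value, one_dp, abs_tol=1e-9) and one_dp != int(one_dp):
        return one_dp
    return float(math.floor(value + 0.5))


def records_from_counts(
    counts: Sequence[int], tissue_type: str = "lung_tumor", percent_stained: float = 100.0
) -> pd.DataFrame:
    """Expand an intensity count row (n at 0, 1+, 2+, 3+) into records.

    Percent-cells of stained cores is arbitrary (positivity summaries do not
    use it) and defaults to 100.
    """
    if len(counts) != 4 or any(c < 0 for c in counts):
        raise ValueError("counts must be 4 non-negative integers")
    rows = []
    k = 0
    for intensity, c in zip(INTENSITY_LEVELS, counts):
        for _ in range(int(c)):
            rows.append(
                {
                    "sample_id": f"core_{k:03d}",
                    "tissue_type": tissue_type,
                    "histology": None,
                    "intensity": intensity,
                    "percent_cells": 0.0 if intensity == 0 else percent_stained,
                }
            )
            k += 1
    if not rows:
        raise ValueError("counts sum to zero")
    return pd.DataFrame(rows)


def read_ihc(path) -> pd.DataFrame:
    """Read an IHC record TSV (sample_id, tissue_type, histology, intensity, percent_cells)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"IHC table {path} lacks columns: {missing}")
    validate_ihc(df)
    return df
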