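"""Consensus construction and inter-rater reliability for ordinal panels.

A rating panel is items x raters with ratings on a 0-3 Likert scale
(0 absent/normal, 1 mild, 2 moderate, 3 severe). Consensus per item is the
modal rating; an item whose ratings span a range of 2 or more is flagged for
re-rating, and a second-round panel can replace the flagged items before the
modes are recomputed.

Reliability is the two-way random-effects absolute-agreement intraclass
correlation, both single-rater ICC(2,1) and average-rater ICC(2,k)
(Shrout & Fleiss). Bands follow the 0.5 / 0.75 / 0.9 convention
(poor / moderate / good / excellent), with boundary values assigned to the
higher band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["ConsensusRatings", "IccResult", "consensus_rating", "icc"]


@dataclass(frozen=True)
class ConsensusRatings:
    """Per-item modal consensus with discrepancy flags."""

    consensus: pd.Series          # item -> modal rating (int)
    flagged: pd.Series            # item -> bool, rating range >= 2
    n_raters_used: pd.Series      # item -> raters contributing

    def values(self) -> pd.Series:
        return self.consensus


def _item_mode(ratings: np.ndarray) -> int:
    """Modal rating; ties resolved toward the item mean, then lower severity."""
    values, counts = np.unique(ratings, return_counts=True)
    top = values[counts == counts.max()]
    if top.size == 1:
        return int(top[0])
    mean = float(np.mean(ratings))
    dist = np.abs(top - mean)
    nearest = top[dist == dist.min()]
    return int(nearest.min())


def consensus_rating(
    panel: pd.DataFrame,
    second_round: pd.DataFrame | None = None,
) -> ConsensusRatings:
    """Modal consensus over an items x raters panel (NaN = missing rating).

    ``second_round``, if given, holds re-ratings for (a superset of) the
    flagged items; flagged items' ratings are replaced wholesale and the
    modes and flags recomputed.
    """
    work = panel.copy()
    counts = work.notna().sum(axis=1)
    if (counts < 2).any():
        bad = list(work.index[counts < 2])
        raise ValueError(f"items with fewer than 2 raters: {bad}")

    def ranges(df: pd.DataFrame) -> pd.Series:
        return df.max(axis=1) - df.min(axis=1)

    if second_round is not None:
        flagged_first = ranges(work) >= 2
        for item in work.index[flagged_first]:
            if item in second_round.index:
                work.loc[item] = second_round.loc[item]

    consensus = {}
    for item in work.index:
        ratings = work.loc[item].dropna().to_numpy(dtype=int)
        consensus[item] = _item_mode(ratings)
    return ConsensusRatings(
        consensus=pd.Series(consensus).reindex(work.index),
        flagged=(ranges(work) >= 2),
        n_raters_used=work.notna().sum(axis=1),
    )


@dataclass(frozen=True)
class IccResult:
    icc_single: float   # ICC(2,1)
    icc_average: float  # ICC(2,k)
    f_stat: float
    p_value: float
    band: str
    n_items: int
    n_raters: int


def _band(value: float) -> str:
    if value >= 0.9:
        return "excellent"
    if value >= 0.75:
        return "good"
    if value >= 0.5:
        return "moderate"
    return "poor"


def icc(panel: pd.DataFrame) -> IccResult:
    """Two-way random-effects, absolute-agreement ICC on an items x raters
    panel. Items with missing ratings are dropped (with a warning); needs at
    least 2 complete items.

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n) and
    ICC(2,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n); the test statistic is
    F = MSR/MSE with (n-1) and (n-1)(k-1) degrees of freedom.
    """
    complete = panel.dropna(axis=0, how="any")
    dropped = len(panel) - len(complete)
    if dropped:
        warnings.warn(f"ICC: dropped {dropped} item(s) with missing ratings", stacklevel=2)
    data = complete.to_numpy(dtype=float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError(f"ICC requires >= 2 complete items and >= 2 raters, got {n}x{k}")

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icck = (msr - mse) / (msr + (msc - mse) / n)
    if mse > 0:
        f = msr / mse
        p = float(scipy.stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    else:
        f, p = float("inf"), 0.0
    return IccResult(
        icc_single=float(icc1),
        icc_average=float(icck),
        f_stat=float(f),
        p_value=p,
        band=_band(float(icc1)),
        n_items=n,
        n_raters=k,
    )
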