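"""Feature screening against consensus ratings and group odds ratios.

The screen is a per-feature Spearman correlation with the consensus rating;
features with two-sided p < alpha survive. No multiplicity correction is
applied by default — the screen is deliberately liberal, feeding everything
nominally associated into the factor analysis — but a Benjamini-Hochberg
flag is available.

Group contrasts use the odds of *any* impairment (consensus >= 1 by
default) in a 2x2 table, with the Haldane-Anscombe +0.5 correction when a
cell is empty and a Woolf (log-scale normal) confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["CorrelationResult", "OddsRatioResult", "spearman_screen", "group_odds_ratio"]


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    rho: float
    p_value: float
    n_used: int
    selected: bool


def spearman_screen(
    features: pd.DataFrame,
    consensus: pd.Series,
    alpha: float = 0.05,
    min_pairs: int = 4,
    fdr: bool = False,
) -> list[CorrelationResult]:
    """Spearman rho (average ranks on ties; p from the t approximation
    t = rho sqrt((n-2)/(1-rho^2))) of each feature column against the
    consensus rating, selecting at unadjusted p < alpha (or BH-adjusted if
    ``fdr``). Features with < ``min_pairs`` complete pairs, or constant on
    the complete pairs, are skipped with a warning.
    """
    results: list[CorrelationResult] = []
    skipped: list[str] = []
    consensus = consensus.astype(float)
    for name in features.columns:
        x = pd.to_numeric(features[name], errors="coerce")
        mask = x.notna() & consensus.reindex(x.index).notna()
        n = int(mask.sum())
        xv = x[mask].to_numpy()
        yv = consensus.reindex(x.index)[mask].to_numpy()
        if n < min_pairs or np.unique(xv).size < 2 or np.unique(yv).size < 2:
            skipped.append(name)
            continue
        rho, p = scipy.stats.spearmanr(xv, yv)
        results.append(CorrelationResult(
            feature=name, rho=float(rho), p_value=float(p), n_used=n, selected=False,
        ))
    if skipped:
        warnings.warn(
            f"spearman_screen skipped {len(skipped)} feature(s) with too few "
            f"complete pairs or no variation", stacklevel=2,
        )
    if not results:
        warnings.warn("spearman_screen: no feature had enough complete pairs", stacklevel=2)
        return []
    pvals = np.array([r.p_value for r in results])
    if fdr:
        order = np.argsort(pvals)
        m = pvals.size
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, pvals[i] * m / (rank_pos + 1))
            adj[i] = running
        selected = adj < alpha
    else:
        selected = pvals < alpha
    return [
        CorrelationResult(r.feature, r.rho, r.p_value, r.n_used, bool(sel))
        for r, sel in zip(results, selected)
    ]


@dataclass(frozen=True)
class OddsRatioResult:
    group_a: str
    group_b: str
    table: tuple[tuple[float, float], tuple[float, float]]  # raw counts
    or_estimate: float
    ci95: tuple[float, float]
    corrected: bool


def _odds_ratio_from_table(a: float, b: float, c: float, d: float) -> OddsRatioResult:
    corrected = 0 in (a, b, c, d)
    if corrected:
        aw, bw, cw, dw = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aw, bw, cw, dw = a, b, c, d
    or_est = (aw * dw) / (bw * cw)
    se = np.sqrt(1 / aw + 1 / bw + 1 / cw + 1 / dw)
    lo = float(np.exp(np.log(or_est) - 1.96 * se))
    hi = float(np.exp(np.log(or_est) + 1.96 * se))
    return OddsRatioResult(
        group_a="A", group_b="B",
        table=((a, b), (c, d)),
        or_estimate=float(or_est),
        ci95=(lo, hi),
        corrected=corrected,
    )


def group_odds_ratio(
    consensus: pd.Series,
    labels: pd.Series,
    group_a: str,
    group_b: str,
    impaired_threshold: int = 1,
) -> OddsRatioResult:
    """Odds ratio of impairment (consensus >= threshold) in group A versus
    group B, from the 2x2 group x impaired table. Zero cells trigger the
    Haldane-Anscombe +0.5 correction on every cell; the CI is Woolf's
    exp(ln OR +- 1.96 sqrt(sum 1/cell)) on the working cells.
    """
    labels = labels.reindex(consensus.index)
    rows = {}
    for grp in (group_a, group_b):
        vals = consensus[labels == grp].dropna()
        if vals.empty:
            raise ValueError(f"group {grp!r} has no consensus ratings")
        impaired = int((vals >= impaired_threshold).sum())
        rows[grp] = (impaired, len(vals) - impaired)
    a, b = rows[group_a]
    c, d = rows[group_b]
    result = _odds_ratio_from_table(a, b, c, d)
    return OddsRatioResult(
        group_a=group_a, group_b=group_b,
        table=result.table,
        or_estimate=result.or_estimate,
        ci95=result.ci95,
        corrected=result.corrected,
    )
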