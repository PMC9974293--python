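"""Paired statistical comparisons between postures.

The per-vessel supine/standing comparisons use Wilcoxon's signed-rank test
for paired samples, exact by full enumeration of the 2^n sign assignments
for n <= 25 (midranks for tied |differences|, zeros dropped), and a
normal approximation with continuity and tie correction above.  Arrival
time-vs-distance regression lines are compared with ANCOVA: an F-test on
the group-by-distance interaction for slopes and, under a common slope, an
F-test on the group offset for intercepts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as _sstats

from .errors import EstimationError

__all__ = [
    "PairedComparison",
    "LineComparison",
    "wilcoxon_signed_rank",
    "ancova_compare_lines",
    "percent_change",
]

_log = logging.getLogger(__name__)

EXACT_MAX_N = 25


@dataclass
class PairedComparison:
    n: int
    delta_pct: float
    W: float                  # sum of positive-difference ranks
    p: float
    method: str               # exact | normal-approx


@dataclass
class LineComparison:
    slopes: dict
    intercepts: dict
    p_slope: float
    p_intercept: float


def percent_change(supine: float, standing: float) -> float:
    """Delta% = 100 (standing - supine) / supine."""
    if supine == 0:
        raise EstimationError("zero baseline: percent change undefined")
    return 100.0 * (standing - supine) / supine


def _midranks(a: np.ndarray) -> np.ndarray:
    return _sstats.rankdata(a, method="average")


def _exact_two_sided_p(ranks2: np.ndarray, w2: int) -> float:
    """Exact two-sided p for the signed-rank statistic.

    ranks2 are the midranks scaled by 2 (integers); w2 the observed positive
    rank sum on the same scale.  The null distribution over the 2^n equally
    likely sign assignments is accumulated by dynamic programming.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    cdf = float(counts[: w2 + 1].sum())
    sf = float(counts[w2:].sum())  # includes P(W = w)
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_signed_rank(x, y) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank test on paired samples (y vs x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1D samples with n >= 2")
    d = y - x
    nz = d != 0
    if np.count_nonzero(nz) == 0:
        raise EstimationError("all paired differences are zero: test undefined")
    if np.count_nonzero(~nz):
        _log.info("dropping %d zero difference(s) from the signed-rank test",
                  int(np.count_nonzero(~nz)))
    d = d[nz]
    n = d.size
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean_x = float(np.mean(x))
    delta = percent_change(mean_x, float(np.mean(y))) if mean_x != 0 else np.nan

    if n <= EXACT_MAX_N:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        p = _exact_two_sided_p(ranks2, int(round(2.0 * w_plus)))
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
        p = float(2.0 * _sstats.norm.sf(abs(z)))
        method = "normal-approx"
    return PairedComparison(n=n, delta_pct=delta, W=w_plus, p=p, method=method)


def ancova_compare_lines(distance, time, group) -> LineComparison:
    """Compare regression lines time ~ distance between two (or more) groups."""
    frame = pd.DataFrame({"distance": np.asarray(distance, dtype=float),
                          "time": np.asarray(time, dtype=float),
                          "group": np.asarray(group)})
    slopes, intercepts = {}, {}
    for g, sub in frame.groupby("group"):
        if len(sub) < 3:
            raise EstimationError(f"group {g!r} has fewer than 3 points")
        if sub["distance"].nunique() < 2:
            raise EstimationError(f"group {g!r} has a degenerate design "
                                  "(single distance)")
        slope, intercept = np.polyfit(sub["distance"], sub["time"], 1)
        slopes[g], intercepts[g] = float(slope), float(intercept)
    if frame["group"].nunique() < 2:
        raise EstimationError("need at least two groups")

    full = smf.ols("time ~ distance * C(group)", data=frame).fit()
    anova = sm.stats.anova_lm(full, typ=2)
    p_slope = float(anova.loc["distance:C(group)", "PR(>F)"])
    common = smf.ols("time ~ distance + C(group)", data=frame).fit()
    anova_c = sm.stats.anova_lm(common, typ=2)
    p_intercept = float(anova_c.loc["C(group)", "PR(>F)"])
    return LineComparison(slopes=slopes, intercepts=intercepts,
                          p_slope=p_slope, p_intercept=p_intercept)
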