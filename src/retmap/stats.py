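"""Cohort-level categorical and rank statistics.

Exact tests for the contingency tables a retinoblastoma mapping study
reports: Fisher's exact test (2x2 with a conditional maximum-likelihood
odds ratio, and 2xK by exact enumeration over tables with fixed margins),
the Wilcoxon rank-sum test, empirical quartile splits for age and tumor
area, sector tallies for fundoscopy-only small tumors, and circular
summaries of polar angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

__all__ = [
    "ContingencyTable",
    "FisherResult",
    "QuartileSplit",
    "fisher_exact",
    "wilcoxon_rank_sum",
    "quartile_split",
    "sector_tally",
    "circular_mean",
]


@dataclass(frozen=True)
class ContingencyTable:
    """A 2xK table of nonnegative counts with optional labels."""

    counts: np.ndarray
    row_labels: tuple | None = None
    col_labels: tuple | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or c.shape[0] != 2 or c.shape[1] < 2:
            raise ValueError("table must be 2xK with K >= 2")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float | None  # conditional MLE, 2x2 only
    odds_ratio_defined: bool


def _log_binom(n, k):
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _exact_2xk_p(counts: np.ndarray) -> float:
    """Two-sided Fisher p for a 2xK table by the point-probability rule.

    Conditional on both margins, the first row (a_1..a_K) follows the
    multivariate hypergeometric law P proportional to prod_j C(c_j, a_j).
    The two-sided p-value sums P over all margin-consistent tables whose
    point probability does not exceed the observed one.  Enumeration is
    depth-first over columns with running row-sum bounds.
    """
    col = counts.sum(axis=0)
    row1 = int(counts[0].sum())
    k = len(col)
    # log-probability offset: prod C(c_j, a_j) / C(N, row1)
    log_denom = _log_binom(counts.sum(), row1)
    obs_logp = sum(_log_binom(col[j], counts[0, j]) for j in range(k)) - log_denom
    # suffix sums of column totals bound the feasible range at each depth
    suffix = np.concatenate([np.cumsum(col[::-1])[::-1], [0]])
    tol = 1e-7
    total = 0.0

    def recurse(j: int, remaining: int, logp: float) -> None:
        nonlocal total
        if j == k:
            if logp <= obs_logp + tol:
                total += math.exp(logp)
            return
        lo = max(0, remaining - int(suffix[j + 1]))
        hi = min(int(col[j]), remaining)
        for a in range(lo, hi + 1):
            recurse(j + 1, remaining - a, logp + _log_binom(col[j], a))

    recurse(0, row1, -log_denom)
    return min(1.0, total)


def fisher_exact(table) -> FisherResult:
    """Fisher's exact test for a 2xK contingency table.

    The two-sided p-value follows the point-probability rule (sum of the
    probabilities of all margin-fixed tables no more probable than the
    observed one).  For 2x2 tables the reported odds ratio is the
    conditional maximum-likelihood estimate under the noncentral
    hypergeometric model, the convention of R's ``fisher.test``.  A zero
    margin yields p = 1 with the odds ratio flagged undefined.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    c = table.counts
    if np.any(c.sum(axis=0) == 0) or np.any(c.sum(axis=1) == 0):
        return FisherResult(1.0, None, False)
    p = _exact_2xk_p(c)
    if c.shape == (2, 2):
        orr = _scipy_odds_ratio(c, kind="conditional")
        return FisherResult(float(p), float(orr.statistic), True)
    return FisherResult(float(p), None, False)


def wilcoxon_rank_sum(x, y, method: str = "auto"):
    """Wilcoxon rank-sum test in the Mann-Whitney U convention.

    W is the rank sum of ``x`` minus its minimum n_x(n_x+1)/2 (i.e. the
    Mann-Whitney U of x over y).  Exact two-sided p for small samples
    without ties, normal approximation with tie correction otherwise.
    Returns ``(W, p_two_sided)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class QuartileSplit:
    """Empirical quartile assignment of a variable."""

    values: np.ndarray
    cuts: tuple  # 25/50/75 percentiles
    quartile: np.ndarray  # 1..4 per value
    degenerate: bool = False

    def counts(self):
        return np.bincount(self.quartile, minlength=5)[1:]


def quartile_split(values, method: str = "linear") -> QuartileSplit:
    """Split values into quartiles at the empirical 25/50/75 percentiles.

    Percentiles use the linear-interpolation definition by default; values
    equal to a cut point go to the lower quartile.  Deterministic; stable
    under monotone transforms of the values.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError("need at least 4 values for a quartile split")
    cuts = np.percentile(v, [25, 50, 75], method=method)
    q = 1 + (v[:, None] > cuts[None, :]).sum(axis=1)
    degenerate = bool(cuts[0] == cuts[2])
    return QuartileSplit(v, tuple(float(c) for c in cuts), q.astype(int), degenerate)


def sector_tally(records) -> tuple[pd.DataFrame, float]:
    """Superior/inferior x age-quartile tally of sector-located tumors.

    ``records`` are :class:`retmap.tumors.SectorRecord` objects (or any
    object with ``vertical`` and ``age_quartile``).  Records on the
    horizontal meridian or in the macula carry no superior/inferior label
    and are excluded from the tally.  Returns the 2x4 table as a DataFrame
    and the exact 2xK Fisher p-value.
    """
    rows = {"superior": [0, 0, 0, 0], "inferior": [0, 0, 0, 0]}
    for rec in records:
        vert = rec.vertical
        if vert in ("meridian", "macula"):
            continue
        if vert not in rows:
            raise ValueError(f"unknown sector label {vert!r}")
        q = rec.age_quartile
        if q is None or not 1 <= q <= 4:
            raise ValueError(f"record missing a valid age quartile: {rec!r}")
        rows[vert][q - 1] += 1
    table = pd.DataFrame(rows, index=[1, 2, 3, 4]).T
    table.index.name = "vertical"
    table.columns.name = "age_quartile"
    counts = table.to_numpy()
    keep = counts.sum(axis=0) > 0
    if keep.sum() < 2 or np.any(counts.sum(axis=1) == 0):
        return table, 1.0
    res = fisher_exact(ContingencyTable(counts[:, keep]))
    return table, res.p_value


def circular_mean(angles_deg):
    """Mean direction and resultant length of polar angles (degrees).

    Returns ``(mean_direction, resultant_length)``; a resultant of
    (numerically) zero leaves the direction undefined and returns NaN for
    the mean.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("need at least one angle")
    s, c = np.sin(a).mean(), np.cos(a).mean()
    r = float(np.hypot(s, c))
    if r < 1e-12:
        return float("nan"), 0.0
    mean = float(np.degrees(np.arctan2(s, c)) % 360.0)
    if mean >= 360.0:  # float wrap of angles just below 0
        mean -= 360.0
    return mean, r
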