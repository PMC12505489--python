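"""Distribution summaries and method-agreement statistics.

Nonparametric summaries (median / IQR) are the package's default because
lipid analytes are right-skewed; quartiles use linear interpolation
(numpy's default rule) and IQR is reported as the single width Q3 - Q1.

Bland-Altman limits use the conventional fixed 1.96 multiplier on the
sample (n-1) standard deviation of paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .units import InvalidInputError

__all__ = [
    "BlandAltmanResult",
    "DegenerateTestError",
    "UndefinedCorrelationError",
    "InsufficientDataError",
    "median_iqr",
    "wilcoxon_signed_rank",
    "spearman_rho",
    "bland_altman",
    "ks_normality",
    "independent_t_test",
    "mann_whitney_u",
]

#: Conventional multiplier for 95% limits of agreement; deliberately fixed.
LOA_MULTIPLIER = 1.96


class DegenerateTestError(ValueError):
    """A paired test with no nonzero differences."""


class UndefinedCorrelationError(ValueError):
    """Correlation of a constant vector is undefined."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


def median_iqr(values) -> dict:
    """Sample median and IQR width (Q3 - Q1, linear-interpolation quartiles)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise InsufficientDataError("median_iqr of an empty sample")
    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
    return {"median": float(q2), "iqr": float(q3 - q1)}


def wilcoxon_signed_rank(x, y) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Uses the normal approximation with mid-ranked ties; zero differences are
    dropped (Wilcoxon's rule). Raises :class:`DegenerateTestError` when every
    difference is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("paired vectors must have equal length")
    if np.all(x == y):
        raise DegenerateTestError("all paired differences are zero")
    res = stats.wilcoxon(x, y, zero_method="wilcox", correction=False, method="approx")
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (mid-ranked ties); requires n >= 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("spearman_rho needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("correlation of a constant vector is undefined")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement for paired method differences."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pct_within_loa: float
    n: int
    mean: np.ndarray = field(repr=False)
    diff: np.ndarray = field(repr=False)

    def series(self) -> pd.DataFrame:
        """(mean, difference) pairs for plotting or CSV export."""
        return pd.DataFrame({"mean": self.mean, "diff": self.diff})


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland-Altman comparison of paired estimates ``a`` and ``b``.

    Differences are ``d = a - b`` and means ``(a + b) / 2``; limits are
    ``bias +/- 1.96 * sd(d)`` with the sample (n-1) standard deviation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("paired vectors must have equal length")
    mask = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[mask], b[mask]
    if a.size < 2:
        raise InsufficientDataError("bland_altman needs at least 2 complete pairs")
    diff = a - b
    mean = (a + b) / 2.0
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    low = bias - LOA_MULTIPLIER * sd
    high = bias + LOA_MULTIPLIER * sd
    within = float(100.0 * np.mean((diff >= low) & (diff <= high)))
    return BlandAltmanResult(
        bias=bias, sd_diff=sd, loa_low=low, loa_high=high,
        pct_within_loa=within, n=int(a.size), mean=mean, diff=diff,
    )


# ---------------------------------------------------------------------------
# thin diagnostic wrappers (cohort descriptives; no bespoke claims)


def ks_normality(values) -> dict:
    """One-sample Kolmogorov-Smirnov test against N(mean, sd) — a pipeline
    diagnostic only; summaries are hard-wired to the nonparametric path."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 3:
        raise InsufficientDataError("ks_normality needs n >= 3")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise DegenerateTestError("constant sample")
    res = stats.kstest(arr, "norm", args=(arr.mean(), sd))
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}


def independent_t_test(x, y) -> dict:
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float))
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}


def mann_whitney_u(x, y) -> dict:
    res = stats.mannwhitneyu(np.asarray(x, float), np.asarray(y, float))
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}
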