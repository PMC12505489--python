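"""Clinical-category assignment, TG stratification, percentage-difference
summaries, cross-tabulation and Cohen's kappa.

Interval conventions
--------------------
Clinical LDL-C treatment categories (mmol/L) are half-open, lower-inclusive:
``[0,1.81) [1.81,2.57) [2.57,3.35) [3.35,4.12) [4.12,4.90) [4.90,inf)``.
Triglyceride strata (mmol/L) partition (0, 9.04], lower-inclusive with a
closed top bound: ``(0,0.57) [0.57,1.13) ... [4.52,9.04]``.

Percentage differences are relative to the second-named (comparator)
equation: ``100 * (a - b) / b``. This denominator choice is a documented
convention and configurable where it matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .agreement import median_iqr, wilcoxon_signed_rank
from .units import InvalidInputError

__all__ = [
    "CLINICAL_CATEGORY_BOUNDS_MMOL",
    "CLINICAL_CATEGORY_LABELS",
    "TG_STRATUM_BOUNDS_MMOL",
    "TG_STRATUM_LABELS",
    "TG_STRATUM_TOP_MMOL",
    "UNCLASSIFIED",
    "CrossTab",
    "KappaResult",
    "ExcludedTgError",
    "UndefinedDifferenceError",
    "EmptyCrossTabError",
    "UndefinedKappaError",
    "assign_clinical_category",
    "category_label",
    "assign_tg_stratum",
    "tg_stratum_label",
    "percent_difference",
    "stratified_difference_summary",
    "category_crosstab",
    "cohen_kappa",
    "kappa_strength",
]

ArrayLike = Union[float, np.ndarray]

#: Lower bounds of clinical categories 2..6 (mmol/L); category 1 starts at 0.
CLINICAL_CATEGORY_BOUNDS_MMOL = np.array([1.81, 2.57, 3.35, 4.12, 4.90])
CLINICAL_CATEGORY_LABELS = (
    "<1.81", "1.81-2.56", "2.57-3.34", "3.35-4.11", "4.12-4.89", ">=4.90",
)

#: Lower bounds of TG strata 2..9 (mmol/L); stratum 1 starts just above 0.
TG_STRATUM_BOUNDS_MMOL = np.array([0.57, 1.13, 1.69, 2.26, 2.82, 3.39, 3.95, 4.52])
TG_STRATUM_TOP_MMOL = 9.04
TG_STRATUM_LABELS = (
    "<0.57", "0.57-1.12", "1.13-1.68", "1.69-2.25", "2.26-2.81",
    "2.82-3.38", "3.39-3.94", "3.95-4.51", "4.52-9.04",
)

#: Sentinel ordinal for estimates that cannot be classified (absent/NaN).
UNCLASSIFIED = 0


class ExcludedTgError(InvalidInputError):
    """TG above the study's 9.04 mmol/L exclusion bound."""


class UndefinedDifferenceError(InvalidInputError):
    """Percentage difference with a zero denominator."""


class EmptyCrossTabError(ValueError):
    """No record is classified by both equations."""


class UndefinedKappaError(ValueError):
    """Kappa undefined (expected agreement equals 1)."""


# ---------------------------------------------------------------------------
# assignments


def assign_clinical_category(ldl_mmol: ArrayLike) -> Union[int, np.ndarray]:
    """Ordinal clinical category 1-6 for an LDL-C estimate in mmol/L.

    Negative (flagged) estimates map to category 1; absent (NaN) estimates
    map to ``UNCLASSIFIED`` (0) in vector mode and raise for scalars.
    """
    values = np.asarray(ldl_mmol, dtype=float)
    idx = np.searchsorted(CLINICAL_CATEGORY_BOUNDS_MMOL, values, side="right") + 1
    idx = np.where(np.isnan(values), UNCLASSIFIED, idx).astype(int)
    if np.isscalar(ldl_mmol) or np.ndim(ldl_mmol) == 0:
        if int(idx) == UNCLASSIFIED:
            raise InvalidInputError("absent estimate cannot be classified")
        return int(idx)
    return idx


def category_label(index: Union[int, np.ndarray]) -> Union[str, np.ndarray]:
    """Printable label for a category ordinal (1-6)."""
    labels = np.asarray(CLINICAL_CATEGORY_LABELS)
    out = labels[np.asarray(index, dtype=int) - 1]
    return str(out) if np.ndim(index) == 0 else out


def assign_tg_stratum(tg_mmol: ArrayLike) -> Union[int, np.ndarray]:
    """Ordinal TG stratum 1-9 for 0 < TG <= 9.04 mmol/L (9.04 in stratum 9)."""
    values = np.asarray(tg_mmol, dtype=float)
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise InvalidInputError("TG must be positive and finite")
    if np.any(values > TG_STRATUM_TOP_MMOL):
        raise ExcludedTgError(
            f"TG > {TG_STRATUM_TOP_MMOL} mmol/L is excluded from the analysis"
        )
    idx = np.searchsorted(TG_STRATUM_BOUNDS_MMOL, values, side="right") + 1
    if np.isscalar(tg_mmol) or np.ndim(tg_mmol) == 0:
        return int(idx)
    return idx.astype(int)


def tg_stratum_label(index: Union[int, np.ndarray]) -> Union[str, np.ndarray]:
    labels = np.asarray(TG_STRATUM_LABELS)
    out = labels[np.asarray(index, dtype=int) - 1]
    return str(out) if np.ndim(index) == 0 else out


# ---------------------------------------------------------------------------
# differences


def percent_difference(a: ArrayLike, b: ArrayLike) -> ArrayLike:
    """100 * (a - b) / b — relative to the second-named (comparator) value."""
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr == 0):
        raise UndefinedDifferenceError("percent difference undefined for b = 0")
    out = 100.0 * (np.asarray(a, dtype=float) - b_arr) / b_arr
    if np.ndim(a) == 0 and np.ndim(b) == 0:
        return float(out)
    return out


def _resolve_column(records: pd.DataFrame, name: str) -> str:
    if name in records.columns:
        return name
    alias = f"ldl_{name}"
    if alias in records.columns:
        return alias
    raise KeyError(f"no estimate column {name!r} (or {alias!r}) in records")


def stratified_difference_summary(
    records: pd.DataFrame,
    pair: Sequence[str],
    tg_col: str = "tg",
) -> pd.DataFrame:
    """Per-TG-stratum summary of percentage differences between two equations.

    ``pair`` names two estimate columns (``"ff"`` resolves to ``"ldl_ff"``
    etc.); rows with either estimate absent are excluded pairwise. Returns one
    row per stratum: ``stratum, stratum_label, n, median, iqr, p``; strata
    with no eligible pair carry ``n=0`` and NaN statistics.
    """
    col_a = _resolve_column(records, pair[0])
    col_b = _resolve_column(records, pair[1])
    tg = records[tg_col].to_numpy(dtype=float)
    # rows outside (0, 9.04] get the UNCLASSIFIED sentinel and never match
    in_range = np.isfinite(tg) & (tg > 0) & (tg <= TG_STRATUM_TOP_MMOL)
    strata = np.full(tg.shape, UNCLASSIFIED)
    strata[in_range] = assign_tg_stratum(tg[in_range])
    a_all = records[col_a].to_numpy(dtype=float)
    b_all = records[col_b].to_numpy(dtype=float)

    rows = []
    for s in range(1, len(TG_STRATUM_LABELS) + 1):
        mask = (strata == s) & ~np.isnan(a_all) & ~np.isnan(b_all) & (b_all != 0)
        n = int(mask.sum())
        median = iqr = p = float("nan")
        if n > 0:
            diffs = percent_difference(a_all[mask], b_all[mask])
            stats = median_iqr(diffs)
            median, iqr = stats["median"], stats["iqr"]
            if n > 1 and np.any(a_all[mask] != b_all[mask]):
                p = wilcoxon_signed_rank(a_all[mask], b_all[mask])["p"]
        rows.append(
            {
                "stratum": s,
                "stratum_label": TG_STRATUM_LABELS[s - 1],
                "n": n,
                "median": median,
                "iqr": iqr,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-tabulation and kappa


@dataclass(frozen=True)
class CrossTab:
    """K x K contingency table of category assignments (rows = equation A)."""

    counts: np.ndarray
    labels: tuple[str, ...] = CLINICAL_CATEGORY_LABELS
    row_name: str = "A"
    col_name: str = "B"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("crosstab must be a square matrix")
        if np.any(counts < 0):
            raise ValueError("crosstab counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row_percentages(self) -> np.ndarray:
        """Row-normalized percentages; NaN rows where the row total is 0."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, 100.0 * self.counts / totals, np.nan)

    def to_frame(self, percentages: bool = False) -> pd.DataFrame:
        data = self.row_percentages() if percentages else self.counts
        return pd.DataFrame(data, index=list(self.labels), columns=list(self.labels))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kwargs) -> "CrossTab":
        return cls(
            counts=frame.to_numpy(dtype=int),
            labels=tuple(str(c) for c in frame.columns),
            **kwargs,
        )


def category_crosstab(
    records: pd.DataFrame,
    eq_a: str,
    eq_b: str,
    tg_window: Optional[tuple[float, float]] = (1.69, 4.51),
    tg_col: str = "tg",
) -> CrossTab:
    """Clinical-category contingency table between two equations.

    Records are restricted to the closed TG window (mmol/L) when given, and
    to rows where both estimates are present.
    """
    col_a = _resolve_column(records, eq_a)
    col_b = _resolve_column(records, eq_b)
    a = records[col_a].to_numpy(dtype=float)
    b = records[col_b].to_numpy(dtype=float)
    mask = ~np.isnan(a) & ~np.isnan(b)
    if tg_window is not None:
        tg = records[tg_col].to_numpy(dtype=float)
        mask &= (tg >= tg_window[0]) & (tg <= tg_window[1])
    if not mask.any():
        raise EmptyCrossTabError("no record classified by both equations")
    cat_a = assign_clinical_category(a[mask])
    cat_b = assign_clinical_category(b[mask])
    k = len(CLINICAL_CATEGORY_LABELS)
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (cat_a - 1, cat_b - 1), 1)
    return CrossTab(counts=counts, row_name=eq_a, col_name=eq_b)


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with observed/expected agreement and a strength label."""

    kappa: float
    p_o: float
    p_e: float
    strength: str
    n: int


def cohen_kappa(crosstab: CrossTab, weights: Optional[str] = None) -> KappaResult:
    """Cohen's kappa of a contingency table (unweighted by default).

    ``weights`` may be ``"linear"`` or ``"quadratic"`` for weighted kappa;
    the unweighted statistic is the package default and the one reported by
    the analysis pipeline.
    """
    counts = crosstab.counts.astype(float)
    n = counts.sum()
    if n <= 0:
        raise EmptyCrossTabError("empty crosstab")
    k = counts.shape[0]
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if weights is None:
        w = np.eye(k)
    elif weights == "linear":
        idx = np.arange(k)
        w = 1.0 - np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    elif weights == "quadratic":
        idx = np.arange(k)
        w = 1.0 - ((idx[:, None] - idx[None, :]) / (k - 1)) ** 2
    else:
        raise InvalidInputError(f"unknown kappa weighting: {weights!r}")
    p_o = float((w * counts).sum() / n)
    p_e = float((w * np.outer(row, col)).sum() / n**2)
    if p_e >= 1.0 - 1e-15:
        raise UndefinedKappaError("expected agreement is 1; kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(
        kappa=float(kappa),
        p_o=p_o,
        p_e=p_e,
        strength=kappa_strength(kappa),
        n=int(n),
    )


def kappa_strength(kappa: float) -> str:
    """Landis-Koch strength band for a kappa value in [-1, 1]."""
    if not np.isfinite(kappa) or kappa < -1 or kappa > 1:
        raise InvalidInputError(f"kappa out of range [-1, 1]: {kappa}")
    if kappa <= 0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"
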