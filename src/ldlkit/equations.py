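"""The three LDL-cholesterol estimating equations and their validity rules.

All equations accept scalar panels or vectorized batches with identical
semantics. Canonical computation units follow each equation's published
form: Friedewald and Sampson-NIH are evaluated in mmol/L, Martin-Hopkins in
mg/dL (factor lookup requires mg/dL strata); results are delivered in the
caller's requested units.

Validity windows (triglycerides, mmol/L):

* Friedewald        : TG < 4.52 (absent at TG >= 4.52)
* Martin-Hopkins    : TG <= 4.51 (original) or TG <= 9.04 (extended table mode)
* Sampson-NIH       : TG <= 9.04
* study-wide filter : records with TG > 9.04 are excluded outright

Negative estimates are returned and flagged ``NEGATIVE_ESTIMATE``, never
clamped; downstream category assignment treats them as the lowest category.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Optional, Union

import numpy as np
import pandas as pd

from .mh_table import ConfigurationError, MhFactorTable, default_factor_table
from .units import (
    CHOL_MGDL_PER_MMOL,
    InvalidInputError,
    LipidPanel,
    Units,
    chol_to_mgdl,
    chol_to_mmol,
)

__all__ = [
    "Reason",
    "Estimate",
    "LdlEstimateSet",
    "FF_TG_LIMIT_MMOL",
    "MH_ORIGINAL_TG_LIMIT_MMOL",
    "EXTENDED_TG_LIMIT_MMOL",
    "non_hdl",
    "ldl_friedewald",
    "ldl_sampson",
    "mh_factor",
    "ldl_martin_hopkins",
    "compute_all",
]

ArrayLike = Union[float, np.ndarray]

#: Friedewald yields no value at or above this TG (mmol/L).
FF_TG_LIMIT_MMOL = 4.52
#: Original Martin-Hopkins table upper TG limit (mmol/L), inclusive.
MH_ORIGINAL_TG_LIMIT_MMOL = 4.51
#: Extended MH / Sampson-NIH upper TG limit and the study exclusion bound.
EXTENDED_TG_LIMIT_MMOL = 9.04


class Reason(IntEnum):
    """Per-estimate validity flag."""

    OK = 0
    NEGATIVE_ESTIMATE = 1  # value present but < 0
    TG_OUT_OF_RANGE = 2    # outside the equation's validity window
    EXCLUDED_TG = 3        # record excluded study-wide (TG > 9.04 mmol/L)


@dataclass(frozen=True)
class Estimate:
    """An equation's result: value(s) with NaN where absent, plus reasons."""

    value: ArrayLike
    reason: Union[Reason, np.ndarray]
    units: Units

    @property
    def present(self) -> Union[bool, np.ndarray]:
        return ~np.isnan(np.asarray(self.value, dtype=float))

    def __iter__(self):  # allows ``value, reason = estimate``
        return iter((self.value, self.reason))


@dataclass(frozen=True)
class LdlEstimateSet:
    """Per-record LDL-C estimates by the three equations plus non-HDL-C."""

    ff: Estimate
    mh: Estimate
    sampson: Estimate
    non_hdl: ArrayLike
    units: Units

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (vector inputs): ldl_* values, *_reason codes, non_hdl."""
        return pd.DataFrame(
            {
                "ldl_ff": np.atleast_1d(np.asarray(self.ff.value, dtype=float)),
                "ldl_mh": np.atleast_1d(np.asarray(self.mh.value, dtype=float)),
                "ldl_sampson": np.atleast_1d(np.asarray(self.sampson.value, dtype=float)),
                "non_hdl": np.atleast_1d(np.asarray(self.non_hdl, dtype=float)),
                "ff_reason": np.atleast_1d(np.asarray(self.ff.reason, dtype=int)),
                "mh_reason": np.atleast_1d(np.asarray(self.mh.reason, dtype=int)),
                "sampson_reason": np.atleast_1d(np.asarray(self.sampson.reason, dtype=int)),
            }
        )


def _is_scalar(panel: LipidPanel) -> bool:
    return np.isscalar(panel.triglycerides) or np.ndim(panel.triglycerides) == 0


def _finalize(
    values: np.ndarray,
    absent: np.ndarray,
    absent_reason: Reason,
    canonical: Units,
    target: Units,
    scalar: bool,
) -> Estimate:
    """Mask absent values, flag negatives, convert canonical -> target units.

    No conversion is applied when target equals the canonical computation
    units, so e.g. mg/dL Martin-Hopkins results are delivered bit-exactly.
    """
    reasons = np.where(
        absent,
        int(absent_reason),
        np.where(values < 0, int(Reason.NEGATIVE_ESTIMATE), int(Reason.OK)),
    )
    values = np.where(absent, np.nan, values)
    if target != canonical:
        values = chol_to_mgdl(values) if target == Units.MG_PER_DL else chol_to_mmol(values)
    if scalar:
        return Estimate(float(values), Reason(int(reasons)), target)
    return Estimate(values, reasons, target)


def non_hdl(panel: LipidPanel) -> ArrayLike:
    """Non-HDL cholesterol = TC - HDL-C, in the panel's own units."""
    return np.subtract(panel.total_cholesterol, panel.hdl_cholesterol)


def ldl_friedewald(panel: LipidPanel, units: Optional[Units] = None) -> Estimate:
    """Friedewald: LDL-C = TC - HDL-C - TG/2.2 (mmol/L); absent at TG >= 4.52."""
    target = Units.parse(units) if units is not None else panel.units
    scalar = _is_scalar(panel)
    p = panel.validate().to(Units.MMOL_PER_L)
    tc = np.asarray(p.total_cholesterol, dtype=float)
    hdl = np.asarray(p.hdl_cholesterol, dtype=float)
    tg = np.asarray(p.triglycerides, dtype=float)
    value = tc - hdl - tg / 2.2
    absent = tg >= FF_TG_LIMIT_MMOL
    return _finalize(value, absent, Reason.TG_OUT_OF_RANGE, Units.MMOL_PER_L, target, scalar)


def ldl_sampson(panel: LipidPanel, units: Optional[Units] = None) -> Estimate:
    """Sampson-NIH bivariate quadratic (mmol/L); absent at TG > 9.04.

    LDL-C = TC/0.948 - HDL/0.971
            - (TG/3.74 + TG*nonHDL/24.16 - TG^2/79.36) - 0.244
    """
    target = Units.parse(units) if units is not None else panel.units
    scalar = _is_scalar(panel)
    p = panel.validate().to(Units.MMOL_PER_L)
    tc = np.asarray(p.total_cholesterol, dtype=float)
    hdl = np.asarray(p.hdl_cholesterol, dtype=float)
    tg = np.asarray(p.triglycerides, dtype=float)
    nonhdl = tc - hdl
    value = (
        tc / 0.948
        - hdl / 0.971
        - (tg / 3.74 + tg * nonhdl / 24.16 - tg**2 / 79.36)
        - 0.244
    )
    absent = tg > EXTENDED_TG_LIMIT_MMOL
    return _finalize(value, absent, Reason.TG_OUT_OF_RANGE, Units.MMOL_PER_L, target, scalar)


def mh_factor(
    tg_mgdl: ArrayLike, nonhdl_mgdl: ArrayLike, table: MhFactorTable
) -> ArrayLike:
    """Adjustable factor for (TG, non-HDL-C) in mg/dL from ``table``."""
    if table is None:
        raise ConfigurationError("a Martin-Hopkins factor table is required")
    if np.any(np.asarray(tg_mgdl, dtype=float) <= 0) or np.any(
        np.asarray(nonhdl_mgdl, dtype=float) <= 0
    ):
        raise InvalidInputError("TG and non-HDL-C must be positive for factor lookup")
    return table.lookup(tg_mgdl, nonhdl_mgdl)


def ldl_martin_hopkins(
    panel: LipidPanel,
    table: Optional[MhFactorTable] = None,
    extended: bool = False,
    units: Optional[Units] = None,
) -> Estimate:
    """Martin-Hopkins: LDL-C = TC - HDL-C - TG/factor, computed in mg/dL.

    ``extended=False`` limits validity to TG <= 4.51 mmol/L (original table);
    ``extended=True`` reports up to TG <= 9.04 mmol/L.
    """
    if table is None:
        table = default_factor_table()
    target = Units.parse(units) if units is not None else panel.units
    scalar = _is_scalar(panel)
    p = panel.validate().to(Units.MG_PER_DL)
    tc = np.asarray(p.total_cholesterol, dtype=float)
    hdl = np.asarray(p.hdl_cholesterol, dtype=float)
    tg = np.asarray(p.triglycerides, dtype=float)
    factor = np.asarray(table.lookup(tg, tc - hdl), dtype=float)
    value_mgdl = tc - hdl - tg / factor
    tg_mmol = np.asarray(panel.to(Units.MMOL_PER_L).triglycerides, dtype=float)
    limit = EXTENDED_TG_LIMIT_MMOL if extended else MH_ORIGINAL_TG_LIMIT_MMOL
    absent = tg_mmol > limit
    return _finalize(value_mgdl, absent, Reason.TG_OUT_OF_RANGE, Units.MG_PER_DL, target, scalar)


def compute_all(
    panel: LipidPanel,
    table: Optional[MhFactorTable] = None,
    extended: bool = False,
    units: Optional[Units] = None,
) -> LdlEstimateSet:
    """Apply all three equations to ``panel``.

    Records with TG > 9.04 mmol/L yield all-absent estimates with reason
    ``EXCLUDED_TG`` (the study-wide exclusion rule).
    """
    target = Units.parse(units) if units is not None else panel.units
    scalar = _is_scalar(panel)
    ff = ldl_friedewald(panel, units=target)
    mh = ldl_martin_hopkins(panel, table=table, extended=extended, units=target)
    sampson = ldl_sampson(panel, units=target)

    tg_mmol = np.asarray(panel.to(Units.MMOL_PER_L).triglycerides, dtype=float)
    excluded = tg_mmol > EXTENDED_TG_LIMIT_MMOL

    def _exclude(est: Estimate) -> Estimate:
        value = np.where(excluded, np.nan, np.asarray(est.value, dtype=float))
        reason = np.where(
            excluded, int(Reason.EXCLUDED_TG), np.asarray(est.reason, dtype=int)
        )
        if scalar:
            return Estimate(float(value), Reason(int(reason[()])), target)
        return Estimate(value, reason, target)

    nh = np.asarray(non_hdl(panel.to(target)), dtype=float)
    if scalar:
        nh = float(nh)
    return LdlEstimateSet(
        ff=_exclude(ff), mh=_exclude(mh), sampson=_exclude(sampson),
        non_hdl=nh, units=target,
    )
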