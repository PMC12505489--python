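"""Concentration units, conversion constants, and the lipid-panel record type.

Cholesterol and triglyceride concentrations convert between mmol/L and
mg/dL with different molar factors:

* cholesterol species (TC, HDL-C, LDL-C, non-HDL-C): 38.67 mg/dL per mmol/L
* triglycerides: 88.57 mg/dL per mmol/L

Both constants are the conventional clinical-chemistry values and are fixed
package-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Union

import numpy as np

__all__ = [
    "Units",
    "CHOL_MGDL_PER_MMOL",
    "TG_MGDL_PER_MMOL",
    "LipidPanel",
    "InvalidInputError",
    "convert_panel_units",
    "chol_to_mgdl",
    "chol_to_mmol",
    "tg_to_mgdl",
    "tg_to_mmol",
]

#: mg/dL per mmol/L for cholesterol species (molar mass 386.65 g/mol).
CHOL_MGDL_PER_MMOL = 38.67

#: mg/dL per mmol/L for triglycerides (average molar mass 885.7 g/mol).
TG_MGDL_PER_MMOL = 88.57

ArrayLike = Union[float, np.ndarray]


class InvalidInputError(ValueError):
    """Raised for physically impossible inputs (non-positive concentrations,
    unknown unit flags, out-of-range statistics)."""


class Units(str, Enum):
    """Measurement units of a lipid panel; one flag applies to all analytes."""

    MMOL_PER_L = "mmol/L"
    MG_PER_DL = "mg/dL"

    @classmethod
    def parse(cls, value: "Units | str") -> "Units":
        if isinstance(value, Units):
            return value
        text = str(value).strip().lower().replace(" ", "")
        aliases = {
            "mmol/l": cls.MMOL_PER_L,
            "mmol_per_l": cls.MMOL_PER_L,
            "mmoll": cls.MMOL_PER_L,
            "mmol": cls.MMOL_PER_L,
            "mg/dl": cls.MG_PER_DL,
            "mg_per_dl": cls.MG_PER_DL,
            "mgdl": cls.MG_PER_DL,
            "mg": cls.MG_PER_DL,
        }
        try:
            return aliases[text]
        except KeyError:
            raise InvalidInputError(f"unknown units flag: {value!r}") from None


def chol_to_mgdl(x: ArrayLike) -> ArrayLike:
    return np.multiply(x, CHOL_MGDL_PER_MMOL)


def chol_to_mmol(x: ArrayLike) -> ArrayLike:
    return np.divide(x, CHOL_MGDL_PER_MMOL)


def tg_to_mgdl(x: ArrayLike) -> ArrayLike:
    return np.multiply(x, TG_MGDL_PER_MMOL)


def tg_to_mmol(x: ArrayLike) -> ArrayLike:
    return np.divide(x, TG_MGDL_PER_MMOL)


@dataclass(frozen=True)
class LipidPanel:
    """One person's (or a vector of persons') TC / HDL-C / TG measurements.

    Fields may be scalars or equally shaped numpy arrays; the ``units`` flag
    applies to all three analytes simultaneously.
    """

    total_cholesterol: ArrayLike
    hdl_cholesterol: ArrayLike
    triglycerides: ArrayLike
    units: Units = Units.MMOL_PER_L

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", Units.parse(self.units))

    # -- validation ------------------------------------------------------

    def validate(self) -> "LipidPanel":
        """Check that every concentration is strictly positive and finite."""
        for name in ("total_cholesterol", "hdl_cholesterol", "triglycerides"):
            value = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(value)) or np.any(value <= 0):
                raise InvalidInputError(
                    f"{name} must be positive and finite for analysis"
                )
        return self

    # -- conversion ------------------------------------------------------

    def to(self, target: Units | str) -> "LipidPanel":
        """Return this panel expressed in ``target`` units (identity if equal)."""
        target = Units.parse(target)
        if target == self.units:
            return self
        if target == Units.MG_PER_DL:
            return replace(
                self,
                total_cholesterol=chol_to_mgdl(self.total_cholesterol),
                hdl_cholesterol=chol_to_mgdl(self.hdl_cholesterol),
                triglycerides=tg_to_mgdl(self.triglycerides),
                units=target,
            )
        return replace(
            self,
            total_cholesterol=chol_to_mmol(self.total_cholesterol),
            hdl_cholesterol=chol_to_mmol(self.hdl_cholesterol),
            triglycerides=tg_to_mmol(self.triglycerides),
            units=target,
        )


def convert_panel_units(panel: LipidPanel, target: Units | str) -> LipidPanel:
    """Convert ``panel`` to ``target`` units (see :meth:`LipidPanel.to`)."""
    return panel.to(target)
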