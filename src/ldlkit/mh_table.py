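"""Martin-Hopkins adjustable-factor lookup table.

The Martin-Hopkins equation replaces Friedewald's fixed triglyceride divisor
with a factor read from a two-way stratification of triglycerides and
non-HDL cholesterol (both in mg/dL). The table shipped with this package
(``data/mh_factors_martin2013.csv``) is a transcription of the 180-cell
(30 TG strata x 6 non-HDL-C strata) median-factor table of Martin et al.,
JAMA 2013;310(19):2061-2068; its provenance is recorded on the object.

Cells are half-open and lower-bound inclusive: a value equal to a stratum
boundary belongs to the upper stratum, and values beyond the last boundary
fall in the outermost (open-ended) stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np

__all__ = ["MhFactorTable", "ConfigurationError", "default_factor_table", "constant_factor_table"]

ArrayLike = Union[float, np.ndarray]

_PACKAGED_TABLE = "mh_factors_martin2013.csv"
_PACKAGED_PROVENANCE = (
    "Transcribed from Martin et al., JAMA 2013;310(19):2061-2068, Table "
    "(median TG:VLDL-C factors, 180 cells: 30 TG strata x 6 non-HDL-C strata, mg/dL)"
)


class ConfigurationError(ValueError):
    """Raised for malformed factor tables or missing configuration."""


@dataclass(frozen=True)
class MhFactorTable:
    """Stratified adjustable-factor lookup (TG strata x non-HDL-C strata).

    ``tg_bounds`` and ``nonhdl_bounds`` are the *lower* bounds of each
    stratum in mg/dL (the first is typically 0); ``factors`` has shape
    ``(len(tg_bounds), len(nonhdl_bounds))``.
    """

    tg_bounds: np.ndarray
    nonhdl_bounds: np.ndarray
    factors: np.ndarray
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        tg = np.asarray(self.tg_bounds, dtype=float)
        nh = np.asarray(self.nonhdl_bounds, dtype=float)
        fac = np.asarray(self.factors, dtype=float)
        if tg.ndim != 1 or nh.ndim != 1:
            raise ConfigurationError("stratum boundaries must be 1-D")
        if np.any(np.diff(tg) <= 0) or np.any(np.diff(nh) <= 0):
            raise ConfigurationError("stratum boundaries must be strictly increasing")
        if fac.shape != (tg.size, nh.size):
            raise ConfigurationError(
                f"factor matrix shape {fac.shape} does not match "
                f"({tg.size} TG strata, {nh.size} non-HDL strata)"
            )
        if not np.all(np.isfinite(fac)) or np.any(fac <= 0):
            raise ConfigurationError("every factor must be finite and > 0")
        object.__setattr__(self, "tg_bounds", tg)
        object.__setattr__(self, "nonhdl_bounds", nh)
        object.__setattr__(self, "factors", fac)

    @property
    def shape(self) -> tuple[int, int]:
        return self.factors.shape

    # -- lookup ----------------------------------------------------------

    def lookup(self, tg_mgdl: ArrayLike, nonhdl_mgdl: ArrayLike) -> ArrayLike:
        """Factor of the unique cell containing (tg, non-HDL), both mg/dL.

        Lower-inclusive half-open cells; inputs below the first bound use the
        first stratum and inputs beyond the last bound the outermost stratum.
        """
        tg = np.asarray(tg_mgdl, dtype=float)
        nh = np.asarray(nonhdl_mgdl, dtype=float)
        i = np.clip(np.searchsorted(self.tg_bounds, tg, side="right") - 1, 0, None)
        j = np.clip(np.searchsorted(self.nonhdl_bounds, nh, side="right") - 1, 0, None)
        out = self.factors[i, j]
        if np.isscalar(tg_mgdl) and np.isscalar(nonhdl_mgdl):
            return float(out)
        return out

    # -- serialization ---------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write as a CSV matrix: header = non-HDL lower bounds, first column
        = TG lower bounds (mg/dL)."""
        header = "tg_lower_mgdl," + ",".join(_fmt(b) for b in self.nonhdl_bounds)
        lines = [header]
        for bound, row in zip(self.tg_bounds, self.factors):
            lines.append(_fmt(bound) + "," + ",".join(_fmt(v) for v in row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str | None = None) -> "MhFactorTable":
        text = Path(path).read_text()
        return cls._parse_csv(text, provenance or f"loaded from {path}")

    @classmethod
    def _parse_csv(cls, text: str, provenance: str) -> "MhFactorTable":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        if len(lines) < 2:
            raise ConfigurationError("factor table CSV needs a header and at least one row")
        nonhdl_bounds = [float(tok) for tok in lines[0].split(",")[1:]]
        tg_bounds, rows = [], []
        for line in lines[1:]:
            cells = line.split(",")
            tg_bounds.append(float(cells[0]))
            rows.append([float(tok) for tok in cells[1:]])
        return cls(
            tg_bounds=np.array(tg_bounds),
            nonhdl_bounds=np.array(nonhdl_bounds),
            factors=np.array(rows),
            provenance=provenance,
        )


def _fmt(value: float) -> str:
    return f"{value:g}"


@lru_cache(maxsize=1)
def default_factor_table() -> MhFactorTable:
    """The packaged 180-cell Martin et al. (2013) median-factor table."""
    text = resources.files("ldlkit").joinpath("data", _PACKAGED_TABLE).read_text()
    return MhFactorTable._parse_csv(text, _PACKAGED_PROVENANCE)


def constant_factor_table(factor: float = 5.0) -> MhFactorTable:
    """A 1x1 table returning ``factor`` everywhere (testing / Friedewald mode)."""
    return MhFactorTable(
        tg_bounds=np.array([0.0]),
        nonhdl_bounds=np.array([0.0]),
        factors=np.array([[factor]]),
        provenance=f"constant factor {factor}",
    )
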