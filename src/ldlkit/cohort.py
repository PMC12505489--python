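"""Synthetic lipid-panel cohort generator with hidden ground truth.

The generator draws per-sex log-normal triglycerides and HDL-C, a log-normal
"true" LDL-C, and composes total cholesterol as the exact sum

    TC = true LDL-C + HDL-C + true VLDL-C            (pre-noise, mmol/L)

where true VLDL-C is TG divided by a TG:VLDL-C ratio ``r`` that ramps
linearly from ``r_min`` (default 5) at 100 mg/dL of TG to ``r_max``
(default 9) at 400 mg/dL, clamped outside. A varying ratio is the mechanism
that makes fixed-ratio LDL-C estimators drift with TG, so the cohort
exercises every downstream comparison with a known answer.

Log-normal marginals are a modeling choice (right-skewed positive analytes
summarized by medians/IQRs), parameterized so the distribution's median and
quartile width match the requested targets exactly. TG and HDL are drawn
independently within sex by default; an optional Gaussian-copula rank
correlation knob exists but defaults to 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .units import CHOL_MGDL_PER_MMOL, TG_MGDL_PER_MMOL, InvalidInputError

__all__ = [
    "SyntheticCohortConfig",
    "lognormal_params_from_median_iqr",
    "generate_cohort",
    "inject_artifacts",
    "TRUTH_COLUMNS",
]

#: Standard-normal upper quartile; fixes the median/IQR -> (mu, sigma) map.
_Z75 = 0.6744897501960817

#: Hidden-truth columns; drop these to form "observed-only" input.
TRUTH_COLUMNS = ("truth_ldl", "truth_vldl", "truth_ratio")

_AGE_BANDS = ((18, 24), (25, 34), (35, 44), (45, 54), (55, 64), (65, 75))
_DEFAULT_AGE_PROBS = (0.0190, 0.0803, 0.2161, 0.2530, 0.2552, 0.1765)

_STUDY_START = np.datetime64("2019-01-01")
_STUDY_END = np.datetime64("2023-12-31")


@dataclass
class SyntheticCohortConfig:
    """Distributional targets and simulation knobs for the generator.

    Defaults reproduce the source cohort's published marginals: 43.05%
    female; per-sex TG medians 0.89 (F) / 1.02 (M) mmol/L with IQRs
    0.54 / 0.71; HDL-C 1.45 / 1.24 with IQRs 0.46 / 0.39; true LDL-C
    median 3.10, IQR 1.42 mmol/L.
    """

    n: int = 20_000
    female_fraction: float = 0.4305
    tg_median: dict = field(default_factory=lambda: {"F": 0.89, "M": 1.02})
    tg_iqr: dict = field(default_factory=lambda: {"F": 0.54, "M": 0.71})
    hdl_median: dict = field(default_factory=lambda: {"F": 1.45, "M": 1.24})
    hdl_iqr: dict = field(default_factory=lambda: {"F": 0.46, "M": 0.39})
    ldl_median: float = 3.10
    ldl_iqr: float = 1.42
    r_min: float = 5.0
    r_max: float = 9.0
    ramp_start_mgdl: float = 100.0
    ramp_end_mgdl: float = 400.0
    noise_cv_tc: float = 0.0
    noise_cv_hdl: float = 0.0
    noise_cv_tg: float = 0.0
    tg_hdl_rank_correlation: float = 0.0
    age_band_probs: tuple = _DEFAULT_AGE_PROBS
    repeat_visit_rate: float = 0.0
    age_outlier_rate: float = 0.0
    tg_outlier_rate: float = 0.0
    seed: int = 0

    def validate(self) -> "SyntheticCohortConfig":
        if self.n < 0:
            raise InvalidInputError("n must be nonnegative")
        for name in ("female_fraction", "repeat_visit_rate", "age_outlier_rate", "tg_outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must be in [0, 1]")
        for sex in ("F", "M"):
            for med, iqr in ((self.tg_median[sex], self.tg_iqr[sex]),
                             (self.hdl_median[sex], self.hdl_iqr[sex])):
                if med <= 0 or iqr < 0:
                    raise InvalidInputError("medians must be > 0 and IQRs >= 0")
        if self.ldl_median <= 0 or self.ldl_iqr < 0:
            raise InvalidInputError("LDL median must be > 0 and IQR >= 0")
        if self.r_min > self.r_max or self.r_min <= 0:
            raise InvalidInputError("require 0 < r_min <= r_max")
        if self.ramp_end_mgdl <= self.ramp_start_mgdl:
            raise InvalidInputError("ratio ramp must have positive width")
        if not -1.0 < self.tg_hdl_rank_correlation < 1.0:
            raise InvalidInputError("rank correlation must be in (-1, 1)")
        probs = np.asarray(self.age_band_probs, dtype=float)
        if probs.size != len(_AGE_BANDS) or np.any(probs < 0) or probs.sum() <= 0:
            raise InvalidInputError("age_band_probs must be 6 nonnegative weights")
        return self

    # -- config file round trip -----------------------------------------

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["age_band_probs"] = list(self.age_band_probs)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticCohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        if "age_band_probs" in kwargs:
            kwargs["age_band_probs"] = tuple(kwargs["age_band_probs"])
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticCohortConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def lognormal_params_from_median_iqr(median: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given median and quartile width.

    The quartile equation ``median * (e^{z s} - e^{-z s}) = iqr`` with
    ``z = Phi^{-1}(0.75)`` solves in closed form:
    ``sigma = asinh(iqr / (2 median)) / z``; ``sigma = 0`` when ``iqr = 0``.
    """
    if median <= 0 or iqr < 0 or not np.isfinite(median) or not np.isfinite(iqr):
        raise InvalidInputError("median must be > 0 and iqr >= 0")
    sigma = float(np.arcsinh(iqr / (2.0 * median)) / _Z75)
    return float(np.log(median)), sigma


def _ratio(tg_mgdl: np.ndarray, config: SyntheticCohortConfig) -> np.ndarray:
    frac = np.clip(
        (tg_mgdl - config.ramp_start_mgdl)
        / (config.ramp_end_mgdl - config.ramp_start_mgdl),
        0.0,
        1.0,
    )
    return config.r_min + (config.r_max - config.r_min) * frac


_COLUMNS = [
    "patient_id", "visit_date", "age", "sex", "tc", "hdl", "tg", "units",
    "truth_ldl", "truth_vldl", "truth_ratio",
]


def generate_cohort(config: SyntheticCohortConfig) -> pd.DataFrame:
    """Draw a cohort per ``config``; deterministic given ``config.seed``.

    Output columns: patient_id, visit_date, age, sex, tc, hdl, tg (mmol/L),
    units, and the hidden-truth columns ``truth_ldl``, ``truth_vldl``,
    ``truth_ratio``.
    """
    config.validate()
    n = config.n
    if n == 0:
        return pd.DataFrame(columns=_COLUMNS)
    rng = np.random.default_rng(config.seed)

    female = rng.random(n) < config.female_fraction
    sex = np.where(female, "F", "M")

    z_tg = rng.standard_normal(n)
    z_extra = rng.standard_normal(n)
    rho = config.tg_hdl_rank_correlation
    z_hdl = rho * z_tg + np.sqrt(1.0 - rho**2) * z_extra
    z_ldl = rng.standard_normal(n)

    tg = np.empty(n)
    hdl = np.empty(n)
    for s, mask in (("F", female), ("M", ~female)):
        mu, sg = lognormal_params_from_median_iqr(config.tg_median[s], config.tg_iqr[s])
        tg[mask] = np.exp(mu + sg * z_tg[mask])
        mu, sg = lognormal_params_from_median_iqr(config.hdl_median[s], config.hdl_iqr[s])
        hdl[mask] = np.exp(mu + sg * z_hdl[mask])

    mu, sg = lognormal_params_from_median_iqr(config.ldl_median, config.ldl_iqr)
    ldl = np.exp(mu + sg * z_ldl)

    tg_mgdl = tg * TG_MGDL_PER_MMOL
    r = _ratio(tg_mgdl, config)
    vldl = (tg_mgdl / r) / CHOL_MGDL_PER_MMOL  # VLDL-C in mmol/L
    tc = ldl + hdl + vldl  # exact pre-noise conservation

    # measurement noise: multiplicative log-normal, sigma = CV (approx)
    for values, cv in ((tc, config.noise_cv_tc), (hdl, config.noise_cv_hdl),
                       (tg, config.noise_cv_tg)):
        if cv > 0:
            values *= np.exp(cv * rng.standard_normal(n))

    band_idx = rng.choice(
        len(_AGE_BANDS),
        size=n,
        p=np.asarray(config.age_band_probs, float) / np.sum(config.age_band_probs),
    )
    lows = np.array([b[0] for b in _AGE_BANDS])[band_idx]
    highs = np.array([b[1] for b in _AGE_BANDS])[band_idx]
    age = lows + rng.integers(0, highs - lows + 1)

    n_days = int((_STUDY_END - _STUDY_START) / np.timedelta64(1, "D")) + 1
    dates = _STUDY_START + rng.integers(0, n_days, size=n).astype("timedelta64[D]")

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "visit_date": pd.to_datetime(dates),
            "age": age.astype(int),
            "sex": sex,
            "tc": tc,
            "hdl": hdl,
            "tg": tg,
            "units": "mmol/L",
            "truth_ldl": ldl,
            "truth_vldl": vldl,
            "truth_ratio": r,
        }
    )


def inject_artifacts(
    records: pd.DataFrame, config: SyntheticCohortConfig
) -> tuple[pd.DataFrame, dict]:
    """Contaminate a clean cohort so the study filters have work to do.

    Adds (1) repeat visits — copies of base rows with the same patient_id and
    a strictly later date; (2) rows with ages outside 18-75; (3) rows with
    TG > 9.04 mmol/L. Injected rows carry a nonempty ``injected`` column.
    Returns ``(raw_records, counts)`` where ``counts`` holds the number of
    rows added per rule, for filter-audit bookkeeping.
    """
    config.validate()
    rng = np.random.default_rng((config.seed, 0xA57))
    base = records.copy()
    base["injected"] = ""
    n = len(base)
    pieces = [base]
    counts = {"repeats": 0, "age_outliers": 0, "tg_outliers": 0}
    if n == 0:
        return base, counts

    next_id = n  # fresh patient ids for non-repeat injections

    k = int(round(config.repeat_visit_rate * n))
    if k > 0:
        idx = rng.choice(n, size=k, replace=False)
        rep = base.iloc[idx].copy()
        rep["visit_date"] = rep["visit_date"] + pd.to_timedelta(
            rng.integers(1, 366, size=k), unit="D"
        )
        rep["injected"] = "repeat"
        pieces.append(rep)
        counts["repeats"] = k

    k = int(round(config.age_outlier_rate * n))
    if k > 0:
        idx = rng.choice(n, size=k, replace=True)
        out = base.iloc[idx].copy()
        young = rng.random(k) < 0.5
        out["age"] = np.where(young, rng.integers(10, 18, size=k), rng.integers(76, 95, size=k))
        out["patient_id"] = [f"P{next_id + i:06d}" for i in range(k)]
        next_id += k
        out["injected"] = "age_outlier"
        pieces.append(out)
        counts["age_outliers"] = k

    k = int(round(config.tg_outlier_rate * n))
    if k > 0:
        idx = rng.choice(n, size=k, replace=True)
        out = base.iloc[idx].copy()
        out["tg"] = rng.uniform(9.05, 20.0, size=k)
        out["patient_id"] = [f"P{next_id + i:06d}" for i in range(k)]
        next_id += k
        out["injected"] = "tg_outlier"
        pieces.append(out)
        counts["tg_outliers"] = k

    raw = pd.concat(pieces, ignore_index=True)
    return raw, counts
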