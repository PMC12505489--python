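"""End-to-end study pipeline: read panels, filter, estimate, summarize.

Filter rules run in a documented order — (0) drop rows with missing or
non-positive analytes, (1) keep ages 18-75 inclusive, (2) keep the earliest
visit per patient (ties broken by stable file order), (3) drop TG > 9.04
mmol/L — and every removed record is attributed to its first failing rule,
so the audit always conserves counts.

Analysis windows (mmol/L): category crosstabs use the closed TG window
[1.69, 4.51]; the Bland-Altman comparison of Martin-Hopkins vs Sampson-NIH
uses TG in (4.51, 9.04].
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    BlandAltmanResult,
    DegenerateTestError,
    InsufficientDataError,
    UndefinedCorrelationError,
    bland_altman,
    median_iqr,
    spearman_rho,
    wilcoxon_signed_rank,
)
from .categories import (
    CrossTab,
    EmptyCrossTabError,
    KappaResult,
    UndefinedKappaError,
    category_crosstab,
    cohen_kappa,
    stratified_difference_summary,
)
from .equations import EXTENDED_TG_LIMIT_MMOL, FF_TG_LIMIT_MMOL, compute_all
from .mh_table import MhFactorTable, default_factor_table
from .units import LipidPanel, Units

__all__ = [
    "SchemaError",
    "FilterAudit",
    "AnalysisConfig",
    "StudyReport",
    "read_panels",
    "apply_study_filters",
    "compute_estimates",
    "run_study_analysis",
    "write_report",
]

REQUIRED_COLUMNS = ("patient_id", "visit_date", "age", "sex", "tc", "hdl", "tg")

_SEX_MAP = {
    "f": "F", "female": "F", "w": "F",
    "m": "M", "male": "M",
}


class SchemaError(ValueError):
    """Input file is missing required columns."""


# ---------------------------------------------------------------------------
# reading


def read_panels(
    path: str | Path,
    default_units: str = "mmol/L",
    reject_path: Optional[str | Path] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a panels CSV, normalize to mmol/L, and collect malformed rows.

    Required columns: patient_id, visit_date, age, sex, tc, hdl, tg. An
    optional per-row ``units`` column overrides ``default_units``. Returns
    ``(records, rejects)``; rejects carry a ``reject_reason`` column and are
    optionally written to ``reject_path``.
    """
    raw = pd.read_csv(path, dtype={"patient_id": str})
    if "date" in raw.columns and "visit_date" not in raw.columns:
        raw = raw.rename(columns={"date": "visit_date"})
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    reasons = pd.Series("", index=raw.index, dtype=str)

    values = {}
    for col in ("tc", "hdl", "tg", "age"):
        values[col] = pd.to_numeric(raw[col], errors="coerce")
        bad = values[col].isna()
        reasons[bad & (reasons == "")] = "MISSING_VALUE"
    for col in ("tc", "hdl", "tg"):
        bad = values[col] <= 0
        reasons[bad & (reasons == "")] = "NONPOSITIVE_VALUE"

    units_col = raw["units"] if "units" in raw.columns else pd.Series(
        default_units, index=raw.index
    )
    units_col = units_col.fillna(default_units).astype(str)
    parsed_units = []
    for i, u in units_col.items():
        try:
            parsed_units.append(Units.parse(u))
        except Exception:
            parsed_units.append(None)
            if reasons[i] == "":
                reasons[i] = "UNKNOWN_UNITS"

    dates = pd.to_datetime(raw["visit_date"], errors="coerce")
    bad = dates.isna()
    reasons[bad & (reasons == "")] = "BAD_DATE"

    ok = reasons == ""
    rejects = raw[~ok].copy()
    rejects["reject_reason"] = reasons[~ok]
    if reject_path is not None and len(rejects):
        rejects.to_csv(reject_path, index=False)

    records = pd.DataFrame(
        {
            "patient_id": raw.loc[ok, "patient_id"].astype(str),
            "visit_date": dates[ok],
            "age": values["age"][ok].astype(float),
            "sex": raw.loc[ok, "sex"].astype(str).str.strip().str.lower().map(_SEX_MAP).fillna("U"),
            "tc": values["tc"][ok].astype(float),
            "hdl": values["hdl"][ok].astype(float),
            "tg": values["tg"][ok].astype(float),
        }
    )
    # normalize any mg/dL rows to the canonical mmol/L
    mgdl = np.array([parsed_units[i] == Units.MG_PER_DL for i in raw.index[ok]])
    if mgdl.any():
        panel = LipidPanel(
            records.loc[mgdl, "tc"].to_numpy(),
            records.loc[mgdl, "hdl"].to_numpy(),
            records.loc[mgdl, "tg"].to_numpy(),
            units=Units.MG_PER_DL,
        ).to(Units.MMOL_PER_L)
        records.loc[mgdl, "tc"] = panel.total_cholesterol
        records.loc[mgdl, "hdl"] = panel.hdl_cholesterol
        records.loc[mgdl, "tg"] = panel.triglycerides
    records["units"] = "mmol/L"
    return records.reset_index(drop=True), rejects


# ---------------------------------------------------------------------------
# filtering


@dataclass(frozen=True)
class FilterAudit:
    """Per-rule removal counts; input = output + sum of removals."""

    n_in: int
    removed_invalid: int
    removed_age: int
    removed_duplicates: int
    removed_tg: int
    n_out: int

    @property
    def conserved(self) -> bool:
        return self.n_in == (
            self.n_out
            + self.removed_invalid
            + self.removed_age
            + self.removed_duplicates
            + self.removed_tg
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def apply_study_filters(records: pd.DataFrame) -> tuple[pd.DataFrame, FilterAudit]:
    """Apply the study's inclusion rules in order; see module docstring."""
    n_in = len(records)
    df = records

    invalid = (
        df[["tc", "hdl", "tg", "age"]].isna().any(axis=1)
        | (df["tc"] <= 0) | (df["hdl"] <= 0) | (df["tg"] <= 0)
    )
    removed_invalid = int(invalid.sum())
    df = df[~invalid]

    age_ok = (df["age"] >= 18) & (df["age"] <= 75)
    removed_age = int((~age_ok).sum())
    df = df[age_ok]

    # earliest visit per patient; ties keep first occurrence in file order
    first_idx = (
        df.assign(_order=np.arange(len(df)))
        .sort_values(["visit_date", "_order"], kind="stable")
        .drop_duplicates("patient_id", keep="first")["_order"]
    )
    keep = np.zeros(len(df), dtype=bool)
    keep[first_idx.to_numpy()] = True
    removed_duplicates = int((~keep).sum())
    df = df[keep]

    tg_ok = df["tg"] <= EXTENDED_TG_LIMIT_MMOL
    removed_tg = int((~tg_ok).sum())
    df = df[tg_ok]

    audit = FilterAudit(
        n_in=n_in,
        removed_invalid=removed_invalid,
        removed_age=removed_age,
        removed_duplicates=removed_duplicates,
        removed_tg=removed_tg,
        n_out=len(df),
    )
    return df.reset_index(drop=True), audit


# ---------------------------------------------------------------------------
# analysis


@dataclass
class AnalysisConfig:
    """Windows and equation options for the study analysis."""

    extended_mh: bool = True
    mh_table_path: Optional[str] = None
    crosstab_window: tuple = (1.69, 4.51)
    ba_window: tuple = (4.51, EXTENDED_TG_LIMIT_MMOL)  # open low, closed high
    # percentage differences are (A - B)/B; orienting each modern equation
    # against Friedewald (and MH against Sampson) reproduces the published
    # sign gradient: negative at low TG, positive at high TG
    pairs: tuple = (("mh", "ff"), ("sampson", "ff"), ("mh", "sampson"))
    # contingency rows/columns follow the published layout: FF on rows
    crosstab_pairs: tuple = (("ff", "mh"), ("ff", "sampson"), ("mh", "sampson"))
    default_units: str = "mmol/L"

    def factor_table(self) -> MhFactorTable:
        if self.mh_table_path:
            return MhFactorTable.from_csv(self.mh_table_path)
        return default_factor_table()

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["pairs"] = [list(p) for p in self.pairs]
        out["crosstab_pairs"] = [list(p) for p in self.crosstab_pairs]
        out["crosstab_window"] = list(self.crosstab_window)
        out["ba_window"] = list(self.ba_window)
        return out


@dataclass
class StudyReport:
    """All analysis outputs; sections that could not be computed are listed
    in ``absent`` with a reason."""

    cohort_summary: pd.DataFrame
    stratified: dict
    crosstabs: dict
    kappas: dict
    bland_altman_mh_sampson: Optional[BlandAltmanResult]
    ba_rho_mean_diff: Optional[float]
    ba_rho_a_b: Optional[float]
    median_diff_series: pd.DataFrame
    estimates: pd.DataFrame
    audit: Optional[FilterAudit]
    config: AnalysisConfig
    absent: dict = field(default_factory=dict)


def compute_estimates(records: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Append ldl_ff / ldl_mh / ldl_sampson (+ reasons, non_hdl) to records."""
    panel = LipidPanel(
        records["tc"].to_numpy(dtype=float),
        records["hdl"].to_numpy(dtype=float),
        records["tg"].to_numpy(dtype=float),
        units=Units.MMOL_PER_L,
    )
    estimates = compute_all(
        panel, table=config.factor_table(), extended=config.extended_mh
    )
    return pd.concat(
        [records.reset_index(drop=True), estimates.to_frame()], axis=1
    )


def _cohort_summary(records: pd.DataFrame) -> pd.DataFrame:
    rows = []
    groups = [("all", records)]
    for sex in ("F", "M"):
        groups.append((sex, records[records["sex"] == sex]))
    n_all = len(records)
    for label, df in groups:
        row = {
            "group": label,
            "n": len(df),
            "pct": 100.0 * len(df) / n_all if n_all else float("nan"),
        }
        for analyte in ("tc", "tg", "hdl"):
            if len(df):
                stats = median_iqr(df[analyte])
                row[f"{analyte}_median"] = stats["median"]
                row[f"{analyte}_iqr"] = stats["iqr"]
            else:
                row[f"{analyte}_median"] = row[f"{analyte}_iqr"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def _pair_key(pair) -> str:
    return f"{pair[0]}_vs_{pair[1]}"


def run_study_analysis(
    records: pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
    audit: Optional[FilterAudit] = None,
) -> StudyReport:
    """Run the full comparison study on filtered records (deterministic)."""
    config = config or AnalysisConfig()
    absent: dict = {}

    est = compute_estimates(records, config)
    summary = _cohort_summary(records)

    stratified = {}
    series = {"stratum_label": None}
    for pair in config.pairs:
        key = _pair_key(pair)
        table = stratified_difference_summary(est, pair)
        stratified[key] = table
        series["stratum_label"] = table["stratum_label"]
        series[f"median_{key}"] = table["median"]
    median_diff_series = pd.DataFrame(series)

    crosstabs: dict = {}
    kappas: dict = {}
    for pair in config.crosstab_pairs:
        key = _pair_key(pair)
        try:
            ct = category_crosstab(est, pair[0], pair[1], tg_window=config.crosstab_window)
            crosstabs[key] = ct
            kappas[key] = cohen_kappa(ct)
        except (EmptyCrossTabError, UndefinedKappaError) as exc:
            absent[f"crosstab_{key}"] = f"{type(exc).__name__}: {exc}"

    lo, hi = config.ba_window
    ba_mask = (est["tg"] > lo) & (est["tg"] <= hi)
    ba_sub = est[ba_mask].dropna(subset=["ldl_mh", "ldl_sampson"])
    ba = rho_md = rho_ab = None
    if len(ba_sub) >= 2:
        ba = bland_altman(ba_sub["ldl_mh"], ba_sub["ldl_sampson"])
        try:
            rho_md = spearman_rho(ba.mean, ba.diff)
        except (InsufficientDataError, UndefinedCorrelationError) as exc:
            absent["ba_rho_mean_diff"] = str(exc)
        try:
            rho_ab = spearman_rho(ba_sub["ldl_mh"], ba_sub["ldl_sampson"])
        except (InsufficientDataError, UndefinedCorrelationError) as exc:
            absent["ba_rho_a_b"] = str(exc)
    else:
        absent["bland_altman_mh_sampson"] = (
            f"only {len(ba_sub)} complete pairs with TG in ({lo}, {hi}]"
        )

    return StudyReport(
        cohort_summary=summary,
        stratified=stratified,
        crosstabs=crosstabs,
        kappas=kappas,
        bland_altman_mh_sampson=ba,
        ba_rho_mean_diff=rho_md,
        ba_rho_a_b=rho_ab,
        median_diff_series=median_diff_series,
        estimates=est,
        audit=audit,
        config=config,
        absent=absent,
    )


# ---------------------------------------------------------------------------
# writing


def write_report(
    report: StudyReport, out_dir: str | Path, plots: bool = False
) -> list[Path]:
    """Write the report as CSV/JSON files; returns the file manifest.

    Re-running on identical input produces byte-identical files (no
    timestamps are written).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []

    def _write_csv(frame: pd.DataFrame, name: str, **kwargs) -> None:
        path = out / name
        frame.to_csv(path, **kwargs)
        manifest.append(path)

    _write_csv(report.cohort_summary, "cohort_summary.csv", index=False)
    _write_csv(report.estimates, "estimates.csv", index=False)
    for key, table in report.stratified.items():
        _write_csv(table, f"table2_{key}.csv", index=False)
    _write_csv(report.median_diff_series, "figure1_median_differences.csv", index=False)

    for key, ct in report.crosstabs.items():
        _write_csv(ct.to_frame(), f"table3_{key}_counts.csv")
        _write_csv(ct.to_frame(percentages=True).round(9), f"table3_{key}_rowpct.csv")

    kappa_payload = {
        key: dataclasses.asdict(res) for key, res in report.kappas.items()
    }
    (out / "kappa.json").write_text(json.dumps(kappa_payload, indent=2, sort_keys=True))
    manifest.append(out / "kappa.json")

    if report.bland_altman_mh_sampson is not None:
        ba = report.bland_altman_mh_sampson
        payload = {
            "bias": ba.bias,
            "sd_diff": ba.sd_diff,
            "loa_low": ba.loa_low,
            "loa_high": ba.loa_high,
            "pct_within_loa": ba.pct_within_loa,
            "n": ba.n,
            "rho_mean_diff": report.ba_rho_mean_diff,
            "rho_a_b": report.ba_rho_a_b,
        }
        (out / "bland_altman.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        manifest.append(out / "bland_altman.json")
        _write_csv(ba.series(), "bland_altman_series.csv", index=False)
        if plots:
            manifest.append(_plot_bland_altman(ba, out / "figure2_bland_altman.png"))

    if plots and len(report.median_diff_series):
        manifest.append(
            _plot_median_differences(report.median_diff_series, out / "figure1_median_differences.png")
        )

    log = {
        "package_version": __version__,
        "config": report.config.to_dict(),
        "audit": report.audit.to_dict() if report.audit else None,
        "absent_sections": report.absent,
        "n_records": int(len(report.estimates)),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    manifest.append(out / "run_log.json")
    return manifest


def _plot_bland_altman(ba: BlandAltmanResult, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ba.mean, ba.diff, s=8, alpha=0.6)
    for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of estimates (mmol/L)")
    ax.set_ylabel("difference (mmol/L)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _plot_median_differences(series: pd.DataFrame, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(series))
    for col in series.columns:
        if col.startswith("median_"):
            ax.plot(x, series[col], marker="o", label=col.removeprefix("median_"))
    ax.set_xticks(x, series["stratum_label"], rotation=45, ha="right")
    ax.set_ylabel("median % difference")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
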