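"""Patient-year claims data model, delimited-text readers, cohort assembly and
descriptive summaries.

The analysis operates on patient-years: a patient's diagnoses are drawn from
the year *before* the cost year (the risk model is prospective), and total
cost is the sum of VA-borne cost and Medicare Parts A/B/D payments for the
cost year. Costs are carried internally in integer cents so that the payer
additivity invariant (total = VA + Medicare) is exact, not a floating-point
approximation.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import percent


class DxSource(str, enum.Enum):
    VA = "VA"
    MEDICARE = "MEDICARE"


class Payer(str, enum.Enum):
    VA = "VA"
    MEDICARE_A = "MEDICARE_A"
    MEDICARE_B = "MEDICARE_B"
    MEDICARE_D = "MEDICARE_D"


MEDICARE_PAYERS = (Payer.MEDICARE_A, Payer.MEDICARE_B, Payer.MEDICARE_D)


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class EmptyCohortError(ValueError):
    """No patient-years survive cohort exclusions."""


def normalize_code(code: str) -> str:
    """Normalize an ICD-9-style code: strip whitespace and dots, upper-case.

    Both dotted ("296.1") and undotted ("2961") dialects are accepted and
    collapse to the same key.
    """
    out = str(code).strip().replace(".", "").upper()
    return out


@dataclass(frozen=True, slots=True)
class DiagnosisEvent:
    patient_id: str
    code: str  # normalized, undotted
    service_date: dt.date
    source: DxSource

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("diagnosis code empty after normalization")


@dataclass(frozen=True, slots=True)
class CostRecord:
    patient_id: str
    payer: Payer
    amount_cents: int  # >= 0
    year: int

    def __post_init__(self) -> None:
        if self.amount_cents < 0:
            raise ValueError("cost amount must be non-negative")

    @property
    def amount(self) -> float:
        return self.amount_cents / 100.0


@dataclass(slots=True)
class PatientYearRecord:
    """One patient-year: the unit of analysis.

    `age` is the age at the start of the cost year; `diagnoses` come from the
    prior (diagnosis) year; `ltc_days` counts days in skilled nursing or
    long-term care during the cost year and drives the community vs.
    institutional risk-score variant.
    """

    patient_id: str
    age: int
    sex: str  # "M" | "F"
    diagnoses: tuple[DiagnosisEvent, ...]
    va_cost_cents: int
    medicare_cost_cents: int
    ltc_days: int
    medication_only: bool = False
    any_va_use: bool = True

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if not (0 <= self.ltc_days <= 366):
            raise ValueError("ltc_days must lie in [0, 366]")
        if self.va_cost_cents < 0 or self.medicare_cost_cents < 0:
            raise ValueError("costs must be non-negative")
        if self.sex not in ("M", "F"):
            raise ValueError(f"unknown sex {self.sex!r}")

    @property
    def total_cost_cents(self) -> int:
        return self.va_cost_cents + self.medicare_cost_cents

    @property
    def va_cost(self) -> float:
        return self.va_cost_cents / 100.0

    @property
    def medicare_cost(self) -> float:
        return self.medicare_cost_cents / 100.0

    @property
    def total_cost(self) -> float:
        return self.total_cost_cents / 100.0


@dataclass
class Cohort:
    records: list[PatientYearRecord]
    cost_year: int
    diagnosis_year: int

    def __post_init__(self) -> None:
        if self.diagnosis_year != self.cost_year - 1:
            raise ValueError("diagnosis_year must equal cost_year - 1")
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("patient_ids must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    def frame(self) -> pd.DataFrame:
        """Per-patient view (one row per patient-year), costs in dollars."""
        return pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in self.records],
                "age": [r.age for r in self.records],
                "sex": [r.sex for r in self.records],
                "va_cost": [r.va_cost for r in self.records],
                "medicare_cost": [r.medicare_cost for r in self.records],
                "total_cost": [r.total_cost for r in self.records],
                "ltc_days": [r.ltc_days for r in self.records],
            }
        )

    def diagnosis_frame(self) -> pd.DataFrame:
        rows = [
            (e.patient_id, e.code, e.service_date, e.source.value)
            for r in self.records
            for e in r.diagnoses
        ]
        return pd.DataFrame(rows, columns=["patient_id", "code", "service_date", "source"])

    def total_costs(self) -> np.ndarray:
        return np.array([r.total_cost for r in self.records], dtype=float)


# ---------------------------------------------------------------------------
# Readers


@dataclass
class ParseReport:
    """Row-level rejections collected while reading claim files."""

    errors: list[tuple[str, int, str]] = field(default_factory=list)

    def add(self, filename: str, line: int, message: str) -> None:
        self.errors.append((filename, line, message))

    @property
    def n_rejected(self) -> int:
        return len(self.errors)


@dataclass
class ClaimsTables:
    """Normalized claim tables as read from delimited text."""

    diagnoses: pd.DataFrame  # patient_id, code, service_date, source
    costs: pd.DataFrame  # patient_id, payer, amount_cents, year
    demographics: pd.DataFrame  # patient_id, age, sex, ltc_days, medication_only, any_va_use
    report: ParseReport


DEFAULT_SCHEMA: dict[str, dict[str, str]] = {
    "diagnoses": {
        "patient_id": "patient_id",
        "code": "code",
        "service_date": "service_date",
        "source": "source",
    },
    "costs": {
        "patient_id": "patient_id",
        "payer": "payer",
        "amount": "amount",
        "year": "year",
    },
    "demographics": {
        "patient_id": "patient_id",
        "age": "age",
        "sex": "sex",
        "ltc_days": "ltc_days",
        "medication_only": "medication_only",
        "any_va_use": "any_va_use",
    },
}


def _require_columns(df: pd.DataFrame, colmap: Mapping[str, str], filename: str) -> None:
    for logical, actual in colmap.items():
        if actual not in df.columns:
            raise SchemaError(f"{filename}: missing required column {actual!r} (for {logical!r})")


def _as_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    return series.astype(str).str.strip().str.lower().isin(("1", "true", "t", "yes"))


def read_claims(
    paths: Mapping[str, str | Path],
    schema_config: Mapping[str, Mapping[str, str]] | None = None,
) -> ClaimsTables:
    """Read diagnosis, cost and demographics tables from delimited text.

    `paths` maps {"diagnoses": ..., "costs": ..., "demographics": ...} to CSV
    files with header rows; `schema_config` optionally remaps column names per
    file. Unparseable rows (bad dates, negative or non-numeric amounts) are
    rejected and collected in the returned ParseReport with 1-based line
    numbers; a missing column raises SchemaError naming it.
    """
    schema = {k: dict(DEFAULT_SCHEMA[k]) for k in DEFAULT_SCHEMA}
    if schema_config:
        for fname, colmap in schema_config.items():
            schema[fname].update(colmap)
    report = ParseReport()

    for key in ("diagnoses", "costs", "demographics"):
        if key not in paths:
            raise SchemaError(f"missing input file for {key!r}")

    # diagnoses ------------------------------------------------------------
    m = schema["diagnoses"]
    dx = pd.read_csv(paths["diagnoses"], dtype=str)
    _require_columns(dx, m, "diagnoses")
    dx = dx.rename(columns={v: k for k, v in m.items()})
    dx["code"] = dx["code"].map(lambda c: normalize_code(c) if pd.notna(c) else "")
    dates = pd.to_datetime(dx["service_date"], errors="coerce", format="mixed")
    bad = dates.isna() | (dx["code"] == "") | ~dx["source"].isin([s.value for s in DxSource])
    for idx in dx.index[bad]:
        report.add("diagnoses", int(idx) + 2, "unparseable diagnosis row")
    dx = dx.loc[~bad].copy()
    dx["service_date"] = dates.loc[~bad].dt.date
    dx = dx[["patient_id", "code", "service_date", "source"]].reset_index(drop=True)

    # costs ----------------------------------------------------------------
    m = schema["costs"]
    costs = pd.read_csv(paths["costs"], dtype=str)
    _require_columns(costs, m, "costs")
    costs = costs.rename(columns={v: k for k, v in m.items()})
    amounts = pd.to_numeric(costs["amount"], errors="coerce")
    years = pd.to_numeric(costs["year"], errors="coerce")
    bad = (
        amounts.isna()
        | (amounts < 0)
        | ~np.isfinite(amounts.fillna(np.nan))
        | years.isna()
        | ~costs["payer"].isin([p.value for p in Payer])
    )
    for idx in costs.index[bad]:
        report.add("costs", int(idx) + 2, "unparseable or negative cost row")
    costs = costs.loc[~bad].copy()
    costs["amount_cents"] = np.round(amounts.loc[~bad] * 100).astype(np.int64)
    costs["year"] = years.loc[~bad].astype(int)
    costs = costs[["patient_id", "payer", "amount_cents", "year"]].reset_index(drop=True)

    # demographics ----------------------------------------------------------
    m = schema["demographics"]
    demo = pd.read_csv(paths["demographics"], dtype=str)
    _require_columns(demo, m, "demographics")
    demo = demo.rename(columns={v: k for k, v in m.items()})
    ages = pd.to_numeric(demo["age"], errors="coerce")
    ltc = pd.to_numeric(demo["ltc_days"], errors="coerce")
    bad = ages.isna() | (ages < 0) | ltc.isna() | (ltc < 0) | (ltc > 366) | ~demo["sex"].isin(["M", "F"])
    for idx in demo.index[bad]:
        report.add("demographics", int(idx) + 2, "unparseable demographics row")
    demo = demo.loc[~bad].copy()
    demo["age"] = ages.loc[~bad].astype(int)
    demo["ltc_days"] = ltc.loc[~bad].astype(int)
    demo["medication_only"] = _as_bool(demo["medication_only"])
    demo["any_va_use"] = _as_bool(demo["any_va_use"])
    demo = demo[
        ["patient_id", "age", "sex", "ltc_days", "medication_only", "any_va_use"]
    ].reset_index(drop=True)

    return ClaimsTables(diagnoses=dx, costs=costs, demographics=demo, report=report)


# ---------------------------------------------------------------------------
# Cohort assembly


@dataclass(frozen=True)
class CohortConfig:
    cost_year: int
    diagnosis_year: int
    exclude_medication_only: bool = True
    exclude_no_va_use: bool = True

    def __post_init__(self) -> None:
        if self.diagnosis_year != self.cost_year - 1:
            raise ValueError("diagnosis_year must be cost_year - 1")


def assemble_cohort(tables: ClaimsTables, config: CohortConfig) -> Cohort:
    """Apply cohort exclusions, attach prior-year diagnoses, sum payer costs.

    Exclusions mirror the study design: medication-only VA users and patients
    with no VA use at all are dropped (both arrive as explicit flags).
    Diagnoses outside the diagnosis year are not attached; per-patient costs
    for the cost year are summed across payers, VA separately from Medicare
    Parts A/B/D.
    """
    demo = tables.demographics
    keep = pd.Series(True, index=demo.index)
    if config.exclude_medication_only:
        keep &= ~demo["medication_only"]
    if config.exclude_no_va_use:
        keep &= demo["any_va_use"]
    demo = demo.loc[keep]
    if demo.empty:
        raise EmptyCohortError("no patient-years remain after cohort exclusions")

    dx = tables.diagnoses
    if not dx.empty:
        years = pd.to_datetime(dx["service_date"]).dt.year
        dx = dx.loc[years == config.diagnosis_year]
    dx_by_pid: dict[str, list[tuple]] = {}
    for row in dx.itertuples(index=False):
        dx_by_pid.setdefault(row.patient_id, []).append(row)

    costs = tables.costs
    costs = costs.loc[costs["year"] == config.cost_year]
    is_va = costs["payer"] == Payer.VA.value
    va_cents = costs.loc[is_va].groupby("patient_id")["amount_cents"].sum().to_dict()
    med_cents = costs.loc[~is_va].groupby("patient_id")["amount_cents"].sum().to_dict()

    records = []
    for row in demo.itertuples(index=False):
        events = sorted(
            dx_by_pid.get(row.patient_id, []),
            key=lambda e: (e.service_date, e.code, e.source),
        )
        records.append(
            PatientYearRecord(
                patient_id=row.patient_id,
                age=int(row.age),
                sex=row.sex,
                diagnoses=tuple(
                    DiagnosisEvent(e.patient_id, e.code, e.service_date, DxSource(e.source))
                    for e in events
                ),
                va_cost_cents=int(va_cents.get(row.patient_id, 0)),
                medicare_cost_cents=int(med_cents.get(row.patient_id, 0)),
                ltc_days=int(row.ltc_days),
                medication_only=bool(row.medication_only),
                any_va_use=bool(row.any_va_use),
            )
        )
    return Cohort(records=records, cost_year=config.cost_year, diagnosis_year=config.diagnosis_year)


# ---------------------------------------------------------------------------
# Descriptive summary (sample-characteristics table)


def summarize_cohort(
    cohort: Cohort,
    condition_flags: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Descriptive table: overall and stratified by age <65 / >=65.

    `condition_flags` is an optional boolean DataFrame indexed by patient_id
    (one column per condition flag, e.g. diabetes or any-MH/SA as measured by
    either grouper). Returns a tidy frame with one row per (characteristic,
    statistic) and columns overall / age_ge65 / age_lt65. Percentages are
    rounded to one decimal, half away from zero.
    """
    if len(cohort) == 0:
        raise EmptyCohortError("cannot summarize an empty cohort")
    df = cohort.frame().set_index("patient_id")
    if condition_flags is not None:
        missing = set(df.index) - set(condition_flags.index)
        if missing:
            raise ValueError(f"condition_flags missing {len(missing)} patients")
        condition_flags = condition_flags.loc[df.index]

    strata = {
        "overall": pd.Series(True, index=df.index),
        "age_ge65": df["age"] >= 65,
        "age_lt65": df["age"] < 65,
    }

    rows: list[dict] = []

    def add(characteristic: str, statistic: str, fn) -> None:
        row = {"characteristic": characteristic, "statistic": statistic}
        for name, mask in strata.items():
            row[name] = fn(df.loc[mask], mask)
        rows.append(row)

    def _pct(count: float, denom: float) -> float:
        return percent(count, denom) if denom else float("nan")

    add("patients", "n", lambda d, m: int(len(d)))
    add("male", "count", lambda d, m: int((d["sex"] == "M").sum()))
    add("male", "percent", lambda d, m: _pct((d["sex"] == "M").sum(), len(d)))
    add("age", "mean", lambda d, m: float(d["age"].mean()) if len(d) else float("nan"))
    add("age", "sd", lambda d, m: float(d["age"].std(ddof=1)) if len(d) > 1 else 0.0)

    if condition_flags is not None:
        for flag in condition_flags.columns:
            add(flag, "count", lambda d, m, f=flag: int(condition_flags.loc[m, f].sum()))
            add(
                flag,
                "percent",
                lambda d, m, f=flag: _pct(condition_flags.loc[m, f].sum(), m.sum()),
            )

    for costcol in ("total_cost", "va_cost", "medicare_cost"):
        add(costcol, "mean", lambda d, m, c=costcol: float(d[c].mean()) if len(d) else float("nan"))
        add(costcol, "sd", lambda d, m, c=costcol: float(d[c].std(ddof=1)) if len(d) > 1 else 0.0)
        add(costcol, "median", lambda d, m, c=costcol: float(d[c].median()))
        add(costcol, "iqr_lo", lambda d, m, c=costcol: float(d[c].quantile(0.25)))
        add(costcol, "iqr_hi", lambda d, m, c=costcol: float(d[c].quantile(0.75)))

    return pd.DataFrame(rows, columns=["characteristic", "statistic", "overall", "age_ge65", "age_lt65"])


def write_summary(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, index=False)


def write_cohort_files(
    tables: ClaimsTables, outdir: str | Path
) -> dict[str, Path]:
    """Write claim tables back to delimited text (the same dialect read_claims reads)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    dx = tables.diagnoses.copy()
    dx.to_csv(outdir / "diagnoses.csv", index=False)
    paths["diagnoses"] = outdir / "diagnoses.csv"
    costs = tables.costs.copy()
    costs["amount"] = costs.pop("amount_cents") / 100.0
    costs[["patient_id", "payer", "amount", "year"]].to_csv(outdir / "costs.csv", index=False)
    paths["costs"] = outdir / "costs.csv"
    tables.demographics.to_csv(outdir / "demographics.csv", index=False)
    paths["demographics"] = outdir / "demographics.csv"
    return paths
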