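"""47-category psychiatric case-mix classification and the missed-diagnosis analysis.

The psychiatric grouper assigns each patient the subset of 47 named
mental-health / substance-use categories implied by their diagnosis codes,
plus derived condition flags (named unions of categories such as any MH/SA,
PTSD, mood disorder, serious mental illness). The missed-diagnosis analysis
counts, among patients carrying at least one psychiatric category but NO
mental-health HCC under the risk model, which categories the risk model is
blind to — ranked by prevalence within that missed population.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import percent
from .claims_data import Cohort, DiagnosisEvent
from .hcc_engine import HCCProfile, RiskModelSpec, has_mh_hcc

N_CATEGORIES = 47


class CodeListError(ValueError):
    """Invalid psychiatric code-list bundle."""


@dataclass
class PsyCMSCodeList:
    categories: dict[str, str]  # category_id -> display name (exactly 47)
    code_to_categories: dict[str, frozenset[str]]
    flag_definitions: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if len(self.categories) != N_CATEGORIES:
            raise CodeListError(
                f"psychiatric code list must define exactly {N_CATEGORIES} categories, "
                f"got {len(self.categories)}"
            )
        known = set(self.categories)
        for code, cats in self.code_to_categories.items():
            unknown = cats - known
            if unknown:
                raise CodeListError(f"code {code} maps to unknown categories {sorted(unknown)}")
        for flag, cats in self.flag_definitions.items():
            unknown = cats - known
            if unknown:
                raise CodeListError(f"flag {flag} references unknown categories {sorted(unknown)}")

    @property
    def category_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.categories))


@dataclass(frozen=True)
class PsyCMSProfile:
    patient_id: str
    categories: frozenset[str]
    flags: Mapping[str, bool]


@dataclass
class MissedDiagnosisTable:
    """Categories carried by patients the risk model does not flag as MH/SA.

    denominator = |{patients with >=1 psychiatric category and no MH HCC}|;
    rows are (category name, count, percent of denominator) sorted by count
    descending, ties broken by category name. Percentages may sum past 100
    because categories overlap within patients.
    """

    denominator: int
    rows: list[tuple[str, int, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["category", "count", "percent"])

    def write_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.insert(0, "denominator", self.denominator)
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Bundle I/O


def write_codelist(codelist: PsyCMSCodeList, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            (code, cat, codelist.categories[cat])
            for code, cats in sorted(codelist.code_to_categories.items())
            for cat in sorted(cats)
        ],
        columns=["code", "category_id", "category_name"],
    ).to_csv(outdir / "codes.csv", index=False)
    manifest = {
        "categories": dict(sorted(codelist.categories.items())),
        "flags": {k: sorted(v) for k, v in sorted(codelist.flag_definitions.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def load_codelist(bundle_dir: str | Path) -> PsyCMSCodeList:
    bundle_dir = Path(bundle_dir)
    for fname in ("codes.csv", "manifest.json"):
        if not (bundle_dir / fname).exists():
            raise CodeListError(f"code list bundle missing {fname}")
    manifest = json.loads((bundle_dir / "manifest.json").read_text())
    codes = pd.read_csv(bundle_dir / "codes.csv", dtype=str)
    code_to_categories: dict[str, set[str]] = {}
    for row in codes.itertuples(index=False):
        code_to_categories.setdefault(row.code, set()).add(row.category_id)
    return PsyCMSCodeList(
        categories=dict(manifest["categories"]),
        code_to_categories={k: frozenset(v) for k, v in code_to_categories.items()},
        flag_definitions={k: frozenset(v) for k, v in manifest["flags"].items()},
    )


# ---------------------------------------------------------------------------
# Classification


def _flags_for(categories: frozenset[str], codelist: PsyCMSCodeList) -> dict[str, bool]:
    return {flag: bool(categories & cats) for flag, cats in codelist.flag_definitions.items()}


def classify(events: Iterable[DiagnosisEvent], codelist: PsyCMSCodeList,
             patient_id: str | None = None) -> PsyCMSProfile:
    """Classify one patient's diagnosis events into psychiatric categories.

    Unmapped codes are ignored; the result is order-invariant in the event list.
    """
    categories: set[str] = set()
    pid = patient_id or ""
    for event in events:
        pid = pid or event.patient_id
        hit = codelist.code_to_categories.get(event.code)
        if hit:
            categories.update(hit)
    cats = frozenset(categories)
    return PsyCMSProfile(patient_id=pid, categories=cats, flags=_flags_for(cats, codelist))


def classify_cohort(cohort: Cohort, codelist: PsyCMSCodeList) -> list[PsyCMSProfile]:
    """Vectorized classification of every patient-year in a cohort."""
    dx = cohort.diagnosis_frame()
    by_patient: dict[str, set[str]] = {}
    if len(dx):
        code_map = pd.DataFrame(
            [(code, cat) for code, cats in codelist.code_to_categories.items() for cat in sorted(cats)],
            columns=["code", "cat"],
        )
        hits = dx.merge(code_map, on="code", how="inner")[["patient_id", "cat"]].drop_duplicates()
        for row in hits.itertuples(index=False):
            by_patient.setdefault(row.patient_id, set()).add(row.cat)
    profiles = []
    for pid in cohort.patient_ids:
        cats = frozenset(by_patient.get(pid, set()))
        profiles.append(PsyCMSProfile(patient_id=pid, categories=cats, flags=_flags_for(cats, codelist)))
    return profiles


def flag_frame(profiles: Sequence[PsyCMSProfile], codelist: PsyCMSCodeList) -> pd.DataFrame:
    """Boolean DataFrame of derived flags, indexed by patient_id."""
    return pd.DataFrame(
        {flag: [p.flags[flag] for p in profiles] for flag in sorted(codelist.flag_definitions)},
        index=pd.Index([p.patient_id for p in profiles], name="patient_id"),
    )


def category_frame(profiles: Sequence[PsyCMSProfile], codelist: PsyCMSCodeList) -> pd.DataFrame:
    """Boolean patient x category indicator DataFrame in fixed category order."""
    cats = codelist.category_ids
    return pd.DataFrame(
        [[c in p.categories for c in cats] for p in profiles],
        index=pd.Index([p.patient_id for p in profiles], name="patient_id"),
        columns=cats,
    )


# ---------------------------------------------------------------------------
# Missed-diagnosis analysis


def missed_mh_analysis(
    cohort: Cohort,
    hcc_profiles: Sequence[HCCProfile],
    psycms_profiles: Sequence[PsyCMSProfile],
    spec: RiskModelSpec,
    codelist: PsyCMSCodeList,
    top_n: int = 10,
) -> MissedDiagnosisTable:
    """Rank psychiatric categories among patients invisible to the risk model.

    The missed population is {>=1 psychiatric category} minus {any MH HCC}.
    An empty missed population yields an empty table with denominator 0, not
    an error.
    """
    ids = cohort.patient_ids
    if not (len(hcc_profiles) == len(psycms_profiles) == len(ids)):
        raise ValueError("profiles must cover every cohort patient")
    for hp, pp, pid in zip(hcc_profiles, psycms_profiles, ids):
        if hp.patient_id != pid or pp.patient_id != pid:
            raise ValueError("profile order must match cohort order")

    counts: Counter = Counter()
    denominator = 0
    for hp, pp in zip(hcc_profiles, psycms_profiles):
        if pp.categories and not has_mh_hcc(hp, spec):
            denominator += 1
            for cat in pp.categories:
                counts[cat] += 1
    if denominator == 0:
        return MissedDiagnosisTable(denominator=0, rows=[])
    ranked = sorted(
        counts.items(), key=lambda kv: (-kv[1], codelist.categories[kv[0]])
    )[:top_n]
    rows = [
        (codelist.categories[cat], cnt, percent(cnt, denominator))
        for cat, cnt in ranked
    ]
    return MissedDiagnosisTable(denominator=denominator, rows=rows)
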