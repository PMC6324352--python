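"""Specification-driven hierarchical-condition-category (HCC) risk scoring.

A risk-model specification is a table bundle: an ICD->condition-category map,
hierarchy rules (a dominant category suppresses its listed subordinates),
demographic (sex x age-band) coefficient cells, and per-category coefficient
tables for two variants — community and institutional. The institutional
variant applies to patients with more than 90 days in skilled nursing or
long-term care; exactly 90 days is community.

The risk score is linear and additive: the demographic cell coefficient plus
the sum of the coefficients of the patient's post-hierarchy categories, with
no interactions. Hierarchy imposition is single-pass: a rule fires iff its
dominant category is present in the ORIGINAL input set, matching published
CMS-HCC practice (a suppressed category cannot in turn suppress others
unless it was itself present initially — it was, so its rule fires anyway;
the semantics differ from cascading only in that suppression is computed
from the input, not from intermediate states).
"""

from __future__ import annotations

import enum
import graphlib
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .claims_data import Cohort, DiagnosisEvent, PatientYearRecord

INSTITUTIONAL_LTC_THRESHOLD = 90  # strictly more than 90 days -> institutional


class Variant(str, enum.Enum):
    COMMUNITY = "COMMUNITY"
    INSTITUTIONAL = "INSTITUTIONAL"


class ModelSpecError(ValueError):
    """Invalid risk-model specification bundle."""


class NoBandError(LookupError):
    """No demographic cell contains the given (sex, age)."""


@dataclass(frozen=True)
class HierarchyRule:
    dominant: str
    suppressed: frozenset[str]


@dataclass(frozen=True)
class DemographicCell:
    """Half-open age band (age_lo, age_hi] for one sex, one coefficient per variant."""

    sex: str
    age_lo: float
    age_hi: float
    coefficients: Mapping[str, float]  # variant value -> coefficient


@dataclass
class RiskModelSpec:
    icd_to_cc: dict[str, frozenset[str]]
    hierarchies: tuple[HierarchyRule, ...]
    demographic_cells: tuple[DemographicCell, ...]
    cc_coefficients: dict[str, dict[str, float]]  # variant -> {cc: coef}
    mh_hccs: frozenset[str]
    scale: str = "dollar"  # "dollar" | "relative"

    def __post_init__(self) -> None:
        # canonical ordering so spec equality is independent of table row order
        self.hierarchies = tuple(sorted(self.hierarchies, key=lambda r: r.dominant))
        self.demographic_cells = tuple(
            sorted(self.demographic_cells, key=lambda c: (c.sex, c.age_lo))
        )
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for variant in (Variant.COMMUNITY.value, Variant.INSTITUTIONAL.value):
            if variant not in self.cc_coefficients:
                raise ModelSpecError(f"missing coefficient table for variant {variant}")
        known = set(self.cc_coefficients[Variant.COMMUNITY.value])
        if set(self.cc_coefficients[Variant.INSTITUTIONAL.value]) != known:
            raise ModelSpecError("community and institutional tables cover different CCs")

        referenced = set(self.mh_hccs)
        for rule in self.hierarchies:
            referenced.add(rule.dominant)
            referenced.update(rule.suppressed)
        for ccs in self.icd_to_cc.values():
            referenced.update(ccs)
        missing = sorted(referenced - known)
        if missing:
            raise ModelSpecError(f"condition categories without coefficients: {', '.join(missing)}")

        # acyclicity of the dominance graph
        graph: dict[str, set[str]] = {}
        for rule in self.hierarchies:
            for s in rule.suppressed:
                graph.setdefault(s, set()).add(rule.dominant)
        try:
            tuple(graphlib.TopologicalSorter(graph).static_order())
        except graphlib.CycleError as exc:
            cycle = " -> ".join(exc.args[1])
            raise ModelSpecError(f"hierarchy rules contain a cycle: {cycle}") from exc

        # demographic cells partition (sex x age), no overlap, contiguous
        by_sex: dict[str, list[DemographicCell]] = {}
        for cell in self.demographic_cells:
            if cell.age_lo >= cell.age_hi:
                raise ModelSpecError(f"empty age band ({cell.age_lo}, {cell.age_hi}]")
            for variant in (Variant.COMMUNITY.value, Variant.INSTITUTIONAL.value):
                if variant not in cell.coefficients:
                    raise ModelSpecError(f"demographic cell missing {variant} coefficient")
            by_sex.setdefault(cell.sex, []).append(cell)
        for sex, cells in by_sex.items():
            cells = sorted(cells, key=lambda c: c.age_lo)
            for a, b in zip(cells, cells[1:]):
                if b.age_lo < a.age_hi:
                    raise ModelSpecError(f"overlapping demographic bands for sex {sex}")
                if b.age_lo > a.age_hi:
                    raise ModelSpecError(f"gap in demographic bands for sex {sex}")

    @property
    def all_ccs(self) -> frozenset[str]:
        return frozenset(self.cc_coefficients[Variant.COMMUNITY.value])


@dataclass(frozen=True)
class HCCProfile:
    """Post-hierarchy condition categories and the scalar risk score for one patient."""

    patient_id: str
    raw_ccs: frozenset[str]
    hccs: frozenset[str]
    variant: Variant
    score: float
    n_unmapped: int = 0

    def __post_init__(self) -> None:
        if not self.hccs <= self.raw_ccs:
            raise ValueError("post-hierarchy categories must be a subset of raw categories")
        if not np.isfinite(self.score):
            raise ValueError("risk score must be finite")


@dataclass
class MappingResult:
    ccs: frozenset[str]
    n_unmapped: int
    unmapped_codes: Counter


# ---------------------------------------------------------------------------
# Bundle I/O


def write_model_spec(spec: RiskModelSpec, outdir: str | Path) -> Path:
    """Write a spec to its delimited-text bundle (one file per table + manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(code, cc) for code, ccs in sorted(spec.icd_to_cc.items()) for cc in sorted(ccs)],
        columns=["code", "cc"],
    ).to_csv(outdir / "icd_to_cc.csv", index=False)
    pd.DataFrame(
        [(r.dominant, s) for r in spec.hierarchies for s in sorted(r.suppressed)],
        columns=["dominant", "suppressed"],
    ).to_csv(outdir / "hierarchies.csv", index=False)
    pd.DataFrame(
        [
            (c.sex, c.age_lo, c.age_hi, v, coef)
            for c in spec.demographic_cells
            for v, coef in sorted(c.coefficients.items())
        ],
        columns=["sex", "age_lo", "age_hi", "variant", "coefficient"],
    ).to_csv(outdir / "demographics.csv", index=False)
    pd.DataFrame(
        [
            (cc, v, coef)
            for v, table in sorted(spec.cc_coefficients.items())
            for cc, coef in sorted(table.items())
        ],
        columns=["cc", "variant", "coefficient"],
    ).to_csv(outdir / "coefficients.csv", index=False)
    manifest = {"scale": spec.scale, "mh_hccs": sorted(spec.mh_hccs)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def load_model_spec(bundle_dir: str | Path) -> RiskModelSpec:
    """Load and validate a risk-model specification bundle.

    Raises ModelSpecError naming the offending table, category or cycle.
    """
    bundle_dir = Path(bundle_dir)
    for fname in ("manifest.json", "icd_to_cc.csv", "hierarchies.csv", "demographics.csv", "coefficients.csv"):
        if not (bundle_dir / fname).exists():
            raise ModelSpecError(f"model spec bundle missing {fname}")
    manifest = json.loads((bundle_dir / "manifest.json").read_text())

    icd = pd.read_csv(bundle_dir / "icd_to_cc.csv", dtype=str)
    icd_to_cc: dict[str, set[str]] = {}
    for row in icd.itertuples(index=False):
        icd_to_cc.setdefault(row.code, set()).add(row.cc)

    hier = pd.read_csv(bundle_dir / "hierarchies.csv", dtype=str)
    by_dominant: dict[str, set[str]] = {}
    for row in hier.itertuples(index=False):
        by_dominant.setdefault(row.dominant, set()).add(row.suppressed)
    hierarchies = tuple(
        HierarchyRule(dominant=d, suppressed=frozenset(s)) for d, s in sorted(by_dominant.items())
    )

    demo = pd.read_csv(bundle_dir / "demographics.csv")
    cells: dict[tuple[str, float, float], dict[str, float]] = {}
    for row in demo.itertuples(index=False):
        cells.setdefault((row.sex, float(row.age_lo), float(row.age_hi)), {})[row.variant] = float(
            row.coefficient
        )
    demographic_cells = tuple(
        DemographicCell(sex=k[0], age_lo=k[1], age_hi=k[2], coefficients=v)
        for k, v in sorted(cells.items())
    )

    coef = pd.read_csv(bundle_dir / "coefficients.csv")
    cc_coefficients: dict[str, dict[str, float]] = {}
    for row in coef.itertuples(index=False):
        cc_coefficients.setdefault(row.variant, {})[row.cc] = float(row.coefficient)

    return RiskModelSpec(
        icd_to_cc={k: frozenset(v) for k, v in icd_to_cc.items()},
        hierarchies=hierarchies,
        demographic_cells=demographic_cells,
        cc_coefficients=cc_coefficients,
        mh_hccs=frozenset(manifest["mh_hccs"]),
        scale=manifest.get("scale", "dollar"),
    )


# ---------------------------------------------------------------------------
# Scoring operations


def map_diagnoses(events: Iterable[DiagnosisEvent], spec: RiskModelSpec) -> MappingResult:
    """Union of ICD->CC lookups over all diagnosis events.

    Unmapped codes are counted and reported, never errors: real claims always
    contain codes outside the model's map.
    """
    ccs: set[str] = set()
    unmapped: Counter = Counter()
    for event in events:
        hit = spec.icd_to_cc.get(event.code)
        if hit:
            ccs.update(hit)
        else:
            unmapped[event.code] += 1
    return MappingResult(ccs=frozenset(ccs), n_unmapped=sum(unmapped.values()), unmapped_codes=unmapped)


def impose_hierarchies(ccs: frozenset[str] | set[str], spec: RiskModelSpec) -> frozenset[str]:
    """Remove categories suppressed by a dominant category present in the input.

    Single-pass semantics: only rules whose dominant is in the ORIGINAL input
    fire. Output is a subset of the input and a fixed point of re-application.
    """
    ccs = frozenset(ccs)
    suppressed: set[str] = set()
    for rule in spec.hierarchies:
        if rule.dominant in ccs:
            suppressed.update(rule.suppressed)
    return ccs - suppressed


def demographic_coefficient(age: float, sex: str, variant: Variant, spec: RiskModelSpec) -> float:
    """Coefficient of the unique (sex, age) cell; bands are half-open (lo, hi]."""
    if age < 0:
        raise ValueError("age must be non-negative")
    for cell in spec.demographic_cells:
        if cell.sex == sex and cell.age_lo < age <= cell.age_hi:
            return float(cell.coefficients[variant.value])
    raise NoBandError(f"no demographic band contains sex={sex!r}, age={age}")


def variant_for(ltc_days: int) -> Variant:
    return Variant.INSTITUTIONAL if ltc_days > INSTITUTIONAL_LTC_THRESHOLD else Variant.COMMUNITY


def compute_risk_score(record: PatientYearRecord, spec: RiskModelSpec) -> HCCProfile:
    """Score one patient-year: demographic coefficient + sum of HCC coefficients.

    The institutional coefficient set is used iff the patient spent more than
    90 days in skilled nursing / long-term care.
    """
    mapping = map_diagnoses(record.diagnoses, spec)
    hccs = impose_hierarchies(mapping.ccs, spec)
    variant = variant_for(record.ltc_days)
    coefs = spec.cc_coefficients[variant.value]
    score = demographic_coefficient(record.age, record.sex, variant, spec)
    for cc in sorted(hccs):
        score += coefs[cc]
    return HCCProfile(
        patient_id=record.patient_id,
        raw_ccs=mapping.ccs,
        hccs=hccs,
        variant=variant,
        score=score,
        n_unmapped=mapping.n_unmapped,
    )


def has_mh_hcc(profile: HCCProfile, spec: RiskModelSpec) -> bool:
    """True iff the post-hierarchy categories include a mental-health/substance-use HCC."""
    return bool(profile.hccs & spec.mh_hccs)


# ---------------------------------------------------------------------------
# Vectorized cohort-level scoring


def _demographic_vector(
    ages: np.ndarray, sexes: np.ndarray, variants: np.ndarray, spec: RiskModelSpec
) -> np.ndarray:
    out = np.full(len(ages), np.nan)
    for cell in spec.demographic_cells:
        for variant in (Variant.COMMUNITY, Variant.INSTITUTIONAL):
            mask = (
                (sexes == cell.sex)
                & (variants == variant.value)
                & (ages > cell.age_lo)
                & (ages <= cell.age_hi)
            )
            out[mask] = cell.coefficients[variant.value]
    if np.isnan(out).any():
        i = int(np.flatnonzero(np.isnan(out))[0])
        raise NoBandError(f"no demographic band contains sex={sexes[i]!r}, age={ages[i]}")
    return out


def score_from_cc_matrix(
    cc_matrix: pd.DataFrame,
    ages: np.ndarray,
    sexes: np.ndarray,
    ltc_days: np.ndarray,
    spec: RiskModelSpec,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Vectorized scoring from a boolean patient x raw-CC matrix.

    Returns (scores, post-hierarchy boolean matrix, variant labels). This is
    the batch path shared by the pipeline and the synthetic generator's
    ground-truth computation; the scalar compute_risk_score path must agree
    with it (asserted by the test suite).
    """
    cols = sorted(spec.all_ccs)
    mat = cc_matrix.reindex(columns=cols, fill_value=False).to_numpy(dtype=bool)
    post = mat.copy()
    for rule in spec.hierarchies:
        j = cols.index(rule.dominant)
        dominant_present = mat[:, j]
        for s in rule.suppressed:
            post[dominant_present, cols.index(s)] = False

    variants = np.where(
        np.asarray(ltc_days) > INSTITUTIONAL_LTC_THRESHOLD,
        Variant.INSTITUTIONAL.value,
        Variant.COMMUNITY.value,
    )
    scores = _demographic_vector(np.asarray(ages, dtype=float), np.asarray(sexes), variants, spec)
    for variant in (Variant.COMMUNITY, Variant.INSTITUTIONAL):
        vmask = variants == variant.value
        if not vmask.any():
            continue
        coefvec = np.array([spec.cc_coefficients[variant.value][c] for c in cols])
        # column-ordered accumulation matches the sorted-cc sum of the scalar path
        contrib = np.zeros(int(vmask.sum()))
        sub = post[vmask]
        for j, coef in enumerate(coefvec):
            contrib[sub[:, j]] += coef
        scores[vmask] = scores[vmask] + contrib
    post_df = pd.DataFrame(post, index=cc_matrix.index, columns=cols)
    return scores, post_df, variants


def score_cohort(cohort: Cohort, spec: RiskModelSpec) -> tuple[list[HCCProfile], Counter]:
    """Score every patient-year in a cohort (vectorized); returns profiles and
    the pooled counter of unmapped diagnosis codes."""
    ids = cohort.patient_ids
    dx = cohort.diagnosis_frame()
    unmapped: Counter = Counter()
    if len(dx):
        mapped_rows = []
        for code, cnt in dx["code"].value_counts().items():
            if code not in spec.icd_to_cc:
                unmapped[code] += int(cnt)
        code_map = pd.DataFrame(
            [(code, cc) for code, ccs in spec.icd_to_cc.items() for cc in sorted(ccs)],
            columns=["code", "cc"],
        )
        hits = dx.merge(code_map, on="code", how="inner")[["patient_id", "cc"]].drop_duplicates()
        raw = (
            hits.assign(v=True)
            .pivot_table(index="patient_id", columns="cc", values="v", aggfunc="any", fill_value=False)
            .astype(bool)
        )
    else:
        raw = pd.DataFrame(index=pd.Index([], name="patient_id"))
    raw = raw.reindex(index=ids, fill_value=False)

    ages = np.array([r.age for r in cohort.records], dtype=float)
    sexes = np.array([r.sex for r in cohort.records])
    ltc = np.array([r.ltc_days for r in cohort.records])
    scores, post, variants = score_from_cc_matrix(raw, ages, sexes, ltc, spec)

    unmapped_per_patient: dict[str, int] = {}
    for row in dx.itertuples(index=False):
        if row.code not in spec.icd_to_cc:
            unmapped_per_patient[row.patient_id] = unmapped_per_patient.get(row.patient_id, 0) + 1

    cols = list(post.columns)
    raw_np = raw.reindex(columns=cols, fill_value=False).to_numpy(dtype=bool)
    post_np = post.to_numpy(dtype=bool)
    profiles = []
    for i, pid in enumerate(ids):
        profiles.append(
            HCCProfile(
                patient_id=pid,
                raw_ccs=frozenset(c for c, v in zip(cols, raw_np[i]) if v),
                hccs=frozenset(c for c, v in zip(cols, post_np[i]) if v),
                variant=Variant(variants[i]),
                score=float(scores[i]),
                n_unmapped=unmapped_per_patient.get(pid, 0),
            )
        )
    return profiles, unmapped
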