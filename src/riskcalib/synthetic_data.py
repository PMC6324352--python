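"""Synthetic dual-payer claims generator with known ground truth.

Emulates a veteran-like patient-year population: ~93.5% male, mean age 63
(SD 16.1), diabetes prevalence 22.1%, PTSD 10.4%, dementia 0.8%, heavily
right-skewed annual costs (mean far above the median), Medicare costs
concentrated in the >=65 stratum. Patients carry diagnosis codes drawn from
fixture code lists, so the scoring engine and psychiatric grouper do real
mapping work on the generated claims.

The true cost model is known: each patient's expected clinical cost equals
their risk score under the fixture model specification (demographic cell plus
post-hierarchy category coefficients, dollar scale), optionally plus
psychiatric dollar increments the score cannot see. Observed clinical cost is
the expectation times mean-one multiplicative lognormal noise,
cost = mu * exp(eps), eps ~ N(-sigma^2/2, sigma^2). Custodial long-term-care
cost, when enabled, is a deterministic per-diem times LTC days added after
the noise: per-diem custodial spending is mechanically determined by length
of stay, not by episodic utilization.

Mispricing injection modes reproduce the mechanisms under study:

* NONE — exactly priced: expected cost = risk score for every patient.
* MH_UNPRICED — psychiatric categories invisible to the risk model carry
  dollar increments in true cost (the risk model prices only its 4 MH/SA
  categories, so the mental-health subgroup is systematically underpriced).
* DEMENTIA_CUSTODIAL — dementia patients accrue custodial LTC days that grow
  with their clinical risk, billed per diem but absent from the coefficient
  tables (the institutional variant is too small for a custodial-care-heavy
  system).

The fixture risk-model specification and psychiatric code list are SYNTHETIC:
category structure and code ranges are fabricated for testability and are not
the published tables; real tables in the same file format can be dropped in.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .claims_data import (
    ClaimsTables,
    Cohort,
    CohortConfig,
    ParseReport,
    assemble_cohort,
    write_cohort_files,
)
from .hcc_engine import (
    DemographicCell,
    HierarchyRule,
    RiskModelSpec,
    Variant,
    score_from_cc_matrix,
    write_model_spec,
)
from .psycms_grouper import PsyCMSCodeList, write_codelist

# ---------------------------------------------------------------------------
# Fixture risk-model specification (synthetic; dollar-scale coefficients)

# cc id -> (name, community coefficient, codes)
_CC_TABLE: dict[str, tuple[str, float, tuple[str, ...]]] = {
    "CC1": ("hiv_aids", 20000.0, ("042",)),
    "CC8": ("metastatic_cancer", 60000.0, ("1970", "1990")),
    "CC18": ("diabetes_complicated", 13000.0, ("25040", "25060")),
    "CC19": ("diabetes_uncomplicated", 4500.0, ("25000", "25001")),
    "CC40": ("rheumatoid_arthritis", 4500.0, ("7140",)),
    "CC54": ("drug_alcohol_psychosis", 7000.0, ()),  # codes via psychiatric list
    "CC55": ("drug_alcohol_dependence", 5000.0, ()),
    "CC57": ("schizophrenia", 11000.0, ()),
    "CC58": ("major_depressive_bipolar", 4500.0, ()),
    "CC70": ("quadriplegia", 40000.0, ("3440",)),
    "CC85": ("congestive_heart_failure", 20000.0, ("4280", "4281")),
    "CC88": ("vascular_disease", 6500.0, ("4400", "4439")),
    "CC108": ("copd", 8000.0, ("4910", "4920", "496")),
    "CC134": ("dialysis", 60000.0, ("5856", "V4511")),
    "CC136": ("chronic_kidney_disease", 12000.0, ("5853", "5854")),
}

_INSTITUTIONAL_FACTOR = 0.8  # institutional CC coefficients relative to community
_INSTITUTIONAL_DEMOGRAPHIC_OFFSET = 11000.0  # routine institutional per-year baseline

_HIERARCHIES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("CC18", ("CC19",)),
    ("CC54", ("CC55",)),
    ("CC57", ("CC58",)),
    ("CC134", ("CC136",)),
)

_AGE_BANDS: tuple[tuple[float, float], ...] = ((0, 45), (45, 55), (55, 65), (65, 75), (75, 130))
_DEMOGRAPHIC_COMMUNITY: dict[str, tuple[float, ...]] = {
    "M": (1500.0, 1900.0, 2300.0, 2900.0, 3500.0),
    "F": (1700.0, 2100.0, 2500.0, 3100.0, 3700.0),
}

MH_HCCS = frozenset({"CC54", "CC55", "CC57", "CC58"})
DIABETES_CCS = frozenset({"CC18", "CC19"})

# Independent medical condition prevalences (diabetes handled separately).
_MEDICAL_PREVALENCE: dict[str, float] = {
    "CC1": 0.008,
    "CC8": 0.025,
    "CC40": 0.040,
    "CC70": 0.006,
    "CC85": 0.100,
    "CC88": 0.110,
    "CC108": 0.110,
    "CC134": 0.008,
    "CC136": 0.080,
}

# ---------------------------------------------------------------------------
# Fixture psychiatric code list (synthetic; 47 categories)
# category id -> (display name, prevalence, codes, priced CC or None,
#                 unpriced dollar increment used by MH_UNPRICED)
_PSYCH_TABLE: dict[str, tuple[str, float, tuple[str, ...], str | None, float]] = {
    # priced by the risk model (map to MH/SA condition categories)
    "schizophrenia": ("Schizophrenia", 0.024, ("2950", "2953"), "CC57", 0.0),
    "bipolar_disorder": ("Bipolar disorder", 0.018, ("2964", "2966"), "CC58", 0.0),
    "major_depression": ("Major depressive disorder", 0.055, ("2962", "2963"), "CC58", 0.0),
    "alcohol_dependence": ("Alcohol dependence", 0.048, ("3030", "3039"), "CC55", 0.0),
    "drug_dependence": ("Drug dependence", 0.026, ("3041", "3049"), "CC55", 0.0),
    "alcohol_psychosis": ("Alcohol-induced psychosis", 0.005, ("2910",), "CC54", 0.0),
    "drug_psychosis": ("Drug-induced psychosis", 0.004, ("2920",), "CC54", 0.0),
    # invisible to the risk model
    "nicotine_dependence": ("Nicotine dependence", 0.110, ("3051",), None, 900.0),
    "depression_nos": ("Depression, not otherwise specified", 0.125, ("311",), None, 2400.0),
    "ptsd": ("Posttraumatic stress disorder", 0.104, ("30981",), None, 3600.0),
    "anxiety_disorder": ("Anxiety disorder", 0.045, ("30000",), None, 1500.0),
    "organic_other": ("Organic mental disorder, other", 0.012, ("2948",), None, 2200.0),
    "alcohol_abuse": ("Alcohol abuse", 0.080, ("30500",), None, 1300.0),
    "adjustment_reaction": ("Adjustment reaction", 0.015, ("3090",), None, 1100.0),
    "neurotic_depression": ("Neurotic depression", 0.030, ("3004",), None, 1600.0),
    "sexual_dysfunction": ("Sexual dysfunction", 0.012, ("3027",), None, 700.0),
    "general_anxiety": ("Generalized anxiety disorder", 0.012, ("30002",), None, 1400.0),
    "dementia": ("Dementia", 0.008, ("2900", "3310"), None, 0.0),
    "panic_disorder": ("Panic disorder", 0.010, ("30001",), None, 1300.0),
    "personality_disorder": ("Personality disorder", 0.015, ("3019",), None, 1800.0),
    "ocd": ("Obsessive-compulsive disorder", 0.008, ("3003",), None, 600.0),
    "phobia": ("Phobic disorder", 0.007, ("3002",), None, 600.0),
    "social_phobia": ("Social phobia", 0.005, ("30023",), None, 600.0),
    "somatoform": ("Somatoform disorder", 0.006, ("3008",), None, 600.0),
    "eating_disorder": ("Eating disorder", 0.003, ("3071",), None, 600.0),
    "adhd": ("Attention-deficit disorder", 0.006, ("314",), None, 600.0),
    "autism_spectrum": ("Autism spectrum disorder", 0.002, ("2990",), None, 600.0),
    "insomnia_behavioral": ("Behavioral insomnia", 0.008, ("30741",), None, 600.0),
    "impulse_control": ("Impulse control disorder", 0.004, ("3123",), None, 600.0),
    "conduct_disorder": ("Conduct disorder", 0.002, ("3124",), None, 600.0),
    "intellectual_disability": ("Intellectual disability", 0.004, ("317",), None, 600.0),
    "delirium": ("Delirium", 0.006, ("2930",), None, 600.0),
    "amnestic_disorder": ("Amnestic disorder", 0.002, ("2941",), None, 600.0),
    "conversion_disorder": ("Conversion disorder", 0.002, ("30011",), None, 600.0),
    "dissociative_disorder": ("Dissociative disorder", 0.001, ("30015",), None, 600.0),
    "hypochondriasis": ("Hypochondriasis", 0.002, ("3007",), None, 600.0),
    "psychogenic_pain": ("Psychogenic pain", 0.004, ("3078",), None, 600.0),
    "oppositional_disorder": ("Oppositional defiant disorder", 0.001, ("3138",), None, 600.0),
    "tic_disorder": ("Tic disorder", 0.001, ("3072",), None, 600.0),
    "opioid_abuse": ("Opioid abuse", 0.024, ("30550",), None, 600.0),
    "cannabis_abuse": ("Cannabis abuse", 0.045, ("30520",), None, 600.0),
    "cocaine_abuse": ("Cocaine abuse", 0.012, ("30560",), None, 600.0),
    "stimulant_abuse": ("Stimulant abuse", 0.006, ("30570",), None, 600.0),
    "gambling_disorder": ("Gambling disorder", 0.002, ("31231",), None, 600.0),
    "acute_stress_reaction": ("Acute stress reaction", 0.005, ("3080",), None, 600.0),
    "psychosis_nos": ("Psychosis, not otherwise specified", 0.012, ("2989",), None, 600.0),
    "developmental_disorder": ("Developmental disorder", 0.003, ("315",), None, 600.0),
}

_FLAG_DEFINITIONS: dict[str, tuple[str, ...]] = {
    "any_mh_sa": tuple(sorted(c for c in _PSYCH_TABLE if c != "dementia")),
    "ptsd": ("ptsd",),
    "mood_disorder": ("bipolar_disorder", "depression_nos", "major_depression", "neurotic_depression"),
    "serious_mental_illness": ("bipolar_disorder", "psychosis_nos", "schizophrenia"),
    "substance_abuse": (
        "alcohol_abuse",
        "alcohol_dependence",
        "alcohol_psychosis",
        "cannabis_abuse",
        "cocaine_abuse",
        "drug_dependence",
        "drug_psychosis",
        "opioid_abuse",
        "stimulant_abuse",
    ),
    "nicotine_dependence": ("nicotine_dependence",),
    "dementia": ("dementia",),
}

DEFAULT_PSYCH_INCREMENTS: dict[str, float] = {
    cat: inc for cat, (_, _, _, _, inc) in _PSYCH_TABLE.items()
}

UNMAPPED_CODE = "V7009"  # routine exam; deliberately absent from both code lists


def default_model_spec() -> RiskModelSpec:
    """The synthetic fixture risk-model specification (dollar scale)."""
    icd_to_cc: dict[str, set[str]] = {}
    for cc, (_, _, codes) in _CC_TABLE.items():
        for code in codes:
            icd_to_cc.setdefault(code, set()).add(cc)
    for cat, (_, _, codes, cc, _) in _PSYCH_TABLE.items():
        if cc is not None:
            for code in codes:
                icd_to_cc.setdefault(code, set()).add(cc)
    cells = []
    for sex, coefs in _DEMOGRAPHIC_COMMUNITY.items():
        for (lo, hi), coef in zip(_AGE_BANDS, coefs):
            cells.append(
                DemographicCell(
                    sex=sex,
                    age_lo=lo,
                    age_hi=hi,
                    coefficients={
                        Variant.COMMUNITY.value: coef,
                        Variant.INSTITUTIONAL.value: coef + _INSTITUTIONAL_DEMOGRAPHIC_OFFSET,
                    },
                )
            )
    return RiskModelSpec(
        icd_to_cc={k: frozenset(v) for k, v in icd_to_cc.items()},
        hierarchies=tuple(HierarchyRule(d, frozenset(s)) for d, s in _HIERARCHIES),
        demographic_cells=tuple(cells),
        cc_coefficients={
            Variant.COMMUNITY.value: {cc: coef for cc, (_, coef, _) in _CC_TABLE.items()},
            Variant.INSTITUTIONAL.value: {
                cc: coef * _INSTITUTIONAL_FACTOR for cc, (_, coef, _) in _CC_TABLE.items()
            },
        },
        mh_hccs=MH_HCCS,
        scale="dollar",
    )


def default_codelist() -> PsyCMSCodeList:
    """The synthetic fixture 47-category psychiatric code list."""
    code_to_categories: dict[str, set[str]] = {}
    for cat, (_, _, codes, _, _) in _PSYCH_TABLE.items():
        for code in codes:
            code_to_categories.setdefault(code, set()).add(cat)
    return PsyCMSCodeList(
        categories={cat: name for cat, (name, _, _, _, _) in _PSYCH_TABLE.items()},
        code_to_categories={k: frozenset(v) for k, v in code_to_categories.items()},
        flag_definitions={k: frozenset(v) for k, v in _FLAG_DEFINITIONS.items()},
    )


# ---------------------------------------------------------------------------
# Generator configuration


class MispricingMode(str, enum.Enum):
    NONE = "NONE"
    MH_UNPRICED = "MH_UNPRICED"
    DEMENTIA_CUSTODIAL = "DEMENTIA_CUSTODIAL"


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the reference population: 93.5% male, age ~ N(63, 16.1^2)
    truncated to [22, 100], diabetes 22.1%, PTSD 10.4%, dementia 0.8%, mean
    annual cost near $12k with median below half the mean. `sigma` is the
    lognormal noise scale of the mean-one multiplicative cost noise;
    `latent_rho` is the shared-propensity correlation that clusters
    psychiatric comorbidity. Psychiatric increments default to zero (the
    exactly-priced world); use inject_mispricing to turn on a mispricing
    channel.
    """

    n: int = 100_000
    seed: int = 12345
    cost_year: int = 2012
    prop_male: float = 0.935
    age_mean: float = 63.0
    age_sd: float = 16.1
    age_min: int = 22
    age_max: int = 100
    sigma: float = 0.65
    latent_rho: float = 0.45
    diabetes_prevalence: float = 0.221
    diabetes_complicated_share: float = 0.32
    medical_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(_MEDICAL_PREVALENCE)
    )
    psych_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {cat: p for cat, (_, p, _, _, _) in _PSYCH_TABLE.items()}
    )
    psych_increments: Mapping[str, float] = field(
        default_factory=lambda: {cat: 0.0 for cat in _PSYCH_TABLE}
    )
    dementia_custodial_per_diem: float = 0.0
    custodial_ltc_coupling: bool = False
    medication_only_rate: float = 0.015
    no_va_use_rate: float = 0.005
    unmapped_code_rate: float = 0.20
    duplicate_dx_rate: float = 0.25
    medicare_dx_share: float = 0.30
    medicare_ramp: float = 0.045  # Medicare cost share slope per year of age past 64
    medicare_share_cap: float = 0.70

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ConfigError("n must be at least 10")
        if self.sigma < 0:
            raise ConfigError("sigma must be non-negative")
        if not (0 <= self.latent_rho < 1):
            raise ConfigError("latent_rho must lie in [0, 1)")
        rates = {
            "prop_male": self.prop_male,
            "diabetes_prevalence": self.diabetes_prevalence,
            "diabetes_complicated_share": self.diabetes_complicated_share,
            "medication_only_rate": self.medication_only_rate,
            "no_va_use_rate": self.no_va_use_rate,
            "unmapped_code_rate": self.unmapped_code_rate,
            "duplicate_dx_rate": self.duplicate_dx_rate,
            "medicare_dx_share": self.medicare_dx_share,
        }
        rates.update({f"medical[{k}]": v for k, v in self.medical_prevalence.items()})
        rates.update({f"psych[{k}]": v for k, v in self.psych_prevalence.items()})
        for name, value in rates.items():
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"prevalence/rate {name} = {value} outside [0, 1]")
        for cat, inc in self.psych_increments.items():
            if not np.isfinite(inc):
                raise ConfigError(f"psychiatric increment for {cat} is not finite")
        unknown = set(self.psych_prevalence) - set(_PSYCH_TABLE)
        if unknown:
            raise ConfigError(f"unknown psychiatric categories: {sorted(unknown)}")

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["medical_prevalence"] = dict(self.medical_prevalence)
        doc["psych_prevalence"] = dict(self.psych_prevalence)
        doc["psych_increments"] = dict(self.psych_increments)
        return doc

    @classmethod
    def from_dict(cls, doc: Mapping) -> "GeneratorConfig":
        return cls(**doc)


def inject_mispricing(config: GeneratorConfig, mode: MispricingMode | str) -> GeneratorConfig:
    """Return a config differing from `config` only in the stated mispricing channel."""
    mode = MispricingMode(mode)
    if mode is MispricingMode.NONE:
        return dataclasses.replace(
            config,
            psych_increments={cat: 0.0 for cat in _PSYCH_TABLE},
            dementia_custodial_per_diem=0.0,
            custodial_ltc_coupling=False,
        )
    if mode is MispricingMode.MH_UNPRICED:
        return dataclasses.replace(
            config,
            psych_increments=dict(DEFAULT_PSYCH_INCREMENTS),
            dementia_custodial_per_diem=0.0,
            custodial_ltc_coupling=False,
        )
    if mode is MispricingMode.DEMENTIA_CUSTODIAL:
        return dataclasses.replace(
            config,
            psych_increments={cat: 0.0 for cat in _PSYCH_TABLE},
            dementia_custodial_per_diem=250.0,
            custodial_ltc_coupling=True,
        )
    raise ConfigError(f"unknown mispricing mode {mode!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Generation


@dataclass
class SyntheticData:
    """One generated population: raw claim tables, the assembled cohort,
    per-patient ground truth, and the fixture specification bundles."""

    config: GeneratorConfig
    tables: ClaimsTables
    cohort: Cohort
    truth: pd.DataFrame  # all generated patients, including excluded ones
    model_spec: RiskModelSpec
    codelist: PsyCMSCodeList

    def truth_for_cohort(self) -> pd.DataFrame:
        """Ground-truth rows aligned to the assembled cohort's patient order."""
        t = self.truth.set_index("patient_id")
        return t.loc[self.cohort.patient_ids].reset_index()


def generate(config: GeneratorConfig) -> SyntheticData:
    """Generate a synthetic population; fully deterministic given the config seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    spec = default_model_spec()
    codelist = default_codelist()
    dx_year = config.cost_year - 1

    ids = np.array([f"P{i:07d}" for i in range(1, n + 1)])
    sexes = np.where(rng.random(n) < config.prop_male, "M", "F")
    ages = np.clip(
        np.round(rng.normal(config.age_mean, config.age_sd, n)), config.age_min, config.age_max
    ).astype(int)

    # psychiatric categories via a Gaussian copula: one shared latent propensity
    # per patient clusters comorbidity (latent correlation latent_rho)
    psych_cats = list(_PSYCH_TABLE)
    z = rng.standard_normal(n)
    rho = config.latent_rho
    psych = np.zeros((n, len(psych_cats)), dtype=bool)
    for j, cat in enumerate(psych_cats):
        p = config.psych_prevalence.get(cat, 0.0)
        if p <= 0.0:
            continue
        x = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * rng.standard_normal(n)
        psych[:, j] = x > stats.norm.ppf(1.0 - p)

    # medical conditions: independent draws; diabetes split into complicated /
    # uncomplicated, with half of complicated patients also carrying an
    # uncomplicated code (exercises hierarchy imposition downstream)
    diabetic = rng.random(n) < config.diabetes_prevalence
    complicated = diabetic & (rng.random(n) < config.diabetes_complicated_share)
    uncomplicated = diabetic & ~complicated
    extra_uncomp_code = complicated & (rng.random(n) < 0.5)
    medical = {
        cc: rng.random(n) < p for cc, p in config.medical_prevalence.items()
    }

    # raw condition-category matrix implied by the codes each patient will emit
    cc_cols = sorted(spec.all_ccs)
    raw = pd.DataFrame(False, index=ids, columns=cc_cols)
    raw["CC18"] = complicated
    raw["CC19"] = uncomplicated | extra_uncomp_code
    for cc, present in medical.items():
        raw[cc] = raw[cc].to_numpy() | present
    for j, cat in enumerate(psych_cats):
        cc = _PSYCH_TABLE[cat][3]
        if cc is not None:
            raw[cc] = raw[cc].to_numpy() | psych[:, j]

    dementia = psych[:, psych_cats.index("dementia")]

    # long-term-care days; in the custodial channel dementia LTC days grow
    # with clinical risk (sicker dementia patients stay institutionalized longer)
    ltc = np.zeros(n, dtype=int)
    some_ltc = rng.random(n) < 0.004
    ltc[some_ltc] = rng.integers(1, 121, size=int(some_ltc.sum()))
    dem_noise = rng.normal(0.0, 15.0, n)
    base_dem_days = np.clip(np.round(rng.normal(60.0, 60.0, n)), 0, 365).astype(int)
    if config.custodial_ltc_coupling:
        community_score, _, _ = score_from_cc_matrix(raw, ages, sexes, np.zeros(n, dtype=int), spec)
        dem_days = np.clip(np.round(20.0 + community_score / 90.0 + dem_noise), 0, 365).astype(int)
    else:
        dem_days = base_dem_days
    ltc[dementia] = dem_days[dementia]

    # ground-truth score and expected cost
    true_score, post, variants = score_from_cc_matrix(raw, ages, sexes, ltc, spec)
    increments = np.array([config.psych_increments.get(cat, 0.0) for cat in psych_cats])
    psych_lift = psych.astype(float) @ increments
    custodial = np.where(dementia, ltc * config.dementia_custodial_per_diem, 0.0)
    clinical_mu = true_score + psych_lift

    eps = config.sigma * rng.standard_normal(n) - config.sigma**2 / 2.0
    clinical_cost = clinical_mu * np.exp(eps)
    total_cents = np.round((clinical_cost + custodial) * 100.0).astype(np.int64)

    share = np.where(
        ages >= 65,
        np.minimum(config.medicare_share_cap, config.medicare_ramp * (ages - 64)),
        0.0,
    )
    medicare_cents = np.floor(total_cents * share).astype(np.int64)
    va_cents = total_cents - medicare_cents

    medication_only = rng.random(n) < config.medication_only_rate
    any_va_use = rng.random(n) >= config.no_va_use_rate

    # --- diagnosis events ---------------------------------------------------
    cond_codes: list[tuple[np.ndarray, tuple[str, ...]]] = [
        (complicated, _CC_TABLE["CC18"][2]),
        (uncomplicated, _CC_TABLE["CC19"][2]),
        (extra_uncomp_code, _CC_TABLE["CC19"][2]),
    ]
    for cc, present in medical.items():
        cond_codes.append((present, _CC_TABLE[cc][2]))
    for j, cat in enumerate(psych_cats):
        cond_codes.append((psych[:, j], _PSYCH_TABLE[cat][2]))

    pid_parts: list[np.ndarray] = []
    code_parts: list[np.ndarray] = []
    for present, codes in cond_codes:
        idx = np.flatnonzero(present)
        if len(idx) == 0:
            continue
        chosen = np.asarray(codes)[rng.integers(0, len(codes), size=len(idx))]
        dup = rng.random(len(idx)) < config.duplicate_dx_rate
        pid_parts.extend([ids[idx], ids[idx[dup]]])
        code_parts.extend([chosen, chosen[dup]])
    junk = rng.random(n) < config.unmapped_code_rate
    pid_parts.append(ids[junk])
    code_parts.append(np.full(int(junk.sum()), UNMAPPED_CODE))

    dx_pid = np.concatenate(pid_parts)
    dx_code = np.concatenate(code_parts)
    n_events = len(dx_pid)
    day_offsets = rng.integers(0, 365, size=n_events)
    dx_dates = (
        pd.Timestamp(f"{dx_year}-01-01") + pd.to_timedelta(day_offsets, unit="D")
    ).date
    age_by_pid = dict(zip(ids, ages))
    event_ages = np.array([age_by_pid[p] for p in dx_pid])
    medicare_src = (event_ages >= 65) & (rng.random(n_events) < config.medicare_dx_share)
    dx_source = np.where(medicare_src, "MEDICARE", "VA")

    diagnoses = pd.DataFrame(
        {"patient_id": dx_pid, "code": dx_code, "service_date": dx_dates, "source": dx_source}
    ).sort_values(["patient_id", "service_date", "code"], kind="stable").reset_index(drop=True)

    # --- cost records: VA plus a Medicare A/B/D split -----------------------
    med_a = np.floor(medicare_cents * 0.6).astype(np.int64)
    med_b = np.floor(medicare_cents * 0.3).astype(np.int64)
    med_d = medicare_cents - med_a - med_b
    cost_frames = [
        pd.DataFrame({"patient_id": ids, "payer": "VA", "amount_cents": va_cents}),
        pd.DataFrame({"patient_id": ids, "payer": "MEDICARE_A", "amount_cents": med_a}),
        pd.DataFrame({"patient_id": ids, "payer": "MEDICARE_B", "amount_cents": med_b}),
        pd.DataFrame({"patient_id": ids, "payer": "MEDICARE_D", "amount_cents": med_d}),
    ]
    costs = pd.concat(cost_frames, ignore_index=True)
    costs = costs.loc[(costs["amount_cents"] > 0) | (costs["payer"] == "VA")].copy()
    costs["year"] = config.cost_year
    costs = costs.sort_values(["patient_id", "payer"], kind="stable").reset_index(drop=True)

    demographics = pd.DataFrame(
        {
            "patient_id": ids,
            "age": ages,
            "sex": sexes,
            "ltc_days": ltc,
            "medication_only": medication_only,
            "any_va_use": any_va_use,
        }
    )

    tables = ClaimsTables(
        diagnoses=diagnoses, costs=costs, demographics=demographics, report=ParseReport()
    )
    cohort = assemble_cohort(
        tables, CohortConfig(cost_year=config.cost_year, diagnosis_year=dx_year)
    )

    truth = pd.DataFrame(
        {
            "patient_id": ids,
            "age": ages,
            "sex": sexes,
            "variant": variants,
            "true_score": true_score,
            "psych_lift": psych_lift,
            "custodial_cost": custodial,
            "expected_cost": clinical_mu + custodial,
            "total_cost": total_cents / 100.0,
            "ltc_days": ltc,
            "dementia": dementia,
            "included": ~medication_only & any_va_use,
        }
    )
    return SyntheticData(
        config=config,
        tables=tables,
        cohort=cohort,
        truth=truth,
        model_spec=spec,
        codelist=codelist,
    )


def write_files(synth: SyntheticData, outdir: str | Path) -> dict[str, Path]:
    """Write the full bundle: claim files, model spec, code list, truth, config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = write_cohort_files(synth.tables, outdir / "claims")
    paths["model_spec"] = write_model_spec(synth.model_spec, outdir / "model_spec")
    paths["psycms"] = write_codelist(synth.codelist, outdir / "psycms")
    truth_path = outdir / "truth.csv"
    synth.truth.to_csv(truth_path, index=False)
    paths["truth"] = truth_path
    config_path = outdir / "generator_config.json"
    config_path.write_text(json.dumps(synth.config.to_dict(), indent=2, sort_keys=True))
    paths["config"] = config_path
    return paths
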