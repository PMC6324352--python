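import datetime as dt

import pytest

from riskcalib.claims_data import DiagnosisEvent, DxSource, PatientYearRecord
from riskcalib.hcc_engine import DemographicCell, HierarchyRule, RiskModelSpec, Variant
from riskcalib.synthetic_data import GeneratorConfig, default_codelist, default_model_spec, generate


def make_event(code: str, patient_id: str = "P1", day: int = 15) -> DiagnosisEvent:
    return DiagnosisEvent(patient_id, code, dt.date(2011, 3, day % 28 + 1), DxSource.VA)


def make_record(
    patient_id="P1", age=65, sex="M", codes=(), ltc_days=0, va_cents=0, medicare_cents=0
) -> PatientYearRecord:
    return PatientYearRecord(
        patient_id=patient_id,
        age=age,
        sex=sex,
        diagnoses=tuple(make_event(c, patient_id, i) for i, c in enumerate(codes)),
        va_cost_cents=va_cents,
        medicare_cost_cents=medicare_cents,
        ltc_days=ltc_days,
    )


@pytest.fixture(scope="session")
def tiny_spec() -> RiskModelSpec:
    """Five condition categories, chained hierarchy rules A>B and B>C, male
    demographic bands only (female lookups must fail)."""
    variants = (Variant.COMMUNITY.value, Variant.INSTITUTIONAL.value)
    return RiskModelSpec(
        icd_to_cc={
            "C1": frozenset({"A"}),
            "C2": frozenset({"B"}),
            "C3": frozenset({"C"}),
            "C4": frozenset({"D"}),
            "C5": frozenset({"E"}),
        },
        hierarchies=(
            HierarchyRule("A", frozenset({"B"})),
            HierarchyRule("B", frozenset({"C"})),
        ),
        demographic_cells=(
            DemographicCell("M", 0, 60, {v: 0.20 for v in variants}),
            DemographicCell("M", 60, 69, {v: 0.40 for v in variants}),
            DemographicCell("M", 69, 130, {v: 0.60 for v in variants}),
        ),
        cc_coefficients={
            Variant.COMMUNITY.value: {"A": 0.30, "B": 0.25, "C": 0.20, "D": 0.25, "E": 0.10},
            Variant.INSTITUTIONAL.value: {"A": 0.60, "B": 0.50, "C": 0.40, "D": 0.50, "E": 0.20},
        },
        mh_hccs=frozenset({"E"}),
    )


@pytest.fixture(scope="session")
def default_spec():
    return default_model_spec()


@pytest.fixture(scope="session")
def default_codes():
    return default_codelist()


@pytest.fixture(scope="session")
def small_synth():
    """A small exactly-priced synthetic population shared across tests."""
    return generate(GeneratorConfig(n=4000, seed=11))


@pytest.fixture(scope="session")
def big_synth():
    """Default-condition population at the reference evaluation size."""
    return generate(GeneratorConfig(n=100_000, seed=12345))
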