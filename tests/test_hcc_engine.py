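import itertools

import numpy as np
import pytest

from riskcalib.hcc_engine import (
    DemographicCell,
    HierarchyRule,
    ModelSpecError,
    NoBandError,
    RiskModelSpec,
    Variant,
    compute_risk_score,
    demographic_coefficient,
    has_mh_hcc,
    impose_hierarchies,
    load_model_spec,
    map_diagnoses,
    score_cohort,
    write_model_spec,
)

from conftest import make_event, make_record


def brute_force_hierarchy(ccs, rules):
    """Independent oracle: keep a category unless some rule whose dominant is
    in the ORIGINAL input lists it as suppressed."""
    out = set()
    for cc in ccs:
        suppressed = False
        for dominant, subordinates in rules:
            if dominant in ccs and cc in subordinates:
                suppressed = True
        if not suppressed:
            out.add(cc)
    return frozenset(out)


class TestBundleIO:
    def test_round_trip(self, default_spec, tmp_path):
        write_model_spec(default_spec, tmp_path)
        loaded = load_model_spec(tmp_path)
        assert loaded.icd_to_cc == default_spec.icd_to_cc
        assert loaded.cc_coefficients == default_spec.cc_coefficients
        assert loaded.mh_hccs == default_spec.mh_hccs
        assert loaded.hierarchies == default_spec.hierarchies
        assert loaded.demographic_cells == default_spec.demographic_cells

    def test_missing_file_error(self, tmp_path):
        with pytest.raises(ModelSpecError, match="manifest.json"):
            load_model_spec(tmp_path)


class TestSpecValidation:
    def _cells(self):
        v = (Variant.COMMUNITY.value, Variant.INSTITUTIONAL.value)
        return (DemographicCell("M", 0, 130, {k: 1.0 for k in v}),)

    def _coefs(self, ccs):
        return {
            Variant.COMMUNITY.value: {c: 1.0 for c in ccs},
            Variant.INSTITUTIONAL.value: {c: 1.0 for c in ccs},
        }

    def test_unknown_cc_named(self):
        with pytest.raises(ModelSpecError, match="CC99"):
            RiskModelSpec(
                icd_to_cc={},
                hierarchies=(HierarchyRule("CC99", frozenset({"A"})),),
                demographic_cells=self._cells(),
                cc_coefficients=self._coefs(["A"]),
                mh_hccs=frozenset(),
            )

    def test_cycle_error(self):
        with pytest.raises(ModelSpecError, match="cycle"):
            RiskModelSpec(
                icd_to_cc={},
                hierarchies=(
                    HierarchyRule("A", frozenset({"B"})),
                    HierarchyRule("B", frozenset({"A"})),
                ),
                demographic_cells=self._cells(),
                cc_coefficients=self._coefs(["A", "B"]),
                mh_hccs=frozenset(),
            )

    def test_missing_coefficient_named(self):
        with pytest.raises(ModelSpecError, match="B"):
            RiskModelSpec(
                icd_to_cc={"X1": frozenset({"A", "B"})},
                hierarchies=(),
                demographic_cells=self._cells(),
                cc_coefficients=self._coefs(["A"]),
                mh_hccs=frozenset(),
            )

    def test_overlapping_bands_rejected(self):
        v = (Variant.COMMUNITY.value, Variant.INSTITUTIONAL.value)
        cells = (
            DemographicCell("M", 0, 70, {k: 1.0 for k in v}),
            DemographicCell("M", 60, 130, {k: 1.0 for k in v}),
        )
        with pytest.raises(ModelSpecError, match="overlap"):
            RiskModelSpec(
                icd_to_cc={},
                hierarchies=(),
                demographic_cells=cells,
                cc_coefficients=self._coefs([]),
                mh_hccs=frozenset(),
            )


class TestMapping:
    def test_empty_list(self, tiny_spec):
        assert map_diagnoses([], tiny_spec).ccs == frozenset()

    def test_set_semantics_and_unmapped_count(self, tiny_spec):
        events = [make_event("C1"), make_event("C1"), make_event("C2"), make_event("ZZZ")]
        result = map_diagnoses(events, tiny_spec)
        assert result.ccs == frozenset({"A", "B"})
        assert result.n_unmapped == 1
        assert result.unmapped_codes["ZZZ"] == 1

    def test_monotone_in_diagnoses(self, tiny_spec):
        events = [make_event(c) for c in ("C1", "C2", "C3", "ZZZ", "C4")]
        prev = frozenset()
        for k in range(len(events) + 1):
            ccs = map_diagnoses(events[:k], tiny_spec).ccs
            assert prev <= ccs
            prev = ccs


class TestHierarchy:
    def test_identity_and_definition(self, tiny_spec):
        assert impose_hierarchies(frozenset(), tiny_spec) == frozenset()
        assert impose_hierarchies({"A", "B"}, tiny_spec) == frozenset({"A"})

    def test_chained_rules_fire_from_original_set(self, tiny_spec):
        # B is in the original input, so B's rule suppresses C even though A
        # suppresses B itself
        assert impose_hierarchies({"A", "B", "C"}, tiny_spec) == frozenset({"A"})
        assert impose_hierarchies({"B", "C"}, tiny_spec) == frozenset({"B"})

    def test_matches_bruteforce_on_all_subsets(self, tiny_spec):
        rules = [(r.dominant, r.suppressed) for r in tiny_spec.hierarchies]
        universe = ["A", "B", "C", "D", "E"]
        for k in range(len(universe) + 1):
            for subset in itertools.combinations(universe, k):
                got = impose_hierarchies(frozenset(subset), tiny_spec)
                assert got == brute_force_hierarchy(frozenset(subset), rules)

    def test_subset_and_idempotent(self, tiny_spec):
        for subset in ({"A", "B", "C"}, {"B", "C", "E"}, {"C"}, set("ABCDE")):
            once = impose_hierarchies(frozenset(subset), tiny_spec)
            assert once <= frozenset(subset)
            assert impose_hierarchies(once, tiny_spec) == once


class TestDemographics:
    def test_band_lookup_and_half_open_convention(self, tiny_spec):
        assert demographic_coefficient(65, "M", Variant.COMMUNITY, tiny_spec) == 0.40
        # age equal to a band's upper edge belongs to the lower band
        assert demographic_coefficient(69, "M", Variant.COMMUNITY, tiny_spec) == 0.40
        assert demographic_coefficient(70, "M", Variant.COMMUNITY, tiny_spec) == 0.60

    def test_no_band_error(self, tiny_spec):
        with pytest.raises(NoBandError):
            demographic_coefficient(65, "F", Variant.COMMUNITY, tiny_spec)


class TestScoring:
    def test_demographic_only(self, tiny_spec):
        profile = compute_risk_score(make_record(codes=()), tiny_spec)
        assert profile.score == 0.40
        assert profile.hccs == frozenset()

    def test_additive_sum(self, tiny_spec):
        # demographic 0.40 plus two unrelated categories 0.30 + 0.25
        profile = compute_risk_score(make_record(codes=("C1", "C4")), tiny_spec)
        assert profile.score == pytest.approx(0.95)

    def test_removing_an_hcc_removes_its_coefficient(self, tiny_spec):
        with_both = compute_risk_score(make_record(codes=("C1", "C4")), tiny_spec)
        without_d = compute_risk_score(make_record(codes=("C1",)), tiny_spec)
        assert with_both.score - without_d.score == pytest.approx(0.25)

    def test_ltc_threshold_strictly_greater_than_90(self, tiny_spec):
        assert compute_risk_score(make_record(ltc_days=90), tiny_spec).variant is Variant.COMMUNITY
        prof = compute_risk_score(make_record(ltc_days=91), tiny_spec)
        assert prof.variant is Variant.INSTITUTIONAL
        assert prof.score == 0.40  # institutional demographic in the tiny fixture

    def test_has_mh_hcc(self, tiny_spec):
        mh = compute_risk_score(make_record(codes=("C5",)), tiny_spec)
        assert has_mh_hcc(mh, tiny_spec)
        assert not has_mh_hcc(compute_risk_score(make_record(codes=()), tiny_spec), tiny_spec)
        assert not has_mh_hcc(compute_risk_score(make_record(codes=("C1",)), tiny_spec), tiny_spec)


class TestBatchScoring:
    def test_batch_matches_scalar_path(self, small_synth):
        cohort = small_synth.cohort
        profiles, _ = score_cohort(cohort, small_synth.model_spec)
        for record, batch in zip(cohort.records[:300], profiles[:300]):
            scalar = compute_risk_score(record, small_synth.model_spec)
            assert batch.score == scalar.score
            assert batch.hccs == scalar.hccs
            assert batch.raw_ccs == scalar.raw_ccs
            assert batch.variant is scalar.variant
            assert batch.n_unmapped == scalar.n_unmapped

    def test_batch_matches_generator_truth(self, small_synth):
        profiles, _ = score_cohort(small_synth.cohort, small_synth.model_spec)
        truth = small_synth.truth_for_cohort()
        assert np.array_equal(
            np.array([p.score for p in profiles]), truth["true_score"].to_numpy()
        )
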