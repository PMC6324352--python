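import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskcalib._util import percent
from riskcalib.hcc_engine import has_mh_hcc, score_cohort
from riskcalib.psycms_grouper import (
    N_CATEGORIES,
    CodeListError,
    PsyCMSCodeList,
    classify,
    classify_cohort,
    load_codelist,
    missed_mh_analysis,
    write_codelist,
)

from conftest import make_event


class TestCodeList:
    def test_exactly_47_categories_enforced(self, default_codes):
        assert len(default_codes.categories) == N_CATEGORIES
        with pytest.raises(CodeListError, match="47"):
            PsyCMSCodeList(
                categories={"a": "A"}, code_to_categories={}, flag_definitions={}
            )

    def test_flags_reference_known_categories(self, default_codes):
        with pytest.raises(CodeListError, match="nope"):
            PsyCMSCodeList(
                categories=default_codes.categories,
                code_to_categories=default_codes.code_to_categories,
                flag_definitions={"bad": frozenset({"nope"})},
            )

    def test_round_trip(self, default_codes, tmp_path):
        write_codelist(default_codes, tmp_path)
        loaded = load_codelist(tmp_path)
        assert loaded.categories == default_codes.categories
        assert loaded.code_to_categories == default_codes.code_to_categories
        assert loaded.flag_definitions == default_codes.flag_definitions


class TestClassify:
    def test_empty_event_list(self, default_codes):
        profile = classify([], default_codes, patient_id="P1")
        assert profile.categories == frozenset()
        assert not any(profile.flags.values())

    def test_ptsd_flag_union(self, default_codes):
        profile = classify([make_event("30981")], default_codes)
        assert profile.categories == frozenset({"ptsd"})
        assert profile.flags["ptsd"] and profile.flags["any_mh_sa"]
        assert not profile.flags["mood_disorder"]

    def test_two_categories_two_flags(self, default_codes):
        profile = classify([make_event("311"), make_event("3051")], default_codes)
        assert profile.categories == frozenset({"depression_nos", "nicotine_dependence"})
        assert profile.flags["mood_disorder"] and profile.flags["nicotine_dependence"]

    def test_unmapped_ignored(self, default_codes):
        profile = classify([make_event("V7009")], default_codes)
        assert profile.categories == frozenset()

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.permutations(["30981", "311", "3051", "2950", "V7009", "25000"]))
    def test_permutation_invariant(self, codes):
        from riskcalib.synthetic_data import default_codelist

        codelist = default_codelist()
        events = [make_event(c, day=i) for i, c in enumerate(codes)]
        baseline = classify([make_event(c, day=i) for i, c in enumerate(sorted(codes))], codelist)
        assert classify(events, codelist).categories == baseline.categories


class TestMissedAnalysis:
    def test_percent_column_arithmetic(self):
        # percentages from published missed-diagnosis counts
        assert percent(509_926, 1_266_938) == 40.2
        assert percent(396_062, 1_266_938) == 31.3
        assert percent(345_338, 1_266_938) == 27.3

    def test_missed_table_on_synthetic_cohort(self, small_synth):
        cohort = small_synth.cohort
        hcc, _ = score_cohort(cohort, small_synth.model_spec)
        psy = classify_cohort(cohort, small_synth.codelist)
        table = missed_mh_analysis(cohort, hcc, psy, small_synth.model_spec, small_synth.codelist, top_n=10)

        spec = small_synth.model_spec
        expected_denominator = sum(
            1 for h, p in zip(hcc, psy) if p.categories and not has_mh_hcc(h, spec)
        )
        assert table.denominator == expected_denominator
        assert len(table.rows) == 10
        counts = [c for _, c, _ in table.rows]
        assert counts == sorted(counts, reverse=True)
        for _, count, pct in table.rows:
            assert count <= table.denominator
            assert pct == percent(count, table.denominator)

    def test_ties_break_alphabetically(self, default_codes, small_synth):
        # two patients, each with one distinct unpriced category and no MH HCC
        from riskcalib.claims_data import Cohort

        from conftest import make_record

        records = [
            make_record("P1", codes=("30981",)),  # PTSD
            make_record("P2", codes=("30000",)),  # anxiety
        ] + [make_record(f"P{i}", codes=()) for i in range(3, 13)]
        cohort = Cohort(records, 2012, 2011)
        hcc, _ = score_cohort(cohort, small_synth.model_spec)
        psy = classify_cohort(cohort, small_synth.codelist)
        table = missed_mh_analysis(cohort, hcc, psy, small_synth.model_spec, small_synth.codelist, top_n=2)
        assert table.denominator == 2
        assert [name for name, _, _ in table.rows] == ["Anxiety disorder", "Posttraumatic stress disorder"]

    def test_empty_missed_set(self, small_synth):
        from riskcalib.claims_data import Cohort

        from conftest import make_record

        # every psychiatric patient also carries a priced MH category
        records = [make_record("P1", codes=("30981", "2950"))] + [
            make_record(f"P{i}") for i in range(2, 12)
        ]
        cohort = Cohort(records, 2012, 2011)
        hcc, _ = score_cohort(cohort, small_synth.model_spec)
        psy = classify_cohort(cohort, small_synth.codelist)
        table = missed_mh_analysis(cohort, hcc, psy, small_synth.model_spec, small_synth.codelist)
        assert table.denominator == 0 and table.rows == []

    def test_partition_property(self, small_synth):
        """Patients with any psychiatric category split disjointly into
        (has MH HCC) and (missed)."""
        cohort = small_synth.cohort
        spec = small_synth.model_spec
        hcc, _ = score_cohort(cohort, spec)
        psy = classify_cohort(cohort, small_synth.codelist)
        any_psy = np.array([bool(p.categories) for p in psy])
        mh_hcc = np.array([has_mh_hcc(h, spec) for h in hcc])
        table = missed_mh_analysis(cohort, hcc, psy, spec, small_synth.codelist)
        assert table.denominator == int((any_psy & ~mh_hcc).sum())
        assert int(any_psy.sum()) == int((any_psy & mh_hcc).sum()) + table.denominator
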