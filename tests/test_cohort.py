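"""Case deduplication, drug-name matching, and cohort selection."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_casedata, make_demo
from faersig.cohort import (
    CohortError,
    NameMatcher,
    build_case,
    deduplicate,
    exclude_socs,
    match_target,
    select_cohort,
)


class TestDeduplicate:
    def test_latest_fda_date_wins(self):
        demo = make_demo([
            {"primaryid": "1001", "caseid": "100", "fda_dt": "20200101"},
            {"primaryid": "1002", "caseid": "100", "fda_dt": "20200301"},
        ])
        out = deduplicate(demo)
        assert out["primaryid"].tolist() == ["1002"]

    def test_fda_date_tie_broken_by_larger_primaryid(self):
        demo = make_demo([
            {"primaryid": "1003", "caseid": "100", "fda_dt": "20200301"},
            {"primaryid": "1002", "caseid": "100", "fda_dt": "20200301"},
        ])
        out = deduplicate(demo)
        assert out["primaryid"].tolist() == ["1003"]

    def test_primaryid_compared_numerically_not_lexicographically(self):
        demo = make_demo([
            {"primaryid": "999", "caseid": "7", "fda_dt": "20200301"},
            {"primaryid": "1002", "caseid": "7", "fda_dt": "20200301"},
        ])
        out = deduplicate(demo)  # "999" > "1002" as text, 999 < 1002 as numbers
        assert out["primaryid"].tolist() == ["1002"]

    def test_distinct_caseids_pass_through(self):
        demo = make_demo([
            {"primaryid": str(1000 + i), "caseid": str(i), "fda_dt": "20200101"}
            for i in range(5)
        ])
        out = deduplicate(demo)
        assert sorted(out["primaryid"]) == sorted(demo["primaryid"])

    def test_missing_caseid_kept_as_singleton(self):
        demo = make_demo([
            {"primaryid": "1001", "caseid": "", "fda_dt": "20200101"},
            {"primaryid": "1002", "caseid": "", "fda_dt": "20200301"},
        ])
        out = deduplicate(demo)
        assert len(out) == 2  # not merged into one case

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(1, 5), st.integers(1, 28), st.integers(1, 9999)),
            min_size=1, max_size=30, unique_by=lambda t: t[2],
        ),
        st.randoms(use_true_random=False),
    )
    def test_idempotent_and_order_invariant(self, rows, rnd):
        demo = make_demo([
            {"caseid": str(cid), "fda_dt": f"202001{day:02d}", "primaryid": str(pid)}
            for cid, day, pid in rows
        ])
        once = deduplicate(demo)
        assert deduplicate(once).equals(once)
        shuffled = demo.sample(frac=1, random_state=rnd.randint(0, 10**6))
        assert deduplicate(shuffled).equals(once)
        assert once["caseid"].is_unique


class TestNameMatcher:
    matcher = NameMatcher()

    @pytest.mark.parametrize(
        "name, hit",
        [
            ("MYRBETRIQ", True),
            ("Mirabegron 50 MG Tablet", True),
            ("betmiga", True),
            ("MIRTAZAPINE", False),
            ("XMIRABEGRONY", False),  # word boundary required
            ("", False),
        ],
    )
    def test_word_bounded_case_insensitive(self, name, hit):
        assert self.matcher.matches(name) is hit

    def test_matches_active_ingredient_field(self):
        drugs = pd.DataFrame([
            {"drug_seq": "1", "drugname": "SOME BRAND", "prod_ai": "MIRABEGRON"},
            {"drug_seq": "2", "drugname": "ASPIRIN", "prod_ai": ""},
        ])
        assert match_target(drugs, self.matcher) == {"1"}

    def test_empty_patterns_rejected(self):
        with pytest.raises(ValueError):
            NameMatcher(patterns=())


def _three_case_data():
    return make_casedata(
        demo=[
            {"primaryid": "1", "caseid": "1", "occp_cod": "MD"},
            {"primaryid": "2", "caseid": "2", "occp_cod": "CN"},
            {"primaryid": "3", "caseid": "3", "occp_cod": "PH"},
        ],
        drug=[
            {"primaryid": "1", "drugname": "MYRBETRIQ", "role_cod": "PS"},
            {"primaryid": "2", "drugname": "MIRABEGRON", "role_cod": "PS"},
            {"primaryid": "3", "drugname": "MIRABEGRON", "role_cod": "SS"},
            {"primaryid": "3", "drugname": "WARFARIN", "role_cod": "PS"},
        ],
    )


class TestSelectCohort:
    def test_ps_and_hcp_required(self):
        split = select_cohort(_three_case_data())
        assert list(split.target_ids) == ["1"]      # MD + PS
        # case 2 is a consumer report: excluded from both strata
        assert list(split.background_ids) == ["3"]  # SS-only target drug

    def test_partition_is_exhaustive_over_filtered_cases(self, small_dataset):
        _, _, data, split = small_dataset
        hcp = data.demo["occp_cod"].isin({"MD", "PH", "OT"}).sum()
        assert split.n_target + split.n_background == hcp

    def test_adding_reporter_code_grows_strata(self, small_dataset):
        _, _, data, _ = small_dataset
        base = select_cohort(data, reporter_codes=("MD", "PH", "OT"))
        wider = select_cohort(data, reporter_codes=("MD", "PH", "OT", "HP"))
        assert wider.n_target >= base.n_target
        assert wider.n_background >= base.n_background

    def test_strict_ps_drops_reports_with_other_suspects(self):
        data = make_casedata(
            demo=[{"primaryid": "1", "caseid": "1", "occp_cod": "MD"},
                  {"primaryid": "2", "caseid": "2", "occp_cod": "MD"}],
            drug=[
                {"primaryid": "1", "drugname": "MYRBETRIQ", "role_cod": "PS"},
                {"primaryid": "2", "drugname": "MYRBETRIQ", "role_cod": "PS"},
                {"primaryid": "2", "drug_seq": "2", "drugname": "WARFARIN", "role_cod": "PS"},
            ],
        )
        lenient = select_cohort(data)
        strict = select_cohort(data, strict_ps=True)
        assert set(lenient.target_ids) == {"1", "2"}
        assert set(strict.target_ids) == {"1"}

    def test_empty_target_cohort_is_hard_error(self):
        data = make_casedata(
            demo=[{"primaryid": "1", "caseid": "1", "occp_cod": "MD"}],
            drug=[{"primaryid": "1", "drugname": "WARFARIN", "role_cod": "PS"}],
        )
        with pytest.raises(CohortError):
            select_cohort(data)


class TestExcludeSocs:
    events = pd.DataFrame([
        {"primaryid": "1", "pt": "Fall",
         "soc": "Injury, poisoning and procedural complications"},
        {"primaryid": "1", "pt": "Dry mouth", "soc": "Gastrointestinal disorders"},
    ])

    def test_excluded_soc_rows_removed_and_counted(self):
        kept, removed = exclude_socs(self.events)
        assert kept["pt"].tolist() == ["Dry mouth"]
        assert removed == {"Injury, poisoning and procedural complications": 1}

    def test_empty_exclusion_set_is_identity(self):
        kept, removed = exclude_socs(self.events, excluded=())
        assert kept.equals(self.events)
        assert removed == {}


def test_build_case_assembles_report_level_view():
    data = make_casedata(
        demo=[{"primaryid": "1", "caseid": "9", "sex": "F", "occp_cod": "MD",
               "event_dt": "20200126"}],
        drug=[{"primaryid": "1", "drugname": "MYRBETRIQ", "role_cod": "PS"}],
        reac=[{"primaryid": "1", "pt": "Dry mouth"},
              {"primaryid": "1", "pt": "Dry mouth"}],
        outc=[{"primaryid": "1", "outc_cod": "HO"}],
    )
    case = build_case(data, "1", NameMatcher())
    assert case.is_target
    assert case.reactions == frozenset({"Dry mouth"})  # set semantics
    assert case.outcomes == frozenset({"HO"})
    assert case.event_precision == "day"
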