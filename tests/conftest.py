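"""Shared fixtures: small synthetic datasets and hand-built case sets."""

from __future__ import annotations

import pandas as pd
import pytest

from faersig.cohort import CaseData, NameMatcher, select_cohort
from faersig.faers_io import concat_quarters, derive_demo_fields
from faersig.synthetic import SyntheticConfig, generate

DEMO_DEFAULTS = {
    "primaryid": "", "caseid": "", "event_dt": "", "fda_dt": "20200101",
    "age": "", "age_cod": "", "sex": "", "wt": "", "wt_cod": "",
    "occp_cod": "MD", "reporter_country": "US", "occr_country": "US",
}
DRUG_DEFAULTS = {
    "primaryid": "", "caseid": "", "drug_seq": "1", "role_cod": "PS",
    "drugname": "", "prod_ai": "", "dose_amt": "", "dose_unit": "", "dose_freq": "",
}


def make_demo(rows: list[dict]) -> pd.DataFrame:
    return derive_demo_fields(pd.DataFrame([{**DEMO_DEFAULTS, **r} for r in rows]))


def make_casedata(
    demo: list[dict],
    drug: list[dict] | None = None,
    reac: list[dict] | None = None,
    ther: list[dict] | None = None,
    outc: list[dict] | None = None,
    indi: list[dict] | None = None,
) -> CaseData:
    """Assemble a CaseData directly from row dictionaries (no dedup applied)."""
    def frame(rows, defaults):
        rows = rows or []
        return pd.DataFrame([{**defaults, **r} for r in rows]) if rows else pd.DataFrame(
            {k: pd.Series(dtype=str) for k in defaults})

    demo_df = make_demo(demo)
    return CaseData(
        demo=demo_df,
        drug=frame(drug, DRUG_DEFAULTS),
        reac=frame(reac, {"primaryid": "", "caseid": "", "pt": ""}),
        ther=frame(ther, {"primaryid": "", "caseid": "", "dsg_drug_seq": "1",
                          "start_dt": "", "end_dt": ""}),
        outc=frame(outc, {"primaryid": "", "caseid": "", "outc_cod": ""}),
        indi=frame(indi, {"primaryid": "", "caseid": "", "indi_drug_seq": "1",
                          "indi_pt": ""}),
        n_raw_reports=len(demo_df),
    )


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(seed=11, n_target_reports=300, n_background_reports=2500)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(bundles, truth, casedata, cohort split) for a small synthetic run."""
    bundles, truth = generate(small_config)
    data = CaseData.from_bundle(concat_quarters(bundles))
    split = select_cohort(data, NameMatcher())
    return bundles, truth, data, split
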