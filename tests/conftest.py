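"""Shared fixtures: hand-built FAERS tables, case factories, synthetic cohorts."""

from __future__ import annotations

from datetime import date

import pandas as pd
import pytest

from compvig.io import CaseReport, DrugClassMap, MeddraMap, RawRecordSet
from compvig.processing import load_name_list, process_cases
from compvig.synthetic import SyntheticConfig, cohort_to_cases, simulate_cohort


def make_case(
    primaryid: str = "100000001",
    caseid: str | None = None,
    fda_date: date = date(2023, 1, 15),
    drug_class: str | None = "C5",
    ps_drug: str = "eculizumab",
    reaction_pts=("Influenza",),
    outcomes=(),
    **kwargs,
) -> CaseReport:
    return CaseReport(
        primaryid=primaryid,
        caseid=caseid if caseid is not None else primaryid,
        fda_date=fda_date,
        ps_drug=ps_drug,
        drug_class=drug_class,
        reaction_pts=frozenset(reaction_pts),
        outcomes=frozenset(outcomes),
        **kwargs,
    )


@pytest.fixture(scope="session")
def drug_map() -> DrugClassMap:
    return DrugClassMap.default()


@pytest.fixture(scope="session")
def meddra() -> MeddraMap:
    return MeddraMap.default()


@pytest.fixture(scope="session")
def anti_infectives() -> set[str]:
    from importlib import resources

    return load_name_list(resources.files("compvig.data") / "anti_infectives.tsv")


def _table(name: str, rows: list[dict]) -> RawRecordSet:
    return RawRecordSet(name, pd.DataFrame(rows).astype(str))


@pytest.fixture()
def toy_tables() -> dict[str, RawRecordSet]:
    """Five hand-written reports: three with a PS complement inhibitor, one
    with the inhibitor as concomitant only, one with an unrelated PS drug."""
    demo = [
        {"PRIMARYID": f"1000{i}", "CASEID": f"500{i}", "FDA_DT": "20230115",
         "EVENT_DT": "20230101", "AGE": "45", "AGE_COD": "YR", "SEX": "F",
         "WT": "60", "WT_COD": "KG", "OCCP_COD": "MD", "REPORTER_COUNTRY": "US"}
        for i in range(1, 6)
    ]
    drug = [
        {"PRIMARYID": "10001", "DRUG_SEQ": "1", "ROLE_COD": "PS",
         "DRUGNAME": "SOLIRIS", "PROD_AI": "ECULIZUMAB"},
        {"PRIMARYID": "10002", "DRUG_SEQ": "1", "ROLE_COD": "PS",
         "DRUGNAME": "Empaveli", "PROD_AI": "PEGCETACOPLAN"},
        {"PRIMARYID": "10003", "DRUG_SEQ": "1", "ROLE_COD": "PS",
         "DRUGNAME": "FABHALTA", "PROD_AI": "IPTACOPAN"},
        # complement inhibitor present but only as concomitant -> dropped
        {"PRIMARYID": "10004", "DRUG_SEQ": "1", "ROLE_COD": "PS",
         "DRUGNAME": "ASPIRIN", "PROD_AI": "ASPIRIN"},
        {"PRIMARYID": "10004", "DRUG_SEQ": "2", "ROLE_COD": "C",
         "DRUGNAME": "ECULIZUMAB", "PROD_AI": "ECULIZUMAB"},
        {"PRIMARYID": "10005", "DRUG_SEQ": "1", "ROLE_COD": "PS",
         "DRUGNAME": "IBUPROFEN", "PROD_AI": "IBUPROFEN"},
    ]
    reac = [
        {"PRIMARYID": "10001", "PT": "Influenza"},
        {"PRIMARYID": "10001", "PT": "Pyrexia"},
        {"PRIMARYID": "10002", "PT": "Herpes zoster"},
        {"PRIMARYID": "10003", "PT": "Headache"},
        {"PRIMARYID": "10004", "PT": "Nausea"},
        {"PRIMARYID": "10005", "PT": "Fatigue"},
    ]
    outc = [{"PRIMARYID": "10001", "OUTC_COD": "DE"},
            {"PRIMARYID": "10002", "OUTC_COD": "HO"}]
    ther = [{"PRIMARYID": "10001", "DSG_DRUG_SEQ": "1", "START_DT": "20221201"},
            {"PRIMARYID": "10002", "DSG_DRUG_SEQ": "1", "START_DT": "20221115"}]
    indi = [{"PRIMARYID": "10001", "INDI_PT": "Paroxysmal nocturnal haemoglobinuria"}]
    return {
        "DEMO": _table("DEMO", demo),
        "DRUG": _table("DRUG", drug),
        "REAC": _table("REAC", reac),
        "OUTC": _table("OUTC", outc),
        "THER": _table("THER", ther),
        "INDI": _table("INDI", indi),
    }


@pytest.fixture(scope="session")
def cohort60k():
    """Study-scale synthetic cohort: raw truth plus processed cases."""
    config = SyntheticConfig(n_reports=60_000, seed=11)
    truth = simulate_cohort(config)
    cases = cohort_to_cases(truth.cohort)
    kept, excluded = process_cases(cases)
    return {"config": config, "truth": truth, "cases": cases,
            "kept": kept, "excluded": excluded}
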