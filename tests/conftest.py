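import numpy as np
import pandas as pd
import pytest

from faerspv import ingest as fi
from faerspv import synthetic as sy

from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_store(cases):
    """Build a CaseStore from compact per-case dicts.

    Each case dict: ``pid``, optional ``drugs`` [(name, role)], ``pts``
    [str], and demographic overrides (sex, age, weight, country, dates).
    """
    demo_rows, drug_rows, reac_rows = [], [], []
    for i, case in enumerate(cases):
        pid = case.get("pid", 1000 + i)
        demo_rows.append({
            "primaryid": pid,
            "caseid": case.get("caseid", pid),
            "receipt_date": pd.Timestamp(case.get("receipt", "2020-06-01")),
            "event_date": pd.Timestamp(case["event_date"]) if case.get("event_date") else pd.NaT,
            "event_date_imprecise": case.get("event_imprecise", False),
            "sex": case.get("sex", "male"),
            "age_years": case.get("age", 60.0),
            "weight_kg": case.get("weight", 70.0),
            "country": case.get("country", "United States"),
        })
        for name, role in case.get("drugs", []):
            drug_rows.append({
                "primaryid": pid, "generic_name": name, "role": role,
                "therapy_start": pd.Timestamp(case["start"]) if case.get("start") else pd.NaT,
                "therapy_end": pd.NaT,
                "start_imprecise": case.get("start_imprecise", False),
            })
        for pt in case.get("pts", []):
            reac_rows.append({"primaryid": pid, "pt": pt})
    cols_drug = ["primaryid", "generic_name", "role", "therapy_start",
                 "therapy_end", "start_imprecise"]
    cols_reac = ["primaryid", "pt"]
    return fi.CaseStore(
        demo=pd.DataFrame(demo_rows),
        drugs=pd.DataFrame(drug_rows, columns=cols_drug),
        reacs=pd.DataFrame(reac_rows, columns=cols_reac),
    )


@pytest.fixture(scope="session")
def toy_store():
    """Six cases: 2 drugx+event, 1 drugx alone, 1 event alone, 2 neither."""
    return make_store([
        {"drugs": [("drugx", "PS")], "pts": ["Proteinuria", "Nausea"]},
        {"drugs": [("drugx", "PS")], "pts": ["Proteinuria"]},
        {"drugs": [("drugx", "PS")], "pts": ["Nausea"]},
        {"drugs": [("drugy", "PS")], "pts": ["Proteinuria"]},
        {"drugs": [("drugy", "PS")], "pts": ["Rash"]},
        {"drugs": [("drugz", "PS")], "pts": ["Headache"]},
    ])


@pytest.fixture(scope="session")
def small_cohort():
    """Default-catalog cohort with duplicates, both raw tables and truth."""
    cfg = sy.default_config(n_reports=6000, seed=11, duplicate_rate=0.1)
    tables, truth = sy.generate_reports(cfg)
    return cfg, tables, truth


@pytest.fixture(scope="session")
def small_store(small_cohort):
    _, tables, _ = small_cohort
    return fi.build_store(tables)
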