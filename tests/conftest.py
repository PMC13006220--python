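import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from faerspv import cohort, synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dictionary():
    return cohort.load_drug_dictionary()


@pytest.fixture(scope="session")
def meddra():
    return cohort.load_meddra()


@pytest.fixture(scope="session")
def paperlike_small():
    """A quarter-scale paperlike dataset shared across tests (seed fixed)."""
    cfg = synthetic.paperlike_config(seed=11, scale=0.25)
    tables, truth = synthetic.generate(cfg)
    return cfg, tables, truth


@pytest.fixture()
def tiny_tables():
    """Hand-written six-table set: 3 cases (one duplicated), 1 orphan row."""
    demo = pd.DataFrame(
        [
            # caseid 100 has two versions; v2 is newer and must survive
            {"primaryid": "1001", "caseid": "100", "caseversion": "1",
             "fda_dt": "20230101", "event_dt": "20221215", "age": "70",
             "age_cod": "YR", "sex": "F", "occr_country": "US", "occp_cod": "CN"},
            {"primaryid": "1002", "caseid": "100", "caseversion": "2",
             "fda_dt": "20230401", "event_dt": "20221215", "age": "70",
             "age_cod": "YR", "sex": "F", "occr_country": "US", "occp_cod": "CN"},
            {"primaryid": "2001", "caseid": "200", "caseversion": "1",
             "fda_dt": "2023", "event_dt": "20230510", "age": "840",
             "age_cod": "MON", "sex": "M", "occr_country": "GB", "occp_cod": "MD"},
            {"primaryid": "3001", "caseid": "300", "caseversion": "1",
             "fda_dt": "20240105", "event_dt": "202401", "age": "",
             "age_cod": "", "sex": "", "occr_country": "", "occp_cod": ""},
        ],
        dtype=str,
    )
    drug = pd.DataFrame(
        [
            {"primaryid": "1002", "drug_seq": "1", "role_cod": "PS",
             "drugname": "TRELEGY ELLIPTA", "prod_ai": ""},
            {"primaryid": "1002", "drug_seq": "2", "role_cod": "C",
             "drugname": "ASPIRIN", "prod_ai": ""},
            {"primaryid": "2001", "drug_seq": "1", "role_cod": "PS",
             "drugname": "BEVESPI AEROSPHERE", "prod_ai": ""},
            {"primaryid": "3001", "drug_seq": "1", "role_cod": "SS",
             "drugname": "ANORO ELLIPTA", "prod_ai": ""},
        ],
        dtype=str,
    )
    reac = pd.DataFrame(
        [
            {"primaryid": "1002", "pt": "Atrial fibrillation"},
            {"primaryid": "1002", "pt": "Dyspnoea"},
            {"primaryid": "2001", "pt": "Myocardial infarction"},
            {"primaryid": "3001", "pt": "Cough"},
            {"primaryid": "9999", "pt": "Nausea"},  # orphan
        ],
        dtype=str,
    )
    outc = pd.DataFrame(
        [
            {"primaryid": "1002", "outc_cod": "HO"},
            {"primaryid": "1002", "outc_cod": "DE"},
            {"primaryid": "2001", "outc_cod": "OT"},
        ],
        dtype=str,
    )
    ther = pd.DataFrame(
        [
            {"primaryid": "1002", "dsg_drug_seq": "1", "start_dt": "20221201"},
            {"primaryid": "2001", "dsg_drug_seq": "1", "start_dt": "2023"},
        ],
        dtype=str,
    )
    indi = pd.DataFrame(
        [{"primaryid": "1002", "indi_drug_seq": "1",
          "indi_pt": "Chronic obstructive pulmonary disease"}],
        dtype=str,
    )
    return {"DEMO": demo, "DRUG": drug, "REAC": reac, "OUTC": outc, "THER": ther, "INDI": indi}
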