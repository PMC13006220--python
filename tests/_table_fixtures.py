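"""Fixture cohorts rebuilt from published characteristic-table counts.

These builders construct synthetic case lists whose marginal counts equal a
printed characteristics table, so that summary operations can be checked
against the published percentages exactly.
"""

from typing import List

import pandas as pd

from faerspv.cohort import CAECase
from faerspv.faers_io import CaseBundle, Demographics

# Overall column of the published characteristics table: 454 cardiac cases.
SEX_COUNTS = {"F": 198, "M": 195, "unknown": 61}
AGE_BAND_COUNTS = {"19-65": 101, ">65": 209, "unknown": 144}
REGION_COUNTS = {
    "Europe": 34, "North America": 406, "Asia": 5,
    "South America": 2, "Oceania": 6, "unknown": 1,
}
OCCUPATION_COUNTS = {
    "consumer": 226, "health professional": 78, "physician": 89,
    "pharmacist": 30, "other": 16, "unknown": 15,
}
# Outcome per cardiac-PT occurrence: 656 entries over the 454 cases.
OUTCOME_PT_COUNTS = {"DE": 213, "LT": 31, "HO": 288, "DS": 7, "CA": 4, "OT": 113}
N_CASES = 454
N_WITH_OTHER_ADE = 384

_COUNTRY_OF_REGION = {
    "Europe": "GB", "North America": "US", "Asia": "JP",
    "South America": "BR", "Oceania": "AU", "unknown": None,
}


def _spread(counts: dict) -> List:
    out = []
    for key, n in counts.items():
        out.extend([key] * n)
    return out


def _case_level_outcomes() -> List[tuple]:
    """(outcome, n_cardiac_pts) per case so PT-level tallies hit the targets.

    Case-level outcome counts are the PT-level targets scaled to 454; the
    remaining occurrences are realised by giving the first cases of each
    outcome a second cardiac PT.
    """
    case_counts = {"DE": 147, "LT": 21, "HO": 200, "DS": 5, "CA": 3, "OT": 78}
    assert sum(case_counts.values()) == N_CASES
    pairs = []
    for code, n_cases in case_counts.items():
        extra = OUTCOME_PT_COUNTS[code] - n_cases
        assert 0 <= extra <= n_cases
        for i in range(n_cases):
            pairs.append((code, 2 if i < extra else 1))
    assert sum(k for _, k in pairs) == sum(OUTCOME_PT_COUNTS.values())
    return pairs


def characteristics_cohort() -> List[CAECase]:
    """454 cases whose marginals equal the published overall column."""
    sexes = _spread(SEX_COUNTS)
    ages = [40.0] * AGE_BAND_COUNTS["19-65"] + [75.0] * AGE_BAND_COUNTS[">65"]
    ages += [None] * AGE_BAND_COUNTS["unknown"]
    countries = []
    for region, n in REGION_COUNTS.items():
        countries.extend([_COUNTRY_OF_REGION[region]] * n)
    occupations = _spread(OCCUPATION_COUNTS)
    outcome_pairs = _case_level_outcomes()

    cases = []
    for i in range(N_CASES):
        outcome, n_pts = outcome_pairs[i]
        cae_pts = ["Atrial fibrillation", "Myocardial infarction"][:n_pts]
        other_pts = ["Dyspnoea"] if i < N_WITH_OTHER_ADE else []
        bundle = CaseBundle(
            primaryid=str(10000 + i),
            demographics=Demographics(
                age_years=ages[i],
                sex=sexes[i] if sexes[i] in ("F", "M") else "unknown",
                country=countries[i],
                occupation=occupations[i],
            ),
            reactions=cae_pts + other_pts,
            outcomes=[outcome],
        )
        cases.append(
            CAECase(
                bundle=bundle,
                product_id="FUV",
                cae_pts=cae_pts,
                other_pts=other_pts,
                unmapped_pts=[],
                most_severe_outcome=outcome,
            )
        )
    return cases


def top5_class_counts() -> pd.DataFrame:
    """Published per-class top-5 cardiac PT counts as a (product, pt, n) frame.

    Dual-product counts are booked under FG, triple under FUV; the roll-up
    only uses the product -> component-class mapping.
    """
    rows = [
        ("FG", "Atrial fibrillation", 51),
        ("FG", "Myocardial infarction", 46),
        ("FG", "Cardiac failure congestive", 33),
        ("FG", "Cardiac disorder", 21),
        ("FG", "Cardiac arrest", 18),
        ("FUV", "Cardiogenic shock", 43),
        ("FUV", "Arteriosclerosis coronary artery", 40),
        ("FUV", "Ventricular fibrillation", 38),
        ("FUV", "Myocardial infarction", 30),
        ("FUV", "Atrial fibrillation", 28),
    ]
    return pd.DataFrame(rows, columns=["product_id", "pt", "n"])
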