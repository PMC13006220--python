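"""Seeded FAERS-schema data generator with known drug–event dependence.

The generator emits the six quarterly-style ``$``-delimited tables plus a
ground-truth manifest, so every pipeline stage — parsing, deduplication,
cohort matching, disproportionality screening, onset and demographic
subgroups — can be exercised and verified without any external download.

Generative model (per final-version report):

* each PT is drawn independently with its background reporting rate; for an
  injected (product, PT) pair the rate is multiplied by the configured
  reporting ratio R (R = 1 is the null). A report that draws no PT receives
  one fallback PT sampled proportionally to its own effective rates, keeping
  every report non-empty without diluting injected dependence;
  :func:`expected_table` accounts for this exactly.
* demographics follow the configured age normal, female share and
  missingness fractions; countries and reporter occupations are categorical.
* onset time is 0 days with probability ``day0_mass``, otherwise log-normal
  (configurable median and sigma) rounded up to a whole day. The event date
  is placed inside the product's search window and the therapy start date is
  back-dated by the onset; a configurable fraction of starts is omitted or
  truncated to month precision to exercise onset exclusions.
* a configurable fraction of cases receives an extra, earlier DEMO version
  (lower caseversion, earlier receipt date) with its own DRUG/REAC rows, to
  exercise deduplication and orphan accounting.

The default configuration (:func:`paperlike_config`) mirrors the reported
characteristics of the cardiac-event cohort it emulates: ~3,120 target
reports across seven products against a 20,000-report background, female
share ≈ 44%, ≈13% missing sex, ≈32% missing age, mean age 70.5 (SD 12),
day-0 onset mass 0.20 with a 90-day onset median.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import faers_io
from .cohort import load_drug_dictionary

CUTOFF = np.datetime64("2024-09-30")
_EARLIEST = np.datetime64("2014-01-01")


class ConfigError(ValueError):
    """The generator configuration is internally inconsistent."""


@dataclass(frozen=True)
class InjectedSignal:
    product_id: str
    pt: str
    rr: float  # multiplicative reporting ratio, 1.0 = null


def default_background_rates() -> Dict[str, float]:
    """Background per-report PT probabilities over the mock vocabulary.

    Cardiac PTs are rare (0.2–1.2%), common respiratory/general PTs are
    frequent, giving ~2.4 expected PTs per report.
    """
    cardiac = {
        "Atrial fibrillation": 0.012, "Myocardial infarction": 0.012,
        "Cardiac failure congestive": 0.008, "Cardiac disorder": 0.006,
        "Cardiogenic shock": 0.003, "Arteriosclerosis coronary artery": 0.003,
        "Ventricular fibrillation": 0.003, "Cardiac arrest": 0.008,
        "Cardiac failure": 0.008, "Palpitations": 0.010, "Cardiomegaly": 0.002,
        "Ventricular extrasystoles": 0.002, "Coronary artery disease": 0.004,
        "Tachycardia": 0.008, "Bradycardia": 0.004, "Angina pectoris": 0.004,
        "Atrial flutter": 0.002, "Acute myocardial infarction": 0.004,
        "Cardio-respiratory arrest": 0.003, "Supraventricular tachycardia": 0.002,
        "Cardiac failure acute": 0.002, "Cardiac failure chronic": 0.002,
        "Myocardial ischaemia": 0.003,
    }
    other = {
        "Dyspnoea": 0.10, "Chronic obstructive pulmonary disease": 0.06,
        "Cough": 0.05, "Wheezing": 0.02, "Pulmonary embolism": 0.008,
        "Respiratory failure": 0.01, "Asthma": 0.02,
        "Condition aggravated": 0.06, "Fatigue": 0.08, "Malaise": 0.04,
        "Death": 0.03, "Drug ineffective": 0.10, "Oedema peripheral": 0.03,
        "Blood pressure increased": 0.03, "Heart rate increased": 0.02,
        "Weight decreased": 0.02, "Pneumonia": 0.05, "Bronchitis": 0.02,
        "Urinary tract infection": 0.02, "Headache": 0.06, "Dizziness": 0.05,
        "Tremor": 0.02, "Cerebrovascular accident": 0.01, "Thrombosis": 0.01,
        "Hypertension": 0.03, "Hypotension": 0.02, "Anxiety": 0.03,
        "Insomnia": 0.03, "Nausea": 0.07, "Diarrhoea": 0.04, "Vomiting": 0.03,
        "Rash": 0.03, "Pruritus": 0.02, "Fall": 0.03, "Arthralgia": 0.03,
        "Muscle spasms": 0.02, "Decreased appetite": 0.02,
        "Acute kidney injury": 0.01, "Vision blurred": 0.01,
    }
    return {**cardiac, **other}


def default_injected_signals() -> List[InjectedSignal]:
    """Paperlike dependence structure: strong AF signal for the dual product
    FG, weaker for the triple FUV; shock/coronary/ventricular signals
    concentrated on the triple product."""
    return [
        InjectedSignal("FG", "Atrial fibrillation", 10.0),
        InjectedSignal("OT", "Atrial fibrillation", 6.0),
        InjectedSignal("FUV", "Atrial fibrillation", 4.0),
        InjectedSignal("FG", "Myocardial infarction", 4.0),
        InjectedSignal("OT", "Myocardial infarction", 5.0),
        InjectedSignal("FUV", "Myocardial infarction", 4.0),
        InjectedSignal("OT", "Cardiac failure congestive", 5.0),
        InjectedSignal("FUV", "Cardiac failure congestive", 4.0),
        InjectedSignal("OT", "Cardiac arrest", 6.0),
        InjectedSignal("FUV", "Cardiogenic shock", 10.0),
        InjectedSignal("FUV", "Arteriosclerosis coronary artery", 9.0),
        InjectedSignal("FUV", "Ventricular fibrillation", 9.0),
    ]


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_background_reports: int = 20000
    #: ~3,120 target reports in total, concentrated on OT and FUV.
    n_reports_per_product: Dict[str, int] = field(
        default_factory=lambda: {
            "FA": 30, "FG": 350, "IG": 40, "OT": 1100, "VU": 40, "BGF": 60, "FUV": 1500,
        }
    )
    background_pt_rates: Dict[str, float] = field(default_factory=default_background_rates)
    injected_signals: List[InjectedSignal] = field(default_factory=default_injected_signals)
    female_share: float = 0.44
    sex_missing_frac: float = 0.13
    age_mean: float = 70.5
    age_sd: float = 12.0
    age_missing_frac: float = 0.32
    day0_mass: float = 0.20
    onset_median_days: float = 90.0
    onset_sigma: float = 1.2
    therapy_missing_frac: float = 0.20
    partial_date_frac: float = 0.15
    outcome_probs: Dict[str, float] = field(
        default_factory=lambda: {
            "DE": 0.22, "LT": 0.04, "HO": 0.33, "DS": 0.01, "CA": 0.005,
            "OT": 0.17, "none": 0.225,
        }
    )
    extra_outcome_frac: float = 0.15
    duplicate_case_fraction: float = 0.10
    nonsuspect_target_fraction: float = 0.05
    concomitant_frac: float = 0.30
    country_probs: Dict[str, float] = field(
        default_factory=lambda: {
            "US": 0.82, "CA": 0.05, "GB": 0.03, "DE": 0.02, "FR": 0.01,
            "JP": 0.01, "BR": 0.005, "AU": 0.01, "": 0.045,
        }
    )
    occupation_probs: Dict[str, float] = field(
        default_factory=lambda: {
            "CN": 0.50, "HP": 0.17, "MD": 0.20, "PH": 0.065, "OT": 0.03, "": 0.035,
        }
    )
    background_drugnames: Tuple[str, ...] = (
        "METFORMIN", "ASPIRIN", "LISINOPRIL", "ATORVASTATIN", "OMEPRAZOLE",
        "AMLODIPINE", "LEVOTHYROXINE", "ALBUTEROL", "WARFARIN", "PREDNISONE",
    )

    def validate(self) -> None:
        fracs = [
            self.female_share, self.sex_missing_frac, self.age_missing_frac,
            self.day0_mass, self.therapy_missing_frac, self.partial_date_frac,
            self.duplicate_case_fraction, self.nonsuspect_target_fraction,
            self.extra_outcome_frac, self.concomitant_frac,
        ]
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ConfigError("a configured fraction lies outside [0, 1]")
        for pt, rate in self.background_pt_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ConfigError(f"background rate for {pt!r} outside [0, 1]")
        for sig in self.injected_signals:
            if sig.rr <= 0:
                raise ConfigError(f"reporting ratio must be positive: {sig}")
            rate = self.background_pt_rates.get(sig.pt)
            if rate is None:
                raise ConfigError(f"injected PT {sig.pt!r} not in background vocabulary")
            if rate * sig.rr > 1.0:
                raise ConfigError(
                    f"infeasible rate: {sig.pt!r} background {rate} x R {sig.rr} > 1"
                )
            if sig.product_id not in self.n_reports_per_product:
                raise ConfigError(f"injected product {sig.product_id!r} has no reports")
        for name, probs in (("outcome", self.outcome_probs),
                            ("country", self.country_probs),
                            ("occupation", self.occupation_probs)):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} probabilities sum to {total}, not 1")


def paperlike_config(seed: int = 0, scale: float = 1.0) -> GeneratorConfig:
    """The default study conditions, optionally scaled in report counts."""
    cfg = GeneratorConfig(seed=seed)
    if scale != 1.0:
        cfg.n_background_reports = int(round(cfg.n_background_reports * scale))
        cfg.n_reports_per_product = {
            k: max(1, int(round(v * scale))) for k, v in cfg.n_reports_per_product.items()
        }
    return cfg


@dataclass
class SyntheticGroundTruth:
    config: GeneratorConfig
    n_reports: int  # final-version reports
    n_duplicate_cases: int
    product_ps_totals: Dict[str, int]
    pt_totals: Dict[str, int]
    pair_tables: Dict[Tuple[str, str], Tuple[int, int, int, int]]
    injected: Dict[Tuple[str, str], float]
    case_manifest: pd.DataFrame  # primaryid, caseid, product, is_ps, onset_days, ...

    def realized_table(self, product_id: str, pt: str) -> Tuple[int, int, int, int]:
        return self.pair_tables[(product_id, pt)]

    def to_json_dict(self) -> Dict[str, object]:
        return {
            "config": _config_to_dict(self.config),
            "n_reports": self.n_reports,
            "n_duplicate_cases": self.n_duplicate_cases,
            "product_ps_totals": self.product_ps_totals,
            "pt_totals": self.pt_totals,
            "pair_tables": {
                f"{pid}|{pt}": list(t) for (pid, pt), t in self.pair_tables.items()
            },
            "injected": {f"{pid}|{pt}": r for (pid, pt), r in self.injected.items()},
            "cases": self.case_manifest.to_dict("list"),
        }


def _config_to_dict(cfg: GeneratorConfig) -> Dict[str, object]:
    d = dataclasses.asdict(cfg)
    d["injected_signals"] = [dataclasses.asdict(s) for s in cfg.injected_signals]
    d["background_drugnames"] = list(cfg.background_drugnames)
    return d


def _fmt_dates(days: np.ndarray) -> np.ndarray:
    """datetime64[D] array -> YYYYMMDD strings."""
    return pd.DatetimeIndex(days).strftime("%Y%m%d").to_numpy(dtype=object)


def generate(
    config: GeneratorConfig,
    out_dir: Optional[Path] = None,
    build_tables: bool = True,
) -> Tuple[Dict[str, pd.DataFrame], SyntheticGroundTruth]:
    """Generate the six tables plus ground truth; deterministic given seed.

    ``build_tables=False`` skips table assembly (the random draws are
    identical) and returns an empty table dict — useful for simulation
    studies that only need the realized ground-truth counts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dictionary = {e.product_id: e for e in load_drug_dictionary()}

    products = sorted(config.n_reports_per_product)
    pts = sorted(config.background_pt_rates)
    rates = np.array([config.background_pt_rates[p] for p in pts])
    pt_index = {p: i for i, p in enumerate(pts)}

    # ---- report frame -------------------------------------------------
    product_arr: List[str] = []
    for pid in products:
        product_arr.extend([pid] * config.n_reports_per_product[pid])
    product_arr.extend([""] * config.n_background_reports)
    product_arr = np.array(product_arr, dtype=object)
    n = len(product_arr)
    is_target = product_arr != ""
    is_ps = np.ones(n, dtype=bool)
    is_ps[is_target] = rng.random(is_target.sum()) >= config.nonsuspect_target_fraction

    # ---- PT draws ------------------------------------------------------
    probs = np.tile(rates, (n, 1))
    for sig in config.injected_signals:
        mask = (product_arr == sig.product_id) & is_ps
        col = pt_index[sig.pt]
        probs[mask, col] = np.minimum(probs[mask, col] * sig.rr, 1.0)
    draws = rng.random((n, len(pts))) < probs
    empty = ~draws.any(axis=1)
    if empty.any():
        # fallback PT sampled from the row's own effective rates, so injected
        # dependence survives conditioning on a non-empty report
        p_empty = probs[empty]
        cum = np.cumsum(p_empty, axis=1)
        u = rng.random(int(empty.sum())) * cum[:, -1]
        fallback = (cum < u[:, None]).sum(axis=1)
        draws[np.nonzero(empty)[0], fallback] = True

    # ---- demographics --------------------------------------------------
    sex_draw = rng.random(n)
    sex = np.where(
        sex_draw < config.sex_missing_frac, "",
        np.where(sex_draw < config.sex_missing_frac + config.female_share, "F", "M"),
    ).astype(object)
    age = np.clip(np.round(rng.normal(config.age_mean, config.age_sd, n)), 19, 110)
    age_missing = rng.random(n) < config.age_missing_frac
    countries = rng.choice(
        list(config.country_probs), size=n, p=list(config.country_probs.values())
    ).astype(object)
    occupations = rng.choice(
        list(config.occupation_probs), size=n, p=list(config.occupation_probs.values())
    ).astype(object)

    # ---- onsets and dates ----------------------------------------------
    day0 = rng.random(n) < config.day0_mass
    lognorm = rng.lognormal(np.log(config.onset_median_days), config.onset_sigma, n)
    onset = np.where(day0, 0, np.maximum(1, np.round(lognorm))).astype(int)

    window_start = np.full(n, _EARLIEST, dtype="datetime64[D]")
    for pid in products:
        e = dictionary.get(pid)
        if e is None:
            continue
        y, q = e.search_start_quarter
        window_start[product_arr == pid] = np.datetime64(f"{y:04d}-{(q - 1) * 3 + 1:02d}-01")
    span = (CUTOFF - window_start).astype(int)
    event_date = window_start + (rng.random(n) * span).astype(int)
    start_date = event_date - onset
    fda_date = np.minimum(event_date + rng.integers(0, 60, n), CUTOFF)

    therapy_missing = rng.random(n) < config.therapy_missing_frac
    partial_start = (~therapy_missing) & (rng.random(n) < config.partial_date_frac)

    # ---- outcomes -------------------------------------------------------
    outcome_labels = list(config.outcome_probs)
    primary_outcome = rng.choice(
        outcome_labels, size=n, p=list(config.outcome_probs.values())
    ).astype(object)
    has_outcome = primary_outcome != "none"
    extra_mask = has_outcome & (rng.random(n) < config.extra_outcome_frac)
    codes_only = [c for c in outcome_labels if c != "none"]
    code_p = np.array([config.outcome_probs[c] for c in codes_only])
    code_p = code_p / code_p.sum()
    extra_outcome = rng.choice(codes_only, size=n, p=code_p).astype(object)

    # ---- case ids and duplicate versions --------------------------------
    caseids = np.arange(10_000_001, 10_000_001 + n)
    dup = rng.random(n) < config.duplicate_case_fraction
    version = np.where(dup, 2, 1)
    primaryids = np.char.add(caseids.astype(str), version.astype(str)).astype(object)

    # ---- drug name variants ---------------------------------------------
    drugnames = np.empty(n, dtype=object)
    prod_ais = np.full(n, "", dtype=object)
    variant = rng.random(n)
    use_prod_ai = rng.random(n) < 0.5
    bg_names = rng.choice(np.array(config.background_drugnames, dtype=object), size=n)
    for i in np.nonzero(is_target)[0]:
        e = dictionary[product_arr[i]]
        generic = e.generic_names[0]
        if variant[i] < 0.45 and e.brand_names:
            drugnames[i] = e.brand_names[0]
        elif variant[i] < 0.80:
            drugnames[i] = generic.upper()
        else:
            drugnames[i] = "/".join(reversed(generic.split("/"))).upper()
        if use_prod_ai[i]:
            prod_ais[i] = generic.upper()
    drugnames[~is_target] = bg_names[~is_target]
    role = np.where(is_ps, "PS", "SS").astype(object)
    concomitant = rng.random(n) < config.concomitant_frac

    if not build_tables:
        tables: Dict[str, pd.DataFrame] = {}
    else:
        # ---- assemble tables -------------------------------------------------
        fda_str = _fmt_dates(fda_date)
        event_str = _fmt_dates(event_date)
        start_full = _fmt_dates(start_date)
        # month precision = first six characters of YYYYMMDD
        start_str = np.where(partial_start,
                             np.array([s[:6] for s in start_full], dtype=object),
                             start_full)

        demo = pd.DataFrame(
            {
                "primaryid": primaryids,
                "caseid": caseids.astype(str),
                "caseversion": version.astype(str),
                "fda_dt": fda_str,
                "event_dt": event_str,
                "age": np.where(age_missing, "", age.astype(int).astype(str)),
                "age_cod": np.where(age_missing, "", "YR"),
                "sex": sex,
                "occr_country": countries,
                "occp_cod": occupations,
            },
            dtype=str,
        )

        drug_rows = {
            "primaryid": list(primaryids),
            "drug_seq": ["1"] * n,
            "role_cod": list(role),
            "drugname": list(drugnames),
            "prod_ai": list(prod_ais),
        }
        for i in np.nonzero(concomitant)[0]:
            drug_rows["primaryid"].append(primaryids[i])
            drug_rows["drug_seq"].append("2")
            drug_rows["role_cod"].append("C")
            drug_rows["drugname"].append(bg_names[(i + 1) % n])
            drug_rows["prod_ai"].append("")
        drug = pd.DataFrame(drug_rows, dtype=str)

        rows_idx, cols_idx = np.nonzero(draws)
        reac = pd.DataFrame(
            {
                "primaryid": primaryids[rows_idx],
                "pt": np.array(pts, dtype=object)[cols_idx],
            },
            dtype=str,
        )

        outc_ids = list(primaryids[has_outcome])
        outc_codes = list(primary_outcome[has_outcome])
        for i in np.nonzero(extra_mask)[0]:
            if extra_outcome[i] != primary_outcome[i]:
                outc_ids.append(primaryids[i])
                outc_codes.append(extra_outcome[i])
        outc = pd.DataFrame({"primaryid": outc_ids, "outc_cod": outc_codes}, dtype=str)

        ther_mask = ~therapy_missing
        ther = pd.DataFrame(
            {
                "primaryid": primaryids[ther_mask],
                "dsg_drug_seq": "1",
                "start_dt": start_str[ther_mask],
            },
            dtype=str,
        )

        indi = pd.DataFrame(
            {
                "primaryid": primaryids,
                "indi_drug_seq": "1",
                "indi_pt": np.where(
                    is_target, "Chronic obstructive pulmonary disease", "Hypertension"
                ),
            },
            dtype=str,
        )

        # earlier versions of duplicated cases (superseded; dropped by dedup)
        dup_idx = np.nonzero(dup)[0]
        if len(dup_idx):
            old_ids = np.char.add(caseids[dup_idx].astype(str), "1").astype(object)
            old_fda = _fmt_dates(np.maximum(fda_date[dup_idx] - 35, _EARLIEST))
            old_demo = demo.iloc[dup_idx].copy()
            old_demo["primaryid"] = old_ids
            old_demo["caseversion"] = "1"
            old_demo["fda_dt"] = old_fda
            demo = pd.concat([demo, old_demo], ignore_index=True)
            first_pt = np.array(pts, dtype=object)[draws[dup_idx].argmax(axis=1)]
            reac = pd.concat(
                [reac, pd.DataFrame({"primaryid": old_ids, "pt": first_pt}, dtype=str)],
                ignore_index=True,
            )
            drug = pd.concat(
                [
                    drug,
                    pd.DataFrame(
                        {
                            "primaryid": old_ids,
                            "drug_seq": "1",
                            "role_cod": role[dup_idx],
                            "drugname": drugnames[dup_idx],
                            "prod_ai": prod_ais[dup_idx],
                        },
                        dtype=str,
                    ),
                ],
                ignore_index=True,
            )

        tables = {"DEMO": demo, "DRUG": drug, "REAC": reac, "OUTC": outc, "THER": ther, "INDI": indi}

    # ---- ground truth ----------------------------------------------------
    ps_target = is_target & is_ps
    product_ps_totals = {pid: int((product_arr == pid)[ps_target].sum()) for pid in products}
    pt_totals_arr = draws.sum(axis=0)
    pt_totals = {pt: int(pt_totals_arr[i]) for pt, i in pt_index.items()}
    pair_tables: Dict[Tuple[str, str], Tuple[int, int, int, int]] = {}
    for pid in products:
        mask = (product_arr == pid) & is_ps
        n_prod = int(mask.sum())
        a_vec = draws[mask].sum(axis=0)
        for pt, col in pt_index.items():
            a = int(a_vec[col])
            c = int(pt_totals_arr[col]) - a
            pair_tables[(pid, pt)] = (a, n_prod - a, c, n - n_prod - c)
    manifest = pd.DataFrame(
        {
            "primaryid": primaryids,
            "caseid": caseids.astype(str),
            "product": product_arr,
            "is_ps": is_ps,
            "onset_days": onset,
            "therapy_missing": therapy_missing,
            "partial_start": partial_start,
            "duplicated": dup,
            "n_pts": draws.sum(axis=1),
        }
    )
    truth = SyntheticGroundTruth(
        config=config,
        n_reports=n,
        n_duplicate_cases=int(dup.sum()),
        product_ps_totals=product_ps_totals,
        pt_totals=pt_totals,
        pair_tables=pair_tables,
        injected={(s.product_id, s.pt): s.rr for s in config.injected_signals},
        case_manifest=manifest,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        faers_io.write_tables(tables, out_dir)
        with open(out_dir / "groundtruth.json", "w") as fh:
            json.dump(truth.to_json_dict(), fh, indent=1, default=str)
    return tables, truth


def _group_has_pt_prob(eff_probs: np.ndarray) -> np.ndarray:
    """P(report contains PT i) under the draw-plus-fallback scheme."""
    p_none = np.prod(1.0 - eff_probs)
    return eff_probs + p_none * eff_probs / eff_probs.sum()


def expected_table(
    config: GeneratorConfig, product_id: str, pt: str
) -> Tuple[float, float, float, float]:
    """Closed-form expected (a, b, c, d) for one pair under the model."""
    config.validate()
    if product_id not in config.n_reports_per_product:
        raise KeyError(product_id)
    if pt not in config.background_pt_rates:
        raise KeyError(pt)
    pts = sorted(config.background_pt_rates)
    rates = np.array([config.background_pt_rates[p] for p in pts])
    col = pts.index(pt)

    def eff(pid: str, ps: bool) -> np.ndarray:
        p = rates.copy()
        if ps:
            for sig in config.injected_signals:
                if sig.product_id == pid:
                    j = pts.index(sig.pt)
                    p[j] = min(p[j] * sig.rr, 1.0)
        return p

    n_total = config.n_background_reports + sum(config.n_reports_per_product.values())
    frac_ps = 1.0 - config.nonsuspect_target_fraction
    n_ps = config.n_reports_per_product[product_id] * frac_ps
    e_a = n_ps * _group_has_pt_prob(eff(product_id, True))[col]

    e_c = config.n_background_reports * _group_has_pt_prob(rates)[col]
    for pid, n_p in config.n_reports_per_product.items():
        p_ps = _group_has_pt_prob(eff(pid, True))[col]
        p_nonps = _group_has_pt_prob(rates)[col]
        if pid == product_id:
            e_c += n_p * (1.0 - frac_ps) * p_nonps
        else:
            e_c += n_p * frac_ps * p_ps + n_p * (1.0 - frac_ps) * p_nonps
    return (e_a, n_ps - e_a, e_c, (n_total - n_ps) - e_c)
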