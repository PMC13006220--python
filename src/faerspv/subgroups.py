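"""Subgroup analyses of the cardiac-event cohort.

Covers time-to-onset binning and cumulative curves, onset composition by
sex/age stratum, the death-outcome subset with age contrasts, co-reported
non-cardiac events, the demographic summary table, and the component-class
(dual LABA/LAMA vs triple ICS/LABA/LAMA) PT roll-up.

Percentages throughout are rounded half-up to two decimals, the convention
of published FAERS characteristic tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CAECase, DrugDictionaryEntry
from .dates import PartialDate, days_between

#: Onset-time bins (days): day 0, 1–30, 31–90, 91–180, 181–365, 366–730, ≥731.
ONSET_BIN_LABELS = ("day0", "d1_30", "d31_90", "d91_180", "d181_365", "d366_730", "d731_plus")
_ONSET_UPPER = (0, 30, 90, 180, 365, 730, None)

#: Country code -> reporting region roll-up (common FAERS codes).
REGION_BY_COUNTRY = {
    "US": "North America", "CA": "North America", "MX": "North America",
    "GB": "Europe", "DE": "Europe", "FR": "Europe", "IT": "Europe", "ES": "Europe",
    "NL": "Europe", "SE": "Europe", "DK": "Europe", "PL": "Europe", "IE": "Europe",
    "CH": "Europe", "AT": "Europe", "BE": "Europe", "PT": "Europe", "NO": "Europe",
    "FI": "Europe", "GR": "Europe",
    "JP": "Asia", "CN": "Asia", "KR": "Asia", "IN": "Asia", "TW": "Asia",
    "TH": "Asia", "SG": "Asia", "IL": "Asia", "TR": "Asia",
    "BR": "South America", "AR": "South America", "CO": "South America",
    "CL": "South America", "PE": "South America", "VE": "South America",
    "AU": "Oceania", "NZ": "Oceania",
    "ZA": "Africa", "EG": "Africa", "NG": "Africa",
}


def round2(x: float) -> float:
    """Round half-up to 2 decimals (matches printed table percentages)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def pct(count: float, total: float) -> float:
    return round2(100.0 * count / total) if total else 0.0


def onset_bin(days: int) -> str:
    """Bin label for a non-negative whole-day onset."""
    if days < 0:
        raise ValueError("negative onset")
    for label, upper in zip(ONSET_BIN_LABELS, _ONSET_UPPER):
        if upper is None or days <= upper:
            return label
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class OnsetRecord:
    primaryid: str
    product_id: str
    pt: str
    onset_days: int
    bin: str
    sex: str = "unknown"
    age_years: Optional[float] = None


def time_to_onset(
    therapy_start: Optional[PartialDate], event_date: Optional[PartialDate]
) -> Tuple[Optional[int], str]:
    """Whole days from therapy start to event, with an exclusion status.

    Statuses: ``ok`` (days returned), ``partial_date`` (a date is missing or
    not at day precision), ``negative`` (event precedes start; excluded).
    """
    if therapy_start is None or event_date is None:
        return (None, "partial_date")
    if not therapy_start.is_day_precision or not event_date.is_day_precision:
        return (None, "partial_date")
    days = days_between(therapy_start, event_date)
    if days < 0:
        return (None, "negative")
    return (days, "ok")


@dataclass
class OnsetExtraction:
    records: List[OnsetRecord]
    n_cases_in: int
    excluded_partial_dates: int
    excluded_negative: int
    n_cae_cases: int


def make_onset_records(cases: Iterable[CAECase]) -> OnsetExtraction:
    """One record per (case, cardiac PT); cases without usable dates excluded.

    The therapy start is the earliest day-precision start among THER rows of
    the matched target drug's sequences; the event date is the report's
    event_dt (never backfilled from the receipt date, which would deflate
    onsets toward zero).
    """
    records: List[OnsetRecord] = []
    n_in = n_partial = n_negative = n_total = 0
    for case in cases:
        n_total += 1
        starts = [
            case.bundle.therapy_starts[s]
            for s in case.matched_drug_seqs
            if s in case.bundle.therapy_starts
            and case.bundle.therapy_starts[s].is_day_precision
        ]
        start = min(starts, key=lambda p: p.sort_key()) if starts else None
        days, status = time_to_onset(start, case.bundle.demographics.event_date)
        if status == "partial_date":
            n_partial += 1
            continue
        if status == "negative":
            n_negative += 1
            continue
        n_in += 1
        d = case.bundle.demographics
        for pt in case.cae_pts:
            records.append(
                OnsetRecord(
                    primaryid=case.primaryid,
                    product_id=case.product_id,
                    pt=pt,
                    onset_days=days,
                    bin=onset_bin(days),
                    sex=d.sex,
                    age_years=d.age_years,
                )
            )
    return OnsetExtraction(
        records=records,
        n_cases_in=n_in,
        excluded_partial_dates=n_partial,
        excluded_negative=n_negative,
        n_cae_cases=n_total,
    )


@dataclass
class OnsetDistribution:
    bin_counts: pd.Series  # indexed by ONSET_BIN_LABELS
    cumulative: pd.DataFrame  # columns: days, cum_prop (non-decreasing, ends at 1)
    n_cases: int

    @property
    def day0_share(self) -> float:
        return float(self.bin_counts["day0"]) / self.n_cases if self.n_cases else float("nan")

    def cum_prop_at(self, days: int) -> float:
        """Cumulative proportion of cases with onset ≤ days."""
        sub = self.cumulative[self.cumulative["days"] <= days]
        return float(sub["cum_prop"].iloc[-1]) if len(sub) else 0.0


def onset_distribution(records: Sequence[OnsetRecord]) -> OnsetDistribution:
    """Case-level onset histogram over the fixed bins plus cumulative curve."""
    by_case: Dict[str, int] = {}
    for r in records:
        by_case.setdefault(r.primaryid, r.onset_days)
    days = np.sort(np.array(list(by_case.values()), dtype=int))
    counts = pd.Series(0, index=list(ONSET_BIN_LABELS), dtype=int)
    for d in days:
        counts[onset_bin(int(d))] += 1
    if len(days):
        uniq, cum = np.unique(days, return_counts=True)
        cum_prop = np.cumsum(cum) / len(days)
        curve = pd.DataFrame({"days": uniq, "cum_prop": cum_prop})
    else:
        curve = pd.DataFrame(columns=["days", "cum_prop"])
    return OnsetDistribution(bin_counts=counts, cumulative=curve, n_cases=len(days))


def onset_by_stratum(
    records: Sequence[OnsetRecord],
    stratum: str = "sex",
    age_threshold: float = 70.5,
) -> pd.DataFrame:
    """Composition of each onset bin by stratum (case level, percents sum 100).

    ``stratum``: ``sex``, or ``age`` (above/at-or-below ``age_threshold``;
    defaults to the cohort's mean-age convention, with 80 for the very
    elderly contrast). Missing values form their own category; empty bins
    are omitted.
    """
    by_case: Dict[str, OnsetRecord] = {}
    for r in records:
        by_case.setdefault(r.primaryid, r)
    rows = []
    for r in by_case.values():
        if stratum == "sex":
            cat = r.sex
        elif stratum == "age":
            if r.age_years is None:
                cat = "missing"
            else:
                cat = f">{age_threshold:g}" if r.age_years > age_threshold else f"<={age_threshold:g}"
        else:
            raise ValueError(f"unknown stratum: {stratum}")
        rows.append((r.bin, cat))
    if not rows:
        return pd.DataFrame(columns=["bin", "category", "n", "pct"])
    df = pd.DataFrame(rows, columns=["bin", "category"])
    counts = df.groupby(["bin", "category"], as_index=False).size().rename(columns={"size": "n"})
    totals = counts.groupby("bin")["n"].transform("sum")
    counts["pct"] = [pct(n, t) for n, t in zip(counts["n"], totals)]
    counts["bin"] = pd.Categorical(counts["bin"], categories=list(ONSET_BIN_LABELS), ordered=True)
    return counts.sort_values(["bin", "category"]).reset_index(drop=True)


# ---------------------------------------------------------------- deaths


@dataclass
class DeathGroupStats:
    product_id: str
    n_cases: int
    pt_counts: pd.DataFrame  # pt, n (desc, alphabetical ties)
    age_mean: Optional[float]
    age_median: Optional[float]
    ages: List[float]
    age_missing_frac: float


def age_ttest(group_a: Sequence[float], group_b: Sequence[float]):
    """Two-sample Welch t-test on ages; None when a group has < 2 values."""
    if len(group_a) < 2 or len(group_b) < 2:
        return None
    return stats.ttest_ind(list(group_a), list(group_b), equal_var=False)


def _pt_count_frame(pairs: Iterable[Tuple[str]], k: Optional[int] = None) -> pd.DataFrame:
    s = pd.Series([p for (p,) in pairs], dtype=object)
    if s.empty:
        return pd.DataFrame(columns=["pt", "n"])
    counts = s.value_counts().rename_axis("pt").reset_index(name="n")
    counts = counts.sort_values(["n", "pt"], ascending=[False, True]).reset_index(drop=True)
    return counts.head(k) if k else counts


def death_subset(
    cases: Iterable[CAECase], top_k: Optional[int] = None
) -> Tuple[Dict[str, DeathGroupStats], Dict[Tuple[str, str], object]]:
    """Per-product PT ranking and age statistics among death-outcome reports.

    Death means outcome code DE present on the report. Returns
    (per-group stats keyed by product id plus 'ALL', pairwise Welch t-tests
    of each product's ages against the pooled cohort; undersized groups are
    skipped).
    """
    groups: Dict[str, List[CAECase]] = {"ALL": []}
    for case in cases:
        if "DE" not in case.bundle.outcomes:
            continue
        groups["ALL"].append(case)
        groups.setdefault(case.product_id, []).append(case)

    stats_by_group: Dict[str, DeathGroupStats] = {}
    for pid, members in groups.items():
        ages = [
            c.bundle.demographics.age_years
            for c in members
            if c.bundle.demographics.age_years is not None
        ]
        pt_counts = _pt_count_frame(((pt,) for c in members for pt in c.cae_pts), top_k)
        stats_by_group[pid] = DeathGroupStats(
            product_id=pid,
            n_cases=len(members),
            pt_counts=pt_counts,
            age_mean=float(np.mean(ages)) if ages else None,
            age_median=float(np.median(ages)) if ages else None,
            ages=ages,
            age_missing_frac=1 - len(ages) / len(members) if members else 0.0,
        )
    tests: Dict[Tuple[str, str], object] = {}
    all_ages = stats_by_group["ALL"].ages
    for pid, gs in stats_by_group.items():
        if pid == "ALL":
            continue
        res = age_ttest(gs.ages, all_ages)
        if res is not None:
            tests[(pid, "ALL")] = res
    return stats_by_group, tests


# ---------------------------------------------------------- co-reported


@dataclass
class CoReportedResult:
    n_cases: int
    n_with_other: int
    share_pct: float  # percent, 2 decimals
    soc_counts: pd.DataFrame  # soc, n (case-level, desc then alphabetical)
    pt_counts: pd.DataFrame  # pt, n (case-level)


def co_reported(cases: Iterable[CAECase], meddra) -> CoReportedResult:
    """Non-cardiac events co-occurring with cardiac ones.

    A PT (and a SOC) counts once per case. The share is the fraction of
    CAE cases carrying at least one other mapped ADE.
    """
    n_cases = 0
    n_with = 0
    pt_rows: List[Tuple[str]] = []
    soc_rows: List[Tuple[str]] = []
    for case in cases:
        n_cases += 1
        if case.other_pts:
            n_with += 1
        socs = set()
        for pt in case.other_pts:
            pt_rows.append((pt,))
            soc = meddra.soc(pt)
            if soc:
                socs.add(soc)
        for soc in socs:
            soc_rows.append((soc,))
    soc_counts = _pt_count_frame(soc_rows).rename(columns={"pt": "soc"})
    return CoReportedResult(
        n_cases=n_cases,
        n_with_other=n_with,
        share_pct=pct(n_with, n_cases),
        soc_counts=soc_counts,
        pt_counts=_pt_count_frame(pt_rows),
    )


# ------------------------------------------------------------ demographics

_AGE_BANDS = ("<19", "19-65", ">65", "unknown")
_OCCUPATIONS = ("consumer", "health professional", "physician", "pharmacist", "other", "unknown")
_OUTCOME_LABELS = {
    "DE": "Death", "LT": "Life-threatening", "HO": "Hospitalization",
    "DS": "Disability", "CA": "Congenital anomaly", "RI": "Required intervention",
    "OT": "Other serious",
}


@dataclass
class GroupSummary:
    n_cases: int
    sex: Dict[str, Tuple[int, float]]
    age_bands: Dict[str, Tuple[int, float]]
    age_mean: Optional[float]
    region: Dict[str, Tuple[int, float]]
    occupation: Dict[str, Tuple[int, float]]
    outcome_pt_level: Dict[str, Tuple[int, float]]  # over PT occurrences with an outcome
    n_outcome_entries: int
    outcome_case_level: Dict[str, Tuple[int, float]]  # most-severe per case


@dataclass
class DemographicSummary:
    overall: GroupSummary
    per_product: Dict[str, GroupSummary]

    def to_frame(self) -> pd.DataFrame:
        rows = []

        def emit(group: str, gs: GroupSummary) -> None:
            rows.append((group, "total", "cases", gs.n_cases, 100.0))
            for block, data in (
                ("sex", gs.sex),
                ("age", gs.age_bands),
                ("region", gs.region),
                ("occupation", gs.occupation),
                ("outcome_pt", gs.outcome_pt_level),
                ("outcome_case", gs.outcome_case_level),
            ):
                for cat, (n, p) in data.items():
                    rows.append((group, block, cat, n, p))
            if gs.age_mean is not None:
                rows.append((group, "age", "mean", round2(gs.age_mean), float("nan")))
        emit("ALL", self.overall)
        for pid in sorted(self.per_product):
            emit(pid, self.per_product[pid])
        return pd.DataFrame(rows, columns=["group", "block", "category", "count", "pct"])


def region_of(country: Optional[str]) -> str:
    if not country:
        return "unknown"
    return REGION_BY_COUNTRY.get(country.upper(), "unknown")


def _summarize_group(cases: Sequence[CAECase]) -> GroupSummary:
    n = len(cases)

    def block(counts: Dict[str, int], total: int) -> Dict[str, Tuple[int, float]]:
        return {k: (v, pct(v, total)) for k, v in counts.items()}

    sex_counts = {"F": 0, "M": 0, "unknown": 0}
    age_counts = {b: 0 for b in _AGE_BANDS}
    ages: List[float] = []
    region_counts: Dict[str, int] = {}
    occ_counts = {o: 0 for o in _OCCUPATIONS}
    outcome_pt: Dict[str, int] = {}
    outcome_case: Dict[str, int] = {}
    n_entries = 0
    for case in cases:
        d = case.bundle.demographics
        sex_counts[d.sex if d.sex in ("F", "M") else "unknown"] += 1
        if d.age_years is None:
            age_counts["unknown"] += 1
        else:
            ages.append(d.age_years)
            if d.age_years < 19:
                age_counts["<19"] += 1
            elif d.age_years <= 65:
                age_counts["19-65"] += 1
            else:
                age_counts[">65"] += 1
        region_counts[region_of(d.country)] = region_counts.get(region_of(d.country), 0) + 1
        occ_counts[case.bundle.demographics.occupation] += 1
        outcome = case.most_severe_outcome
        if outcome is not None:
            outcome_case[outcome] = outcome_case.get(outcome, 0) + 1
            k = len(case.cae_pts)  # one outcome entry per cardiac PT occurrence
            outcome_pt[outcome] = outcome_pt.get(outcome, 0) + k
            n_entries += k
    if age_counts["<19"] == 0:
        age_counts.pop("<19")
    return GroupSummary(
        n_cases=n,
        sex=block(sex_counts, n),
        age_bands=block(age_counts, n),
        age_mean=float(np.mean(ages)) if ages else None,
        region=block(dict(sorted(region_counts.items())), n),
        occupation=block(occ_counts, n),
        outcome_pt_level=block(dict(sorted(outcome_pt.items())), n_entries),
        n_outcome_entries=n_entries,
        outcome_case_level=block(dict(sorted(outcome_case.items())), n),
    )


def demographic_summary(cases: Iterable[CAECase]) -> DemographicSummary:
    """Characteristics table: per-product and overall counts with percentages.

    The outcome block is reported both per cardiac-PT occurrence (each PT of
    a case inherits the case's most severe outcome; denominator = outcome
    entries) and per case (most-severe rule; denominator = cases), since the
    two conventions answer different questions.
    """
    all_cases = list(cases)
    per_product: Dict[str, List[CAECase]] = {}
    for c in all_cases:
        per_product.setdefault(c.product_id, []).append(c)
    return DemographicSummary(
        overall=_summarize_group(all_cases),
        per_product={pid: _summarize_group(v) for pid, v in per_product.items()},
    )


# ------------------------------------------------------- component classes


def cae_pt_counts(cases: Iterable[CAECase]) -> pd.DataFrame:
    """Per-(product, PT) cardiac event counts, one count per case."""
    rows = [(c.product_id, pt) for c in cases for pt in c.cae_pts]
    if not rows:
        return pd.DataFrame(columns=["product_id", "pt", "n"])
    df = pd.DataFrame(rows, columns=["product_id", "pt"])
    return df.groupby(["product_id", "pt"], as_index=False).size().rename(columns={"size": "n"})


@dataclass
class ClassRollup:
    per_class: Dict[str, pd.DataFrame]  # class -> top-k (pt, n)
    overall: pd.DataFrame  # element-wise class sums, top-k


def component_class_rollup(
    pt_counts: pd.DataFrame,
    dictionary: Sequence[DrugDictionaryEntry],
    k: int = 5,
) -> ClassRollup:
    """Top-k PT counts per component class and their element-wise overall sum.

    ``pt_counts`` needs columns (product_id, pt, n) — e.g. from
    :func:`cae_pt_counts` or a screen table's ``a`` column renamed to ``n``.
    Ties break alphabetically for determinism.
    """
    class_of = {e.product_id: e.component_class for e in dictionary}
    df = pt_counts.copy()
    df["component_class"] = df["product_id"].map(class_of)
    df = df.dropna(subset=["component_class"])

    def top(frame: pd.DataFrame) -> pd.DataFrame:
        agg = frame.groupby("pt", as_index=False)["n"].sum()
        agg = agg.sort_values(["n", "pt"], ascending=[False, True]).reset_index(drop=True)
        return agg.head(k)

    per_class = {
        cls: top(sub) for cls, sub in df.groupby("component_class", sort=True)
    }
    return ClassRollup(per_class=per_class, overall=top(df))
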