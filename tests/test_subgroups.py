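import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from faerspv.cohort import CAECase, load_meddra
from faerspv.dates import PartialDate
from faerspv.faers_io import CaseBundle, Demographics
from faerspv.subgroups import (
    ONSET_BIN_LABELS,
    OnsetRecord,
    age_ttest,
    cae_pt_counts,
    co_reported,
    component_class_rollup,
    death_subset,
    demographic_summary,
    make_onset_records,
    onset_bin,
    onset_by_stratum,
    onset_distribution,
    round2,
    time_to_onset,
)
from _table_fixtures import characteristics_cohort, top5_class_counts


def _case(pid, product="FUV", cae=("Atrial fibrillation",), other=(), outcomes=(),
          age=None, sex="unknown", event=None, start=None, seq=1):
    bundle = CaseBundle(
        primaryid=pid,
        demographics=Demographics(
            age_years=age, sex=sex, event_date=PartialDate.parse(event)
        ),
        reactions=list(cae) + list(other),
        outcomes=list(outcomes),
        therapy_starts={seq: PartialDate.parse(start)} if start else {},
    )
    return CAECase(
        bundle=bundle, product_id=product, cae_pts=list(cae), other_pts=list(other),
        unmapped_pts=[], most_severe_outcome=(outcomes[0] if outcomes else None),
        matched_drug_seqs=[seq],
    )


class TestTimeToOnset:
    @pytest.mark.parametrize(
        "start, event, days, status",
        [
            ("20200101", "20200101", 0, "ok"),
            ("20200101", "20200401", 91, "ok"),
            ("2020", "20200401", None, "partial_date"),
            ("202003", "20200401", None, "partial_date"),
            ("20200401", "20200101", None, "negative"),
            (None, "20200101", None, "partial_date"),
        ],
    )
    def test_examples(self, start, event, days, status):
        got_days, got_status = time_to_onset(
            PartialDate.parse(start) if start else None, PartialDate.parse(event)
        )
        assert (got_days, got_status) == (days, status)

    @given(st.integers(0, 3000))
    def test_bin_consistent_with_cutpoints(self, days):
        label = onset_bin(days)
        edges = {"day0": (0, 0), "d1_30": (1, 30), "d31_90": (31, 90),
                 "d91_180": (91, 180), "d181_365": (181, 365),
                 "d366_730": (366, 730), "d731_plus": (731, 10**9)}
        lo, hi = edges[label]
        assert lo <= days <= hi

    def test_exclusion_accounting(self):
        cases = [
            _case("1", start="20200101", event="20200301"),
            _case("2", start="2020", event="20200301"),  # partial start
            _case("3", start="20200601", event="20200101"),  # negative
            _case("4"),  # no dates at all
        ]
        ext = make_onset_records(cases)
        assert ext.n_cases_in == 1
        assert ext.excluded_partial_dates == 2
        assert ext.excluded_negative == 1
        assert ext.n_cases_in + ext.excluded_partial_dates + ext.excluded_negative == 4


class TestOnsetDistribution:
    def test_bin_counts_and_cumulative(self):
        recs = [
            OnsetRecord(str(i), "FUV", "Atrial fibrillation", d, onset_bin(d))
            for i, d in enumerate([0, 0, 15, 100])
        ]
        dist = onset_distribution(recs)
        assert dist.bin_counts["day0"] == 2
        assert dist.bin_counts["d1_30"] == 1
        assert dist.bin_counts["d91_180"] == 1
        assert dist.cum_prop_at(90) == pytest.approx(0.75)
        assert dist.day0_share == pytest.approx(0.5)

    def test_all_day0_curve_is_flat_one(self):
        recs = [OnsetRecord(str(i), "FUV", "X", 0, "day0") for i in range(5)]
        dist = onset_distribution(recs)
        assert list(dist.cumulative["cum_prop"]) == [1.0]

    @given(st.lists(st.integers(0, 1500), min_size=1, max_size=80))
    def test_cumulative_monotone_reaching_one(self, onsets):
        recs = [
            OnsetRecord(str(i), "FUV", "X", d, onset_bin(d)) for i, d in enumerate(onsets)
        ]
        dist = onset_distribution(recs)
        props = list(dist.cumulative["cum_prop"])
        assert all(x <= y + 1e-12 for x, y in zip(props, props[1:]))
        assert props[-1] == pytest.approx(1.0)
        assert int(dist.bin_counts.sum()) == len(onsets)


class TestOnsetStrata:
    def test_shares_sum_to_100_per_bin(self):
        recs = [
            OnsetRecord("1", "FUV", "X", 5, onset_bin(5), sex="F"),
            OnsetRecord("2", "FUV", "X", 10, onset_bin(10), sex="F"),
            OnsetRecord("3", "FUV", "X", 20, onset_bin(20), sex="F"),
            OnsetRecord("4", "FUV", "X", 25, onset_bin(25), sex="M"),
            OnsetRecord("5", "FUV", "X", 400, onset_bin(400), sex="M"),
        ]
        df = onset_by_stratum(recs, "sex")
        d1_30 = df[df["bin"] == "d1_30"]
        assert dict(zip(d1_30["category"], d1_30["pct"])) == {"F": 75.0, "M": 25.0}
        assert df.groupby("bin", observed=True)["pct"].sum().sub(100).abs().max() < 0.02

    def test_age_threshold_categories(self):
        recs = [
            OnsetRecord(str(i), "FUV", "X", 5, onset_bin(5), age_years=a)
            for i, a in enumerate([60.0, 71.0, 80.0, None])
        ]
        df = onset_by_stratum(recs, "age", age_threshold=70.5)
        counts = dict(zip(df["category"], df["n"]))
        assert counts == {">70.5": 2, "<=70.5": 1, "missing": 1}

    def test_age_independent_onsets_are_homogeneous(self):
        """With onsets independent of age, stratum shares are uniform across
        bins: a chi-square homogeneity test should rarely reject at 1%."""
        from scipy.stats import chi2_contingency

        rejections = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            days = np.where(rng.random(600) < 0.2, 0,
                            np.maximum(1, rng.lognormal(np.log(90), 1.2, 600))).astype(int)
            ages = rng.normal(70, 12, 600)
            recs = [
                OnsetRecord(str(i), "FUV", "X", int(d), onset_bin(int(d)),
                            age_years=float(a))
                for i, (d, a) in enumerate(zip(days, ages))
            ]
            df = onset_by_stratum(recs, "age", age_threshold=70.5)
            pivot = df.pivot_table(index="bin", columns="category", values="n",
                                   fill_value=0, observed=True)
            pivot = pivot.loc[(pivot.sum(axis=1) >= 10)]
            if chi2_contingency(pivot.to_numpy())[1] < 0.01:
                rejections += 1
        assert rejections <= 0.05 * n_seeds + 1


class TestDeathSubset:
    def test_median_and_mean(self):
        cases = [
            _case("1", outcomes=("DE",), age=54.0),
            _case("2", outcomes=("DE",), age=63.0),
            _case("3", outcomes=("HO",), age=80.0),  # not a death report
        ]
        stats, _ = death_subset(cases)
        assert stats["ALL"].n_cases == 2
        assert stats["ALL"].age_median == pytest.approx(58.5)
        assert stats["ALL"].age_mean == pytest.approx(58.5)

    def test_all_ages_missing(self):
        cases = [_case("1", outcomes=("DE",)), _case("2", outcomes=("DE",))]
        stats, tests = death_subset(cases)
        assert stats["ALL"].age_mean is None
        assert stats["ALL"].age_missing_frac == 1.0
        assert tests == {}  # undersized/empty age groups skipped

    def test_ttest_power_under_ten_year_shift(self):
        """n=100 per arm, 10-year mean shift: rejection at 1% nearly always."""
        rejections = 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            res = age_ttest(rng.normal(70, 12, 100), rng.normal(60, 12, 100))
            rejections += res.pvalue < 0.01
        assert rejections >= 0.99 * n_seeds - 1


class TestCoReported:
    def test_half_share(self, meddra):
        cases = [
            _case("1", other=("Dyspnoea",)),
            _case("2"),
        ]
        res = co_reported(cases, meddra)
        assert res.share_pct == 50.0
        assert res.n_with_other == 1

    def test_pt_counted_once_per_case(self, meddra):
        cases = [_case("1", other=("Dyspnoea",)), _case("2", other=("Dyspnoea", "Cough"))]
        res = co_reported(cases, meddra)
        counts = dict(zip(res.pt_counts["pt"], res.pt_counts["n"]))
        assert counts == {"Dyspnoea": 2, "Cough": 1}
        socs = dict(zip(res.soc_counts["soc"], res.soc_counts["n"]))
        assert socs == {"Respiratory, thoracic and mediastinal disorders": 2}

    def test_share_complements_pure_cardiac_fraction(self, meddra):
        cases = [_case(str(i), other=("Dyspnoea",) if i % 3 else ()) for i in range(30)]
        res = co_reported(cases, meddra)
        pure = sum(1 for c in cases if not c.other_pts) / len(cases)
        assert res.share_pct == pytest.approx(100 * (1 - pure), abs=0.01)


class TestDemographicSummary:
    def test_percentages_recompute_from_counts(self):
        cases = characteristics_cohort()
        summary = demographic_summary(cases).overall
        for block in (summary.sex, summary.age_bands, summary.region,
                      summary.occupation, summary.outcome_pt_level):
            total = sum(n for n, _ in block.values())
            for n, p in block.values():
                assert p == round2(100.0 * n / total)

    def test_empty_product_group_no_division_error(self):
        summary = demographic_summary([])
        assert summary.overall.n_cases == 0
        assert summary.overall.sex["F"] == (0, 0.0)

    def test_case_vs_pt_level_outcomes(self):
        cases = [
            _case("1", cae=("Atrial fibrillation", "Cardiac arrest"), outcomes=("DE",)),
            _case("2", outcomes=("HO",)),
        ]
        s = demographic_summary(cases).overall
        assert s.outcome_case_level["DE"][0] == 1
        assert s.outcome_pt_level["DE"][0] == 2  # two cardiac PTs inherit DE
        assert s.n_outcome_entries == 3


class TestComponentClassRollup:
    def test_published_class_sums(self, dictionary):
        rollup = component_class_rollup(top5_class_counts(), dictionary, k=5)
        overall = dict(zip(rollup.overall["pt"], rollup.overall["n"]))
        assert overall["Atrial fibrillation"] == 79
        assert overall["Myocardial infarction"] == 76

    def test_k_larger_than_vocabulary(self, dictionary):
        df = pd.DataFrame(
            [("FG", "Atrial fibrillation", 2)], columns=["product_id", "pt", "n"]
        )
        rollup = component_class_rollup(df, dictionary, k=10)
        assert len(rollup.overall) == 1

    def test_matches_brute_force_group_by(self, dictionary, paperlike_small):
        from faerspv import pipeline

        _, tables, _ = paperlike_small
        res = pipeline.run_from_frames(tables)
        counts = cae_pt_counts(res.cae_cases)
        rollup = component_class_rollup(counts, dictionary, k=3)
        class_of = {e.product_id: e.component_class for e in dictionary}
        brute = {}
        for c in res.cae_cases:
            cls = class_of[c.product_id]
            for pt in c.cae_pts:
                brute[(cls, pt)] = brute.get((cls, pt), 0) + 1
        for cls, frame in rollup.per_class.items():
            for rec in frame.itertuples():
                assert brute[(cls, rec.pt)] == rec.n
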