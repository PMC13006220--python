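import pytest
from hypothesis import given
from hypothesis import strategies as st

from faerspv.cohort import (
    CARDIAC_SOC,
    SEVERITY_ORDER,
    DrugDictionaryEntry,
    entry_for,
    extract_cae,
    in_search_window,
    match_candidates,
    match_case,
    match_target,
    most_severe,
    normalize_name,
    soc_distribution,
)
from faerspv.faers_io import CaseBundle, Demographics, DrugRecord


def _drug(drugname="", prod_ai=None, role="PS", seq=1):
    return DrugRecord(drug_seq=seq, drugname=drugname, prod_ai=prod_ai, role_cod=role)


def _bundle(pid="1", pts=(), drugs=(), quarter=None, outcomes=()):
    return CaseBundle(
        primaryid=pid,
        demographics=Demographics(event_quarter=quarter),
        drugs=list(drugs),
        reactions=list(pts),
        outcomes=list(outcomes),
    )


class TestNormalizeName:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("Trelegy  Ellipta.", "TRELEGY ELLIPTA"),
            ("fluticasone/umeclidinium/vilanterol", "FLUTICASONE/UMECLIDINIUM/VILANTEROL"),
            ("", ""),
            ("  anoro -- ellipta  ", "ANORO ELLIPTA"),
        ],
    )
    def test_examples(self, raw, expected):
        assert normalize_name(raw) == expected

    @given(st.text(max_size=40))
    def test_idempotent(self, s):
        assert normalize_name(normalize_name(s)) == normalize_name(s)


class TestMatchTarget:
    def test_brand_name_primary_suspect(self, dictionary):
        assert match_target(_drug("DUAKLIR PRESSAIR"), dictionary) == "FA"

    def test_non_ps_role_never_matches(self, dictionary):
        assert match_target(_drug("TRELEGY ELLIPTA", role="SS"), dictionary) is None

    def test_component_order_insensitive_in_prod_ai(self, dictionary):
        drug = _drug("", prod_ai="VILANTEROL/UMECLIDINIUM")
        assert match_target(drug, dictionary) == "VU"

    def test_triple_generic_prefers_most_specific_product(self, dictionary):
        # the triple name contains the dual component set; must resolve to FUV
        drug = _drug("FLUTICASONE/UMECLIDINIUM/VILANTEROL")
        assert match_candidates(drug, dictionary) == ["FUV"]
        assert match_target(drug, dictionary) == "FUV"
        bgf = _drug("BUDESONIDE/GLYCOPYRROLATE/FORMOTEROL")
        assert match_candidates(bgf, dictionary) == ["BGF"]

    def test_true_ambiguity_excluded(self):
        dup_dict = [
            DrugDictionaryEntry("P1", "LABA/LAMA", ("Alpha/beta",), (), (2014, 1)),
            DrugDictionaryEntry("P2", "LABA/LAMA", ("Alpha/gamma",), (), (2014, 1)),
        ]
        drug = _drug("ALPHA/BETA/GAMMA")
        assert match_target(drug, dup_dict) is None

    def test_case_with_two_products_excluded(self, dictionary):
        bundle = _bundle(
            drugs=[_drug("TRELEGY ELLIPTA", seq=1), _drug("ANORO ELLIPTA", seq=2)]
        )
        m = match_case(bundle, dictionary)
        assert m.product_id is None and m.ambiguous

    def test_matched_sequences_recorded(self, dictionary):
        bundle = _bundle(drugs=[_drug("ASPIRIN", seq=1), _drug("STIOLTO RESPIMAT", seq=2)])
        m = match_case(bundle, dictionary)
        assert m.product_id == "OT" and m.matched_drug_seqs == [2]


class TestSearchWindow:
    @pytest.mark.parametrize(
        "product, quarter, expected",
        [
            ("VU", (2014, 1), True),
            ("FUV", (2017, 3), False),
            ("FUV", (2017, 4), True),
            ("VU", (2024, 4), False),
        ],
    )
    def test_window_bounds(self, dictionary, product, quarter, expected):
        entry = entry_for(product, dictionary)
        assert in_search_window(_bundle(quarter=quarter), entry) is expected

    def test_missing_quarter_excluded(self, dictionary):
        entry = entry_for("VU", dictionary)
        assert in_search_window(_bundle(quarter=None), entry) is False

    def test_widening_window_is_monotone(self, dictionary):
        entry = entry_for("FUV", dictionary)
        widened = DrugDictionaryEntry(
            entry.product_id, entry.component_class, entry.generic_names,
            entry.brand_names, (2014, 1),
        )
        quarters = [(y, q) for y in range(2014, 2025) for q in range(1, 5)]
        for q in quarters:
            if in_search_window(_bundle(quarter=q), entry):
                assert in_search_window(_bundle(quarter=q), widened)


class TestMostSevere:
    @pytest.mark.parametrize(
        "codes, expected",
        [(["HO", "DE"], "DE"), (["OT"], "OT"), (["CA", "HO", "LT"], "LT"), ([], None)],
    )
    def test_examples(self, codes, expected):
        assert most_severe(codes) == expected

    def test_unknown_code_named_in_error(self):
        with pytest.raises(ValueError, match="XX"):
            most_severe(["DE", "XX"])

    @given(st.lists(st.sampled_from(SEVERITY_ORDER), min_size=1, max_size=7))
    def test_agrees_with_rank_minimum(self, codes):
        assert most_severe(codes) == min(codes, key=SEVERITY_ORDER.index)


class TestExtractCae:
    def test_partition_and_filtering(self, meddra):
        mixed = _bundle("1", ["Atrial fibrillation", "Dyspnoea", "MysteryTerm"])
        pure_other = _bundle("2", ["Cough"])
        result = extract_cae([(mixed, "FUV", [1]), (pure_other, "FUV", [1])], meddra)
        assert len(result.cases) == 1
        case = result.cases[0]
        assert case.cae_pts == ["Atrial fibrillation"]
        assert case.other_pts == ["Dyspnoea"]
        assert case.unmapped_pts == ["MysteryTerm"]
        assert result.unmapped_tally == {"MysteryTerm": 1}
        assert result.n_without_cae == 1

    def test_pt_partition_is_exhaustive(self, meddra):
        bundle = _bundle("1", ["Atrial fibrillation", "Dyspnoea", "Weird", "Nausea",
                              "Cardiac arrest", "Dyspnoea"])
        result = extract_cae([(bundle, "OT", [1])], meddra)
        case = result.cases[0]
        n_unique = len(set(bundle.reactions))
        assert len(case.cae_pts) + len(case.other_pts) + len(case.unmapped_pts) == n_unique
        assert not set(case.cae_pts) & set(case.other_pts)

    def test_planted_cardiac_cases_recovered(self, meddra, dictionary, paperlike_small):
        """Every generated PS report with a cardiac PT is extracted, no more."""
        from faerspv import pipeline

        _, tables, truth = paperlike_small
        res = pipeline.run_from_frames(tables)
        cardiac_pts = {pt for pt, (_, soc, _) in meddra._map.items()
                       if soc == CARDIAC_SOC}
        manifest = truth.case_manifest
        # expected: PS target reports whose drawn PTs include a cardiac one
        reac = tables["REAC"]
        cardiac_ids = set(
            reac[reac["pt"].str.lower().isin(cardiac_pts)]["primaryid"]
        )
        target_ps = manifest[(manifest["product"] != "") & manifest["is_ps"]]
        expected = set(target_ps["primaryid"]) & cardiac_ids
        assert {c.primaryid for c in res.cae_cases} == expected


class TestSocDistribution:
    def test_percentages_sum_to_100_per_product(self, meddra):
        bundles = [
            (_bundle("1", ["Atrial fibrillation", "Dyspnoea"]), "FUV"),
            (_bundle("2", ["Cough", "Nausea", "Dyspnoea"]), "FUV"),
            (_bundle("3", ["Cardiac arrest"]), "FG"),
        ]
        dist = soc_distribution(bundles, meddra)
        sums = dist.groupby("product_id")["pct"].sum()
        assert all(abs(s - 100.0) < 1e-9 for s in sums)
        fuv = dist[dist["product_id"] == "FUV"]
        resp = fuv[fuv["soc"] == "Respiratory, thoracic and mediastinal disorders"]
        assert resp["n_events"].iloc[0] == 3  # Dyspnoea twice (2 reports) + Cough

    def test_cardiac_rank_matches_independent_tally(self, meddra, paperlike_small):
        from faerspv import pipeline

        _, tables, _ = paperlike_small
        res = pipeline.run_from_frames(tables)
        dist = res.soc_dist
        fuv = dist[dist["product_id"] == "FUV"].reset_index(drop=True)
        # independent tally straight from the REAC table
        reac = tables["REAC"]
        matched_ids = {b.primaryid for b, pid, _ in res.matched if pid == "FUV"}
        sub = reac[reac["primaryid"].isin(matched_ids)].drop_duplicates()
        socs = sub["pt"].map(lambda p: meddra.soc(p) or "unmapped")
        top_soc = socs.value_counts().idxmax()
        assert fuv.iloc[0]["soc"] == top_soc
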