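"""HLI scoring: aMED quintiles, factor criteria, change categorisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organclock import columns as C
from organclock.lifestyle import (ALTERNATIVE_DEFINITIONS, FactorDefinitions,
                                  build_hli_records, categorize_change,
                                  classify_factors, compute_hli,
                                  load_definitions, score_amed)


def _diet_frame(rng, n):
    return pd.DataFrame({c: rng.uniform(10, 500, n) for c in C.DIET_COMPONENTS})


@pytest.fixture(scope="module")
def reference():
    return _diet_frame(np.random.default_rng(0), 500)


class TestAmed:
    def test_most_protective_extreme_scores_35(self, reference):
        person = {c: [reference[c].max() + 1] for c in C.DIET_COMPONENTS}
        person["diet_red_meat"] = [reference["diet_red_meat"].min() - 1]
        score = score_amed(pd.DataFrame(person), reference)
        assert score.iloc[0] == 35

    def test_least_protective_extreme_scores_7(self, reference):
        person = {c: [reference[c].min() - 1] for c in C.DIET_COMPONENTS}
        person["diet_red_meat"] = [reference["diet_red_meat"].max() + 1]
        score = score_amed(pd.DataFrame(person), reference)
        assert score.iloc[0] == 7

    def test_degenerate_constant_reference_scores_everyone_21(self):
        const = pd.DataFrame({c: np.full(50, 7.0) for c in C.DIET_COMPONENTS})
        scores = score_amed(const)
        assert (scores == 21).all()  # every component ties -> quintile 3

    def test_population_quintiles_are_even(self):
        rng = np.random.default_rng(1)
        pop = _diet_frame(rng, 1000)
        scores = score_amed(pop)
        assert scores.between(7, 35).all()
        # with smooth intakes the per-component quintiles are exact fifths,
        # so the mean component score is 3
        assert abs(scores.mean() - 21) < 0.5

    def test_missing_component_gives_nan(self, reference):
        person = reference.head(3).copy()
        person.loc[person.index[1], "diet_fish"] = np.nan
        scores = score_amed(person, reference)
        assert np.isnan(scores.iloc[1]) and not np.isnan(scores.iloc[0])

    def test_empty_reference_rejected(self, reference):
        with pytest.raises(ValueError):
            score_amed(reference.head(1), reference.iloc[0:0])

    @given(st.sampled_from(["log", "cube", "affine"]))
    @settings(max_examples=3, deadline=None)
    def test_invariant_to_monotone_intake_transforms(self, transform):
        """Rank-based scoring ignores any strictly monotone re-expression
        of a component's intake scale."""
        rng = np.random.default_rng(5)
        pop = _diet_frame(rng, 300)
        base = score_amed(pop)
        fn = {"log": np.log, "cube": lambda v: v**3,
              "affine": lambda v: 2.5 * v + 7}[transform]
        warped = pop.copy()
        warped["diet_fruits"] = fn(warped["diet_fruits"])
        assert (score_amed(warped) == base).all()


def _raw_record(smoking="never", drink=0.0, exercise="3-5_per_week", sleep=7.5):
    rec = {C.SMOKING_STATUS: [smoking], C.DRINK_FREQ: [drink],
           C.EXERCISE_FREQ: [exercise], C.SLEEP_HOURS: [sleep]}
    for c in C.DIET_COMPONENTS:
        rec[c] = [100.0]
    return pd.DataFrame(rec)


class TestFactorClassification:
    def test_fully_healthy_record(self):
        rec = _raw_record()
        flags = classify_factors(rec, amed=pd.Series([30.0]), amed_threshold=25.0)
        out = compute_hli(flags)
        assert out["hli"].iloc[0] == 5
        assert out["hli_category"].iloc[0] == "healthy"

    def test_fully_unhealthy_record(self):
        rec = _raw_record(smoking="current", drink=7.0, exercise="never", sleep=5.0)
        flags = classify_factors(rec, amed=pd.Series([10.0]), amed_threshold=25.0)
        out = compute_hli(flags)
        assert out["hli"].iloc[0] == 0
        assert out["hli_category"].iloc[0] == "unfavorable"

    @pytest.mark.parametrize("sleep,healthy", [
        (7.0, 1), (8.0, 1), (7.5, 1), (6.99, 0), (8.01, 0)])
    def test_sleep_interval_is_closed(self, sleep, healthy):
        rec = _raw_record(sleep=sleep)
        flags = classify_factors(rec, amed=pd.Series([30.0]), amed_threshold=25.0)
        assert flags["healthy_sleep"].iloc[0] == healthy

    @pytest.mark.parametrize("drink,healthy", [(0.0, 1), (0.99, 1), (1.0, 0), (3.0, 0)])
    def test_alcohol_strictly_below_once_a_week(self, drink, healthy):
        rec = _raw_record(drink=drink)
        flags = classify_factors(rec, amed=pd.Series([30.0]), amed_threshold=25.0)
        assert flags["healthy_alcohol"].iloc[0] == healthy

    def test_former_smoker_unhealthy_under_primary_but_not_alternative(self):
        rec = _raw_record(smoking="former")
        amed, thr = pd.Series([30.0]), 25.0
        assert classify_factors(rec, amed=amed, amed_threshold=thr)["healthy_smoking"].iloc[0] == 0
        alt = ALTERNATIVE_DEFINITIONS["smoking"]
        assert classify_factors(rec, alt, amed=amed, amed_threshold=thr)["healthy_smoking"].iloc[0] == 1

    def test_diet_median_threshold_is_inclusive(self):
        rec = pd.concat([_raw_record()] * 4, ignore_index=True)
        amed = pd.Series([10.0, 20.0, 20.0, 30.0])
        flags = classify_factors(rec, amed=amed)  # median = 20
        assert flags["healthy_diet"].tolist() == [0, 1, 1, 1]

    def test_unknown_category_level_rejected(self):
        rec = _raw_record(smoking="vaping")
        with pytest.raises(ValueError, match="smoking"):
            classify_factors(rec, amed=pd.Series([30.0]), amed_threshold=25.0)


class TestHLI:
    @given(st.lists(st.integers(0, 1), min_size=5, max_size=5))
    @settings(max_examples=40, deadline=None)
    def test_sum_and_dichotomy(self, bits):
        flags = pd.DataFrame([dict(zip(
            [f"healthy_{f}" for f in C.LIFESTYLE_FACTORS], bits))])
        out = compute_hli(flags)
        assert out["hli"].iloc[0] == sum(bits)
        expected = "healthy" if sum(bits) >= 4 else "unfavorable"
        assert out["hli_category"].iloc[0] == expected

    def test_permutation_invariance(self):
        cols = [f"healthy_{f}" for f in C.LIFESTYLE_FACTORS]
        a = pd.DataFrame([dict(zip(cols, [1, 0, 1, 0, 1]))])
        b = pd.DataFrame([dict(zip(cols, [0, 1, 1, 1, 0]))])
        assert compute_hli(a)["hli"].iloc[0] == compute_hli(b)["hli"].iloc[0]

    def test_non_binary_flags_rejected(self):
        cols = [f"healthy_{f}" for f in C.LIFESTYLE_FACTORS]
        bad = pd.DataFrame([dict(zip(cols, [2, 0, 0, 0, 0]))])
        with pytest.raises(ValueError):
            compute_hli(bad)


def _two_wave_records(hli0_flags, hli1_flags):
    cols = [f"healthy_{f}" for f in C.LIFESTYLE_FACTORS]
    rows = []
    for wave, flags in ((0, hli0_flags), (1, hli1_flags)):
        rec = dict(zip(cols, flags))
        rec.update(person_id=1, wave=wave)
        rows.append(rec)
    df = pd.DataFrame(rows)
    return compute_hli(df)


class TestChangeCategories:
    def test_score_rise_is_healthier_on_both_scales(self):
        rec = _two_wave_records([1, 1, 0, 0, 0], [1, 1, 1, 1, 0])  # 2 -> 4
        ch = categorize_change(rec)
        assert ch["change_hli_range"].iloc[0] == "healthier"
        assert ch["change_hli_category"].iloc[0] == "healthier"

    def test_no_change(self):
        rec = _two_wave_records([1] * 5, [1] * 5)
        ch = categorize_change(rec)
        assert ch["change_hli_range"].iloc[0] == "unchanged"
        assert all(ch[f"change_{f}"].iloc[0] == "unchanged" for f in C.LIFESTYLE_FACTORS)

    def test_factor_relapse_is_unhealthier(self):
        rec = _two_wave_records([1, 1, 1, 1, 1], [0, 1, 1, 1, 1])
        ch = categorize_change(rec)
        assert ch["change_smoking"].iloc[0] == "unhealthier"

    def test_antisymmetry_under_wave_swap(self):
        rec = _two_wave_records([1, 0, 1, 0, 0], [0, 1, 1, 1, 0])
        swapped = rec.copy()
        swapped["wave"] = 1 - swapped["wave"]
        ch, ch_sw = categorize_change(rec), categorize_change(swapped)
        flip = {"healthier": "unhealthier", "unhealthier": "healthier",
                "unchanged": "unchanged"}
        for col in [c for c in ch.columns if c.startswith("change_")]:
            assert ch_sw[col].iloc[0] == flip[ch[col].iloc[0]]


class TestEndToEndScoring:
    def test_build_hli_records_covers_everyone(self, study_cohort):
        data, _ = study_cohort
        rec = build_hli_records(data)
        assert len(rec) == len(data)
        assert rec["hli"].between(0, 5).all()
        assert rec["amed"].between(7, 35).all()
        # per-wave median split makes ~half the wave healthy on diet
        share = rec.groupby("wave")["healthy_diet"].mean()
        assert ((share - 0.5).abs() < 0.05).all()

    def test_shipped_definitions_roundtrip(self):
        primary, alts = load_definitions()
        assert primary == FactorDefinitions()
        assert set(alts) == set(C.LIFESTYLE_FACTORS)
        assert alts["sleep"].sleep_range == (6.0, 9.0)
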