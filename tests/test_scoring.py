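"""Unit and property tests for the 2023 Nutri-Score point engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutrisurv.scoring import (
    KJ_PER_KCAL,
    ConfigurationError,
    FoodCategory,
    NutrientProfile,
    classify_letter,
    compute_favourable_points,
    compute_score,
    compute_unfavourable_points,
    load_point_tables,
    points_for_component,
    profile_from_row,
    score_extrema,
)

GENERAL = FoodCategory.GENERAL
ALL_SCORED = [FoodCategory.GENERAL, FoodCategory.BEVERAGE, FoodCategory.FATS_OILS,
              FoodCategory.CHEESE, FoodCategory.RED_MEAT]


def oracle_points(component, value, category):
    """Independent linear scan of the transcribed threshold lists."""
    from nutrisurv.scoring import _CATEGORY_TABLE
    groups = load_point_tables()["components"][_CATEGORY_TABLE[category][0]]
    spec = (groups["unfavourable"] | groups["favourable"])[component]
    pts = spec.get("points", list(range(1, len(spec["thresholds"]) + 1)))
    best = 0
    for th, p in zip(spec["thresholds"], pts):
        if value > th:
            best = p
    return best


class TestPointLookup:
    def test_below_first_threshold_is_zero(self):
        assert points_for_component("sugars", 0.0, GENERAL) == 0

    def test_saturates_at_component_maximum(self):
        assert points_for_component("sugars", 999.0, GENERAL) == 15
        assert points_for_component("salt", 999.0, GENERAL) == 20

    def test_exact_threshold_earns_lower_points(self):
        # 3.4 g sugars is the first threshold: equal stays at 0
        assert points_for_component("sugars", 3.4, GENERAL) == 0
        assert points_for_component("sugars", 3.4 + 1e-9, GENERAL) == 1

    @pytest.mark.parametrize("category", ALL_SCORED)
    def test_matches_linear_scan_oracle_at_boundaries(self, category):
        from nutrisurv.scoring import _CATEGORY_TABLE
        groups = load_point_tables()["components"][_CATEGORY_TABLE[category][0]]
        for gname in ("unfavourable", "favourable"):
            for comp, spec in groups[gname].items():
                for th in spec["thresholds"]:
                    for v in (th - 1e-9, th, th + 1e-9):
                        assert points_for_component(comp, v, category) == \
                            oracle_points(comp, v, category), (comp, v)

    def test_unknown_pairing_raises_naming_both(self):
        with pytest.raises(ConfigurationError, match="satfat_ratio.*general_food"):
            points_for_component("satfat_ratio", 1.0, GENERAL)

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            points_for_component("sugars", -1.0, GENERAL)


def profile(**kw):
    base = dict(energy_kj=0, sugars_g=0, saturated_fat_g=0, salt_g=0,
                fibre_g=0, protein_g=0, fvl_percent=0, total_fat_g=0)
    base.update(kw)
    return NutrientProfile(**base)


class TestUnfavourable:
    def test_all_zero_profile(self):
        assert compute_unfavourable_points(profile(), GENERAL) == 0

    def test_saturated_profile_reaches_55(self):
        p = profile(energy_kj=4000, sugars_g=60, saturated_fat_g=12,
                    salt_g=5, total_fat_g=30)
        assert compute_unfavourable_points(p, GENERAL) == 55

    def test_midrange_profile_is_componentwise_sum(self):
        p = profile(energy_kj=1500, sugars_g=12, saturated_fat_g=4.5,
                    salt_g=0.9, total_fat_g=10)
        expected = (oracle_points("energy", 1500, GENERAL)
                    + oracle_points("sugars", 12, GENERAL)
                    + oracle_points("saturated_fat", 4.5, GENERAL)
                    + oracle_points("salt", 0.9, GENERAL))
        assert compute_unfavourable_points(p, GENERAL) == expected == 4 + 3 + 4 + 4

    def test_fats_ratio_rule_and_energy_from_saturates(self):
        # olive-oil-like: 14% saturates of 100 g fat -> 1 ratio point,
        # energy from saturates 14*37=518 kJ -> 1 energy point
        p = profile(energy_kj=3700, saturated_fat_g=14, total_fat_g=100)
        assert compute_unfavourable_points(p, FoodCategory.FATS_OILS) == 2

    def test_fats_ratio_with_zero_total_fat_is_zero_points(self):
        p = profile(energy_kj=100)
        assert compute_unfavourable_points(p, FoodCategory.FATS_OILS) == 0


class TestFavourable:
    MAXED = dict(fibre_g=8, protein_g=18, fvl_percent=100)

    def test_all_zero_profile(self):
        assert compute_favourable_points(profile(), GENERAL, a_points=0) == 0

    def test_maximum_is_17_below_protein_cutoff(self):
        assert compute_favourable_points(profile(**self.MAXED), GENERAL, a_points=10) == 17

    def test_protein_suppressed_at_cutoff(self):
        assert compute_favourable_points(profile(**self.MAXED), GENERAL, a_points=11) == 10

    def test_cheese_exempt_from_suppression(self):
        assert compute_favourable_points(
            profile(**self.MAXED), FoodCategory.CHEESE, a_points=30) == 17

    def test_red_meat_protein_capped_at_two(self):
        assert compute_favourable_points(
            profile(**self.MAXED), FoodCategory.RED_MEAT, a_points=0) == 12


class TestScore:
    def test_all_zero_general_food_scores_zero(self):
        fs = compute_score(profile(), GENERAL)
        assert (fs.a_points, fs.c_points, fs.score) == (0, 0, 0)

    def test_printed_range_endpoints(self):
        worst = profile(energy_kj=4000, sugars_g=60, saturated_fat_g=12,
                        salt_g=5, total_fat_g=30)
        best = profile(fibre_g=8, protein_g=18, fvl_percent=100)
        assert compute_score(worst, GENERAL).score == 55
        assert compute_score(best, GENERAL).score == -17

    def test_water_is_class_a_score_zero(self):
        fs = compute_score(None, FoodCategory.WATER)
        assert (fs.score, fs.letter) == (0, "A")

    def test_validation_error_names_field(self):
        with pytest.raises(ValueError, match="sugars_g"):
            profile(sugars_g=-0.1)
        with pytest.raises(ValueError, match="saturated_fat_g"):
            profile(saturated_fat_g=5, total_fat_g=2)

    @settings(max_examples=150, deadline=None)
    @given(
        energy=st.floats(0, 4000), sugars=st.floats(0, 80),
        satfrac=st.floats(0, 1), fat=st.floats(0, 100), salt=st.floats(0, 6),
        fibre=st.floats(0, 15), prot=st.floats(0, 40), fvl=st.floats(0, 100),
        category=st.sampled_from(ALL_SCORED),
    )
    def test_score_equals_a_minus_c_with_bounds(self, energy, sugars, satfrac,
                                                fat, salt, fibre, prot, fvl, category):
        p = profile(energy_kj=energy, sugars_g=sugars, saturated_fat_g=fat * satfrac,
                    salt_g=salt, fibre_g=fibre, protein_g=prot, fvl_percent=fvl,
                    total_fat_g=fat)
        fs = compute_score(p, category)
        assert fs.score == fs.a_points - fs.c_points
        lo, hi = score_extrema(category)
        assert lo <= fs.score <= hi
        if category is GENERAL:
            assert 0 <= fs.a_points <= 55 and 0 <= fs.c_points <= 17

    @settings(max_examples=60, deadline=None)
    @given(
        energy=st.floats(0, 3000), sugars=st.floats(0, 40),
        sat=st.floats(0, 12), salt=st.floats(0, 3),
        bump=st.floats(0.1, 20),
        comp=st.sampled_from(["energy_kj", "sugars_g", "saturated_fat_g", "salt_g"]),
    )
    def test_increasing_unfavourable_never_decreases_score(self, energy, sugars,
                                                           sat, salt, bump, comp):
        kw = dict(energy_kj=energy, sugars_g=sugars, saturated_fat_g=sat,
                  salt_g=salt, total_fat_g=100, fibre_g=5, protein_g=10,
                  fvl_percent=50)
        s0 = compute_score(profile(**kw), GENERAL).score
        kw[comp] += bump * (100 if comp == "energy_kj" else 1)
        assert compute_score(profile(**kw), GENERAL).score >= s0

    @settings(max_examples=60, deadline=None)
    @given(fibre=st.floats(0, 10), fvl=st.floats(0, 90), bump=st.floats(0.1, 10),
           comp=st.sampled_from(["fibre_g", "fvl_percent"]))
    def test_increasing_favourable_never_increases_score(self, fibre, fvl, bump, comp):
        kw = dict(energy_kj=800, sugars_g=5, saturated_fat_g=2, salt_g=0.5,
                  fibre_g=fibre, protein_g=8, fvl_percent=fvl, total_fat_g=5)
        s0 = compute_score(profile(**kw), GENERAL).score
        kw[comp] = min(kw[comp] + bump, 100 if comp == "fvl_percent" else kw[comp] + bump)
        assert compute_score(profile(**kw), GENERAL).score <= s0


class TestLetters:
    def test_endpoints_of_attainable_range(self):
        lo, hi = score_extrema(GENERAL)
        assert classify_letter(lo, GENERAL) == "A"
        assert classify_letter(hi, GENERAL) == "E"

    @pytest.mark.parametrize("score,letter", [
        (0, "A"), (1, "B"), (2, "B"), (3, "C"), (10, "C"),
        (11, "D"), (18, "D"), (19, "E"),
    ])
    def test_general_band_boundaries(self, score, letter):
        assert classify_letter(score, GENERAL) == letter

    def test_fats_band_shifted_a_boundary(self):
        assert classify_letter(-6, FoodCategory.FATS_OILS) == "A"
        assert classify_letter(-5, FoodCategory.FATS_OILS) == "B"

    def test_five_classes_over_food_ranges(self):
        for cat in (GENERAL, FoodCategory.FATS_OILS, FoodCategory.CHEESE):
            lo, hi = score_extrema(cat)
            letters = {classify_letter(s, cat) for s in range(lo, hi + 1)}
            assert letters == {"A", "B", "C", "D", "E"}

    def test_beverages_span_b_to_e_water_is_a(self):
        lo, hi = score_extrema(FoodCategory.BEVERAGE)
        letters = {classify_letter(s, FoodCategory.BEVERAGE) for s in range(lo, hi + 1)}
        assert letters == {"B", "C", "D", "E"}
        assert classify_letter(0, FoodCategory.WATER) == "A"

    def test_letters_monotone_in_score(self):
        for cat in ALL_SCORED:
            lo, hi = score_extrema(cat)
            seq = [classify_letter(s, cat) for s in range(lo, hi + 1)]
            assert seq == sorted(seq)

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            classify_letter(56, GENERAL)


class TestExtrema:
    def test_general_food_range_is_minus17_to_55(self):
        assert score_extrema(GENERAL) == (-17, 55)

    def test_beverage_extrema_match_enumeration_oracle(self):
        # brute force over the transcribed beverage point values
        import itertools
        groups = load_point_tables()["components"]["beverage"]
        unf = [[0] + s.get("points", list(range(1, len(s["thresholds"]) + 1)))
               for s in groups["unfavourable"].values()]
        fav = [[0] + s.get("points", list(range(1, len(s["thresholds"]) + 1)))
               for s in groups["favourable"].values()]
        scores = [sum(a) - sum(c) for a in itertools.product(*unf)
                  for c in itertools.product(*fav)]
        assert score_extrema(FoodCategory.BEVERAGE) == (min(scores), max(scores))

    def test_degenerate_empty_tables_give_zero_range(self):
        import copy
        degenerate = copy.deepcopy(load_point_tables())
        for group in degenerate["components"]["general"].values():
            for spec in group.values():
                spec["thresholds"] = []
                spec.pop("points", None)
        assert score_extrema(GENERAL, degenerate) == (0, 0)

    def test_water_extrema(self):
        assert score_extrema(FoodCategory.WATER) == (0, 0)


class TestIngestion:
    def test_kcal_to_kj_and_sodium_to_salt(self):
        row = dict(energy_kcal=100.0, sugars_g=1.0, satfat_g=0.5, totalfat_g=1.0,
                   sodium_g=0.4, fibre_g=0.0, protein_g=2.0, fvl_pct=0.0)
        p = profile_from_row(row)
        assert p.energy_kj == pytest.approx(100 * KJ_PER_KCAL)
        assert p.salt_g == pytest.approx(1.0)
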