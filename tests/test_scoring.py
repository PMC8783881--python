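"""Original algorithm: band lookups, protein rule, score and classes.

The lookup oracle is an independent straight-line threshold scan; expected
spot values are the published band edges (27 g sugar -> 5 pts etc.).
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nutriscore_wg import (
    FoodCategory,
    FoodRecord,
    FoodScorer,
    assign_class,
    component_points,
    protein_rule,
    satfat_ratio_points,
    score_food_original,
)
from nutriscore_wg.bands import FVNLO_MAX_PTS, default_band_tables

from tests.conftest import random_foods_frame


def scan_points(value, table):
    """Linear threshold scan: advance while the band test passes."""
    idx = 0
    inclusive = table.comparison in ("at_least", "strictly_less")
    for t in table.thresholds:
        if (value >= t) if inclusive else (value > t):
            idx += 1
        else:
            break
    return table.points[idx]


@pytest.mark.parametrize("value,component,category,expected", [
    (27, "sugar", "solid_food", 5),      # inclusive upper edge of band 5
    (27.01, "sugar", "solid_food", 6),
    (3, "satfat", "solid_food", 2),
    (540, "sodium", "solid_food", 5),
    (180, "sodium", "solid_food", 1),
    (4.8, "fibre", "solid_food", 5),     # above the 4.7 g maximum threshold
    (4.7, "fibre", "solid_food", 4),
    (0, "energy", "solid_food", 0),
    (3350, "energy", "solid_food", 9),
    (3351, "energy", "solid_food", 10),
    (100, "fvnlo", "solid_food", 5),
    (0, "energy", "beverage", 0),
    (30, "energy", "beverage", 1),       # "≤ 30 kJ" stays in the 1-point band
    (271, "energy", "beverage", 10),
    (0, "sugar", "beverage", 0),
    (13.6, "sugar", "beverage", 10),
    (100, "fvnlo", "beverage", 10),
])
def test_component_points_spot_values(value, component, category, expected):
    assert component_points(value, component, category) == expected


def test_lookup_matches_threshold_scan_oracle():
    """Engine lookup equals a linear scan for 1000 random values per table."""
    rng = np.random.default_rng(42)
    for (comp, cat), table in default_band_tables().items():
        hi = table.thresholds[-1] * 1.3
        values = np.concatenate([
            rng.uniform(0, hi, 1000),
            np.asarray(table.thresholds, dtype=float),  # exact edges
        ])
        got = table.lookup_array(values)
        expected = [scan_points(v, table) for v in values]
        assert got.tolist() == expected, (comp, cat)


@pytest.mark.parametrize("satfat,totalfat,expected", [
    (5, 100, 0),     # ratio 5, below the first cut
    (0, 50, 0),
    (64, 100, 10),   # ratio 64 is inside the top band (closed below)
    (63.9, 100, 9),
    (10, 100, 1),
])
def test_satfat_ratio_points(satfat, totalfat, expected):
    assert satfat_ratio_points(satfat, totalfat) == expected


def test_satfat_ratio_requires_fat():
    with pytest.raises(ValueError):
        satfat_ratio_points(1, 0)


def test_protein_rule_exhaustive_grid():
    """Rule table over the full a_total × fvnlo grid, all categories.

    Protein drops iff a_total ≥ 11 and FVNLO points are below the category
    maximum; cheese is always exempt.
    """
    for category in FoodCategory:
        fv_max = FVNLO_MAX_PTS[category]
        for a_total in range(41):
            for fv in range(fv_max + 1):
                expected = (
                    category is FoodCategory.cheese
                    or a_total < 11
                    or fv == fv_max
                )
                assert protein_rule(a_total, fv, category) is expected


def _solid(**over):
    base = dict(food_id="S", category="solid_food", energy_kj=0, satfat_g=0,
                totalfat_g=0, sugar_g=0, sodium_mg=0, fibre_g=0, protein_g=0,
                fvnlo_pct=0, wholegrain_g=0, water_g=0)
    base.update(over)
    return FoodRecord(**base)


def test_score_extremes():
    """All-zero food scores 0; maximised favourables −15; worst case +40."""
    assert score_food_original(_solid())[1] == 0
    best = _solid(fvnlo_pct=100, fibre_g=10, protein_g=20)
    assert score_food_original(best)[1] == -15
    worst = _solid(energy_kj=3700, satfat_g=20, totalfat_g=30, sugar_g=90,
                   sodium_mg=2000, protein_g=20)  # protein dropped by the rule
    pb, score = score_food_original(worst)
    assert score == 40 and not pb.protein_counted


@pytest.mark.parametrize("score,category,is_water,expected", [
    (-15, "solid_food", False, "A"), (-1, "solid_food", False, "A"),
    (0, "solid_food", False, "B"), (2, "solid_food", False, "B"),
    (3, "solid_food", False, "C"), (10, "solid_food", False, "C"),
    (11, "solid_food", False, "D"), (18, "solid_food", False, "D"),
    (19, "solid_food", False, "E"), (40, "solid_food", False, "E"),
    (0, "beverage", True, "A"), (25, "beverage", True, "A"),
    (-3, "beverage", False, "B"), (1, "beverage", False, "B"),
    (2, "beverage", False, "C"), (5, "beverage", False, "C"),
    (6, "beverage", False, "D"), (9, "beverage", False, "D"),
    (10, "beverage", False, "E"),
])
def test_assign_class_boundaries(score, category, is_water, expected):
    assert assign_class(score, category, is_water) == expected


def test_scalar_and_vector_paths_agree():
    """FoodScorer (vectorised) equals the per-record scalar scoring."""
    df = random_foods_frame(400, seed=11)
    scored = FoodScorer().fit().transform(df)
    for i in np.random.default_rng(0).choice(len(df), 60, replace=False):
        rec = FoodRecord(**df.iloc[int(i)].to_dict())
        pb, score = score_food_original(rec)
        row = scored.iloc[int(i)]
        assert row["original_score"] == score
        assert row["a_total"] == pb.a_total and row["c_total"] == pb.c_total


nutrient = st.floats(0, 100, allow_nan=False)


@given(
    energy=st.floats(0, 3700), sugar=nutrient, satfat=st.floats(0, 50),
    sodium=st.floats(0, 2000), fibre=st.floats(0, 15), protein=st.floats(0, 40),
    fvnlo=nutrient, bump=st.floats(0.1, 50),
    which=st.sampled_from(["energy_kj", "sugar_g", "sodium_mg", "satfat_g",
                           "fibre_g", "protein_g", "fvnlo_pct"]),
)
def test_score_monotone_in_each_component(energy, sugar, satfat, sodium,
                                          fibre, protein, fvnlo, bump, which):
    """More of an unfavourable nutrient never lowers the score; more fibre
    or FVNLO never raises it (protein may flip the counting rule either
    way, so it is checked only when counted in both states)."""
    base = dict(food_id="S", category="solid_food", energy_kj=energy,
                satfat_g=satfat, totalfat_g=satfat, sugar_g=sugar,
                sodium_mg=sodium, fibre_g=fibre, protein_g=protein,
                fvnlo_pct=fvnlo, wholegrain_g=0, water_g=0)
    bumped = dict(base)
    bumped[which] = min(bumped[which] + bump, 100) if which == "fvnlo_pct" else bumped[which] + bump
    if which == "satfat_g":
        bumped["totalfat_g"] = bumped["satfat_g"]
    pb0, s0 = score_food_original(FoodRecord(**base))
    pb1, s1 = score_food_original(FoodRecord(**bumped))
    if which in ("energy_kj", "sugar_g", "sodium_mg", "satfat_g"):
        assert s1 >= s0
    elif which in ("fibre_g", "fvnlo_pct"):
        assert s1 <= s0
    elif pb0.protein_counted and pb1.protein_counted:
        assert s1 <= s0


def test_range_conservation_on_random_suite():
    """Scores of random valid solid/cheese/added-fat foods stay in [−15, 40]."""
    df = random_foods_frame(100_000, seed=5,
                            categories=["solid_food", "cheese", "added_fat"])
    scored = FoodScorer().fit().transform(df)
    assert scored["original_score"].between(-15, 40).all()


def test_missing_band_table_is_configuration_error(default_cfg):
    with pytest.raises(LookupError):
        component_points(1.0, "unobtainium", "solid_food", default_cfg)
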