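import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nutriscore_wg import FoodScorer, GeneratorConfig, ScoringConfig, simulate
from nutriscore_wg.dietscore import DietScorer

settings.register_profile(
    "suite", derandomize=True, max_examples=150,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cfg():
    return ScoringConfig.default()


@pytest.fixture(scope="session")
def survey():
    """One full-scale synthetic survey shared across statistical tests."""
    foods, intakes, dq, gt = simulate(GeneratorConfig(seed=7))
    return {"foods": foods, "intakes": intakes, "dq": dq, "ground_truth": gt}


@pytest.fixture(scope="session")
def scored_survey(survey):
    scored = FoodScorer().fit().transform(survey["foods"])
    merged = survey["foods"].merge(
        scored.drop(columns=["group", "category", "is_water"]), on="food_id"
    )
    return merged


@pytest.fixture(scope="session")
def survey_diets(survey, scored_survey):
    scorer = DietScorer().fit(scored_survey)
    diets = scorer.transform(survey["intakes"])
    return diets, scorer.excluded_persons_


def random_foods_frame(n: int, seed: int, categories=None) -> pd.DataFrame:
    """Random *valid* foods table built directly with numpy (fast at 1e5)."""
    rng = np.random.default_rng(seed)
    if categories is None:
        categories = ["solid_food", "beverage", "cheese", "added_fat"]
        probs = [0.7, 0.1, 0.1, 0.1]
    else:
        probs = None
    cat = rng.choice(categories, size=n, p=probs)
    water = np.round(rng.uniform(0, 95, n), 1)
    dry = np.round(100.0 - water, 9)
    totalfat = np.round(rng.uniform(0, 100, n), 2)
    totalfat = np.where(cat == "added_fat", np.maximum(totalfat, 1.0), totalfat)
    satfat = np.round(totalfat * rng.uniform(0, 1, n), 2)
    wg = np.where(rng.random(n) < 0.4,
                  np.floor(rng.uniform(0, 1, n) * dry * 100) / 100, 0.0)
    return pd.DataFrame({
        "food_id": [f"R{i:06d}" for i in range(n)],
        "name": "random", "group": "random", "category": cat,
        "is_water": False,
        "energy_kj": np.round(rng.uniform(0, 3700, n), 1),
        "satfat_g": satfat, "totalfat_g": totalfat,
        "sugar_g": np.round(rng.uniform(0, 100, n), 2),
        "sodium_mg": np.round(rng.uniform(0, 2000, n), 1),
        "fibre_g": np.round(rng.uniform(0, 15, n), 2),
        "protein_g": np.round(rng.uniform(0, 40, n), 2),
        "fvnlo_pct": np.round(rng.uniform(0, 100, n), 1),
        "wholegrain_g": wg, "water_g": water,
    })
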