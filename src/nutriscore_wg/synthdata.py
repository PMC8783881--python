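"""Seeded generator of food-composition and single-day intake tables.

The generator emulates the statistical shape of a national food-composition
database (nutrient distributions per food group, a grain group spanning the
whole-grain bands with point masses at 0% and 100% of dry matter) and a
one-day dietary survey (per-person food lists with energy, a designed
fraction of whole-grain non-consumers, and a pseudo diet-quality index with
a configurable correlation to the whole-diet score). Same seed, same bytes.

Nutrients are truncated log-normals per group; saturated fat is a Beta
fraction of total fat so the composition invariants hold by construction.
Grain-group fibre rises with whole-grain content (whole-meal flour carries
roughly twice the fibre of white), which is what makes high whole-grain
foods score better even before the whole-grain points are added.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .model import DRY_MATTER_DECIMALS, FoodCategory, validate_foods_frame

__all__ = ["GroupProfile", "GeneratorConfig", "generate_foods",
           "generate_intakes", "simulate"]


class GroupProfile(BaseModel):
    """Distribution parameters for one food group.

    Nutrient medians are per 100 g as consumed; ``*_sigma`` are log-scale
    standard deviations of the log-normal draws. ``wg_prob`` is the chance a
    food contains whole grain at all; among those, ``wg_full_prob`` is the
    chance of exactly 100% of dry matter and the rest is uniform over
    5–99% so every cut-off band is populated.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    category: FoodCategory = FoodCategory.solid_food
    weight: float = Field(gt=0)
    is_water: bool = False
    grain_group: bool = False
    energy_median: float = 800.0
    energy_sigma: float = 0.4
    totalfat_median: float = 4.0
    totalfat_sigma: float = 0.7
    satfat_frac_alpha: float = 2.0
    satfat_frac_beta: float = 4.0
    sugar_median: float = 5.0
    sugar_sigma: float = 0.8
    sodium_median: float = 200.0
    sodium_sigma: float = 0.8
    fibre_median: float = 1.5
    fibre_sigma: float = 0.5
    protein_median: float = 6.0
    protein_sigma: float = 0.4
    fvnlo_range: tuple[float, float] = (0.0, 10.0)
    water_range: tuple[float, float] = (40.0, 80.0)
    wg_prob: float = Field(default=0.0, ge=0, le=1)
    wg_full_prob: float = Field(default=0.2, ge=0, le=1)


DEFAULT_GROUPS: tuple[GroupProfile, ...] = (
    GroupProfile(name="grain products", weight=0.20, grain_group=True,
                 energy_median=1300, sugar_median=4, sodium_median=300,
                 fibre_median=2.5, fibre_sigma=0.35, protein_median=9,
                 protein_sigma=0.3, totalfat_median=3,
                 fvnlo_range=(0, 20), water_range=(5, 45),
                 wg_prob=0.55, wg_full_prob=0.18),
    GroupProfile(name="cereal based dishes", weight=0.12, grain_group=True,
                 energy_median=900, sugar_median=6, sodium_median=350,
                 fibre_median=1.8, protein_median=7, totalfat_median=7,
                 fvnlo_range=(0, 40), water_range=(40, 70),
                 wg_prob=0.15, wg_full_prob=0.05),
    GroupProfile(name="vegetables", weight=0.12, energy_median=150,
                 sugar_median=3, sodium_median=30, fibre_median=2.5,
                 protein_median=2, totalfat_median=0.5,
                 fvnlo_range=(80, 100), water_range=(80, 95)),
    GroupProfile(name="fruit", weight=0.10, energy_median=250,
                 sugar_median=10, sodium_median=5, fibre_median=2,
                 protein_median=1, totalfat_median=0.3,
                 fvnlo_range=(90, 100), water_range=(75, 90)),
    GroupProfile(name="meat poultry and fish", weight=0.12, energy_median=800,
                 sugar_median=0.5, sodium_median=350, fibre_median=0.2,
                 fibre_sigma=0.8, protein_median=20, protein_sigma=0.2,
                 totalfat_median=8, fvnlo_range=(0, 5), water_range=(55, 75)),
    GroupProfile(name="milk and yoghurt", weight=0.08, energy_median=350,
                 sugar_median=6, sodium_median=60, fibre_median=0.1,
                 fibre_sigma=0.8, protein_median=4, totalfat_median=3,
                 satfat_frac_alpha=6, satfat_frac_beta=3,
                 fvnlo_range=(0, 5), water_range=(75, 90)),
    GroupProfile(name="cheese", weight=0.06, category=FoodCategory.cheese,
                 energy_median=1400, sugar_median=1, sodium_median=700,
                 fibre_median=0.05, fibre_sigma=0.8, protein_median=22,
                 protein_sigma=0.2, totalfat_median=28, totalfat_sigma=0.3,
                 satfat_frac_alpha=8, satfat_frac_beta=4,
                 fvnlo_range=(0, 0), water_range=(35, 55)),
    GroupProfile(name="snacks and confectionery", weight=0.08,
                 energy_median=1900, energy_sigma=0.25, sugar_median=30,
                 sugar_sigma=0.5, sodium_median=250, fibre_median=1.5,
                 protein_median=5, totalfat_median=18, totalfat_sigma=0.4,
                 satfat_frac_alpha=5, satfat_frac_beta=4,
                 fvnlo_range=(0, 15), water_range=(2, 15),
                 wg_prob=0.10, wg_full_prob=0.0, grain_group=False),
    GroupProfile(name="fats and oils", weight=0.05,
                 category=FoodCategory.added_fat, energy_median=3000,
                 energy_sigma=0.15, sugar_median=0.2, sodium_median=300,
                 fibre_median=0.05, fibre_sigma=0.8, protein_median=0.5,
                 totalfat_median=80, totalfat_sigma=0.15,
                 satfat_frac_alpha=3, satfat_frac_beta=4,
                 fvnlo_range=(0, 60), water_range=(2, 20)),
    GroupProfile(name="beverages", weight=0.07,
                 category=FoodCategory.beverage, energy_median=140,
                 energy_sigma=0.5, sugar_median=6, sugar_sigma=0.6,
                 sodium_median=10, fibre_median=0.1, fibre_sigma=0.8,
                 protein_median=0.3, totalfat_median=0.1,
                 fvnlo_range=(0, 100), water_range=(85, 98)),
)


class GeneratorConfig(BaseModel):
    """Stated world of the synthetic survey; defaults are the test scale.

    ``consumer_fraction`` of persons eat at least one whole-grain food
    (about half, as in surveys where a majority are non-consumers);
    ``dq_target_corr`` is the target Pearson correlation between the pseudo
    diet-quality score and the person's whole-diet score (negative: a lower
    profiling score means a better diet). ``wg_fibre_effect`` is the extra
    fibre (g/100 g) a food gains going from 0% to 100% whole grain.
    """

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_foods: int = Field(default=500, ge=20)
    n_persons: int = Field(default=2000, ge=1)
    groups: tuple[GroupProfile, ...] = DEFAULT_GROUPS
    n_water_items: int = 2
    foods_per_person_mean: float = 15.0
    foods_per_person_min: int = 5
    foods_per_person_max: int = 30
    grams_median: float = 80.0
    grams_sigma: float = 0.6
    consumer_fraction: float = Field(default=0.5, ge=0, le=1)
    wg_items_rate: float = 3.0
    dq_target_corr: float = Field(default=-0.6, ge=-1, le=1)
    wg_fibre_effect: float = 6.0
    include_water_only_person: bool = True


def _lognormal(rng, median, sigma, n, cap):
    return np.minimum(median * np.exp(sigma * rng.standard_normal(n)), cap)


def generate_foods(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a validated foods table (canonical foods.csv columns).

    The first grain group deterministically includes foods at exactly 0%,
    25%, 50% and 100% whole grain of dry matter so every band edge is
    represented; remaining whole-grain contents are drawn from the
    zero/full/uniform mixture.
    """
    rng = np.random.default_rng(config.seed)
    weights = np.array([g.weight for g in config.groups], dtype=float)
    counts = np.maximum(
        np.round(weights / weights.sum() * (config.n_foods - config.n_water_items)),
        1,
    ).astype(int)
    rows: list[dict] = []
    grain_edges_pending = [0.0, 25.0, 50.0, 100.0]
    for profile, n in zip(config.groups, counts):
        water = np.round(rng.uniform(*profile.water_range, n), 1)
        dry = np.round(100.0 - water, DRY_MATTER_DECIMALS)
        energy = np.round(_lognormal(rng, profile.energy_median, profile.energy_sigma, n, 3700))
        totalfat = np.round(_lognormal(rng, profile.totalfat_median, profile.totalfat_sigma, n, 100), 2)
        if profile.category is FoodCategory.added_fat:
            totalfat = np.maximum(totalfat, 40.0)
        satfrac = rng.beta(profile.satfat_frac_alpha, profile.satfat_frac_beta, n)
        satfat = np.round(totalfat * satfrac, 2)
        sugar = np.round(_lognormal(rng, profile.sugar_median, profile.sugar_sigma, n, 95), 2)
        sodium = np.round(_lognormal(rng, profile.sodium_median, profile.sodium_sigma, n, 4000), 1)
        protein = np.round(_lognormal(rng, profile.protein_median, profile.protein_sigma, n, 60), 2)
        fvnlo = np.round(rng.uniform(*profile.fvnlo_range, n), 1)

        has_wg = rng.random(n) < profile.wg_prob
        full = rng.random(n) < profile.wg_full_prob
        wg_pct = np.where(has_wg, np.where(full, 100.0, rng.uniform(5, 99, n)), 0.0)
        if profile.grain_group and grain_edges_pending:
            take = min(len(grain_edges_pending), n)
            water[:take] = 10.0
            dry = np.round(100.0 - water, DRY_MATTER_DECIMALS)
            wg_pct[:take] = grain_edges_pending[:take]
            del grain_edges_pending[:take]
        # floor to 2 decimals so rounding never pushes wg above dry matter;
        # exact-100% foods get wg == dry so the percentage round-trips to 100
        wg_g = np.floor(wg_pct / 100.0 * dry * 100.0) / 100.0
        wg_g[wg_pct == 100.0] = dry[wg_pct == 100.0]
        fibre_base = _lognormal(rng, profile.fibre_median, profile.fibre_sigma, n, 25)
        fibre = np.round(fibre_base + config.wg_fibre_effect * wg_pct / 100.0, 2)

        for i in range(n):
            rows.append({
                "name": f"{profile.name} item {i + 1}",
                "group": profile.name,
                "category": profile.category.value,
                "is_water": False,
                "energy_kj": float(energy[i]), "satfat_g": float(satfat[i]),
                "totalfat_g": float(totalfat[i]), "sugar_g": float(sugar[i]),
                "sodium_mg": float(sodium[i]), "fibre_g": float(fibre[i]),
                "protein_g": float(protein[i]), "fvnlo_pct": float(fvnlo[i]),
                "wholegrain_g": float(wg_g[i]), "water_g": float(water[i]),
            })
    for i in range(config.n_water_items):
        rows.append({
            "name": f"water item {i + 1}", "group": "water",
            "category": FoodCategory.beverage.value, "is_water": True,
            "energy_kj": 0.0, "satfat_g": 0.0, "totalfat_g": 0.0,
            "sugar_g": 0.0, "sodium_mg": 0.0, "fibre_g": 0.0,
            "protein_g": 0.0, "fvnlo_pct": 0.0, "wholegrain_g": 0.0,
            "water_g": 100.0,
        })
    foods = pd.DataFrame(rows)
    foods.insert(0, "food_id", [f"F{i:05d}" for i in range(1, len(foods) + 1)])
    _, rejections = validate_foods_frame(foods)
    if rejections:
        raise RuntimeError(f"generator produced invalid foods: {rejections[:3]}")
    return foods


def generate_intakes(
    config: GeneratorConfig, foods: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate one survey day per person plus the pseudo diet-quality table.

    Returns ``(intakes, dietquality, ground_truth)``. Consumers draw
    1 + Poisson whole-grain items with grams scaled by a personal
    whole-grain propensity, producing a within-consumer intake gradient;
    non-consumers never touch a whole-grain-containing food. The
    diet-quality score is a noisy linear function of the person's negated
    modified whole-diet score calibrated to ``dq_target_corr``.
    """
    from .dietscore import DietScorer
    from .scoring import FoodScorer

    rng = np.random.default_rng(config.seed + 1)
    wg_ids = foods.loc[foods["wholegrain_g"] > 0, "food_id"].to_numpy()
    plain = foods.loc[
        (foods["wholegrain_g"] == 0) & (foods["energy_kj"] > 0), "food_id"
    ].to_numpy()
    water_ids = foods.loc[foods["is_water"], "food_id"].to_numpy()
    energy_per_100g = foods.set_index("food_id")["energy_kj"]

    rows: list[dict] = []
    person_ids = [f"P{i:05d}" for i in range(1, config.n_persons + 1)]
    consumer = rng.random(config.n_persons) < config.consumer_fraction
    if len(wg_ids) == 0:
        consumer[:] = False
    for pid, is_consumer in zip(person_ids, consumer):
        n_items = int(np.clip(rng.poisson(config.foods_per_person_mean),
                              config.foods_per_person_min,
                              config.foods_per_person_max))
        chosen: list[str] = []
        propensity = 0.0
        if is_consumer:
            propensity = rng.uniform(0.2, 1.0)
            k_wg = int(min(1 + rng.poisson(config.wg_items_rate * propensity),
                           max(n_items - 1, 1), len(wg_ids)))
            chosen += list(rng.choice(wg_ids, size=k_wg, replace=False))
        k_plain = max(n_items - len(chosen), 1)
        chosen += list(rng.choice(plain, size=min(k_plain, len(plain)), replace=False))
        grams = np.round(np.clip(
            config.grams_median * np.exp(config.grams_sigma * rng.standard_normal(len(chosen))),
            10, 500), 1)
        if is_consumer:
            grams[: len(chosen) - k_plain] = np.round(
                grams[: len(chosen) - k_plain] * (0.5 + propensity), 1)
        for fid, g in zip(chosen, grams):
            rows.append({
                "person_id": pid, "food_id": fid, "grams_consumed": float(g),
                "energy_kj_consumed": round(float(g) * float(energy_per_100g[fid]) / 100.0, 1),
            })
        if len(water_ids) and rng.random() < 0.3:
            rows.append({"person_id": pid,
                         "food_id": str(rng.choice(water_ids)),
                         "grams_consumed": 250.0, "energy_kj_consumed": 0.0})
    water_only_person = None
    if config.include_water_only_person and len(water_ids):
        water_only_person = "P00000"
        rows.append({"person_id": water_only_person, "food_id": str(water_ids[0]),
                     "grams_consumed": 500.0, "energy_kj_consumed": 0.0})
    intakes = pd.DataFrame(rows, columns=["person_id", "food_id",
                                          "grams_consumed", "energy_kj_consumed"])
    intakes = intakes.sort_values(["person_id", "food_id"], kind="stable").reset_index(drop=True)

    # pseudo diet-quality index calibrated to the modified whole-diet score
    scored = FoodScorer().fit().transform(foods)
    food_info = scored.merge(foods[["food_id", "wholegrain_g"]], on="food_id")
    diets = DietScorer().fit(food_info).transform(intakes)
    score = diets["whole_diet_modified"].to_numpy(float)
    z = (score - score.mean()) / score.std() if score.std() > 0 else np.zeros_like(score)
    rho = config.dq_target_corr
    noise = rng.standard_normal(len(score))
    dq_z = rho * z + np.sqrt(max(1.0 - rho ** 2, 0.0)) * noise
    dq = np.clip(np.round(50.0 + 15.0 * dq_z, 2), 0.0, 100.0)
    dietquality = pd.DataFrame({"person_id": diets["person_id"], "dq_score": dq})

    ground_truth = {
        "seed": config.seed,
        "n_foods": int(len(foods)),
        "n_persons": config.n_persons,
        "consumer_fraction": config.consumer_fraction,
        "realised_consumer_fraction": float(consumer.mean()),
        "dq_target_corr": config.dq_target_corr,
        "wg_fibre_effect": config.wg_fibre_effect,
        "water_only_person": water_only_person,
    }
    return intakes, dietquality, ground_truth


def simulate(config: GeneratorConfig, out_dir: str | Path | None = None):
    """Run the full generator; optionally write the four output files."""
    foods = generate_foods(config)
    intakes, dietquality, ground_truth = generate_intakes(config, foods)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        foods.to_csv(out / "foods.csv", index=False)
        intakes.to_csv(out / "intakes.csv", index=False)
        dietquality.to_csv(out / "dietquality.csv", index=False)
        (out / "ground_truth.json").write_text(json.dumps(ground_truth, indent=2))
    return foods, intakes, dietquality, ground_truth
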