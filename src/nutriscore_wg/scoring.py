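"""The points-based nutrient-profiling score and its A–E classes.

A food earns unfavourable ("A") points for energy, saturated fat, total
sugar and sodium (0–10 each) and favourable ("C") points for FVNLO, fibre
and protein (0–5 each; beverage FVNLO up to 10). The final score is

    score = A_total − (FVNLO + fibre + protein·[protein counted])

where protein is dropped when A_total ≥ 11 unless the food is a cheese or
already holds maximal FVNLO points. Solid foods range over −15 (best) to
+40 (worst); five classes A–E are assigned from fixed integer boundaries,
with bottled/plain water always labelled A.

:class:`FoodScorer` is the sklearn-style transformer over a validated foods
table; the module-level functions are scalar wrappers around the same band
tables.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .bands import FVNLO_MAX_PTS, WG_PRESETS, ScoringConfig
from .model import BandTable, FoodCategory, FoodRecord, PointsBreakdown
from .wholegrain import wg_dry_pct_array

__all__ = [
    "component_points",
    "satfat_ratio_points",
    "protein_rule",
    "score_food_original",
    "assign_class",
    "exhaustive_score_range",
    "FoodScorer",
    "FOOD_CLASS_UPPER",
    "BEVERAGE_CLASS_UPPER",
]

#: Inclusive upper score bound per class for foods: A ≤ −1, B ≤ 2, C ≤ 10, D ≤ 18, E above.
FOOD_CLASS_UPPER = ((-1, "A"), (2, "B"), (10, "C"), (18, "D"))
#: For beverages (water is forced to A): B ≤ 1, C ≤ 5, D ≤ 9, E ≥ 10.
BEVERAGE_CLASS_UPPER = ((1, "B"), (5, "C"), (9, "D"))

# which table category serves each (component, food category)
_BEVERAGE_OWN = {"energy", "sugar", "fvnlo"}


def _resolve_table(
    tables: Mapping[tuple[str, FoodCategory], BandTable],
    component: str,
    category: FoodCategory,
) -> BandTable:
    cat = (
        FoodCategory.beverage
        if category is FoodCategory.beverage and component in _BEVERAGE_OWN
        else FoodCategory.solid_food
    )
    key = (component, cat)
    if key not in tables:
        raise LookupError(f"no band table configured for {key}")
    return tables[key]


def component_points(
    value: float,
    component: str,
    category: FoodCategory | str,
    config: ScoringConfig | None = None,
) -> int:
    """Points for one component content under the category's band table."""
    category = FoodCategory(category)
    cfg = config or ScoringConfig.default()
    return _resolve_table(cfg.tables(), component, category).lookup(value)


def satfat_ratio_points(
    satfat_g: float, totalfat_g: float, config: ScoringConfig | None = None
) -> int:
    """Added-fat saturated-fat points from the ratio 100·satfat/totalfat."""
    if totalfat_g <= 0:
        raise ValueError("added fat requires totalfat_g > 0")
    cfg = config or ScoringConfig.default()
    table = cfg.tables()[("satfat_ratio", FoodCategory.added_fat)]
    return table.lookup(100.0 * satfat_g / totalfat_g)


def protein_rule(a_total: int, fvnlo_pts: int, category: FoodCategory | str) -> bool:
    """Whether protein points count towards the final score.

    Protein is excluded when unfavourable points reach 11, unless the food
    is a cheese or already earns its category's maximal FVNLO points.
    """
    category = FoodCategory(category)
    if category is FoodCategory.cheese:
        return True
    return a_total < 11 or fvnlo_pts >= FVNLO_MAX_PTS[category]


def assign_class(score: int, category: FoodCategory | str, is_water: bool = False) -> str:
    """Map an integer score to its A–E class; water is always A."""
    category = FoodCategory(category)
    if category is FoodCategory.beverage:
        if is_water:
            return "A"
        for upper, label in BEVERAGE_CLASS_UPPER:
            if score <= upper:
                return label
        return "E"
    for upper, label in FOOD_CLASS_UPPER:
        if score <= upper:
            return label
    return "E"


def _breakdown(record: FoodRecord, cfg: ScoringConfig) -> PointsBreakdown:
    tables = cfg.tables()
    cat = record.category
    energy = _resolve_table(tables, "energy", cat).lookup(record.energy_kj)
    sugar = _resolve_table(tables, "sugar", cat).lookup(record.sugar_g)
    sodium = _resolve_table(tables, "sodium", cat).lookup(record.sodium_mg)
    if cat is FoodCategory.added_fat:
        satfat = satfat_ratio_points(record.satfat_g, record.totalfat_g, cfg)
    else:
        satfat = _resolve_table(tables, "satfat", cat).lookup(record.satfat_g)
    fvnlo = _resolve_table(tables, "fvnlo", cat).lookup(record.fvnlo_pct)
    fibre = _resolve_table(tables, "fibre", cat).lookup(record.fibre_g)
    protein = _resolve_table(tables, "protein", cat).lookup(record.protein_g)
    a_total = energy + satfat + sugar + sodium
    counted = protein_rule(a_total, fvnlo, cat)
    if cat in cfg.wholegrain.apply_to:
        wg = cfg.wholegrain.to_band_table().lookup(
            float(wg_dry_pct_array([record.wholegrain_g], [record.water_g])[0])
        )
    else:
        wg = 0
    return PointsBreakdown(
        energy_pts=energy, satfat_pts=satfat, sugar_pts=sugar, sodium_pts=sodium,
        fvnlo_pts=fvnlo, fibre_pts=fibre, protein_pts=protein,
        protein_counted=counted, wg_pts=wg,
    )


def score_food_original(
    record: FoodRecord, config: ScoringConfig | None = None
) -> tuple[PointsBreakdown, int]:
    """Score one validated food under the original algorithm."""
    cfg = config or ScoringConfig.default()
    pb = _breakdown(record, cfg)
    return pb, pb.a_total - pb.c_total


def exhaustive_score_range() -> tuple[int, int]:
    """Min/max solid-food score over every component-point combination.

    Enumerates the full lattice of unfavourable (4 × 0–10) and favourable
    (3 × 0–5) component points, applying the protein rule, and returns the
    attained (min, max) — the printed −15…+40 range.
    """
    e, s, su, so = np.meshgrid(*(np.arange(11),) * 4, indexing="ij", sparse=True)
    a = (e + s + su + so).reshape(-1, 1, 1, 1)
    fv, fi, pr = np.meshgrid(*(np.arange(6),) * 3, indexing="ij", sparse=True)
    counted = (a < 11) | (fv == 5)
    score = a - fv - fi - np.where(counted, pr, 0)
    return int(score.min()), int(score.max())


class FoodScorer(TransformerMixin, BaseEstimator):
    """Score a foods table under the original and whole-grain-modified algorithm.

    Parameters
    ----------
    config : ScoringConfig, str path, or None
        Full engine configuration; None uses the built-in defaults.
    fibre_method : {'aoac', 'nsp'} or None
        Overrides the config's fibre band scale.
    wg_preset : str or None
        Named whole-grain band preset ('wgi-135' default, 'wgi-245').
    apply_wholegrain : bool
        If False, the modified score equals the original.

    After ``fit``, ``transform`` maps a validated foods DataFrame (the
    canonical foods.csv columns) to a per-food DataFrame of component
    points, totals, both scores and both classes.
    """

    def __init__(self, config=None, *, fibre_method=None, wg_preset=None,
                 apply_wholegrain=True):
        self.config = config
        self.fibre_method = fibre_method
        self.wg_preset = wg_preset
        self.apply_wholegrain = apply_wholegrain

    def fit(self, X=None, y=None):
        if isinstance(self.config, ScoringConfig):
            cfg = self.config
        else:
            cfg = ScoringConfig.from_file(self.config)
        if self.fibre_method is not None:
            cfg = cfg.model_copy(update={"fibre_method": self.fibre_method})
        if self.wg_preset is not None:
            wg = cfg.wholegrain.model_copy(update={"bands": WG_PRESETS[self.wg_preset]})
            cfg = cfg.model_copy(update={"wholegrain": wg})
        self.config_ = cfg
        self.tables_ = cfg.tables()
        self.wg_table_ = cfg.wholegrain.to_band_table()
        return self

    def _check_fitted(self):
        if not hasattr(self, "config_"):
            raise NotFittedError("FoodScorer is not fitted; call fit() first")

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Score every food row; X must already pass validation."""
        self._check_fitted()
        required = ["food_id", "category", "energy_kj", "satfat_g", "totalfat_g",
                    "sugar_g", "sodium_mg", "fibre_g", "protein_g", "fvnlo_pct",
                    "wholegrain_g", "water_g"]
        missing = [c for c in required if c not in X.columns]
        if missing:
            raise ValueError(f"foods table is missing columns: {missing}")
        cat = X["category"].astype(str).to_numpy()
        is_bev = cat == FoodCategory.beverage.value
        is_cheese = cat == FoodCategory.cheese.value
        is_fat = cat == FoodCategory.added_fat.value
        is_water = (
            X["is_water"].astype(bool).to_numpy() if "is_water" in X.columns
            else np.zeros(len(X), bool)
        )

        def solid(comp):
            return self.tables_[(comp, FoodCategory.solid_food)]

        def bev(comp):
            return self.tables_[(comp, FoodCategory.beverage)]

        def dual(comp, values):
            pts = solid(comp).lookup_array(values)
            if is_bev.any():
                pts = np.where(is_bev, bev(comp).lookup_array(values), pts)
            return pts

        energy_pts = dual("energy", X["energy_kj"].to_numpy(float))
        sugar_pts = dual("sugar", X["sugar_g"].to_numpy(float))
        fvnlo_pts = dual("fvnlo", X["fvnlo_pct"].to_numpy(float))
        sodium_pts = solid("sodium").lookup_array(X["sodium_mg"].to_numpy(float))
        fibre_pts = solid("fibre").lookup_array(X["fibre_g"].to_numpy(float))
        protein_pts = solid("protein").lookup_array(X["protein_g"].to_numpy(float))

        satfat = X["satfat_g"].to_numpy(float)
        satfat_pts = solid("satfat").lookup_array(satfat)
        if is_fat.any():
            totalfat = X["totalfat_g"].to_numpy(float)
            if np.any(is_fat & (totalfat <= 0)):
                raise ValueError("added_fat rows require totalfat_g > 0")
            ratio = np.zeros(len(X))
            np.divide(100.0 * satfat, totalfat, out=ratio, where=is_fat)
            ratio_tab = self.tables_[("satfat_ratio", FoodCategory.added_fat)]
            satfat_pts = np.where(is_fat, ratio_tab.lookup_array(ratio), satfat_pts)

        a_total = energy_pts + satfat_pts + sugar_pts + sodium_pts
        fvnlo_max = np.where(is_bev, 10, 5)
        protein_counted = (a_total < 11) | is_cheese | (fvnlo_pts >= fvnlo_max)
        c_total = fvnlo_pts + fibre_pts + np.where(protein_counted, protein_pts, 0)
        original = a_total - c_total

        wg_pct = wg_dry_pct_array(
            X["wholegrain_g"].to_numpy(float), X["water_g"].to_numpy(float)
        )
        wg_applies = np.isin(cat, [c.value for c in self.config_.wholegrain.apply_to])
        if not self.apply_wholegrain:
            wg_applies = np.zeros(len(X), bool)
        wg_pts = np.where(wg_applies, self.wg_table_.lookup_array(wg_pct), 0)
        modified = original + wg_pts

        def classes(scores):
            return np.array([
                assign_class(int(s), c, w)
                for s, c, w in zip(scores, cat, is_water)
            ])

        out = pd.DataFrame({
            "food_id": X["food_id"].to_numpy(),
            "group": X["group"].to_numpy() if "group" in X.columns else "",
            "category": cat,
            "is_water": is_water,
            "energy_pts": energy_pts, "satfat_pts": satfat_pts,
            "sugar_pts": sugar_pts, "sodium_pts": sodium_pts,
            "fvnlo_pts": fvnlo_pts, "fibre_pts": fibre_pts,
            "protein_pts": protein_pts, "protein_counted": protein_counted,
            "a_total": a_total, "c_total": c_total,
            "wg_pct_dry": wg_pct, "wg_pts": wg_pts,
            "original_score": original, "modified_score": modified,
            "original_class": classes(original), "modified_class": classes(modified),
        })
        return out

    def get_feature_names_out(self, input_features=None):
        self._check_fitted()
        return np.asarray([
            "food_id", "group", "category", "is_water",
            "energy_pts", "satfat_pts", "sugar_pts", "sodium_pts",
            "fvnlo_pts", "fibre_pts", "protein_pts", "protein_counted",
            "a_total", "c_total", "wg_pct_dry", "wg_pts",
            "original_score", "modified_score", "original_class", "modified_class",
        ], dtype=object)
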