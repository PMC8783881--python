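"""Domain types shared by the scoring engine, diet aggregation and generator.

The engine works on two tabular inputs:

* a food-composition table — one row per food with per-100 g nutrient
  contents, a four-way category (solid food / beverage / cheese / added fat),
  the combined fruit-vegetable-nut-legume-oil percentage (FVNLO), and the
  whole-grain ingredient content in grams of dry ingredient per 100 g of food
  as consumed;
* a single-day intake table — one row per (person, food) with grams and
  energy consumed.

Records are validated with pydantic; DataFrame-level validation with
row-by-row rejection reporting lives in :func:`validate_foods_frame`.
"""

from __future__ import annotations

import enum
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "FoodCategory",
    "FoodRecord",
    "BandTable",
    "PointsBreakdown",
    "ScoredFood",
    "IntakeRecord",
    "DietScoreResult",
    "validate_food",
    "validate_foods_frame",
    "FOODS_COLUMNS",
    "INTAKES_COLUMNS",
    "DRY_MATTER_DECIMALS",
]

#: Canonical CSV headers (order matters; readers require an exact match).
FOODS_COLUMNS = [
    "food_id", "name", "group", "category", "is_water",
    "energy_kj", "satfat_g", "totalfat_g", "sugar_g", "sodium_mg",
    "fibre_g", "protein_g", "fvnlo_pct", "wholegrain_g", "water_g",
]
INTAKES_COLUMNS = ["person_id", "food_id", "grams_consumed", "energy_kj_consumed"]

#: Dry matter (100 - water_g) is rounded to this many decimals before use so
#: that a food written as "100% whole grain on dry basis" round-trips through
#: CSV to exactly 100% (binary floats make 100 - 89.9 slightly off 10.1).
DRY_MATTER_DECIMALS = 9

_TOL = 1e-9


class FoodCategory(str, enum.Enum):
    """The four Nutri-Score scoring classes a food can fall in.

    Each category selects its own set of component band tables; water is a
    flag on top of ``beverage`` (it always labels class A and is excluded
    from diet-level analyses).
    """

    solid_food = "solid_food"
    beverage = "beverage"
    cheese = "cheese"
    added_fat = "added_fat"


class FoodRecord(BaseModel):
    """One food with per-100 g composition.

    ``wholegrain_g`` is grams of whole-grain ingredients on a dry-ingredient
    basis per 100 g of food as consumed; it can therefore never exceed the
    food's dry matter ``100 - water_g``.
    """

    model_config = ConfigDict(frozen=True)

    food_id: str
    name: str = ""
    group: str = ""
    category: FoodCategory
    is_water: bool = False
    energy_kj: float = Field(ge=0)
    satfat_g: float = Field(ge=0)
    totalfat_g: float = Field(ge=0)
    sugar_g: float = Field(ge=0)
    sodium_mg: float = Field(ge=0)
    fibre_g: float = Field(ge=0)
    protein_g: float = Field(ge=0)
    fvnlo_pct: float = Field(ge=0, le=100)
    wholegrain_g: float = Field(ge=0)
    water_g: float = Field(ge=0, le=100)

    @model_validator(mode="after")
    def _check_cross_field(self) -> "FoodRecord":
        if self.satfat_g > self.totalfat_g + _TOL:
            raise ValueError(
                f"satfat_g ({self.satfat_g}) exceeds totalfat_g ({self.totalfat_g})"
            )
        dry = round(100.0 - self.water_g, DRY_MATTER_DECIMALS)
        if self.wholegrain_g > dry + _TOL:
            raise ValueError(
                f"wholegrain_g ({self.wholegrain_g}) exceeds dry matter ({dry})"
            )
        if self.is_water and self.category is not FoodCategory.beverage:
            raise ValueError("is_water requires category = beverage")
        if self.category is FoodCategory.added_fat and self.totalfat_g <= 0:
            raise ValueError("added_fat requires totalfat_g > 0")
        return self


class BandTable(BaseModel):
    """Ordered threshold -> points mapping for one scoring component.

    ``points`` has one more entry than ``thresholds``; ``points[0]`` is the
    score below the first threshold. ``comparison`` fixes the boundary
    semantics: ``strictly_greater``/``at_most`` advance a band only when the
    value strictly exceeds a threshold (a content equal to a threshold stays
    in the lower-points band, matching "≤ 27 g ↔ ≤ 5 points" style edges),
    while ``at_least``/``strictly_less`` advance on equality (used for the
    added-fat saturated-fat ratio, where ≥ 64 earns the top band).
    """

    model_config = ConfigDict(frozen=True)

    component: str
    category: FoodCategory
    thresholds: tuple[float, ...]
    points: tuple[int, ...]
    comparison: Literal[
        "strictly_greater", "at_most", "at_least", "strictly_less"
    ] = "strictly_greater"

    @model_validator(mode="after")
    def _check_bands(self) -> "BandTable":
        t = np.asarray(self.thresholds, dtype=float)
        if len(t) == 0:
            raise ValueError("band table needs at least one threshold")
        if not np.all(np.diff(t) > 0):
            raise ValueError("thresholds must be strictly increasing")
        if len(self.points) != len(t) + 1:
            raise ValueError("points must have len(thresholds) + 1 entries")
        d = np.diff(self.points)
        if not (np.all(d >= 0) or np.all(d <= 0)):
            raise ValueError("points must be monotone in band index")
        return self

    @property
    def side(self) -> str:
        # searchsorted side: 'left' counts thresholds < v, 'right' counts <= v
        return "left" if self.comparison in ("strictly_greater", "at_most") else "right"

    def lookup(self, value: float) -> int:
        """Points of the deepest band whose threshold test passes."""
        return int(self.points[int(np.searchsorted(self.thresholds, value, side=self.side))])

    def lookup_array(self, values: np.ndarray | Sequence[float]) -> np.ndarray:
        pts = np.asarray(self.points)
        idx = np.searchsorted(self.thresholds, np.asarray(values, dtype=float), side=self.side)
        return pts[idx]


class PointsBreakdown(BaseModel):
    """Per-component points for one food.

    ``a_total`` sums the four unfavourable components (0–40); favourable
    "C" components subtract. ``wg_pts`` is the whole-grain modification
    (0 or −1…−5, solid foods only); ``protein_counted`` records whether the
    protein points entered the final score.
    """

    model_config = ConfigDict(frozen=True)

    energy_pts: int = Field(ge=0, le=10)
    satfat_pts: int = Field(ge=0, le=10)
    sugar_pts: int = Field(ge=0, le=10)
    sodium_pts: int = Field(ge=0, le=10)
    fvnlo_pts: int = Field(ge=0, le=10)
    fibre_pts: int = Field(ge=0, le=5)
    protein_pts: int = Field(ge=0, le=5)
    protein_counted: bool
    wg_pts: int = Field(ge=-5, le=0)

    @property
    def a_total(self) -> int:
        return self.energy_pts + self.satfat_pts + self.sugar_pts + self.sodium_pts

    @property
    def c_total(self) -> int:
        return self.fvnlo_pts + self.fibre_pts + (self.protein_pts if self.protein_counted else 0)


class ScoredFood(BaseModel):
    model_config = ConfigDict(frozen=True)

    food_id: str
    original_score: int
    modified_score: int
    original_class: Literal["A", "B", "C", "D", "E"]
    modified_class: Literal["A", "B", "C", "D", "E"]


class IntakeRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    person_id: str
    food_id: str
    grams_consumed: float = Field(gt=0)
    energy_kj_consumed: float = Field(ge=0)


class DietScoreResult(BaseModel):
    """Per-person whole-diet summary for one survey day."""

    model_config = ConfigDict(frozen=True)

    person_id: str
    whole_diet_score_original: float
    whole_diet_score_modified: float
    total_energy_kj: float = Field(gt=0)
    wg_intake_g_per_10mj: float = Field(ge=0)


def validate_food(record: FoodRecord | Mapping) -> FoodRecord:
    """Validate a food record, returning the typed record or raising ValueError.

    Accepts either an already-typed :class:`FoodRecord` (re-checked) or a raw
    mapping such as a parsed CSV row.
    """
    if isinstance(record, FoodRecord):
        record = record.model_dump()
    try:
        return FoodRecord(**dict(record))
    except Exception as exc:  # pydantic ValidationError or ValueError
        raise ValueError(str(exc)) from exc


def validate_foods_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Validate a foods table row by row.

    Returns the accepted rows (original dtypes preserved, index reset) and a
    list of ``(row_position, reason)`` rejections.
    """
    missing = [c for c in FOODS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"foods table is missing columns: {missing}")
    keep, rejections = [], []
    for pos, (_, row) in enumerate(df.iterrows()):
        try:
            validate_food(row.to_dict())
            keep.append(pos)
        except ValueError as exc:
            rejections.append((pos, str(exc)))
    return df.iloc[keep].reset_index(drop=True), rejections
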