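"""Whole-diet nutritional score per person and whole-grain intake density.

For one person-day the whole-diet score is the energy-weighted mean of the
consumed foods' scores,

    whole-diet score = Σ FS_i · E_i / Σ E_i ,

where FS_i is the food or beverage score and E_i the energy consumed from
it. Water and other zero-energy items are excluded first, and persons left
with no energy-bearing intake are dropped from the output (and reported).
Whole-grain intake is summarised as grams of whole-grain ingredients (dry
basis) per 10 MJ of energy intake per day.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .model import IntakeRecord

__all__ = ["whole_diet_score", "wg_density", "DietScorer", "KJ_PER_10MJ"]

#: 10 MJ expressed in kJ — the denominator unit of whole-grain intake density.
KJ_PER_10MJ = 1.0e4

# food-level columns DietScorer.fit needs (an `excluded` bool column is optional)
_FIT_COLUMNS = ["food_id", "original_score", "modified_score", "wholegrain_g", "is_water"]


def whole_diet_score(
    intakes: Iterable[IntakeRecord] | pd.DataFrame,
    scores: Mapping[str, float],
) -> float:
    """Energy-weighted mean score for one person's intake rows.

    Zero-energy rows are ignored; a person with no positive-energy rows has
    no defined whole-diet score and raises ValueError.
    """
    if isinstance(intakes, pd.DataFrame):
        rows = list(zip(intakes["food_id"], intakes["energy_kj_consumed"]))
    else:
        rows = [(r.food_id, r.energy_kj_consumed) for r in intakes]
    rows = [(f, e) for f, e in rows if e > 0]
    total = sum(e for _, e in rows)
    if total <= 0:
        raise ValueError("no positive-energy intake; person is excluded")
    return sum(scores[f] * e for f, e in rows) / total


def wg_density(
    intakes: Iterable[IntakeRecord] | pd.DataFrame,
    foods: pd.DataFrame,
) -> float:
    """Whole-grain grams (dry basis) per 10 MJ of energy for one person-day."""
    if not isinstance(intakes, pd.DataFrame):
        intakes = pd.DataFrame([r.model_dump() for r in intakes])
    merged = intakes.merge(
        foods[["food_id", "wholegrain_g"]], on="food_id", how="left", validate="m:1"
    )
    if merged["wholegrain_g"].isna().any():
        raise ValueError("intake references food_id absent from foods table")
    total_kj = merged["energy_kj_consumed"].clip(lower=0).sum()
    if total_kj <= 0:
        raise ValueError("no positive-energy intake; person is excluded")
    wg_g = (merged["grams_consumed"] * merged["wholegrain_g"] / 100.0).sum()
    return float(wg_g / (total_kj / KJ_PER_10MJ))


class DietScorer(TransformerMixin, BaseEstimator):
    """Aggregate per-food scores into per-person whole-diet scores.

    ``fit`` takes a per-food table carrying ``food_id``, both scores,
    ``wholegrain_g``, ``is_water`` and an optional boolean ``excluded``
    column (alcohol, supplements, medical beverages flagged by the data
    provider). ``transform`` maps an intakes table to one row per scoreable
    person with columns ``person_id, whole_diet_original,
    whole_diet_modified, energy_kj, wg_per_10mj, consumer_flag``; persons
    whose entire day is water/zero-energy/excluded items are dropped and
    listed in ``excluded_persons_``.
    """

    def fit(self, X: pd.DataFrame, y=None):
        missing = [c for c in _FIT_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"food table for DietScorer is missing columns: {missing}")
        foods = X.drop_duplicates("food_id").set_index("food_id")
        excluded = foods["excluded"].astype(bool) if "excluded" in foods.columns else False
        self.food_info_ = pd.DataFrame({
            "original_score": foods["original_score"].astype(float),
            "modified_score": foods["modified_score"].astype(float),
            "wholegrain_g": foods["wholegrain_g"].astype(float),
            "food_excluded": foods["is_water"].astype(bool) | excluded,
        })
        return self

    def transform(self, intakes: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "food_info_"):
            raise NotFittedError("DietScorer is not fitted; call fit() first")
        missing = [c for c in
                   ("person_id", "food_id", "grams_consumed", "energy_kj_consumed")
                   if c not in intakes.columns]
        if missing:
            raise ValueError(f"intakes table is missing columns: {missing}")
        merged = intakes.merge(
            self.food_info_, left_on="food_id", right_index=True,
            how="left", validate="m:1",
        )
        if merged["original_score"].isna().any():
            unknown = sorted(merged.loc[merged["original_score"].isna(), "food_id"].unique())
            raise ValueError(f"intakes reference unknown food_ids: {unknown[:5]}")
        keep = (merged["energy_kj_consumed"] > 0) & ~merged["food_excluded"]
        valid = merged[keep].copy()
        all_persons = pd.unique(intakes["person_id"])
        kept_persons = pd.unique(valid["person_id"])
        self.excluded_persons_ = sorted(set(all_persons) - set(kept_persons))

        e = valid["energy_kj_consumed"]
        valid["_w_orig"] = valid["original_score"] * e
        valid["_w_mod"] = valid["modified_score"] * e
        valid["_wg_g"] = valid["grams_consumed"] * valid["wholegrain_g"] / 100.0
        g = valid.groupby("person_id", sort=True)
        agg = g.agg(
            energy_kj=("energy_kj_consumed", "sum"),
            _w_orig=("_w_orig", "sum"),
            _w_mod=("_w_mod", "sum"),
            _wg_g=("_wg_g", "sum"),
        )
        out = pd.DataFrame({
            "person_id": agg.index,
            "whole_diet_original": (agg["_w_orig"] / agg["energy_kj"]).to_numpy(),
            "whole_diet_modified": (agg["_w_mod"] / agg["energy_kj"]).to_numpy(),
            "energy_kj": agg["energy_kj"].to_numpy(),
            "wg_per_10mj": (agg["_wg_g"] / (agg["energy_kj"] / KJ_PER_10MJ)).to_numpy(),
        }).reset_index(drop=True)
        out["consumer_flag"] = out["wg_per_10mj"] > 0
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(
            ["person_id", "whole_diet_original", "whole_diet_modified",
             "energy_kj", "wg_per_10mj", "consumer_flag"], dtype=object)
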