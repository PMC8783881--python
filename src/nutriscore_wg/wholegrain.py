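"""Whole-grain modification: dry-matter percentage and sliding-scale points.

A food's whole-grain content is expressed as a percentage of its dry matter:

    wg%_dry = 100 · wholegrain_g / (100 − water_g)

with ``wholegrain_g`` already on a dry-ingredient basis. Foods below 25%
whole grain score 0; from 25% a non-linear sliding scale awards up to −5
favourable points (−5 at exactly 100%), with a deliberate jump at the 50%
"whole-grain food" definition cut-off to reward reformulation past it. The
modification applies to solid foods only and the modified score re-uses the
unchanged A–E class boundaries.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .bands import ScoringConfig
from .model import DRY_MATTER_DECIMALS, FoodCategory, FoodRecord, ScoredFood

__all__ = ["wg_dry_pct", "wg_dry_pct_array", "wg_points", "score_food_modified"]


def wg_dry_pct_array(
    wholegrain_g: Sequence[float] | np.ndarray,
    water_g: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Vectorised whole-grain % of dry matter, capped at 100.

    Dry matter is rounded to a fixed decimal before dividing so that values
    round-tripped through CSV still hit the 100% band exactly. Zero dry
    matter with zero whole grain yields 0%; zero dry matter with positive
    whole grain is a validation error upstream and raises here.
    """
    wg = np.asarray(wholegrain_g, dtype=float)
    water = np.asarray(water_g, dtype=float)
    dry = np.round(100.0 - water, DRY_MATTER_DECIMALS)
    bad = (dry <= 0) & (wg > 0)
    if bad.any():
        raise ValueError("wholegrain_g > 0 with zero dry matter")
    pct = np.zeros_like(wg)
    np.divide(100.0 * wg, dry, out=pct, where=dry > 0)
    return np.minimum(pct, 100.0)


def wg_dry_pct(record: FoodRecord) -> float:
    """Whole-grain percentage of dry matter for one validated food."""
    return float(wg_dry_pct_array([record.wholegrain_g], [record.water_g])[0])


def wg_points(
    wg_pct: float,
    category: FoodCategory | str,
    config: ScoringConfig | None = None,
) -> int:
    """Whole-grain points (0 or −1…−5) for a whole-grain % of dry matter.

    Non-solid categories always score 0 regardless of content.
    """
    if not 0 <= wg_pct <= 100:
        raise ValueError(f"wg_pct must be in [0, 100], got {wg_pct}")
    cfg = config or ScoringConfig.default()
    if FoodCategory(category) not in cfg.wholegrain.apply_to:
        return 0
    return cfg.wholegrain.to_band_table().lookup(wg_pct)


def score_food_modified(
    record: FoodRecord, config: ScoringConfig | None = None
) -> ScoredFood:
    """Score one food under both algorithms; classes share one threshold set."""
    from .scoring import assign_class, score_food_original  # circular at import time

    cfg = config or ScoringConfig.default()
    pb, original = score_food_original(record, cfg)
    modified = original + pb.wg_pts
    return ScoredFood(
        food_id=record.food_id,
        original_score=original,
        modified_score=modified,
        original_class=assign_class(original, record.category, record.is_water),
        modified_class=assign_class(modified, record.category, record.is_water),
    )
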