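"""Default component band tables, class thresholds and the scoring config.

The point scales are the pre-2023 Nutri-Score / FSA-NPS tables: up to +10
points each for energy, saturated fat, total sugar and sodium; up to −5 each
for fibre, protein and FVNLO (−10 for beverage FVNLO). Thresholds are
exclusive on the favourable side — a content exactly on a threshold stays in
the lower-points band (27 g sugar earns 5 points, not 6) — except the
added-fat saturated-fat ratio, whose bands are closed below (ratio ≥ 64
earns the full 10).

Two fibre scales ship: ``aoac`` (default) and ``nsp`` for Englyst fibre
values as reported in UK composition data.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model import BandTable, FoodCategory

__all__ = [
    "default_band_tables",
    "ScoringConfig",
    "WholeGrainConfig",
    "WG_PRESETS",
    "FVNLO_MAX_PTS",
]

_R10 = tuple(range(11))  # 0..10
_R5 = tuple(range(6))    # 0..5


def _bt(component, category, thresholds, points, comparison="strictly_greater"):
    return BandTable(
        component=component, category=category,
        thresholds=tuple(thresholds), points=tuple(points), comparison=comparison,
    )


#: Fibre thresholds by analytical method (g/100 g -> 1..5 points).
FIBRE_THRESHOLDS = {
    "aoac": (0.9, 1.9, 2.8, 3.7, 4.7),
    "nsp": (0.7, 1.4, 2.1, 2.8, 3.5),
}

#: Maximum FVNLO points per category (the protein-rule override level).
FVNLO_MAX_PTS = {
    FoodCategory.solid_food: 5,
    FoodCategory.cheese: 5,
    FoodCategory.added_fat: 5,
    FoodCategory.beverage: 10,
}


def default_band_tables(fibre_method: str = "aoac") -> dict[tuple[str, FoodCategory], BandTable]:
    """Build the default (component, category) -> BandTable mapping.

    Solid-food tables also serve cheese and added fats (except the added-fat
    saturated-fat ratio); beverages have their own energy, sugar and FVNLO
    scales.
    """
    if fibre_method not in FIBRE_THRESHOLDS:
        raise ValueError(f"unknown fibre method {fibre_method!r}; use 'aoac' or 'nsp'")
    sf = FoodCategory.solid_food
    bev = FoodCategory.beverage
    tables = {
        ("energy", sf): _bt("energy", sf, [335 * k for k in range(1, 11)], _R10),
        ("sugar", sf): _bt("sugar", sf, [4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45], _R10),
        ("satfat", sf): _bt("satfat", sf, list(range(1, 11)), _R10),
        ("sodium", sf): _bt("sodium", sf, [90 * k for k in range(1, 11)], _R10),
        ("fibre", sf): _bt("fibre", sf, FIBRE_THRESHOLDS[fibre_method], _R5),
        ("protein", sf): _bt("protein", sf, [1.6, 3.2, 4.8, 6.4, 8.0], _R5),
        ("fvnlo", sf): _bt("fvnlo", sf, [40, 60, 80], [0, 1, 2, 5]),
        # Beverage scales: ≤0 kJ scores 0, each further 30 kJ one more point.
        ("energy", bev): _bt("energy", bev, [30 * k for k in range(10)], _R10, "at_most"),
        ("sugar", bev): _bt("sugar", bev, [1.5 * k for k in range(10)], _R10, "at_most"),
        ("fvnlo", bev): _bt("fvnlo", bev, [40, 60, 80], [0, 2, 4, 10]),
        # Added fats replace the saturated-fat scale with 100·satfat/totalfat.
        ("satfat_ratio", FoodCategory.added_fat): _bt(
            "satfat_ratio", FoodCategory.added_fat,
            [10, 16, 22, 28, 34, 40, 46, 52, 58, 64], _R10, "at_least",
        ),
    }
    return tables


class WholeGrainConfig(BaseModel):
    """Whole-grain modification bands on % of food dry matter.

    ``bands`` is a list of ``(min_pct_dry, points)`` pairs with negative,
    non-increasing points; content below the first cut-off scores 0. Two
    readings of the published two-row cut-off table ship as presets (see
    :data:`WG_PRESETS`); the modification applies only to the categories in
    ``apply_to`` (solid foods by default).
    """

    model_config = ConfigDict(frozen=True)

    bands: tuple[tuple[float, int], ...] = ((25.0, -1), (50.0, -3), (100.0, -5))
    apply_to: tuple[FoodCategory, ...] = (FoodCategory.solid_food,)

    @model_validator(mode="after")
    def _check(self) -> "WholeGrainConfig":
        cuts = [c for c, _ in self.bands]
        pts = [p for _, p in self.bands]
        if not cuts:
            raise ValueError("whole-grain bands cannot be empty")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("whole-grain cut-offs must be strictly increasing")
        if any(b > a for a, b in zip(pts, pts[1:])) or any(p > 0 for p in pts):
            raise ValueError("whole-grain points must be non-positive and non-increasing")
        if cuts[0] < 25 - 1e-12:
            raise ValueError("whole-grain content below 25% must score 0")
        if cuts[-1] > 100 or pts[-1] != -5:
            raise ValueError("100% whole grain must score -5")
        return self

    def to_band_table(self) -> BandTable:
        cuts = tuple(c for c, _ in self.bands)
        pts = (0,) + tuple(p for _, p in self.bands)
        return BandTable(
            component="wholegrain", category=FoodCategory.solid_food,
            thresholds=cuts, points=pts, comparison="at_least",
        )


#: Named presets for the two readings of the whole-grain cut-off table.
WG_PRESETS = {
    # default: jump to −3 at the 50% "whole-grain food" cut-off
    "wgi-135": ((25.0, -1), (50.0, -3), (100.0, -5)),
    # alternative column alignment: −2 / −4 / −5
    "wgi-245": ((25.0, -2), (50.0, -4), (100.0, -5)),
}


class ScoringConfig(BaseModel):
    """Complete engine configuration: band tables + whole-grain modification.

    ``overrides`` deep-merges user-provided band definitions (from YAML or
    JSON) over the defaults keyed as ``bands.<category>.<component>``.
    """

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    fibre_method: Literal["aoac", "nsp"] = "aoac"
    wholegrain: WholeGrainConfig = Field(default_factory=WholeGrainConfig)
    band_overrides: tuple[BandTable, ...] = ()

    def tables(self) -> dict[tuple[str, FoodCategory], BandTable]:
        tables = default_band_tables(self.fibre_method)
        for bt in self.band_overrides:
            tables[(bt.component, bt.category)] = bt
        return tables

    @classmethod
    def default(cls, fibre_method: str = "aoac", wg_preset: str = "wgi-135") -> "ScoringConfig":
        return cls(
            fibre_method=fibre_method,
            wholegrain=WholeGrainConfig(bands=WG_PRESETS[wg_preset]),
        )

    @classmethod
    def from_mapping(cls, data: dict) -> "ScoringConfig":
        fibre_method = data.get("fibre_method", "aoac")
        wg = data.get("wholegrain", {})
        if isinstance(wg, str):
            wg_cfg = WholeGrainConfig(bands=WG_PRESETS[wg])
        else:
            kwargs = {}
            if "bands" in wg:
                kwargs["bands"] = tuple((float(c), int(p)) for c, p in wg["bands"])
            if "apply_to" in wg:
                kwargs["apply_to"] = tuple(FoodCategory(c) for c in wg["apply_to"])
            wg_cfg = WholeGrainConfig(**kwargs)
        overrides = []
        for cat, comps in data.get("bands", {}).items():
            for comp, spec in comps.items():
                overrides.append(BandTable(
                    component=comp, category=FoodCategory(cat),
                    thresholds=tuple(float(t) for t in spec["thresholds"]),
                    points=tuple(int(p) for p in spec["points"]),
                    comparison=spec.get("comparison", "strictly_greater"),
                ))
        return cls(fibre_method=fibre_method, wholegrain=wg_cfg,
                   band_overrides=tuple(overrides))

    @classmethod
    def from_file(cls, path: str | Path | None) -> "ScoringConfig":
        """Load a YAML (or JSON) config; no file -> built-in defaults."""
        if path is None:
            return cls.default()
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_mapping(data or {})
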