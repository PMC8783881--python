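"""CSV readers/writers for the documented schemas and config loading.

All files are UTF-8 CSV with "." decimals and a required header. Readers
validate row by row: malformed headers are hard errors naming the missing
columns; invalid rows are rejected and logged with their position while the
remainder is returned.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .bands import ScoringConfig
from .model import FOODS_COLUMNS, INTAKES_COLUMNS, validate_foods_frame

__all__ = ["read_foods", "read_intakes", "read_diet_quality", "load_config"]

logger = logging.getLogger("nutriscore_wg")

_FOOD_DTYPES = {"food_id": str, "name": str, "group": str, "category": str}


def _check_header(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns: {missing}")


def read_foods(path: str | Path) -> pd.DataFrame:
    """Read and validate foods.csv; invalid rows are dropped and logged."""
    df = pd.read_csv(path, dtype=_FOOD_DTYPES)
    _check_header(df, FOODS_COLUMNS, "foods.csv")
    numeric = [c for c in FOODS_COLUMNS if c not in _FOOD_DTYPES and c != "is_water"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["is_water"] = df["is_water"].astype(bool)
    bad_numeric = df[numeric].isna().any(axis=1)
    for pos in df.index[bad_numeric]:
        logger.warning("foods.csv row %d rejected: unparseable numeric value", pos)
    df = df[~bad_numeric]
    valid, rejections = validate_foods_frame(df)
    for pos, reason in rejections:
        logger.warning("foods.csv row %d rejected: %s", pos, reason)
    return valid


def read_intakes(path: str | Path) -> pd.DataFrame:
    """Read intakes.csv; zero-energy rows are kept (excluded downstream)."""
    df = pd.read_csv(path, dtype={"person_id": str, "food_id": str})
    _check_header(df, INTAKES_COLUMNS, "intakes.csv")
    for col in ("grams_consumed", "energy_kj_consumed"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[["grams_consumed", "energy_kj_consumed"]].isna().any(axis=1)
    bad |= (df["grams_consumed"] <= 0) | (df["energy_kj_consumed"] < 0)
    for pos in df.index[bad]:
        logger.warning("intakes.csv row %d rejected: invalid amounts", pos)
    return df[~bad].reset_index(drop=True)


def read_diet_quality(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str})
    _check_header(df, ["person_id", "dq_score"], "dietquality.csv")
    df["dq_score"] = pd.to_numeric(df["dq_score"], errors="coerce")
    bad = df["dq_score"].isna()
    for pos in df.index[bad]:
        logger.warning("dietquality.csv row %d rejected: unparseable dq_score", pos)
    return df[~bad].reset_index(drop=True)


def load_config(path: str | Path | None = None) -> ScoringConfig:
    """Load the engine config (YAML or JSON), or the built-in defaults."""
    return ScoringConfig.from_file(path)
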