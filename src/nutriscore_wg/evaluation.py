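"""Comparison statistics between the original and modified algorithms.

Four analyses mirror how a nutrient-profiling modification is evaluated
against survey data:

* rank (Spearman) correlations of each component's content with the food
  score, per food group, for both algorithms;
* the 5×5 class-transition matrix and the share of foods whose score or
  class changed;
* Pearson correlation of whole-diet scores with an externally supplied
  diet-quality index (expected negative: lower profiling score = better
  diet);
* group means of the whole-diet scores across whole-grain non-consumers and
  consumer intake quartiles, with a one-way ANOVA across groups.

Water items (100% water, 0 kJ) are excluded from food-level statistics and
from percentage denominators.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COMPONENT_COLUMNS",
    "component_score_correlations",
    "transition_matrix",
    "class_transition",
    "diet_quality_correlation",
    "wg_quantile_groups",
    "wg_quantile_analysis",
    "CLASSES",
    "WG_GROUP_LABELS",
]

CLASSES = ["A", "B", "C", "D", "E"]
WG_GROUP_LABELS = ["non-consumer", "Q1", "Q2", "Q3", "Q4"]

#: component label -> content column (units: g, mg or kJ per 100 g;
#: whole grain in g dry weight, FVNLO as the % field the schema carries).
COMPONENT_COLUMNS: Mapping[str, str] = {
    "wholegrain": "wholegrain_g",
    "fibre": "fibre_g",
    "protein": "protein_g",
    "fvnlo": "fvnlo_pct",
    "energy": "energy_kj",
    "satfat": "satfat_g",
    "sugar": "sugar_g",
    "sodium": "sodium_mg",
}

_SCORE_COLS = {"original": "original_score", "modified": "modified_score"}


def _drop_water(scored: pd.DataFrame) -> pd.DataFrame:
    if "is_water" in scored.columns:
        return scored[~scored["is_water"].astype(bool)]
    return scored


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def component_score_correlations(
    scored_foods: pd.DataFrame,
    group_col: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman rho of component content vs both scores, overall and per group.

    ``scored_foods`` must carry the nutrient content columns alongside
    ``original_score``/``modified_score`` (i.e. foods.csv merged with the
    scorer output). Returns a tidy frame with one row per
    (group, component, score variant); constant columns yield missing rho.
    """
    df = _drop_water(scored_foods)
    groups: list[tuple[str, pd.DataFrame]] = [("all", df)]
    if group_col is not None:
        groups += [(str(g), sub) for g, sub in df.groupby(group_col, sort=True)]
    rows = []
    for gname, sub in groups:
        for comp, col in COMPONENT_COLUMNS.items():
            for variant, score_col in _SCORE_COLS.items():
                rho, p = _spearman(
                    sub[col].to_numpy(float), sub[score_col].to_numpy(float)
                )
                rows.append({
                    "group": gname, "component": comp, "score": variant,
                    "rho": rho, "p_value": p, "n": len(sub),
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                })
    return pd.DataFrame(rows)


def transition_matrix(scored_foods: pd.DataFrame) -> pd.DataFrame:
    """5×5 count matrix of original class (rows) vs modified class (columns)."""
    df = _drop_water(scored_foods)
    return (
        pd.crosstab(df["original_class"], df["modified_class"])
        .reindex(index=CLASSES, columns=CLASSES, fill_value=0)
        .rename_axis(index="original", columns="modified")
    )


def class_transition(
    scored_foods: pd.DataFrame, group_col: str | None = None
) -> pd.DataFrame:
    """Counts and percentages of score / class changers, overall and per group."""
    df = _drop_water(scored_foods)
    groups: list[tuple[str, pd.DataFrame]] = [("all", df)]
    if group_col is not None:
        groups += [(str(g), sub) for g, sub in df.groupby(group_col, sort=True)]
    rows = []
    for gname, sub in groups:
        n = len(sub)
        n_score = int((sub["original_score"] != sub["modified_score"]).sum())
        n_class = int((sub["original_class"] != sub["modified_class"]).sum())
        rows.append({
            "group": gname, "n": n,
            "n_score_changed": n_score,
            "pct_score_changed": 100.0 * n_score / n if n else float("nan"),
            "n_class_changed": n_class,
            "pct_class_changed": 100.0 * n_class / n if n else float("nan"),
        })
    return pd.DataFrame(rows)


def diet_quality_correlation(
    diets: pd.DataFrame, dq_scores: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r of each whole-diet score with the diet-quality index.

    ``dq_scores`` has columns ``person_id, dq_score``; persons are matched
    on id (inner join). Zero-variance inputs give missing r.
    """
    merged = diets.merge(dq_scores, on="person_id", how="inner", validate="1:1")
    rows = []
    for variant in ("original", "modified"):
        x = merged[f"whole_diet_{variant}"].to_numpy(float)
        y = merged["dq_score"].to_numpy(float)
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            r, p = float("nan"), float("nan")
        else:
            r, p = (float(v) for v in stats.pearsonr(x, y))
        rows.append({"score": variant, "r": r, "p_value": p, "n": len(merged)})
    return pd.DataFrame(rows)


def wg_quantile_groups(diets: pd.DataFrame) -> pd.Series:
    """Label each person non-consumer or consumer quartile Q1–Q4.

    Quartile cuts are type-7 (linear-interpolation) quantiles of
    ``wg_per_10mj`` among consumers; a value tied with a cut point goes to
    the lower quartile.
    """
    consumer = diets["consumer_flag"].astype(bool).to_numpy()
    wg = diets["wg_per_10mj"].to_numpy(float)
    labels = np.where(consumer, "", WG_GROUP_LABELS[0]).astype(object)
    if consumer.any():
        cuts = np.quantile(wg[consumer], [0.25, 0.5, 0.75])  # type-7 default
        qidx = np.searchsorted(cuts, wg[consumer], side="left")
        labels[consumer] = np.array(WG_GROUP_LABELS[1:], dtype=object)[qidx]
    return pd.Series(labels, index=diets.index, name="wg_group")


def wg_quantile_analysis(
    diets: pd.DataFrame, dq_scores: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group means across whole-grain intake groups plus one-way ANOVA.

    Returns ``(group_table, anova_table)``. The group table has one row per
    non-empty group (ordered non-consumer, Q1–Q4) with mean whole-diet
    scores, mean whole-grain density and, when supplied, mean diet-quality
    score. The ANOVA table has one row per outcome with the F statistic and
    p-value across groups; degenerate layouts (fewer than two groups, or no
    variance anywhere) report missing values.
    """
    n_consumers = int(diets["consumer_flag"].astype(bool).sum())
    if 0 < n_consumers < 4:
        raise ValueError("quartile analysis needs at least 4 consumers")
    df = diets.copy()
    df["wg_group"] = wg_quantile_groups(df)
    if dq_scores is not None:
        df = df.merge(dq_scores, on="person_id", how="left", validate="1:1")
    outcomes = {"original": "whole_diet_original", "modified": "whole_diet_modified"}
    if dq_scores is not None:
        outcomes["dq"] = "dq_score"

    rows = []
    for label in WG_GROUP_LABELS:
        sub = df[df["wg_group"] == label]
        if sub.empty:
            continue
        row = {"wg_group": label, "n": len(sub),
               "mean_wg_per_10mj": float(sub["wg_per_10mj"].mean())}
        for name, col in outcomes.items():
            row[f"mean_{name}"] = float(sub[col].mean())
        rows.append(row)
    group_table = pd.DataFrame(rows)

    anova_rows = []
    for name, col in outcomes.items():
        samples = [
            sub[col].dropna().to_numpy(float)
            for _, sub in df.groupby("wg_group")
            if len(sub[col].dropna()) > 0
        ]
        if len(samples) < 2 or all(np.ptp(s) == 0 for s in samples):
            f, p = float("nan"), float("nan")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f, p = (float(v) for v in stats.f_oneway(*samples))
        anova_rows.append({"outcome": name, "F": f, "p_value": p,
                           "significant": bool(p < 0.05) if np.isfinite(p) else False})
    return group_table, pd.DataFrame(anova_rows)
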