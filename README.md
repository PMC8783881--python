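# nutriscore-wg

A scoring engine for the Nutri-Score nutrient-profiling algorithm with a
whole-grain modification, plus the tooling needed to study that
modification on dietary-survey-shaped data: per-food scoring, energy-weighted
whole-diet scores, evaluation statistics, and a seeded synthetic generator of
food-composition and single-day intake tables.

## Who this is for

Nutrition and public-health researchers who want to prototype changes to
points-based front-of-pack profiling systems — here, rewarding whole-grain
content — without access to national food-composition databases
(AUSNUT/CIQUAL/NDNS-like) or survey microdata. Everything runs on a
documented CSV schema, and the bundled generator emulates the statistical
structure such databases have.

## The algorithm

For each food, unfavourable "A" points (0–10 each) accrue for energy (kJ),
saturated fat (g), total sugar (g) and sodium (mg) per 100 g; favourable "C"
points (0–5 each; beverage FVNLO 0–10) for fibre, protein, and the combined
fruit/vegetable/nut/legume/oil percentage (FVNLO). The food score is

```
score = (energy + satfat + sugar + sodium) − (FVNLO + fibre + protein·[counted])
```

with protein dropped when A-points reach 11, unless the food is a cheese or
already holds maximal FVNLO points. Band tables differ for solid foods,
beverages and added fats (saturated fat replaced by the ratio
100·satfat/totalfat). Solid-food scores span −15…+40 and map to classes
A (≤ −1), B (0–2), C (3–10), D (11–18), E (≥ 19); beverages use
B ≤ 1 / C 2–5 / D 6–9 / E ≥ 10, with water always A.

The whole-grain modification adds up to −5 points for solid foods by
whole-grain percentage of dry matter, `100·wholegrain_g/(100−water_g)`:
0 below 25%, −1 from 25%, −3 from 50% (the "whole-grain food" definition
cut-off), −5 at exactly 100%. Class boundaries are unchanged.

Per person-day, the whole-diet score is the energy-weighted mean
`Σ FSᵢ·Eᵢ / Σ Eᵢ` over consumed items (water and zero-energy items
excluded), and whole-grain intake is expressed as g per 10 MJ of energy.

## Worked example

```bash
nutriscore-wg simulate --seed 1 --n-foods 200 --n-persons 300 --out-dir demo
nutriscore-wg score-foods demo/foods.csv --out demo/scored_foods.csv
nutriscore-wg score-diets demo/intakes.csv --foods demo/foods.csv \
    --scored demo/scored_foods.csv --out demo/diets.csv
nutriscore-wg evaluate --foods demo/foods.csv --scored demo/scored_foods.csv \
    --diets demo/diets.csv --diet-quality demo/dietquality.csv --out-dir demo/eval
```

Scored grain foods (from `demo/scored_foods.csv` merged with the inputs):

```
food_id          group  sugar_g  fibre_g  wholegrain_g  original_score  modified_score
 F00002 grain products     1.93     4.96         22.50              -4              -5
 F00003 grain products     5.68     5.08         45.00              -5              -8
 F00004 grain products     4.69     8.57         90.00              -5             -10
```

F00002 is 25% whole grain of dry matter (22.5 g on 90 g dry matter) and
gains −1; F00004 is 100% and gains the full −5. The evaluation step prints:

```
score changers: 23 (11.5%), class changers: 8 (4.0%)
diet-quality r (original): -0.622
diet-quality r (modified): -0.631
ANOVA original: F=11.91, p=5.49e-09
ANOVA modified: F=21.95, p=7.11e-16
```

23 of 200 non-water foods change score under the modification; the
whole-diet score correlates negatively with the (synthetic) diet-quality
index — lower profiling score, better diet — slightly more strongly for the
modified algorithm, and mean whole-diet scores differ significantly across
whole-grain intake groups (non-consumers plus consumer quartiles).

The same operations are available as a library: `FoodScorer` and
`DietScorer` are sklearn-style transformers (`fit`/`transform`,
`get_params`), so they compose with pipelines; `score_food_original`,
`score_food_modified`, `whole_diet_score`, `wg_density` and the
`evaluation` module expose the individual steps.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-scores benchmark foods through the full pipeline and reports the
component points the band tables award at published edge contents (sugar at
27 g/100 g, saturated fat at 3 g/100 g, sodium at 540 and 180 mg/100 g) as
a JSON map of target ids to values.

## Configuration

Band tables, class-relevant whole-grain bands and the fibre method are
overridable from YAML/JSON (`score-foods --bands config.yaml`), e.g.:

```yaml
fibre_method: nsp            # Englyst fibre thresholds (UK data)
wholegrain:
  bands: [[25, -2], [50, -4], [100, -5]]   # alternative preset wgi-245
```

See `docs/methods.md` for the model details, generator assumptions and
known limitations.
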