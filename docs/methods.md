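# Methods

## Scoring model

The engine implements the pre-2023 Nutri-Score / FSA-NPS points system.
Component contents per 100 g are mapped to points through ordered band
tables (`nutriscore_wg.bands`):

| component | category | thresholds → points |
|---|---|---|
| energy (kJ) | solid | 335, 670, …, 3350 → 1…10 |
| sugar (g) | solid | 4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45 → 1…10 |
| saturated fat (g) | solid | 1, 2, …, 10 → 1…10 |
| sodium (mg) | solid | 90, 180, …, 900 → 1…10 |
| fibre (g, AOAC) | all | 0.9, 1.9, 2.8, 3.7, 4.7 → 1…5 |
| fibre (g, NSP/Englyst) | all | 0.7, 1.4, 2.1, 2.8, 3.5 → 1…5 |
| protein (g) | all | 1.6, 3.2, 4.8, 6.4, 8.0 → 1…5 |
| FVNLO (%) | solid | 40, 60, 80 → 1, 2, 5 |
| energy (kJ) | beverage | 0, 30, …, 270 → 1…10 |
| sugar (g) | beverage | 0, 1.5, …, 13.5 → 1…10 |
| FVNLO (%) | beverage | 40, 60, 80 → 2, 4, 10 |
| 100·satfat/totalfat | added fat | 10, 16, 22, …, 64 → 1…10 |

Boundary semantics: thresholds are exclusive on the favourable side — a
content equal to a threshold stays in the lower-points band (sugar at
exactly 27 g earns 5 points, sodium at 180 mg earns 1). The one exception
is the added-fat ratio scale, whose bands are closed below (ratio ≥ 64
earns 10). Cheese uses the solid-food tables but is exempt from the
protein-exclusion rule; beverages have their own energy, sugar and FVNLO
scales. No rounding is applied to nutrient inputs before lookup (avoids
double rounding; scores are integers by construction).

The protein rule: protein points are dropped iff A-points ≥ 11, the food is
not a cheese, and its FVNLO points are below the category maximum (5, or 10
for beverages).

Exhaustive enumeration of the solid-food point lattice attains exactly
−15…+40. A beverage can in principle reach −20 (FVNLO 10 plus fibre and
protein 5 each at zero unfavourable points); such a composition does not
occur in realistic data and the generator never emits one, so the −15 bound
is asserted only for the solid-food algorithm.

## Whole-grain modification

Whole-grain content is stored as grams of whole-grain ingredients on a dry
basis per 100 g of food as consumed, and converted to a percentage of the
food's dry matter: `100·wholegrain_g/(100−water_g)`, capped at 100. Dry
matter is rounded to 9 decimals first so a 100%-whole-grain food written to
CSV still reads back as exactly 100% despite binary-float noise in
`100 − water`.

Points (solid foods only; other categories always 0):

| % of dry matter | < 25 | ≥ 25 | ≥ 50 | 100 |
|---|---|---|---|---|
| default `wgi-135` | 0 | −1 | −3 | −5 |
| preset `wgi-245` | 0 | −2 | −4 | −5 |

The published two-row cut-off table does not pin the intermediate scores
unambiguously; `wgi-135` is the default because the deliberately non-linear
jump at 50% mirrors the stated intent of rewarding the "whole-grain food"
definition threshold, and the alternative alignment ships as a named
preset. Whole-grain points are always counted (they do not participate in
the protein-style exclusion rule; making them conditional on a detrimental
point cap is explicitly future work). The modified score is
`original + wg_points`; class boundaries are not rescaled for the extended
[−20, 40] range, so the modification can only improve (never worsen) a
class.

## Whole-diet score

Per person-day: energy-weighted mean of food scores, `Σ FSᵢEᵢ / Σ Eᵢ`.
Water and zero-energy items are removed first; a person whose whole day is
such items has no defined score and is dropped (reported via
`DietScorer.excluded_persons_`). Whole-grain intake density is
`Σ gramsᵢ·wholegrainᵢ/100` scaled to a 10 MJ day, i.e. divided by
`Σ E_kJ / 10⁴` (10 MJ = 10 000 kJ). An optional boolean `excluded` column
on the foods table lets a data provider flag alcohol, supplements and
medical beverages; name matching is deliberately not attempted.

## Evaluation statistics

* **Component–score correlations** — Spearman rho (scipy, t-approximation
  p-values) of each content column against both scores, overall and per
  food group; water items excluded; constant columns reported as missing.
* **Class transitions** — 5×5 original-by-modified class counts plus the
  share of foods changing score and changing class; water items excluded
  from denominators.
* **Diet-quality correlation** — Pearson r of each whole-diet score with an
  externally supplied per-person index; expected sign negative.
* **Whole-grain quantile analysis** — persons split into non-consumers and
  consumer quartiles of whole-grain g/10 MJ. Quartile cuts are type-7
  (linear-interpolation) quantiles among consumers; a value tied with a cut
  goes to the lower quartile (deterministic, standard). Group means for
  both scores (and diet quality when supplied) plus a one-way ANOVA across
  groups; degenerate layouts (all consumers tied, fewer than two groups, no
  variance) report missing F/p rather than failing.

## Synthetic generator

The generator states a world resembling a national composition database
joined to a one-day intake survey:

* ~500 foods in ten groups (grain products, cereal dishes, vegetables,
  fruit, meat/fish, dairy, cheese, snacks, added fats, beverages, water)
  with truncated log-normal nutrients per group, Beta-distributed
  saturated-fat shares of total fat, and uniform FVNLO/water ranges chosen
  to be category-plausible. Invariants (satfat ≤ totalfat, whole grain ≤
  dry matter) hold by construction and are re-checked through the validator.
* Whole-grain content is a mixture with point masses at 0% and 100% of dry
  matter and a uniform spread between, so every scoring band is populated;
  four edge foods at exactly 0/25/50/100% are injected deterministically.
  Fibre rises with whole-grain share (default +6 g/100 g at 100%,
  roughly the whole-meal vs white flour gap), which is what makes
  high-whole-grain foods score better even before the modification.
* 2000 persons, one day each, 5–30 items per person; half are designed
  whole-grain consumers (a majority of non-consumers is typical of national
  surveys), with a per-consumer propensity that scales both the number and
  portions of whole-grain items to create an intake gradient. Some persons
  add a zero-energy water row, and one designed water-only person exercises
  the exclusion path.
* The pseudo diet-quality score is a noisy linear function of the person's
  negated *modified* whole-diet score, calibrated so its Pearson
  correlation with that score hits the configured target (−0.6 by default).
  Defining "true healthfulness" off the modified score encodes the world in
  which whole-grain foods genuinely carry better diets; the original
  score's correlation then comes out marginally weaker because the two
  scores correlate near 1, reproducing the expected ordering without
  tuning.

What a green test does *not* establish: the generator draws food picks
almost uniformly within the consumer/non-consumer design, has no portion
size–food interaction, no survey weights, no under-reporting, and no
country-specific nutrient distributions, so the package's statistics on
generated data validate the machinery, not any country-level estimate.
In particular, non-consumers are not designed to differ from low-quartile
consumers, so the monotone score gradient is asserted across consumer
quartiles, with non-consumers checked only against the top quartile.

## Numerical choices

* Band lookup is a `searchsorted` count of passed thresholds; the test
  suite checks it against a literal linear threshold scan on random values
  and exact edges.
* Validation tolerances of 1e-9 absorb representable-decimal noise
  (e.g. satfat equal to totalfat after rounding).
* Generated nutrient values are rounded to fixed decimals (energy 0–1 dp,
  nutrients 2 dp) so CSV round-trips are bit-exact; whole-grain grams are
  floored to 2 dp so rounding can never push them above dry matter, with
  exact-100% foods set to the dry matter itself.
* Seeds: foods use `seed`, intakes `seed + 1` (two deterministic streams
  so each stage is reproducible standalone).

## Limitations

* Only the original (pre-2023) algorithm; no revised 2023 scale, red-meat
  or sweetener rules.
* No recipe/ingredient decomposition: FVNLO % and whole-grain grams are
  input fields, not derived.
* Single-day intakes; no usual-intake modelling or survey weighting.
* The four national diet-quality indices are out of scope; the evaluation
  accepts any per-person index column.
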