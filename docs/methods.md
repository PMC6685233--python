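# Methods

`dietscreen` implements the full development-and-validation pipeline for a
brief diet-quality screening questionnaire: diet scoring, energy-reporting
plausibility filtering, decision-tree learning, questionnaire export, and
screening-accuracy evaluation, exercised end to end on a synthetic cohort
generator.

## AHEI-2010 scoring

Diet quality is measured with the 11-component Alternative Healthy Eating
Index (AHEI-2010). Each component earns 0–10 points; the total spans
0–110. Components and criteria:

| component | units | 0 points | 10 points |
|---|---|---|---|
| vegetables | servings/day | 0 | ≥ 5 |
| fruit | servings/day | 0 | ≥ 4 |
| whole grains | g/day | 0 | ≥ 75 (women) / ≥ 90 (men) |
| sugar-sweetened beverages & fruit juice | servings/day | ≥ 1 | 0 |
| nuts & legumes | servings/day | 0 | ≥ 1 |
| red/processed meat | servings/day | ≥ 1.5 | 0 |
| trans fat | % energy | ≥ 4 | ≤ 0.5 |
| EPA+DHA | mg/day | 0 | ≥ 250 |
| PUFA | % energy | ≤ 2 | ≥ 10 |
| sodium | mg/day | highest decile | lowest decile |
| alcohol | drinks/day | ≥ 2.5 (women) / ≥ 3.5 (men) | 0.5–1.5 (women) / 0.5–2.0 (men) |

Published criteria fix only the endpoints, so scores are prorated linearly
between them; this follows the index's original design and is the choice
every practical implementation makes. Decisions at the unstated margins:

- **Alcohol.** Non-drinkers (exactly 0 drinks/day) receive 2.5 points, the
  index's special-case rule. Between 0 and the moderate band the score
  rises linearly from 2.5 at 0 to 10 at 0.5 drinks/day — continuous and
  consistent with the special case, but a genuine interpolation choice.
- **Sodium.** Decile boundaries are the 10th–90th inclusive
  linear-interpolated percentiles of a reference population (by default
  the scored cohort itself; a separate reference can be supplied). Decile
  rank r ∈ {1..10} (1 = lowest intake) scores 10·(10−r)/9, mapping deciles
  evenly onto 0–10. Amounts tied with a boundary fall in the lower decile,
  so a degenerate reference population (all values equal) scores everyone
  10.
- **Percent-of-energy conversion** uses 9 kcal/g of fat (Atwater factor).
- **Classification.** A diet is "high quality" when the unrounded total is
  ≥ 65 of 110 points, "low quality" otherwise; the comparison is exact and
  inclusive.

Component amounts come from an item catalog that maps each FFQ question to
per-serving nutrient contributions and component memberships. The catalog
is a versioned JSON/YAML schema; the bundled demonstration catalog has ~30
items and 8 food groups. Intakes are servings/day throughout.

## Plausibility filtering

Reported energy intake (rEI) is the catalog energy implied by a
respondent's intakes. Basal metabolic rate (eBMR) uses the Mifflin-St Jeor
equation (men: 10·kg + 6.25·cm − 5·y + 5; women: − 161). The Goldberg
band classifies rEI:eBMR ≥ 1.2 and < 2.4 as plausible (lower bound
inclusive, upper exclusive); below it under-reporting, at or above it
over-reporting. Development runs keep plausible reporters only; external
validation keeps everyone and annotates status — the asymmetry mirrors
real deployment, where reporting status is unknown.

## Classification tree

A from-scratch binary CART on Gini impurity (entropy available).
Predictors: non-excluded item intakes, food-group sums, age (years), and
sex (0 = female, 1 = male; splits at 0.5). Rows with value < threshold go
left, ≥ goes right, including exact ties. Candidate thresholds are
midpoints of consecutive sorted distinct values; the search is exhaustive,
maximizing the n-weighted impurity decrease with deterministic tie-breaks
(lowest predictor index, then lowest threshold, equality within 1e-12).
Leaf predictions are majority class with ties to "low" — the screening
task flags poor diets, so ambiguity errs toward flagging.

Growth defaults: `min_node_size=20`, `min_leaf_size=7` (common CART
practice), `max_depth=6` (a screening questionnaire should stay answerable
in a few minutes; published brief tools of this kind use pathways of at
most six questions).

**Pruning** is weakest-link cost-complexity: repeatedly collapse the
internal node whose per-leaf training-misclassification improvement
g(t) = (miss(t as leaf) − miss(subtree))/(leaves−1) is smallest, while
g(t) < cp·n. cp=0 keeps the grown tree; cp=∞ collapses to the root;
results are nested in cp, and training error is non-decreasing in cp.

**Complexity selection**: candidate cp values come from the full tree's
weakest-link sequence (geometric midpoints between critical values). Each
candidate is scored by cross-validated holdout misclassification, either
ten repeated class-stratified 90/10 random splits (default, "Monte Carlo")
or standard stratified 10-fold. The default rule picks the candidate with
minimum mean error, ties toward the largest cp (simplest tree). An
optional one-standard-error rule picks the largest candidate within one SE
of the minimum; in the Monte-Carlo mode the SE uses the Nadeau–Bengio
variance correction (1/R + n_test/n_train), since overlapping training
sets make the naive 1/R factor an underestimate.

The two rules trade bias for variance in the usual way. With genuinely
informative predictors the minimum-error rule retains the richer trees
needed to cover several distinct food signals; under label noise it can
chase holdout fluctuations and keep spurious splits (reference CART
implementations behave the same way), which is what the 1-SE guard is
for — on pure-noise labels, 10-fold selection with the 1-SE rule collapses
the tree to the root in the large majority of runs.

## Questionnaire export

Each internal node becomes one yes/no question ("Do you consume ≥ X
servings per day of …?"; age and sex nodes are phrased demographically);
yes follows the ≥ branch. Pathways (root-to-leaf question sequences) end
in a low/high verdict. Thresholds are rendered to two decimals in question
text but routing uses unrounded values, so administering the questionnaire
reproduces the source tree's prediction exactly — the central correctness
property, tested on random respondents. Serialization is schema-versioned
JSON with stable key order; deserialization validates branch references
and rejects cycles.

## Accuracy metrics

The positive (screening) class is low diet quality. From the confusion
matrix: sensitivity tp/(tp+fn), specificity tn/(tn+fp), agreement
(tp+tn)/n, PPV tp/(tp+fp), NPV tn/(tn+fn); zero-denominator ratios are
reported as undefined rather than 0. Proportions carry Wilson 95%
confidence intervals (the method is a package choice; the underlying
study reports CIs without naming one). The ROC ranks respondents by leaf
P(low); its trapezoidal area equals the Mann–Whitney statistic with
half-credit ties (both implementations exist, one checks the other), and
the AUC interval is a class-stratified bootstrap (2000 resamples, seeded).
A helper partitions truly-low respondents into true positives and false
negatives with covariates attached, for downstream group comparisons by
the user (no bespoke test is provided).

## Synthetic cohorts

No real cohort is distributable, so a seeded generator emulates webFFQ-style
data. Each respondent has latent diet quality q ~ N(0,1). Item intakes are
zero-inflated lognormal; the log-location shifts by
direction·weight·latent_effect·q (direction +1 healthful, −1 unhealthful,
0 neutral) and the zero-probability follows a logistic link in the same
signal, because non-consumption is itself informative in FFQ data.
Per-item parameters (zero probability, log-location/scale, direction,
weight) live in the catalog's `simulation` blocks, not in code; four
driver signals (processed meat, soft drinks, vegetables, whole-grain
bread) carry full weight. With the development preset (latent effect 0.8)
the latent factor separates the realized classes with AUC ≈ 0.95,
a strong-but-imperfect signal regime.

Reported energy is the catalog energy of the generated intakes; every
respondent's intakes are then rescaled so the rEI:eBMR ratio lands at a
drawn target — inside the Goldberg band for plausible reporters, outside
it (half under, half over) for a controllable misreporter fraction, which
therefore matches the Goldberg failure rate by construction.

The prevalence of low diet quality is calibrated to a target by bisection
(≤ 25 iterations, tolerance 0.01) on an additive healthfulness shift of
the item log-locations; the recorded true class is always what the AHEI
scorer assigns to the generated intakes, so truth and scorer agree by
construction. Cardiometabolic covariates (waist, blood pressure, lipids,
glucose, insulin) are Gaussian given the true class with configurable
standardized mean differences — worse profiles in the low class.

Presets mirror the two study samples: development (n=1040, age 45.4 ± 14.2
years in [18, 72], BMI 27.7 ± 5.3, no misreporters — that sample was
already plausibility-filtered; target low prevalence 0.59, from the
published AHEI mean/SD via a normal approximation) and external (n=3344,
age 66.5 ± 6.4 in [47, 91], BMI 27.1 ± 4.8, target prevalence 0.55,
misreporter fraction 0.25 — the rate is a package choice; the study does
not report one).

Randomness uses one named substream per variable (each demographic field,
each item's zero/amount draws, reporting targets, each covariate), all
spawned from the single cohort seed: runs are deterministic and the first
n respondents are unchanged when a cohort is enlarged. Truncation of age,
height and BMI to their ranges is by clipping, which slightly inflates
the boundary mass; the published means are still matched to well within
one year of age.

What the generator does **not** emulate: the real correlation matrix
between foods, item non-response, portion-size measurement error distinct
from the lognormal noise, and any real cohort's covariate means. Passing
tests therefore demonstrate correctness of the pipeline's machinery and
recoverability of planted structure at a realistic signal strength — not
that the published instrument or its accuracy values are reproduced.
Published headline metrics (development AUC 0.92, external 0.79) depend on
the two real cohorts and are deliberately not targets.

## Pipeline and reproducibility

`run_development` chains simulate/load → plausibility filter → AHEI
scoring (sodium deciles within the analyzed sample) → cross-validated tree
fit → questionnaire export → in-sample accuracy report, writing every
artifact plus a manifest (config, derived seeds, SHA-256 of each file).
`run_external_validation` applies a fitted tree to a new cohort without
filtering. All randomness derives from the single run seed via named
spawn keys; identical config and seed reproduce every artifact byte for
byte (manifests contain no timestamps). Stage failures abort with the
stage name.

Default problem sizes used by the test suite (cohorts of 250–1040;
20 recovery replicates; 2000-resample bootstrap in pipeline runs, fewer in
smoke tests) were chosen to exercise the claimed behaviour at the study's
own scale while keeping a full run of the suite under a minute of compute
for the unit portion and a few minutes overall.

## Known limitations

- The demonstration catalog is illustrative, not a reconstruction of the
  proprietary 136-question instrument; absolute AHEI totals depend on its
  per-serving values.
- Trans-fat intakes realistic for a contemporary diet sit near the
  10-point criterion, so that component contributes little variance.
- The alcohol and sodium interpolation rules at unstated margins are
  package choices (documented above) and can shift individual totals by a
  few points.
- CART instability: different seeds select different (correlated) food
  predictors; only the planted drivers are expected to recur.
- The bootstrap AUC interval is percentile-based; no DeLong variance, no
  calibration assessment.
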