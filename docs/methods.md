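# Methods

This note documents the statistical model, the numerical choices, the
synthetic-cohort generator and the known limitations of `timediet`, in
the package's own terms. Nothing here asserts an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Scoring

Diet items are coded 0 ("not at all") to 3 ("more than twice"), one
instance of intake counted as one serving, and summed within food
groups: fruit and vegetables (3 items, 0–9), discretionary foods
(4 items, 0–12), sugar-sweetened beverages (2 items, 0–6). Any missing
item voids that group's score and the record is dropped from the
analytic sample — the simplest rule consistent with a complete-case
analysis, chosen because no partial-sum convention is defensible for a
2–4 item sum.

The physical-functioning scale is the mean of the eight 0–4 PedsQL teen
items, reverse-mapped linearly to 0–100 as `25 × (4 − mean)`; the score
is missing when five or more items are missing. The linear reverse
mapping is the standard PedsQL transformation and is the unique affine
map satisfying the scale endpoints (all-0 → 100, all-4 → 0).

## Compositional preprocessing

Durations are treated as a composition closed to 1440 min/day. Diary
zeros are interpreted as below-detection values, not structural
absences; they are only permitted in the five behaviours that can
plausibly be skipped on a single diary day (not sleep or self-care).

**Zero replacement.** An EM-style imputation on additive log-ratio
(alr) coordinates, with the first zero-free part as reference: zeros are
initialised at 0.65 × cap, then each iteration (1) estimates the mean
and covariance of the alr coordinates over the whole sample,
(2) replaces each censored coordinate with its Gaussian conditional
expectation given the row's observed coordinates, *truncated* to
log-ratios at or below the cap (the cap acts as a detection limit —
this keeps imputed values strictly inside (0, cap] instead of piling up
at the cap), and (3) maps back to minutes and rescales the row's
observed parts by a common factor so it closes to 1440, which preserves
all ratios among originally non-zero parts. Convergence: largest
relative change of any imputed value < 1e-6, at most 50 iterations.
Default cap 10 min. With fewer than three rows, no covariance is
estimable and the capped initial values are kept (equivalent to simple
multiplicative replacement, which is also shipped as
`multiplicative_replacement` and used as an independent oracle in the
tests).

**ilr basis.** Pivot balances in the declared part order (sleep,
self-care, screen, quiet, physical activity, school, domestic/social):
row *i* contrasts part *i* against all later parts. Any other
sequential-binary-partition basis spans the same column space, so
fitted values, RSS, the composition block F and the diet standardized
betas are basis-invariant; the tests verify this to 1e-8 against a
randomly permuted basis.

**Reference profile.** The time reference is the closed geometric mean
rounded to the nearest 10 min with halves away from zero. Naive
rounding can break the 1440 total (the shipped example mean rounds to
1450), so a largest-remainder adjustment moves 10 min at a time from
the part whose rounding error is most in the surplus direction, ties
broken toward the part with the larger raw duration (adjusting a long
behaviour perturbs relative time use least). A pre-computed mean passed
as a single row is used at its reported precision rather than
re-closed first — re-closure before rounding would corrupt means that
only fail to sum to 1440 because they were rounded when reported. Diet references are
arithmetic means rounded to the nearest integer serve.

## Outcome model

OLS of the Box-Cox transformed score on the six ilr coordinates, three
diet scores and age/sex/SEP (13 parameters). Numerical choices:

* λ by profile likelihood on [−5, 5]: a 41-point grid scan followed by
  bounded Brent refinement (tolerance 1e-6). When a design matrix is
  supplied the regression likelihood is profiled (λ chosen to normalise
  the residuals); the marginal version is used for a bare response.
  The estimate agrees with an off-the-shelf Box-Cox MLE to 1e-3 in the
  tests.
* A shift of +1 is applied before transforming whenever the score
  attains 0 (the scale floor), and recorded in the model artifact.
* Rank-deficient designs raise an error naming the collinear columns.
  A saturated fit (n = 13) is allowed but flagged, with σ² reported
  as 0.
* Sex is coded 0/1; for prediction it is fixed at the sample mode, with
  ties broken toward 0 (female) — arbitrary, documented, and irrelevant
  to differences because the model has no interactions.
* The sex-interaction screen adds sex × block terms (the six ilr
  coordinates jointly; each diet score singly) and reports the partial
  F per block. Stratification is never performed.

Standardized betas are `b × sd(x) / sd(t)` with both SDs computed on
the analytic sample, t the transformed outcome.

## Equivalence engine

* **Time grid**: all zero-sum vectors with every component a multiple
  of 10 min in [−30, +30] — the "30-min radius" is per-behaviour
  (Chebyshev), matching a grid that is defined per behaviour; a
  Euclidean ball would arbitrarily exclude feasible profiles that move
  several behaviours by ±30 min simultaneously. 60,691 vectors for 7 parts,
  verified against brute-force enumeration of the 7⁷ lattice.
* **Diet grid**: ±1.5 serves in 0.5 steps per score, filtered so
  reference + delta stays inside each score's range; at the default
  reference (4, 2, 1) the SSB decrease is thereby capped at −1 serve
  and the grid has 7 × 7 × 6 = 294 triples.
* **Predicted differences** are computed on the back-transformed 0–100
  scale (differences are reported in scale points), with covariates
  fixed. The model is linear on the transformed scale, so the full
  table decomposes into a time contribution plus a diet contribution
  and the 17.8 M predictions vectorise into one broadcast and one
  back-transform (~5 s, ~150 MB).
* **Banding**: a combination belongs to band *T* when
  |difference − T| < 0.25, i.e. half the 0.5-point target spacing —
  the largest tolerance giving disjoint, exhaustive bands. A tolerance
  above half the spacing is rejected. The alternative convention
  (round to the nearest 0.5) is equivalent except on the
  measure-zero band boundaries.
* **Interactive filtering** is conjunctive row filtering: fixing a
  behaviour's delta restricts the remaining option set, the deltas
  offered for each unselected behaviour are exactly the distinct values
  present in the remaining set, and the final subset is independent of
  selection order.
* Row order is lexicographic in (time grid, diet grid), so exported
  tables are byte-stable across runs; the pipeline writes the extreme
  bands by default (the full banded table runs to millions of rows).

## Synthetic cohort generator

The generator produces item-level data so the entire pipeline —
scoring, validation, zero replacement, model fit — is exercised
end-to-end, with known ground truth for recovery tests.

* **Time use**: ilr coordinates drawn from a multivariate normal
  centred on the configured compositional mean (default: sleep 741,
  self-care 125, screen 163, quiet 175, physical activity 50, school
  129, domestic/social 58, closed to 1440). The covariance is the
  projection of independent per-part log-spreads `s` through the clr
  geometry, with `s = (0.15, 0.46, 1.03, 0.71, 1.23, 1.27, 1.20)`
  calibrated numerically so the arithmetic SDs of the generated minutes
  match realistic diary spreads (≈ 59/169/116/100/192/109 min for the
  six non-sleep parts). Sleep's arithmetic SD is closure-driven in this
  family (≈ 170 min, higher than a real diary's ≈ 82): matching it
  simultaneously with the other six is not possible with independent
  log-normal parts, and the other six take priority because they carry
  the behaviour effects. Durations are rounded to whole minutes by
  per-row largest-remainder so each day sums to exactly 1440.
* **Diary zeros**: with small per-behaviour probabilities (0.2–0.8%,
  five allowed behaviours; ≈ 2% of days carry a zero) a behaviour's
  whole duration is redistributed pro-rata over the remaining parts.
  Pro-rata donation preserves the ratios among the remaining
  behaviours, so the cohort's compositional mean stays centred on the
  configured one — donation to a single part would visibly inflate that
  part's compositional mean. The rates are deliberately small: each
  zeroed day re-enters the analysis with the behaviour imputed at
  ≤ 10 min, which pulls that behaviour's geometric mean down by roughly
  `rate × ln(mean/imputed) × mean` minutes; the defaults keep this
  displacement under the generator's 5-min calibration contract while
  still exercising the EM imputation with dozens of rows per cohort.
* **Diet**: independent categorical item draws with probabilities
  calibrated so the serving scores average ≈ 3.7 / 2.0 / 0.6 serves.
  Item independence understates the score SDs somewhat (e.g. 1.8 vs a
  real ≈ 2.2 for fruit/veg); a correlation copula was judged not worth
  the complexity for what the tests need.
* **Covariates**: age ~ N(14.4, 0.5²), sex ~ Bernoulli(0.5),
  SEP ~ N(0, 1).
* **Outcome**: the latent transformed score is built from the *same*
  preprocessing chain the analysis uses (zero replacement, ilr in the
  configured basis), true coefficients, and Gaussian noise; it is
  back-transformed (λ = 2), clamped to [0, 100] and quantised onto the
  8-item grid (nearest achievable item sum, spread evenly across
  items — the re-scored value reproduces the score to within half the
  25/8-point grid resolution). Missingness is injected afterwards
  (missing at random): 1% per PedsQL item, 0.4% whole-scale skips,
  0.5% per diet item.
* **True effects** are specified as a sum-zero coefficient vector on
  log-parts (a log-contrast), mapped to ilr coefficients through the
  basis. Defaults: positive for sleep and physical activity, negative
  for self-care, screen, quiet and domestic/social, near-zero for
  school; diet +30/−25/−45 transformed units per serve; residual SD 268
  transformed units (≈ 3 score points). These give behaviour-change
  effects of ~4.5 points across the full reallocation grid and
  population score mean ≈ 89.3 with SD ≈ 4.5.

**What the generator does not emulate.** The outcome spread is
deliberately narrower than a real adolescent cohort's (≈ 4.5 vs ≈ 13
points): with a mean near 89 a realistic SD would place ~20% of the
latent scores above the 100-point ceiling, and a heavily censored scale
cannot support exact coefficient recovery or calibrated confidence
intervals — the properties the recovery and calibration tests are for.
Passing tests therefore demonstrate correctness of the pipeline under a
well-specified latent-Gaussian model; they do not demonstrate
robustness to the strong ceiling effects, school/non-school day
structure, or item correlation of real diary and questionnaire data.
Likewise the generator draws each person independently (no survey
design, no clustering) and one diary day per person.

**Estimation noise and band membership.** Replacing the fitted model
with the generator's true model perturbs each predicted difference by
the coefficient-estimation error (≈ 0.1–0.4 points at n = 2000), which
is material relative to the 0.25-point band half-width; at n = 2000
roughly a fifth of the 17.8 M combinations change band, falling as
1/√n (≈ 4% at n = 20,000). The tests assert exactly this scaling. Band
*counts* and per-behaviour summaries are far more stable than
individual memberships.

## Problem sizes used in the packaged checks

Simulation-based checks use the sizes at which their statistical
guarantees are sharp enough to be meaningful while the whole suite
stays quick: single-cohort recovery and the dual-path enumeration at
n = 2000 (the full 60,691 × 294 table); CI coverage over 200 replicates
of n = 2000 pooled across the 12 slope coefficients; block-test type-I
calibration over 500 replicates of n = 400; generator calibration at
n = 5000; the acceptance script at the study-scale n = 2123.
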