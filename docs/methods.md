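# Methods

This note documents the models and procedures implemented in
`tunadrivers`, the assumptions behind the synthetic-data generator,
and the numerical choices a maintainer would want to know about. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Effort harmonization

tRFMO gridded catch-effort extracts report effort in the unit each
fleet logs. All units are converted to a common *days fished*:

| unit  | conversion | parameters |
|-------|------------|------------|
| days  | identity   | — |
| hours | value / hours_per_day | 24 h/day |
| trips | value × days_per_trip | 11 (small purse seine), 16 (baitboat), 30 (gillnet) |
| sets  | value / sets_per_day | 0.8 (purse seine, FAD-inclusive), 5 (eastern-Pacific baitboat school sets) |
| hooks | (value / hooks_per_set) × (soak_hours / 24) | 2750 standard longline; 1600 swordfish/shark-target; 1200 fresh; 1865 eastern Pacific; soak 19 h (IATTC), 22 h (CCSBT), else 24 h |

Choices that the source material leaves open:

* **Hooks → days.** No explicit formula is published for "hooks and
  soak time to days"; we use hooks → sets (divide by hooks-per-set)
  and scale a set by soak_hours/24, so a 24-hour soak equates one set
  with one day. Where a fleet's observed soak time is shorter (19 h,
  22 h) a set counts as proportionally less than a day.
* **Sets per day 0.8.** Read as a rate (sets per day), so
  days = sets / 0.8, applied uniformly to the purse-seine fleets that
  report sets. The multiply reading (days = 0.8 × sets) differs by
  56% and is rejected for consistency with the "per day" phrasing.
* **Trip-duration ranges** (7–15, 30–45 days) are never sampled; the
  stated point values (11, 30) are used.
* **ISC fleets** have no published conversion rows; they mirror
  standard western-Pacific practice (longline 2750 hooks/set, 24 h
  soak; other gears already report days).
* Fractional days are kept as reals; conversions are linear, so total
  days are conserved under any grouping order.

The registry ships as `data/conversion_rules.csv` (long format:
org, gear, subtype, unit, parameter, value, reference) and can be
overridden per run (`--conversion-rules`). Duplicate (org, gear,
subtype, unit) keys are a configuration error; an explicit-subtype
rule beats a wildcard.

## Shannon–Wiener spatial spread

For one fleet (tRFMO × stock × year × gear) with days fished E_a over
occupied cells a = 1…A and shares p_a = E_a/ΣE:

    H = −Σ_a p_a ln p_a,   0 ≤ H ≤ ln A

H = 0 iff a single cell was fished; the maximum is attained by a
perfectly even spread. Natural log is the default (a `base` option
exists); zero cells contribute nothing; an all-zero group is emitted
as missing, not zero, since "no effort" carries no spread information.
Note the sign convention: the index is entropy itself (one minus-sign),
so more even spread ⇒ larger index.

Cell identity is the (lat, lon, cell-size) triple after harmonization;
longline fleets are gridded at 5°, all others at 1°, and gears are
never mixed within a group. The index enters the regression as the
`SW` column, one value per (stock, gear, year) row — gear-specific
rows are kept (rather than averaged across gears) to match the gear
dummy variables.

## Real prices

Nominal series are converted to USD with the year's FX rate, then
deflated relative to base year 2014:

    real_y = nominal_y × fx_y × (I_2014 / I_y)

Fish prices (fresh and frozen, ¥/kg ex-vessel) use a fish-price index;
fuel ($/barrel) uses an average-spot-price index; the deflator is a
per-series input, never hard-coded. Deflation is the only de-trending
applied — no additional linear detrend. The base-year identity
(real = nominal USD at 2014) and invertibility (re-inflating recovers
the nominal series) are tested properties. Conversion happens before
within-year averaging. Year-on-year percent changes
100·(x_t − x_{t−1})/x_{t−1} are provided as the volatility diagnostic
that motivates the ±25% perturbation size below.

## The analysis matrix

One row per (stock, gear, year): 34 predictors + response.

* continuous: `realfuel`, `realfrozp`, `realfresp` (matched to the
  row's species), `SW`, `HDI` (mean over the stock region's
  countries);
* 10 annual climate indices (EA, WP, EP_NP, PNA, DMI, TNA, TSA, PDO,
  SOI, NAO), attached by year;
* dummies: all 10 stock-region levels; species with albacore as
  reference; gear with baitboat as reference.

The full stock encoding is deliberately redundant with the intercept
(the penalized fit handles it; see below). Missing drivers cause
listwise deletion with logged counts — no imputation. The Pearson
correlation matrix of the 15 continuous columns, ordered by
average-linkage clustering on distance 1 − r, is the standard
multicollinearity diagnostic.

## Ridge regression

The estimator is written from scratch:

    β̂(λ) = (Z′Z + λI_p)⁻¹ Z′y_c

minimizing Σᵢ(yᵢ − Σⱼzᵢⱼβⱼ)² + λΣⱼβⱼ². Implementation contract:

* **Standardization.** All predictors — dummies included — are scaled
  to mean 0, unit population variance before penalization; a single λ
  across heterogeneous units is only meaningful on a common scale.
  Returned coefficients are back-transformed to the original scale;
  the per-SD ("standardized") coefficients are also exposed.
* **Intercept** is unpenalized, handled by centering y.
* **λ scale.** λ multiplies the raw *sum* of squares (`lambda_scale=
  "sum"`, the default). Much penalized-regression software divides the
  loss by n, which rescales λ by n; reported λ values are therefore
  not comparable across conventions (a `"mean"` option is provided).
* **Solver.** Cholesky factorization of (Z′Z + λI); no explicit
  inverse. At λ = 0 an ill-conditioned Gram matrix raises a
  `SingularMatrixError` advising a positive penalty.
* **Exact collinearity.** The full 10-level stock block plus intercept
  makes Z′Z exactly singular at λ = 0 (centered dummies of a complete
  factor sum to zero): coefficients are estimable only up to that null
  direction. `ols_min_norm` provides the SVD-based minimum-norm
  solution — the λ→0 limit of the ridge path — for identifiability
  checks; the strict solvers intentionally refuse the singular system.
* **λ grid.** 100 log-spaced values from λ_max = maxⱼ|z_j′y_c| down to
  10⁻⁴λ_max.
* **Cross-validation.** Seeded k-fold (default 10): rows are randomly
  partitioned into near-equal folds; standardization is recomputed
  inside each training fold (no leakage). λ_min minimizes mean
  held-out MSE (ties break toward more shrinkage); λ_1se is the
  largest λ with mean MSE within one standard error of the minimum.
* **Final procedure.** Rows are split 2/3 train, 1/3 test; CV on the
  training set selects λ_min; test MSE and R² come from the
  training-only fit applied to held-out rows; the primary coefficient
  estimates are a refit at λ_min on the full data (both fits are
  returned). Deviance explained is 1 − RSS/TSS of the full-data fit.

Oracles in the test suite: direct numerical minimization of the
penalized objective (scipy BFGS) on random small instances,
scikit-learn's Ridge on the pre-standardized design, and closed forms
(orthogonal design shrinkage n/(n+λ), total-shrinkage limit).

## Elasticities

For each continuous driver and each stock: scale the driver by
1 ± 0.25 on every row of that stock (dummies and all other columns
fixed), recompute predictions, and average the per-row percent change
100·(ŷ′ − ŷ)/ŷ. Averaging over the stock's observed rows — rather
than predicting at a single mean row — respects the gear/species
composition of multi-gear stocks. For a linear fit the two directions
are exactly antisymmetric and a zero coefficient gives exactly zero;
both facts are tested, and the re-prediction route is cross-checked
against the closed form 100·β_j·factor·x_j/ŷ to 1e-10. Percent
changes are ill-behaved near ŷ = 0: stocks with any baseline
prediction below 0.05 carry a stability flag. The perturbation is
multiplicative on each row's own value, including for signed climate
indices (a "25% increase in the index").

## HDI versus status

Countries map to stock regions via an input table (the generator
emits a consistent one). Per stock and per period (1990–2001,
2002–2012 by default, configurable and non-overlapping), the
unweighted mean HDI over (countries × years) is paired with the mean
F/F_MSY over years; counts above/below F/F_MSY = 1 and a per-period
least-squares trend of mean F/F_MSY on mean HDI summarize the
comparison. No catch weighting is applied — only country means.

## Synthetic-data generator

The generator fabricates all six input classes and then *runs the
real pipeline stages* (harmonize → diversity → deflate → assemble) on
its own draws, writing the response on top of the assembled matrix:

    F/F_MSY = α + Z β_true + ε,   ε ~ N(0, σ²)

with Z the standardized feature matrix and β_true on the per-SD scale.

Emulated structure, and what is *not* emulated:

* Effort is drawn per fleet-year in the fleet's native unit (whatever
  its tRFMO reports), spread over grid cells by a Dirichlet with a
  fleet-specific concentration (log-uniform over ~0.2–5), so true
  spatial spread varies across fleets. No spatial population dynamics,
  no fleet behaviour, no vessel-level structure.
* Prices follow a multiplicative inflation trend (≈1.5%/yr fish,
  2.5%/yr fuel) times log-normal noise, with yen/kg levels of
  250–3000 by species and form; FX ≈ 110 ¥/$; deflators grow ≈2%/yr.
  Deflation is therefore a meaningful, testable step. No price
  formation or demand dynamics.
* Climate indices are mean-zero stationary AR(1) series (default
  autocorrelation 0.4, unit variance), annual only.
* HDI is a slow upward random walk in [0, 1] per country, three
  countries per region.
* Default dimensions: the 19 assessed stocks, 48 stock×gear fleets
  (every stock longline + purse seine; skipjack stocks add baitboat,
  Indian Ocean stocks gillnet, two albacore stocks troll, east
  Atlantic bluefin the single trap fishery), 23 years ending at the
  2014 base year → 1104 rows × 35 columns. All dimensions are
  configurable; tests run smaller.
* One RNG stream per input class, each derived from the master seed,
  so adding a class never perturbs existing draws; a fixed seed gives
  byte-identical bundles.

**Ground truth and identifiability.** β_true defaults to a fixed
sign/size pattern typical of fitted tuna-status drivers (frozen price
dominant among the economic drivers, modest climate effects, strong
regional contrasts), scaled so the linear predictor SD is ≈0.33 around
an intercept of 0.766 — chosen so the simulated F/F_MSY distribution
is realistic (mean ≈0.8, SD ≈0.4, essentially all mass in (0, 2.5)).
Because the full stock-dummy block is exactly collinear with the
intercept (and short simulated series add exact collinearities among
year-level covariates), the generator projects β_true onto the row
space of the realized design and exposes the result as
`beta_identifiable` — the unique minimum-norm representative; the
projection leaves the linear predictor untouched. Recovery tests
target this vector.

**Positivity.** F/F_MSY is modelled untransformed and must stay
positive. With noise, rows drawn ≤ 0 have their noise redrawn (up to
100 rounds, then a 10⁻³ floor as a last resort) — a mild truncation
affecting only the lowest-predictor rows (~4% of draws at default
settings). Without noise, a single global shift (recorded in
`intercept_used`) keeps the exact linear model intact. The error
distribution of real assessment F/F_MSY around any linear predictor is
unknown; Gaussian noise is an assumption of the generator, not a claim
about real data.

**Noise calibration.** With `noise_sd=None` (default) σ is set from
the realized linear-predictor variance so the population R² equals
`target_r2` (default 0.65). Passing tests on this surface demonstrates
correctness of the computations and estimator calibration under the
assumed data-generating process — not predictive skill on real
fisheries data, whose drivers are more collinear, gappier and not
linear-Gaussian.

## Problem sizes and determinism

Default study conditions are 1104 rows × 34 predictors; the CV uses
10 folds over a 100-point λ grid (≈1000 small Cholesky solves per
model selection — well under a second). Property suites use 50 random
ridge instances, 1000 random Shannon vectors, and 10–20 seeds for the
stochastic recovery/calibration checks. All randomness flows through
seeded `numpy` generators: the pipeline fans a master seed out to
deterministic per-stage seeds, and identical config + seed reproduces
every artifact hash.

## Known limitations

* The conversion registry encodes point values; uncertainty in the
  effort conversions (trip-length ranges, FAD vs free-school set
  rates) is not propagated.
* Ridge standard errors / p-values are out of scope; the model is
  used for prediction and sensitivity, not inference.
* Elasticities are ratios of model predictions; they inherit the
  model's linearity and are unstable where predicted F/F_MSY ≈ 0
  (flagged, not suppressed).
* λ values are tied to the sum-of-squares objective scaling and are
  not comparable to mean-loss implementations without multiplying
  by n.
* The HDI comparison is descriptive; no causal claims, no
  catch-share weighting of country means.
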