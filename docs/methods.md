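# Methods

## The food-level score

`nutrisurv.scoring` implements the updated (2023) Nutri-Score nutrient
profiling model. Each item is scored per 100 g of food or 100 mL of
beverage. Unfavourable ("A") components — energy (kJ), sugars, saturated
fat and salt — and favourable ("C") components — protein, fibre and the
fruit/vegetable/legume (FVL) percentage — each earn points from ordered
threshold tables; the final score is `A − C` after a conditional protein
rule, and maps to the five front-of-pack letters. For general foods the
attainable range is −17 (best) to +55 (worst).

Category-specific rules, as transcribed from the official 2023 algorithm
(Nutri-Score international scientific committee update reports):

* **General foods** — A maxima 10/15/10/20 (energy/sugars/saturated
  fat/salt), C maxima 7/5/5 (protein/fibre/FVL, the FVL points being the
  non-contiguous 0/1/2/5). Protein points are dropped once A ≥ 11.
* **Cheeses** — general tables, but protein always counts.
* **Red meat and products** — general tables with protein capped at 2
  points.
* **Fats, oils, nuts and seeds** — the energy component is scored on the
  *energy from saturates* (37 kJ per g of saturated fat) and the
  saturated-fat component on the saturates-to-total-fat ratio
  (thresholds 10…64%); a fat-free item earns 0 ratio points by
  convention. Letter band A extends down from −6.
* **Beverages** — per-100 mL tables with their own energy (30…390 kJ),
  sugar (0.5…11 g) and protein (1.2…3.0 g) thresholds and FVL points
  0/2/4/6; the letter A is reserved for water, so non-water beverages
  span B–E. The 2023 beverage algorithm's non-nutritive-sweetener
  penalty is out of scope here because the composition schema carries no
  sweetener field.

All thresholds live in `data/nutriscore_points_2023.yaml`; the code is
table-driven, and a single boundary convention applies everywhere: a
value exactly equal to a threshold earns the lower point count. Energy
is stored in kJ (1 kcal = 4.184 kJ) and salt may be derived from sodium
(× 2.5) at ingestion. `score_extrema` enumerates every combination of
attainable per-component point values (honouring the conditional
protein rule), so the printed −17…+55 range is a computed, not asserted,
property.

## From FFQ to dietary index

The FFQ engine maps the nine ordinal frequency levels to servings/day
with fixed constants (never = 0; 1–3/month = 2/30; 1/week = 1/7;
2–4/week = 3/7; 5–6/week = 5.5/7; 1/day = 1; 2–3/day = 2.5;
4–6/day = 5; >6/day = 7). These interior constants are configuration —
standard FFQ conventions — because only the scale endpoints are fixed by
the instrument. Grams/day = rate × portion; item energy follows from the
per-100 g composition. A missing item level within an otherwise complete
FFQ counts as "never".

Cohort exclusions are applied in a fixed order with strict boundary
semantics: missing baseline dietary data; implausible energy (women
< 500 or ≥ 3500 kcal/d, men < 800 or ≥ 4000 kcal/d); no follow-up. The
filter is idempotent and reports per-reason counts.

The individual dietary index is the energy-weighted mean of the scores
of everything consumed, `DI = Σ NSᵢEᵢ / Σ Eᵢ` — a convex combination of
item scores, computed on raw (not energy-adjusted) intakes because the
weighting is explicitly by energy. The residual method (OLS of an intake
on total energy; adjusted value = residual + prediction at mean energy)
is provided for nutrient and food covariates such as ultra-processed
grams/day; it preserves the sample mean and zeroes the correlation with
energy by construction.

The analysis exposure is the cumulative average of the DI over all FFQs
up to each time point. Cohort quintile cuts are computed **once**, on
the end-of-follow-up cumulative averages (linear-interpolation
percentiles, ties to the lower quintile); the time-varying covariate
carries the quintile of the current cumulative average against those
fixed cuts. Whether cuts should be recomputed at each update is an open
design choice; fixed cuts keep quintile membership interpretable.

## Survival models

Intervals are the half-open inter-FFQ periods `[start, stop)` with the
exposure updated exactly at visit times (no interpolation) and the event
on the final interval only; interval lengths sum to follow-up time.
Fitting uses the Cox partial likelihood (Efron ties — the tie-handling
choice is ours; simulated times are continuous so it is inconsequential)
with late-entry risk sets, via lifelines. Cluster-robust sandwich
variance uses a household cluster identifier, since some participants
are recruited as household pairs. Cause-specific models censor at
competing deaths.

* **Quintile models** report HR (Q1 reference), 95% CI, Wald p, cases,
  person-years and deaths per 1000 person-years per quintile, for a
  minimally adjusted model (age, sex) and a fully adjusted model (plus
  total energy, intervention group, education, smoking, physical
  activity, BMI ≥ 25, alcohol, family history of cancer, diabetes,
  hypertension, hypercholesterolemia). Complete-case analysis
  throughout.
* **Trend test**: the observed quintile medians enter the same model as
  a continuous variable; p is the Wald p-value of that coefficient.
* **Per-SD model**: exposure standardized by the sample SD of the
  participant-level exposure at analysis entry (one value per
  participant, ddof = 1). The synthetic generator standardizes its
  hazard the same way, so recovery comparisons are exact.
* **Interactions**: likelihood-ratio tests on exposure×modifier product
  terms (plain ML, not sandwich), modifiers being sex, education, BMI
  ≥ 25, and median splits of age, Mediterranean-diet adherence score and
  ultra-processed intake; subgroup per-SD HRs accompany each test.
* **Early-death sensitivity**: participants whose death falls inside the
  first 1 or 2 years are dropped entirely and the models refit with the
  main-analysis quintile cuts.
* **Baseline-exposure sensitivity**: the time-fixed baseline DI replaces
  the cumulative average; with a single FFQ the two models coincide
  exactly.

## Fine–Gray competing risks

No installed Python package offers Fine–Gray *regression* (only
nonparametric cumulative incidence), so `nutrisurv.finegray` implements
the estimator directly: subjects failing from a competing cause remain
in the risk set after failure with inverse-probability-of-censoring
weights `G(t−)/G(Tᵢ−)` from the Kaplan–Meier of the censoring
distribution, and the weighted Cox partial likelihood is maximized on
the expanded counting-process data with robust variance. On a seeded
fixture the coefficients agree with R's `cmprsk::crr` to ~1e-3. The
exposure entering the Fine–Gray sensitivity analysis is the time-fixed
end-of-follow-up cumulative average (subdistribution hazards with
internal time-varying covariates are not well defined).

## The synthetic cohort

`nutrisurv.simulate` generates everything the pipeline consumes, with
ground truth stored separately:

* **Food database** — 137 items drawn from Mediterranean-diet archetype
  groups (vegetables, fruits, legumes, cereals, dairy, cheese, fish,
  meats, olive oil and other fats, nuts, sweets, snacks, ready meals and
  beverages including water), each with realistic per-100 g composition
  ranges and portion sizes. Two engineered items
  (`synthetic_score_floor`, `synthetic_score_ceiling`) pin the −17 and
  +55 extremes so item scores span the full scale.
* **Responses** — a latent diet-quality trait θ (higher = less healthy)
  shifts item propensities along the standardized item score; a shared
  per-person appetite effect and a male shift move all items together;
  item-level noise is AR(1) across annual visits (ρ = 0.7). The latent
  value is cut into the nine ordinal levels. Base propensities were
  calibrated once, by inverting the expected serving rate per archetype
  against typical Mediterranean daily gram intakes, to give a baseline
  energy distribution near 2,200 ± 540 kcal/d (higher in men), a DI
  distribution near 4 ± 2, and ≈ 1% implausible-energy exclusions.
* **Survival** — cause-specific piecewise-exponential hazards, constant
  between FFQ visits, with linear predictor β_cause·z(t) + age and sex
  effects (+ optional shared log-normal cluster frailty, variance 0 by
  default), where z(t) is the cumulative-average DI standardized by its
  baseline mean/SD. Event times come from exact inverse-CDF sampling of
  the piecewise-exponential; the first event wins; administrative
  censoring is Uniform(3, 9) years, giving a median follow-up near 6
  years. Default baseline hazards give ≈ 7% deaths split roughly
  103:169:153 across cardiovascular, cancer and other causes; default
  per-SD HRs are 1.38 (CVD), 1.05 (cancer), 1.15 (other). Hazard
  covariate effects are deliberately limited to age and sex so the
  minimally adjusted analysis model is correctly specified and
  parameter-recovery experiments measure estimator behaviour, not
  omitted-variable effects.

The generator's DI is computed with the same arithmetic as the pipeline
(and a test asserts bit-level agreement), so recovery studies are free
of artificial measurement-error attenuation. What the generator does
**not** emulate: real food-frequency correlation structure beyond the
single trait + appetite factors, seasonal or secular intake drift,
informative censoring, covariate-dependent diet–disease confounding, and
any intervention effect. Passing tests therefore demonstrate correctness
of the estimators under the stated model, not robustness to every
real-data pathology.

## Simulation study sizes and tolerances

* Parameter recovery: 200 replicates of n = 2,000 (3 annual FFQs), true
  per-SD HR 1.4 for cardiovascular death; the mean estimated log-HR must
  sit within 3 Monte-Carlo SEs of truth and the 95% CI coverage inside
  the exact binomial 95% interval. Observed (seed 20230901): bias
  +0.007 on a truth of 0.336 (0.7 MC SEs), coverage 95.5%, empirical SE
  0.140 vs mean model SE 0.140.
* Type-I error: 400 null replicates of n = 600 with elevated baseline
  hazards (≈ 25% events) so each fit has adequate events; trend-test and
  interaction-LRT rejections at α = 0.05 must fall inside the exact
  binomial 95% interval [12, 29] of 400.

Numerical conventions: percentile cuts by linear interpolation; sample
SDs with ddof = 1; 95% CIs as exp(β ± 1.96·se); ties at quintile cuts to
the lower bin; zero-energy visits are an error rather than a silent NaN.

## Known limitations

* The point tables are a transcription of the official 2023 algorithm;
  the table file is versioned and checksummed (`table_checksum`) so a
  transcription correction never touches code.
* The Fine–Gray implementation expands competing-risk risk sets
  explicitly; it is quadratic-ish in events and intended for cohort
  sizes in the thousands, not millions.
* Subgroup fits inside `interaction_test` can be unstable in small
  strata; they are reported as `None` when a stratum has fewer than two
  events.
* The exclusion filter assumes binary recorded sex because the
  energy-plausibility windows are sex-specific.
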