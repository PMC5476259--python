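# Methods

This note records the statistical models the package implements, the
design decisions taken where the procedure was genuinely open, and what
the synthetic-data tests do and do not demonstrate.

## Record model and standardisation

A record is one volunteer report of a murmuration: day of season
(1 = 1 October; the accepted window runs to day 179, late March of a
leap-year season), estimated flock size, display duration in minutes,
whether and how the event ended, and — depending on survey-year schema —
either exact reporting lag, coordinates, settlement class and habitat
(year 1) or a coarse recency category, temperature and per-species
predator activity (year 2).

The standardisation chain applies five rules in a fixed order:
historical (reporting lag > 31 days, or the `over_month` recency
category), incomplete, zero birds, zero duration, garden/parkland
feeding. A record violating several rules is attributed to the first,
which makes per-rule counts an exact partition of the removals and makes
the chain idempotent. Records are excluded, never edited. No further
outlier heuristics are applied: the chain is meant to be auditable, and
anything beyond these rules would be an undocumented judgement call.

Murmuration selection keeps flocks of at least 500 birds — a threshold
motivated by field observations that definite murmuration patterns
emerge at roughly 430–450 birds — optionally requiring a witnessed
ending, mass descent to roost, and UK records only.

## Day length

Photoperiod is computed from the NOAA solar-position equations
(Julian-century ephemeris for the apparent declination; closed-form
sunrise hour angle) at a solar altitude of −0.833°, which folds in
standard atmospheric refraction (≈ 0.567°) and the solar semi-diameter.
A single reference coordinate — the geographical centre of the UK — is
used for every record: the covariate is a national seasonal signal, not
a site property. Latitudes poleward of ±66.5° are rejected explicitly
rather than returning polar-day/night artefacts.

The test suite checks the implementation against an independently coded
astronomy path (sun right ascension/declination plus sidereal-time hour
angle, bisecting the altitude crossings, with no equation-of-time step);
the two agree within 0.16 minutes across the season. Two physical facts
worth recording because they are easy to misstate: at −0.833° the
equinox day at UK latitude is about 12 h 09 m, not 12 h 00 m; and the
mean day-length difference between the UK centre and its latitudinal
extremes over an October–March season is tens of minutes (exceeding
100 minutes at midwinter between 50° N and 58.6° N). The single-point
covariate is nonetheless adequate because weekly aggregation (below)
averages out within-country scatter.

## Seasonal trends

Size and duration are fitted by least-squares polynomials in day of
season. Degree selection among candidates (default {1, 2}) uses
**adjusted** R² with ties broken toward the lower degree; raw R² is
available for compatibility, but raw R² can never prefer the simpler
nested model, so it is not the default. Saturated fits (n = degree + 1)
are permitted and report R² = 1 with no residual degrees of freedom.

The duration–day-length regression uses weekly aggregates: weeks are
`ceil(day_index / 7)` from season start, each retained week contributes
its mean (SEM reported when n > 1), and all weeks are weighted equally.
Weekly aggregation prevents single days with atypically clustered
records from dominating a covariate that is shared across the country.

## REVS

"Empirical support" is the one genuinely underdetermined ingredient of
Regression with Empirical Variable Selection, and the package's default
is **best-subsets frequency**: for each subset size s the minimum-RSS
(equivalently minimum-AIC, since k is fixed at a given size) subset is
found — exhaustively for p ≤ 15, via greedy forward search beyond — and
a predictor's support score is the number of best subsets containing it.
Ties break by univariate AIC, then input order. A univariate ranking
(single-predictor AIC) is available as an alternative. Constant columns
are flagged and ranked last.

The nested sequence fits models on rank-order prefixes; a predictor
whose addition makes the design singular is skipped with a warning. AIC
is `n·ln(RSS/n) + 2k` with k counting intercept, slopes and error
variance; the additive Gaussian constant is dropped because only ΔAIC is
interpreted (the tests verify ΔAIC is identical under the full
log-likelihood form). The ΔAIC threshold is closed at 2.0, so a model at
exactly 2.000 still qualifies. Within the candidate set, MAM minimises
(predictor count, AIC), Optimal is the ΔAIC = 0 model (ties to fewer
predictors), and Maximum maximises adjusted R² (ties to fewer
predictors); when no smaller model qualifies, MAM coincides with
Optimal. ΔAIC is always computed within the nested sequence, not over a
wider candidate set. No small-sample correction is applied by default
(n greatly exceeds p in the intended use); AICc can be obtained by
adjusting the threshold externally. p-values are reported at model level
only. Responses are untransformed; a lognormal observation-error mode in
the generator exists for robustness studies of untrained-observer count
error.

Presence and activity designs are never mixed for one species: presence
equals the sum of the four activity indicators, an exact collinearity
that `validate_predictors` detects by a sequential rank test (it also
reports near-collinear pairs above a configurable |r| bound). The
Durbin–Watson statistic `Σ(eₜ−eₜ₋₁)²/Σeₜ²` is computed on residuals in
caller-supplied order; the pipeline orders records by time within
location before fitting.

## Association battery

The t-test uses the pooled-variance form (integer degrees of freedom
n₁+n₂−2); Welch is available through scipy directly. The chi-square test
of association is the uncorrected Pearson statistic with
(r−1)(c−1) degrees of freedom, warning when any expected count drops
below 5. The terminal-behaviour table is 2×3: bird of prey
present/absent against roost-en-masse / dispersed / other, where "other"
collects partial roosting and flock splitting, and corvids and gulls —
recorded because their silhouettes can be mistaken for a raptor at dusk —
never count as "bird of prey present".

## Synthetic data generator

The generator's defaults describe a realistic UK season: day of season
uniform over a 174-day window; temperature a sinusoid coldest in
mid-January (mean 7 °C, amplitude 5 °C, noise SD 3 °C); flock size a
dome-shaped quadratic peaking in early February (~58k birds at peak)
plus per-species presence effects and Gaussian noise with a plausibility
floor; duration a covariate model — intercept 5 min, +2 min per hour of
day length, −0.3 min/°C, plus species × activity effects confined to
"flying" and "engaging" — or, alternatively, a direct quadratic in day
of season for trend-recovery studies. Presence probabilities follow the
observed frequency ordering (sparrowhawk most common; a raptor at ~30%
of events; corvids 15.8%, gulls 17.6%). Endings are sampled conditional
on raptor presence (defaults 0.85 vs 0.65 probability of mass descent;
a third of endings unwitnessed). Dirty records are injected by
corrupting otherwise-valid rows, at most one corruption category per
record, so per-rule removal counts are exactly binomial. Everything is
driven by one seed; identical configurations give byte-identical CSV.

The recovery study uses a fixed configuration (`recovery_study_config`)
with raised presence probabilities so each true-effect indicator occurs
in roughly 3–7% of events; at n = 1000 every true effect then sits at
≥ 4 design-based standard errors, chosen a priori so the study is
informative about the selection machinery rather than about sampling
accidents. Replicates derive their seeds deterministically from a base
seed.

What the generator does **not** emulate: spatial structure beyond a
country flag and uniform UK coordinates, observer-effort bursts after
publicity, duplicate reports of one physical event, day-to-day weather
autocorrelation, and any real distribution of observer counting error
(both Gaussian-on-raw-scale and lognormal modes are provided; neither is
claimed as truth). Passing recovery tests therefore show the estimators
and the selection rules work when the model is correctly specified at
realistic sizes and rates — they do not validate the models against the
messiness of real volunteer data.

## Problem sizes and numerical choices

Simulation-based tests use n = 300–1000 records and 20–1000 replicates
depending on the statistic being calibrated — large enough that binomial
99% intervals and 3-standard-error bounds are meaningful, small enough
to keep the suite fast. Durations are serialised at two decimal places,
which bounds "exact" zero-noise recovery at that precision. Exhaustive
best-subsets search switches to greedy forward selection above 15
predictors (the 29-predictor activity design uses the greedy path). The
subset-RSS solver works from the Gram matrix of the intercept-augmented
design with a least-squares fallback on singular subsets. Degenerate
inputs are first-class: saturated fits flag AIC as undefined, all-zero
residuals make Durbin–Watson an explicit error, zero row/column margins
make the contingency test an explicit error, and empty inputs return
empty outputs rather than raising.

## Known limitations

* Greedy ranking above 15 predictors is a restricted search; the nested
  sequence may miss the all-subsets best model (this is inherent to
  REVS — the gap is a diagnostic, not a defect).
* The day-length covariate is national, so latitude-driven photoperiod
  variation among records is deliberately ignored.
* Habitat enters only as a grouping label for ANOVA; no habitat
  effects exist in the generator, so habitat analyses are calibration
  (type-I) checks only.
* The pipeline assumes complete cases for the regression designs
  (records without temperature are dropped from REVS).
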