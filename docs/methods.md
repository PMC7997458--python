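# Methods

This note documents the models and conventions implemented in
`phenotherm`, the choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Snow seasons

A site's snow season is read from a daily percent-cover series.
Definitive snowmelt is the first date from which every later non-missing
observation is at or below a 10 % margin; the first permanent winter
snow is the first post-melt date from which cover stays above the margin
to the end of the record.  Cloud days (missing values) are skipped in
both scans — they neither violate nor satisfy the criterion, and nothing
is imputed.  On full-year series, where the record necessarily ends
under snow, `snow_season` first locates the longest run of below-margin
observations; its first day coincides with the suffix criterion applied
to the series truncated before the winter return.

*Day-count convention.*  Snow-free days are counted inclusive of the
melt date and exclusive of the winter-onset date, i.e. the plain
difference in days.  The emulated campaign's published table is
consistent with this convention (a 31 Aug melt and 8 May onset give
250 days = 8.2 months at 365.25/12 days per month, rounded half-up to
one decimal); the source material does not state its convention
explicitly, so ours is documented and tested rather than assumed
universal.

## Temperature reconstruction

One weather station provides the continuous daily Tmin/Tmax record.
Short paired-logger deployments give, for each contiguous pair of sites,
the average monthly difference in air temperature.  The station series
is first shifted by a single calibration offset (mean logger tmean minus
mean station tmean over the overlap window; requires ≥ 30 common days)
to define the reference site, then propagated along the chain of sites
by adding the signed monthly offsets, applied equally to Tmin and Tmax.
Month boundaries follow the station date's calendar month.  The
operation is exactly invertible, and a site not connected to the
reference through the offset graph is a hard error naming the site.
Missing days inside any requested window are likewise hard errors — the
campaign design has no gaps, and silent interpolation would corrupt
thermal sums.

## Thermal sums

The daily increment is `max((Tmax + Tmin)/2 − T_base, 0)`, with a day
whose mean exactly equals the base contributing zero.  No sine-wave
(Baskerville–Emin) refinement is used: the simple daily-mean form is the
field's convention for this kind of study.  Accumulation runs from the
snowmelt biofix to the event date, *inclusive of both endpoints*; the
inclusive end is exposed as a flag (`include_end`) because the
convention is not universal.  `n_growth_days` counts strictly positive
increments, and the growing-season fraction divides it by the snow-free
day count.

Base-temperature scenarios are either fixed (one value everywhere;
5 °C and 1 °C are the conventional choices) or graded:
`base(site) = base(ref) − (mean(ref) − mean(site))`, the means being
site mean temperatures over each site's own snow-free period.  The
graded series expresses the hypothesis that a population's thermal
threshold for growth tracks the elevational decline in growing-season
temperature.

## Flowering metrics

Censuses (per-plant open-flower counts on visits 3–5 days apart) are
snapped to the nearest interval of a regular 3-day grid anchored at the
first visit; when two visits fall in one interval the larger count is
kept.  A plant is *in phenophase* in an interval if its count is
positive there, or — the bracketing rule — if the interval lies between
two in-flower intervals of the same plant (erratic openings and missed
visits).  Bracketed gaps set only the boolean; counts are never
invented.

The season is extrapolated by a least-squares quadratic of total open
flowers on day number; its real roots give the season start and end.  A
convex or complex-root fit falls back to the first/last nonzero
observation dates, flagged in the result.  Plants already in flower at
the first visit are granted extra leading in-phenophase intervals
proportional to their share of the first-visit display:
`round(k · c_i / c_max)` of the `k` grid intervals between the
extrapolated season start and the first visit.  This implements the
idea that large displays imply longer prior flowering; the exact
allocation rule is our interpretation and is confined to the phenophase
booleans.

Metrics: FF is the first interval with any plant in phenophase; FL50
the first interval with at least half the monitored plants
*simultaneously* in phenophase (a cumulative-onset variant, the first
interval by which half the plants have begun flowering, is also
computed — the simultaneous reading is the default because it matches
percent-in-phenophase curves); FLP and FLSP are the earliest intervals
attaining the maximum simultaneous plant count and the maximum summed
flower count.  All ties at maxima resolve to the earliest interval.
Per-plant FF_POP and FLP_POP are each plant's first in-phenophase
interval and earliest own-count maximum; population summaries use
medians — of days for reporting, and of per-plant GDD values when the
metrics enter thermal-sum regressions.

Augspurger's synchrony index for plant *i* is
`X_i = (1/(n−1)) (1/f_i) Σ_{j≠i} e_ij` with `f_i` the number of
in-phenophase intervals of *i* and `e_ij` the number of intervals *i*
and *j* share; the site value Z is the mean.  Plants that never flower
are excluded from the index and reported.

Elevational trends are ordinary least squares of a per-site scalar on
elevation, with the slope reported per 100 m and the regression F on
(1, n−2) degrees of freedom.  Site effects on per-plant distributions
use the Kruskal–Wallis test with tie correction, followed by Dunn's
pairwise z comparisons on mean ranks with Bonferroni adjustment (the
post-hoc is implemented directly; no suitable dependency ships it).

## Flower longevity and RPR

A flower open and closed on the same day lived 1 day
(`closure − anthesis + 1`), which makes the shortest observable
life-span 1 d, matching published 1–7 d ranges.  The unit of analysis
everywhere is the mean over a plant's flowers; batch values are means of
plant means.  RPR = 1 − AFL/PFL at site level; negative values (noise
pushing AFL above PFL) are flagged but not clipped, so aggregation stays
unbiased.

Seasonal weighting multiplies each batch value by floral abundance — the
site's total open-flower count averaged over the nearest census date(s)
flanking the batch — and divides by the summed weights.  The normalized
form is the default because it preserves units (weighted fruit set stays
a percentage); the unnormalized product-mean is exposed for comparison.

Temperature responses are OLS of batch-mean longevity on batch-mean
ambient temperature (the mean over each flower's open days, then plant,
then batch).  PFL and AFL lines are compared by the Chow coincidence
test, `F = [(SSR_p − SSR_A − SSR_B)/2] / [(SSR_A + SSR_B)/(n_A+n_B−4)]`,
plus the interaction-term t test of the combined model for slope
equality.  The warming experiment is analysed per site with two-sided
Mann–Whitney tests on plant means and overall with the factorial ANCOVA
`longevity ~ diameter + treatment × site` (type-II sums of squares).

The observational mixed ANCOVA is
`longevity ~ treatment + diameter + temperature + soil moisture` with
random intercepts for site and for batch nested in site, fitted by REML
through statsmodels MixedLM.  If the nested fit is singular the model
downgrades to a site-only intercept with a logged warning recorded in
the output metadata.  Fixed-effect inference uses the normal
approximation (z); Satterthwaite denominator degrees of freedom are not
available through the delegated fitter, so the table reports z in the
statistic column.  Constant predictors (e.g. a single treatment level)
are dropped and listed in the metadata.

## Fitness

Fruit set is fruits over retrieved flowers per batch; batches with
nothing retrieved are excluded with a log entry.  The
autonomous-selfing contrast is a Pearson chi-square without continuity
correction on the 2×2 fruit-by-treatment table, reported with both
proportions.  Site effects use one-way ANOVA with Tukey HSD for fruit
set and ovule counts, and the rank-based site test for seeds per fruit.
Ovule counts made at the fruiting stage and from pickled flowers are
treated as one exchangeable column.

## The synthetic-data generator

The generator emulates the campaign's *structure*, with defaults fixed
at the emulated study's conditions:

* **Sites**: five, at 2341/2596/2736/2967/3151 m (810 m span).
* **Temperature**: one annual harmonic peaking mid-January (austral
  summer), annual mean 7 °C and amplitude 9 °C at the lowest site, a
  4.8 °C/km lapse, iid daily noise of 1.5 °C, and a fixed ±6 °C diurnal
  half-range around the mean (the campaign reports no diurnal model;
  the half-range is configurable).
* **Snow**: melt on 31 Aug at the lowest site, delayed 4.6 d per 100 m;
  a 5-day linear ramp that stays above the 10 % margin until the true
  melt date, so clean detection is exact; one common winter-onset date
  (8 May) giving 250 snow-free days at the lowest site.  Optional
  transient post-melt spikes default off and sit at 8 % cover, below
  the margin.
* **Flowering**: 50 plants per site; onset when GDD since melt (at a
  per-site *graded* truth threshold anchored at 5 °C on the lowest
  site) crosses a N(150, 40²) degree-day threshold; concave parabolic
  count trajectories over N(45, 10²)-day durations with Poisson(20)
  peaks; visits every 3–5 days.
* **Longevity**: 17/17/16/16/9 batches per site (75 total), six plants
  per treatment arm, five flowers per plant; potential life-span
  `4.5 − 0.132·T` days plus a 0.3-d plant effect and 0.6-d flower
  noise, floored at 1 d; pollinator arrival exponential with rate
  `0.07 · max(T − 10 °C, 0)` per day; actual life-span
  `min(PFL, arrival + 1 d)`; fruit on arrival before closure, 1.1 %
  autonomous selfing in the excluded arm.  The arrival rate constant
  was set so that open-pollination fruit set lands near the emulated
  study's whole-season value (≈ 44 %) at typical mid-season
  temperatures; the 10 °C activity threshold is a modelling choice for
  ectothermic alpine bees, not a published value.

Each flower's life-span and its ambient temperature are mutually
dependent (the life-span fixes the open-day window whose mean
temperature fixes the life-span), so generation solves that fixed point
directly; the covariate the analysis measures is then exactly the
generative one, and recovery tests are free of measurement-error
attenuation by construction.

All generators draw from per-stream substreams of one global seed, so
identical seeds give byte-identical tables and adding a generator does
not perturb the others.

### What the generator does not emulate — and a structural caveat

No spatial pollinator foraging, no floral-morph genetics, no multi-year
dynamics, no cloud gaps in the snow series by default, no census gaps.
Passing recovery tests on this world shows the estimators are correct
under the stated generative model; it does not validate the model
against real field data.

Two model-level consequences are worth stating plainly.  First, because
actual longevity is the *minimum* of potential longevity and a
temperature-dependent arrival time, the marginal temperature slope of
AFL is steeper than the configured PFL slope (≈ −0.20 vs −0.132 d/°C at
default settings), and a pooled two-arm model with an additive treatment
term estimates a blend (≈ −0.17).  Parameter-recovery checks therefore
target the pollinator-excluded arm, where the configured linear law is
the data-generating process; the pooled estimate is still computed and
reported by the pipeline.  Second, graded onset thresholds need not
delay flowering calendar dates at higher sites: later-melting sites
accumulate thermal time nearer the summer peak against a lower base, and
at the default settings their onset dates compress to within a day or
two of the lowest site's.  The invariant property is equality of onset
*thermal sums*, not calendar ordering.

## Numerical conventions

Rounding of published-style summaries (months, days per 100 m) is
half-up to one decimal.  Grid snapping uses nearest-interval rounding.
Quadratic season roots are rounded to whole days.  GDD at the boundary
(daily mean equal to the base) is exactly zero.  Monotone integer
rounding (`rint`) keeps generated AFL ≤ PFL after discretisation.
Degenerate inputs — constant regressors or responses, empty treatment
arms, zero-margin contingency tables, inverted date pairs — raise
errors or return the documented limiting values rather than NaNs.

## Problem sizes

Default analyses run on one season of daily data for five sites,
50 plants per site and 75 flower batches (4 500 flowers); the full test
suite and the acceptance script each complete in well under a minute of
CPU on this scale.
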