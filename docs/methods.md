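# Methods

This note documents the models, conventions and design choices behind
`urbanheat`, in the order the pipeline runs.

## Synthetic ensemble

The generator emulates the statistical structure of downscaled daily
climate projections for a set of cities, an observation-like reference
series, and SSP-style city population totals. It exists so every stage of
the analysis is exercisable and testable offline; it does not claim
meteorological realism.

**Daily maximum temperature** for city *c* on day *d* of year *y* is

    T(d) = mu_c + A_c * cos(2*pi*(doy - peak)/365)
           + rate_s * (y - 2015)/10 + episode(d) + eps(d)

with `eps` a stationary AR(1) process (coefficient `phi`, marginal
standard deviation `sigma`, innovations scaled by `sigma*sqrt(1-phi^2)`,
100-day burn-in). Daily minimum is the maximum minus a diurnal offset
plus small independent noise, clipped so `tasmax >= tasmin` holds on
every day. All synthetic series use a 365-day no-leap calendar, matching
common climate-model calendars and removing leap-day branching.

Key defaults (degrees Celsius unless noted):

| parameter | default | rationale |
|---|---|---|
| cities x models | 10 x 5 | full pipeline runs in seconds |
| annual-mean range `mu_c` | 30 down to 14 | hot-to-cool gradient; city 0 hottest |
| seasonal half-amplitude `A_c` | 8–14 | mid-latitude annual cycle |
| AR(1) `phi` | 0.7 | multi-day persistence of daily anomalies |
| anomaly std `sigma` | 2.0 | typical synoptic variability |
| warming rate, moderate / high pathway | 0.25 / 0.50 per decade | lands near the ~2.7 / ~4.5 degC end-of-century levels the two pathways represent |
| model bias `b_m` | ±0.4·(m+1) | strictly ordered magnitudes, alternating sign |
| model noise | 0.5 · (1 + 0.1·m) | weaker models are also noisier |
| observation noise | 0.3 | reference closely tracks truth |
| heat domes | 1.5/season, 3–7 days, +4.0 | additive block shifts in May–September so multi-day runs occur |
| diurnal offset | 10.0 | tasmax − tasmin |

Warming accrues from 2015 (the year scenario pathways diverge), so
far-future windows are genuinely warmer than near-future ones and an
injected rate is recoverable from any window's annual means. The
historical scenario and the reference carry no trend.

Model series are the shared truth plus an additive bias and white noise;
the reference is truth plus small observation noise. Populations are
`base_city * multiplier(SSP, year) * lognormal jitter` with 2020
SSP-independent; the SSP3 far-future multiplier (0.88) exercises
population decline. All randomness flows from numpy's PCG64 seeded by a
`SeedSequence` over `(rng_seed, stream tags)`, so a fixed seed gives
bit-identical output; the generator algorithm is named here precisely so
fixtures can be reproduced elsewhere.

What the generator does **not** emulate: humidity, spatial correlation
between cities, model drift or variance trends, calendar irregularities,
gridded population. Passing tests therefore demonstrate correctness of
the *pipeline mechanics* under the assumed statistical structure, not
skill on real projections.

## Detection and indices

Thresholds pool all baseline-window days into one empirical quantile per
city and diurnal variable (linear-interpolation / "type 7" convention).
Pooling, rather than day-of-year windows, matches a single fixed
threshold per city; thresholds are never recomputed for future windows.
Exceedance is strict (`>`): a day exactly at the threshold is not a
heatwave day. Events are the maximal runs of strict exceedance with
length ≥ 3 (configurable); detection runs on the continuous multi-year
series so an event straddling 31 December is one event.

Year attribution: HWN counts events by their start year; HWTD, HWMT and
HHT attribute each heatwave day to its own calendar year; HWLD is the
longest within-year consecutive stretch. No day is double-counted and no
event is split at detection time. In event-free years HWMT and HHT are
missing values, never zeros — averaging zeros would corrupt intensity
statistics. Period means therefore average intensity indices over event
years only and record the count of contributing years.

## Model ranking

Deviations are absolute differences of period means, per city and index
component (ten components when both diurnal datasets are supplied: five
indices × day/night). Per component, models are ranked ascending by
deviation with ties receiving the average of the tied positions; a
missing component (event-free intensity on either side) is dropped from
that model's average with the divisor reduced. Averaged ranks convert to
an ordinal 1..n ordering, ties broken by model id, so points stay
integers and the 1450/725 arithmetic is exact. Selection is strict:
a model must *surpass* the half-maximum bar, not meet it. R² for series
validation is the squared Pearson correlation with pairwise deletion of
missing days; zero variance yields an undefined (NaN) result, never 0.

## Percentage changes and trends

Each future year is compared to the same model's own baseline-period
mean — never the reference's — as `(future − baseline)/baseline × 100`.
Intensity changes are computed on Celsius values; the percentage is not
unit-invariant, so the convention is fixed and asserted in tests.
Aggregation order: city values average (unweighted) into the five
regions first, then the multi-model median and 25th–75th percentile
spread are taken across models, per year. Trends are ordinary
least-squares fits of the regional *median* series on year, fitted
within each future window separately; a constant series gets slope 0
with r² flagged undefined.

## Composite heatwave index

Normalization follows the displayed min-max equations: across cities,
within one period × dataset × model slice. (Looser phrasing would pool
all models and periods into one normalization; the per-slice equations
are implemented, and this choice is the authoritative one here.)
Degenerate all-equal metrics map every city to 0 — a metric with no
spread should raise no city's hazard — and missing intensity components
impute 0 after normalization, the least possible burden for an
event-free city. The ensemble CHI is the per-city median of the
per-model *combined* index across selected models, re-normalized across
cities, so the ensemble product again attains exactly 1 and 0 at the
extremes; re-applying the final normalization after the median mirrors
the definition of the final step as a cross-city rescaling of combined
values.

## Risk overlay

Population quantities min-max normalize within one (SSP, horizon) slice,
the comparison a single heatmap panel makes. Signed percentage changes
normalize like any other values, so the most-declining city maps to 0 on
the same scale as growing cities. Risk products are plain multiplications
of unit-interval factors, hence bounded by each factor. The pairing of
climate scenario with SSP population pathway is an argument, never
hard-coded; the pipeline computes all combinations.

## Coastal classification

Distance is great-circle from the city point to the nearest point of any
coastline segment: spherical cross-track distance with endpoint clamping
(R = 6371 km). The 10-km buffer is boundary-inclusive. Segments are
geodesic chords; a zonal coastline must be densified (the synthetic south
coast uses 1° steps) because a long east-west chord bulges tens of km
poleward of the parallel it nominally follows. Coast groups come from
the city table; they are descriptive labels, not derived geometry. Box
summaries are Tukey: quartiles by linear interpolation, whiskers at the
most extreme observations within 1.5·IQR of the box edges, outliers
beyond.

## Numerical conventions and degenerate inputs

- One quantile convention (linear interpolation between order
  statistics) everywhere: thresholds, ensemble IQR, box statistics.
- Temperatures are Celsius internally; Kelvin only at NetCDF ingest.
- Two calendars (standard, no-leap); a series declares its calendar and
  CSV ingest infers it from gap-freeness (a span containing a skipped
  Feb 29 is only gap-free as no-leap).
- Missing values are allowed only in the reference series and handled by
  pairwise deletion (R²), reduced divisors (rank averaging, regional
  means) or explicit missing propagation (deviations).
- Zero baselines make percentage change undefined (NaN, flagged), common
  for HWN in cool cities; zero variance flags r² undefined.
- Ties break deterministically by identifier (model id, city id)
  wherever an ordinal order is required.

## Problem sizes

The default pipeline configuration is 10 cities × 5 models × three
30-year windows × two emission scenarios, chosen so a full run completes
in well under a minute; statistical tests use 20-replicate
(bias-ordering) and 50-seed (trend recovery) simulations at the same
series lengths. These sizes are the package's test-bed conditions; all
statistical tolerances quoted in the tests were set from the generative
parameters, not fitted to outcomes.

## Known limitations

- The ranking scheme's count-index deviations carry little signal for a
  purely additive model bias (the bias cancels against the model's own
  threshold); bias-order recovery rests mainly on the intensity indices
  and on noise ordering, and full-order recovery of five models is
  probabilistic (~80% under the default ensemble).
- The CHI is a relative index: values are comparable only within the
  normalization slice that produced them.
- Point-to-polyline coastal distance ignores city polygon footprints.
- No humidity-based metrics (heat index, wet-bulb temperature); the
  indices are temperature-only by design.
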