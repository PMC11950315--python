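"""Synthetic multi-city, multi-model daily temperature and population generator.

The generator emulates the statistical structure the downstream analysis
assumes: a seasonal cycle with AR(1) day-to-day autocorrelation, per-scenario
linear warming, per-model additive biases around a shared "truth", occasional
multi-day heat-dome episodes in the warm season, and SSP-style population
multipliers.  It stands in for downscaled CMIP6 daily projections, an
ERA5-like reference, and gridded SSP population totals, so that every
pipeline stage is testable without any download.

All randomness flows from numpy's PCG64 generator seeded with a
``SeedSequence`` built from ``(rng_seed, stream tags)``; a fixed seed yields
bit-identical output across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .io import (
    CityRecord, DailySeries, PeriodWindow, REFERENCE_ID, logger,
)

_SCENARIO_CODE = {"historical": 0, "ssp245": 1, "ssp585": 2, "reference": 3}

#: Year from which scenario warming accrues (CMIP6 scenarios begin in 2015).
TREND_EPOCH = 2015

#: Warm-season day-of-year span (May-September) in which heat domes occur.
_SEASON = (121, 273)

#: Default per-SSP population multipliers relative to 2020 (2050, 2090).
DEFAULT_SSP_MULTIPLIERS = {
    "SSP1": {2050: 1.12, 2090: 1.18},
    "SSP2": {2050: 1.18, 2090: 1.32},
    "SSP3": {2050: 0.97, 2090: 0.88},
    "SSP4": {2050: 1.08, 2090: 1.12},
    "SSP5": {2050: 1.28, 2090: 1.55},
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic ensemble.

    Defaults are sized to 10 cities x 5 models x 30-year windows so the full
    pipeline runs in seconds while exercising every downstream stage.
    Warming rates are degrees Celsius per decade, accrued from 2015
    (0.25 for the moderate and 0.50 for the high-emission pathway, chosen to
    land near the ~2.7 degC and ~4.5 degC end-of-century global warming
    levels the two pathways represent).
    """

    n_cities: int = 10
    n_models: int = 5
    mean_low: float = 14.0        # coolest-city annual mean, degC
    mean_high: float = 30.0       # hottest-city annual mean, degC
    amp_low: float = 8.0          # seasonal half-amplitude range, degC
    amp_high: float = 14.0
    peak_doy: int = 200           # day-of-year of seasonal maximum
    phi: float = 0.7              # AR(1) coefficient of daily anomalies
    sigma: float = 2.0            # stationary std of daily anomalies, degC
    warming_rates: dict = field(default_factory=lambda: {
        "historical": 0.0, "reference": 0.0, "ssp245": 0.25, "ssp585": 0.50})
    model_bias_scale: float = 0.4   # |bias| of model m is scale*(m+1), degC
    model_noise_sd: float = 0.5     # white noise added per model series, degC
    model_noise_inflation_step: float = 0.1
    obs_noise_sd: float = 0.3       # observation noise of the reference, degC
    episode_rate: float = 1.5       # heat-dome episodes per warm season
    episode_len_min: int = 3
    episode_len_max: int = 7
    episode_amp: float = 4.0        # uniform additive shift over an episode
    diurnal_offset: float = 10.0    # tasmax - tasmin, degC
    diurnal_noise_sd: float = 0.5
    pop_base_max: float = 6.0e6     # largest city's 2020 population
    pop_decay: float = 0.85         # geometric decay of base population
    pop_jitter_sd: float = 0.05     # lognormal sigma on future populations
    ssp_multipliers: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_SSP_MULTIPLIERS.items()})
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.phi < 1.0):
            raise ValueError(f"AR(1) coefficient must be in [0,1), got {self.phi}"
                             " (phi >= 1 is non-stationary)")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.episode_len_min < 1 or self.episode_len_max < self.episode_len_min:
            raise ValueError("episode length bounds must satisfy 1 <= min <= max")

    # per-city climatology -------------------------------------------------
    def city_mean(self, i: int) -> float:
        if self.n_cities == 1:
            return self.mean_high
        # hottest city first, so city 0 is the most heatwave-prone
        return self.mean_high - (self.mean_high - self.mean_low) * i / (
            self.n_cities - 1)

    def city_amplitude(self, i: int) -> float:
        if self.n_cities == 1:
            return self.amp_low
        return self.amp_low + (self.amp_high - self.amp_low) * i / (
            self.n_cities - 1)

    def model_bias(self, m: int) -> float:
        return self.model_bias_scale * (m + 1) * (1 if m % 2 == 0 else -1)

    def model_inflation(self, m: int) -> float:
        return 1.0 + self.model_noise_inflation_step * m

    def city_ids(self) -> list[str]:
        return [f"city{i:02d}" for i in range(self.n_cities)]

    def model_ids(self) -> list[str]:
        return [f"model{m:02d}" for m in range(self.n_models)]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _rng(spec: SyntheticSpec, *tags: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.rng_seed) % (2 ** 31), *[int(t) for t in tags]]))


def _ar1(rng: np.random.Generator, n: int, phi: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) anomalies with marginal std ``sigma``."""
    if sigma == 0.0:
        return np.zeros(n)
    burn = 100
    innov = rng.normal(0.0, sigma * np.sqrt(1.0 - phi ** 2), size=n + burn)
    x = signal.lfilter([1.0], [1.0, -phi], innov)
    return x[burn:]


def _episodes(rng: np.random.Generator, years: np.ndarray, doy: np.ndarray,
              spec: SyntheticSpec) -> np.ndarray:
    """Additive heat-dome block shifts in the warm season only."""
    bump = np.zeros(len(years))
    if spec.episode_rate <= 0 or spec.episode_amp == 0:
        return bump
    lo, hi = _SEASON
    for yr in np.unique(years):
        n_ep = rng.poisson(spec.episode_rate)
        for _ in range(n_ep):
            start_doy = int(rng.integers(lo, hi + 1))
            length = int(rng.integers(spec.episode_len_min,
                                      spec.episode_len_max + 1))
            sel = (years == yr) & (doy >= start_doy) & (doy < start_doy + length)
            bump[sel] += spec.episode_amp
    return bump


def generate_truth(spec: SyntheticSpec, city: int, scenario: str,
                   window: PeriodWindow) -> tuple[DailySeries, DailySeries]:
    """Generate the shared 'truth' (tasmax, tasmin) pair for one city.

    The daily maximum follows ``mu_c + A_c*cos(2*pi*(doy - peak)/365) +
    rate*(year - 2015)/10 + episode(d) + eps(d)`` with ``eps`` an AR(1)
    process; the minimum is the maximum minus the diurnal offset plus small
    independent noise, clipped so tasmax >= tasmin on every day.
    """
    if scenario not in _SCENARIO_CODE:
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = _rng(spec, 1, city, _SCENARIO_CODE[scenario],
               window.start_year, window.end_year)
    n = 365 * window.n_years
    years = np.repeat(np.arange(window.start_year, window.end_year + 1), n // window.n_years)
    doy = np.tile(np.arange(1, 366), window.n_years)
    rate = spec.warming_rates.get(scenario, 0.0)
    seasonal = spec.city_mean(city) + spec.city_amplitude(city) * np.cos(
        2.0 * np.pi * (doy - spec.peak_doy) / 365.0)
    trend = rate * (years - TREND_EPOCH) / 10.0 if rate else 0.0
    eps = _ar1(rng, n, spec.phi, spec.sigma)
    bump = _episodes(rng, years, doy, spec)
    tasmax_vals = seasonal + trend + bump + eps
    dnoise = (rng.normal(0.0, spec.diurnal_noise_sd, size=n)
              if spec.diurnal_noise_sd > 0 else np.zeros(n))
    tasmin_vals = np.minimum(tasmax_vals,
                             tasmax_vals - spec.diurnal_offset + dnoise)
    cid = spec.city_ids()[city]
    mk = lambda var, vals: DailySeries.from_window(
        cid, "truth", scenario, var, window.start_year, window.end_year,
        vals, "noleap")
    return mk("tasmax", tasmax_vals), mk("tasmin", tasmin_vals)


def generate_model_ensemble(spec: SyntheticSpec, scenario: str,
                            window: PeriodWindow) -> list[DailySeries]:
    """All model series plus one reference series, for every city and variable.

    Each model is the shared truth plus its additive bias and inflated white
    noise; the reference is the truth plus small observation noise.  The
    reference carries the reserved model token and scenario ``reference``.
    """
    out: list[DailySeries] = []
    for city in range(spec.n_cities):
        tmax, tmin = generate_truth(spec, city, scenario, window)
        for m in range(spec.n_models):
            rng = _rng(spec, 2, city, _SCENARIO_CODE[scenario],
                       window.start_year, m)
            bias = spec.model_bias(m)
            sd = spec.model_noise_sd * spec.model_inflation(m)
            for truth in (tmax, tmin):
                noise = rng.normal(0.0, sd, size=len(truth)) if sd > 0 else 0.0
                out.append(DailySeries.from_window(
                    truth.city_id, spec.model_ids()[m], scenario,
                    truth.diurnal_var, window.start_year, window.end_year,
                    truth.values + bias + noise, "noleap"))
        rng = _rng(spec, 3, city, _SCENARIO_CODE[scenario], window.start_year)
        for truth in (tmax, tmin):
            noise = (rng.normal(0.0, spec.obs_noise_sd, size=len(truth))
                     if spec.obs_noise_sd > 0 else 0.0)
            out.append(DailySeries.from_window(
                truth.city_id, REFERENCE_ID, "reference", truth.diurnal_var,
                window.start_year, window.end_year,
                truth.values + noise, "noleap"))
    # enforce the tasmax >= tasmin contract after additive noise
    by_key = {(s.city_id, s.model_id, s.diurnal_var): s for s in out}
    for (cid, mid, var), s in by_key.items():
        if var == "tasmin":
            smax = by_key[(cid, mid, "tasmax")]
            np.minimum(s.values, smax.values, out=s.values)
    return out


def generate_cities(spec: SyntheticSpec) -> list[CityRecord]:
    """Deterministic city table with three coastal cities and inland rest.

    City 0 sits ~4 km east of the synthetic west coastline, city 1 ~4 km
    north of the south coastline and city 2 ~3 km west of the east-north
    coastline; all remaining cities are inland.  Regions cycle through the
    five-region set.
    """
    regions = ["West", "Southwest", "Midwest", "Southeast", "Northeast"]
    placements = {
        0: (-123.95, 40.0, "WestCoast"),
        1: (-95.0, 29.04, "SouthCoast"),
        2: (-74.04, 40.5, "EastNorthCoast"),
    }
    cities = []
    for i, cid in enumerate(spec.city_ids()):
        if i in placements:
            lon, lat, group = placements[i]
        else:
            lon = -115.0 + 5.0 * i
            lat = 33.0 + (i % 4) * 2.0
            group = "Inland"
        cities.append(CityRecord(cid, f"Synthetic City {i}",
                                 regions[i % 5], lon, lat, group))
    return cities


def synthetic_coastline() -> dict:
    """GeoJSON MultiLineString: west meridian, south parallel, east meridian.

    The zonal (east-west) south coast is densified at 1-degree steps so the
    polyline tracks the latitude parallel: a single 18-degree geodesic chord
    would bulge tens of kilometres poleward of it.
    """
    south = [[float(lon), 29.0] for lon in range(-100, -81)]
    return {
        "type": "MultiLineString",
        "coordinates": [
            [[-124.0, 30.0], [-124.0, 48.0]],
            south,
            [[-74.0, 35.0], [-74.0, 45.0]],
        ],
    }


def generate_population(spec: SyntheticSpec) -> pd.DataFrame:
    """City population totals for 2020/2050/2090 under the five SSPs.

    ``pop(city, year, ssp) = base(city) * multiplier(ssp, year) * jitter``
    with deterministic lognormal jitter (disabled when ``pop_jitter_sd`` is
    0).  2020 populations are SSP-independent by construction.  SSP3
    multipliers below 1 model population decline.
    """
    bases = {cid: spec.pop_base_max * spec.pop_decay ** i
             for i, cid in enumerate(spec.city_ids())}
    if any(b <= 0 for b in bases.values()):
        raise ValueError("base populations must be positive")
    rng = _rng(spec, 4)
    rows = []
    for ssp, mults in sorted(spec.ssp_multipliers.items()):
        for i, (cid, base) in enumerate(bases.items()):
            rows.append((cid, 2020, ssp, base))
            for year in sorted(mults):
                jit = (float(np.exp(rng.normal(0.0, spec.pop_jitter_sd)))
                       if spec.pop_jitter_sd > 0 else 1.0)
                rows.append((cid, int(year), ssp, base * mults[year] * jit))
    df = pd.DataFrame(rows, columns=["city_id", "year", "ssp", "population"])
    logger.info("synthetic population: %d rows, %d cities, %d SSPs",
                len(df), spec.n_cities, len(spec.ssp_multipliers))
    return df
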