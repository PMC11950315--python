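"""Percentage changes, regional aggregation, ensemble spread and trends.

Each future year's index value is compared to the same model's own
baseline-period mean (never the reference dataset's), as
``(future - baseline)/baseline * 100``.  City values are averaged into the
five regions first, then the multi-model median and interquartile range are
taken across models, and a least-squares trend is fitted to the median
series per region.  Intensity (HWMT/HHT) changes are computed on Celsius
values; the percentage is not unit-invariant, so the Celsius convention is
fixed throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import INDEX_NAMES, PeriodWindow, REGIONS, logger


@dataclass(frozen=True)
class TrendFit:
    """OLS slope (units/yr) and squared correlation of value on year."""

    slope: float
    r2: float
    n_years: int


@dataclass(frozen=True)
class RegionalMean:
    mean: float
    n: int


def percentage_change(future_value: float, baseline_mean: float) -> float:
    """((future - baseline) / baseline) * 100; NaN when the baseline is 0."""
    if baseline_mean == 0:
        logger.warning("percentage_change undefined: baseline mean is 0")
        return float("nan")
    return (future_value - baseline_mean) / baseline_mean * 100.0


def regional_average(city_values: Mapping[str, float],
                     region_map: Mapping[str, str]) -> dict[str, RegionalMean]:
    """Unweighted mean of city values per region, excluding missing values.

    Every city must map to exactly one of the five regions; the count of
    contributing (non-missing) cities is recorded per region.
    """
    acc: dict[str, list[float]] = {}
    for city, value in city_values.items():
        if city not in region_map:
            raise ValueError(f"city {city!r} has no region assignment")
        region = region_map[city]
        if region not in REGIONS:
            raise ValueError(f"city {city!r} mapped to unknown region {region!r}")
        acc.setdefault(region, [])
        if value is not None and np.isfinite(value):
            acc[region].append(float(value))
    return {
        region: RegionalMean(float(np.mean(vals)) if vals else float("nan"),
                             len(vals))
        for region, vals in acc.items()
    }


def ensemble_median_iqr(model_values) -> tuple[float, float, float]:
    """Multi-model median with 25th/75th percentiles (linear interpolation)."""
    vals = np.asarray(list(model_values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ensemble_median_iqr needs at least one model value")
    q25, med, q75 = np.percentile(vals, [25, 50, 75], method="linear")
    return float(med), float(q25), float(q75)


def linear_trend(years, values) -> TrendFit:
    """Least-squares slope and r-squared of value on year."""
    years = np.asarray(list(years), dtype=float)
    values = np.asarray(list(values), dtype=float)
    if years.size != values.size:
        raise ValueError("years and values must have equal length")
    if np.unique(years).size < 3:
        raise ValueError("linear_trend needs >= 3 distinct years")
    if np.ptp(values) == 0:
        logger.warning("linear_trend: constant values; r2 undefined")
        return TrendFit(0.0, float("nan"), int(years.size))
    fit = stats.linregress(years, values)
    return TrendFit(float(fit.slope), float(fit.rvalue ** 2), int(years.size))


def annual_percentage_changes(records: pd.DataFrame,
                              baseline_window: PeriodWindow,
                              index_names=INDEX_NAMES) -> pd.DataFrame:
    """Per-year percentage change of each index vs the model's own baseline.

    ``records`` is the annual index table (all scenarios).  Baseline means
    are taken from each (city, model, diurnal_var)'s ``historical`` rows in
    the baseline window; intensity baselines average event years only.
    Future rows are every non-historical scenario-year.  Output columns:
    city_id, model_id, scenario, diurnal_var, index_name, year, pct_change.
    """
    base = records[(records["scenario"] == "historical")
                   & (records["year"] >= baseline_window.start_year)
                   & (records["year"] <= baseline_window.end_year)]
    if base.empty:
        raise ValueError("no historical baseline rows in records")
    keys = ["city_id", "model_id", "diurnal_var"]
    base_means = base.groupby(keys)[list(index_names)].mean()  # NaN-skipping
    fut = records[~records["scenario"].isin(["historical", "reference"])]
    out = []
    for key, grp in fut.groupby(keys, sort=True):
        if key not in base_means.index:
            raise ValueError(f"no baseline mean for {key}")
        bm = base_means.loc[key]
        for row in grp.itertuples():
            for name in index_names:
                out.append({
                    "city_id": key[0], "model_id": key[1],
                    "scenario": row.scenario, "diurnal_var": key[2],
                    "index_name": name, "year": int(row.year),
                    "pct_change": percentage_change(
                        getattr(row, name), float(bm[name])),
                })
    return pd.DataFrame(out)


def regional_ensemble_series(pct_changes: pd.DataFrame,
                             region_map: Mapping[str, str]) -> pd.DataFrame:
    """Region x scenario x variable x index x year ensemble summaries.

    Aggregation order: city -> region average (per model, per year), then
    multi-model median and IQR across models.  Output columns: region,
    scenario, diurnal_var, index_name, year, median, q25, q75, n_models.
    """
    rows = []
    keys = ["scenario", "diurnal_var", "index_name", "year"]
    if "period" in pct_changes.columns:
        keys = ["period"] + keys
    for key, grp in pct_changes.groupby(keys, sort=True):
        per_model: dict[str, float] = {}
        for mid, mgrp in grp.groupby("model_id"):
            regs = regional_average(
                dict(zip(mgrp["city_id"], mgrp["pct_change"])), region_map)
            for region, rm in regs.items():
                per_model.setdefault(region, {})[mid] = rm.mean
        for region, models in per_model.items():
            vals = [v for v in models.values() if np.isfinite(v)]
            if not vals:
                continue
            med, q25, q75 = ensemble_median_iqr(vals)
            rows.append(dict(zip(keys, key)) | {
                "region": region, "median": med, "q25": q25, "q75": q75,
                "n_models": len(vals)})
    cols = (["region"] + [k for k in keys if k != "year"] + ["year",
            "median", "q25", "q75", "n_models"])
    sort_cols = [c for c in cols if c not in ("median", "q25", "q75",
                                              "n_models")]
    return pd.DataFrame(rows)[cols].sort_values(sort_cols).reset_index(drop=True)


def regional_trends(ensemble_series: pd.DataFrame) -> pd.DataFrame:
    """Trend of the regional median series per region/scenario/var/index.

    When a ``period`` column is present (near vs far future), trends are
    fitted within each period window separately.
    """
    rows = []
    keys = ["region", "scenario", "diurnal_var", "index_name"]
    if "period" in ensemble_series.columns:
        keys = ["period"] + keys
    for key, grp in ensemble_series.groupby(keys, sort=True):
        grp = grp.sort_values("year")
        fit = linear_trend(grp["year"], grp["median"])
        rows.append(dict(zip(keys, key)) | {
            "slope": fit.slope, "r2": fit.r2, "n_years": fit.n_years})
    return pd.DataFrame(rows)
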