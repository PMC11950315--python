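"""Percentile thresholds, heatwave event detection, and the five annual indices.

A heatwave is a run of at least ``min_event_days`` consecutive days whose
temperature is strictly above the city's fixed baseline-period percentile
threshold (95th by default).  Thresholds are computed once on the baseline
window, pooling all its days, and reused unchanged for future windows so
that future indices are measured against historical norms.

The five annual metrics:

=====  =============================================================
HWN    annual count of events (attributed to the event's start year)
HWTD   number of heatwave days falling in the year
HWLD   longest within-year stretch of consecutive heatwave days
HWMT   mean temperature over the year's heatwave days (missing if none)
HHT    hottest single heatwave-day temperature in the year (missing if none)
=====  =============================================================

Detection runs on the continuous multi-year series, so an event straddling
31 December is one event; its days are attributed to their own calendar
years and no day is double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DailySeries, PeriodWindow, logger


@dataclass(frozen=True)
class Threshold:
    """A fixed percentile threshold for one city and diurnal variable."""

    city_id: str
    diurnal_var: str
    q: float
    value: float
    window: PeriodWindow


@dataclass
class HeatwaveEvent:
    """A maximal run of strict threshold exceedances of qualifying length."""

    city_id: str
    model_id: str
    scenario: str
    diurnal_var: str
    start_date: str
    end_date: str
    duration: int
    temps: np.ndarray
    start_index: int  # position of the first event day in the source series

    @property
    def start_year(self) -> int:
        return int(self.start_date[:4])


def baseline_threshold(series: DailySeries, window: PeriodWindow,
                       q: float) -> Threshold:
    """Empirical quantile of all baseline-window days, pooled.

    Uses the linear-interpolation ("type 7") quantile convention; the value
    is order-invariant in the input days.  Missing values (reference series)
    are ignored.
    """
    if not (0.0 < q < 1.0):
        raise ValueError(f"quantile q must be in (0,1), got {q}")
    covered = set(series.covered_years())
    missing_years = [y for y in window.years if y not in covered]
    if missing_years:
        raise ValueError(
            f"series ({series.city_id}, {series.model_id}, {series.diurnal_var}) "
            f"does not cover window years {missing_years}"
        )
    sub = series.subset_window(window)
    vals = sub.values[np.isfinite(sub.values)]
    value = float(np.quantile(vals, q, method="linear"))
    return Threshold(series.city_id, series.diurnal_var, q, value, window)


def detect_events(series: DailySeries, threshold: Threshold,
                  min_event_days: int = 3) -> list[HeatwaveEvent]:
    """Maximal runs of strict exceedance with length >= ``min_event_days``.

    Events are returned in chronological order and never overlap; a day
    exactly equal to the threshold does not exceed it.
    """
    if threshold.city_id != series.city_id:
        raise ValueError(
            f"threshold city {threshold.city_id!r} does not match series "
            f"city {series.city_id!r}")
    if threshold.diurnal_var != series.diurnal_var:
        raise ValueError(
            f"threshold variable {threshold.diurnal_var!r} does not match "
            f"series variable {series.diurnal_var!r}")
    if min_event_days < 1:
        raise ValueError("min_event_days must be >= 1")
    hot = series.values > threshold.value  # NaN compares False
    if not hot.any():
        return []
    # run boundaries of the boolean mask
    edges = np.diff(np.concatenate(([0], hot.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)  # exclusive
    dates = None
    events = []
    for s, e in zip(starts, ends):
        if e - s < min_event_days:
            continue
        if dates is None:
            dates = series.dates_iso()
        events.append(HeatwaveEvent(
            series.city_id, series.model_id, series.scenario,
            series.diurnal_var, dates[s], dates[e - 1], int(e - s),
            series.values[s:e].copy(), int(s)))
    return events


def heatwave_day_mask(series: DailySeries,
                      events: list[HeatwaveEvent]) -> np.ndarray:
    """Boolean mask over the series marking every heatwave day."""
    mask = np.zeros(len(series), dtype=bool)
    for ev in events:
        mask[ev.start_index:ev.start_index + ev.duration] = True
    return mask


def annual_indices(events: list[HeatwaveEvent], series: DailySeries,
                   year: int) -> dict:
    """The five Table-style metrics for one calendar year.

    HWN counts events starting in the year; HWTD/HWMT/HHT are computed over
    heatwave days whose own date falls in the year; HWLD is the longest
    within-year consecutive stretch of heatwave days.  HWMT and HHT are NaN
    (missing) in event-free years — never zero.
    """
    if year not in set(int(y) for y in np.unique(series.year)):
        raise ValueError(f"year {year} outside series coverage")
    mask = heatwave_day_mask(series, events)
    in_year = series.year_mask(year)
    ymask = mask & in_year
    hwtd = int(ymask.sum())
    hwn = sum(1 for ev in events if ev.start_year == year)
    if hwtd:
        ym = ymask[in_year]
        edges = np.diff(np.concatenate(([0], ym.view(np.int8), [0])))
        runs = np.flatnonzero(edges == -1) - np.flatnonzero(edges == 1)
        hwld = int(runs.max())
        temps = series.values[ymask]
        hwmt = float(np.mean(temps))
        hht = float(np.max(temps))
    else:
        hwld, hwmt, hht = 0, np.nan, np.nan
    return {"city_id": series.city_id, "model_id": series.model_id,
            "scenario": series.scenario, "diurnal_var": series.diurnal_var,
            "year": year, "hwn": hwn, "hwtd": hwtd, "hwld": hwld,
            "hwmt": hwmt, "hht": hht}


def annual_indices_table(series: DailySeries, threshold: Threshold,
                         min_event_days: int = 3,
                         years=None) -> pd.DataFrame:
    """Annual index records for every (fully covered) year of the series."""
    events = detect_events(series, threshold, min_event_days)
    if years is None:
        years = series.covered_years()
    rows = [annual_indices(events, series, y) for y in years]
    return pd.DataFrame(rows)


def period_mean_indices(records: pd.DataFrame,
                        window: PeriodWindow) -> pd.DataFrame:
    """Per city-model-scenario-variable mean of each index over a window.

    Count indices (HWN/HWTD/HWLD) average over every window year; intensity
    indices (HWMT/HHT) average over years with events only, and the number
    of contributing years is recorded as ``n_intensity_years`` (a mean of
    NaN where no year had events).
    """
    if records.empty:
        raise ValueError("empty index record set")
    sub = records[(records["year"] >= window.start_year)
                  & (records["year"] <= window.end_year)]
    keys = ["city_id", "model_id", "scenario", "diurnal_var"]
    out = []
    for key, grp in sub.groupby(keys, sort=True):
        have = sorted(grp["year"].unique())
        missing = [y for y in window.years if y not in have]
        if missing:
            raise ValueError(
                f"records for {key} missing window years {missing}")
        row = dict(zip(keys, key))
        for name in ("hwn", "hwtd", "hwld"):
            row[name] = float(grp[name].mean())
        present = grp["hwmt"].notna()
        row["n_intensity_years"] = int(present.sum())
        row["hwmt"] = float(grp.loc[present, "hwmt"].mean()) if present.any() else np.nan
        row["hht"] = float(grp.loc[present, "hht"].mean()) if present.any() else np.nan
        out.append(row)
    logger.debug("period_mean_indices: %d groups over %s", len(out), window.label)
    return pd.DataFrame(out)
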