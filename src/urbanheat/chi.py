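"""The composite heatwave index (CHI).

For one period, scenario and model, each of the five period-mean metrics is
min-max normalized across cities separately for the daytime (tasmax) and
nighttime (tasmin) datasets; the five normalized components are averaged
into a daytime composite C_d and a nighttime composite C_n; the combined
index is (C_d + C_n)/2; and a final min-max normalization across cities
rescales the combined index so the most heatwave-burdened city scores
exactly 1 and the least exactly 0.

Normalization spans the cities of one period x dataset x model slice (the
displayed normalization equations), not all models and periods pooled.  An
event-free city's missing intensity components are imputed as 0 after
normalization — the least possible intensity burden.  The ensemble CHI is
the per-city median of the per-model combined index across the selected
models, re-normalized across cities.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import INDEX_NAMES, logger


def minmax_normalize(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """(x - min)/(max - min) across cities; all-equal input maps to all 0.

    The degenerate rule (no spread -> hazard floor 0 for every city) is
    deliberate: a metric with no spread should not raise any city's hazard.
    Missing entries stay missing.
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 2:
        raise ValueError("min-max normalization needs >= 2 cities")
    lo, hi = s.min(skipna=True), s.max(skipna=True)
    if not np.isfinite(lo):  # all missing
        return s
    if hi == lo:
        out = s.copy()
        out[s.notna()] = 0.0
        return out
    return (s - lo) / (hi - lo)


def composite_per_dataset(components: Iterable[float]) -> float:
    """Arithmetic mean of the five normalized metrics for one dataset.

    A missing component (event-free city intensity) is imputed as 0 before
    averaging; all five missing is an error.
    """
    comp = np.asarray(list(components), dtype=float)
    if comp.size != 5:
        raise ValueError(f"expected exactly 5 components, got {comp.size}")
    if np.all(np.isnan(comp)):
        raise ValueError("all five components missing")
    finite = comp[np.isfinite(comp)]
    if np.any((finite < 0) | (finite > 1)):
        raise ValueError("components must be normalized to [0, 1]")
    return float(np.nan_to_num(comp, nan=0.0).mean())


def combine_day_night(c_day: float, c_night: float) -> float:
    """CHI = (C_day + C_night) / 2."""
    for name, v in (("c_day", c_day), ("c_night", c_night)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    return (c_day + c_night) / 2.0


def final_normalize(chi_combined: Mapping[str, float] | pd.Series) -> pd.Series:
    """Final min-max rescaling so CHI spans exactly [0, 1] across cities."""
    s = pd.Series(chi_combined, dtype=float)
    if len(s) < 2:
        raise ValueError("final normalization needs >= 2 cities")
    if s.max() == s.min():
        logger.warning("final_normalize: degenerate all-equal CHI; all set to 0")
    return minmax_normalize(s)


def compute_chi(period_means: pd.DataFrame, scenario: str, period: str,
                models: Iterable[str] | None = None,
                index_names=INDEX_NAMES) -> pd.DataFrame:
    """Per-model CHI table for one scenario and period.

    ``period_means`` holds per-(city, model, diurnal_var) period-mean
    indices (both tasmax and tasmin rows required).  Returns one row per
    city x model with c_day, c_night, chi_combined and chi_final.
    """
    df = period_means
    if models is not None:
        df = df[df["model_id"].isin(set(models))]
    if df.empty:
        raise ValueError("no period-mean rows for the requested models")
    rows = []
    for mid, grp in df.groupby("model_id", sort=True):
        comps = {}
        for var, label in (("tasmax", "day"), ("tasmin", "night")):
            sub = grp[grp["diurnal_var"] == var].set_index("city_id")
            if sub.empty:
                raise ValueError(f"model {mid!r} lacks {var} period means")
            norm = {name: minmax_normalize(sub[name]) for name in index_names}
            comps[label] = {
                city: composite_per_dataset(
                    [norm[name].get(city, np.nan) for name in index_names])
                for city in sub.index
            }
        cities = sorted(set(comps["day"]) & set(comps["night"]))
        combined = {c: combine_day_night(comps["day"][c], comps["night"][c])
                    for c in cities}
        final = final_normalize(pd.Series(combined))
        for c in cities:
            rows.append({
                "city_id": c, "model_id": mid, "scenario": scenario,
                "period": period, "c_day": comps["day"][c],
                "c_night": comps["night"][c], "chi_combined": combined[c],
                "chi_final": float(final[c])})
    return pd.DataFrame(rows)


def ensemble_chi(per_model_chi: pd.DataFrame,
                 selected_models: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-city ensemble CHI: median combined index, re-normalized.

    The median of the per-model combined index is taken across the selected
    models city by city, then the final min-max normalization is applied to
    the medians so the ensemble CHI again spans [0, 1].
    """
    df = per_model_chi
    if selected_models is not None:
        df = df[df["model_id"].isin(set(selected_models))]
    if df.empty:
        raise ValueError("no per-model CHI rows for the selected models")
    med = df.groupby("city_id")["chi_combined"].median()
    final = final_normalize(med)
    scenario = df["scenario"].iloc[0]
    period = df["period"].iloc[0]
    return pd.DataFrame({
        "city_id": med.index, "model_id": "ensemble", "scenario": scenario,
        "period": period, "c_day": np.nan, "c_night": np.nan,
        "chi_combined": med.values, "chi_final": final.values,
    }).reset_index(drop=True)
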