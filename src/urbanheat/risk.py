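"""Population overlay: the two heat-risk indices and hotspot tables.

Absolute risk is the product of the ensemble CHI (in [0,1]) and the city's
min-max-normalized absolute population; change-based risk multiplies CHI by
the normalized percentage population change with respect to 2020, so the
most-declining city maps to 0 on the same scale as growing cities.
Population quantities are normalized within one (SSP, horizon) slice — the
comparison a single heatmap panel makes — never across slices.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .chi import minmax_normalize
from .io import logger


def population_change(pop_future: float, pop_2020: float) -> float:
    """Percentage population change vs 2020; negative values permitted."""
    if pop_2020 <= 0:
        raise ValueError(f"2020 population must be positive, got {pop_2020}")
    return (pop_future - pop_2020) / pop_2020 * 100.0


def normalize_population(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """Min-max normalization of population quantities across cities.

    Applies within one (SSP, horizon) slice; signed percentage changes
    normalize like any other values.  All-equal input maps to 0 (flagged).
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 2:
        raise ValueError("population normalization needs >= 2 cities")
    if s.max() == s.min():
        logger.warning("normalize_population: degenerate all-equal values")
    return minmax_normalize(s)


def risk_products(chi_final: float, pop_norm: float,
                  pop_change_norm: float) -> tuple[float, float]:
    """(risk_abs, risk_change) = (CHI x pop_norm, CHI x pop_change_norm)."""
    for name, v in (("chi_final", chi_final), ("pop_norm", pop_norm),
                    ("pop_change_norm", pop_change_norm)):
        if not (np.isnan(v) or 0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    return chi_final * pop_norm, chi_final * pop_change_norm


def build_risk_table(chi_table: pd.DataFrame, population: pd.DataFrame,
                     ssp: str, horizon: int, scenario: str) -> pd.DataFrame:
    """One risk record per city for a (climate scenario, SSP, horizon) slice.

    ``chi_table`` is the ensemble CHI for the matching scenario and period
    (2050 pairs with the near-future window, 2090 with the far-future);
    ``population`` has columns city_id/year/ssp/population including 2020.
    """
    pop = population[population["ssp"] == ssp]
    p2020 = pop[pop["year"] == 2020].set_index("city_id")["population"]
    pfut = pop[pop["year"] == horizon].set_index("city_id")["population"]
    chi = chi_table.set_index("city_id")["chi_final"]
    cities = sorted(set(chi.index) & set(p2020.index) & set(pfut.index))
    if len(cities) < 2:
        raise ValueError("risk table needs >= 2 cities with CHI and population")
    pchg = pd.Series({c: population_change(pfut[c], p2020[c]) for c in cities})
    pop_norm = normalize_population(pfut[cities])
    pchg_norm = normalize_population(pchg)
    rows = []
    for c in cities:
        r_abs, r_chg = risk_products(float(chi[c]), float(pop_norm[c]),
                                     float(pchg_norm[c]))
        rows.append({
            "city_id": c, "scenario": scenario, "ssp": ssp,
            "horizon": horizon, "pop": float(pfut[c]),
            "pop_change_pct": float(pchg[c]), "pop_norm": float(pop_norm[c]),
            "pop_change_norm": float(pchg_norm[c]),
            "chi_final": float(chi[c]), "risk_abs": r_abs,
            "risk_change": r_chg})
    return pd.DataFrame(rows)


def hotspot_table(risk_records: pd.DataFrame, region_map: Mapping[str, str],
                  value_col: str = "risk_abs") -> pd.DataFrame:
    """Cities ordered by risk within region, with slice-wide ranks.

    All records must share one (scenario, SSP, horizon) slice; ties are
    broken by city_id ascending.
    """
    slices = risk_records[["scenario", "ssp", "horizon"]].drop_duplicates()
    if len(slices) != 1:
        raise ValueError(
            f"hotspot_table expects one (scenario, ssp, horizon) slice, "
            f"got {len(slices)}")
    df = risk_records.copy()
    unmapped = [c for c in df["city_id"] if c not in region_map]
    if unmapped:
        raise ValueError(f"cities without region assignment: {sorted(set(unmapped))}")
    df["region"] = df["city_id"].map(region_map)
    df = df.sort_values([value_col, "city_id"],
                        ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    df = df.sort_values(["region", value_col, "city_id"],
                        ascending=[True, False, True], kind="mergesort")
    return df.reset_index(drop=True)
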