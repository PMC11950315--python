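"""Core domain types, unit handling, file I/O, configuration and logging.

Everything downstream of this module works in degrees Celsius; Kelvin is
accepted only at ingest (CMIP6 NetCDF carries ``tasmax``/``tasmin`` in K).
Two daily calendars are supported: the proleptic standard calendar and the
365-day "no-leap" calendar used by many CMIP6 models.  A series declares
its calendar and is never mixed with the other.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("urbanheat")

#: Reserved model token for the observational reference dataset (ERA5-like).
REFERENCE_ID = "REF"

REGIONS = frozenset({"Northeast", "Southeast", "Midwest", "Southwest", "West"})
COAST_GROUPS = frozenset(
    {"WestCoast", "SouthCoast", "EastNorthCoast", "Inland", "Unclassified"}
)
SCENARIOS = frozenset({"historical", "ssp245", "ssp585", "reference"})
DIURNAL_VARS = frozenset({"tasmax", "tasmin"})
CALENDARS = frozenset({"standard", "noleap"})

#: The five annual heatwave metrics, in canonical order.
INDEX_NAMES = ("hwn", "hwtd", "hwld", "hwmt", "hht")


def configure_logging(level: str = "INFO") -> None:
    """Attach a structured stderr handler to the package logger."""
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


# ---------------------------------------------------------------------------
# Units
# ---------------------------------------------------------------------------

def to_celsius(values: Sequence[float] | np.ndarray, input_unit: str) -> np.ndarray:
    """Convert a temperature sequence to degrees Celsius.

    Parameters
    ----------
    values
        Temperature values in the declared unit.
    input_unit
        ``"K"`` (Kelvin, shifted by -273.15) or ``"C"`` (returned unchanged).
    """
    arr = np.asarray(values, dtype=float)
    if input_unit == "K":
        return arr - 273.15
    if input_unit == "C":
        return arr.copy()
    raise ValueError(f"unknown temperature unit {input_unit!r}; expected 'K' or 'C'")


# ---------------------------------------------------------------------------
# Calendars
# ---------------------------------------------------------------------------

_NOLEAP_MONTH_LEN = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_NOLEAP_MONTH_START = np.concatenate([[0], np.cumsum(_NOLEAP_MONTH_LEN)])  # doy offsets


def noleap_ordinal(year: np.ndarray, month: np.ndarray, day: np.ndarray) -> np.ndarray:
    """Days since year 0 under a fixed 365-day calendar (Feb 29 invalid)."""
    year = np.asarray(year, dtype=np.int64)
    month = np.asarray(month, dtype=np.int64)
    day = np.asarray(day, dtype=np.int64)
    if np.any((month == 2) & (day == 29)):
        bad = np.argmax((month == 2) & (day == 29))
        raise ValueError(
            f"Feb 29 ({int(year[bad])}-02-29) is not a valid no-leap calendar date"
        )
    return year * 365 + _NOLEAP_MONTH_START[month - 1] + (day - 1)


def calendar_days(start_year: int, end_year: int, calendar: str):
    """(year, month, day) arrays covering whole years [start_year, end_year]."""
    if calendar == "standard":
        idx = pd.date_range(f"{start_year}-01-01", f"{end_year}-12-31", freq="D")
        return idx.year.to_numpy(), idx.month.to_numpy(), idx.day.to_numpy()
    if calendar == "noleap":
        n_years = end_year - start_year + 1
        doy_month = np.repeat(np.arange(1, 13), _NOLEAP_MONTH_LEN)
        doy_day = np.concatenate([np.arange(1, n + 1) for n in _NOLEAP_MONTH_LEN])
        years = np.repeat(np.arange(start_year, end_year + 1), 365)
        return years, np.tile(doy_month, n_years), np.tile(doy_day, n_years)
    raise ValueError(f"unknown calendar {calendar!r}")


def _ordinals(year, month, day, calendar: str) -> np.ndarray:
    if calendar == "noleap":
        return noleap_ordinal(year, month, day)
    ts = pd.to_datetime(
        pd.DataFrame({"year": year, "month": month, "day": day})
    )
    return ts.values.astype("datetime64[D]").astype("int64")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CityRecord:
    """One study city: identifier, display name, region and location."""

    city_id: str
    name: str
    region: str
    lon: float
    lat: float
    coast_group: str = "Unclassified"

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r} for city {self.city_id}")
        if self.coast_group not in COAST_GROUPS:
            raise ValueError(f"unknown coast_group {self.coast_group!r}")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} out of range for {self.city_id}")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} out of range for {self.city_id}")


@dataclass(frozen=True)
class PeriodWindow:
    """An inclusive analysis window of whole calendar years."""

    label: str
    start_year: int
    end_year: int

    def __post_init__(self):
        if self.end_year < self.start_year:
            raise ValueError(
                f"window {self.label}: end_year {self.end_year} < start_year "
                f"{self.start_year}"
            )

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    def contains(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year


#: Study windows: 30-year baseline, near-future and far-future periods.
DEFAULT_WINDOWS = {
    "baseline": PeriodWindow("baseline", 1985, 2014),
    "near_future": PeriodWindow("near_future", 2025, 2054),
    "far_future": PeriodWindow("far_future", 2065, 2094),
}


@dataclass
class DailySeries:
    """A gap-free daily temperature record for one city x model x scenario.

    Values are degrees Celsius, one per calendar day under the declared
    calendar.  Missing values (NaN) are permitted only in the observational
    reference series; model series must be complete.
    """

    city_id: str
    model_id: str
    scenario: str
    diurnal_var: str
    year: np.ndarray
    month: np.ndarray
    day: np.ndarray
    values: np.ndarray
    calendar: str = "noleap"

    def __post_init__(self):
        self.year = np.asarray(self.year, dtype=np.int64)
        self.month = np.asarray(self.month, dtype=np.int64)
        self.day = np.asarray(self.day, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.diurnal_var not in DIURNAL_VARS:
            raise ValueError(f"unknown diurnal_var {self.diurnal_var!r}")
        if self.calendar not in CALENDARS:
            raise ValueError(f"unknown calendar {self.calendar!r}")
        if len(self.values) != len(self.year):
            raise ValueError("values and dates differ in length")
        ords = _ordinals(self.year, self.month, self.day, self.calendar)
        steps = np.diff(ords)
        if np.any(steps != 1):
            i = int(np.argmax(steps != 1))
            kind = "duplicate or non-increasing" if steps[i] < 1 else "gap"
            raise ValueError(
                f"daily calendar {kind} after "
                f"{self.year[i]:04d}-{self.month[i]:02d}-{self.day[i]:02d} "
                f"in series ({self.city_id}, {self.model_id}, {self.scenario}, "
                f"{self.diurnal_var})"
            )
        if self.model_id != REFERENCE_ID and not np.all(np.isfinite(self.values)):
            raise ValueError(
                f"non-finite values in model series ({self.city_id}, "
                f"{self.model_id}); missing values are allowed only in the "
                f"reference series"
            )

    @classmethod
    def from_window(cls, city_id, model_id, scenario, diurnal_var, start_year,
                    end_year, values, calendar="noleap"):
        """Build a series spanning whole years from a flat value array."""
        y, m, d = calendar_days(start_year, end_year, calendar)
        return cls(city_id, model_id, scenario, diurnal_var, y, m, d, values, calendar)

    def __len__(self) -> int:
        return len(self.values)

    def dates_iso(self) -> np.ndarray:
        return np.array(
            [f"{y:04d}-{m:02d}-{d:02d}" for y, m, d in
             zip(self.year, self.month, self.day)]
        )

    def year_mask(self, year: int) -> np.ndarray:
        return self.year == year

    def subset_window(self, window: PeriodWindow) -> "DailySeries":
        mask = (self.year >= window.start_year) & (self.year <= window.end_year)
        return DailySeries(
            self.city_id, self.model_id, self.scenario, self.diurnal_var,
            self.year[mask], self.month[mask], self.day[mask],
            self.values[mask], self.calendar,
        )

    def covered_years(self) -> list[int]:
        """Calendar years fully covered by the series."""
        full = 365 if self.calendar == "noleap" else None
        out = []
        for yr, cnt in zip(*np.unique(self.year, return_counts=True)):
            need = full if full is not None else (
                366 if pd.Timestamp(int(yr), 12, 31).is_leap_year else 365
            )
            if cnt == need:
                out.append(int(yr))
        return out


@dataclass
class AnalysisConfig:
    """Configuration for a full pipeline run."""

    percentile_q: float = 0.95
    min_event_days: int = 3
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    buffer_km: float = 10.0
    selection_fraction: float = 0.5
    rng_seed: int = 0
    region_map: dict = field(default_factory=dict)
    ssp_multipliers: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.percentile_q < 1.0):
            raise ValueError(f"percentile_q must be in (0,1), got {self.percentile_q}")
        if self.min_event_days < 1:
            raise ValueError("min_event_days must be >= 1")
        if self.buffer_km <= 0:
            raise ValueError("buffer_km must be positive")
        fixed = {}
        for key, win in self.windows.items():
            if isinstance(win, PeriodWindow):
                fixed[key] = win
            else:
                fixed[key] = PeriodWindow(win["label"], win["start_year"],
                                          win["end_year"])
        self.windows = fixed

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["windows"] = {k: asdict(w) for k, w in self.windows.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        data = asdict(self)
        data["windows"] = {k: asdict(w) for k, w in self.windows.items()}
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["city_id", "model_id", "scenario", "diurnal_var", "date", "value_c"]


def _infer_calendar(year, month, day) -> str:
    """Choose the calendar under which the date sequence is gap-free."""
    for cal in ("standard", "noleap"):
        try:
            ords = _ordinals(year, month, day, cal)
        except ValueError:
            continue
        if np.all(np.diff(ords) == 1):
            return cal
    return "standard"  # let DailySeries raise the precise gap error


def read_daily_series(path, dialect: str = "csv_long",
                      calendar: str = "infer") -> list[DailySeries]:
    """Read daily temperature series from disk.

    ``csv_long`` expects the header ``city_id, model_id, scenario,
    diurnal_var, date, value_c`` with ISO dates and Celsius values.
    ``netcdf_cf`` expects CF-style ``tasmax``/``tasmin`` variables in Kelvin
    with a ``time`` coordinate (read through xarray; Kelvin is converted on
    ingest).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv_long":
        return _read_csv_long(path, calendar)
    if dialect == "netcdf_cf":
        return _read_netcdf_cf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_csv_long(path, calendar) -> list[DailySeries]:
    df = pd.read_csv(path, dtype={"city_id": str, "model_id": str})
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    if df.empty:
        return out
    bad_var = set(df["diurnal_var"]) - DIURNAL_VARS
    if bad_var:
        raise ValueError(f"{path}: unknown diurnal_var token(s) {sorted(bad_var)}")
    parts = df["date"].str.split("-", expand=True).astype(int)
    df = df.assign(_y=parts[0], _m=parts[1], _d=parts[2])
    keys = ["city_id", "model_id", "scenario", "diurnal_var"]
    for key, grp in df.groupby(keys, sort=True):
        grp = grp.sort_values(["_y", "_m", "_d"])
        y, m, d = grp["_y"].to_numpy(), grp["_m"].to_numpy(), grp["_d"].to_numpy()
        cal = _infer_calendar(y, m, d) if calendar == "infer" else calendar
        out.append(DailySeries(*key, y, m, d, grp["value_c"].to_numpy(float), cal))
    return out


def _read_netcdf_cf(path) -> list[DailySeries]:
    import xarray as xr

    ds = xr.open_dataset(path, engine="scipy", decode_times=True)
    model_id = ds.attrs.get("model_id", "nc_model")
    scenario = ds.attrs.get("scenario", "historical")
    out = []
    for var in ("tasmax", "tasmin"):
        if var not in ds:
            continue
        da = ds[var]
        time = pd.DatetimeIndex(da["time"].values)
        if "city" in da.dims:
            cities = [str(c) for c in da["city"].values]
            for i, cid in enumerate(cities):
                vals = to_celsius(da.isel(city=i).values, "K")
                out.append(DailySeries(
                    cid, model_id, scenario, var,
                    time.year.to_numpy(), time.month.to_numpy(),
                    time.day.to_numpy(), vals, "standard"))
        else:  # (time, lat, lon) grid: one series per grid point
            stacked = da.stack(_pt=("lat", "lon"))
            for j in range(stacked.sizes["_pt"]):
                lat, lon = (float(v) for v in stacked["_pt"].values[j])
                vals = to_celsius(stacked.isel(_pt=j).values, "K")
                out.append(DailySeries(
                    f"pt_{lat:g}_{lon:g}", model_id, scenario, var,
                    time.year.to_numpy(), time.month.to_numpy(),
                    time.day.to_numpy(), vals, "standard"))
    ds.close()
    return out


def write_daily_series(series: Iterable[DailySeries], path,
                       float_fmt: str = "%.3f") -> None:
    """Write series to the long CSV format (values rounded to ``float_fmt``)."""
    frames = []
    for s in series:
        frames.append(pd.DataFrame({
            "city_id": s.city_id, "model_id": s.model_id,
            "scenario": s.scenario, "diurnal_var": s.diurnal_var,
            "date": s.dates_iso(), "value_c": s.values,
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=_CSV_COLUMNS))
    df.to_csv(path, index=False, float_format=float_fmt)


def read_city_table(path) -> list[CityRecord]:
    df = pd.read_csv(path, dtype={"city_id": str})
    need = ["city_id", "name", "region", "lon", "lat", "coast_group"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: city table missing columns {missing}")
    if df["city_id"].duplicated().any():
        dup = df.loc[df["city_id"].duplicated(), "city_id"].iloc[0]
        raise ValueError(f"{path}: duplicate city_id {dup!r}")
    return [CityRecord(r.city_id, r.name, r.region, float(r.lon), float(r.lat),
                       r.coast_group) for r in df.itertuples()]


def write_city_table(cities: Sequence[CityRecord], path) -> None:
    pd.DataFrame([asdict(c) for c in cities])[
        ["city_id", "name", "region", "lon", "lat", "coast_group"]
    ].to_csv(path, index=False)


def select_top_cities(population_table: Mapping[str, float], k: int) -> list[str]:
    """Rank cities by 2020 population (descending) and return the top ``k``.

    Ties are broken by ``city_id`` ascending.  The study design selects the
    50 most populous urban areas this way.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > len(population_table):
        raise ValueError(f"k={k} exceeds table size {len(population_table)}")
    if any(v < 0 for v in population_table.values()):
        raise ValueError("populations must be non-negative")
    ranked = sorted(population_table.items(), key=lambda kv: (-kv[1], kv[0]))
    return [cid for cid, _ in ranked[:k]]


# ---------------------------------------------------------------------------
# Typed result tables
# ---------------------------------------------------------------------------

TABLE_COLUMNS = {
    "indices": ["city_id", "model_id", "scenario", "diurnal_var", "year",
                "hwn", "hwtd", "hwld", "hwmt", "hht"],
    "scores": ["model_id", "cumulative_score", "selected"],
    "chi": ["city_id", "model_id", "scenario", "period",
            "c_day", "c_night", "chi_combined", "chi_final"],
    "risk": ["city_id", "scenario", "ssp", "horizon", "pop", "pop_change_pct",
             "pop_norm", "pop_change_norm", "chi_final", "risk_abs",
             "risk_change"],
}


def write_table(records: pd.DataFrame, path, kind: str,
                allow_empty: bool = False) -> None:
    """Write a typed result table with a fixed, documented column order."""
    if kind not in TABLE_COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}")
    cols = TABLE_COLUMNS[kind]
    if records.empty and not allow_empty:
        raise ValueError("refusing to write empty table without allow_empty=True")
    extra = [c for c in records.columns if c not in cols]
    missing = [c for c in cols if c not in records.columns]
    if extra or missing:
        raise ValueError(
            f"records do not match table kind {kind!r} "
            f"(missing={missing}, unexpected={extra})"
        )
    records[cols].to_csv(path, index=False)


def read_table(path, kind: str) -> pd.DataFrame:
    if kind not in TABLE_COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path, dtype={c: str for c in
                                  ("city_id", "model_id", "scenario",
                                   "diurnal_var", "ssp", "period")
                                  if c in TABLE_COLUMNS[kind]})
    missing = [c for c in TABLE_COLUMNS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: not a {kind!r} table, missing {missing}")
    return df


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
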