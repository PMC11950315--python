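import numpy as np
import pytest

from urbanheat import AnalysisConfig, DailySeries, PeriodWindow, SyntheticSpec
from urbanheat.io import calendar_days


def make_series(values, year0=2001, city_id="cityA", model_id="m1",
                scenario="historical", diurnal_var="tasmax",
                calendar="noleap"):
    """A gap-free daily series starting 1 Jan of ``year0`` (partial years ok)."""
    values = np.asarray(values, dtype=float)
    n_years = int(np.ceil(len(values) / 365)) + 1
    y, m, d = calendar_days(year0, year0 + n_years, calendar)
    n = len(values)
    return DailySeries(city_id, model_id, scenario, diurnal_var,
                       y[:n], m[:n], d[:n], values, calendar)


@pytest.fixture
def small_windows():
    return {
        "baseline": PeriodWindow("baseline", 1990, 1997),
        "near_future": PeriodWindow("near_future", 2025, 2032),
        "far_future": PeriodWindow("far_future", 2065, 2072),
    }


@pytest.fixture
def small_spec():
    return SyntheticSpec(n_cities=4, n_models=3, rng_seed=7)


@pytest.fixture
def small_config(small_windows):
    return AnalysisConfig(rng_seed=7, windows=small_windows)
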