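"""Climate-model skill ranking against the reference dataset.

For each city the absolute differences between model and reference
period-mean heatwave indices are ranked per index (rank 1 = smallest
deviation, ties averaged), the per-index ranks are averaged into a single
comprehensive rank, and points are awarded on a descending linear scale:
the model ranked first among ``n`` models in a city earns ``n`` points, the
last earns 1 (with 29 models, 29 points down to 1).  Points are summed over
cities into a cumulative score; models whose score strictly exceeds
``selection_fraction * n_cities * n_models`` (half the 1450-point maximum
for 50 cities x 29 models, i.e. 725) are selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import INDEX_NAMES, REFERENCE_ID, logger


@dataclass
class ModelScore:
    """Ranking outcome for one model across all cities."""

    model_id: str
    per_city_rank: dict = field(default_factory=dict)
    per_city_points: dict = field(default_factory=dict)
    cumulative_score: int = 0
    selected: bool = False


def means_to_long(period_means: pd.DataFrame,
                  index_names=INDEX_NAMES) -> pd.DataFrame:
    """Reshape a period-mean table to (model_id, city_id, index_name, value).

    When both diurnal variables are present each index appears twice
    (e.g. ``hwn_tasmax`` and ``hwn_tasmin``), so ranks average over all ten
    components.
    """
    frames = []
    for name in index_names:
        sub = period_means[["model_id", "city_id", "diurnal_var", name]].copy()
        sub["index_name"] = name + "_" + sub["diurnal_var"]
        sub = sub.rename(columns={name: "value"})
        frames.append(sub[["model_id", "city_id", "index_name", "value"]])
    return pd.concat(frames, ignore_index=True)


def deviations(model_means: pd.DataFrame,
               reference_means: pd.DataFrame) -> pd.DataFrame:
    """Elementwise |model - reference| period-mean deviations.

    Both inputs are long tables with columns ``model_id/city_id/index_name/
    value`` (the reference table needs no ``model_id``).  Missing intensity
    means on either side propagate as missing deviations.
    """
    ref = reference_means[["city_id", "index_name", "value"]].rename(
        columns={"value": "ref_value"})
    merged = model_means.merge(ref, on=["city_id", "index_name"], how="left",
                               indicator=True)
    unmatched = merged["_merge"] == "left_only"
    if unmatched.any():
        missing = merged.loc[unmatched, ["city_id", "index_name"]]
        raise ValueError(
            "reference means missing for keys: "
            + ", ".join(f"({r.city_id}, {r.index_name})"
                        for r in missing.drop_duplicates().itertuples()))
    merged["deviation"] = (merged["value"] - merged["ref_value"]).abs()
    return merged[["model_id", "city_id", "index_name", "deviation"]]


def comprehensive_rank(dev: pd.DataFrame, city: str) -> dict[str, int]:
    """Ordinal 1..n model ranking for one city.

    Per index, models are ranked by deviation (ties get the average of the
    tied positions); a model's per-index ranks are averaged, dropping
    indices where its deviation is missing (divisor reduced accordingly);
    the averaged ranks are converted to an ordinal 1..n ordering with ties
    broken by model_id ascending.
    """
    sub = dev[dev["city_id"] == city]
    if sub.empty:
        raise ValueError(f"no deviations for city {city!r}")
    wide = sub.pivot_table(index="model_id", columns="index_name",
                           values="deviation", dropna=False)
    if wide.isna().all(axis=None):
        raise ValueError(f"all deviations missing for city {city!r}")
    ranks = pd.DataFrame(index=wide.index, columns=wide.columns, dtype=float)
    for col in wide.columns:
        vals = wide[col]
        ok = vals.notna()
        if ok.any():
            ranks.loc[ok, col] = stats.rankdata(vals[ok], method="average")
    avg = ranks.mean(axis=1, skipna=True)
    if avg.isna().any():
        bad = list(avg.index[avg.isna()])
        raise ValueError(f"models {bad} have no usable deviations in {city!r}")
    order = sorted(avg.index, key=lambda m: (avg[m], m))
    return {m: i + 1 for i, m in enumerate(order)}


def award_points(rank: int, n_models: int) -> int:
    """Linear descending point scale: rank 1 earns ``n_models`` points."""
    if not (1 <= rank <= n_models):
        raise ValueError(f"rank {rank} out of range 1..{n_models}")
    return n_models - rank + 1


def cumulative_and_select(per_city_points: pd.DataFrame, n_cities: int,
                          n_models: int,
                          selection_fraction: float = 0.5) -> list[ModelScore]:
    """Sum points over cities and flag models above the half-maximum bar.

    ``per_city_points`` has columns ``model_id, city_id, points``.  The
    threshold is ``selection_fraction * n_cities * n_models`` and selection
    is strict (a model must surpass the mark, not meet it).  Output is
    sorted by score descending, ties by model_id.
    """
    counts = per_city_points.groupby("model_id")["city_id"].nunique()
    if (counts != n_cities).any():
        bad = list(counts.index[counts != n_cities])
        raise ValueError(f"models {bad} lack points in some cities")
    threshold = selection_fraction * n_cities * n_models
    out = []
    for mid, grp in per_city_points.groupby("model_id"):
        score = int(grp["points"].sum())
        out.append(ModelScore(
            model_id=mid,
            per_city_points=dict(zip(grp["city_id"], grp["points"])),
            cumulative_score=score,
            selected=score > threshold))
    out.sort(key=lambda s: (-s.cumulative_score, s.model_id))
    logger.info("model selection: threshold=%.1f, selected %d of %d models",
                threshold, sum(s.selected for s in out), len(out))
    return out


def score_models(period_means: pd.DataFrame,
                 reference_id: str = REFERENCE_ID,
                 selection_fraction: float = 0.5,
                 index_names=INDEX_NAMES) -> list[ModelScore]:
    """Full ranking pipeline from a combined period-mean index table.

    The table holds per-(city, model, diurnal_var) period means including
    the reference rows (``model_id == reference_id``).
    """
    long = means_to_long(period_means, index_names)
    ref_long = long[long["model_id"] == reference_id]
    mod_long = long[long["model_id"] != reference_id]
    if ref_long.empty:
        raise ValueError(f"no reference rows (model_id == {reference_id!r})")
    dev = deviations(mod_long, ref_long)
    cities = sorted(dev["city_id"].unique())
    models = sorted(dev["model_id"].unique())
    rows = []
    rank_by_model: dict[str, dict] = {m: {} for m in models}
    for city in cities:
        city_ranks = comprehensive_rank(dev, city)
        for m, r in city_ranks.items():
            rank_by_model[m][city] = r
            rows.append({"model_id": m, "city_id": city,
                         "points": award_points(r, len(models))})
    scores = cumulative_and_select(pd.DataFrame(rows), len(cities),
                                   len(models), selection_fraction)
    for s in scores:
        s.per_city_rank = rank_by_model[s.model_id]
    return scores


def scores_to_frame(scores: list[ModelScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"model_id": s.model_id, "cumulative_score": s.cumulative_score,
          "selected": s.selected} for s in scores])


def r_squared(series_a, series_b) -> float:
    """Squared Pearson correlation of paired daily values in [0, 1].

    Pairs with a missing value on either side are deleted; at least three
    complete pairs are required.  Zero variance in either series leaves the
    correlation undefined: NaN is returned (flagged), never 0.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 overlapping pairs, got {int(ok.sum())}")
    a, b = a[ok], b[ok]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("r_squared undefined: zero variance in an input series")
        return float("nan")
    r = stats.pearsonr(a, b).statistic
    return float(min(1.0, r * r))
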