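"""End-to-end orchestration: simulate -> indices -> rank -> changes -> CHI
-> risk -> coastal, with CSV intermediates and a reproducibility manifest.

Every stage writes its result as CSV into the working directory so each
step is inspectable and re-runnable; the JSON manifest records the config
hash, the seed, and a SHA-256 digest of every output file.  All stages are
deterministic functions of the configuration and seed, so re-running with
the same inputs reproduces byte-identical outputs (the manifest's
timestamps aside).
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .changes import (annual_percentage_changes, regional_ensemble_series,
                      regional_trends)
from .chi import compute_chi, ensemble_chi
from .coastal import classify_coastal, group_box_stats, load_coastline
from .indices import annual_indices_table, baseline_threshold
from .io import (AnalysisConfig, INDEX_NAMES, REFERENCE_ID, logger,
                 sha256_file, write_city_table, write_table)
from .synthetic import (SyntheticSpec, generate_cities,
                        generate_model_ensemble, generate_population,
                        synthetic_coastline)

FUTURE_WINDOWS = {"near_future": 2050, "far_future": 2090}


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    rng_seed: int
    software_version: str
    started: str
    finished: str = ""
    stages: list = dataclasses.field(default_factory=list)

    def add_stage(self, name: str, outputs: dict) -> None:
        self.stages.append({"stage": name, "outputs": outputs})

    def output_digests(self) -> dict:
        out = {}
        for st in self.stages:
            out.update(st["outputs"])
        return out

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _digests(workdir: Path, names) -> dict:
    return {n: sha256_file(workdir / n) for n in names}


def _series_frame(series_list) -> pd.DataFrame:
    """Long-format frame for a batch of series sharing one window/calendar."""
    date_cache: dict = {}
    frames = []
    for s in series_list:
        key = (int(s.year[0]), int(s.year[-1]), s.calendar, len(s))
        if key not in date_cache:
            date_cache[key] = s.dates_iso()
        frames.append(pd.DataFrame({
            "city_id": s.city_id, "model_id": s.model_id,
            "scenario": s.scenario, "diurnal_var": s.diurnal_var,
            "date": date_cache[key], "value_c": np.round(s.values, 3)}))
    return pd.concat(frames, ignore_index=True)


def run_all(config: AnalysisConfig, workdir,
            spec: SyntheticSpec | None = None) -> RunManifest:
    """Run the full synthetic-ensemble analysis into ``workdir``."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if spec is None:
        spec = SyntheticSpec(rng_seed=config.rng_seed)
    manifest = RunManifest(
        config_hash=config.config_hash(), rng_seed=config.rng_seed,
        software_version=__version__,
        started=datetime.now(timezone.utc).isoformat())

    windows = config.windows
    baseline = windows["baseline"]
    scenarios = ("ssp245", "ssp585")

    # ---- stage: simulate -------------------------------------------------
    logger.info("stage simulate: %d cities x %d models", spec.n_cities,
                spec.n_models)
    cities = generate_cities(spec)
    region_map = config.region_map or {c.city_id: c.region for c in cities}
    write_city_table(cities, workdir / "cities.csv")
    (workdir / "coastline.geojson").write_text(
        json.dumps(synthetic_coastline()))
    population = generate_population(spec)
    population.to_csv(workdir / "population.csv", index=False,
                      float_format="%.1f")
    config.to_yaml(workdir / "config.yaml")
    spec.to_yaml(workdir / "synthetic_spec.yaml")

    ensembles = {}  # (scenario, window label) -> list of DailySeries
    ensembles[("historical", "baseline")] = generate_model_ensemble(
        spec, "historical", baseline)
    for scen in scenarios:
        for wlabel in ("near_future", "far_future"):
            ens = generate_model_ensemble(spec, scen, windows[wlabel])
            # the observational reference does not extend into the future
            ensembles[(scen, wlabel)] = [
                s for s in ens if s.model_id != REFERENCE_ID]
    sim_files = []
    for (scen, wlabel), series_list in ensembles.items():
        fname = f"series_{scen}_{wlabel}.csv"
        _series_frame(series_list).to_csv(workdir / fname, index=False)
        sim_files.append(fname)
    manifest.add_stage("simulate", _digests(
        workdir, sim_files + ["cities.csv", "coastline.geojson",
                              "population.csv", "config.yaml",
                              "synthetic_spec.yaml"]))

    # ---- stage: indices --------------------------------------------------
    logger.info("stage indices: thresholds q=%.2f, min %d days",
                config.percentile_q, config.min_event_days)
    thresholds = {}
    for s in ensembles[("historical", "baseline")]:
        thresholds[(s.city_id, s.model_id, s.diurnal_var)] = \
            baseline_threshold(s, baseline, config.percentile_q)
    record_frames = []
    for (scen, wlabel), series_list in ensembles.items():
        for s in series_list:
            thr = thresholds[(s.city_id, s.model_id, s.diurnal_var)]
            record_frames.append(
                annual_indices_table(s, thr, config.min_event_days))
    records = pd.concat(record_frames, ignore_index=True)
    write_table(records, workdir / "indices.csv", "indices")
    manifest.add_stage("indices", _digests(workdir, ["indices.csv"]))

    # ---- stage: period means --------------------------------------------
    from .indices import period_mean_indices
    mean_frames = []
    for wlabel, window in windows.items():
        if wlabel == "baseline":
            sub = records[records["scenario"].isin(["historical", "reference"])]
        else:
            sub = records[records["scenario"].isin(scenarios)]
        sub = sub[(sub["year"] >= window.start_year)
                  & (sub["year"] <= window.end_year)]
        pm = period_mean_indices(sub, window)
        pm["period"] = wlabel
        mean_frames.append(pm)
    period_means = pd.concat(mean_frames, ignore_index=True)
    period_means.to_csv(workdir / "period_means.csv", index=False)
    manifest.add_stage("period_means", _digests(workdir, ["period_means.csv"]))

    # ---- stage: rank models ---------------------------------------------
    from .selection import score_models, scores_to_frame
    base_means = period_means[period_means["period"] == "baseline"]
    scores = score_models(base_means, REFERENCE_ID, config.selection_fraction)
    selected = [s.model_id for s in scores if s.selected]
    if not selected:  # degenerate tie landscape: fall back to all models
        logger.warning("no model surpassed the selection threshold; "
                       "using the full ensemble downstream")
        selected = [s.model_id for s in scores]
    write_table(scores_to_frame(scores), workdir / "scores.csv", "scores")
    manifest.add_stage("rank_models", _digests(workdir, ["scores.csv"]))

    # ---- stage: changes --------------------------------------------------
    logger.info("stage changes: %d selected models", len(selected))
    pct = annual_percentage_changes(records[records["model_id"] != REFERENCE_ID],
                                    baseline)
    pct = pct[pct["model_id"].isin(selected)].copy()
    year_period = {y: wlabel for wlabel in FUTURE_WINDOWS
                   for y in windows[wlabel].years}
    pct["period"] = pct["year"].map(year_period)
    ens_series = regional_ensemble_series(pct, region_map)
    ens_series.to_csv(workdir / "changes_regional.csv", index=False,
                      float_format="%.4f")
    trends = regional_trends(ens_series)
    trends.to_csv(workdir / "trends.csv", index=False, float_format="%.5f")
    manifest.add_stage("changes", _digests(
        workdir, ["changes_regional.csv", "trends.csv"]))

    # ---- stage: chi ------------------------------------------------------
    chi_frames = []
    chi_slices = [("historical", "baseline")] + [
        (scen, wlabel) for scen in scenarios
        for wlabel in ("near_future", "far_future")]
    for scen, wlabel in chi_slices:
        pm = period_means[(period_means["period"] == wlabel)
                          & (period_means["scenario"] ==
                             ("historical" if wlabel == "baseline" else scen))]
        per_model = compute_chi(pm, scen if wlabel != "baseline" else
                                "historical", wlabel, models=selected)
        chi_frames.append(per_model)
        chi_frames.append(ensemble_chi(per_model, selected))
    chi_table = pd.concat(chi_frames, ignore_index=True)
    write_table(chi_table.round(6), workdir / "chi.csv", "chi")
    manifest.add_stage("chi", _digests(workdir, ["chi.csv"]))

    # ---- stage: risk -----------------------------------------------------
    from .risk import build_risk_table, hotspot_table
    ssps = sorted(population["ssp"].unique())
    risk_frames = []
    for scen in scenarios:
        for wlabel, horizon in FUTURE_WINDOWS.items():
            ens = chi_table[(chi_table["model_id"] == "ensemble")
                            & (chi_table["scenario"] == scen)
                            & (chi_table["period"] == wlabel)]
            for ssp in ssps:
                risk_frames.append(
                    build_risk_table(ens, population, ssp, horizon, scen))
    risk_table = pd.concat(risk_frames, ignore_index=True)
    write_table(risk_table.round(6), workdir / "risk.csv", "risk")
    first = risk_frames[0]
    hotspots = hotspot_table(first, region_map)
    hotspots.round(6).to_csv(workdir / "hotspots.csv", index=False)
    manifest.add_stage("risk", _digests(workdir, ["risk.csv", "hotspots.csv"]))

    # ---- stage: coastal --------------------------------------------------
    coastline = load_coastline(workdir / "coastline.geojson")
    classes = [classify_coastal(c, coastline, config.buffer_km)
               for c in cities]
    pd.DataFrame([dataclasses.asdict(c) for c in classes]).round(3).to_csv(
        workdir / "coastal.csv", index=False)
    group_of = {c.city_id: c.coast_group for c in classes}
    sel_means = base_means[base_means["model_id"].isin(selected)]
    box_rows = []
    for var, name in ((v, n) for v in ("tasmax", "tasmin")
                      for n in INDEX_NAMES):
        grp = sel_means[sel_means["diurnal_var"] == var]
        city_vals = grp.groupby("city_id")[name].mean()
        by_group: dict[str, list] = {}
        for cid, val in city_vals.items():
            by_group.setdefault(group_of[cid], []).append(val)
        for gname, vals in sorted(by_group.items()):
            bs = group_box_stats(vals, gname)
            box_rows.append({
                "group": gname, "diurnal_var": var, "index_name": name,
                "median": bs.median, "q25": bs.q25, "q75": bs.q75,
                "whisker_low": bs.whisker_low, "whisker_high": bs.whisker_high,
                "n_outliers": len(bs.outliers), "n": bs.n})
    pd.DataFrame(box_rows).round(4).to_csv(
        workdir / "coastal_box_stats.csv", index=False)
    manifest.add_stage("coastal", _digests(
        workdir, ["coastal.csv", "coastal_box_stats.csv"]))

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.to_json(workdir / "manifest.json")
    logger.info("pipeline complete: %d stages, %d output files",
                len(manifest.stages), len(manifest.output_digests()))
    return manifest
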