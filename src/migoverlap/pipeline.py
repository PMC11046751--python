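"""End-to-end orchestration: simulate -> qc -> classify -> bbmm -> popdist
-> mrsa -> overlap, from one config with one root seed.

Every stage draws randomness from a named substream of the root seed, so a
rerun with the same config reproduces identical outputs (and identical
content hashes in the run manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bbmm, classification, overlap, population, preprocessing, rangeshift
from .bbmm import BBMMParams, Grid
from .classification import ClusterParams, SeasonWindows
from .preprocessing import QCConfig
from .synthetic import PopulationConfig, simulate_population
from .tracks import Track, write_tracks

ALL_STAGES = ("simulate", "qc", "classify", "bbmm", "corridor", "mrsa", "overlap")


@dataclass
class PipelineConfig:
    population: PopulationConfig = field(default_factory=PopulationConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    bbmm: BBMMParams = field(default_factory=BBMMParams)
    cluster_separation: dict = field(
        default_factory=lambda: {"deer": 2500.0, "moose": 4000.0, "wolf": 8000.0}
    )
    contour_level: float = 0.95
    min_locations: int = 50
    corridor_min_frac: float = 0.05
    logit_caps: tuple[float, float] = (0.025, 0.975)
    fl_area_km2: float = 561.0
    alpha: float = 0.05
    grid_margin: float = 1500.0
    seed: int = 0
    stages: tuple = ALL_STAGES

    def cluster_params(self, species: str) -> ClusterParams:
        return ClusterParams(min_separation=self.cluster_separation[species])

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self), default=str))


@dataclass
class PipelineResult:
    tracks: list[Track]
    ledger: object
    clean: dict[str, Track]
    status: pd.DataFrame
    timing: pd.DataFrame
    seasons: SeasonWindows
    distributions: dict[tuple[str, str], population.DistributionSet]
    corridor: population.DistributionSet | None
    mrsa: pd.DataFrame | None
    records: pd.DataFrame | None
    models: dict[str, overlap.ModelFitResult] | None
    mw_table: pd.DataFrame | None
    manifest: dict


def _substream(seed: int, name: str) -> int:
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute the configured stages in dependency order."""
    stages = tuple(config.stages)
    if "overlap" in stages and "corridor" not in stages:
        raise ValueError("overlap stage requires the corridor stage")
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "outputs": {}}

    # --- simulate -----------------------------------------------------------
    tracks, ledger = simulate_population(
        config.population, _substream(config.seed, "simulate")
    )
    if outdir is not None:
        write_tracks(tracks, outdir / "tracks.csv")
        ledger.write(outdir / "ledger.csv")

    # --- qc -----------------------------------------------------------------
    clean: dict[str, Track] = {}
    qc_log = []
    for tr in tracks:
        if "qc" in stages:
            out, log = preprocessing.qc_pipeline(tr, config.qc)
        else:
            out, log = tr, {}
        clean[tr.id] = out
        qc_log.append({"id": tr.id, "n_in": tr.n, "n_out": out.n, **log})
    if outdir is not None:
        pd.DataFrame(qc_log).to_csv(outdir / "qc_log.csv", index=False)
        write_tracks(list(clean.values()), outdir / "tracks_clean.csv")

    # --- classify -----------------------------------------------------------
    status_rows = []
    events_by_id = {}
    segments_by_id = {}
    for tr in tracks:
        ct = clean[tr.id]
        params = config.cluster_params(ct.species)
        segs = classification.detect_segments(ct, params)
        span = float((ct.t[-1] - ct.t[0]) / np.timedelta64(1, "D")) if ct.n else 0.0
        st = classification.classify(segs, span, params)
        segments_by_id[tr.id] = segs
        events_by_id[tr.id] = classification.select_seasonal_events(
            classification.extract_events(segs, params)
        )
        status_rows.append(
            {
                "id": tr.id,
                "species": ct.species,
                "status": st.status,
                "displacement_km": st.displacement_km,
                "n_segments": len(classification.home_segments(segs, params)),
            }
        )
    status = pd.DataFrame(status_rows).set_index("id")
    deer_migr = status.query("species == 'deer' and status == 'migratory'").index
    deer_events = [e for i in deer_migr for e in events_by_id[i]]
    timing = classification.timing_table(deer_events)
    seasons = classification.define_seasons(timing)
    if outdir is not None:
        status.to_csv(outdir / "status.csv")
        timing.to_csv(outdir / "timing.csv")
        with open(outdir / "seasons.json", "w") as fh:
            json.dump(
                {s: list(map(list, seasons.window(s))) for s in classification.SEASONS},
                fh,
            )

    result = PipelineResult(
        tracks=tracks, ledger=ledger, clean=clean, status=status, timing=timing,
        seasons=seasons, distributions={}, corridor=None, mrsa=None,
        records=None, models=None, mw_table=None, manifest=manifest,
    )
    if "bbmm" not in stages:
        _finish_manifest(manifest, outdir)
        return result

    # --- bbmm + population distributions ------------------------------------
    grid = Grid.from_tracks(
        list(clean.values()), resolution=config.bbmm.resolution,
        margin=config.grid_margin,
    )

    def season_rasters(tr: Track) -> dict[tuple[str, int], bbmm.ProbabilityRaster]:
        labels, years = seasons.season_year(tr.t)
        out = {}
        for season in classification.SEASONS:
            for year in np.unique(years[labels == season]):
                mask = (labels == season) & (years == year)
                sub = tr.subset(mask)
                if sub.n < 3:
                    continue
                try:
                    var = bbmm.estimate_motion_variance(
                        sub, config.bbmm.location_error_sd, config.bbmm.max_lag
                    )
                    p = dataclasses.replace(config.bbmm, motion_variance=var)
                    out[(season, int(year))] = bbmm.occurrence_distribution(sub, p, grid)
                except ValueError:
                    continue
        return out

    pop_members = {
        "wolf": [i for i, r in status.iterrows() if r.species == "wolf"],
        "moose": [i for i, r in status.iterrows() if r.species == "moose"],
        "deer-composite": [i for i, r in status.iterrows() if r.species == "deer"],
        "deer-migratory": list(deer_migr),
        "deer-resident": list(
            status.query("species == 'deer' and status == 'resident'").index
        ),
    }
    indiv: dict[str, dict[tuple[str, int], bbmm.ProbabilityRaster]] = {}
    for i in status.index:
        if clean[i].n >= 3:
            indiv[i] = season_rasters(clean[i])

    wolf_season_regions: dict[tuple[str, str, int], bbmm.ContourRegion] = {}
    for i in pop_members["wolf"]:
        for (season, year), raster in indiv.get(i, {}).items():
            wolf_season_regions[(i, season, year)] = bbmm.contour(
                raster, config.contour_level
            )

    distributions = {}
    migratory_sy = {}
    for pop, members in pop_members.items():
        keyed = {
            (i, year, season): raster
            for i in members
            for (season, year), raster in indiv.get(i, {}).items()
        }
        if not keyed:
            continue
        dists = population.build_population_distribution(
            keyed, pop, level=config.contour_level
        )
        for season, ds in dists.items():
            distributions[(pop, season)] = ds
        if pop == "deer-migratory":
            migratory_sy = population.season_year_rasters(keyed)
    result.distributions = distributions

    corridor = None
    if "corridor" in stages:
        spring = {y: r for (s, y), r in migratory_sy.items() if s == "spring"}
        fall = {y: r for (s, y), r in migratory_sy.items() if s == "fall"}
        corridor = population.build_corridor(
            spring, fall, level=config.contour_level
        )
        result.corridor = corridor

    if outdir is not None:
        inv = []
        for (pop, season), ds in sorted(distributions.items()):
            stem = f"dist_{pop}_{season}"
            ds.raster.write_ascii(outdir / f"{stem}.asc")
            ds.contour95.write_geojson(outdir / f"{stem}.geojson")
            inv.append({"population": pop, "season": season, "year": "all"})
        if corridor is not None:
            corridor.raster.write_ascii(outdir / "dist_corridor_migration.asc")
            corridor.contour95.write_geojson(outdir / "dist_corridor_migration.geojson")
            inv.append(
                {"population": "deer-migratory", "season": "migration", "year": "all"}
            )
        pd.DataFrame(inv).to_csv(outdir / "distribution_manifest.csv", index=False)

    # --- mrsa ---------------------------------------------------------------
    if "mrsa" in stages:
        rows = []
        for i in pop_members["wolf"]:
            tr = clean[i]
            if tr.n < 30:
                rows.append({"id": i, "status": "unknown"})
                continue
            fit = rangeshift.test_track(
                tr, seed=_substream(config.seed, f"mrsa:{i}"), seasons=seasons,
                alpha=config.alpha, compute_ci=True,
            )
            rows.append(
                {
                    "id": i,
                    "status": rangeshift.classify_shift(fit, config.alpha),
                    "p_value": fit.p_value,
                    "t1": str(fit.t1),
                    "dt_days": fit.dt_days,
                    "ci_t1": str(fit.ci_t1) if fit.ci_t1 else "",
                    "ci_dt_days": str(fit.ci_dt_days) if fit.ci_dt_days else "",
                }
            )
        result.mrsa = pd.DataFrame(rows)
        if outdir is not None:
            result.mrsa.to_csv(outdir / "mrsa.csv", index=False)

    # --- overlap -------------------------------------------------------------
    if "overlap" in stages and corridor is not None:
        wolf_tracks = [clean[i] for i in pop_members["wolf"] if clean[i].n > 0]
        retained = overlap.corridor_filter(
            wolf_tracks, corridor.contour95, config.corridor_min_frac
        )
        rec_rows = []
        for tr in retained:
            # floating wolves: year-round 95% range larger than the threshold
            try:
                var = bbmm.estimate_motion_variance(
                    tr, config.bbmm.location_error_sd, config.bbmm.max_lag
                )
                p = dataclasses.replace(config.bbmm, motion_variance=var)
                full = bbmm.occurrence_distribution(tr, p, grid)
                area = bbmm.contour(full, config.contour_level).area_km2
            except ValueError:
                area = 0.0
            pack = overlap.assign_pack(area, tr.pack or "FL", config.fl_area_km2)
            for (season, year), sub in overlap.season_filter(
                tr, seasons, config.min_locations
            ).items():
                region = wolf_season_regions.get((tr.id, season, year))
                if region is None:
                    continue
                for prey in (
                    "moose", "corridor", "deer-composite",
                    "deer-migratory", "deer-resident",
                ):
                    if prey == "corridor":
                        prey_region = corridor.contour95
                    else:
                        ds = distributions.get((prey, season))
                        if ds is None:
                            continue
                        prey_region = ds.contour95
                    prop = overlap.proportional_overlap(region, prey_region)
                    rec_rows.append(
                        {
                            "wolf_id": tr.id,
                            "season": season,
                            "year": year,
                            "prey": prey,
                            "proportion": prop,
                            "logit_value": overlap.logit_cap(
                                prop, *config.logit_caps
                            ),
                            "sex": tr.sex,
                            "pack": pack,
                            "n_locations": sub.n,
                        }
                    )
        records = pd.DataFrame(rec_rows)
        result.records = records
        models = {}
        for prey in records["prey"].unique() if len(records) else []:
            try:
                models[prey] = overlap.fit_overlap_model(records, prey)
            except ValueError:
                continue
        result.models = models
        result.mw_table = (
            overlap.seasonal_mann_whitney(records) if len(records) else pd.DataFrame()
        )
        if outdir is not None:
            records.to_csv(outdir / "overlap_records.csv", index=False)
            if models:
                pd.concat(
                    {k: m.table for k, m in models.items()}, names=["prey", "term"]
                ).to_csv(outdir / "overlap_models.csv")
            result.mw_table.to_csv(outdir / "mann_whitney.csv", index=False)

    _finish_manifest(manifest, outdir)
    return result


def _finish_manifest(manifest: dict, outdir: Path | None) -> None:
    if outdir is None:
        return
    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def demo_config(seed: int = 0) -> PipelineConfig:
    """The packaged synthetic study: 30 deer, 10 moose, 6 wolves, 2 years."""
    pop = PopulationConfig(
        counts={
            "deer": {"migratory": 20, "resident": 10},
            "moose": {"migratory": 2, "resident": 4, "nomadic": 4},
            "wolf": {"resident": 6},
        },
        monitor_start="2019-02-13T00:00:00",
        monitor_end="2021-02-13T00:00:00",
    )
    return PipelineConfig(population=pop, seed=seed)


def directional_config(seed: int = 0) -> PipelineConfig:
    """A one-year world where wolves redistribute toward the deer corridor
    in fall; used for the directional overlap check."""
    pop = PopulationConfig(
        counts={
            "deer": {"migratory": 8, "resident": 3},
            "moose": {"resident": 3},
            "wolf": {"resident": 6},
        },
        monitor_start="2019-02-13T00:00:00",
        monitor_end="2020-02-13T00:00:00",
    )
    return PipelineConfig(population=pop, seed=seed, stages=(
        "simulate", "qc", "classify", "bbmm", "corridor", "overlap"
    ))


def config_to_yaml(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def config_from_yaml(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    pop = PopulationConfig(**raw.pop("population", {}))
    qc = QCConfig(**raw.pop("qc", {}))
    bb_raw = raw.pop("bbmm", {})
    bb = BBMMParams(**{k: v for k, v in bb_raw.items()})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    extra = {k: v for k, v in raw.items() if k in known}
    if "logit_caps" in extra:
        extra["logit_caps"] = tuple(extra["logit_caps"])
    if "stages" in extra:
        extra["stages"] = tuple(extra["stages"])
    return PipelineConfig(population=pop, qc=qc, bbmm=bb, **extra)
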