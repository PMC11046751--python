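"""Hierarchical population-level distributions and the migration corridor.

Individual occurrence distributions are merged in three levels: cell-wise
mean over individuals within a season and year, then mean over years,
giving one final distribution per population and season (years weigh
equally regardless of how many animals each contributed). The migration
corridor adds one step: spring and fall season-year distributions of the
migratory population are averaged before the across-year merge, and the
result is treated as a single non-seasonal distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bbmm import ContourRegion, Grid, ProbabilityRaster, contour

POPULATIONS = ("wolf", "moose", "deer-composite", "deer-migratory", "deer-resident")


@dataclass
class DistributionSet:
    population: str
    season: str  # winter|spring|summer|fall or "migration" for the corridor
    year: str  # calendar year or "all"
    raster: ProbabilityRaster
    contour95: ContourRegion


def mean_merge(rasters: list[ProbabilityRaster]) -> ProbabilityRaster:
    """Cell-wise arithmetic mean, renormalized to unit mass."""
    if not rasters:
        raise ValueError("cannot merge an empty list of rasters")
    grid = rasters[0].grid
    if any(r.grid != grid for r in rasters):
        raise ValueError("all rasters must share one grid")
    mean = np.mean([r.values for r in rasters], axis=0)
    return ProbabilityRaster(grid, mean / mean.sum())


def build_population_distribution(
    individual_rasters: dict[tuple[str, int, str], ProbabilityRaster],
    population: str,
    level: float = 0.95,
) -> dict[str, DistributionSet]:
    """Final per-season distributions from rasters keyed (animal, year, season).

    Hierarchy: individual -> season-year mean -> across-year mean. Returns
    one :class:`DistributionSet` per season present, with its 95% contour.
    """
    if not individual_rasters:
        raise ValueError("no individual rasters supplied")
    by_season_year: dict[tuple[str, int], list[ProbabilityRaster]] = {}
    for (animal, year, season), raster in individual_rasters.items():
        by_season_year.setdefault((season, int(year)), []).append(raster)
    season_year = {k: mean_merge(v) for k, v in sorted(by_season_year.items())}
    out = {}
    for season in sorted({s for s, _ in season_year}):
        years = [r for (s, _), r in sorted(season_year.items()) if s == season]
        final = mean_merge(years)
        out[season] = DistributionSet(
            population=population,
            season=season,
            year="all",
            raster=final,
            contour95=contour(final, level),
        )
    return out


def season_year_rasters(
    individual_rasters: dict[tuple[str, int, str], ProbabilityRaster],
) -> dict[tuple[str, int], ProbabilityRaster]:
    """Season-and-year mean distributions (the middle hierarchy level)."""
    by_season_year: dict[tuple[str, int], list[ProbabilityRaster]] = {}
    for (animal, year, season), raster in individual_rasters.items():
        by_season_year.setdefault((season, int(year)), []).append(raster)
    return {k: mean_merge(v) for k, v in sorted(by_season_year.items())}


def build_corridor(
    spring: dict[int, ProbabilityRaster],
    fall: dict[int, ProbabilityRaster],
    population: str = "deer-migratory",
    level: float = 0.95,
) -> DistributionSet:
    """Migration-corridor distribution from spring and fall season-year
    distributions: merge the two seasons within each year, then across years.
    """
    if not spring or not fall:
        raise ValueError("corridor needs both spring and fall distributions")
    years = sorted(set(spring) | set(fall))
    per_year = []
    for y in years:
        both = [r for r in (spring.get(y), fall.get(y)) if r is not None]
        per_year.append(mean_merge(both))
    final = mean_merge(per_year)
    return DistributionSet(
        population=population,
        season="migration",
        year="all",
        raster=final,
        contour95=contour(final, level),
    )


def corridor_similarity(
    region_a: ContourRegion, region_b: ContourRegion, denominator: str = "smaller"
) -> float:
    """Areal overlap of two contour regions, in [0, 1].

    ``denominator``: "smaller" (default; intersection over the smaller
    region's area, symmetric and robust to nesting), "union", or "mean".
    """
    if region_a.area_km2 <= 0 or region_b.area_km2 <= 0:
        raise ValueError("zero-area region")
    inter = region_a.intersection_area_m2(region_b) / 1e6
    if denominator == "smaller":
        return inter / min(region_a.area_km2, region_b.area_km2)
    if denominator == "union":
        return inter / (region_a.area_km2 + region_b.area_km2 - inter)
    if denominator == "mean":
        return inter / ((region_a.area_km2 + region_b.area_km2) / 2.0)
    raise ValueError(f"unknown denominator {denominator!r}")


@dataclass
class CorridorUseRaster:
    grid: Grid
    values: np.ndarray  # per-cell fraction of individuals using the cell

    def __post_init__(self) -> None:
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("corridor-use fractions must lie in [0, 1]")


def corridor_use(regions: list[ContourRegion], grid: Grid) -> CorridorUseRaster:
    """Fraction of individuals whose region covers each cell center."""
    if not regions:
        raise ValueError("need at least one region")
    xc, yc = np.meshgrid(grid.x_centers, grid.y_centers)
    centers = np.column_stack([xc.ravel(), yc.ravel()])
    acc = np.zeros(centers.shape[0])
    for region in regions:
        if region.mask is not None and region.grid == grid:
            acc += region.mask.ravel()
        else:
            acc += region.covers_points(centers)
    return CorridorUseRaster(grid, (acc / len(regions)).reshape(grid.n_rows, grid.n_cols))
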