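"""Predator-prey proportional overlap and its statistical comparisons.

For each retained wolf-season, the proportional overlap with a prey
population is area(wolf 95% UD region intersect prey 95% region) divided by
the wolf region's area. Overlaps are logit-transformed (capped at
0.025/0.975 because logit(0) and logit(1) diverge) and modeled by ordinary
least squares against season with sex and pack affiliation as nuisance
covariates -- one model per prey distribution. Seasonal contrasts between
prey populations use Mann-Whitney rank tests with midranks for ties and an
exact tail when the group sizes allow enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, log

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .bbmm import ContourRegion
from .classification import SeasonWindows
from .tracks import Track

PACKS = ("NE", "NW", "SW", "FL")
FL_AREA_KM2 = 561.0  # year-round ranges above this are "floating" wolves


@dataclass
class OverlapRecord:
    wolf_id: str
    season: str
    prey: str
    proportion: float
    logit_value: float
    sex: str
    pack: str
    n_locations: int
    year: int

    def __post_init__(self) -> None:
        if not 0 <= self.proportion <= 1:
            raise ValueError("proportion must be in [0, 1]")
        if self.n_locations < 50:
            raise ValueError("records require >= 50 locations")


def corridor_filter(
    tracks: list[Track], corridor: ContourRegion, min_frac: float = 0.05
) -> list[Track]:
    """Keep wolves with at least ``min_frac`` of fixes inside the corridor."""
    kept = []
    for tr in tracks:
        if tr.n == 0:
            continue
        frac = float(np.mean(corridor.covers_points(tr.xy)))
        if frac >= min_frac:
            kept.append(tr)
    return kept


def season_filter(
    track: Track, seasons: SeasonWindows, min_locs: int = 50
) -> dict[tuple[str, int], Track]:
    """Split a track into wolf-seasons, dropping those with too few fixes."""
    labels, years = seasons.season_year(track.t)
    out = {}
    for season in ("winter", "spring", "summer", "fall"):
        for year in np.unique(years[labels == season]):
            mask = (labels == season) & (years == year)
            if int(mask.sum()) >= min_locs:
                out[(season, int(year))] = track.subset(mask)
    return out


def proportional_overlap(
    wolf_region: ContourRegion, prey_region: ContourRegion
) -> float:
    """area(wolf intersect prey) / area(wolf), in [0, 1]."""
    if wolf_region.area_km2 <= 0:
        raise ValueError("wolf region has zero area")
    p = wolf_region.intersection_area_m2(prey_region) / 1e6 / wolf_region.area_km2
    return float(min(max(p, 0.0), 1.0))


def logit_cap(p: float, lo: float = 0.025, hi: float = 0.975) -> float:
    """Logit of the proportion after capping into [lo, hi]."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    q = min(max(p, lo), hi)
    return log(q / (1.0 - q))


def assign_pack(
    area_km2: float, observed_pack: str, threshold_km2: float = FL_AREA_KM2
) -> str:
    """Floating (FL) when the year-round range exceeds the area threshold."""
    return "FL" if area_km2 > threshold_km2 else observed_pack


@dataclass
class ModelFitResult:
    prey: str
    table: pd.DataFrame  # index: term; columns: coef, se, p
    n: int


def fit_overlap_model(records: pd.DataFrame, prey: str) -> ModelFitResult:
    """OLS of logit overlap on season + sex + pack for one prey population.

    Reference levels: winter (season), F (sex), FL (pack). Raises on a
    rank-deficient design, naming the offending term.
    """
    df = records[records["prey"] == prey].copy()
    if df.empty:
        raise ValueError(f"no records for prey {prey!r}")
    if df["season"].nunique() < 2:
        raise ValueError("need at least two seasons represented")
    terms = []
    if df["season"].nunique() > 1:
        terms.append('C(season, Treatment(reference="winter"))')
    if df["sex"].nunique() > 1:
        terms.append('C(sex, Treatment(reference="F"))')
    if df["pack"].nunique() > 1:
        ref = "FL" if "FL" in set(df["pack"]) else sorted(df["pack"].unique())[0]
        terms.append(f'C(pack, Treatment(reference="{ref}"))')
    formula = "logit_value ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        for j in range(model.exog.shape[1]):
            sub = np.delete(model.exog, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(
                    f"rank-deficient design: term {model.exog_names[j]!r} is aliased"
                )
        raise ValueError("rank-deficient design")
    fit = model.fit()
    names = [
        n.replace('C(season, Treatment(reference="winter"))[T.', "season:")
        .replace('C(sex, Treatment(reference="F"))[T.', "sex:")
        .replace("]", "")
        for n in fit.params.index
    ]
    names = [
        n.split("[T.")[-1].join(["pack:", ""]) if "C(pack" in n else n for n in names
    ]
    table = pd.DataFrame(
        {"coef": fit.params.values, "se": fit.bse.values, "p": fit.pvalues.values},
        index=names,
    )
    return ModelFitResult(prey=prey, table=table, n=len(df))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    ra = ranks[: len(a)].sum()
    return float(ra - len(a) * (len(a) + 1) / 2.0)


def _exact_two_sided(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Exact two-sided tail by dynamic programming over (doubled) midranks."""
    na, nb = len(a), len(b)
    n = na + nb
    ranks = stats.rankdata(np.concatenate([a, b]))
    s = np.rint(2 * ranks).astype(int)  # half-ranks doubled to integers
    max_sum = int(s.sum())
    # count[j, t] = number of j-subsets of the pooled ranks with doubled-rank sum t
    count = np.zeros((na + 1, max_sum + 1))
    count[0, 0] = 1.0
    for si in s:
        count[1:, si:] += count[:-1, : max_sum + 1 - si]
    total = comb(n, na)
    sums = np.arange(max_sum + 1)
    u_vals = sums / 2.0 - na * (na + 1) / 2.0
    weights = count[na]
    p_le = weights[u_vals <= u_obs + 1e-9].sum() / total
    p_ge = weights[u_vals >= u_obs - 1e-9].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def mann_whitney(group_a, group_b, exact_limit: int = 400) -> tuple[float, float]:
    """Mann-Whitney U (oriented to the first group) and two-sided p.

    Midranks handle ties. The p-value is exact (full enumeration of group
    assignments via a rank-sum distribution) when nA*nB <= ``exact_limit``,
    otherwise a normal approximation with tie and continuity corrections.
    Both orientations are recoverable: U_b = nA*nB - U_a.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    u = _u_statistic(a, b)
    na, nb = len(a), len(b)
    if na * nb <= exact_limit:
        return u, _exact_two_sided(a, b, u)
    n = na + nb
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    mean = na * nb / 2.0
    if var <= 0:
        return u, 1.0
    z = (u - mean - np.sign(u - mean) * 0.5) / np.sqrt(var)
    return u, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def seasonal_mann_whitney(records: pd.DataFrame, comparisons=None) -> pd.DataFrame:
    """Per-season rank tests between prey populations (wide-format table)."""
    if comparisons is None:
        comparisons = [
            ("deer-composite", "moose"),
            ("deer-resident", "deer-migratory"),
        ]
    rows = []
    for pop1, pop2 in comparisons:
        for season in ("winter", "spring", "summer", "fall"):
            g1 = records.query("prey == @pop1 and season == @season")["proportion"]
            g2 = records.query("prey == @pop2 and season == @season")["proportion"]
            if g1.empty or g2.empty:
                continue
            u, p = mann_whitney(g1.to_numpy(), g2.to_numpy())
            greater = "N/A"
            if p < 0.05:
                greater = pop1 if g1.median() > g2.median() else pop2
            rows.append(
                {
                    "population_1": pop1,
                    "population_2": pop2,
                    "season": season,
                    "W": u,
                    "W_reversed": len(g1) * len(g2) - u,
                    "p_value": p,
                    "greater_overlap": greater,
                }
            )
    return pd.DataFrame(rows)
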