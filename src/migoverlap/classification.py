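"""Home-range segmentation, movement-strategy classification and seasons.

The classification follows the standard net-squared-displacement view of
ungulate movement: an animal occupying one spatial cluster year-round is
resident; one shifting seasonally between 2-3 distinct clusters is
migratory; one drifting among >= 4 distinct clusters without returning is
nomadic; an animal not monitored long enough to tell is unknown.

Detection is automated with a spatial clustering + dwell-time rule set:
fixes are assigned online to running-mean cluster centers, small transit
clusters are discarded as travel, and maximal temporal runs within one
cluster lasting at least ``min_dwell_days`` become home-range segments.
Concentrated pauses shorter than 30 days between two home ranges are
stopovers and belong to the migration event, not to the home-range count.

Analysis seasons are delineated from the migratory population's timing
quantiles: spring and fall windows run from the 25% departure date to the
75% arrival date; summer and winter are the complements, winter wrapping
the year boundary.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import DAY, MONITOR_YEAR_START, Track, study_day, study_year

SEASONS = ("winter", "spring", "summer", "fall")


@dataclass
class ClusterParams:
    """Spatial segmentation settings; scale with the species' range size."""

    min_separation: float = 2500.0  # m between distinct range centers
    min_dwell_days: float = 30.0  # minimum stay to count as a home range
    stopover_max_days: float = 30.0
    substantial_fixes: int = 18  # clusters smaller than this are travel noise
    min_span_days: float = 60.0  # shorter monitoring => status unknown

    @property
    def assign_radius(self) -> float:
        return self.min_separation / 2.0


@dataclass
class RangeSegment:
    center: tuple[float, float]
    start: np.datetime64
    end: np.datetime64
    first_fix: int
    last_fix: int
    cluster: int

    @property
    def duration_days(self) -> float:
        return float((self.end - self.start) / DAY)


@dataclass
class MigrationEvent:
    depart: np.datetime64
    arrive: np.datetime64
    from_segment: RangeSegment
    to_segment: RangeSegment
    season_label: str
    stopovers: list[RangeSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.depart < self.arrive:
            raise ValueError("depart must precede arrive")
        for s in self.stopovers:
            if s.duration_days >= 30.0:
                raise ValueError("stopovers must last < 30 days")


@dataclass
class MovementStatus:
    status: str  # migratory | resident | nomadic | unknown
    displacement_km: float | None = None

    def __post_init__(self) -> None:
        if (self.status == "migratory") != (self.displacement_km is not None):
            raise ValueError("displacement_km present iff migratory")


def nsd(track: Track) -> np.ndarray:
    """Net squared displacement (km^2) of each fix from the first fix."""
    if track.n == 0:
        raise ValueError("empty track")
    d = track.xy - track.xy[0]
    return (d[:, 0] ** 2 + d[:, 1] ** 2) / 1e6


def _online_clusters(xy: np.ndarray, params: ClusterParams) -> np.ndarray:
    """Greedy online assignment to running-mean centers."""
    centers: list[np.ndarray] = []
    counts: list[int] = []
    labels = np.empty(len(xy), dtype=int)
    r = params.assign_radius
    for i, p in enumerate(xy):
        if centers:
            d = np.array([np.hypot(*(p - c)) for c in centers])
            j = int(np.argmin(d))
            if d[j] < r:
                labels[i] = j
                counts[j] += 1
                centers[j] += (p - centers[j]) / counts[j]
                continue
        centers.append(p.astype(float).copy())
        counts.append(1)
        labels[i] = len(centers) - 1
    # merge substantial centers within min_separation by weighted centroid
    # linkage: satellite sub-centers fold into their parent range without
    # chaining genuinely distinct ranges together (single link would chain)
    k = len(centers)
    substantial = [i for i in range(k) if counts[i] >= params.substantial_fixes]
    group_of = {i: gi for gi, i in enumerate(substantial)}
    g_centers = [centers[i].copy() for i in substantial]
    g_counts = [float(counts[i]) for i in substantial]
    g_members: list[list[int]] = [[i] for i in substantial]
    active = list(range(len(g_centers)))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                d = float(np.hypot(*(g_centers[a] - g_centers[b])))
                if d < params.min_separation and (best is None or d < best[0]):
                    best = (d, a, b)
        if best is None:
            break
        _, a, b = best
        w = g_counts[a] + g_counts[b]
        g_centers[a] = (g_counts[a] * g_centers[a] + g_counts[b] * g_centers[b]) / w
        g_counts[a] = w
        g_members[a].extend(g_members[b])
        active.remove(b)
    final = {}
    for gi in active:
        for i in g_members[gi]:
            final[i] = gi
    out = np.array([final.get(l, -1) for l in labels])
    return out


def detect_segments(
    track: Track, params: ClusterParams | None = None
) -> list[RangeSegment]:
    """Detect occupancy segments (home ranges and stopovers) in time order.

    Returns every maximal within-cluster run; callers separate home ranges
    (duration >= min_dwell_days) from stopovers (< 30 days between ranges).
    """
    params = params or ClusterParams()
    if track.n == 0:
        return []
    labels = _online_clusters(track.xy, params)
    idx = np.flatnonzero(labels >= 0)
    segments: list[RangeSegment] = []
    if idx.size == 0:
        return segments
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if labels[i] != labels[prev]:
            segments.append(_make_segment(track, labels, run_start, prev))
            run_start = i
        prev = i
    segments.append(_make_segment(track, labels, run_start, prev))
    return segments


def _make_segment(track, labels, first, last) -> RangeSegment:
    members = np.flatnonzero(labels[first : last + 1] == labels[first]) + first
    center = track.xy[members].mean(axis=0)
    return RangeSegment(
        center=(float(center[0]), float(center[1])),
        start=track.t[first],
        end=track.t[last],
        first_fix=int(first),
        last_fix=int(last),
        cluster=int(labels[first]),
    )


def home_segments(
    segments: list[RangeSegment], params: ClusterParams | None = None
) -> list[RangeSegment]:
    params = params or ClusterParams()
    return [s for s in segments if s.duration_days >= params.min_dwell_days]


def extract_events(
    segments: list[RangeSegment], params: ClusterParams | None = None
) -> list[MigrationEvent]:
    """Migration events between consecutive distinct home-range segments.

    The departure is the end of the source segment (its last day in range)
    and the arrival is the start of the target segment. Shorter occupancy
    runs falling between the two homes are stopovers of the event.
    """
    params = params or ClusterParams()
    homes = home_segments(segments, params)
    events = []
    for a, b in zip(homes[:-1], homes[1:]):
        if a.cluster == b.cluster:
            continue
        stopovers = [
            s
            for s in segments
            if s.duration_days < params.stopover_max_days
            and s.start > a.end
            and s.end < b.start
        ]
        month = pd.Timestamp(a.end).month
        label = "spring" if month in (2, 3, 4, 5, 6, 7) else "fall"
        events.append(
            MigrationEvent(
                depart=a.end,
                arrive=b.start,
                from_segment=a,
                to_segment=b,
                season_label=label,
                stopovers=stopovers,
            )
        )
    return events


def classify(
    segments: list[RangeSegment],
    monitoring_span_days: float,
    params: ClusterParams | None = None,
) -> MovementStatus:
    """Movement strategy from the number of distinct home-range clusters."""
    params = params or ClusterParams()
    if monitoring_span_days < params.min_span_days:
        return MovementStatus("unknown")
    homes = home_segments(segments, params)
    clusters = {s.cluster for s in homes}
    if len(clusters) == 0:
        return MovementStatus("unknown")
    if len(clusters) == 1:
        return MovementStatus("resident")
    if len(clusters) >= 4:
        return MovementStatus("nomadic")
    disp = displacement_km(segments, params)
    return MovementStatus("migratory", displacement_km=disp)


def displacement_km(
    segments: list[RangeSegment], params: ClusterParams | None = None
) -> float:
    """Centroid-to-centroid displacement (km) between seasonal ranges.

    One displacement measure per unordered pair of ranges; an animal without
    range fidelity (different summer ranges across years) gets the mean of
    its per-pair measures.
    """
    params = params or ClusterParams()
    events = extract_events(segments, params)
    if not events:
        raise ValueError("displacement requires at least one migration event")
    per_pair: dict[tuple[int, int], list[float]] = {}
    for e in events:
        key = tuple(sorted((e.from_segment.cluster, e.to_segment.cluster)))
        d = np.hypot(
            e.to_segment.center[0] - e.from_segment.center[0],
            e.to_segment.center[1] - e.from_segment.center[1],
        ) / 1000.0
        per_pair.setdefault(key, []).append(float(d))
    return float(np.mean([np.mean(v) for v in per_pair.values()]))


def displacement(status: MovementStatus, segments, params=None) -> float:
    if status.status != "migratory":
        raise ValueError("displacement is defined for migratory animals only")
    return displacement_km(segments, params)


def select_seasonal_events(
    events: list[MigrationEvent],
) -> list[MigrationEvent]:
    """One event per (season, monitoring year): when an animal bounced
    between ranges repeatedly, keep the movement associated with the longest
    stay in either flanking range."""
    chosen: dict[tuple[str, int], MigrationEvent] = {}
    for e in events:
        key = (e.season_label, int(study_year([e.depart])[0]))
        best = chosen.get(key)
        stay = max(e.from_segment.duration_days, e.to_segment.duration_days)
        if best is None or stay > max(
            best.from_segment.duration_days, best.to_segment.duration_days
        ):
            chosen[key] = e
    return sorted(chosen.values(), key=lambda e: e.depart)


TIMING_COLUMNS = [
    "start_05",
    "start_25",
    "mean_start",
    "mean_finish",
    "finish_75",
    "finish_95",
]


def timing_table(events: list[MigrationEvent]) -> pd.DataFrame:
    """Migration-timing quantile table per season.

    Columns: 5% and 25% quantiles of departure, mean departure, mean
    arrival, 75% and 95% quantiles of arrival -- empirical quantiles with
    linear interpolation, on the study-day scale (days since 13 February).
    A season with no events is omitted.
    """
    rows = {}
    for season in ("spring", "fall"):
        ev = [e for e in events if e.season_label == season]
        if not ev:
            continue
        dep = study_day([e.depart for e in ev])
        arr = study_day([e.arrive for e in ev])
        rows[season] = [
            float(np.quantile(dep, 0.05)),
            float(np.quantile(dep, 0.25)),
            float(np.mean(dep)),
            float(np.mean(arr)),
            float(np.quantile(arr, 0.75)),
            float(np.quantile(arr, 0.95)),
        ]
    if not rows:
        raise ValueError("no migration events")
    return pd.DataFrame.from_dict(rows, orient="index", columns=TIMING_COLUMNS)


def study_day_to_date(day: float, year: int = 2021) -> dt.date:
    """Map a study day to a calendar date in a reference (non-leap) year."""
    m, d = MONITOR_YEAR_START
    return dt.date(year, m, d) + dt.timedelta(days=int(round(day)))


@dataclass
class SeasonWindows:
    """Four (start, end) month-day windows partitioning the year.

    Both endpoints are inclusive at day granularity; winter wraps the year
    boundary.
    """

    spring: tuple[tuple[int, int], tuple[int, int]]
    summer: tuple[tuple[int, int], tuple[int, int]]
    fall: tuple[tuple[int, int], tuple[int, int]]
    winter: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        for year in (2021, 2020):  # one common year, one leap year
            counts = np.zeros(4, dtype=int)
            day = dt.date(year, 1, 1)
            while day.year == year:
                md = (day.month, day.day)
                hits = [
                    _in_window(md, w)
                    for w in (self.spring, self.summer, self.fall, self.winter)
                ]
                if sum(hits) != 1:
                    raise ValueError(f"seasons do not partition the year at {md}")
                counts[hits.index(True)] += 1
                day += dt.timedelta(days=1)

    def window(self, season: str):
        return getattr(self, season)

    def season_of(self, times) -> np.ndarray:
        idx = pd.DatetimeIndex(np.asarray(times, dtype="datetime64[s]"))
        md = idx.month.to_numpy() * 100 + idx.day.to_numpy()
        out = np.empty(len(idx), dtype=object)
        for season in SEASONS:
            (sm, sd), (em, ed) = self.window(season)
            s, e = sm * 100 + sd, em * 100 + ed
            hit = (md >= s) & (md <= e) if s <= e else (md >= s) | (md <= e)
            out[hit] = season
        return out

    def season_year(self, times) -> tuple[np.ndarray, np.ndarray]:
        """(season, year) labels; a wrapped winter belongs to its start year."""
        idx = pd.DatetimeIndex(np.asarray(times, dtype="datetime64[s]"))
        md = idx.month.to_numpy() * 100 + idx.day.to_numpy()
        seasons = self.season_of(times)
        years = idx.year.to_numpy().copy()
        for season in SEASONS:
            (sm, sd), (em, ed) = self.window(season)
            s, e = sm * 100 + sd, em * 100 + ed
            if s > e:  # wrapped window: the tail belongs to the start year
                years[(seasons == season) & (md <= e)] -= 1
        return seasons, years


def _in_window(md, window) -> bool:
    start, end = window
    if start <= end:
        return start <= md <= end
    return md >= start or md <= end


def _next_md(md: tuple[int, int]) -> tuple[int, int]:
    d = dt.date(2021, *md) + dt.timedelta(days=1)
    return (d.month, d.day)


def _prev_md(md: tuple[int, int]) -> tuple[int, int]:
    d = dt.date(2021, *md) - dt.timedelta(days=1)
    return (d.month, d.day)


def define_seasons(timing: pd.DataFrame | dict) -> SeasonWindows:
    """Season windows from the migratory population's timing quantiles.

    Spring and fall run from the 25% departure date to the 75% arrival date;
    summer is the gap between them and winter the wrapped remainder. The
    input is a :func:`timing_table` frame (study-day scale) or a mapping
    ``{season: (start date, end date)}`` of explicit quartile dates.
    """
    if isinstance(timing, pd.DataFrame):
        if not {"spring", "fall"} <= set(timing.index):
            raise ValueError("timing table needs both spring and fall rows")
        windows = {
            s: (
                study_day_to_date(timing.loc[s, "start_25"]),
                study_day_to_date(timing.loc[s, "finish_75"]),
            )
            for s in ("spring", "fall")
        }
    else:
        windows = {s: tuple(timing[s]) for s in ("spring", "fall")}
    spring = tuple((d.month, d.day) for d in windows["spring"])
    fall = tuple((d.month, d.day) for d in windows["fall"])
    if not (windows["spring"][0] <= windows["spring"][1] < windows["fall"][0] <= windows["fall"][1]):
        raise ValueError("spring and fall migration windows overlap or are out of order")
    summer = (_next_md(spring[1]), _prev_md(fall[0]))
    winter = (_next_md(fall[1]), _prev_md(spring[0]))
    return SeasonWindows(spring=spring, summer=summer, fall=fall, winter=winter)
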