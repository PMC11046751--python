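"""Synthetic GPS-collar track generator with a ground-truth ledger.

The generator emulates the statistical structure the downstream analysis
assumes for a northern-forest wolf/moose/white-tailed-deer system:

* within-range movement is a discrete Ornstein-Uhlenbeck (OU) process around
  the active range center, which gives a stationary home range and an exact
  analytic transition density for testing;
* migratory ungulates relocate their range center along a shared corridor
  polyline at a fixed transit speed, with synchronous spring departures and
  asynchronous fall departures;
* nomads move among >= 4 distinct centers without returning;
* territorial wolves keep one territory year-round but may redistribute
  within it seasonally (a within-territory offset of the OU center);
* collars take fixes on a regular interval with i.i.d. Bernoulli dropouts,
  GPS error, and optional mortality that either truncates the track or pins
  it at the death site (emulating a collar transmitting from a carcass).

Every simulated truth (strategy, range centers, departure and arrival times,
mortality) is recorded in a :class:`TruthLedger` so recovery tests can score
the analysis against what actually generated the data.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .tracks import HOUR, MONITOR_YEAR_START, Track

SPECIES = ("deer", "moose", "wolf")
STRATEGIES = ("migratory", "resident", "nomadic")

#: default nominal season windows used only to schedule wolf within-territory
#: redistribution in the generator ((start month, day), (end month, day)).
NOMINAL_SEASONS = {
    "spring": ((4, 4), (5, 2)),
    "summer": ((5, 3), (10, 9)),
    "fall": ((10, 10), (11, 28)),
    "winter": ((11, 29), (4, 3)),
}


def _md(ts: np.datetime64) -> tuple[int, int]:
    t = pd.Timestamp(ts)
    return (t.month, t.day)


def _in_window(md, window) -> bool:
    start, end = window
    if start <= end:
        return start <= md <= end
    return md >= start or md <= end


def season_of_md(md: tuple[int, int], windows=NOMINAL_SEASONS) -> str:
    for name, window in windows.items():
        if _in_window(md, window):
            return name
    raise ValueError(f"month-day {md} not covered by season windows")


@dataclass
class AgentSpec:
    """Everything needed to simulate one collared animal."""

    id: str
    species: str
    sex: str
    pack: str | None
    strategy: str
    range_centers: list[tuple[float, float]]
    range_sd: float  # m, stationary OU SD per coordinate
    ou_timescale: float  # h
    depart_day_mean: list[float] = field(default_factory=list)  # study days
    depart_day_sd: list[float] = field(default_factory=list)
    transit_speed: float = 350.0  # m/h
    corridor_waypoints: list[tuple[float, float]] = field(default_factory=list)
    monitor_start: np.datetime64 = np.datetime64("2019-02-13T00:00:00")
    monitor_end: np.datetime64 = np.datetime64("2020-02-13T00:00:00")
    fix_interval: float = 4.0  # h
    dropout_prob: float = 0.02
    gps_error_sd: float = 15.0  # m
    seasonal_offsets: dict[str, tuple[float, float]] | None = None
    season_windows: dict = field(default_factory=lambda: dict(NOMINAL_SEASONS))
    mortality_day: float | None = None  # study day in first monitoring year
    post_mortality_static: bool = False

    def __post_init__(self) -> None:
        self.monitor_start = np.datetime64(self.monitor_start, "s")
        self.monitor_end = np.datetime64(self.monitor_end, "s")
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        n = len(self.range_centers)
        if self.strategy == "resident" and n != 1:
            raise ValueError("resident agents have exactly 1 range center")
        if self.strategy == "migratory" and not 2 <= n <= 3:
            raise ValueError("migratory agents have 2-3 range centers")
        if self.strategy == "nomadic" and n < 4:
            raise ValueError("nomadic agents have >= 4 range centers")
        if self.fix_interval <= 0:
            raise ValueError("fix_interval must be positive")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        if len(self.depart_day_mean) != len(self.depart_day_sd):
            raise ValueError("depart day mean/sd lists differ in length")
        if self.strategy != "resident" and len(self.depart_day_mean) < 1:
            raise ValueError("non-resident agents need departure days")


@dataclass
class AgentTruth:
    """Ground truth for one simulated agent."""

    id: str
    species: str
    strategy: str
    centers: list[tuple[float, float]]
    # (season label, depart, arrive) per realized transition
    migrations: list[tuple[str, np.datetime64, np.datetime64]]
    mortality: np.datetime64 | None


@dataclass
class TruthLedger:
    """One record per simulated agent; the oracle for recovery tests."""

    agents: dict[str, AgentTruth]

    def __post_init__(self) -> None:
        if len(self.agents) == 0:
            raise ValueError("empty ledger")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.agents.values():
            rows.append(
                {
                    "id": a.id,
                    "species": a.species,
                    "strategy": a.strategy,
                    "n_centers": len(a.centers),
                    "centers": json.dumps([list(c) for c in a.centers]),
                    "migrations": json.dumps(
                        [[s, str(d), str(ar)] for s, d, ar in a.migrations]
                    ),
                    "mortality": "" if a.mortality is None else str(a.mortality),
                }
            )
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _polyline_interp(points: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Positions at arc-length `dist` along the polyline `points`."""
    seg = np.diff(points, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    d = np.clip(dist, 0.0, cum[-1])
    out = np.empty((d.size, 2))
    idx = np.clip(np.searchsorted(cum, d, side="right") - 1, 0, len(seglen) - 1)
    frac = np.where(seglen[idx] > 0, (d - cum[idx]) / np.where(seglen[idx] > 0, seglen[idx], 1.0), 0.0)
    out = points[idx] + frac[:, None] * seg[idx]
    return out


def _year_anchors(spec: AgentSpec) -> list[np.datetime64]:
    """13-February anchors of every monitoring year touching the window."""
    start = pd.Timestamp(spec.monitor_start)
    end = pd.Timestamp(spec.monitor_end)
    m, d = MONITOR_YEAR_START
    y0 = start.year if (start.month, start.day) >= (m, d) else start.year - 1
    anchors = []
    y = y0
    while True:
        a = pd.Timestamp(year=y, month=m, day=d)
        if a > end:
            break
        anchors.append(np.datetime64(a, "s"))
        y += 1
    return anchors


def _resolve_transitions(spec: AgentSpec, rng: np.random.Generator):
    """Draw departure times and build the realized center itinerary.

    Returns a list of (depart_ts, route points array, speed) in time order,
    starting from range_centers[0].
    """
    transitions = []
    centers = [np.asarray(c, float) for c in spec.range_centers]
    if spec.strategy == "resident":
        return transitions
    current = 0
    if spec.strategy == "migratory":
        # Winter range is centers[0]; summer ranges cycle through centers[1:]
        # (a third center, when present, models summer-range infidelity).
        summer_pool = list(range(1, len(centers)))
        for yi, anchor in enumerate(_year_anchors(spec)):
            summer = summer_pool[yi % len(summer_pool)]
            for j, (mean, sd) in enumerate(
                zip(spec.depart_day_mean, spec.depart_day_sd)
            ):
                day = rng.normal(mean, sd)
                depart = anchor + np.timedelta64(int(round(day * 86400)), "s")
                if not (spec.monitor_start <= depart < spec.monitor_end):
                    continue
                target = summer if j % 2 == 0 else 0
                if target == current:
                    continue
                waypoints = [np.asarray(w, float) for w in spec.corridor_waypoints]
                if current != 0:  # returning: traverse the corridor backwards
                    waypoints = waypoints[::-1]
                route = np.array([centers[current]] + waypoints + [centers[target]])
                transitions.append((depart, route, spec.transit_speed))
                current = target
    else:  # nomadic: march through the centers once, no return
        anchor = _year_anchors(spec)[0]
        for j, (mean, sd) in enumerate(zip(spec.depart_day_mean, spec.depart_day_sd)):
            if j + 1 >= len(centers):
                break
            day = rng.normal(mean, sd)
            depart = anchor + np.timedelta64(int(round(day * 86400)), "s")
            if not (spec.monitor_start <= depart < spec.monitor_end):
                continue
            route = np.array([centers[j], centers[j + 1]])
            transitions.append((depart, route, spec.transit_speed))
    transitions.sort(key=lambda tr: tr[0])
    return transitions


def _center_path(spec: AgentSpec, times: np.ndarray, transitions) -> np.ndarray:
    th = (times - spec.monitor_start) / HOUR
    centers = np.tile(np.asarray(spec.range_centers[0], float), (times.size, 1))
    for depart, route, speed in transitions:
        d0 = float((depart - spec.monitor_start) / HOUR)
        seg = np.diff(route, axis=0)
        length = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
        dur = length / speed
        moving = (th >= d0) & (th < d0 + dur)
        after = th >= d0 + dur
        if moving.any():
            centers[moving] = _polyline_interp(route, (th[moving] - d0) * speed)
        centers[after] = route[-1]
    if spec.seasonal_offsets:
        mds = [(t.month, t.day) for t in pd.DatetimeIndex(times)]
        for i, md in enumerate(mds):
            off = spec.seasonal_offsets.get(
                season_of_md(md, spec.season_windows)
            )
            if off is not None:
                centers[i] += off
    return centers


def _simulate_with_truth(spec: AgentSpec, seed: int) -> tuple[Track, AgentTruth]:
    span_h = float((spec.monitor_end - spec.monitor_start) / HOUR)
    if span_h < spec.fix_interval:
        raise ValueError("monitoring window shorter than one fix interval")
    rng = np.random.default_rng(seed)
    n = int(np.floor(span_h / spec.fix_interval)) + 1
    times = spec.monitor_start + (
        np.arange(n) * spec.fix_interval * 3600
    ).astype("timedelta64[s]")

    transitions = _resolve_transitions(spec, rng)
    centers = _center_path(spec, times, transitions)

    # Exact discrete OU around the (possibly moving) center; deviation starts
    # at the center itself, so net squared displacement plateaus at
    # 2 * range_sd^2 for residents.
    a = np.exp(-spec.fix_interval / spec.ou_timescale)
    innov_sd = spec.range_sd * np.sqrt(1.0 - a * a)
    eps = rng.normal(0.0, innov_sd, size=(n, 2))
    eps[0] = 0.0
    dev = lfilter([1.0], [1.0, -a], eps, axis=0)
    xy = centers + dev + rng.normal(0.0, spec.gps_error_sd, size=(n, 2))

    mortality_ts = None
    if spec.mortality_day is not None:
        anchor = _year_anchors(spec)[0]
        mortality_ts = anchor + np.timedelta64(
            int(round(spec.mortality_day * 86400)), "s"
        )
        dead = times >= mortality_ts
        if dead.any():
            k = int(np.argmax(dead))
            if spec.post_mortality_static:
                carcass = xy[max(k - 1, 0)]
                xy[dead] = carcass + rng.normal(0.0, 3.0, size=(int(dead.sum()), 2))
            else:
                times, xy = times[:k], xy[:k]

    keep = rng.random(times.size) >= spec.dropout_prob
    times, xy = times[keep], xy[keep]

    migrations = []
    for depart, route, speed in transitions:
        seg = np.diff(route, axis=0)
        length = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
        arrive = depart + np.timedelta64(int(round(length / speed * 3600)), "s")
        label = "spring" if pd.Timestamp(depart).month in (2, 3, 4, 5, 6, 7) else "fall"
        migrations.append((label, depart, arrive))

    track = Track(spec.id, spec.species, spec.sex, spec.pack, times, xy)
    truth = AgentTruth(
        id=spec.id,
        species=spec.species,
        strategy=spec.strategy,
        centers=[tuple(map(float, c)) for c in spec.range_centers],
        migrations=migrations,
        mortality=mortality_ts,
    )
    return track, truth


def simulate_track(spec: AgentSpec, seed: int) -> Track:
    """Simulate one collar track; same spec and seed give identical output."""
    track, _ = _simulate_with_truth(spec, seed)
    return track


# ---------------------------------------------------------------------------
# Population-level generation
# ---------------------------------------------------------------------------


@dataclass
class PopulationConfig:
    """Counts, geometry and timing for a whole synthetic study population.

    Distances in meters, speeds in m/h, departure days in study days
    (days since 13 February). Spring departures are synchronous (small sd),
    fall departures asynchronous (large sd), matching the migratory system
    the analysis targets.
    """

    counts: dict = field(
        default_factory=lambda: {
            "deer": {"migratory": 20, "resident": 10, "nomadic": 0},
            "moose": {"migratory": 2, "resident": 4, "nomadic": 4},
            "wolf": {"resident": 6},
        }
    )
    monitor_start: str = "2019-02-13T00:00:00"
    monitor_end: str = "2020-02-13T00:00:00"
    corridor_waypoints: list[tuple[float, float]] = field(
        default_factory=lambda: [
            (0.0, 2000.0),
            (800.0, 6000.0),
            (-800.0, 10000.0),
            (0.0, 13000.0),
        ]
    )
    deer_winter_center: tuple[float, float] = (0.0, -500.0)
    deer_winter_spread: float = 1200.0
    deer_summer_xlim: tuple[float, float] = (-6000.0, 6000.0)
    deer_summer_ylim: tuple[float, float] = (14500.0, 18500.0)
    deer_resident_xlim: tuple[float, float] = (-6000.0, 6000.0)
    deer_resident_ylim: tuple[float, float] = (-4000.0, -1000.0)
    moose_xlim: tuple[float, float] = (-8000.0, 8000.0)
    moose_ylim: tuple[float, float] = (1000.0, 17000.0)
    range_sd: dict = field(
        default_factory=lambda: {"deer": 600.0, "moose": 1000.0, "wolf": 2000.0}
    )
    ou_timescale: dict = field(
        default_factory=lambda: {"deer": 6.0, "moose": 8.0, "wolf": 2.0}
    )
    transit_speed: dict = field(default_factory=lambda: {"deer": 350.0, "moose": 300.0})
    spring_day: tuple[float, float] = (56.0, 2.0)  # ~10 April, synchronous
    fall_day: tuple[float, float] = (255.0, 12.0)  # ~late October, asynchronous
    nomad_day_spacing: float = 85.0
    wolf_pack_centers: dict = field(
        default_factory=lambda: {
            "SW": (-3200.0, 2500.0),
            "NW": (-3500.0, 8500.0),
            "NE": (3300.0, 10500.0),
        }
    )
    # Magnitude (m) of the within-territory redistribution of wolf activity
    # toward the deer corridor, per season. Non-zero fall bias encodes the
    # prey-switching scenario; set all to 0 for strictly stationary wolves.
    wolf_season_bias: dict = field(
        default_factory=lambda: {"spring": 0.0, "summer": 500.0, "fall": 2000.0, "winter": 0.0}
    )
    n_floaters: int = 0
    floater_range_sd: float = 6500.0
    fix_interval: float = 4.0
    dropout_prob: float = 0.02
    gps_error_sd: float = 15.0
    mortality_prob: float = 0.0
    season_windows: dict = field(default_factory=lambda: dict(NOMINAL_SEASONS))


def _uniform_in(rng, xlim, ylim):
    return (rng.uniform(*xlim), rng.uniform(*ylim))


def _nomad_centers(rng, cfg: PopulationConfig, sd: float, k: int):
    """Distinct nomad ranges: consecutive steps of 7-11 SD, all pairs
    at least 6 SD apart (relaxed slowly if the study box is too tight)."""
    xlim = (cfg.moose_xlim[0] - 4.0 * sd, cfg.moose_xlim[1] + 4.0 * sd)
    ylim = (cfg.moose_ylim[0] - 4.0 * sd, cfg.moose_ylim[1] + 4.0 * sd)
    centers = [np.asarray(_uniform_in(rng, xlim, ylim))]
    floor = 6.0 * sd
    attempts = 0
    while len(centers) < k:
        ang = rng.uniform(0, 2 * np.pi)
        step = rng.uniform(7.0 * sd, 11.0 * sd)
        cand = centers[-1] + step * np.array([np.cos(ang), np.sin(ang)])
        cand[0] = np.clip(cand[0], *xlim)
        cand[1] = np.clip(cand[1], *ylim)
        attempts += 1
        if attempts % 200 == 0:
            floor *= 0.9
        if all(np.hypot(*(cand - c)) > floor for c in centers):
            centers.append(cand)
    return [tuple(map(float, c)) for c in centers]


def _toward_corridor(center, waypoints, magnitude):
    """Offset of given magnitude from `center` toward the nearest corridor waypoint."""
    if magnitude == 0.0:
        return (0.0, 0.0)
    pts = np.asarray(waypoints, float)
    d = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    tgt = pts[int(np.argmin(d))]
    vec = tgt - np.asarray(center, float)
    norm = np.hypot(*vec)
    if norm == 0:
        return (0.0, 0.0)
    off = vec / norm * min(magnitude, norm)
    return (float(off[0]), float(off[1]))


def build_specs(config: PopulationConfig, seed: int) -> list[AgentSpec]:
    """Deterministically expand a population config into agent specs."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 901]))
    specs: list[AgentSpec] = []
    start = np.datetime64(config.monitor_start, "s")
    end = np.datetime64(config.monitor_end, "s")
    common = dict(
        monitor_start=start,
        monitor_end=end,
        fix_interval=config.fix_interval,
        dropout_prob=config.dropout_prob,
        gps_error_sd=config.gps_error_sd,
        season_windows=config.season_windows,
    )
    counter = 0

    def next_id(species):
        nonlocal counter
        counter += 1
        return f"{species[0].upper()}{counter:03d}"

    for species in ("deer", "moose"):
        sd = config.range_sd[species]
        tau = config.ou_timescale[species]
        speed = config.transit_speed[species]
        for strategy, k in sorted(config.counts.get(species, {}).items()):
            for _ in range(int(k)):
                sex = "F" if rng.random() < 0.5 else "M"
                mort = None
                if config.mortality_prob > 0 and rng.random() < config.mortality_prob:
                    mort = float(rng.uniform(120.0, 330.0))
                if strategy == "migratory":
                    if species == "deer":
                        winter = tuple(
                            np.asarray(config.deer_winter_center)
                            + rng.uniform(-1, 1, 2) * config.deer_winter_spread
                        )
                        summer = _uniform_in(
                            rng, config.deer_summer_xlim, config.deer_summer_ylim
                        )
                        waypoints = list(config.corridor_waypoints)
                    else:
                        winter = _uniform_in(rng, config.moose_xlim, config.moose_ylim)
                        ang = rng.uniform(0, 2 * np.pi)
                        disp = rng.uniform(3000.0, 8000.0)
                        summer = (
                            winter[0] + disp * np.cos(ang),
                            winter[1] + disp * np.sin(ang),
                        )
                        waypoints = []
                    specs.append(
                        AgentSpec(
                            id=next_id(species),
                            species=species,
                            sex=sex,
                            pack=None,
                            strategy="migratory",
                            range_centers=[tuple(map(float, winter)), tuple(map(float, summer))],
                            range_sd=sd,
                            ou_timescale=tau,
                            depart_day_mean=[config.spring_day[0], config.fall_day[0]],
                            depart_day_sd=[config.spring_day[1], config.fall_day[1]],
                            transit_speed=speed,
                            corridor_waypoints=waypoints,
                            mortality_day=mort,
                            **common,
                        )
                    )
                elif strategy == "resident":
                    if species == "deer":
                        center = _uniform_in(
                            rng, config.deer_resident_xlim, config.deer_resident_ylim
                        )
                    else:
                        center = _uniform_in(rng, config.moose_xlim, config.moose_ylim)
                    specs.append(
                        AgentSpec(
                            id=next_id(species),
                            species=species,
                            sex=sex,
                            pack=None,
                            strategy="resident",
                            range_centers=[tuple(map(float, center))],
                            range_sd=sd,
                            ou_timescale=tau,
                            mortality_day=mort,
                            **common,
                        )
                    )
                else:  # nomadic
                    k_centers = int(rng.integers(4, 6))
                    centers = _nomad_centers(rng, config, sd, k_centers)
                    first = float(rng.uniform(40.0, 70.0))
                    days = [
                        first + j * config.nomad_day_spacing + rng.uniform(-12, 12)
                        for j in range(k_centers - 1)
                    ]
                    specs.append(
                        AgentSpec(
                            id=next_id(species),
                            species=species,
                            sex=sex,
                            pack=None,
                            strategy="nomadic",
                            range_centers=centers,
                            range_sd=sd,
                            ou_timescale=tau,
                            depart_day_mean=days,
                            depart_day_sd=[1.0] * len(days),
                            transit_speed=speed,
                            mortality_day=mort,
                            **common,
                        )
                    )

    packs = sorted(config.wolf_pack_centers)
    n_wolves = int(config.counts.get("wolf", {}).get("resident", 0))
    for i in range(n_wolves):
        pack = packs[i % len(packs)]
        base = np.asarray(config.wolf_pack_centers[pack], float)
        center = tuple(base + rng.uniform(-1, 1, 2) * 800.0)
        offsets = {
            s: _toward_corridor(center, config.corridor_waypoints, mag)
            for s, mag in config.wolf_season_bias.items()
        }
        specs.append(
            AgentSpec(
                id=next_id("wolf"),
                species="wolf",
                sex="F" if i % 2 == 0 else "M",
                pack=pack,
                strategy="resident",
                range_centers=[tuple(map(float, center))],
                range_sd=config.range_sd["wolf"],
                ou_timescale=config.ou_timescale["wolf"],
                seasonal_offsets=offsets,
                **common,
            )
        )
    for i in range(int(config.n_floaters)):
        center = (float(rng.uniform(-4000, 4000)), float(rng.uniform(0, 13000)))
        specs.append(
            AgentSpec(
                id=next_id("wolf"),
                species="wolf",
                sex="F" if i % 2 == 0 else "M",
                pack=sorted(config.wolf_pack_centers)[i % len(packs)],
                strategy="resident",
                range_centers=[center],
                range_sd=config.floater_range_sd,
                ou_timescale=config.ou_timescale["wolf"],
                **common,
            )
        )
    return specs


def simulate_population(
    config: PopulationConfig, seed: int
) -> tuple[list[Track], TruthLedger]:
    """Simulate every agent in the config; deterministic under the seed."""
    total = sum(int(v) for sp in config.counts.values() for v in sp.values()) + int(
        config.n_floaters
    )
    if total <= 0:
        raise ValueError("population config requests zero agents")
    specs = build_specs(config, seed)
    child_seeds = np.random.SeedSequence([int(seed), 902]).generate_state(len(specs))
    tracks, truths = [], {}
    for spec, s in zip(specs, child_seeds):
        track, truth = _simulate_with_truth(spec, int(s) % (2**31))
        tracks.append(track)
        truths[truth.id] = truth
    return tracks, TruthLedger(truths)
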