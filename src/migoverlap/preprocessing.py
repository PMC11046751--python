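"""Track regularization and censoring of anomalous or post-mortality fixes.

The cleaning rules mirror standard GPS-collar practice for 4-h ungulate and
wolf collars: snap fixes to a regular interval grid, truncate terminal
low-movement runs attributable to mortality, drop fixes implying implausible
movement speeds, and drop out-and-back spikes flagged jointly by small first
passage time and a near-reversal turning angle. Censoring only ever removes
fixes; the output is always a subsequence of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracks import HOUR, Track


@dataclass
class QCConfig:
    target_interval: float = 4.0  # h
    snap_tolerance: float = 2.0  # h
    vmax: float = 10.8  # km/h
    fpt_radius: float = 300.0  # m
    fpt_max: float = 1.0  # h
    turn_lo: float = 179.0  # degrees
    turn_hi: float = 181.0
    mortality_window: float = 48.0  # h
    mortality_dist: float = 50.0  # m

    def __post_init__(self) -> None:
        if self.vmax <= 0:
            raise ValueError("vmax must be positive")
        if self.turn_lo >= self.turn_hi:
            raise ValueError("turn_lo must be below turn_hi")
        if self.fpt_radius <= 0:
            raise ValueError("fpt_radius must be positive")


def regularize(track: Track, cfg: QCConfig) -> Track:
    """Snap fixes onto the target-interval grid anchored at the first fix.

    Each grid slot takes the nearest original fix within ``snap_tolerance``;
    slots with no candidate stay empty; no fix is used twice. Output
    timestamps lie exactly on the grid.
    """
    if track.n == 0:
        return track
    th = track.hours()
    if np.any(np.diff(th) <= 0):
        raise ValueError("track must be strictly time-ordered")
    slot = np.rint(th / cfg.target_interval).astype(int)
    offset = np.abs(th - slot * cfg.target_interval)
    keep_idx = []
    slot_times = []
    for s in np.unique(slot):
        members = np.flatnonzero(slot == s)
        best = members[np.argmin(offset[members])]
        if offset[best] <= cfg.snap_tolerance:
            keep_idx.append(best)
            slot_times.append(s)
    t0 = track.t[0]
    new_t = t0 + (
        np.asarray(slot_times, float) * cfg.target_interval * 3600
    ).astype("timedelta64[s]")
    return Track(track.id, track.species, track.sex, track.pack, new_t, track.xy[keep_idx])


def censor_mortality(track: Track, cfg: QCConfig) -> Track:
    """Remove a terminal run of fixes consistent with a dead/shed collar.

    A terminal run qualifies when it spans at least ``mortality_window``
    hours and every fix of the run lies within ``mortality_dist`` of the
    run's centroid (net movement below the threshold; GPS jitter at a
    carcass still accumulates path length, so cumulative path is the wrong
    measure). The maximal qualifying run is removed entirely. Interior
    low-movement runs are retained: a living animal may rest and resume
    moving.
    """
    if track.n < 2:
        return track
    xy = track.xy
    n = track.n
    # suffix bounding-box diagonal, computed from the end
    rx = np.maximum.accumulate(xy[::-1, 0]) - np.minimum.accumulate(xy[::-1, 0])
    ry = np.maximum.accumulate(xy[::-1, 1]) - np.minimum.accumulate(xy[::-1, 1])
    diag = np.hypot(rx, ry)[::-1]  # diag[s] for suffix starting at s
    dur = (track.t[-1] - track.t) / HOUR
    # diagonal bounds the centroid radius: diag/(2*sqrt(2)) <= r_max <= diag
    candidates = np.flatnonzero(
        (diag <= 2.0 * np.sqrt(2.0) * cfg.mortality_dist)
        & (dur >= cfg.mortality_window)
    )
    for s in candidates:
        suffix = xy[s:]
        r = np.hypot(*(suffix - suffix.mean(axis=0)).T).max()
        if r <= cfg.mortality_dist:
            return track.subset(np.arange(s))
    return track


def filter_speed(track: Track, cfg: QCConfig) -> Track:
    """Iteratively remove fixes with implausible incoming speed.

    The later fix of an offending consecutive pair is removed (the earlier
    one is corroborated by prior history); speeds are recomputed after each
    removal until no pair exceeds ``vmax``.
    """
    t = track.t.copy()
    xy = track.xy.copy()
    keep = np.arange(track.n)
    while keep.size >= 2:
        th = (t[keep] - t[keep][0]) / HOUR
        d_km = np.hypot(*np.diff(xy[keep], axis=0).T) / 1000.0
        dt_h = np.diff(th)
        speed = d_km / dt_h
        bad = np.flatnonzero(speed > cfg.vmax)
        if bad.size == 0:
            break
        keep = np.delete(keep, bad[0] + 1)
    return track.subset(keep)


def first_passage_time(track: Track, radius: float) -> np.ndarray:
    """First passage time (h) through a circle of `radius` around each fix.

    FPT(i) = time to first exit walking forward plus time to first exit
    walking backward, with the crossing instant linearly interpolated along
    track segments. If the circle is never exited on one side the FPT is
    censored (NaN).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    th = track.hours()
    xy = track.xy
    n = track.n
    out = np.full(n, np.nan)

    def _exit_time(i: int, direction: int) -> float:
        c = xy[i]
        j = i
        while 0 <= j + direction < n:
            k = j + direction
            if np.hypot(*(xy[k] - c)) > radius:
                # crossing is on segment j -> k; interpolate
                p0, p1 = xy[j], xy[k]
                d = p1 - p0
                f = p0 - c
                a = d @ d
                b = 2.0 * (f @ d)
                cc = f @ f - radius * radius
                disc = b * b - 4 * a * cc
                disc = max(disc, 0.0)
                roots = [(-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a)]
                roots = [r for r in roots if -1e-12 <= r <= 1 + 1e-12]
                frac = min(roots) if roots else 1.0
                return abs(th[k] - th[j]) * frac + abs(th[j] - th[i])
            j = k
        return np.nan

    for i in range(n):
        fwd = _exit_time(i, +1)
        bwd = _exit_time(i, -1)
        out[i] = fwd + bwd  # NaN-propagating: censored if either side never exits
    return out


def turning_angles(track: Track) -> np.ndarray:
    """Relative turning angle (deg, in [0, 180]) at each interior fix.

    0 means continuing straight; 180 means an exact reversal. Endpoints and
    fixes adjacent to zero-length steps are NaN.
    """
    xy = track.xy
    out = np.full(track.n, np.nan)
    v1 = xy[1:-1] - xy[:-2]
    v2 = xy[2:] - xy[1:-1]
    n1 = np.hypot(*v1.T)
    n2 = np.hypot(*v2.T)
    ok = (n1 > 0) & (n2 > 0)
    cosang = np.full(v1.shape[0], np.nan)
    cosang[ok] = np.clip(
        (v1[ok] * v2[ok]).sum(axis=1) / (n1[ok] * n2[ok]), -1.0, 1.0
    )
    out[1:-1] = np.degrees(np.arccos(cosang))
    return out


def filter_fpt_turn(track: Track, cfg: QCConfig) -> Track:
    """Censor out-and-back spike fixes.

    A fix is removed only when BOTH its first passage time is at most
    ``fpt_max`` hours AND its turning angle falls in the near-reversal band.
    The configured [turn_lo, turn_hi] band (e.g. 179-181 degrees) maps onto
    [turn_lo, 180] in the relative-angle convention used here.
    """
    if track.n < 3:
        return track
    fpt = first_passage_time(track, cfg.fpt_radius)
    turn = turning_angles(track)
    lo = min(cfg.turn_lo, 360.0 - cfg.turn_hi)
    with np.errstate(invalid="ignore"):
        bad = (fpt <= cfg.fpt_max) & (turn >= lo)
    return track.subset(~np.nan_to_num(bad, nan=False).astype(bool))


def qc_pipeline(track: Track, cfg: QCConfig) -> tuple[Track, dict]:
    """Full cleaning chain; returns the cleaned track and per-rule counts."""
    log = {}
    out = regularize(track, cfg)
    log["regularize_removed"] = track.n - out.n
    before = out.n
    out = censor_mortality(out, cfg)
    log["mortality_removed"] = before - out.n
    before = out.n
    out = filter_speed(out, cfg)
    log["speed_removed"] = before - out.n
    before = out.n
    out = filter_fpt_turn(out, cfg)
    log["fpt_turn_removed"] = before - out.n
    return out, log
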