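"""Mechanistic range-shift analysis for territorial predators.

The migratory white-noise range-shift model treats relocations as
independent isotropic bivariate normal observations about a mean path that
sits at a first center until the shift starts at ``t1``, moves linearly to
a second center over ``dt`` hours, and stays there. Because the centers and
the noise SD profile out in closed form (weighted least squares), the
likelihood is maximized over (t1, dt) only. A likelihood-ratio test against
the single-center null (chi-square, df = 4 extra free parameters: second
center, shift start and duration) decides whether a shift occurred; profile
likelihood gives 95% confidence intervals for shift timing and duration.

Candidate shift times come from a 3-cluster scan: k-means on coordinates,
with candidates at the temporal boundaries between maximal runs of cluster
assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.cluster import KMeans

from .tracks import HOUR, Track

_CHI2_1_95 = stats.chi2.ppf(0.95, 1)  # profile-likelihood cutoff (2*dll)


@dataclass
class RangeShiftFit:
    mu1: tuple[float, float]
    mu2: tuple[float, float]
    t1: np.datetime64  # shift start
    t1_hours: float  # hours since first fix
    dt_days: float  # shift duration
    sigma: float  # white-noise SD per coordinate (m)
    loglik_alt: float
    loglik_null: float
    p_value: float
    ci_t1: tuple[np.datetime64, np.datetime64] | None = None
    ci_dt_days: tuple[float, float] | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged:
            if self.dt_days < 0:
                raise ValueError("dt must be >= 0")
            if self.loglik_alt < self.loglik_null - 1e-9:
                raise ValueError("alternative likelihood must dominate the null")
            if not 0 <= self.p_value <= 1:
                raise ValueError("p_value must lie in [0, 1]")


def _profile_bound(prof, x_hat, cut, lo, hi, direction, step=6.0):
    """Walk outward from the MLE until the profile drops below the cutoff,
    then refine the crossing by bisection."""
    x_prev = x_hat
    x = x_hat + direction * step
    while lo <= x <= hi:
        if prof(x) < cut:
            break
        x_prev = x
        x = x + direction * step
    else:
        return float(np.clip(x, lo, hi))
    a, b = sorted((x_prev, x))
    for _ in range(25):
        m = 0.5 * (a + b)
        if prof(m) >= cut:
            if direction > 0:
                a = m
            else:
                b = m
        else:
            if direction > 0:
                b = m
            else:
                a = m
        if b - a < 0.25:
            break
    return 0.5 * (a + b)


def cluster_scan(
    track: Track,
    k: int = 3,
    seed: int = 0,
    seasons=None,
    max_candidates: int = 5,
) -> list[float]:
    """Candidate shift times (hours since first fix) from a k-means scan.

    When season windows are given, the scan runs on the track restricted to
    each contiguous three-season window and candidates are pooled; otherwise
    it runs once on the whole track. Candidates are the temporal boundaries
    between maximal runs of cluster assignment, de-duplicated within one day
    and capped at the ``max_candidates`` with the longest flanking runs.
    """
    if track.n < 30:
        raise ValueError("cluster scan needs at least 30 fixes")
    th = track.hours()
    windows = [None]
    if seasons is not None:
        order = ["winter", "spring", "summer", "fall"]
        windows = [tuple(order[(i + j) % 4] for j in range(3)) for i in range(4)]
        labels = seasons.season_of(track.t)
    raw: list[tuple[float, float]] = []  # (candidate hours, flank score)
    for window in windows:
        if window is None:
            sel = np.arange(track.n)
        else:
            sel = np.flatnonzero(np.isin(labels, window))
        if sel.size < 30:
            continue
        km = KMeans(n_clusters=k, n_init=5, random_state=seed)
        assign = km.fit_predict(track.xy[sel])
        change = np.flatnonzero(np.diff(assign) != 0)
        bounds = np.concatenate([[0], change + 1, [sel.size]])
        run_len = np.diff(bounds)
        for j, c in enumerate(change):
            t_mid = 0.5 * (th[sel[c]] + th[sel[c + 1]])
            score = min(run_len[j], run_len[j + 1])
            raw.append((float(t_mid), float(score)))
    raw.sort(key=lambda x: (-x[1], x[0]))
    out: list[float] = []
    for t_mid, _ in raw:
        if all(abs(t_mid - o) > 24.0 for o in out):
            out.append(t_mid)
        if len(out) >= max_candidates:
            break
    return sorted(out)


def _profile_loglik(th: np.ndarray, xy: np.ndarray, t1: float, dt: float):
    """Log-likelihood at (t1, dt) with centers and sigma profiled out."""
    dt = max(dt, 1e-6)
    w = np.clip((th - t1) / dt, 0.0, 1.0)
    X = np.column_stack([1.0 - w, w])
    beta, *_ = np.linalg.lstsq(X, xy, rcond=None)
    resid = xy - X @ beta
    rss = float((resid**2).sum())
    n_obs = 2 * len(th)
    rss = max(rss, 1e-12)
    ll = -0.5 * n_obs * (np.log(2 * np.pi * rss / n_obs) + 1.0)
    return ll, beta, np.sqrt(rss / n_obs)


def fit_shift(
    track: Track,
    candidate: float | np.datetime64,
    seed: int = 0,
    compute_ci: bool = True,
    dt_fixed: float | None = None,
    n_restarts: int = 5,
) -> RangeShiftFit:
    """Fit the white-noise range-shift model starting from a candidate t1.

    ``candidate`` is hours since the first fix (or a timestamp). Bounded
    quasi-Newton (L-BFGS-B) restarts from jittered candidates; the best
    restart wins. ``dt_fixed`` pins the shift duration (0 = step shift).
    """
    th = track.hours()
    xy = track.xy
    if isinstance(candidate, np.datetime64) or hasattr(candidate, "to_datetime64"):
        candidate = float((np.datetime64(candidate, "s") - track.t[0]) / HOUR)
    span = float(th[-1] - th[0])
    if not 0.0 <= candidate <= span:
        raise ValueError("candidate must lie inside the monitoring span")
    rng = np.random.default_rng(seed)

    # null: one center
    mu0 = xy.mean(axis=0)
    rss0 = float(((xy - mu0) ** 2).sum())
    n_obs = 2 * len(th)
    ll0 = -0.5 * n_obs * (np.log(2 * np.pi * rss0 / n_obs) + 1.0)

    if dt_fixed is None:

        def neg(params):
            t1, dt = params
            return -_profile_loglik(th, xy, t1, dt)[0]

        bounds = [(0.0, span), (1e-3, span)]
        starts = [(candidate, 24.0 * d) for d in (1.0, 5.0, 15.0)]
        for _ in range(max(n_restarts - len(starts), 0)):
            starts.append(
                (
                    float(np.clip(candidate + rng.normal(0, 72.0), 0, span)),
                    float(rng.uniform(6.0, 24.0 * 20)),
                )
            )
        best = None
        for s in starts[:n_restarts]:
            res = optimize.minimize(neg, s, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            return RangeShiftFit(
                (np.nan, np.nan), (np.nan, np.nan), track.t[0], np.nan, np.nan,
                np.nan, np.nan, np.nan, np.nan, converged=False,
            )
        t1_hat, dt_hat = float(best.x[0]), float(best.x[1])
    else:
        t1_hat, dt_hat = float(candidate), float(dt_fixed)
        res = optimize.minimize_scalar(
            lambda t1: -_profile_loglik(th, xy, t1, dt_hat)[0],
            bounds=(0.0, span), method="bounded",
        )
        t1_hat = float(res.x)

    ll1, beta, sigma = _profile_loglik(th, xy, t1_hat, dt_hat)
    ll1 = max(ll1, ll0)  # the null is nested in the shift model's closure
    p = float(stats.chi2.sf(2.0 * (ll1 - ll0), df=4))

    ci_t1 = ci_dt = None
    if compute_ci and dt_fixed is None:
        cut = ll1 - _CHI2_1_95 / 2.0

        def prof_t1(t1):
            r = optimize.minimize_scalar(
                lambda d: -_profile_loglik(th, xy, t1, d)[0],
                bounds=(1e-3, span), method="bounded",
                options={"xatol": 0.1},
            )
            return -r.fun

        def prof_dt(d):
            r = optimize.minimize_scalar(
                lambda t1: -_profile_loglik(th, xy, t1, d)[0],
                bounds=(0.0, span), method="bounded",
                options={"xatol": 0.1},
            )
            return -r.fun

        lo = _profile_bound(prof_t1, t1_hat, cut, 0.0, span, direction=-1)
        hi = _profile_bound(prof_t1, t1_hat, cut, 0.0, span, direction=+1)
        ci_t1 = (
            track.t[0] + np.timedelta64(int(round(lo * 3600)), "s"),
            track.t[0] + np.timedelta64(int(round(hi * 3600)), "s"),
        )
        lo = _profile_bound(prof_dt, dt_hat, cut, 1e-3, span, direction=-1)
        hi = _profile_bound(prof_dt, dt_hat, cut, 1e-3, span, direction=+1)
        ci_dt = (lo / 24.0, hi / 24.0)

    return RangeShiftFit(
        mu1=(float(beta[0, 0]), float(beta[0, 1])),
        mu2=(float(beta[1, 0]), float(beta[1, 1])),
        t1=track.t[0] + np.timedelta64(int(round(t1_hat * 3600)), "s"),
        t1_hours=t1_hat,
        dt_days=dt_hat / 24.0,
        sigma=float(sigma),
        loglik_alt=float(ll1),
        loglik_null=float(ll0),
        p_value=p,
        ci_t1=ci_t1,
        ci_dt_days=ci_dt,
    )


def classify_shift(fit: RangeShiftFit, alpha: float = 0.05) -> str:
    """'shift' if the likelihood-ratio test rejects at alpha, else 'no_shift'."""
    if not fit.converged:
        raise ValueError("cannot classify a non-converged fit")
    return "shift" if fit.p_value < alpha else "no_shift"


def test_track(
    track: Track,
    k: int = 3,
    seed: int = 0,
    seasons=None,
    alpha: float = 0.05,
    compute_ci: bool = False,
    max_candidates: int = 1,
) -> RangeShiftFit:
    """Scan for the best-supported candidate shift and fit one model to it.

    One model is fit per animal, starting at the candidate with the longest
    flanking cluster runs (raise ``max_candidates`` to fit several and keep
    the best-likelihood fit, at the cost of extra selection optimism).
    """
    candidates = cluster_scan(
        track, k=k, seed=seed, seasons=seasons, max_candidates=max_candidates
    )
    if not candidates:
        candidates = [float(track.hours()[-1] / 2.0)]
    fits = [
        fit_shift(track, c, seed=seed, compute_ci=False) for c in candidates
    ]
    fits = [f for f in fits if f.converged]
    best = max(fits, key=lambda f: f.loglik_alt)
    if compute_ci and best.p_value < alpha:
        best = fit_shift(track, best.t1_hours, seed=seed, compute_ci=True)
    return best
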