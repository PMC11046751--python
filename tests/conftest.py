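import numpy as np
import pytest

from migoverlap.tracks import Track

T0 = np.datetime64("2019-02-13T00:00:00")


def make_track(hours, xy, species="deer", tid="T1", sex="F", pack=None, t0=T0):
    hours = np.asarray(hours, float)
    t = t0 + (hours * 3600).astype("timedelta64[s]")
    return Track(tid, species, sex, pack, t, np.asarray(xy, float))


def regular_track(xy, interval_h=4.0, **kw):
    n = len(xy)
    return make_track(np.arange(n) * interval_h, xy, **kw)


def white_noise_track(n, sigma, seed, shift=None, interval_h=4.0, species="wolf"):
    """Stationary iid-normal track, optionally with a linear mean shift
    (magnitude m, start index, duration in fixes)."""
    rng = np.random.default_rng(seed)
    xy = rng.normal(0.0, sigma, (n, 2))
    if shift is not None:
        mag, start, dur = shift
        th = np.arange(n) * interval_h
        w = np.clip((th - start * interval_h) / (dur * interval_h), 0.0, 1.0)
        xy[:, 0] += w * mag
    return make_track(np.arange(n) * interval_h, xy, species=species)


def brownian_track(n, sigma2m, delta, seed, interval_h=4.0):
    """Pure Brownian motion observed with GPS error."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(sigma2m * interval_h), (n, 2))
    steps[0] = 0.0
    xy = np.cumsum(steps, axis=0) + rng.normal(0.0, delta, (n, 2))
    return make_track(np.arange(n) * interval_h, xy)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
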