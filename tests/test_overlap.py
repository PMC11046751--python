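"""Overlap proportions, logit transform, OLS models and rank tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from shapely.geometry import box

from migoverlap.bbmm import ContourRegion
from migoverlap.classification import define_seasons
from migoverlap.overlap import (
    assign_pack,
    corridor_filter,
    fit_overlap_model,
    logit_cap,
    mann_whitney,
    proportional_overlap,
    season_filter,
)

from conftest import T0, make_track

import datetime as dt

SEASONS = define_seasons(
    {
        "spring": (dt.date(2021, 4, 4), dt.date(2021, 5, 2)),
        "fall": (dt.date(2021, 10, 10), dt.date(2021, 11, 28)),
    }
)


def square(x0, y0, side=100.0):
    return ContourRegion.from_polygons(box(x0, y0, x0 + side, y0 + side))


class TestProportionalOverlap:
    def test_nested_full(self):
        wolf = square(10, 10, 50)
        prey = square(0, 0, 100)
        assert proportional_overlap(wolf, prey) == pytest.approx(1.0)

    def test_disjoint_zero(self):
        assert proportional_overlap(square(0, 0), square(500, 500)) == 0.0

    def test_half_covered(self):
        wolf = square(0, 0, 100)
        prey = ContourRegion.from_polygons(box(50, -10, 300, 110))
        assert proportional_overlap(wolf, prey) == pytest.approx(0.5)

    def test_monotone_in_prey(self):
        wolf = square(0, 0, 100)
        small = square(60, 0, 50)
        large = square(50, -20, 200)
        assert proportional_overlap(wolf, small) <= proportional_overlap(wolf, large)

    def test_zero_wolf_area_rejected(self):
        bad = ContourRegion(level=0.95, area_km2=0.0, _polygons=box(0, 0, 0, 0))
        with pytest.raises(ValueError):
            proportional_overlap(bad, square(0, 0))


class TestLogitCap:
    def test_midpoint(self):
        assert logit_cap(0.5) == 0.0

    def test_capped_extremes(self):
        assert logit_cap(1.0) == pytest.approx(np.log(0.975 / 0.025))
        assert logit_cap(1.0) == pytest.approx(3.6636, abs=1e-4)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_antisymmetric(self, p):
        assert logit_cap(p) == pytest.approx(-logit_cap(1.0 - p), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            logit_cap(1.5)


class TestFilters:
    def _wolf_track(self, n_inside, n_outside):
        n = n_inside + n_outside
        xy = np.vstack(
            [
                np.tile([50.0, 50.0], (n_inside, 1)),
                np.tile([5000.0, 5000.0], (n_outside, 1)),
            ]
        )
        return make_track(np.arange(n) * 4.0, xy, species="wolf", tid="W1")

    def test_corridor_filter_boundary_fraction(self):
        corridor = square(0, 0, 100)
        # exactly 5.0% inside is retained; 4.9% is excluded
        assert corridor_filter([self._wolf_track(5, 95)], corridor, 0.05)
        assert not corridor_filter([self._wolf_track(49, 951)], corridor, 0.05)
        assert not corridor_filter([self._wolf_track(0, 60)], corridor, 0.05)
        assert corridor_filter([self._wolf_track(60, 0)], corridor, 0.05)

    def test_season_filter_min_locations(self):
        # 49 summer fixes dropped, 50 retained
        t0 = np.datetime64("2019-06-01T00:00:00")
        for n, kept in ((49, 0), (50, 1)):
            tr = make_track(np.arange(n) * 4.0, np.zeros((n, 2)), t0=t0)
            out = season_filter(tr, SEASONS, 50)
            assert len(out) == kept

    def test_season_boundary_dates(self):
        t = [np.datetime64("2019-10-09T12:00:00"), np.datetime64("2019-10-10T00:00:00")]
        labels = SEASONS.season_of(t)
        assert list(labels) == ["summer", "fall"]


class TestAssignPack:
    def test_large_range_floats(self):
        assert assign_pack(600.0, "SW") == "FL"

    def test_boundary_strictly_greater(self):
        assert assign_pack(561.0, "SW") == "SW"

    def test_small_range_keeps_label(self):
        assert assign_pack(80.0, "SW") == "SW"


def _u_and_p_oracle(a, b):
    """Brute-force permutation oracle: enumerate all group assignments."""
    pooled = np.concatenate([a, b])
    na = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2

    def u_of(idx):
        return ranks[list(idx)].sum() - na * (na + 1) / 2

    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), na)]
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_fully_separated_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_matches_permutation_oracle(self, rng):
        for trial in range(25):
            na = int(rng.integers(1, 6))
            nb = int(rng.integers(1, 6))
            # small integer alphabet forces ties
            a = rng.integers(0, 4, na).astype(float)
            b = rng.integers(0, 4, nb).astype(float)
            u, p = mann_whitney(a, b)
            u_exp, p_exp = _u_and_p_oracle(a, b)
            assert u == pytest.approx(u_exp)
            assert p == pytest.approx(p_exp, abs=1e-12), (a, b)

    def test_orientation_complement(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=8)
        ua, _ = mann_whitney(a, b)
        ub, _ = mann_whitney(b, a)
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_large_sample_normal_approximation(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.5, 1, 40)
        u, p = mann_whitney(a, b)  # na*nb = 1600 > exact limit
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["wolf_id", "season", "prey", "proportion", "logit_value", "sex", "pack"],
    )


class TestOverlapModel:
    def test_matches_normal_equations_oracle(self):
        # tiny design solved from scratch with the normal equations
        rows = []
        data = [
            ("w1", "winter", "F", "FL", -1.0),
            ("w1", "fall", "F", "FL", 0.8),
            ("w2", "winter", "M", "NE", -0.2),
            ("w2", "fall", "M", "NE", 1.9),
            ("w3", "winter", "F", "NE", 0.1),
            ("w3", "fall", "F", "NE", 2.2),
        ]
        for wid, season, sex, pack, y in data:
            rows.append([wid, season, "moose", 0.5, y, sex, pack])
        df = _records(rows)
        fit = fit_overlap_model(df, "moose")
        X = np.array(
            [
                [1, 0, 0, 0],
                [1, 1, 0, 0],
                [1, 0, 1, 1],
                [1, 1, 1, 1],
                [1, 0, 0, 1],
                [1, 1, 0, 1],
            ],
            float,
        )  # intercept, fall, male, NE
        y = np.array([d[4] for d in data])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        got = fit.table["coef"].to_numpy()
        order = ["Intercept", "season:fall", "sex:M", "pack:NE"]
        got = fit.table.loc[order, "coef"].to_numpy()
        assert np.allclose(got, beta, atol=1e-10)

    def test_constant_response_zero_slopes(self):
        rows = []
        for i, season in enumerate(["winter", "fall", "summer", "winter", "fall", "summer"]):
            rows.append([f"w{i%2}", season, "moose", 0.5, 1.7, "F", "NE"])
        fit = fit_overlap_model(_records(rows), "moose")
        assert fit.table.loc["Intercept", "coef"] == pytest.approx(1.7)
        slopes = fit.table.drop("Intercept")["coef"]
        assert np.allclose(slopes, 0.0, atol=1e-12)

    def test_coefficient_coverage(self):
        # true fall effect of +1.5 logits recovered within 2 SE in >= 93/100
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(100):
            n = 100
            season = rng.choice(["winter", "summer", "fall"], n)
            sex = rng.choice(["F", "M"], n)
            pack = rng.choice(["FL", "NE", "SW"], n)
            y = (
                1.5 * (season == "fall")
                + 0.4 * (sex == "M")
                - 0.3 * (pack == "NE")
                + rng.normal(0, 1, n)
            )
            df = pd.DataFrame(
                {
                    "prey": "moose",
                    "season": season,
                    "sex": sex,
                    "pack": pack,
                    "logit_value": y,
                }
            )
            fit = fit_overlap_model(df, "moose")
            c = fit.table.loc["season:fall"]
            hits += abs(c["coef"] - 1.5) <= 2 * c["se"]
        assert hits >= 93

    def test_single_season_rejected(self):
        rows = [["w1", "winter", "moose", 0.5, 0.0, "F", "NE"]] * 4
        with pytest.raises(ValueError):
            fit_overlap_model(_records(rows), "moose")

    def test_aliased_design_rejected_with_term_named(self):
        # pack perfectly aliased with sex
        rows = []
        for i, season in enumerate(["winter", "fall"] * 4):
            sex = "F" if i % 2 else "M"
            pack = "NE" if sex == "F" else "SW"
            rows.append([f"w{i}", season, "moose", 0.5, float(i), sex, pack])
        with pytest.raises(ValueError, match="aliased|rank"):
            fit_overlap_model(_records(rows), "moose")
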