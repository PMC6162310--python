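import numpy as np
import pytest

from sbtmig import hmm, simulator
from sbtmig.summaries import (migration_time_vs_max_distance, outward_inward_ratio,
                              run_lengths, state_occupancy, westward_extent_by_age)
from sbtmig.tracks_io import Track, TrackSet


def _decoding(path):
    path = np.asarray(path, dtype=int)
    post = np.zeros((len(path), 3))
    post[np.arange(len(path)), path] = 1.0
    return hmm.Decoding(path, post, 0.0)


class TestStateOccupancy:
    def test_single_all_resident_fish(self):
        s = state_occupancy([_decoding(np.zeros(50, dtype=int))])
        assert s.pooled[0] == 1.0 and s.iqr[0] == 0.0

    def test_equal_length_resident_and_outward_fish(self):
        s = state_occupancy([_decoding(np.zeros(40, dtype=int)),
                             _decoding(np.ones(40, dtype=int))])
        np.testing.assert_allclose(s.pooled, [0.5, 0.5, 0.0])

    def test_pooled_equals_step_weighted_average(self, decoded_population):
        _, _, decs = decoded_population
        s = state_occupancy(decs)
        weights = np.array([len(d.states) for d in decs], dtype=float)
        manual = (s.per_fish.to_numpy() * weights[:, None]).sum(axis=0) / weights.sum()
        np.testing.assert_allclose(s.pooled, manual, atol=1e-12)
        assert s.pooled.sum() == pytest.approx(1.0, abs=1e-9)

    def test_posterior_variant_sums_to_one(self, decoded_population):
        _, _, decs = decoded_population
        s = state_occupancy(decs, use_posterior=True)
        assert s.pooled.sum() == pytest.approx(1.0, abs=1e-9)


class TestRunLengths:
    def test_worked_example(self):
        rl = run_lengths([_decoding([0, 0, 0, 1, 1, 2])])
        assert list(rl[0]) == [3] and list(rl[1]) == [2] and list(rl[2]) == [1]

    def test_single_step_track(self):
        rl = run_lengths([_decoding([2])])
        assert list(rl[2]) == [1]

    def test_mass_conservation(self, decoded_population):
        _, _, decs = decoded_population
        rl = run_lengths(decs)
        for s in range(3):
            assert rl[s].sum() == sum(int((d.states == s).sum()) for d in decs)

    def test_geometric_mean_run_length(self, rng):
        p = 0.9
        P = np.array([[p, 1 - p], [1 - p, p]])
        seq = simulator.simulate_states(P, 50_000, rng)
        post = np.zeros((len(seq), 3))
        rl = run_lengths([hmm.Decoding(seq, post, 0.0)])
        mean_run = np.concatenate([rl[0], rl[1]]).mean()
        assert mean_run == pytest.approx(1 / (1 - p), rel=0.1)


class TestMigrationTimeVsMaxDistance:
    def _population(self, n, migration_days, max_d, rng):
        ts = TrackSet()
        decs = []
        for k in range(n):
            m = int(migration_days[k])
            path = np.array([1] * m + [0] * (60 - m))
            from sbtmig.geometry import destination_point
            lat0, lon0 = destination_point(-32, 130, 270, max_d[k])
            lat = np.concatenate([[lat0], np.full(60, -32.0)])
            lon = np.concatenate([[lon0], np.full(60, 130.0)])
            dates = np.arange(np.datetime64("2000-01-01"),
                              np.datetime64("2000-01-01") + np.timedelta64(61, "D"))
            ts.add(Track(f"f{k}", dates, lat, lon))
            decs.append(_decoding(path))
        return ts, decs

    def test_collinear_points_slope_exact(self, rng):
        max_d = np.arange(1000.0, 5001.0, 500.0)   # 0.01*max_d stays integral
        mig = 10 + 0.01 * max_d
        ts, decs = self._population(len(max_d), mig, max_d, rng)
        table, fit = migration_time_vs_max_distance(ts, decs)
        assert fit["slope"] == pytest.approx(0.01, abs=1e-9)
        x = table["max_d_gab_km"].to_numpy()
        np.testing.assert_allclose(fit["spline"](x), 10 + 0.01 * x, atol=0.5)

    def test_zero_slope_within_confidence(self, rng):
        max_d = np.linspace(1000, 5000, 30)
        mig = np.clip(np.round(30 + rng.normal(0, 3, 30)), 0, 60)
        ts, decs = self._population(30, mig, max_d, rng)
        _, fit = migration_time_vs_max_distance(ts, decs)
        assert abs(fit["slope"]) < 2.5 * fit["stderr"] + 1e-12

    def test_simulated_population_positive_slope(self, small_population, decoded_population):
        _, trackset, _ = small_population
        _, _, decs = decoded_population
        _, fit = migration_time_vs_max_distance(trackset, decs)
        assert fit["slope"] > 0
        assert fit["pvalue"] < 0.05

    def test_too_few_fish_errors(self, rng):
        ts, decs = self._population(2, [10, 20], [1000, 2000], rng)
        with pytest.raises(ValueError):
            migration_time_vs_max_distance(ts, decs)


class TestWestwardExtentByAge:
    def _track(self, fid, lons, age, start="2000-06-01"):
        n = len(lons)
        dates = np.arange(np.datetime64(start), np.datetime64(start) + np.timedelta64(n, "D"))
        return Track(fid, dates, np.full(n, -32.0), np.asarray(lons, dtype=float), age)

    def test_stay_at_home_fish(self):
        ts = TrackSet()
        ts.add(self._track("a", [130.0] * 10, age=2))
        out = westward_extent_by_age(ts)
        assert out.loc[out.age == 2, "mean_min_lon"].iloc[0] == 130.0

    def test_age_advances_at_calendar_year(self):
        ts = TrackSet()
        lons = [130.0] * 214 + [80.0] * 200  # crosses Jan 1 into the next track-year
        ts.add(self._track("a", lons, age=1))
        out = westward_extent_by_age(ts).set_index("age")
        assert out.loc[1, "mean_min_lon"] == 130.0
        assert out.loc[2, "mean_min_lon"] == 80.0

    def test_missing_age_skipped_with_warning(self, caplog):
        import logging
        ts = TrackSet()
        ts.add(self._track("a", [130.0] * 5, age=None))
        ts.add(self._track("b", [120.0] * 5, age=3))
        with caplog.at_level(logging.WARNING, logger="sbtmig.summaries"):
            out = westward_extent_by_age(ts)
        assert set(out.age) == {3}
        assert "without age" in caplog.text

    def test_longer_deployments_reach_further_west(self, rng):
        """Older track-years accumulate more chance to extend west."""
        ts = TrackSet()
        for k in range(12):
            drift = np.minimum(0.2 * np.arange(500), 60.0)
            lons = 130.0 - drift - rng.uniform(0, 2, 500).cumsum() * 0.02
            ts.add(self._track(f"f{k}", np.clip(lons, 40, 130), age=1, start="2000-01-15"))
        out = westward_extent_by_age(ts).set_index("age")
        assert out.loc[2, "mean_min_lon"] < out.loc[1, "mean_min_lon"]


class TestOutwardInwardRatio:
    def test_fitted_scale_values(self):
        assert outward_inward_ratio([0.0, 39.02, -31.08]) == pytest.approx(25.55, abs=0.01)

    def test_equal_means_zero_percent(self):
        assert outward_inward_ratio([0.0, 31.0, -31.0]) == 0.0

    def test_double_means_hundred_percent(self):
        assert outward_inward_ratio([0.0, 62.0, -31.0]) == 100.0

    def test_tiny_inward_mean_errors(self):
        with pytest.raises(ValueError):
            outward_inward_ratio([0.0, 39.0, -1e-9])
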