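"""Colony growth models, random-walk migration and the movie simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonyscope import (
    GrowthParams,
    MigrationParams,
    classify_capture,
    gillespie_division_times,
    random_walk_step,
    simulate_movie,
    synchronized_cell_count,
)
from colonyscope.colony import gillespie_counts_at, simulate_capture_batch


class _FixedStream:
    """Deterministic stand-in for an RNG: random() always returns ``value``."""

    def __init__(self, value):
        self.value = value

    def random(self):
        return self.value


class TestSynchronizedGrowth:
    @pytest.mark.parametrize(
        "t_min, expected",
        [(0.0, 1), (719.4, 1), (720.0, 2), (96 * 60.0, 256)],
    )
    def test_count_doubles_every_interval(self, t_min, expected, growth):
        assert synchronized_cell_count(t_min, growth) == expected

    def test_four_day_radius_is_120_um(self, growth):
        n = synchronized_cell_count(96 * 60.0, growth)
        assert growth.r1 * math.sqrt(n) == pytest.approx(120.0)

    def test_negative_time_rejected(self, growth):
        with pytest.raises(ValueError):
            synchronized_cell_count(-1.0, growth)


class TestGillespieGrowth:
    def test_injected_stream_gives_exact_waiting_times(self, growth):
        # u = e^-1 makes every waiting time exactly interval/n:
        # 720, 360, 240, 180 min cumulatively
        events = gillespie_division_times(1500.0, growth, _FixedStream(math.exp(-1.0)))
        assert np.allclose(events, [720.0, 1080.0, 1320.0, 1500.0])

    def test_mean_first_waiting_time_is_the_division_interval(self, growth):
        # first event time is -interval * ln(u), an exponential with mean 720
        # min; runs whose first division falls beyond the horizon are censored,
        # so the observed mean matches the truncated-exponential expectation
        rng = np.random.default_rng(7)
        horizon = 2880.0
        firsts = []
        for _ in range(4000):
            events = gillespie_division_times(horizon, growth, rng)
            if len(events):
                firsts.append(events[0])
        firsts = np.array(firsts)
        p_cens = math.exp(-horizon / 720.0)
        truncated_mean = 720.0 - horizon * p_cens / (1.0 - p_cens)
        se = firsts.std(ddof=1) / math.sqrt(len(firsts))
        assert abs(firsts.mean() - truncated_mean) <= 3.0 * se

    def test_counts_are_nondecreasing_from_one(self, growth):
        rng = np.random.default_rng(3)
        events = gillespie_division_times(96 * 60.0, growth, rng)
        assert np.all(np.diff(events) > 0)
        assert len(events) >= 1

    def test_frame_sampler_matches_event_by_event_oracle(self, growth):
        """The negative-binomial frame-skipping sampler and the naive
        event-by-event loop realise the same pure-birth process."""
        frame_times = np.arange(0, 1441, 15.0)
        rng = np.random.default_rng(11)
        counts = gillespie_counts_at(frame_times, growth, rng, n_movies=4000)
        oracle_rng = np.random.default_rng(12)
        oracle = np.array(
            [
                1 + np.searchsorted(gillespie_division_times(1440.0, growth, oracle_rng), 1440.0)
                for _ in range(4000)
            ]
        )
        se = math.sqrt(counts[:, -1].var(ddof=1) / 4000 + oracle.var(ddof=1) / 4000)
        assert abs(counts[:, -1].mean() - oracle.mean()) <= 3.0 * se
        assert np.all(np.diff(counts, axis=1) >= 0)


class TestRandomWalk:
    def test_zero_step_is_identity(self):
        rng = np.random.default_rng(0)
        assert random_walk_step((3.0, -2.0), 0.0, rng) == (3.0, -2.0)

    @given(step=st.floats(0.01, 50.0), seed=st.integers(0, 2**16))
    @settings(max_examples=100, deadline=None)
    def test_step_preserves_length(self, step, seed):
        rng = np.random.default_rng(seed)
        x0, y0 = 1.0, 2.0
        x1, y1 = random_walk_step((x0, y0), step, rng)
        assert math.hypot(x1 - x0, y1 - y0) == pytest.approx(step, rel=1e-12)

    def test_mean_squared_displacement_is_k_L_squared(self):
        # independent increments: MSD after k steps of length L is k * L^2
        rng = np.random.default_rng(42)
        k, L, n = 100, 2.0, 10_000
        theta = rng.uniform(0, 2 * np.pi, (n, k))
        disp = L * np.stack([np.cos(theta).sum(axis=1), np.sin(theta).sum(axis=1)], axis=1)
        msd = (disp**2).sum(axis=1)
        se = msd.std(ddof=1) / math.sqrt(n)
        assert abs(msd.mean() - k * L**2) <= 3.0 * se


class TestSimulateMovie:
    def test_zero_motion_reduces_to_centered_geometry(self, camera_fov, growth):
        still = MigrationParams.per_minute(speed=0.0)
        res = simulate_movie(growth, still, camera_fov, duration_hr=96.0, seed=1)
        assert len(res.times) == 96 * 60 // 15 + 1
        # trajectory equals that of a centered disk growing to 120 um
        assert res.min_fraction == pytest.approx(0.950846, abs=1e-4)
        assert res.capture_fraction[0] == 1.0

    def test_zero_duration_single_full_frame(self, camera_fov, growth, migration):
        res = simulate_movie(growth, migration, camera_fov, duration_hr=0.0, seed=0)
        assert list(res.capture_fraction) == [1.0]
        assert list(res.n_cells) == [1]

    def test_same_seed_is_deterministic(self, camera_fov, growth, migration):
        a = simulate_movie(growth, migration, camera_fov, 24.0, seed=99)
        b = simulate_movie(growth, migration, camera_fov, 24.0, seed=99)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.capture_fraction, b.capture_fraction)

    def test_area_conservation(self, camera_fov, migration):
        growth = GrowthParams(mode="gillespie")
        res = simulate_movie(growth, migration, camera_fov, 48.0, seed=5)
        assert np.allclose(res.radius**2, res.n_cells * growth.r1**2)
        assert np.all(np.diff(res.n_cells) >= 0)

    def test_capture_is_one_while_disk_inside(self, camera_fov, growth):
        slow = MigrationParams.per_minute(speed=0.1)
        res = simulate_movie(growth, slow, camera_fov, 12.0, seed=2)
        inside = (
            np.abs(res.centers).max(axis=1) + res.radius <= camera_fov.half_width
        )
        assert np.all(res.capture_fraction[inside] == 1.0)

    def test_unknown_growth_mode_rejected(self):
        with pytest.raises(ValueError):
            GrowthParams(mode="exponential")

    def test_frame_interval_divisibility_enforced(self):
        with pytest.raises(ValueError):
            MigrationParams(speed=1.0, step_interval=4.0, frame_interval=15.0)

    def test_batch_matches_single_movie_distribution(self, camera_fov, growth, migration):
        rng = np.random.default_rng(0)
        mins, finals = simulate_capture_batch(64, growth, migration, camera_fov, 24.0, rng)
        assert mins.shape == (64,)
        assert np.all((mins >= 0) & (mins <= 1))
        assert np.all(mins <= finals + 1e-12)

    def test_movie_table_round_trip(self, camera_fov, growth, migration):
        res = simulate_movie(growth, migration, camera_fov, 6.0, seed=3)
        df = res.to_frame()
        assert list(df.columns) == [
            "movie_id", "time_min", "n_cells", "radius_um", "x_um", "y_um", "capture_fraction",
        ]
        assert len(df) == len(res.times)
        assert res.summary()["min_fraction"] == res.min_fraction


class TestClassifyCapture:
    def test_thresholds_nested(self, camera_fov, growth):
        still = MigrationParams.per_minute(speed=0.0)
        res = simulate_movie(growth, still, camera_fov, 96.0, seed=0)
        out = classify_capture(res)
        assert out == {0.5: True, 0.9: True}

    def test_partial_capture(self, camera_fov, growth):
        res = simulate_movie(growth, MigrationParams.per_minute(), camera_fov, 1.0, seed=0)
        res.capture_fraction = np.array([1.0, 0.95, 0.7])
        assert classify_capture(res) == {0.5: True, 0.9: False}
        assert classify_capture(res, criterion="final_frame") == {0.5: True, 0.9: False}
        res.capture_fraction = np.array([1.0, 0.95, 0.91])
        assert classify_capture(res, thresholds=(0.9,)) == {0.9: True}

    def test_invalid_inputs_rejected(self, camera_fov, growth, migration):
        res = simulate_movie(growth, migration, camera_fov, 1.0, seed=0)
        with pytest.raises(ValueError):
            classify_capture(res, thresholds=(1.5,))
        with pytest.raises(ValueError):
            classify_capture(res, criterion="midpoint")
        res.capture_fraction = np.array([])
        with pytest.raises(ValueError):
            classify_capture(res)
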