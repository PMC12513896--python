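"""Falling-object kinematics, termination rules, and catch adjudication."""

import numpy as np
import pytest

from galatrack import (
    KinematicsParams,
    ObjectState,
    adjudicate_catch,
    adjust_fall_duration,
    mirror_config,
    simulate_trial,
    simulate_trials,
    step_object,
)
from galatrack.errors import ValidationError

from conftest import make_config


@pytest.mark.parametrize(
    "onset, base, min_post, expected",
    [
        (0.73, 3.0, 2.0, 3.0),  # earliest stimulus onset: base suffices
        (3.26, 3.0, 2.0, 5.26),  # latest onset forces an extension
        (1.0, 3.0, 2.0, 3.0),
    ],
)
def test_fall_duration_is_max_of_base_and_onset_plus_minimum(onset, base, min_post, expected):
    assert adjust_fall_duration(onset, base, min_post) == pytest.approx(expected)


def test_fall_duration_rejects_non_positive_inputs():
    with pytest.raises(ValidationError):
        adjust_fall_duration(-0.1, 3.0, 2.0)
    with pytest.raises(ValidationError):
        adjust_fall_duration(1.0, 0.0, 2.0)


class TestStepObject:
    corridor = (0.08, 0.40)

    def _state(self, x, d):
        return ObjectState(x=x, y=0.5, dir=d, speed_x=0.25 / 60, speed_y=1e-3)

    def test_boundary_flip_wins_even_with_large_draw(self, kinematics):
        # at the outer edge heading outward: reversal regardless of u
        out = step_object(self._state(0.40, +1), self.corridor, kinematics, u=0.9)
        assert out.dir == -1
        assert self.corridor[0] <= out.x <= self.corridor[1]

    def test_interior_large_draw_keeps_heading(self, kinematics):
        out = step_object(self._state(0.24, +1), self.corridor, kinematics, u=0.5)
        assert out.dir == +1
        assert out.x == pytest.approx(0.24 + 0.25 / 60)

    def test_small_draw_flips_in_the_interior(self, kinematics):
        out = step_object(self._state(0.24, +1), self.corridor, kinematics, u=0.01)
        assert out.dir == -1

    def test_y_is_non_increasing(self, kinematics):
        out = step_object(self._state(0.24, +1), self.corridor, kinematics, u=0.5)
        assert out.y < 0.5

    def test_empirical_flip_rate_matches_binomial(self, kinematics):
        """Interior flip frequency over 1e5 steps ≈ 1/40 within 3 binomial SE."""
        rng = np.random.default_rng(123)
        n = 100_000
        us = rng.random(n)
        # a huge corridor so the boundary never interferes
        wide = (-1000.0, 1000.0)
        state = ObjectState(x=0.0, y=1e9 * 1e-3, dir=+1, speed_x=0.25 / 60, speed_y=1e-3)
        flips = 0
        for u in us:
            new = step_object(state, wide, kinematics, u)
            flips += new.dir != state.dir
            state = new
        p = 1.0 / 40.0
        se = np.sqrt(p * (1 - p) / n)
        assert abs(flips / n - p) < 3 * se


@pytest.mark.parametrize(
    "diff, expected",
    [(0.04, True), (0.05, False), (0.0, True)],  # strict inequality at the 5% bound
)
def test_catch_is_strictly_within_tolerance(diff, expected):
    assert adjudicate_catch(0.1, 0.1 + diff, 0.05) is expected


class TestSimulateTrial:
    def test_never_clicking_agent_runs_to_the_bottom(
        self, geometry, kinematics, non_clicker, config
    ):
        log = simulate_trial(config, geometry, kinematics, non_clicker, seed=5)
        fall = adjust_fall_duration(config.target_onset_s, 3.0, 2.0)
        assert log.end_reason == "objects_reached_bottom"
        assert log.click_time_s is None
        assert abs(log.duration_s - fall) < 1.0 / kinematics.fps
        # objects land just above the spaceship
        assert log.obj_y[-1] == pytest.approx(geometry.bottom_y)

    def test_click_during_audio_ends_200ms_after_sound(self, geometry, kinematics, quiet_agent):
        cfg = make_config(onset=1.0, audio=3.5)
        log = simulate_trial(cfg, geometry, kinematics, quiet_agent, seed=2)
        assert log.click_time_s is not None and log.click_time_s < cfg.audio_dur_s
        assert log.end_reason == "audio_tail"
        assert log.duration_s == pytest.approx(cfg.audio_dur_s + kinematics.tail_s)

    def test_click_after_audio_ends_200ms_after_click(self, geometry, kinematics, quiet_agent):
        cfg = make_config(onset=3.0, audio=3.2)
        log = simulate_trial(cfg, geometry, kinematics, quiet_agent, seed=2)
        assert log.click_time_s is not None and log.click_time_s >= cfg.audio_dur_s
        assert log.end_reason == "click"
        assert log.duration_s == pytest.approx(log.click_time_s + kinematics.tail_s)

    def test_mirrored_config_negates_x_traces_exactly(
        self, geometry, kinematics, quiet_agent, config
    ):
        for seed in range(10):
            log = simulate_trial(config, geometry, kinematics, quiet_agent, seed)
            mlog = simulate_trial(
                mirror_config(config), geometry, kinematics, quiet_agent, seed
            )
            assert np.array_equal(log.x, -mlog.x)
            assert np.array_equal(log.obj_left_x, -mlog.obj_right_x)
            assert log.caught == mlog.caught

    def test_logs_reproducible_bit_identically(self, geometry, kinematics, quiet_agent, config):
        a = simulate_trial(config, geometry, kinematics, quiet_agent, seed=42)
        b = simulate_trial(config, geometry, kinematics, quiet_agent, seed=42)
        assert np.array_equal(a.t, b.t) and np.array_equal(a.x, b.x)
        assert a.click_time_s == b.click_time_s and a.caught == b.caught

    def test_batch_equals_single_trial_simulation(self, geometry, kinematics, quiet_agent):
        configs = [make_config(onset=o, item=f"h{i:02d}", index=i + 1) for i, o in enumerate([0.8, 1.5, 2.2])]
        batch = simulate_trials(
            configs, geometry, kinematics, [quiet_agent] * 3, seeds=[7, 8, 9]
        )
        for cfg, seed, from_batch in zip(configs, [7, 8, 9], batch):
            solo = simulate_trial(cfg, geometry, kinematics, quiet_agent, seed)
            assert np.array_equal(solo.x, from_batch.x)
            assert np.array_equal(solo.obj_left_x, from_batch.obj_left_x)

    def test_objects_stay_in_corridor_and_post_onset_window_holds(
        self, geometry, kinematics, non_clicker
    ):
        """Containment and the ≥2 s post-onset guarantee over 200 seeded trials."""
        rng = np.random.default_rng(0)
        onsets = rng.uniform(0.73, 3.26, size=200)
        configs = [
            make_config(onset=o, audio=o + 1.0, item=f"h{i:02d}", index=i + 1)
            for i, o in enumerate(onsets)
        ]
        logs = simulate_trials(
            configs, geometry, kinematics, [non_clicker] * 200, seeds=list(range(200))
        )
        ll, lh = geometry.corridor_left
        rl, rh = geometry.corridor_right
        for log in logs:
            assert np.all((log.obj_left_x >= ll - 1e-12) & (log.obj_left_x <= lh + 1e-12))
            assert np.all((log.obj_right_x >= rl - 1e-12) & (log.obj_right_x <= rh + 1e-12))
            assert log.duration_s - log.config.target_onset_s >= kinematics.min_post_onset_s
            assert np.all(np.diff(log.obj_y) <= 0)
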