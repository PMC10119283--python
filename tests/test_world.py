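"""World simulation: SG sampling, kinematics, adjudication, skill measures."""

import math

import numpy as np
import pytest

from boatdock.world import (
    CursorSpec,
    OutOfFuelError,
    SGPair,
    State,
    UnterminatedTraceError,
    WorldConfig,
    adjudicate,
    compute_skill,
    congruent_cursor,
    incongruent_cursor,
    run_schedule,
    sample_sg,
    step_dynamics,
)


class TestCursorGeometry:
    def test_headings_are_2pi3_apart_and_interleave(self):
        cong, incong = congruent_cursor(), incongruent_cursor()
        both = sorted(np.mod(cong.headings + incong.headings, 2 * math.pi))
        gaps = np.diff(both + [both[0] + 2 * math.pi])
        assert np.allclose(gaps, math.pi / 3)

    def test_rejects_irregular_headings(self):
        with pytest.raises(ValueError):
            CursorSpec("congruent", (0.0, 1.0, 2.0))


class TestSampleSG:
    def test_deterministic_under_seeding(self, config):
        a = sample_sg(np.random.default_rng(7), config)
        b = sample_sg(np.random.default_rng(7), config)
        assert a == b

    def test_constraints_hold_on_many_draws(self, config, rng):
        rmax = config.grid_radius - config.perimeter_margin
        for _ in range(10_000):
            sg = sample_sg(rng, config)
            assert np.linalg.norm(sg.start) <= rmax
            assert np.linalg.norm(sg.goal) <= rmax
            assert sg.distance >= config.min_sg_separation

    def test_start_centroid_near_grid_centre(self, config, rng):
        starts = np.array([sample_sg(rng, config).start for _ in range(10_000)])
        # symmetry of the admissible region: centroid at the origin up to
        # Monte-Carlo error (sd/sqrt(n) per axis, sd < rmax)
        assert np.all(np.abs(starts.mean(axis=0)) < 3 * 3.5 / math.sqrt(10_000))


class TestStepDynamics:
    def test_no_throttle_is_inertial(self, config):
        s = State((1.0, -0.5), (0.0, 0.0), config.fuel_units)
        for _ in range(100):
            s = step_dynamics(s, None, congruent_cursor(), config)
        assert s.pos == (1.0, -0.5)
        assert s.fuel == 360

    def test_sixty_throttled_frames_reach_dock_speed_limit(self, config):
        s = State((0.0, 0.0), (0.0, 0.0), config.fuel_units)
        cur = congruent_cursor()
        for _ in range(60):
            s = step_dynamics(s, 1, cur, config)  # middle finger: straight up
        assert math.hypot(*s.vel) == pytest.approx(config.dock_speed_limit)
        assert s.fuel == 300

    def test_displacement_quadratic_fuel_linear(self, config):
        cur = congruent_cursor()

        def fly(T):
            s = State((0.0, 0.0), (0.0, 0.0), config.fuel_units)
            for _ in range(T):
                s = step_dynamics(s, 1, cur, config)
            return s

        d1, d2 = fly(30), fly(60)
        assert 360 - d2.fuel == 2 * (360 - d1.fuel)  # fuel linear in T
        # displacement superlinear: doubling throttle time ~4x displacement
        assert d2.pos[1] / d1.pos[1] > 3.5

    def test_empty_tank_throttle_raises(self, config):
        s = State((0.0, 0.0), (0.0, 0.0), 0)
        with pytest.raises(OutOfFuelError):
            step_dynamics(s, 0, congruent_cursor(), config)


class TestAdjudication:
    def _straight_up_sg(self, dist):
        return SGPair((0.0, -dist / 2), (0.0, dist / 2))

    def test_dock_at_exact_speed_limit_is_inclusive(self, config):
        # 60 accel frames reach exactly the limit; coast into the goal disc
        sg = self._straight_up_sg(3.0)
        schedule = [1] * 60 + [None] * 200
        trace = run_schedule(schedule, sg, congruent_cursor(), config)
        out = adjudicate(trace, sg, config)
        assert out.kind == "dock"
        assert out.reward == pytest.approx(300 / 360)

    def test_too_fast_above_limit(self, config):
        sg = self._straight_up_sg(3.0)
        schedule = [1] * 70 + [None] * 200
        trace = run_schedule(schedule, sg, congruent_cursor(), config)
        assert adjudicate(trace, sg, config).kind == "too_fast"

    def test_out_of_gas_after_360_throttled_frames(self, config):
        # cycling all three headings sums to zero thrust: the cursor wiggles
        # near the start and burns the full tank
        sg = SGPair((0.0, -1.0), (0.0, 1.0))
        schedule = [0, 1, 2] * 120
        trace = run_schedule(schedule, sg, congruent_cursor(), config)
        out = adjudicate(trace, sg, config)
        assert out.kind == "out_of_gas"
        assert out.reward == 0.0
        assert trace.fuel[-1] == 0

    def test_left_grid(self, config):
        sg = SGPair((3.0, 0.0), (0.0, 0.0))
        schedule = [1] * 60 + [None] * 600  # straight up from near the edge
        trace = run_schedule(schedule, sg, congruent_cursor(), config)
        assert adjudicate(trace, sg, config).kind == "left_grid"

    def test_unterminated_trace_raises(self, config):
        sg = self._straight_up_sg(3.0)
        trace = run_schedule([None] * 10, sg, congruent_cursor(), config)
        with pytest.raises(UnterminatedTraceError):
            adjudicate(trace, sg, config)

    def test_fuel_conservation_and_determinism(self, config, rng):
        sg = self._straight_up_sg(2.0)
        schedule = [int(t) if t >= 0 else None
                    for t in rng.integers(-1, 3, size=150)]
        t1 = run_schedule(schedule, sg, congruent_cursor(), config)
        t2 = run_schedule(schedule, sg, congruent_cursor(), config)
        assert np.array_equal(t1.x, t2.x) and np.array_equal(t1.fuel, t2.fuel)
        throttled = int(np.sum(t1.throttle >= 0))
        assert throttled + t1.fuel[-1] == 360


class TestSkillMeasures:
    def test_direction_change_counting(self, config):
        sg = SGPair((0.0, -1.5), (0.0, 1.5))
        # all-same presses -> 0 changes
        t0 = run_schedule([1] * 60 + [None] * 300, sg,
                          congruent_cursor(), config)
        assert compute_skill(t0, sg, config).direction_changes == 0
        # adjacent-distinct count: A,B,A,C,C,...,C -> 3 changes
        t3 = run_schedule([0, 1, 0] + [2] * 57 + [None] * 300, sg,
                          congruent_cursor(), config)
        assert compute_skill(t3, sg, config).direction_changes == 3

    def test_temporal_skill_zero_when_final_is_max(self, config):
        sg = SGPair((0.0, -1.5), (0.0, 1.5))
        trace = run_schedule([1] * 55 + [None] * 300, sg,
                             congruent_cursor(), config)
        sk = compute_skill(trace, sg, config)
        assert sk.temporal_skill == pytest.approx(0.0)

    def test_temporal_skill_undefined_without_crossing(self, config):
        sg = SGPair((3.0, 0.0), (0.0, 0.0))
        trace = run_schedule([1] * 60 + [None] * 600, sg,
                             congruent_cursor(), config)
        assert compute_skill(trace, sg, config).temporal_skill is None

    def test_reward_monotone_in_throttled_frames(self, config):
        sg = SGPair((0.0, -2.0), (0.0, 2.0))
        rewards = []
        for n in (40, 50, 60):
            trace = run_schedule([1] * n + [None] * 500, sg,
                                 congruent_cursor(), config)
            out = adjudicate(trace, sg, config)
            assert out.kind == "dock"
            rewards.append(out.reward)
        assert rewards[0] > rewards[1] > rewards[2]
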