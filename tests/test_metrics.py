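"""Trajectory metrics against brute-force oracles and symmetry properties."""

import math

import numpy as np
import pytest

import buridan as b
from buridan import Trajectory, TrajectorySegment

from conftest import random_trajectory


def straight_walk(step_mm: float, dt: float = 1.0, n: int = 5) -> Trajectory:
    t = np.arange(n) * dt
    return Trajectory("s", "g", [TrajectorySegment(t, t * step_mm / dt, np.zeros(n))])


def trajectory_from_speeds(speeds, dt: float = 1.0) -> Trajectory:
    """A 1-D path whose inter-sample speeds equal *speeds* exactly."""
    x = np.concatenate([[0.0], np.cumsum(np.asarray(speeds, dtype=float) * dt)])
    t = np.arange(x.size) * dt
    return Trajectory("v", "g", [TrajectorySegment(t, x, np.zeros_like(x))])


class TestFrameSpeeds:
    def test_constant_walk(self):
        _, v = b.frame_speeds(straight_walk(10.0))
        np.testing.assert_allclose(v, 10.0)

    def test_no_speed_across_segment_boundary(self):
        segs = [
            TrajectorySegment([0, 1, 2], [0, 1, 2], [0, 0, 0]),
            TrajectorySegment([5, 6, 7], [9, 9, 9], [0, 1, 2]),
        ]
        _, v = b.frame_speeds(Trajectory("f", "g", segs))
        assert v.size == 4  # 2 + 2, never 5

    def test_matches_per_pair_loop_oracle(self):
        traj = random_trajectory(np.random.default_rng(1), 100, n_segments=2)
        _, v = b.frame_speeds(traj)
        oracle = []
        for seg in traj.segments:
            for i in range(seg.n_samples - 1):
                d = math.hypot(seg.x[i + 1] - seg.x[i], seg.y[i + 1] - seg.y[i])
                oracle.append(d / (seg.t[i + 1] - seg.t[i]))
        np.testing.assert_allclose(v, oracle, atol=1e-12)

    def test_non_increasing_time_rejected(self):
        with pytest.raises(b.MalformedTrajectoryError):
            TrajectorySegment([0, 2, 1], [0, 0, 0], [0, 0, 0])

    def test_overlapping_segments_rejected(self):
        with pytest.raises(b.MalformedTrajectoryError):
            Trajectory(
                "f",
                "g",
                [
                    TrajectorySegment([0, 1], [0, 0], [0, 0]),
                    TrajectorySegment([0.5, 2], [0, 0], [0, 0]),
                ],
            )


class TestMedianSpeed:
    def test_jump_excluded_from_median(self):
        traj = trajectory_from_speeds([10, 10, 60, 10])
        assert b.median_speed(traj) == 10.0

    def test_single_speed(self):
        assert b.median_speed(trajectory_from_speeds([5])) == 5.0

    def test_boundary_speed_exactly_50_is_retained(self):
        traj = trajectory_from_speeds([50, 50, 10])
        assert b.median_speed(traj) == 50.0

    def test_contaminated_lognormal_matches_sort_and_pick_oracle(self):
        rng = np.random.default_rng(3)
        speeds = rng.lognormal(2.0, 0.5, 1000)
        speeds[rng.random(1000) < 0.02] = 80.0
        traj = trajectory_from_speeds(speeds)
        kept = sorted(s for s in speeds if s <= 50.0)
        n = len(kept)
        oracle = kept[n // 2] if n % 2 else 0.5 * (kept[n // 2 - 1] + kept[n // 2])
        assert b.median_speed(traj) == pytest.approx(oracle, abs=1e-12)

    def test_never_exceeds_threshold(self):
        rng = np.random.default_rng(4)
        traj = trajectory_from_speeds(rng.uniform(0, 120, 200))
        assert b.median_speed(traj) <= 50.0

    def test_all_jump_frames_is_an_error(self):
        with pytest.raises(b.NoValidFramesError):
            b.median_speed(trajectory_from_speeds([60, 70, 80]))


class TestStripeDeviation:
    def test_walking_straight_at_stripe_is_zero(self, arena):
        traj = straight_walk(10.0)  # along +x toward the stripe at (+146.5, 0)
        assert b.stripe_deviation(traj, arena) == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_walk_is_ninety_degrees(self, arena):
        t = np.arange(4.0)
        traj = Trajectory("p", "g", [TrajectorySegment(t, np.zeros(4), t * 5.0)])
        # from the centre both stripes subtend 90 deg to a +y velocity,
        # but away from the centre the nearer-stripe angle dips below 90
        seg = traj.segments[0]
        angles = []
        for i in range(3):
            px, py, vx, vy = seg.x[i], seg.y[i], 0.0, 5.0
            best = math.pi
            for cx, cy in arena.stripe_centers:
                tx, ty = cx - px, cy - py
                best = min(best, abs(math.atan2(vx * ty - vy * tx, vx * tx + vy * ty)))
            angles.append(math.degrees(best))
        assert b.stripe_deviation(traj, arena) == pytest.approx(np.median(angles), abs=1e-9)
        assert angles[0] == pytest.approx(90.0)  # at the centre exactly

    def test_oblique_position_matches_atan2_oracle(self, arena):
        v = np.array([1.0, 1.0]) / math.sqrt(2)
        start = np.array([30.0, 20.0])
        pos = np.vstack([start, start + v, start + 2 * v])
        traj = Trajectory(
            "o", "g", [TrajectorySegment([0, 1, 2], pos[:, 0], pos[:, 1])]
        )
        expected = []
        for i in range(2):
            px, py = pos[i]
            per_stripe = []
            for cx, cy in arena.stripe_centers:
                tx, ty = cx - px, cy - py
                dot = v[0] * tx + v[1] * ty
                cross = v[0] * ty - v[1] * tx
                per_stripe.append(abs(math.atan2(cross, dot)))
            expected.append(math.degrees(min(per_stripe)))
        # unit-speed steps: keep the movement gate safely below 1 mm/s
        assert b.stripe_deviation(traj, arena, movement_threshold=0.5) == pytest.approx(
            float(np.median(expected)), abs=1e-9
        )

    def test_resting_frames_are_excluded(self, arena):
        # second step is 0.1 mm/s, below the 1 mm/s movement gate
        x = np.array([0.0, 10.0, 10.1, 20.1])
        traj = Trajectory("r", "g", [TrajectorySegment(np.arange(4.0), x, np.zeros(4))])
        assert b.stripe_deviation(traj, arena) == pytest.approx(0.0, abs=1e-9)
        with pytest.raises(b.NoValidFramesError):
            b.stripe_deviation(traj, arena, movement_threshold=50.0)

    def test_angle_bounds(self, arena):
        traj = random_trajectory(np.random.default_rng(6), 200)
        dev = b.stripe_deviation(traj, arena)
        assert 0.0 <= dev <= 180.0

    @pytest.mark.parametrize("angle", [0.3, 1.2, -2.0])
    def test_rotation_equivariance(self, arena, angle):
        traj = random_trajectory(np.random.default_rng(7), 120)
        c, s = math.cos(angle), math.sin(angle)
        rot = Trajectory(
            "rot",
            "g",
            [
                TrajectorySegment(
                    seg.t, c * seg.x - s * seg.y, s * seg.x + c * seg.y
                )
                for seg in traj.segments
            ],
        )
        rot_arena = arena.rotated(angle)
        assert b.stripe_deviation(rot, rot_arena) == pytest.approx(
            b.stripe_deviation(traj, arena), abs=1e-9
        )
        assert b.median_speed(rot) == pytest.approx(b.median_speed(traj), abs=1e-9)

    def test_scale_covariance(self, arena):
        traj = random_trajectory(np.random.default_rng(8), 120)
        factor = 2.5
        scaled = Trajectory(
            "sc",
            "g",
            [
                TrajectorySegment(seg.t, factor * seg.x, factor * seg.y)
                for seg in traj.segments
            ],
        )
        sc_arena = arena.scaled(factor)
        assert b.stripe_deviation(
            scaled, sc_arena, movement_threshold=factor * 1.0, jump_threshold=factor * 50.0
        ) == pytest.approx(b.stripe_deviation(traj, arena), abs=1e-9)
        assert b.median_speed(scaled, jump_threshold=factor * 50.0) == pytest.approx(
            factor * b.median_speed(traj), rel=1e-12
        )


class TestCohortMetrics:
    def test_group_mean_and_sem_closed_form(self, arena):
        flies = [trajectory_from_speeds([s] * 10) for s in (8.0, 10.0, 12.0)]
        for i, f in enumerate(flies):
            f.fly_id = f"f{i}"
            f.genotype = "g"
        cohort = b.CohortTrajectorySet(flies, ["g"])
        _, groups, _ = b.cohort_metrics(cohort, arena)
        row = groups.iloc[0]
        assert row["speed_mean"] == pytest.approx(10.0)
        assert row["speed_sem"] == pytest.approx(2.0 / math.sqrt(3))

    def test_identical_trajectories_have_zero_sem(self, arena):
        flies = [trajectory_from_speeds([9.0] * 10) for _ in range(4)]
        for i, f in enumerate(flies):
            f.fly_id = f"f{i}"
            f.genotype = "g"
        cohort = b.CohortTrajectorySet(flies, ["g"])
        _, groups, _ = b.cohort_metrics(cohort, arena)
        assert groups.iloc[0]["speed_sem"] == 0.0

    def test_matches_per_fly_loop_oracle(self, arena, small_config):
        cohort = b.simulate_cohort(small_config, [b.GenotypeEffect(label="g")])
        per_fly, _, _ = b.cohort_metrics(cohort, arena)
        for _, row in per_fly.iterrows():
            traj = next(f for f in cohort.flies if f.fly_id == row["fly_id"])
            assert row["median_speed_mm_s"] == b.median_speed(traj)
            assert row["stripe_deviation_deg"] == b.stripe_deviation(traj, arena)

    def test_flagged_flies_are_excluded_with_reason(self, arena):
        good = trajectory_from_speeds([10.0] * 10)
        good.fly_id, good.genotype = "good", "g"
        bad = trajectory_from_speeds([60.0] * 10)  # every frame a jump
        bad.fly_id, bad.genotype = "bad", "g"
        cohort = b.CohortTrajectorySet([good, bad], ["g"])
        per_fly, _, exclusions = b.cohort_metrics(cohort, arena)
        assert list(per_fly["fly_id"]) == ["good"]
        assert exclusions and exclusions[0]["fly_id"] == "bad"
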