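"""Migration descriptors: per-step, per-cell and population statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from halotrack.metrics import (
    Calibration,
    InsufficientDataError,
    compare_groups,
    pause_fraction,
    speeds_and_accelerations,
    step_angles,
    step_distances,
    step_extremes_and_moments,
    summarize_cell,
    summarize_population,
    total_and_euclidean,
)
from halotrack.track import Track, TrackPoint


def _track(points, cell_id=1, status="complete"):
    return Track(
        cell_id=cell_id,
        points=[TrackPoint(frame=i, x=float(x), y=float(y), converged=True)
                for i, (x, y) in enumerate(points)],
        status=status,
    )


CAL1 = Calibration(um_per_px=1.0, min_per_frame=1.0)


class TestStepDistances:
    def test_three_four_five(self):
        assert step_distances(_track([(0, 0), (3, 4)]), CAL1).tolist() == [5.0]

    def test_stationary_track_all_zero(self):
        steps = step_distances(_track([(2, 2)] * 10), CAL1)
        assert len(steps) == 9 and (steps == 0).all()

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientDataError):
            step_distances(_track([(0, 0)]), CAL1)

    def test_matches_pairwise_oracle(self, rng):
        pos = rng.normal(size=(50, 2)) * 10
        cal = Calibration(um_per_px=0.645, min_per_frame=4.0)
        expected = [
            cal.um_per_px * math.hypot(*(pos[i + 1] - pos[i])) for i in range(49)
        ]
        np.testing.assert_allclose(step_distances(pos, cal), expected, rtol=1e-12)


class TestTotalAndEuclidean:
    def test_straight_path_persistence_one(self):
        d_ttl, d_se, pers = total_and_euclidean(
            _track([(0, 0), (0, 5), (0, 10)]), CAL1
        )
        assert (d_ttl, d_se, pers) == (10.0, 10.0, 1.0)

    def test_closed_loop_persistence_missing(self):
        _, d_se, pers = total_and_euclidean(
            _track([(0, 0), (5, 0), (5, 5), (0, 5), (0, 0)]), CAL1
        )
        assert d_se == 0.0 and math.isnan(pers)

    def test_matches_bruteforce_sums(self, rng):
        pos = np.cumsum(rng.normal(size=(50, 2)), axis=0)
        d_ttl, d_se, pers = total_and_euclidean(pos, CAL1)
        exp_ttl = sum(math.hypot(*(pos[i + 1] - pos[i])) for i in range(49))
        exp_se = math.hypot(*(pos[-1] - pos[0]))
        assert d_ttl == pytest.approx(exp_ttl, abs=1e-9)
        assert d_se == pytest.approx(exp_se, abs=1e-9)
        assert pers == pytest.approx(exp_ttl / exp_se, abs=1e-9)


class TestStepMoments:
    def test_constant_steps(self):
        assert step_extremes_and_moments([5, 5, 5]) == (5, 5, 5, 0)

    def test_extremes(self):
        d_min, d_max, _, _ = step_extremes_and_moments([0, 12])
        assert (d_min, d_max) == (0, 12)

    def test_matches_moment_formulas(self, rng):
        s = rng.uniform(0, 10, 40)
        d_min, d_max, mean, sd = step_extremes_and_moments(s)
        assert mean == pytest.approx(s.sum() / 40, rel=1e-12)
        assert sd == pytest.approx(
            math.sqrt(((s - s.mean()) ** 2).sum() / 39), rel=1e-12
        )


class TestSpeedsAccelerations:
    def test_uniform_motion(self):
        v, a = speeds_and_accelerations([4.0] * 6, Calibration(1.0, 4.0))
        assert (v == 1.0).all() and len(a) == 5 and (a == 0.0).all()

    def test_acceleration_arithmetic(self):
        v, a = speeds_and_accelerations([4.0, 12.0], Calibration(1.0, 4.0))
        np.testing.assert_allclose(v, [1.0, 3.0])
        np.testing.assert_allclose(a, [0.5])

    def test_matches_finite_difference_oracle(self, rng):
        steps = rng.uniform(0, 8, 30)
        cal = Calibration(1.0, 4.0)
        v, a = speeds_and_accelerations(steps, cal)
        np.testing.assert_allclose(v, steps / 4.0, rtol=1e-12)
        np.testing.assert_allclose(
            a, [(v[i + 1] - v[i]) / 4.0 for i in range(len(v) - 1)], rtol=1e-12
        )


class TestPauseFraction:
    def test_half_below_threshold(self):
        assert pause_fraction([0.1, 0.5, 0.1, 0.9], 0.2) == 50.0

    def test_zero_threshold_strict(self):
        assert pause_fraction([0.0, 0.0, 1.0], 0.0) == 0.0

    def test_matches_counting_oracle(self, rng):
        v = rng.uniform(0, 2, 100)
        thr = 0.7
        assert pause_fraction(v, thr) == 100.0 * sum(x < thr for x in v) / 100


class TestStepAngles:
    @pytest.mark.parametrize(
        "disp,expected",
        [((1, 0), 0.0), ((0, -1), 90.0), ((-1, 0), 180.0), ((0, 1), -90.0)],
    )
    def test_cardinal_directions_image_coords(self, disp, expected):
        ang = step_angles(_track([(0, 0), disp]))
        assert ang[0] == pytest.approx(expected)

    def test_zero_step_is_missing(self):
        ang = step_angles(_track([(1, 1), (1, 1), (2, 1)]))
        assert math.isnan(ang[0]) and ang[1] == 0.0

    def test_matches_atan2_oracle(self, rng):
        pos = rng.normal(size=(30, 2))
        ang = step_angles(pos)
        for i in range(29):
            dx, dy = pos[i + 1] - pos[i]
            assert ang[i] == pytest.approx(math.degrees(math.atan2(-dy, dx)))


class TestSummarizeCell:
    def test_closed_square_path(self):
        tr = _track([(0, 0), (5, 0), (5, 5), (0, 5), (0, 0)])
        s = summarize_cell(tr, CAL1)
        assert s.d_ttl == 20.0 and s.d_SE == 0.0 and math.isnan(s.persistence)

    def test_straight_constant_speed(self):
        tr = _track([(0, i * 2) for i in range(10)])
        s = summarize_cell(tr, CAL1, pause_threshold=0.5)
        assert s.speed_sd == 0.0 and s.accel_mean == 0.0 and s.pause_pct == 0.0
        assert s.persistence == pytest.approx(1.0)

    def test_circular_angle_mean_option(self):
        # signed mean of +170 and -170 is 0; circular mean is 180
        tr = _track([(0, 0), (-10, -math.tan(math.radians(10)) * 10), (-20, 0)])
        signed = summarize_cell(tr, CAL1, angle_method="signed").angle_mean
        circular = summarize_cell(tr, CAL1, angle_method="circular").angle_mean
        assert signed == pytest.approx(0.0, abs=1e-9)
        assert abs(circular) == pytest.approx(180.0, abs=1e-9)


class TestInvariants:
    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        arrays(
            float,
            st.tuples(st.integers(3, 30), st.just(2)),
            elements=st.floats(-100, 100, allow_nan=False),
        )
    )
    def test_persistence_at_least_one_when_defined(self, pos):
        _, d_se, pers = total_and_euclidean(pos, CAL1)
        if d_se > 0:
            assert pers >= 1.0 - 1e-12

    def test_step_mean_between_extremes_and_speed_link(self, rng):
        cal = Calibration(um_per_px=0.8, min_per_frame=4.0)
        for _ in range(50):
            pos = np.cumsum(rng.normal(size=(20, 2)), axis=0)
            steps = step_distances(pos, cal)
            d_min, d_max, mean, _ = step_extremes_and_moments(steps)
            assert d_min <= mean <= d_max
            v, _ = speeds_and_accelerations(steps, cal)
            assert v.mean() == pytest.approx(mean / cal.min_per_frame, rel=1e-12)

    def test_rotation_invariance_of_distance_stats(self, rng):
        pos = np.cumsum(rng.normal(size=(25, 2)), axis=0) + 50
        theta = math.radians(37.0)
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        rotated = (pos - 30.0) @ rot.T + 30.0  # rotate about (30, 30)
        t1 = summarize_cell(_track(pos), CAL1)
        t2 = summarize_cell(_track(rotated), CAL1)
        for f in ("d_ttl", "d_SE", "persistence", "d_min", "d_max", "step_mean",
                  "step_sd", "speed_mean", "speed_sd", "accel_mean", "accel_sd",
                  "pause_pct"):
            assert getattr(t1, f) == pytest.approx(getattr(t2, f), abs=1e-9)
        # angles shift by the rotation angle (mod 360); image y-flip negates it
        a1, a2 = step_angles(pos), step_angles(rotated)
        shift = (a2 - a1) % 360.0
        np.testing.assert_allclose(np.minimum(shift, 360 - shift),
                                   math.degrees(theta), atol=1e-9)

    def test_calibration_linearity(self, rng):
        pos = np.cumsum(rng.normal(size=(15, 2)), axis=0)
        c = 3.7
        s1 = summarize_cell(_track(pos), Calibration(1.0, 4.0))
        s2 = summarize_cell(_track(pos), Calibration(c, 4.0))
        for f in ("d_ttl", "d_SE", "d_min", "d_max", "step_mean", "step_sd",
                  "speed_mean", "speed_sd", "accel_mean", "accel_sd"):
            assert getattr(s2, f) == pytest.approx(c * getattr(s1, f), rel=1e-12)
        assert s2.persistence == pytest.approx(s1.persistence, rel=1e-12)


class TestPopulation:
    def test_identical_cells_zero_dispersion(self):
        tr = _track([(0, i * 2.0) for i in range(8)])
        stats = [summarize_cell(tr, CAL1) for _ in range(5)]
        pop = summarize_population(stats)
        assert pop["n_cells"].iloc[0] == 5
        assert pop["speed_mean"].iloc[0] == pytest.approx(stats[0].speed_mean)
        assert pop["speed_sd"].iloc[0] == pytest.approx(0.0)

    def test_mean_of_means(self):
        t1 = _track([(0, i * 1.0) for i in range(5)], cell_id=1)
        t2 = _track([(0, i * 3.0) for i in range(5)], cell_id=2)
        pop = summarize_population([summarize_cell(t, CAL1) for t in (t1, t2)])
        assert pop["speed_mean"].iloc[0] == pytest.approx(2.0)

    def test_two_level_scheme_matches_oracle(self, rng):
        stats = []
        for cid in range(6):
            pos = np.cumsum(rng.normal(size=(12, 2)), axis=0)
            stats.append(summarize_cell(_track(pos, cell_id=cid + 1), CAL1))
        pop = summarize_population(stats)
        assert pop["step_mean"].iloc[0] == pytest.approx(
            np.mean([s.step_mean for s in stats])
        )
        assert pop["step_sd"].iloc[0] == pytest.approx(
            np.mean([s.step_sd for s in stats])
        )


class TestCompareGroups:
    def _stats(self, values):
        out = []
        for i, v in enumerate(values):
            tr = _track([(0, j * v) for j in range(5)], cell_id=i + 1)
            out.append(summarize_cell(tr, CAL1))
        return out

    def test_identical_groups_p_one(self):
        g = self._stats([2.0, 2.0, 2.0])
        t, p = compare_groups(g, g, "speed_mean")
        assert (t, p) == (0.0, 1.0)

    def test_separated_groups_tiny_p(self, rng):
        a = self._stats(0.0 + rng.normal(0, 1e-6, 4))
        b = self._stats(10.0 + rng.normal(0, 1e-6, 4))
        _, p = compare_groups(a, b, "speed_mean")
        assert p < 1e-3

    def test_matches_textbook_t_formula(self, rng):
        a = self._stats(rng.normal(2, 0.5, 6))
        b = self._stats(rng.normal(2.5, 0.5, 7))
        t, p = compare_groups(a, b, "speed_mean")
        xa = np.array([s.speed_mean for s in a])
        xb = np.array([s.speed_mean for s in b])
        na, nb = len(xa), len(xb)
        sp2 = ((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1)) / (na + nb - 2)
        t_exp = (xa.mean() - xb.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(t_exp, rel=1e-12)

    def test_small_group_rejected(self):
        g = self._stats([1.0])
        with pytest.raises(InsufficientDataError):
            compare_groups(g, g, "speed_mean")
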