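"""TDOA solving, error sensitivity, subset weighting and the full pipeline."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from tdoatrack.geometry_io import PlanePoint
from tdoatrack.position import (
    DegenerateGeometryError,
    SubsetSolution,
    combine_position,
    error_sensitivity,
    group_by_transmission,
    position_run,
    solve_tdoa_triple,
)
from tdoatrack.simulate import (
    PropagationModel,
    ReceiverArray,
    TagSpec,
    TagTrajectory,
    gen_transmission_times,
    simulate_detections,
    simulate_moving_track,
)

C = 1447.0


def forward_arrivals(receivers, p, c=C, t0=0.0):
    """Forward-model oracle: exact arrival times for a source at p."""
    receivers = np.asarray(receivers, dtype=float)
    d = np.hypot(*(np.asarray(p) - receivers).T)
    return t0 + d / c


def fd_sensitivity(receivers, p, c=C, step=1e-7):
    """Finite-difference oracle for the arrival-time Jacobian norm."""
    receivers = np.asarray(receivers, dtype=float)
    a0 = forward_arrivals(receivers, p, c, t0=1.0)
    J = np.zeros((2, 3))
    for j in range(3):
        cols = []
        for sgn in (+1, -1):
            a = a0.copy()
            a[j] += sgn * step
            sols = solve_tdoa_triple(receivers, a, c)
            best = min(
                sols, key=lambda s: (s.position.x - p[0]) ** 2 + (s.position.y - p[1]) ** 2
            )
            cols.append(np.array([best.position.x, best.position.y]))
        J[:, j] = (cols[0] - cols[1]) / (2 * step)
    return float(np.sqrt(np.sum(J**2)))


class TestGrouping:
    def mkdet(self, rows):
        import pandas as pd

        return pd.DataFrame(rows, columns=["receiver_id", "tag_id", "time_s"])

    def test_two_transmissions_split_into_two_groups(self, hex_array):
        det = self.mkdet(
            [("R0", "t", 0.00), ("R1", "t", 0.03), ("R2", "t", 0.05),
             ("R0", "t", 4.00), ("R1", "t", 4.02), ("R3", "t", 4.06)]
        )
        groups = group_by_transmission(det, hex_array, C)
        assert [len(g) for g in groups] == [3, 3]

    def test_group_below_three_receivers_discarded(self, hex_array):
        det = self.mkdet([("R0", "t", 0.0), ("R1", "t", 0.03)])
        assert group_by_transmission(det, hex_array, C) == []

    def test_duplicate_receiver_keeps_earliest_and_counts_distinct(self, hex_array):
        det = self.mkdet(
            [("R0", "t", 0.00), ("R0", "t", 0.02), ("R1", "t", 0.03), ("R2", "t", 0.05)]
        )
        (group,) = group_by_transmission(det, hex_array, C)
        assert len(group) == 3
        r0 = [d for d in group if d.receiver_id == "R0"]
        assert len(r0) == 1 and r0[0].arrival_time == 0.0

    def test_tags_grouped_independently(self, hex_array):
        det = self.mkdet(
            [("R0", "a", 0.00), ("R1", "a", 0.02), ("R2", "a", 0.04),
             ("R0", "b", 0.01), ("R1", "b", 0.03), ("R2", "b", 0.05)]
        )
        groups = group_by_transmission(det, hex_array, C)
        assert sorted(g[0].tag_id for g in groups) == ["a", "b"]


class TestSolveTriple:
    def test_equilateral_equal_arrivals_gives_circumcentre(self):
        # circumcentre of this equilateral triangle is its centroid
        r = 100 * np.array(
            [[np.cos(a), np.sin(a)] for a in np.deg2rad([90, 210, 330])]
        )
        sols = solve_tdoa_triple(r, [1.0, 1.0, 1.0], C)
        centroid = r.mean(axis=0)
        d = [np.hypot(s.position.x - centroid[0], s.position.y - centroid[1]) for s in sols]
        assert min(d) < 1e-6

    def test_zero_noise_recovery_random_interior(self, rng):
        receivers = np.array([[0.0, 0.0], [90.0, 10.0], [40.0, 80.0]])
        for _ in range(100):
            p = receivers.mean(axis=0) + rng.uniform(-25, 25, 2)
            sols = solve_tdoa_triple(receivers, forward_arrivals(receivers, p, t0=3.0), C)
            err = min(
                np.hypot(s.position.x - p[0], s.position.y - p[1]) for s in sols
            )
            assert err < 1e-6

    def test_recovers_emission_time(self):
        receivers = np.array([[0.0, 0.0], [90.0, 10.0], [40.0, 80.0]])
        p = (30.0, 25.0)
        sols = solve_tdoa_triple(receivers, forward_arrivals(receivers, p, t0=5.5), C)
        best = min(sols, key=lambda s: abs(s.position.x - p[0]) + abs(s.position.y - p[1]))
        assert best.emission_time == pytest.approx(5.5, abs=1e-9)
        assert best.emission_time < 5.5 + 1e-6  # earlier than every arrival

    def test_collinear_receivers_raise(self):
        with pytest.raises(DegenerateGeometryError):
            solve_tdoa_triple(
                [[0, 0], [50, 0], [100, 0]], [0.1, 0.1, 0.1], C
            )


class TestErrorSensitivity:
    def test_rotational_symmetry_of_equilateral_subsets(self):
        # rotating an equilateral subset around a central source leaves
        # the geometry, hence the sensitivity, unchanged
        sens = []
        for rot in (0.0, 40.0, 77.0):
            ang = np.deg2rad(np.array([90, 210, 330]) + rot)
            r = 100 * np.column_stack([np.cos(ang), np.sin(ang)])
            sols = solve_tdoa_triple(r, forward_arrivals(r, (0, 0), t0=1.0), C)
            best = min(sols, key=lambda s: s.position.x**2 + s.position.y**2)
            sens.append(best.sensitivity)
        assert np.ptp(sens) < 1e-6 * sens[0]

    def test_closed_form_matches_finite_difference(self, rng):
        receivers = np.array([[0.0, 0.0], [90.0, 10.0], [40.0, 80.0]])
        for _ in range(20):
            p = receivers.mean(axis=0) + rng.uniform(-30, 30, 2)
            sols = solve_tdoa_triple(
                receivers, forward_arrivals(receivers, p, t0=1.0), C
            )
            best = min(
                sols, key=lambda s: (s.position.x - p[0]) ** 2 + (s.position.y - p[1]) ** 2
            )
            assert best.sensitivity == pytest.approx(
                fd_sensitivity(receivers, p), rel=1e-3
            )

    def test_sensitivity_grows_far_outside_the_array(self, hex_array):
        sub = hex_array.xy[[1, 3, 5]]

        def sens_at(p):
            sols = solve_tdoa_triple(sub, forward_arrivals(sub, p, t0=1.0), C)
            best = min(
                sols, key=lambda s: (s.position.x - p[0]) ** 2 + (s.position.y - p[1]) ** 2
            )
            return best.sensitivity

        inside = sens_at(sub.mean(axis=0))
        outside = sens_at(np.array([5 * hex_array.diameter, 0.0]))
        assert outside > inside


class TestCombine:
    def mksol(self, x, y, s, t=0.0):
        return SubsetSolution(PlanePoint(x, y), t, s, ("a", "b", "c"))

    def test_single_subset_is_identity(self):
        fix = combine_position([self.mksol(3.0, -2.0, 5.0, t=1.5)], "t")
        assert (fix.x, fix.y, fix.time) == (3.0, -2.0, 1.5)
        assert fix.sensitivity == 5.0

    def test_identical_positions_unchanged_by_weights(self):
        fix = combine_position(
            [self.mksol(4.0, 4.0, 1.0), self.mksol(4.0, 4.0, 9.0)], "t"
        )
        assert (fix.x, fix.y) == (4.0, 4.0)

    def test_inverse_square_weighting_hand_arithmetic(self):
        # w = 1/1 and 1/9: x = (1*0 + (1/9)*10) / (1 + 1/9) = (10/9)/(10/9) = 1.0
        fix = combine_position([self.mksol(0, 0, 1.0), self.mksol(10, 0, 3.0)], "t")
        assert fix.x == pytest.approx(1.0)
        assert fix.y == 0.0
        assert fix.sensitivity == 1.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            combine_position([], "t")

    def test_fix_lies_in_convex_hull_of_subsets(self, rng):
        for _ in range(20):
            pts = rng.uniform(-50, 50, (6, 2))
            sols = [
                self.mksol(x, y, s)
                for (x, y), s in zip(pts, rng.uniform(0.5, 5.0, 6))
            ]
            fix = combine_position(sols, "t")
            hull = ConvexHull(pts)
            inside = np.all(
                hull.equations[:, :2] @ [fix.x, fix.y] + hull.equations[:, 2] <= 1e-9
            )
            assert inside


class TestPositionRun:
    def test_zero_noise_stationary_recovery(self, hex_array, rng):
        model = PropagationModel(sigma_t=0.0)
        traj = TagTrajectory.stationary((22.0, -13.0), 160)
        times = gen_transmission_times(160, TagSpec("t", 1, 2), rng)
        det = simulate_detections(hex_array, traj, times, model, rng, "t")
        track = position_run(det, hex_array)["t"]
        assert len(track) == len(times)
        err = np.hypot(track.xy[:, 0] - 22.0, track.xy[:, 1] + 13.0)
        assert err.max() < 1e-6
        assert np.all(track.n_receivers >= 3)

    def test_zero_noise_moving_recovery(self, hex_array, rng):
        model = PropagationModel(sigma_t=0.0)
        traj = simulate_moving_track([(-40, -20), (40, 0), (0, 50)], 1.2, 1.0)
        times = gen_transmission_times(traj.t_end, TagSpec("t", 1, 2), rng)
        det = simulate_detections(hex_array, traj, times, model, rng, "t")
        track = position_run(det, hex_array)["t"]
        truth = traj.at(track.times)
        err = np.hypot(*(track.xy - truth).T)
        assert err.max() < 1e-6

    def test_fixes_time_ordered(self, hex_array, rng):
        traj = TagTrajectory.stationary((5, 5), 120)
        times = gen_transmission_times(120, TagSpec("t", 1, 2), rng)
        det = simulate_detections(hex_array, traj, times, PropagationModel(), rng, "t")
        track = position_run(det, hex_array)["t"]
        assert np.all(np.diff(track.times) > 0)
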