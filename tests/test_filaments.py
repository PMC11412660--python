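"""Tip detection, trajectory linking, activation phase and phase defects."""

import numpy as np
import pytest

import rotorlab as rl
from rotorlab.filaments import (TipPoint, TipSpec, activation_phase,
                                bilinear_face_intersection, detect_tips,
                                link_trajectories, phase_defect_density)

from _oracles import newton_face_intersections


def _bilinear(corners, s, t):
    c00, c10, c01, c11 = corners
    return (c00 * (1 - s) * (1 - t) + c10 * s * (1 - t)
            + c01 * (1 - s) * t + c11 * s * t)


class TestBilinearFaceIntersection:
    def test_linear_case_center(self):
        # f = s - 0.5, g = t - 0.5 (corner data of linear fields)
        f = [-0.5, 0.5, -0.5, 0.5]
        g = [-0.5, -0.5, 0.5, 0.5]
        pts = bilinear_face_intersection(f, g, 0.0, 0.0)
        assert len(pts) == 1
        assert pts[0] == pytest.approx((0.5, 0.5), abs=1e-12)

    def test_parallel_isolines_no_intersection(self):
        f = [-0.5, 0.5, -0.5, 0.5]
        g = [v + 1.0 for v in f]
        assert bilinear_face_intersection(f, g, 0.0, 0.0) == []

    def test_constant_interpolant_at_isovalue_is_line_not_point(self):
        f = [0.0, 0.0, 0.0, 0.0]
        g = [-0.5, 0.5, -0.5, 0.5]
        assert bilinear_face_intersection(f, g, 0.0, 0.0) == []

    def test_two_intersections_possible(self):
        # strongly bilinear pair with two crossings inside the face
        f = [1.0, -1.0, -1.0, 1.0]
        g = [0.5, -0.3, -0.7, 1.1]
        pts = bilinear_face_intersection(f, g, 0.0, 0.1)
        want = newton_face_intersections(f, g, 0.0, 0.1)
        assert len(pts) == len(want)

    def test_residuals_and_newton_oracle_on_random_faces(self, rng):
        n_faces = 500
        n_checked = 0
        for _ in range(n_faces):
            f = rng.normal(size=4)
            g = rng.normal(size=4)
            fi, gi = rng.normal(scale=0.3), rng.normal(scale=0.3)
            pts = bilinear_face_intersection(f, g, fi, gi)
            for s, t in pts:
                assert abs(_bilinear(f, s, t) - fi) <= 1e-10 * max(
                    np.abs(f - fi).max(), 1.0)
                assert abs(_bilinear(g, s, t) - gi) <= 1e-10 * max(
                    np.abs(g - gi).max(), 1.0)
            want = newton_face_intersections(f, g, fi, gi)
            assert len(pts) == len(want)
            for (s, t), (ws, wt) in zip(sorted(pts), want):
                assert s == pytest.approx(ws, abs=1e-10)
                assert t == pytest.approx(wt, abs=1e-10)
                n_checked += 1
        assert n_checked > 100   # the ensemble really exercised crossings


class TestDetectTips:
    def test_planar_wave_has_no_tips(self):
        # parallel isolines of u and v everywhere
        g = rl.GridSpec((20, 10), (1.0, 1.0))
        x = g.positions()[0]
        state = np.stack([np.sin(x / 3.0), np.cos(x / 3.0)])
        tips = detect_tips(state, g, rl.InhomField.uniform(g),
                           TipSpec(0, 0.0, 1, 0.0))
        assert tips == []

    def test_constructed_crossing_located_within_half_voxel(self):
        # u = x - cx, v = y - cy with the crossing at a grid vertex: the
        # intersection sits on the shared corner of 4 faces
        g = rl.GridSpec((11, 9), (1.0, 1.0))
        cx, cy = 5.0, 4.0
        x, y = g.positions()
        state = np.stack([x - cx, y - cy])
        tips = detect_tips(state, g, rl.InhomField.uniform(g),
                           TipSpec(0, 0.0, 1, 0.0))
        assert len(tips) == 4
        centroid = np.mean([t.position for t in tips], axis=0)
        assert np.linalg.norm(centroid - [cx, cy]) <= 0.5

    def test_crossing_inside_face_found_once(self):
        g = rl.GridSpec((8, 8), (1.0, 1.0))
        x, y = g.positions()
        state = np.stack([x - 3.25, y - 4.75])
        tips = detect_tips(state, g, rl.InhomField.uniform(g),
                           TipSpec(0, 0.0, 1, 0.0))
        assert len(tips) == 1
        assert tips[0].position == pytest.approx((3.25, 4.75), abs=1e-9)
        assert tips[0].plane == (0, 1)
        assert tips[0].anchor == (3, 4)

    def test_faces_with_exterior_corners_skipped(self):
        g = rl.GridSpec((8, 8), (1.0, 1.0))
        x, y = g.positions()
        state = np.stack([x - 3.25, y - 4.75])
        labels = np.ones((8, 8), dtype=np.int32)
        labels[3, 4] = 0   # kill the anchor corner of the crossing face
        tips = detect_tips(state, g, rl.InhomField(labels, g),
                           TipSpec(0, 0.0, 1, 0.0))
        assert tips == []

    def test_exterior_relabeling_far_away_is_invariant(self):
        g = rl.GridSpec((12, 12), (1.0, 1.0))
        x, y = g.positions()
        state = np.stack([x - 3.25, y - 4.75])
        labels = np.ones((12, 12), dtype=np.int32)
        tips_a = detect_tips(state, g, rl.InhomField(labels, g),
                             TipSpec(0, 0.0, 1, 0.0))
        labels2 = labels.copy()
        labels2[10:, 10:] = 2      # relabel a far corner
        labels2[0, 11] = 0
        tips_b = detect_tips(state, g, rl.InhomField(labels2, g),
                             TipSpec(0, 0.0, 1, 0.0))
        assert [t.position for t in tips_a] == [t.position for t in tips_b]

    def test_isovalue_out_of_range_warns_empty(self):
        g = rl.GridSpec((6, 6), (1.0, 1.0))
        state = np.zeros((2, 6, 6))
        with pytest.warns(UserWarning, match="isovalues"):
            tips = detect_tips(state, g, rl.InhomField.uniform(g),
                               TipSpec(0, 5.0, 1, 5.0))
        assert tips == []

    def test_3d_scans_all_three_plane_families(self):
        # filament along z: u = x - cx, v = y - cy at every z
        g = rl.GridSpec((7, 7, 4), (1.0, 1.0, 1.0))
        x, y, z = g.positions()
        state = np.stack([x - 3.25, y - 3.75])
        tips = detect_tips(state, g, rl.InhomField.uniform(g),
                           TipSpec(0, 0.0, 1, 0.0))
        planes = {t.plane for t in tips}
        assert planes == {(0, 1)}          # only xy-faces intersect both
        assert len(tips) == 4              # one per z-layer
        zs = sorted(t.position[2] for t in tips)
        assert zs == [0.0, 1.0, 2.0, 3.0]

    def test_delayed_mode_uses_previous_frame(self):
        g = rl.GridSpec((8, 8), (1.0, 1.0))
        x, y = g.positions()
        now = x - 3.25
        before = y - 4.75
        state = np.stack([now, np.zeros_like(now)])
        tips = detect_tips(state, g, rl.InhomField.uniform(g),
                           TipSpec(0, 0.0, mode="delayed", delay=10.0),
                           prev_layer=before)
        assert len(tips) == 1


class TestLinking:
    @staticmethod
    def _tip(t, x, y):
        return TipPoint(t, (x, y), (0, 1), (int(x), int(y)), (0, 1),
                        (0.5, 0.5), (0.0, 0.0))

    def test_stationary_tip_single_open_trajectory(self):
        frames = [(float(k), [self._tip(float(k), 5.0, 5.0)])
                  for k in range(10)]
        trajs = link_trajectories(frames, max_link_distance=2.0)
        assert len(trajs) == 1
        assert len(trajs[0].points) == 10
        assert trajs[0].is_open

    def test_disappearing_tip_closed_with_death_time(self):
        frames = [(float(k), [self._tip(float(k), 5.0, 5.0)] if k < 5 else [])
                  for k in range(8)]
        trajs = link_trajectories(frames, max_link_distance=2.0)
        assert len(trajs) == 1
        assert trajs[0].death_time == 5.0
        assert not trajs[0].is_open

    def test_distant_swap_does_not_link(self):
        # two tips exchanging positions at separation >> link radius: greedy
        # matching agrees with exhaustive assignment — each trajectory keeps
        # its own position (identity match), no cross-link
        radius = 1.0
        frames = [
            (0.0, [self._tip(0.0, 0.0, 0.0), self._tip(0.0, 10.0, 0.0)]),
            (1.0, [self._tip(1.0, 10.0, 0.0), self._tip(1.0, 0.0, 0.0)]),
        ]
        trajs = link_trajectories(frames, max_link_distance=radius)
        assert len(trajs) == 2
        for traj in trajs:
            assert traj.is_open
            xs = {p.position[0] for p in traj.points}
            assert len(xs) == 1   # stationary, not swapped across 10 mm

    def test_greedy_matches_nearest_first(self):
        frames = [
            (0.0, [self._tip(0.0, 0.0, 0.0), self._tip(0.0, 3.0, 0.0)]),
            (1.0, [self._tip(1.0, 0.4, 0.0), self._tip(1.0, 2.8, 0.0)]),
        ]
        trajs = link_trajectories(frames, max_link_distance=1.0)
        assert len(trajs) == 2
        ends = sorted(t.points[-1].position[0] for t in trajs)
        starts = sorted(t.points[0].position[0] for t in trajs)
        assert starts == [0.0, 3.0] and ends == [0.4, 2.8]


class TestActivationPhase:
    def test_phase_zero_when_t_equals_lat(self):
        lat = np.full((4, 4), 7.0)
        field = activation_phase(lat, t=7.0, period=100.0)
        assert np.allclose(field.values, 0.0)

    def test_half_period_maps_to_plus_pi(self):
        lat = np.zeros((3, 3))
        field = activation_phase(lat, t=50.0, period=100.0)
        assert np.allclose(field.values, np.pi)

    def test_sentinel_vertices_excluded(self):
        lat = np.array([[5.0, -1.0], [5.0, 5.0]])
        field = activation_phase(lat, t=5.0, period=10.0)
        assert not field.valid[0, 1]
        assert np.isnan(field.values[0, 1])

    def test_all_sentinel_rejected(self):
        with pytest.raises(rl.ValidationError):
            activation_phase(np.full((3, 3), -1.0), 10.0, 100.0)

    def test_plane_wave_gives_spatial_sawtooth(self):
        # LAT = x/c -> phase sawtooth in x with spatial period c*T
        c, period = 0.5, 40.0
        x = np.arange(100) * 1.0
        lat = x / c
        field = activation_phase(lat, t=300.0, period=period)
        phi = field.values
        # analytic: wrap(2 pi (t - x/c)/T); spatial period c*T = 20 vertices.
        # Compare on the circle (the +-pi boundary is FP-fragile).
        circ = np.angle(np.exp(1j * (phi[:50] - phi[20:70])))
        assert np.allclose(circ, 0.0, atol=1e-9)
        # sawtooth resets: between adjacent samples the wrap jump is
        # 2 pi minus one ramp step of 2 pi dx/(c T)
        jumps = np.abs(np.diff(phi))
        want = 2 * np.pi * (1.0 - 1.0 / (c * period))
        assert np.isclose(jumps[jumps > 1].mean(), want, rtol=1e-6)


class TestPhaseDefectDensity:
    def test_constant_phase_zero_density(self):
        rho = phase_defect_density(np.full((5, 5), 1.2))
        assert np.all(rho == 0.0)

    def test_pi_jump_closed_form(self):
        # two half-planes at phases 0 and pi: a vertex adjacent to the jump
        # has one cross-boundary neighbor out of its 4 (interior) neighbors,
        # contributing (1 - cos(pi))/2 = 1, so rho = 1/4 there (1/3 at edges)
        phi = np.zeros((6, 8))
        phi[3:, :] = np.pi
        rho = phase_defect_density(phi)
        inner = rho[2, 1:-1]
        assert np.allclose(inner, 0.25)
        assert rho[2, 0] == pytest.approx(1.0 / 3.0)
        assert np.all(rho[0, :] == 0.0)
        # jump-adjacent rows are the argmax
        rows = np.argsort(rho.max(axis=1))[-2:]
        assert set(rows) == {2, 3}

    def test_smooth_ramp_second_order(self):
        # |grad phi| dx = delta -> rho ~ (1 - cos delta)/2 = delta^2/4 + O(d^4)
        for delta in (0.2, 0.1, 0.05):
            phi = np.outer(np.arange(20) * delta, np.ones(5))
            rho = phase_defect_density(phi)
            interior = rho[1:-1, 1:-1]
            want = 0.5 * (1 - np.cos(delta))
            # interior vertices average two cross-gradient and two flat
            # neighbors in y... the x-neighbors carry the ramp:
            assert np.allclose(interior, want / 2.0, rtol=1e-12)

    def test_isolated_vertex_zero(self):
        g = rl.GridSpec((3, 3), (1.0, 1.0))
        labels = np.zeros((3, 3), dtype=np.int32)
        labels[1, 1] = 1
        rho = phase_defect_density(np.ones((3, 3)), rl.InhomField(labels, g))
        assert rho[1, 1] == 0.0


class TestTipCountParity:
    def test_s1s2_tip_count_changes_by_small_steps(self, s1s2_run):
        """Tip counts start at zero, become positive after S2, and change
        between consecutive frames by pair creation/annihilation (+-2) or
        single boundary events (+-1)."""
        _, res = s1s2_run
        counts = res.tip_counts()
        assert counts[0] == 0
        assert max(counts) >= 1
        diffs = np.abs(np.diff(counts))
        assert diffs.max() <= 2
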