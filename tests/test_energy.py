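import numpy as np
import pytest

from cororeg.carm import backproject_ray, project
from cororeg.energy import (EnergyWeights, deform, deform_branches, energy_cont,
                            energy_curv, energy_image, _grad_cont, _grad_curv,
                            _grad_image, _rays)
from cororeg.matching import match_points
from cororeg.synthetic import SimConfig, make_case


def straight3(n=21, spacing=1.0):
    return np.stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)], axis=1)


class TestEnergyCont:
    def test_uniform_spacing_zero(self):
        per, total = energy_cont(straight3(), dbar=1.0)
        assert total == 0.0

    def test_single_stretched_gap(self):
        pts = straight3()
        pts[10:] += np.array([1.0, 0.0, 0.0])  # one interval at dbar + 1
        per, total = energy_cont(pts, dbar=1.0)
        assert per[10] == pytest.approx(1.0)
        assert total == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        pts = straight3() + rng.normal(scale=0.2, size=(21, 3))
        dbar = 1.0
        per, total = energy_cont(pts, dbar)
        oracle = sum((dbar - np.linalg.norm(pts[i] - pts[i - 1])) ** 2
                     for i in range(1, 21))
        assert total == pytest.approx(oracle, rel=1e-12)
        assert per[0] == 0.0


class TestEnergyCurv:
    def test_collinear_zero(self):
        _, total = energy_curv(straight3())
        assert total == 0.0

    def test_right_angle_corner(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float)
        per, total = energy_curv(pts)
        # v0 - 2 v1 + v2 = (-1, 1, 0): squared norm 2
        assert per[1] == pytest.approx(2.0)
        assert total == pytest.approx(2.0)

    def test_matches_loop_oracle(self, rng):
        pts = rng.normal(size=(15, 3))
        _, total = energy_curv(pts)
        oracle = sum(np.linalg.norm(pts[i - 1] - 2 * pts[i] + pts[i + 1]) ** 2
                     for i in range(1, 14))
        assert total == pytest.approx(oracle, rel=1e-12)


class TestEnergyImage:
    def test_point_on_ray_zero(self, geometry):
        pts = straight3() + np.array([0.0, 5.0, 0.0])
        uv = project(pts, geometry)
        valid = np.ones(len(pts), bool)
        origins, dirs = _rays(uv, valid, geometry)
        _, total = energy_image(pts, valid, origins, dirs)
        assert total == pytest.approx(0.0, abs=1e-18)

    def test_invalid_points_contribute_nothing(self, geometry):
        pts = straight3()
        valid = np.zeros(len(pts), bool)
        origins = np.zeros((len(pts), 3))
        dirs = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
        _, total = energy_image(pts, valid, origins, dirs)
        assert total == 0.0

    def test_two_mm_off_ray_gives_four(self, geometry):
        uv = np.array([[0.0, 0.0]])
        o, d = backproject_ray(uv[0], geometry)
        perp = np.cross(d, [1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        p = (o + 500 * d + 2.0 * perp)[None]
        per, total = energy_image(p, np.ones(1, bool), o[None], d[None])
        assert total == pytest.approx(4.0, rel=1e-9)


class TestGradients:
    def numeric_grad(self, f, pts, eps=1e-6):
        g = np.zeros_like(pts)
        for i in range(pts.shape[0]):
            for j in range(3):
                p1, p2 = pts.copy(), pts.copy()
                p1[i, j] += eps
                p2[i, j] -= eps
                g[i, j] = (f(p1) - f(p2)) / (2 * eps)
        return g

    def test_analytic_gradients_match_finite_differences(self, geometry, rng):
        pts = straight3(12) + rng.normal(scale=0.3, size=(12, 3))
        dbar = 1.0
        np.testing.assert_allclose(
            _grad_cont(pts, dbar),
            self.numeric_grad(lambda p: energy_cont(p, dbar)[1], pts), atol=1e-5)
        np.testing.assert_allclose(
            _grad_curv(pts),
            self.numeric_grad(lambda p: energy_curv(p)[1], pts), atol=1e-5)
        uv = project(pts + rng.normal(scale=0.5, size=(12, 3)), geometry)
        valid = np.ones(12, bool)
        origins, dirs = _rays(uv, valid, geometry)
        np.testing.assert_allclose(
            _grad_image(pts, valid, origins, dirs),
            self.numeric_grad(
                lambda p: energy_image(p, valid, origins, dirs)[1], pts),
            atol=1e-5)


class TestDeform:
    def test_zero_displacement_converges_immediately(self, geometry):
        pts = straight3() + np.array([0.0, 10.0, 0.0])
        target2d = project(pts, geometry)
        state = deform(pts, target2d, geometry, max_iter=200)
        final = state.energy_trace[-1]
        assert final["e_image"] < 1e-6
        assert state.iterations < 200 or state.converged

    def test_straight_uniform_line_is_fixed_point_without_image(self, geometry):
        pts = straight3()
        w = EnergyWeights(mu=0.5, tau=0.4, phi=0.0)
        state = deform(pts, project(pts, geometry), geometry, weights=w,
                       max_iter=50)
        np.testing.assert_allclose(state.branches[0], pts, atol=1e-12)

    def test_energy_nonincreasing_between_rematches(self, geometry, rng):
        pts = straight3(30)
        target = pts + np.array([0.0, 2.0, 0.0])
        uv = project(target, geometry)
        state = deform(pts, uv, geometry, step=1e-4, max_iter=100,
                       rematch_every=25, tol=0.0)
        trace = state.energy_trace
        for a, b in zip(trace[:-1], trace[1:]):
            if (b["iter"] - 1) % 25 != 0:  # exclude refresh boundaries
                assert b["total"] <= a["total"] + 1e-9

    def test_recovers_smooth_displacement_on_simulator_case(self):
        cfg = SimConfig(rigid_frac=0.0)
        case = make_case(cfg, seed=77)
        gt2d = case.tree2d_clean.all_points()
        edge_order = sorted(case.correspondences)
        branches = [case.tree3d.edge_centerline(*e).points.copy()
                    for e in edge_order]
        cands = [case.correspondences[e] for e in edge_order]
        from scipy.spatial import cKDTree
        kd = cKDTree(gt2d)
        pre = np.mean(kd.query(project(np.vstack(branches), case.geometry))[0])
        state = deform_branches(branches, cands, case.geometry)
        post_pts = project(np.vstack(state.branches), case.geometry)
        post = np.mean(kd.query(post_pts)[0])
        assert post < 0.5
        assert post < 0.2 * pre

    def test_topology_preserved(self, geometry):
        t = np.linspace(0, np.pi, 40)
        pts = np.stack([20 * np.cos(t), 20 * np.sin(t), np.zeros(40)], axis=1)
        target = pts + np.array([1.5, -1.0, 0.5])
        state = deform(pts, project(target, geometry), geometry)
        out = state.branches[0]
        assert out.shape == pts.shape
        seg_in = np.diff(pts, axis=0)
        seg_out = np.diff(out, axis=0)
        cosines = np.einsum("ij,ij->i", seg_in, seg_out) / (
            np.linalg.norm(seg_in, axis=1) * np.linalg.norm(seg_out, axis=1))
        assert cosines.min() > 0.0  # no direction reversal introduced

    def test_shared_bifurcation_points_stay_coincident(self, geometry):
        a = straight3(15)
        b = np.stack([14.0 + np.arange(15.0), np.arange(15.0) * 0.5,
                      np.zeros(15)], axis=1)
        assert np.allclose(a[-1], b[0])
        ta = project(a + np.array([0, 1.0, 0]), geometry)
        tb = project(b + np.array([0, 1.0, 0]), geometry)
        state = deform_branches([a, b], [ta, tb], geometry, max_iter=100)
        np.testing.assert_allclose(state.branches[0][-1], state.branches[1][0],
                                   atol=1e-9)
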