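"""Deformable model: speed factors, SDF handling, topology-guarded evolution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from delfmap.levelset import (LevelSet, SpeedParams, advection_velocity,
                              binary_topology, combine_factors,
                              combined_probability, distance_factor, evolve,
                              init_sdf, mean_curvature, smooth_surface,
                              stopping_factor)
from delfmap.volume import ScalarVolume


def sphere_sdf(n=30, R=10.0, h=1.0):
    c = (n - 1) / 2
    idx = np.indices((n, n, n)).astype(float)
    r = np.sqrt(((idx - c) ** 2).sum(axis=0)) * h
    return r - R, r


class TestLogisticFactors:
    def test_beta_midpoint_and_extremes(self):
        assert stopping_factor(0.8, 40, 0.8) == pytest.approx(0.0, abs=1e-15)
        assert stopping_factor(1.0, 40, 0.8) == pytest.approx(
            2 / (1 + np.exp(-8)) - 1)
        assert stopping_factor(0.0, 40, 0.8) == pytest.approx(
            2 / (1 + np.exp(32)) - 1)
        assert stopping_factor(1.0, 40, 0.8) == pytest.approx(0.99933, abs=1e-5)

    def test_gamma_midpoint_and_extremes(self):
        assert distance_factor(6.0, 40, 6.0) == pytest.approx(0.0, abs=1e-15)
        assert distance_factor(0.0, 40, 6.0) == pytest.approx(
            2 / (1 + np.exp(-20)) - 1)
        assert distance_factor(12.0, 40, 6.0) == pytest.approx(-1.0, abs=1e-8)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_beta_monotone(self, p1, p2):
        # strictly monotone wherever the logistic is resolvable in double
        # precision; never decreasing anywhere
        if p1 == p2:
            return
        lo, hi = sorted([p1, p2])
        assert stopping_factor(lo) <= stopping_factor(hi)
        if 0.5 <= lo and hi - lo > 1e-6:
            assert stopping_factor(lo) < stopping_factor(hi)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0, 11.9), st.floats(0, 11.9))
    def test_gamma_antitone_below_saturation(self, d1, d2):
        if d1 == d2:
            return
        lo, hi = sorted([d1, d2])
        assert distance_factor(hi) <= distance_factor(lo)
        if hi <= 9.0 and hi - lo > 1e-6:
            assert distance_factor(hi) < distance_factor(lo)

    def test_or_sign_combination(self):
        assert combine_factors(0.5, 0.5) == pytest.approx(0.25)
        assert combine_factors(0.5, -0.5) == pytest.approx(-0.25)
        assert combine_factors(-0.5, 0.5) == pytest.approx(-0.25)
        assert combine_factors(-0.5, -0.5) == pytest.approx(-0.25)
        assert combine_factors(0.0, 0.7) == 0.0


class TestCombinedProbability:
    def test_uniform_field_is_preserved(self):
        p = np.full((8, 8, 8), 0.6)
        out = combined_probability(p * 0.5, p * 0.5, None)
        np.testing.assert_allclose(out, 0.6)

    def test_skeleton_masks_neighbours(self):
        pg = np.full((5, 5, 5), 1.0)
        pw = np.zeros((5, 5, 5))
        s = np.ones((5, 5, 5), bool)
        s[2, 2, 2] = False
        out = combined_probability(pg, pw, s, w0=0.5, neighborhood=18)
        # all neighbours are barrier voxels: only the centre term remains
        assert out[2, 2, 2] == pytest.approx(0.5)


class TestSdf:
    def test_ball_sdf_near_interface(self):
        phi, r = sphere_sdf(32, 10.0)
        mask = phi < 0
        ls = init_sdf(mask, 1.0)
        band = np.abs(r - 10.0) < 2
        assert np.abs(ls.ls.data[band] - (r - 10.0)[band]).max() <= 0.5 + 0.2
        assert (ls.ls.data[mask] < 0).all()

    def test_halfspace_sdf_linear_along_axis(self):
        m = np.zeros((16, 16, 16), bool)
        m[:, :, :8] = True
        ls = init_sdf(m, 1.0)
        col = ls.ls.data[8, 8]
        np.testing.assert_allclose(np.diff(col), 1.0)
        assert col[7] == pytest.approx(-0.5)
        assert col[8] == pytest.approx(0.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            init_sdf(np.zeros((8, 8, 8), bool), 1.0)

    def test_multi_component_warns(self):
        m = np.zeros((12, 12, 12), bool)
        m[2:4, 2:4, 2:4] = True
        m[8:10, 8:10, 8:10] = True
        with pytest.warns(UserWarning):
            init_sdf(m, 1.0)


class TestCurvature:
    def test_plane_has_zero_curvature(self):
        z = np.indices((12, 12, 12)).astype(float)[2]
        ls = LevelSet(ScalarVolume(z - 6.0, 1.0))
        k = mean_curvature(ls)
        assert np.abs(k[2:-2, 2:-2, 2:-2]).max() < 1e-10

    def test_sphere_curvature_is_2_over_R(self):
        phi, r = sphere_sdf(30, 10.0)
        ls = LevelSet(ScalarVolume(phi, 1.0))
        k = mean_curvature(ls)
        sh = np.abs(phi) < 0.8
        assert k[sh].mean() == pytest.approx(0.2, rel=0.1)

    def test_cylinder_curvature_is_1_over_R(self):
        n = 30
        c = (n - 1) / 2
        idx = np.indices((n, n, n)).astype(float)
        rc = np.sqrt(((idx[:2] - c) ** 2).sum(axis=0))
        ls = LevelSet(ScalarVolume(rc - 8.0, 1.0))
        k = mean_curvature(ls)
        sh = (np.abs(rc - 8.0) < 0.8)
        sh[:, :, :3] = sh[:, :, -3:] = False
        assert k[sh].mean() == pytest.approx(1 / 8, rel=0.1)


class TestAdvectionVelocity:
    def test_zero_beta_gives_zero_velocity(self):
        phi, _ = sphere_sdf(20, 6.0)
        v = advection_velocity(ScalarVolume(-phi, 1.0), np.zeros(phi.shape))
        assert np.abs(v).max() == 0.0

    def test_positive_beta_points_outward_in_potential_mode(self):
        # potential decays outward, so -grad(phi_pot) is outward
        phi, r = sphere_sdf(20, 6.0)
        pot = np.exp(-r)          # monotone decreasing outward
        v = advection_velocity(ScalarVolume(pot, 1.0), np.ones(phi.shape),
                               source="potential")
        c = (20 - 1) / 2
        idx = np.indices((20, 20, 20)).astype(float)
        rhat = (idx - c) / np.maximum(r, 1e-9)
        dot = (v * rhat).sum(axis=0)
        sh = (r > 3) & (r < 8)
        assert dot[sh].min() > 0.9


class TestEvolution:
    def test_null_evolution_is_identity(self):
        phi, _ = sphere_sdf(24, 8.0)
        ls = LevelSet(ScalarVolume(phi.copy(), 1.0))
        out = evolve(ls, np.zeros((3, 24, 24, 24)),
                     SpeedParams(w_alpha=1.0, w_kappa=0.0), None, max_iter=5)
        np.testing.assert_array_equal(out.ls.data, phi)

    def test_curvature_flow_shrinks_sphere_by_law(self):
        phi, r = sphere_sdf(30, 10.0)
        ls = LevelSet(ScalarVolume(phi, 1.0))
        out = evolve(ls, None, SpeedParams(w_alpha=0.0, w_kappa=1.0), None,
                     max_iter=120, conv_tol=0.0)
        t = 120 / 12.0
        sh = np.abs(out.ls.data) < 1.5
        R_est = (r[sh] - out.ls.data[sh]).mean()
        assert R_est ** 2 == pytest.approx(100 - 4 * t, rel=0.05)

    def test_spike_erodes_monotonically_under_curvature_flow(self):
        # curvature flow shrinks high-curvature perturbations: the spike
        # column never regrows and is shorter after enough iterations
        n = 24
        m = np.zeros((n, n, n), bool)
        m[:, :, :8] = True
        m[12, 12, 8:12] = True     # 4-voxel spike on a plane
        cur = init_sdf(m, 1.0)
        start = cur.inside[12, 12].sum()
        heights = []
        for _ in range(4):
            cur = smooth_surface(cur, 8)
            heights.append(cur.inside[12, 12].sum())
        assert all(a >= b for a, b in zip(heights, heights[1:]))
        assert heights[-1] < start

    def test_smoothing_preserves_sphere_topology(self):
        phi, _ = sphere_sdf(24, 8.0)
        ls = LevelSet(ScalarVolume(phi, 1.0))
        out = smooth_surface(ls, 3)
        assert binary_topology(out.inside) == binary_topology(ls.inside)

    def test_zero_iterations_is_identity(self):
        phi, _ = sphere_sdf(20, 6.0)
        ls = LevelSet(ScalarVolume(phi.copy(), 1.0))
        assert smooth_surface(ls, 0) is ls

    def test_topology_invariant_under_aggressive_advection(self):
        # inward+outward mixed velocity trying to pinch the dumbbell
        n = 40
        idx = np.indices((n, n, 20)).astype(float)
        c1 = np.array([12.0, 20.0, 10.0])
        c2 = np.array([28.0, 20.0, 10.0])
        d1 = np.sqrt(((idx - c1[:, None, None, None]) ** 2).sum(axis=0)) - 6
        d2 = np.sqrt(((idx - c2[:, None, None, None]) ** 2).sum(axis=0)) - 6
        phi = np.minimum(d1, d2)    # two overlapping balls: one component
        ls = LevelSet(ScalarVolume(phi, 1.0))
        before = binary_topology(ls.inside)
        rng = np.random.default_rng(5)
        v = rng.normal(0, 1.0, (3, n, n, 20))
        out = evolve(ls, v, SpeedParams(w_alpha=1.0, w_kappa=0.0), None,
                     max_iter=60, conv_tol=0.0)
        assert binary_topology(out.inside) == before

    def test_reinitialized_band_has_unit_gradient(self):
        phi, _ = sphere_sdf(30, 10.0)
        ls = LevelSet(ScalarVolume(phi, 1.0))
        out = evolve(ls, None, SpeedParams(w_alpha=0.0, w_kappa=1.0), None,
                     max_iter=20, conv_tol=0.0)
        p = out.ls.data
        gx, gy, gz = np.gradient(p, 1.0)
        mag = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)
        band = np.abs(p) < 4.0
        frac = (np.abs(mag[band] - 1.0) < 0.1).mean()
        assert frac > 0.98

    def test_barrier_voxels_never_flip(self):
        # outward advection everywhere, a barrier shell must stop it
        n = 30
        phi, r = sphere_sdf(n, 6.0)
        ls = LevelSet(ScalarVolume(phi, 1.0))
        shell = (r >= 9.0) & (r < 10.5)
        v = np.zeros((3, n, n, n))
        c = (n - 1) / 2
        idx = np.indices((n, n, n)).astype(float)
        rhat = (idx - c) / np.maximum(r, 1e-9)
        v[:] = rhat
        out = evolve(ls, v, SpeedParams(w_alpha=1.0, w_kappa=0.0), shell,
                     max_iter=60, conv_tol=0.0)
        assert not (out.inside & shell).any()
        assert binary_topology(out.inside) == binary_topology(ls.inside)
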