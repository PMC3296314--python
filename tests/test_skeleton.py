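"""Sulcal medial-surface skeleton: shock and correspondence detectors."""

import numpy as np
import pytest
from scipy import ndimage

from conftest import banks_separated, build_stack, roi_mask
from delfmap.field import solve_dielectric_field
from delfmap.phantom import PhantomSpec
from delfmap.skeleton import (hausdorff_voxels, skeleton_from_correspondence,
                              skeleton_from_shocks)
from delfmap.transport import solve_distance


class TestShockDetector:
    def test_slab_has_no_shocks(self, slab_stack):
        sk = skeleton_from_shocks(slab_stack.distance, slab_stack.wm)
        assert sk.s.sum() == 0

    def test_grad_d_above_shock_threshold_off_skeleton(self, sulcus_fused):
        # the shock signature ||grad d|| < T is absent at nearly all
        # GM voxels outside the detected skeleton
        d = sulcus_fused.distance.d.data
        g = np.gradient(d, sulcus_fused.distance.d.spacing)
        mag = np.sqrt(sum(a ** 2 for a in g))
        gm = sulcus_fused.phantom.gm_hard & ~sulcus_fused.skeleton.s
        assert (mag[gm] > 0.8).mean() >= 0.95

    def test_shocks_on_bisector_of_colliding_flows(self):
        # two facing WM balls: streamlines collide frontally at the
        # bisector plane, where centred ||grad d|| collapses
        nx, ny, nz = 64, 48, 48
        h = 0.5
        x = np.arange(nx)[:, None, None] * h
        y = np.arange(ny)[None, :, None] * h
        z = np.arange(nz)[None, None, :] * h
        cy, cz = (ny - 1) / 2 * h, (nz - 1) / 2 * h
        xc = (nx - 1) / 2 * h
        r1 = np.sqrt((x - xc + 7) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
        r2 = np.sqrt((x - xc - 7) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
        wm = (r1 <= 5.0) | (r2 <= 5.0)
        pot = solve_dielectric_field(np.ones(wm.shape), wm, spacing=h)
        d = solve_distance(pot)
        sk = skeleton_from_shocks(d, wm)
        shape = wm.shape
        mid = ((np.abs(np.broadcast_to(y, shape) - cy) < 6) &
               (np.abs(np.broadcast_to(z, shape) - cz) < 6) &
               (np.abs(np.broadcast_to(x, shape) - xc) < 5))
        sel = sk.s & mid
        assert sel.sum() > 0
        off = np.abs(np.broadcast_to(x, shape)[sel] - xc) / h
        assert off.max() <= 1.0

    def test_threshold_validation(self, slab_stack):
        with pytest.raises(ValueError):
            skeleton_from_shocks(slab_stack.distance, slab_stack.wm, T=1.0)


class TestCorrespondenceDetector:
    def test_slab_empty(self, slab_stack):
        sk = skeleton_from_correspondence(slab_stack.psi, slab_stack.wm)
        assert sk.s.sum() == 0

    def test_fused_sulcus_within_one_voxel_of_medial_plane(self, sulcus_fused):
        ph = sulcus_fused.phantom
        roi = roi_mask(ph)
        sel = sulcus_fused.skeleton.s & roi
        assert sel.sum() > 100
        x3 = np.broadcast_to(ph.p_w.world_grids()[0], sel.shape)
        off = np.abs(x3[sel] - ph.ground_truth["medial_plane_x"]) / 0.5
        assert off.max() <= 1.0

    def test_no_detections_near_wm(self, sulcus_resolved, sulcus_fused):
        for stack in (sulcus_resolved, sulcus_fused):
            dwm = ndimage.distance_transform_edt(~stack.wm)
            assert (stack.skeleton.s & (dwm <= 1.0)).sum() == 0

    @pytest.mark.parametrize("variant", ["resolved", "unresolved", "bridged"])
    def test_separates_banks(self, variant, sulcus_resolved,
                             sulcus_unresolved, sulcus_bridged):
        stack = {"resolved": sulcus_resolved,
                 "unresolved": sulcus_unresolved,
                 "bridged": sulcus_bridged}[variant]
        assert banks_separated(stack)

    def test_bridged_skeleton_spans_bridge(self, sulcus_bridged):
        # label GM voxels by the bank of their source point; S must
        # separate the two labels across the bridge band
        ph = sulcus_bridged.phantom
        gt = ph.ground_truth
        h = 0.5
        z_lo = gt["z_fundus"] + 6.0
        z_hi = gt["z_fundus"] + 9.0
        shape = sulcus_bridged.wm.shape
        x3 = np.broadcast_to(ph.p_w.world_grids()[0], shape)
        z3 = np.broadcast_to(ph.p_w.world_grids()[2], shape)
        roi = roi_mask(ph) & (z3 >= z_lo) & (z3 <= z_hi)
        src_left = sulcus_bridged.psi.psi[0] < gt["medial_plane_x"]
        gm = ph.gm_hard & roi & ~sulcus_bridged.skeleton.s
        lab, _ = ndimage.label(gm & True)
        left_ids = set(np.unique(lab[gm & src_left])) - {0}
        right_ids = set(np.unique(lab[gm & ~src_left])) - {0}
        assert not (left_ids & right_ids)

    def test_parameter_validation(self, slab_stack):
        with pytest.raises(ValueError):
            skeleton_from_correspondence(slab_stack.psi, slab_stack.wm,
                                         d_min_vox=0)
        with pytest.raises(ValueError):
            skeleton_from_correspondence(slab_stack.psi, slab_stack.wm,
                                         neighborhood=10)


class TestRobustness:
    def test_noise_drift_bounded(self, sulcus_fused):
        noisy = build_stack(PhantomSpec(geometry="sulcus", gap_mm=0.0,
                                        noise_sigma=0.1, seed=7))
        roi = roi_mask(sulcus_fused.phantom)
        hd = hausdorff_voxels(sulcus_fused.skeleton.s & roi,
                              noisy.skeleton.s & roi)
        assert hd <= 2.0

    def test_correspondence_more_regular_than_shocks(self):
        noisy = build_stack(PhantomSpec(geometry="sulcus", gap_mm=0.0,
                                        noise_sigma=0.1, seed=7))
        shock = skeleton_from_shocks(noisy.distance, noisy.wm)
        s26 = np.ones((3, 3, 3))
        _, n_corr = ndimage.label(noisy.skeleton.s, structure=s26)
        _, n_shock = ndimage.label(shock.s, structure=s26)
        assert n_corr <= n_shock

    def test_ridge_concentrates_toward_sulcal_centre(self):
        # asymmetric banks: the dielectric-field ridge sits nearer the
        # CSF centre line than the Laplace-field ridge
        spec = PhantomSpec(geometry="sulcus", gap_mm=4.0,
                           bank_thickness_mm=(1.5, 3.5))
        diel = build_stack(spec)
        lap = build_stack(spec, uniform_eps=True)
        roi = roi_mask(diel.phantom)
        xc = diel.phantom.ground_truth["csf_center_x"]
        x3 = np.broadcast_to(diel.phantom.p_w.world_grids()[0],
                             diel.wm.shape)
        off_d = np.abs(x3[diel.skeleton.s & roi] - xc).mean()
        off_l = np.abs(x3[lap.skeleton.s & roi] - xc).mean()
        assert off_d < off_l
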