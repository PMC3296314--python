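"""Shared fixtures: phantoms and their solved field/transport/skeleton stacks.

The heavier PDE solves are session-scoped so several tests can share one
solution of the same study condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from scipy import ndimage

from delfmap.field import compute_permittivity, solve_dielectric_field
from delfmap.phantom import PhantomSpec, PhantomOutput, make_phantom
from delfmap.skeleton import SkeletonMask, skeleton_from_correspondence
from delfmap.transport import solve_correspondence, solve_distance

SPACING = 0.5

SLAB_SPEC = PhantomSpec(geometry="slab", shape=(40, 40, 48), spacing=SPACING)
SPHERES_SPEC = PhantomSpec(geometry="spheres", shape=(64, 64, 64), spacing=SPACING)
SLAB_NEUMANN = ("x-", "x+", "y-", "y+", "z-")


@dataclass
class Stack:
    """One phantom with its solved field, transport and skeleton."""

    phantom: PhantomOutput
    wm: np.ndarray
    potential: object
    distance: object
    psi: object
    skeleton: SkeletonMask


def build_stack(spec: PhantomSpec, eps_max: float = 100.0,
                uniform_eps: bool = False,
                neumann_faces=()) -> Stack:
    ph = make_phantom(spec)
    wm = ph.wm_mask.data.astype(bool)
    if uniform_eps:
        pot = solve_dielectric_field(np.ones(wm.shape), wm,
                                     spacing=spec.spacing,
                                     neumann_faces=neumann_faces)
    else:
        perm = compute_permittivity(ph.p_w, ph.p_g, wm_mask=wm,
                                    eps_max=eps_max)
        pot = solve_dielectric_field(perm, wm, spacing=spec.spacing,
                                     neumann_faces=neumann_faces)
    dist = solve_distance(pot)
    psi = solve_correspondence(pot)
    skel = skeleton_from_correspondence(psi, wm)
    return Stack(ph, wm, pot, dist, psi, skel)


def roi_mask(ph: PhantomOutput) -> np.ndarray:
    """Boolean mask of the sulcus phantom's skeleton-check ROI."""
    gt = ph.ground_truth
    shape = ph.wm_mask.data.shape
    x, y, z = ph.p_w.world_grids()
    x3, y3, z3 = (np.broadcast_to(g, shape) for g in (x, y, z))
    return ((x3 >= gt["roi_x"][0]) & (x3 <= gt["roi_x"][1]) &
            (y3 >= gt["roi_y"][0]) & (y3 <= gt["roi_y"][1]) &
            (z3 >= gt["roi_z"][0]) & (z3 <= gt["roi_z"][1]))


def banks_separated(stack: Stack) -> bool:
    """Whether removing the skeleton 6-disconnects the two GM banks
    within the slit-interior ROI."""
    ph = stack.phantom
    gt = ph.ground_truth
    roi = roi_mask(ph)
    x3 = np.broadcast_to(ph.p_w.world_grids()[0], stack.wm.shape)
    lab, _ = ndimage.label(roi & ~stack.wm & ~stack.skeleton.s)
    gm = ph.gm_hard
    left = gm & roi & (x3 < gt["medial_plane_x"]) & ~stack.skeleton.s
    right = gm & roi & (x3 > gt["medial_plane_x"]) & ~stack.skeleton.s
    assert left.any() and right.any()
    ll = set(np.unique(lab[left])) - {0}
    rr = set(np.unique(lab[right])) - {0}
    return not (ll & rr)


@pytest.fixture(scope="session")
def slab_stack() -> Stack:
    return build_stack(SLAB_SPEC, neumann_faces=SLAB_NEUMANN)


@pytest.fixture(scope="session")
def spheres_stack() -> Stack:
    return build_stack(SPHERES_SPEC)


@pytest.fixture(scope="session")
def sulcus_resolved() -> Stack:
    return build_stack(PhantomSpec(geometry="sulcus"))


@pytest.fixture(scope="session")
def sulcus_unresolved() -> Stack:
    return build_stack(PhantomSpec(geometry="sulcus", unresolved_fundus=True))


@pytest.fixture(scope="session")
def sulcus_bridged() -> Stack:
    return build_stack(PhantomSpec(geometry="sulcus", bridged=True))


@pytest.fixture(scope="session")
def sulcus_fused() -> Stack:
    return build_stack(PhantomSpec(geometry="sulcus", gap_mm=0.0))


@pytest.fixture(scope="session")
def spheres_pipeline():
    from delfmap.pipeline import run_pipeline

    ph = make_phantom(SPHERES_SPEC)
    return ph, run_pipeline(ph.p_w, ph.p_g, ph.wm_mask)


@pytest.fixture(scope="session")
def bridged_pipeline():
    from delfmap.pipeline import run_pipeline

    ph = make_phantom(PhantomSpec(geometry="sulcus", bridged=True))
    return ph, run_pipeline(ph.p_w, ph.p_g, ph.wm_mask)
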