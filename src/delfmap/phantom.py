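"""Synthetic tissue-probability phantoms with known ground-truth geometry.

Three families of phantoms emulate the situations the reconstruction
pipeline has to handle:

* ``sulcus`` — two white-matter (WM) stalks separated by a narrow sulcal
  slit with a gently rounded fundus, each bank coated by a gray-matter
  (GM) layer.  Variant flags produce a fully resolved sulcus, a sulcus
  whose fundus is filled with unresolved GM, and a sulcus whose banks are
  bridged by GM partway up the slit.
* ``slab`` — a WM half-space capped by a GM layer of constant thickness;
  every streamline of the field is a straight vertical line, which makes
  the transport and thickness stages exactly solvable.
* ``spheres`` — a WM ball of radius R1 inside a GM shell of outer radius
  R2; the field, distances and thickness all have closed forms.

Hard tissue labels are converted to probability maps by a small Gaussian
blur (default 0.5 voxel) emulating partial-volume soft classification,
optionally followed by independent per-voxel Gaussian noise, clipping to
[0, 1] and renormalisation where P_w + P_g would exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .volume import ScalarVolume

__all__ = ["PhantomSpec", "PhantomOutput", "make_phantom",
           "make_sulcus_phantom", "make_slab_phantom", "make_spheres_phantom"]


@dataclass
class PhantomSpec:
    """Parameters of a synthetic phantom.  All lengths in mm."""

    geometry: str = "sulcus"
    shape: tuple = (72, 48, 72)
    spacing: float = 0.5

    # --- sulcus geometry ---
    fundus_radius_mm: float = 10.0      # curvature radius of the WM fundus
    bank_thickness_mm: tuple = (2.0, 2.0)  # GM thickness (left, right bank)
    gap_mm: float = 1.0                 # CSF slit width between the GM banks
    sulcus_depth_mm: float = 12.0       # depth of the slit below the WM top
    margin_mm: float = 3.0              # background clearance around the coat
    unresolved_fundus: bool = False     # GM fills the bottom of the slit
    unresolved_height_mm: float = 4.0
    bridged: bool = False               # GM bridge partway up the slit
    bridge_z_mm: tuple = (6.0, 9.0)     # bridge band, relative to the fundus

    # --- slab geometry ---
    slab_wm_top_mm: float = 8.0         # z of the WM/GM interface
    slab_gm_thickness_mm: float = 2.0

    # --- spheres geometry ---
    r1_mm: float = 8.0
    r2_mm: float = 10.5

    # --- probability model ---
    blur_sigma_vox: float = 0.5         # partial-volume blur of hard labels
    noise_sigma: float = 0.0            # additive Gaussian noise on P
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.geometry not in ("sulcus", "slab", "spheres"):
            raise ValueError(f"unknown geometry {self.geometry!r}")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape, dtype=float) * self.spacing


@dataclass
class PhantomOutput:
    """Probability volumes, binary WM mask and analytic ground truth."""

    p_w: ScalarVolume
    p_g: ScalarVolume
    wm_mask: ScalarVolume          # uint8 {0,1}; topology-corrected WM analogue
    ground_truth: dict = field(default_factory=dict)
    spec: Optional[PhantomSpec] = None

    @property
    def gm_hard(self) -> np.ndarray:
        """Noise-free hard GM labels used to build P_g (bool array)."""
        return self.ground_truth["gm_hard"]


def _probabilities(spec: PhantomSpec, wm: np.ndarray, gm: np.ndarray):
    """Hard labels -> (P_w, P_g) with partial-volume blur and noise."""
    p_w = ndimage.gaussian_filter(wm.astype(np.float64), spec.blur_sigma_vox)
    p_g = ndimage.gaussian_filter(gm.astype(np.float64), spec.blur_sigma_vox)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        p_w = p_w + rng.normal(0.0, spec.noise_sigma, wm.shape)
        p_g = p_g + rng.normal(0.0, spec.noise_sigma, gm.shape)
    np.clip(p_w, 0.0, 1.0, out=p_w)
    np.clip(p_g, 0.0, 1.0, out=p_g)
    s = p_w + p_g
    over = s > 1.0
    if np.any(over):
        p_w[over] /= s[over]
        p_g[over] /= s[over]
    return p_w, p_g


def _finalize(spec: PhantomSpec, wm: np.ndarray, gm: np.ndarray,
              truth: dict) -> PhantomOutput:
    p_w, p_g = _probabilities(spec, wm, gm)
    sp = spec.spacing
    truth["gm_hard"] = gm
    return PhantomOutput(
        p_w=ScalarVolume(p_w, sp),
        p_g=ScalarVolume(p_g, sp),
        wm_mask=ScalarVolume(wm.astype(np.uint8), sp),
        ground_truth=truth,
        spec=spec,
    )


def make_sulcus_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Two GM-coated WM stalks separated by a sulcal slit.

    The slit is symmetric about the medial plane ``x = x_c`` (the exact
    mirror axis of the grid); the WM walls sit at ``x_c -/+ (gap/2 + t)``
    with per-bank GM thickness ``t``, so unequal bank thicknesses move the
    WM walls, not the CSF slit.  The fundus is a circular arc of the
    requested curvature radius clipped to the slit width, i.e. a gently
    rounded valley bottom.  The slit is cut through the full y-extent of
    the WM block, so the sulcus opens at both ends like a real fold.
    """
    if spec.geometry != "sulcus":
        raise ValueError("spec.geometry must be 'sulcus'")
    sp = spec.spacing
    ex, ey, ez = spec.extent_mm
    t_l, t_r = spec.bank_thickness_mm
    if min(t_l, t_r) <= 0 or spec.gap_mm < 0 or spec.fundus_radius_mm <= 0:
        raise ValueError("sulcus geometry lengths must be positive (gap >= 0)")
    t_max = max(t_l, t_r)

    # mirror axis of the grid (index (nx-1)/2) -> exact symmetry when t_l == t_r
    x_c = (spec.shape[0] - 1) / 2.0 * sp
    a_l = spec.gap_mm / 2.0 + t_l            # left WM wall offset from x_c
    a_r = spec.gap_mm / 2.0 + t_r
    m = spec.margin_mm + t_max
    bx = x_c - m                             # half-width of the WM block
    if bx <= a_l + 2.0 or bx <= a_r + 2.0:
        raise ValueError("sulcal slit does not fit inside the WM block")
    y0, y1 = m, ey - m
    z0 = m
    z_top = ez - m - t_max - 1.0             # top of the WM stalks
    z_f = z_top - spec.sulcus_depth_mm       # fundus z at the medial plane
    if y1 - y0 < 4.0 or z_f - z0 < 2.0:
        raise ValueError("sulcus geometry does not fit inside the grid")

    vol = ScalarVolume(np.zeros(spec.shape), sp)
    x, y, z = vol.world_grids()
    box = ((x >= x_c - bx) & (x <= x_c + bx) &
           (y >= y0) & (y <= y1) & (z >= z0) & (z <= z_top))

    # valley: circular-arc bottom of radius r_f, clipped to the slit walls
    r_f = spec.fundus_radius_mm
    dx = x - x_c
    arc = np.sqrt(np.maximum(r_f ** 2 - np.minimum(dx ** 2, r_f ** 2), 0.0))
    z_valley = z_f + r_f - arc
    valley = (dx > -a_l) & (dx < a_r) & (z > z_valley)
    wm = box & ~valley

    # GM coat of per-bank thickness (linear blend across the slit)
    dist = ndimage.distance_transform_edt(~wm, sampling=sp)
    blend = max(spec.gap_mm / 2.0 + min(t_l, t_r) / 2.0, 1.0)
    frac = np.clip((dx + blend) / (2.0 * blend), 0.0, 1.0)
    t_of_x = t_l + (t_r - t_l) * frac
    gm = (~wm) & (dist <= t_of_x)

    in_slit = (valley & (dx > -a_l + 1e-9) & (dx < a_r - 1e-9) &
               (y >= y0) & (y <= y1))
    if spec.unresolved_fundus:
        gm |= in_slit & ~wm & (z < z_f + spec.unresolved_height_mm)
    if spec.bridged:
        zb0, zb1 = spec.bridge_z_mm
        gm |= in_slit & ~wm & (z >= z_f + zb0) & (z <= z_f + zb1)

    truth = {
        "medial_plane_x": x_c,
        "csf_center_x": x_c,
        "z_fundus": z_f,
        "z_top_wm": z_top,
        "gap_mm": spec.gap_mm,
        "bank_thickness_mm": (t_l, t_r),
        "wall_offsets_mm": (a_l, a_r),
        "box_x": (x_c - bx, x_c + bx),
        "box_y": (y0, y1),
        # region of interest for skeleton checks: the interior section of
        # the slit.  The banks legitimately connect around the fundus, at
        # the open sulcus ends and over the rim, and near the fundus and
        # rim the medial surface fans out over a transition zone of about
        # one bank thickness, so the ROI stays clear of both.
        "roi_x": (x_c - a_l - 2.0, x_c + a_r + 2.0),
        "roi_y": (y0 + 2.0, y1 - 2.0),
        "roi_z": (z_f + t_max + 2.5, z_top - t_max - 0.5),
    }
    return _finalize(spec, wm, gm, truth)


def make_slab_phantom(spec: PhantomSpec) -> PhantomOutput:
    """WM half-space ``z <= z_w`` capped by a GM layer of thickness t."""
    if spec.geometry != "slab":
        raise ValueError("spec.geometry must be 'slab'")
    t = spec.slab_gm_thickness_mm
    z_w = spec.slab_wm_top_mm
    if t <= 0 or z_w <= 0:
        raise ValueError("slab geometry lengths must be positive")
    if z_w + t >= spec.extent_mm[2] - 2.0:
        raise ValueError("slab does not fit inside the grid")
    vol = ScalarVolume(np.zeros(spec.shape), spec.spacing)
    _, _, z = vol.world_grids()
    z = np.broadcast_to(z, spec.shape)
    wm = z <= z_w
    gm = (z > z_w) & (z <= z_w + t)
    truth = {
        "thickness_mm": t,
        "wm_top_mm": z_w,
        "gm_top_mm": z_w + t,
    }
    return _finalize(spec, wm, gm, truth)


def make_spheres_phantom(spec: PhantomSpec) -> PhantomOutput:
    """WM ball of radius R1 inside a concentric GM shell of radius R2."""
    if spec.geometry != "spheres":
        raise ValueError("spec.geometry must be 'spheres'")
    r1, r2 = spec.r1_mm, spec.r2_mm
    if not 0 < r1 < r2:
        raise ValueError("need 0 < R1 < R2")
    if r2 >= spec.extent_mm.min() / 2.0 - 1.0:
        raise ValueError("outer sphere does not fit inside the grid")
    vol = ScalarVolume(np.zeros(spec.shape), spec.spacing)
    center = (np.asarray(spec.shape) - 1) / 2.0 * spec.spacing
    x, y, z = vol.world_grids()
    r = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2)
    wm = r <= r1
    gm = (r > r1) & (r <= r2)
    truth = {
        "center_mm": center,
        "r1_mm": r1,
        "r2_mm": r2,
        "thickness_mm": r2 - r1,
        "radius_map": r,
    }
    return _finalize(spec, wm, gm, truth)


_MAKERS = {
    "sulcus": make_sulcus_phantom,
    "slab": make_slab_phantom,
    "spheres": make_spheres_phantom,
}


def make_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Dispatch on ``spec.geometry``."""
    return _MAKERS[spec.geometry](spec)
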