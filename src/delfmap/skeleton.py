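"""Sulcal medial-surface skeleton detection.

Where streamlines from opposite sulcal banks collide, the distance field
develops shocks (centred differences of d give ||grad d|| well below 1)
and the correspondence functions jump (adjacent voxels map to WM source
points on different banks).  Either signature yields a voxel skeleton S
of the sulcal medial surface, used downstream as a hard barrier that
keeps the two pial banks separated.

The correspondence detector needs no minimum-distance cutoff: close to
the WM boundary neighbouring streamlines originate from nearby source
points, so no spurious detections arise there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .transport import CorrespondenceVolume, DistanceField

__all__ = ["SkeletonMask", "skeleton_from_shocks",
           "skeleton_from_correspondence", "hausdorff_voxels"]

_OFFSETS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
_OFFSETS_18 = _OFFSETS_6 + [
    (a, b, 0) for a in (-1, 1) for b in (-1, 1)] + [
    (a, 0, b) for a in (-1, 1) for b in (-1, 1)] + [
    (0, a, b) for a in (-1, 1) for b in (-1, 1)]
_OFFSETS_26 = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1)
               for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)]
NEIGHBOR_OFFSETS = {6: _OFFSETS_6, 18: _OFFSETS_18, 26: _OFFSETS_26}


@dataclass
class SkeletonMask:
    """Binary skeleton S on Omega \\ Omega_w, plus the parameters used."""

    s: np.ndarray
    params: dict = field(default_factory=dict)


def _shift(arr: np.ndarray, off) -> np.ndarray:
    """arr sampled at index + off, edge-replicated."""
    out = arr
    for ax, o in enumerate(off):
        if o == 0:
            continue
        out = np.take(out, np.clip(np.arange(out.shape[ax]) + o, 0,
                                   out.shape[ax] - 1), axis=ax)
    return out


def skeleton_from_shocks(d: DistanceField, omega_w, T: float = 0.8,
                         d_min_skel: float = 1.0) -> SkeletonMask:
    """Shock detector: voxels beyond ``d_min_skel`` mm where the centred
    gradient magnitude of d drops below ``T`` (< 1).

    Voxels the transport stage flagged as degenerate (clamped
    streamlines) are added unconditionally: they sit among the shocks.
    """
    if not 0 < T < 1:
        raise ValueError("T must lie in (0, 1)")
    wm = np.asarray(omega_w).astype(bool)
    arr = d.d.data
    g = np.gradient(arr, d.d.spacing)
    mag = np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)
    s = (~wm) & (arr > d_min_skel) & (mag < T)
    s |= d.degenerate & ~wm
    return SkeletonMask(s, {"method": "shock", "T": T,
                            "d_min_skel": d_min_skel})


def skeleton_from_correspondence(psi: CorrespondenceVolume, omega_w,
                                 d_min_vox: float = 4.0,
                                 neighborhood: int = 6) -> SkeletonMask:
    """Correspondence detector: voxels whose source point lies more than
    ``d_min_vox`` voxels from a neighbour's source point.

    The jump threshold is stated in voxels and converted to mm through
    the grid spacing, keeping the criterion resolution independent.
    """
    if d_min_vox <= 0:
        raise ValueError("d_min_vox must be positive")
    if neighborhood not in NEIGHBOR_OFFSETS:
        raise ValueError("neighborhood must be 6, 18 or 26")
    wm = np.asarray(omega_w).astype(bool)
    thr = d_min_vox * psi.spacing
    maxjump = np.zeros(wm.shape)
    for off in NEIGHBOR_OFFSETS[neighborhood]:
        d2 = np.zeros(wm.shape)
        for c in range(3):
            d2 += (psi.psi[c] - _shift(psi.psi[c], off)) ** 2
        np.maximum(maxjump, d2, out=maxjump)
    s = (~wm) & (np.sqrt(maxjump) > thr)
    return SkeletonMask(s, {"method": "correspondence",
                            "d_min_vox": d_min_vox,
                            "neighborhood": neighborhood})


def hausdorff_voxels(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two voxel sets, in voxels."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if not a.any() or not b.any():
        return np.inf
    da = ndimage.distance_transform_edt(~a)
    db = ndimage.distance_transform_edt(~b)
    return float(max(db[a].max(), da[b].max()))
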