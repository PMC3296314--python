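"""Streamline length and correspondence transport along the field gradient.

Let N = grad(phi)/||grad(phi)|| be the unit tangent field of the
potential.  Streamlines leave the WM boundary (phi = 1) and run downhill
to the grounded border.  Along a streamline the arc length d from the WM
boundary satisfies the first-order transport equation

    (-N) . grad d = 1,        d = 0 on the WM boundary,

and the source-point coordinates psi_i are constant along streamlines:

    (-N) . grad psi_i = 0,    psi_i = x_i on the WM boundary.

(The potential here is 1 on WM and decays outward, so the *downhill*
direction -N is the direction of growing d.)

Both PDEs are discretised with first-order one-sided (upwind)
differences selected per axis by the sign of the tangent component, the
upwind neighbour being the one nearer the WM, and iterated to a fixed
point with full-grid Jacobi sweeps.  Because the upwind dependency
follows the monotone potential, information propagates outward one
voxel layer per sweep and the iteration converges in roughly the number
of voxels along the longest streamline.

A Lagrangian fourth-order Runge-Kutta streamline tracer
(:func:`trace_streamlines`) provides an independent route to the same
quantities for verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .field import Potential
from .volume import ScalarVolume

__all__ = ["DistanceField", "CorrespondenceVolume", "normalized_gradient",
           "solve_distance", "solve_correspondence", "trace_streamlines"]


@dataclass
class DistanceField:
    """Streamline arc length (mm) from the WM boundary; 0 inside WM."""

    d: ScalarVolume
    degenerate: np.ndarray   # voxels without a usable upwind stencil
    iterations: int = 0


@dataclass
class CorrespondenceVolume:
    """World coordinates (mm) of each streamline's WM source point."""

    psi: np.ndarray          # shape (3, nx, ny, nz), world mm
    degenerate: np.ndarray
    spacing: float = 1.0
    iterations: int = 0


def normalized_gradient(phi, rel_eps: float = 1e-8):
    """Unit tangent field of the potential and a degeneracy flag.

    Central differences in the interior, one-sided at the volume border.
    Voxels whose gradient magnitude is below ``rel_eps`` times the global
    maximum are flagged degenerate and get a zero vector.
    """
    arr = phi.phi.data if isinstance(phi, Potential) else np.asarray(phi)
    g = np.stack(np.gradient(arr.astype(np.float64)))
    mag = np.sqrt((g ** 2).sum(axis=0))
    degenerate = mag <= rel_eps * max(mag.max(), np.finfo(float).tiny)
    safe = np.where(degenerate, 1.0, mag)
    g /= safe
    g[:, degenerate] = 0.0
    return g, degenerate


def _upwind_sweeps(phi: Potential, omega_w, rhs: float, init: np.ndarray,
                   tol: float, max_iter: int):
    """Shared Jacobi fixed-point driver for the d and psi transport PDEs.

    ``init`` has shape (m, nx, ny, nz); each component is transported
    independently with source term ``rhs`` (1 for d, 0 for psi).
    Returns (values, degenerate mask, iterations).
    """
    wm = np.asarray(omega_w).astype(bool)
    g, degen = normalized_gradient(phi)
    h = phi.phi.spacing
    shape = wm.shape

    a = np.abs(g)                       # upwind weights per axis
    toward_wm = g > 0                   # move along +N to climb toward WM
    # drop axes whose upwind neighbour would fall outside the grid
    for ax in range(3):
        first = [slice(None)] * 3
        first[ax] = 0
        last = [slice(None)] * 3
        last[ax] = -1
        a[(ax,) + tuple(first)] = np.where(toward_wm[(ax,) + tuple(first)],
                                           a[(ax,) + tuple(first)], 0.0)
        a[(ax,) + tuple(last)] = np.where(toward_wm[(ax,) + tuple(last)],
                                          0.0, a[(ax,) + tuple(last)])
    denom = a.sum(axis=0)
    degen = degen | (denom < 1e-12)
    free = ~wm & ~degen
    denom_safe = np.where(denom < 1e-12, 1.0, denom)

    vals = init.copy()
    m = vals.shape[0]

    def gather(v):
        """sum_ax a_ax * v[upwind neighbour], for one component."""
        out = np.zeros(shape)
        for ax in range(3):
            plus = np.empty_like(v)
            minus = np.empty_like(v)
            sl_dst = [slice(None)] * 3
            sl_src = [slice(None)] * 3
            sl_dst[ax] = slice(None, -1)
            sl_src[ax] = slice(1, None)
            plus[tuple(sl_dst)] = v[tuple(sl_src)]
            edge = [slice(None)] * 3
            edge[ax] = -1
            plus[tuple(edge)] = v[tuple(edge)]
            sl_dst[ax] = slice(1, None)
            sl_src[ax] = slice(None, -1)
            minus[tuple(sl_dst)] = v[tuple(sl_src)]
            edge[ax] = 0
            minus[tuple(edge)] = v[tuple(edge)]
            out += a[ax] * np.where(toward_wm[ax], plus, minus)
        return out

    it = 0
    for it in range(1, max_iter + 1):
        diff = 0.0
        for c in range(m):
            new = (rhs * h + gather(vals[c])) / denom_safe
            delta = np.abs(new - vals[c])[free]
            if delta.size:
                diff = max(diff, delta.max())
            vals[c][free] = new[free]
        if diff < tol:
            break
    # degenerate voxels inherit a plain neighbour average so they carry a
    # finite, harmless value; they stay flagged for the skeleton stage
    fill = degen & ~wm
    if fill.any():
        k = np.zeros((3, 3, 3))
        k[1, 1, :] = k[1, :, 1] = k[:, 1, 1] = 1.0
        k[1, 1, 1] = 0.0
        for c in range(m):
            avg = ndimage.convolve(vals[c], k, mode="nearest") / 6.0
            vals[c][fill] = avg[fill]
    return vals, degen, it


def solve_distance(phi: Potential, omega_w=None, tol: float = 1e-4,
                   max_iter: int = 0) -> DistanceField:
    """Eulerian streamline arc length from the WM boundary."""
    wm = phi.omega_w if omega_w is None else np.asarray(omega_w).astype(bool)
    if max_iter <= 0:
        max_iter = 2 * sum(wm.shape) + 200
    init = np.zeros((1,) + wm.shape)
    vals, degen, it = _upwind_sweeps(phi, wm, 1.0, init, tol, max_iter)
    d = np.maximum(vals[0], 0.0)
    d[wm] = 0.0
    return DistanceField(ScalarVolume(d, phi.phi.spacing), degen & ~wm, it)


def solve_correspondence(phi: Potential, omega_w=None, tol: float = 1e-4,
                         max_iter: int = 0) -> CorrespondenceVolume:
    """Eulerian WM source-point coordinates along each streamline."""
    wm = phi.omega_w if omega_w is None else np.asarray(omega_w).astype(bool)
    if max_iter <= 0:
        max_iter = 2 * sum(wm.shape) + 200
    vol = phi.phi
    x, y, z = vol.world_grids()
    init = np.stack([np.broadcast_to(x, wm.shape).copy(),
                     np.broadcast_to(y, wm.shape).copy(),
                     np.broadcast_to(z, wm.shape).copy()])
    vals, degen, it = _upwind_sweeps(phi, wm, 0.0, init, tol, max_iter)
    # boundary condition: on WM (including its boundary layer) psi is the
    # voxel's own coordinate
    for c, grid in enumerate((x, y, z)):
        comp = vals[c]
        comp[wm] = np.broadcast_to(grid, wm.shape)[wm]
    return CorrespondenceVolume(vals, degen & ~wm, vol.spacing, it)


def trace_streamlines(phi: Potential, seeds_index: np.ndarray,
                      step_vox: float = 0.25, max_steps: int = 0):
    """Lagrangian RK4 integration of streamlines from seed voxels to WM.

    Seeds are index coordinates, shape (n, 3).  Each streamline follows
    the uphill unit tangent +N of the potential until it enters the WM
    region.  Returns ``(lengths_mm, endpoints_mm, ok)`` where ``ok``
    marks streamlines that reached WM within the step budget.  This is
    an independent (non-Eulerian) route to d and psi.
    """
    vol = phi.phi
    g, _ = normalized_gradient(phi)
    wm = phi.omega_w.astype(np.float64)
    shape = vol.shape
    h = vol.spacing
    if max_steps <= 0:
        max_steps = int(4 * max(shape) / step_vox)

    def tangent(pos):
        """Unit uphill direction at fractional index positions (n, 3)."""
        coords = pos.T
        v = np.stack([ndimage.map_coordinates(g[c], coords, order=1,
                                              mode="nearest") for c in range(3)],
                     axis=1)
        n = np.linalg.norm(v, axis=1, keepdims=True)
        n[n < 1e-12] = 1.0
        return v / n

    def in_wm(pos):
        return ndimage.map_coordinates(wm, pos.T, order=1, mode="nearest") >= 0.5

    pos = np.asarray(seeds_index, dtype=np.float64).copy()
    n = len(pos)
    length = np.zeros(n)
    done = in_wm(pos)
    endpoint = pos.copy()
    active = ~done
    hi = np.asarray(shape, dtype=float) - 1.0
    for _ in range(max_steps):
        if not active.any():
            break
        p = pos[active]
        k1 = tangent(p)
        k2 = tangent(np.clip(p + 0.5 * step_vox * k1, 0, hi))
        k3 = tangent(np.clip(p + 0.5 * step_vox * k2, 0, hi))
        k4 = tangent(np.clip(p + step_vox * k3, 0, hi))
        newp = np.clip(p + (step_vox / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), 0, hi)
        hit = in_wm(newp)
        if hit.any():
            # bisect the entry point along the last segment
            a = p[hit]
            b = newp[hit]
            for _ in range(12):
                mid = 0.5 * (a + b)
                inside = in_wm(mid)
                b[inside] = mid[inside]
                a[~inside] = mid[~inside]
            idx = np.flatnonzero(active)[hit]
            frac = np.linalg.norm(b - p[hit], axis=1)
            length[idx] += frac * h
            endpoint[idx] = b
            done[idx] = True
        idx_cont = np.flatnonzero(active)[~hit]
        length[idx_cont] += step_vox * h
        pos[active] = newp
        active = ~done
    ok = done
    endpoints_mm = vol.index_to_world(endpoint)
    return length, endpoints_mm, ok
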