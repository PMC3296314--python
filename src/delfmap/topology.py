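"""Digital topology: simple points under the (26, 6) connectivity pair.

A voxel is *simple* when flipping it between foreground and background
leaves the digital topology of both phases unchanged.  For the standard
pair (26-connected foreground, 6-connected background) this holds iff
both topological numbers equal one:

* T26 — the number of 26-components of the foreground restricted to the
  26-neighbourhood of the voxel (centre excluded);
* T6  — the number of 6-components of the background restricted to the
  18-neighbourhood, counting only components 6-adjacent to the centre,
  with 6-paths confined to the 18-neighbourhood.

The checks are compiled with numba because the level set evolution
queries them for every candidate sign flip.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["is_simple_point", "simple_in_mask"]

# index layout of the 3x3x3 neighbourhood: i = x*9 + y*3 + z, centre = 13


@njit(cache=True)
def _t26(cfg):
    """Number of 26-components of foreground within N26 (centre excluded)."""
    visited = np.zeros(27, dtype=np.uint8)
    stack = np.empty(27, dtype=np.int64)
    count = 0
    for s in range(27):
        if s == 13 or cfg[s] == 0 or visited[s]:
            continue
        count += 1
        visited[s] = 1
        stack[0] = s
        sp = 1
        while sp > 0:
            sp -= 1
            j = stack[sp]
            xj, yj, zj = j // 9, (j // 3) % 3, j % 3
            for dx in (-1, 0, 1):
                x = xj + dx
                if x < 0 or x > 2:
                    continue
                for dy in (-1, 0, 1):
                    y = yj + dy
                    if y < 0 or y > 2:
                        continue
                    for dz in (-1, 0, 1):
                        z = zj + dz
                        if z < 0 or z > 2:
                            continue
                        k = x * 9 + y * 3 + z
                        if k == 13 or k == j:
                            continue
                        if cfg[k] and not visited[k]:
                            visited[k] = 1
                            stack[sp] = k
                            sp += 1
    return count


@njit(cache=True)
def _t6(cfg):
    """Number of 6-components of background within N18 that touch a face
    neighbour of the centre (geodesic 6-connectivity inside N18)."""
    visited = np.zeros(27, dtype=np.uint8)
    stack = np.empty(27, dtype=np.int64)
    count = 0
    # seed flood fills only from the six face neighbours
    for fx, fy, fz in ((0, 1, 1), (2, 1, 1), (1, 0, 1),
                       (1, 2, 1), (1, 1, 0), (1, 1, 2)):
        s = fx * 9 + fy * 3 + fz
        if cfg[s] != 0 or visited[s]:
            continue
        count += 1
        visited[s] = 1
        stack[0] = s
        sp = 1
        while sp > 0:
            sp -= 1
            j = stack[sp]
            xj, yj, zj = j // 9, (j // 3) % 3, j % 3
            for d in range(6):
                x, y, z = xj, yj, zj
                if d == 0:
                    x -= 1
                elif d == 1:
                    x += 1
                elif d == 2:
                    y -= 1
                elif d == 3:
                    y += 1
                elif d == 4:
                    z -= 1
                else:
                    z += 1
                if x < 0 or x > 2 or y < 0 or y > 2 or z < 0 or z > 2:
                    continue
                # stay inside N18: skip the 8 corners and the centre
                n_off = (x != 1) + (y != 1) + (z != 1)
                if n_off == 3 or n_off == 0:
                    continue
                k = x * 9 + y * 3 + z
                if cfg[k] == 0 and not visited[k]:
                    visited[k] = 1
                    stack[sp] = k
                    sp += 1
    return count


@njit(cache=True)
def _simple_cfg(cfg):
    return _t26(cfg) == 1 and _t6(cfg) == 1


@njit(cache=True)
def simple_in_mask(mask, i, j, k):
    """Simple-point test for voxel (i, j, k) of a binary volume.

    Out-of-volume voxels count as background.  The current value of the
    centre voxel is irrelevant: simpleness is symmetric under the flip.
    """
    cfg = np.zeros(27, dtype=np.uint8)
    nx, ny, nz = mask.shape
    for dx in (-1, 0, 1):
        x = i + dx
        if x < 0 or x >= nx:
            continue
        for dy in (-1, 0, 1):
            y = j + dy
            if y < 0 or y >= ny:
                continue
            for dz in (-1, 0, 1):
                z = k + dz
                if z < 0 or z >= nz:
                    continue
                if mask[x, y, z]:
                    cfg[(dx + 1) * 9 + (dy + 1) * 3 + (dz + 1)] = 1
    return _simple_cfg(cfg)


def is_simple_point(neighborhood: np.ndarray) -> bool:
    """Whether flipping the centre of a 3x3x3 binary configuration
    preserves digital topology under (26-foreground, 6-background).

    The centre voxel's own value does not enter the test.
    """
    arr = np.ascontiguousarray(np.asarray(neighborhood, dtype=np.uint8))
    if arr.shape != (3, 3, 3):
        raise ValueError("neighborhood must be a 3x3x3 array")
    return bool(_simple_cfg(arr.ravel()))
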