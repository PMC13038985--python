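"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: flood-fill labelling by
breadth-first search, sphere fitting by exhaustive center enumeration,
porosity by explicit loops, and t-distribution tail mass by quadrature of
the density.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
from scipy import integrate


def flood_fill_despeckle(slice2d: np.ndarray, min_pixels: int, connectivity: int = 8) -> np.ndarray:
    """Remove small bright components from one 2D slice by BFS labelling."""
    sl = slice2d.copy()
    seen = np.zeros_like(sl, dtype=bool)
    if connectivity == 8:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    ny, nx = sl.shape
    for y in range(ny):
        for x in range(nx):
            if sl[y, x] and not seen[y, x]:
                comp = [(y, x)]
                seen[y, x] = True
                queue = deque([(y, x)])
                while queue:
                    cy, cx = queue.popleft()
                    for dy, dx in nbrs:
                        py, px = cy + dy, cx + dx
                        if 0 <= py < ny and 0 <= px < nx and sl[py, px] and not seen[py, px]:
                            seen[py, px] = True
                            comp.append((py, px))
                            queue.append((py, px))
                if len(comp) < min_pixels:
                    for py, px in comp:
                        sl[py, px] = False
    return sl


def exhaustive_local_thickness(mask: np.ndarray, voxel_size: float = 1.0) -> np.ndarray:
    """Maximal-inscribed-sphere thickness by testing every candidate center.

    For each void voxel c the fitting radius squared is the minimum squared
    distance to any background voxel; a sphere covers voxels at strictly
    smaller squared offset.  Thickness at p is the largest diameter over
    all covering spheres.  Returns float32 with the same value expression
    as the implementation so agreement can be exact.
    """
    void = np.argwhere(mask)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape, dtype=np.float32)
    if void.size == 0:
        return out
    if bg.size == 0:
        raise ValueError("oracle requires background voxels")
    q = np.empty(len(void), dtype=np.int64)
    for i, c in enumerate(void):
        d2 = ((bg - c) ** 2).sum(axis=1)
        q[i] = int(d2.min())
    vals = np.zeros(len(void), dtype=np.float32)
    for c, qc in zip(void, q):
        val = np.float32(2.0 * math.sqrt(qc) * voxel_size)
        d2 = ((void - c) ** 2).sum(axis=1)
        sel = (d2 < qc) & (vals < val)
        vals[sel] = val
    out[tuple(void.T)] = vals
    return out


def brute_force_porosity(bone: np.ndarray, envelope: np.ndarray, slices) -> float:
    """ROI void fraction by explicit per-voxel loops."""
    zs, ys, xs = slices
    n_env = 0
    n_void = 0
    for z in range(*zs.indices(bone.shape[0])):
        for y in range(*ys.indices(bone.shape[1])):
            for x in range(*xs.indices(bone.shape[2])):
                if envelope[z, y, x]:
                    n_env += 1
                    if not bone[z, y, x]:
                        n_void += 1
    return n_void / n_env if n_env else float("nan")


def t_two_tailed_quadrature(t: float, df: int) -> float:
    """Two-tailed tail mass of Student's t by integrating the density."""
    c = math.gamma((df + 1) / 2.0) / (math.sqrt(df * math.pi) * math.gamma(df / 2.0))

    def dens(u):
        return c * (1.0 + u * u / df) ** (-(df + 1) / 2.0)

    tail, _ = integrate.quad(dens, abs(t), np.inf)
    return 2.0 * tail
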