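"""Numba kernels for the reference transport engine.

The engine sums, for every target voxel, contributions from all source
voxels whose radiological distance (density-weighted path length through
the voxelized medium, expressed in reference-medium millimetres) lies
within the kernel support.  Paths between voxel centers are traced with the
standard Amanatides-Woo / Siddon voxel traversal.

Two exact shortcuts keep this tractable on one CPU:

* a per-pair lower bound on the radiological distance from the minimum
  density over the z-slab range spanned by the pair rejects far pairs
  without tracing;
* when the density is constant over that z-slab range (uniform compartments
  of slab and phantom geometries) the radiological distance is the geometric
  distance scaled by that density, so no trace is needed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["slab_range_tables", "rt_accumulate"]


def slab_range_tables(rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Range-min and range-max of per-z-slab density extrema.

    ``rngmin[z1, z2]`` is the minimum density over slabs z1..z2 inclusive
    (z1 <= z2); analogously for ``rngmax``.
    """
    nz = rho.shape[2]
    slab_min = rho.min(axis=(0, 1))
    slab_max = rho.max(axis=(0, 1))
    rngmin = np.empty((nz, nz))
    rngmax = np.empty((nz, nz))
    for z1 in range(nz):
        rngmin[z1, z1:] = np.minimum.accumulate(slab_min[z1:])
        rngmax[z1, z1:] = np.maximum.accumulate(slab_max[z1:])
        rngmin[z1, :z1] = np.inf  # unused half
        rngmax[z1, :z1] = -np.inf
    return rngmin, rngmax


@njit(cache=True)
def _trace_leff(rho, sx, sy, sz, tx, ty, tz, voxel, rho_ref, r_cutoff):
    """Radiological path length (mm, reference medium) between voxel centers.

    Returns a value > r_cutoff as soon as the accumulated path exceeds the
    cutoff (early exit).
    """
    p0x, p0y, p0z = sx + 0.5, sy + 0.5, sz + 0.5
    dx, dy, dz = tx - sx + 0.0, ty - sy + 0.0, tz - sz + 0.0
    length_mm = np.sqrt(dx * dx + dy * dy + dz * dz) * voxel

    ix, iy, iz = sx, sy, sz
    big = 1e30
    step_x = 1 if dx > 0 else (-1 if dx < 0 else 0)
    step_y = 1 if dy > 0 else (-1 if dy < 0 else 0)
    step_z = 1 if dz > 0 else (-1 if dz < 0 else 0)
    tdx = abs(1.0 / dx) if dx != 0 else big
    tdy = abs(1.0 / dy) if dy != 0 else big
    tdz = abs(1.0 / dz) if dz != 0 else big
    tmx = ((ix + (1 if step_x > 0 else 0)) - p0x) / dx if dx != 0 else big
    tmy = ((iy + (1 if step_y > 0 else 0)) - p0y) / dy if dy != 0 else big
    tmz = ((iz + (1 if step_z > 0 else 0)) - p0z) / dz if dz != 0 else big

    t = 0.0
    acc = 0.0  # integral of rho dt
    max_steps = int(abs(dx) + abs(dy) + abs(dz)) + 3
    for _ in range(max_steps):
        if ix == tx and iy == ty and iz == tz:
            break
        tnext = min(tmx, tmy, tmz)
        if tnext > 1.0:
            tnext = 1.0
        acc += rho[ix, iy, iz] * (tnext - t)
        t = tnext
        if acc * length_mm / rho_ref > r_cutoff:
            return 2.0 * r_cutoff + 1.0
        if tmx <= tmy and tmx <= tmz:
            tmx += tdx
            ix += step_x
        elif tmy <= tmz:
            tmy += tdy
            iy += step_y
        else:
            tmz += tdz
            iz += step_z
    acc += rho[tx, ty, tz] * (1.0 - t)
    return acc * length_mm / rho_ref


@njit(cache=True)
def _interp_sorted(xs, ys, x):
    n = xs.size
    if x <= xs[0]:
        return ys[0]
    if x >= xs[n - 1]:
        return ys[n - 1]
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if xs[mid] <= x:
            lo = mid
        else:
            hi = mid
    f = (x - xs[lo]) / (xs[hi] - xs[lo])
    return ys[lo] * (1.0 - f) + ys[hi] * f


@njit(cache=True)
def rt_accumulate(
    n,
    rho,
    targets,
    voxel,
    phi,
    r_step,
    r_cutoff,
    s_grid,
    self_bracket,
    rho_ref,
    win,
    rngmin,
    rngmax,
    out,
):
    """Accumulate transport dose (MeV/g per voxel) into ``out`` at targets."""
    nx, ny, nz = n.shape
    nphi = phi.size
    for m in range(targets.shape[0]):
        tx, ty, tz = targets[m, 0], targets[m, 1], targets[m, 2]
        rho_t = rho[tx, ty, tz]
        acc = 0.0
        for sx in range(max(0, tx - win), min(nx, tx + win + 1)):
            ddx = (sx - tx) * (sx - tx)
            for sy in range(max(0, ty - win), min(ny, ty + win + 1)):
                ddy = (sy - ty) * (sy - ty)
                for sz in range(max(0, tz - win), min(nz, tz + win + 1)):
                    ns = n[sx, sy, sz]
                    if ns <= 0.0:
                        continue
                    if sx == tx and sy == ty and sz == tz:
                        s = rho_t / rho_ref
                        selfb = _interp_sorted(s_grid, self_bracket, s)
                        acc += ns * selfb * (rho_ref / rho_t)
                        continue
                    ddz = (sz - tz) * (sz - tz)
                    dist = np.sqrt(ddx + ddy + ddz) * voxel
                    z1 = min(sz, tz)
                    z2 = max(sz, tz)
                    rmin = rngmin[z1, z2]
                    if dist * rmin / rho_ref > r_cutoff:
                        continue
                    if rngmax[z1, z2] - rmin < 1e-12:
                        leff = dist * rmin / rho_ref
                    else:
                        leff = _trace_leff(
                            rho, sx, sy, sz, tx, ty, tz, voxel, rho_ref, r_cutoff
                        )
                    if leff <= 0.0 or leff > r_cutoff:
                        continue
                    pos = leff / r_step
                    i0 = int(pos)
                    if i0 >= nphi - 1:
                        continue
                    f = pos - i0
                    p = phi[i0] * (1.0 - f) + phi[i0 + 1] * f
                    ratio = leff / dist
                    acc += ns * p * ratio * ratio * ratio * (rho_ref / rho_t)
        out[tx, ty, tz] = acc
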