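"""Immersed-boundary coupling: spread membrane forces to the fluid grid and
interpolate fluid velocity back at membrane vertices with a smoothed delta
kernel (4-point Peskin by default, 2-point hat optionally).

Positions here are in lattice units (node spacing 1); the engine converts
from micrometres.  Both operations share the same kernel, so a partition of
unity holds: spreading conserves total force, and interpolating a uniform
field returns it exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["ibm_spread", "ibm_interpolate", "kernel_weights"]

_KERNELS = {"peskin4": 4, "hat2": 2}


@njit(cache=True, inline="always")
def _phi4(r):
    a = abs(r)
    if a <= 1.0:
        return 0.125 * (3.0 - 2.0 * a + np.sqrt(1.0 + 4.0 * a - 4.0 * a * a))
    if a <= 2.0:
        return 0.125 * (5.0 - 2.0 * a - np.sqrt(-7.0 + 12.0 * a - 4.0 * a * a))
    return 0.0


@njit(cache=True, inline="always")
def _phi2(r):
    a = abs(r)
    return 1.0 - a if a <= 1.0 else 0.0


@njit(cache=True)
def _spread(pos, forces, grid_force, nx, ny, nz, px, py, pz, width):
    half = width // 2
    for v in range(pos.shape[0]):
        x, y, z = pos[v, 0], pos[v, 1], pos[v, 2]
        ix0 = int(np.floor(x)) - half + 1
        iy0 = int(np.floor(y)) - half + 1
        iz0 = int(np.floor(z)) - half + 1
        for a in range(width):
            ix = ix0 + a
            wx = _phi4(x - ix) if width == 4 else _phi2(x - ix)
            if wx == 0.0:
                continue
            jx = ix % nx if px else min(max(ix, 0), nx - 1)
            for b in range(width):
                iy = iy0 + b
                wy = _phi4(y - iy) if width == 4 else _phi2(y - iy)
                if wy == 0.0:
                    continue
                jy = iy % ny if py else min(max(iy, 0), ny - 1)
                for c in range(width):
                    iz = iz0 + c
                    wz = _phi4(z - iz) if width == 4 else _phi2(z - iz)
                    if wz == 0.0:
                        continue
                    jz = iz % nz if pz else min(max(iz, 0), nz - 1)
                    w = wx * wy * wz
                    n = (jx * ny + jy) * nz + jz
                    grid_force[n, 0] += w * forces[v, 0]
                    grid_force[n, 1] += w * forces[v, 1]
                    grid_force[n, 2] += w * forces[v, 2]


@njit(cache=True)
def _interpolate(pos, field, out, nx, ny, nz, px, py, pz, width):
    half = width // 2
    for v in range(pos.shape[0]):
        x, y, z = pos[v, 0], pos[v, 1], pos[v, 2]
        ix0 = int(np.floor(x)) - half + 1
        iy0 = int(np.floor(y)) - half + 1
        iz0 = int(np.floor(z)) - half + 1
        sx = 0.0
        sy = 0.0
        sz = 0.0
        for a in range(width):
            ix = ix0 + a
            wx = _phi4(x - ix) if width == 4 else _phi2(x - ix)
            if wx == 0.0:
                continue
            jx = ix % nx if px else min(max(ix, 0), nx - 1)
            for b in range(width):
                iy = iy0 + b
                wy = _phi4(y - iy) if width == 4 else _phi2(y - iy)
                if wy == 0.0:
                    continue
                jy = iy % ny if py else min(max(iy, 0), ny - 1)
                for c in range(width):
                    iz = iz0 + c
                    wz = _phi4(z - iz) if width == 4 else _phi2(z - iz)
                    if wz == 0.0:
                        continue
                    jz = iz % nz if pz else min(max(iz, 0), nz - 1)
                    w = wx * wy * wz
                    n = (jx * ny + jy) * nz + jz
                    sx += w * field[n, 0]
                    sy += w * field[n, 1]
                    sz += w * field[n, 2]
        out[v, 0] = sx
        out[v, 1] = sy
        out[v, 2] = sz


@njit(cache=True)
def _ibm_tables(pos, nx, ny, nz, px, py, pz, width, idx, wts):
    """Per-vertex kernel weights and wrapped node indices along each axis,
    computed once per step and shared by spread and interpolate."""
    half = width // 2
    for v in range(pos.shape[0]):
        for d in range(3):
            x = pos[v, d]
            i0 = int(np.floor(x)) - half + 1
            n = nx if d == 0 else (ny if d == 1 else nz)
            per = px if d == 0 else (py if d == 1 else pz)
            for a in range(width):
                i = i0 + a
                wts[v, d, a] = _phi4(x - i) if width == 4 else _phi2(x - i)
                if per:
                    idx[v, d, a] = i % n
                else:
                    idx[v, d, a] = min(max(i, 0), n - 1)


@njit(cache=True)
def _spread_cached(idx, wts, forces, grid_force, ny, nz, width):
    for v in range(idx.shape[0]):
        fx = forces[v, 0]
        fy = forces[v, 1]
        fz = forces[v, 2]
        for a in range(width):
            wx = wts[v, 0, a]
            if wx == 0.0:
                continue
            jx = idx[v, 0, a]
            for b in range(width):
                wxy = wx * wts[v, 1, b]
                if wxy == 0.0:
                    continue
                row = (jx * ny + idx[v, 1, b]) * nz
                for c in range(width):
                    w = wxy * wts[v, 2, c]
                    if w == 0.0:
                        continue
                    n = row + idx[v, 2, c]
                    grid_force[n, 0] += w * fx
                    grid_force[n, 1] += w * fy
                    grid_force[n, 2] += w * fz


@njit(cache=True)
def _interp_cached(idx, wts, field, out, ny, nz, width):
    for v in range(idx.shape[0]):
        sx = 0.0
        sy = 0.0
        sz = 0.0
        for a in range(width):
            wx = wts[v, 0, a]
            if wx == 0.0:
                continue
            jx = idx[v, 0, a]
            for b in range(width):
                wxy = wx * wts[v, 1, b]
                if wxy == 0.0:
                    continue
                row = (jx * ny + idx[v, 1, b]) * nz
                for c in range(width):
                    w = wxy * wts[v, 2, c]
                    if w == 0.0:
                        continue
                    n = row + idx[v, 2, c]
                    sx += w * field[n, 0]
                    sy += w * field[n, 1]
                    sz += w * field[n, 2]
        out[v, 0] = sx
        out[v, 1] = sy
        out[v, 2] = sz


def _check_inside(lattice, pos_lb):
    for d, (n, per) in enumerate(
        zip(lattice.shape, lattice.periodic)
    ):
        if per:
            continue
        bad = np.nonzero((pos_lb[:, d] < 0.5) | (pos_lb[:, d] > n - 1.5))[0]
        if len(bad):
            raise ValueError(
                f"vertex {bad[0]} outside domain along axis {d}: "
                f"coordinate {pos_lb[bad[0], d]:.2f} of {n}"
            )


def kernel_weights(kernel: str) -> int:
    try:
        return _KERNELS[kernel]
    except KeyError:
        raise ValueError(f"unknown IBM kernel {kernel!r}; have {sorted(_KERNELS)}")


def ibm_spread(forces_lb, positions_lb, lattice, kernel: str = "peskin4"):
    """Accumulate vertex forces (lattice units) into ``lattice.force``.

    The kernel weights sum to one, so the spread nodal forces sum to the
    input vertex forces exactly (wall-adjacent vertices spread part of their
    force onto wall nodes, where it is absorbed by the boundary).
    """
    width = kernel_weights(kernel)
    pos = np.ascontiguousarray(positions_lb, dtype=np.float64)
    _check_inside(lattice, pos)
    _spread(
        pos,
        np.ascontiguousarray(forces_lb, dtype=np.float64),
        lattice.force,
        lattice.nx,
        lattice.ny,
        lattice.nz,
        lattice.periodic[0],
        lattice.periodic[1],
        lattice.periodic[2],
        width,
    )
    return lattice


def ibm_interpolate(lattice, positions_lb, kernel: str = "peskin4"):
    """Sample the fluid velocity (lattice units) at vertex positions."""
    width = kernel_weights(kernel)
    pos = np.ascontiguousarray(positions_lb, dtype=np.float64)
    _check_inside(lattice, pos)
    out = np.empty_like(pos)
    _interpolate(
        pos,
        lattice.u,
        out,
        lattice.nx,
        lattice.ny,
        lattice.nz,
        lattice.periodic[0],
        lattice.periodic[1],
        lattice.periodic[2],
        width,
    )
    return out
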