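"""Coupled membrane-fluid simulation engine.

Couples the triangulated cell membranes (forces in Newtons, positions in
micrometres) to the D3Q19 fluid through the immersed-boundary kernels each
step:

1. membrane constitutive forces (link / bend / area / volume) on packed
   arrays, plus short-range inter-cell contact repulsion and a wall margin
   force (numerical contact model for the coarse desk-scale resolution);
2. spread to the lattice force field (Guo forcing);
3. one BGK collide-stream;
4. interpolate fluid velocity at vertices and advect them (forward Euler).

The packed-array membrane kernel is cross-checked in the tests against the
reference implementation in :mod:`hemoflow.membrane`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .ibm import _ibm_tables, _interp_cached, _spread_cached, kernel_weights

#: lexicographically positive half of the 27-cell neighbourhood (first row =
#: the centre cell itself, handled with an index-ordering guard)
_HALF_STENCIL = np.array(
    [(0, 0, 0)]
    + [
        (ox, oy, oz)
        for ox in (-1, 0, 1)
        for oy in (-1, 0, 1)
        for oz in (-1, 0, 1)
        if (ox, oy, oz) > (0, 0, 0)
    ],
    dtype=np.int64,
)
from .lattice import WALL, FluidLattice, StabilityError
from .membrane import CellModelParams
from .mesh import TriMesh

__all__ = ["Simulation"]


@njit(cache=True)
def _cell_volumes(verts, faces, face_cell, n_cells):
    vols = np.zeros(n_cells)
    for t in range(faces.shape[0]):
        a, b, c = faces[t, 0], faces[t, 1], faces[t, 2]
        vols[face_cell[t]] += (
            verts[a, 0] * (verts[b, 1] * verts[c, 2] - verts[b, 2] * verts[c, 1])
            + verts[a, 1] * (verts[b, 2] * verts[c, 0] - verts[b, 0] * verts[c, 2])
            + verts[a, 2] * (verts[b, 0] * verts[c, 1] - verts[b, 1] * verts[c, 0])
        ) / 6.0
    return vols


@njit(cache=True)
def _membrane_forces(
    verts,
    forces,
    edges,
    edge_l0,
    edge_k_over_p,
    tau_l,
    tris,
    tri_a0,
    tri_k,
    tau_a,
    tri_cell,
    cell_a0,
    cell_kag,
    quads,
    quad_th0,
    quad_k,
    tau_b,
    faces,
    face_cell,
    cell_v0,
    cell_kv,
    clamp,
):
    """Membrane forces [N] for all cells at once; verts in um.

    Returns (clamp_count, max_strain).  With clamp=False a strain at the pole
    guard returns clamp_count = -(element index + 1) as an error signal.
    """
    um = 1.0e-6
    n_clamped = 0
    max_strain = 0.0
    forces[:] = 0.0

    # link forces
    for e in range(edges.shape[0]):
        i, j = edges[e, 0], edges[e, 1]
        dx = verts[i, 0] - verts[j, 0]
        dy = verts[i, 1] - verts[j, 1]
        dz = verts[i, 2] - verts[j, 2]
        L = np.sqrt(dx * dx + dy * dy + dz * dz)
        dL = (L - edge_l0[e]) / edge_l0[e]
        if abs(dL) > max_strain:
            max_strain = abs(dL)
        lim = 0.98 * tau_l
        if abs(dL) >= lim:
            if not clamp:
                return -(e + 1), abs(dL)
            dL = lim if dL > 0 else -lim
            n_clamped += 1
        g = edge_k_over_p[e] * dL * (1.0 + 1.0 / (tau_l * tau_l - dL * dL))
        fx = -g * dx / L
        fy = -g * dy / L
        fz = -g * dz / L
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz

    # per-triangle area forces (+ whole-cell bilayer area penalty applied
    # along the same area gradients)
    n_cells = cell_v0.shape[0]
    cell_area = np.zeros(n_cells)
    for t in range(tris.shape[0]):
        a, b, c = tris[t, 0], tris[t, 1], tris[t, 2]
        abx = verts[b, 0] - verts[a, 0]
        aby = verts[b, 1] - verts[a, 1]
        abz = verts[b, 2] - verts[a, 2]
        acx = verts[c, 0] - verts[a, 0]
        acy = verts[c, 1] - verts[a, 1]
        acz = verts[c, 2] - verts[a, 2]
        nx = aby * acz - abz * acy
        ny = abz * acx - abx * acz
        nz = abx * acy - aby * acx
        cell_area[tri_cell[t]] += 0.5 * np.sqrt(nx * nx + ny * ny + nz * nz)
    for t in range(tris.shape[0]):
        a, b, c = tris[t, 0], tris[t, 1], tris[t, 2]
        abx = verts[b, 0] - verts[a, 0]
        aby = verts[b, 1] - verts[a, 1]
        abz = verts[b, 2] - verts[a, 2]
        acx = verts[c, 0] - verts[a, 0]
        acy = verts[c, 1] - verts[a, 1]
        acz = verts[c, 2] - verts[a, 2]
        nx = aby * acz - abz * acy
        ny = abz * acx - abx * acz
        nz = abx * acy - aby * acx
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        area = 0.5 * nn
        dA = (area - tri_a0[t]) / tri_a0[t]
        lim = 0.98 * tau_a
        if abs(dA) >= lim:
            if not clamp:
                return -(t + 1), abs(dA)
            dA = lim if dA > 0 else -lim
            n_clamped += 1
        coef = -tri_k[t] * dA * (1.0 + 1.0 / (tau_a * tau_a - dA * dA)) / (tri_a0[t] * um)
        cid = tri_cell[t]
        d_atot = (cell_area[cid] - cell_a0[cid]) / cell_a0[cid]
        coef -= cell_kag[cid] * d_atot / (cell_a0[cid] * um)
        nhx, nhy, nhz = nx / nn, ny / nn, nz / nn
        cbx = verts[c, 0] - verts[b, 0]
        cby = verts[c, 1] - verts[b, 1]
        cbz = verts[c, 2] - verts[b, 2]
        # grad_a A = 0.5 * nhat x (c - b), cyclic for b and c
        forces[a, 0] += coef * 0.5 * (nhy * cbz - nhz * cby)
        forces[a, 1] += coef * 0.5 * (nhz * cbx - nhx * cbz)
        forces[a, 2] += coef * 0.5 * (nhx * cby - nhy * cbx)
        forces[b, 0] += coef * 0.5 * (nhy * (-acz) - nhz * (-acy))
        forces[b, 1] += coef * 0.5 * (nhz * (-acx) - nhx * (-acz))
        forces[b, 2] += coef * 0.5 * (nhx * (-acy) - nhy * (-acx))
        forces[c, 0] += coef * 0.5 * (nhy * abz - nhz * aby)
        forces[c, 1] += coef * 0.5 * (nhz * abx - nhx * abz)
        forces[c, 2] += coef * 0.5 * (nhx * aby - nhy * abx)

    # bending forces (dihedral restoring)
    for q in range(quads.shape[0]):
        i, j, k, l = quads[q, 0], quads[q, 1], quads[q, 2], quads[q, 3]
        ex = verts[j, 0] - verts[i, 0]
        ey = verts[j, 1] - verts[i, 1]
        ez = verts[j, 2] - verts[i, 2]
        e2 = ex * ex + ey * ey + ez * ez
        el = np.sqrt(e2)
        kx = verts[k, 0] - verts[i, 0]
        ky = verts[k, 1] - verts[i, 1]
        kz = verts[k, 2] - verts[i, 2]
        lx = verts[l, 0] - verts[i, 0]
        ly = verts[l, 1] - verts[i, 1]
        lz = verts[l, 2] - verts[i, 2]
        n1x = ey * kz - ez * ky
        n1y = ez * kx - ex * kz
        n1z = ex * ky - ey * kx
        n2x = ly * ez - lz * ey
        n2y = lz * ex - lx * ez
        n2z = lx * ey - ly * ex
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        cx = n1y * n2z - n1z * n2y
        cy = n1z * n2x - n1x * n2z
        cz = n1x * n2y - n1y * n2x
        sin_t = (cx * ex + cy * ey + cz * ez) / el
        cos_t = n1x * n2x + n1y * n2y + n1z * n2z
        theta = np.arctan2(sin_t, cos_t)
        dth = theta - quad_th0[q]
        lim = 0.98 * tau_b
        if abs(dth) >= lim:
            if not clamp:
                return -(q + 1), abs(dth)
            dth = lim if dth > 0 else -lim
            n_clamped += 1
        moment = -quad_k[q] * dth * (1.0 + 1.0 / (tau_b * tau_b - dth * dth)) / um
        N1x, N1y, N1z = n1x / n1sq, n1y / n1sq, n1z / n1sq
        N2x, N2y, N2z = n2x / n2sq, n2y / n2sq, n2z / n2sq
        ak = ((kx - ex) * ex + (ky - ey) * ey + (kz - ez) * ez) / e2
        al = ((lx - ex) * ex + (ly - ey) * ey + (lz - ez) * ez) / e2
        bk = (kx * ex + ky * ey + kz * ez) / e2
        bl = (lx * ex + ly * ey + lz * ez) / e2
        gkx, gky, gkz = -el * N1x, -el * N1y, -el * N1z
        glx, gly, glz = -el * N2x, -el * N2y, -el * N2z
        gix = -el * (ak * N1x + al * N2x)
        giy = -el * (ak * N1y + al * N2y)
        giz = -el * (ak * N1z + al * N2z)
        gjx = el * (bk * N1x + bl * N2x)
        gjy = el * (bk * N1y + bl * N2y)
        gjz = el * (bk * N1z + bl * N2z)
        forces[i, 0] += moment * gix
        forces[i, 1] += moment * giy
        forces[i, 2] += moment * giz
        forces[j, 0] += moment * gjx
        forces[j, 1] += moment * gjy
        forces[j, 2] += moment * gjz
        forces[k, 0] += moment * gkx
        forces[k, 1] += moment * gky
        forces[k, 2] += moment * gkz
        forces[l, 0] += moment * glx
        forces[l, 1] += moment * gly
        forces[l, 2] += moment * glz

    # global volume penalty
    vols = _cell_volumes(verts, faces, face_cell, n_cells)
    for t in range(faces.shape[0]):
        cid = face_cell[t]
        dV = (vols[cid] - cell_v0[cid]) / cell_v0[cid]
        coef = -cell_kv[cid] * dV / (cell_v0[cid] * um) / 6.0
        a, b, c = faces[t, 0], faces[t, 1], faces[t, 2]
        forces[a, 0] += coef * (verts[b, 1] * verts[c, 2] - verts[b, 2] * verts[c, 1])
        forces[a, 1] += coef * (verts[b, 2] * verts[c, 0] - verts[b, 0] * verts[c, 2])
        forces[a, 2] += coef * (verts[b, 0] * verts[c, 1] - verts[b, 1] * verts[c, 0])
        forces[b, 0] += coef * (verts[c, 1] * verts[a, 2] - verts[c, 2] * verts[a, 1])
        forces[b, 1] += coef * (verts[c, 2] * verts[a, 0] - verts[c, 0] * verts[a, 2])
        forces[b, 2] += coef * (verts[c, 0] * verts[a, 1] - verts[c, 1] * verts[a, 0])
        forces[c, 0] += coef * (verts[a, 1] * verts[b, 2] - verts[a, 2] * verts[b, 1])
        forces[c, 1] += coef * (verts[a, 2] * verts[b, 0] - verts[a, 0] * verts[b, 2])
        forces[c, 2] += coef * (verts[a, 0] * verts[b, 1] - verts[a, 1] * verts[b, 0])
    return n_clamped, max_strain


@njit(cache=True)
def _contact_forces(
    verts,
    cellid,
    forces,
    k_rep,
    d0,
    box_um,
    periodic_x,
):
    """Short-range linear repulsion between vertices of different cells,
    with minimum-image wrapping along x when periodic.  Cell-linked binning
    at the cutoff length."""
    n = verts.shape[0]
    lx = box_um[0]
    nbx = max(int(lx / d0), 1)
    bsx = lx / nbx  # x bin size >= d0, tiling the period exactly
    nby = max(int(box_um[1] / d0), 1)
    nbz = max(int(box_um[2] / d0), 1)
    # bin vertices (counting sort)
    bins = np.empty(n, dtype=np.int64)
    for v in range(n):
        bx = int(np.floor(verts[v, 0] / bsx))
        if periodic_x:
            bx %= nbx
        else:
            bx = min(max(bx, 0), nbx - 1)
        by = min(max(int(verts[v, 1] / d0), 0), nby - 1)
        bz = min(max(int(verts[v, 2] / d0), 0), nbz - 1)
        bins[v] = (bx * nby + by) * nbz + bz
    nbins = nbx * nby * nbz
    count = np.zeros(nbins + 1, dtype=np.int64)
    for v in range(n):
        count[bins[v] + 1] += 1
    for b in range(nbins):
        count[b + 1] += count[b]
    order = np.empty(n, dtype=np.int64)
    fill = count[:-1].copy()
    for v in range(n):
        order[fill[bins[v]]] = v
        fill[bins[v]] += 1

    # half stencil: same bin with w > v, plus 13 lexicographically-positive
    # neighbour offsets (each pair visited once)
    for v in range(n):
        bx = int(np.floor(verts[v, 0] / bsx))
        if periodic_x:
            bx %= nbx
        else:
            bx = min(max(bx, 0), nbx - 1)
        by = min(max(int(verts[v, 1] / d0), 0), nby - 1)
        bz = min(max(int(verts[v, 2] / d0), 0), nbz - 1)
        for o in range(14):
            ox = _HALF_STENCIL[o, 0]
            oy = _HALF_STENCIL[o, 1]
            oz = _HALF_STENCIL[o, 2]
            tx = bx + ox
            if periodic_x:
                tx %= nbx
            elif tx < 0 or tx >= nbx:
                continue
            ty = by + oy
            if ty < 0 or ty >= nby:
                continue
            tz = bz + oz
            if tz < 0 or tz >= nbz:
                continue
            b = (tx * nby + ty) * nbz + tz
            same_bin = o == 0
            for s in range(count[b], count[b + 1]):
                w = order[s]
                if (same_bin and w <= v) or cellid[w] == cellid[v]:
                    continue
                dxv = verts[v, 0] - verts[w, 0]
                if periodic_x:
                    # cells are re-folded regularly, so one wrap suffices
                    if dxv > 0.5 * lx:
                        dxv -= lx
                    elif dxv < -0.5 * lx:
                        dxv += lx
                dyv = verts[v, 1] - verts[w, 1]
                dzv = verts[v, 2] - verts[w, 2]
                d2 = dxv * dxv + dyv * dyv + dzv * dzv
                if d2 >= d0 * d0 or d2 < 1e-12:
                    continue
                d = np.sqrt(d2)
                mag = k_rep * (1.0 - d / d0) / d
                forces[v, 0] += mag * dxv
                forces[v, 1] += mag * dyv
                forces[v, 2] += mag * dzv
                forces[w, 0] -= mag * dxv
                forces[w, 1] -= mag * dyv
                forces[w, 2] -= mag * dzv


class Simulation:
    """Cells + fluid, advanced in lock-step.

    Geometry comes from the lattice: a tube (periodic x, staircase wall) or a
    plane-shear box (periodic x/z, moving y walls).  Cell positions are in
    micrometres relative to the lattice origin (node 0 at 0).
    """

    def __init__(
        self,
        lattice: FluidLattice,
        kernel: str = "peskin4",
        k_rep: float = 4.0e-12,  # N at full overlap
        contact_range_um: float = 0.8,
        wall_margin_um: float = 0.6,
        clamp_membrane: bool = False,
        viscosity_contrast_every: int = 20,
        force_cap: float = 0.0,
    ):
        self.lattice = lattice
        self.kernel = kernel
        self.k_rep = k_rep
        self.contact_range_um = contact_range_um
        self.wall_margin_um = wall_margin_um
        self.clamp_membrane = clamp_membrane
        self.viscosity_contrast_every = viscosity_contrast_every
        #: optional per-vertex force magnitude cap [N] (0 = off).  Caution:
        #: a cap below the pole-restoring force scale (~5e-11 N) defeats the
        #: strain guards; it exists as a last-resort diagnostic knob only
        self.force_cap = force_cap
        self.force_cap_events = 0
        self.meshes: list[TriMesh] = []
        self.params: list[CellModelParams] = []
        self._packed = False
        self.clamp_events = 0
        self.time = 0.0
        self.history: dict = {"times": [], "com": [], "volumes": []}
        self.snapshots: list = []

    # -- setup -----------------------------------------------------------------

    def add_cell(self, mesh: TriMesh, params: CellModelParams):
        self.meshes.append(mesh)
        self.params.append(params)
        self._packed = False

    def _pack(self):
        off = 0
        edges, l0, kp = [], [], []
        tris, a0, ka = [], [], []
        quads, th0, kb = [], [], []
        faces, fcell = [], []
        v0, kv, a0cell, kag = [], [], [], []
        verts = []
        cellid = []
        for cid, (m, p) in enumerate(zip(self.meshes, self.params)):
            verts.append(m.vertices)
            cellid.append(np.full(m.n_vertices, cid))
            edges.append(m.edges + off)
            l0.append(m.reference_edge_lengths)
            kp.append(np.full(len(m.edges), p.kappa_link / p.p))
            tris.append(m.triangles + off)
            a0.append(m.reference_triangle_areas)
            ka.append(np.full(len(m.triangles), p.kappa_area))
            quads.append(m.bend_quads + off)
            th0.append(m.reference_dihedrals)
            kb.append(np.full(len(m.bend_quads), p.kappa_bend))
            faces.append(m.triangles + off)
            fcell.append(np.full(len(m.triangles), cid))
            v0.append(m.reference_volume)
            kv.append(p.kappa_volume)
            a0cell.append(m.reference_total_area)
            kag.append(p.kappa_area_global)
            off += m.n_vertices
        self.verts = np.ascontiguousarray(np.concatenate(verts))
        self.cellid = np.concatenate(cellid).astype(np.int64)
        self._edges = np.ascontiguousarray(np.concatenate(edges))
        self._l0 = np.concatenate(l0)
        self._kp = np.concatenate(kp)
        self._tris = np.ascontiguousarray(np.concatenate(tris))
        self._a0 = np.concatenate(a0)
        self._ka = np.concatenate(ka)
        self._quads = np.ascontiguousarray(np.concatenate(quads))
        self._th0 = np.concatenate(th0)
        self._kb = np.concatenate(kb)
        self._faces = np.ascontiguousarray(np.concatenate(faces))
        self._fcell = np.concatenate(fcell)
        self._v0 = np.array(v0)
        self._kv = np.array(kv)
        self._xshift = np.zeros(len(self.meshes))
        self._has_contrast = any(p.Lambda != 1.0 for p in self.params)
        self._a0cell = np.array(a0cell)
        self._kag = np.array(kag)
        self.forces = np.zeros_like(self.verts)
        p0 = self.params[0]
        self._tau_l, self._tau_a, self._tau_b = p0.tau_l, p0.tau_area, p0.tau_bend
        self._vert_slices = []
        off = 0
        for m in self.meshes:
            self._vert_slices.append(slice(off, off + m.n_vertices))
            off += m.n_vertices
        self._packed = True

    # -- per-step pieces ---------------------------------------------------------

    def membrane_forces(self) -> np.ndarray:
        """Membrane constitutive forces [N] on all vertices (packed kernel)."""
        if not self._packed:
            self._pack()
        status, strain = _membrane_forces(
            self.verts,
            self.forces,
            self._edges,
            self._l0,
            self._kp,
            self._tau_l,
            self._tris,
            self._a0,
            self._ka,
            self._tau_a,
            self._fcell,
            self._a0cell,
            self._kag,
            self._quads,
            self._th0,
            self._kb,
            self._tau_b,
            self._faces,
            self._fcell,
            self._v0,
            self._kv,
            self.clamp_membrane,
        )
        if status < 0:
            raise StabilityError(
                f"membrane strain {strain:.3f} reached the pole guard at "
                f"element {-status - 1} (t = {self.time:.3e} s)"
            )
        self.clamp_events += status
        return self.forces

    def _wall_forces(self):
        """Margin force keeping vertices off the boundary nodes."""
        lat = self.lattice
        margin = self.wall_margin_um
        dx_um = lat.dx * 1e6
        if hasattr(lat, "tube_radius_um"):
            cy, cz = lat.axis_center_um
            y = self.verts[:, 1] - cy
            z = self.verts[:, 2] - cz
            r = np.sqrt(y * y + z * z)
            rmax = lat.tube_radius_um - margin
            over = r > rmax
            if over.any():
                mag = self.k_rep * (r[over] - rmax) / margin
                self.forces[over, 1] -= mag * y[over] / r[over]
                self.forces[over, 2] -= mag * z[over] / r[over]
        elif not lat.periodic[1]:
            y = self.verts[:, 1]
            lo = 0.5 * dx_um + margin
            hi = (lat.ny - 1.5) * dx_um - margin
            below, above = y < lo, y > hi
            self.forces[below, 1] += self.k_rep * (lo - y[below]) / margin
            self.forces[above, 1] -= self.k_rep * (y[above] - hi) / margin

    def compute_forces(self) -> np.ndarray:
        self.membrane_forces()
        if len(self.meshes) > 1:
            box = (
                self.lattice.nx * self.lattice.dx * 1e6,
                self.lattice.ny * self.lattice.dx * 1e6,
                self.lattice.nz * self.lattice.dx * 1e6,
            )
            _contact_forces(
                self.verts,
                self.cellid,
                self.forces,
                self.k_rep,
                self.contact_range_um,
                np.array(box),
                self.lattice.periodic[0],
            )
        self._wall_forces()
        if self.force_cap:
            mag = np.sqrt((self.forces**2).sum(axis=1))
            over = mag > self.force_cap
            if over.any():
                self.force_cap_events += int(over.sum())
                self.forces[over] *= (self.force_cap / mag[over])[:, None]
        return self.forces

    def step(self, n_steps: int = 1, sample_every: int | None = None):
        if not self._packed:
            self._pack()
        lat = self.lattice
        if lat._nbr is None:
            lat._rebuild_neighbors()
        dx_um = lat.dx * 1e6
        width = kernel_weights(self.kernel)
        force_scale = lat.dt**2 / (lat.rho_phys * lat.dx**4)
        n_verts = len(self.verts)
        idx = np.empty((n_verts, 3, width), dtype=np.int64)
        wts = np.empty((n_verts, 3, width))
        for s in range(n_steps):
            self.compute_forces()
            lat.force[:] = 0.0
            pos_lb = self.verts / dx_um
            _ibm_tables(
                pos_lb,
                lat.nx,
                lat.ny,
                lat.nz,
                lat.periodic[0],
                lat.periodic[1],
                lat.periodic[2],
                width,
                idx,
                wts,
            )
            _spread_cached(
                idx, wts, self.forces * force_scale, lat.force, lat.ny, lat.nz, width
            )
            lat.step()
            v_lb = np.empty_like(pos_lb)
            _interp_cached(idx, wts, lat.u, v_lb, lat.ny, lat.nz, width)
            # vertices stay unwrapped along periodic x (the IBM kernels wrap
            # indices); membrane geometry is then always single-image
            self.verts += v_lb * dx_um
            self.time += lat.dt
            if lat.periodic[0] and (s + 1) % 200 == 0:
                self._fold_cells()
            if (
                self._has_contrast
                and self.viscosity_contrast_every
                and (s + 1) % self.viscosity_contrast_every == 0
            ):
                self._refresh_viscosity_contrast()
            if sample_every and (s + 1) % sample_every == 0:
                self.record()
        return self

    # -- observables -----------------------------------------------------------

    def _fold_cells(self):
        """Shift each cell by whole periods so its centre stays in [0, L);
        the accumulated shift keeps reported trajectories continuous."""
        lx = self.lattice.nx * self.lattice.dx * 1e6
        for c, sl in enumerate(self._vert_slices):
            k = np.floor(self.verts[sl, 0].mean() / lx)
            if k != 0:
                self.verts[sl, 0] -= k * lx
                self._xshift[c] += k * lx

    def _refresh_viscosity_contrast(self):
        """Re-classify interior fluid nodes of cells with Lambda != 1
        (amortised: called every `viscosity_contrast_every` steps)."""
        from .lattice import set_viscosity_contrast

        meshes, lambdas = [], []
        lx = self.lattice.nx * self.lattice.dx * 1e6
        for m, p, sl in zip(self.meshes, self.params, self._vert_slices):
            if p.Lambda == 1.0:
                continue
            mm = m.copy()
            mm.vertices = self.verts[sl].copy()
            if self.lattice.periodic[0]:
                mm.vertices[:, 0] -= np.floor(mm.vertices[:, 0].mean() / lx) * lx
            meshes.append(mm)
            lambdas.append(p.Lambda)
        set_viscosity_contrast(self.lattice, meshes, lambdas)

    def centers_of_mass(self) -> np.ndarray:
        """Per-cell centre of mass (continuous along the periodic axis)."""
        if not self._packed:
            self._pack()
        out = np.empty((len(self.meshes), 3))
        for c, sl in enumerate(self._vert_slices):
            out[c] = self.verts[sl].mean(axis=0)
        out[:, 0] += self._xshift
        return out

    def cell_volumes(self) -> np.ndarray:
        return _cell_volumes(self.verts, self._faces, self._fcell, len(self.meshes))

    def volume_drift(self) -> np.ndarray:
        return self.cell_volumes() / self._v0 - 1.0

    def cell_areas(self) -> np.ndarray:
        from .mesh import triangle_areas

        areas = triangle_areas(self.verts, self._faces)
        out = np.zeros(len(self.meshes))
        np.add.at(out, self._fcell, areas)
        return out

    def area_drift(self) -> np.ndarray:
        ref = np.array([m.reference_total_area for m in self.meshes])
        return self.cell_areas() / ref - 1.0

    def record(self):
        self.history["times"].append(self.time)
        self.history["com"].append(self.centers_of_mass())
        self.history["volumes"].append(self.cell_volumes())

    def snapshot(self):
        self.snapshots.append((self.time, self.verts.copy()))

    def current_meshes(self, fold: bool = False) -> list[TriMesh]:
        """Meshes at the current positions.  With ``fold=True`` each cell is
        shifted by a multiple of the periodic x length so its centre of mass
        lies in [0, L); cells straddling the boundary additionally yield a
        ghost copy shifted by one period (for voxel-based profiles)."""
        out = []
        lx = self.lattice.nx * self.lattice.dx * 1e6
        for m, sl in zip(self.meshes, self._vert_slices):
            mm = m.copy()
            mm.vertices = self.verts[sl].copy()
            if fold and self.lattice.periodic[0]:
                shift = np.floor(mm.vertices[:, 0].mean() / lx) * lx
                mm.vertices[:, 0] -= shift
                if mm.vertices[:, 0].min() < 0:
                    ghost = mm.copy()
                    ghost.vertices = ghost.vertices + np.array([lx, 0, 0])
                    out.append(ghost)
                elif mm.vertices[:, 0].max() > lx:
                    ghost = mm.copy()
                    ghost.vertices = ghost.vertices - np.array([lx, 0, 0])
                    out.append(ghost)
            out.append(mm)
        return out

    def species_labels(self) -> list[str]:
        return [m.species_label for m in self.meshes]

    # -- checkpointing -----------------------------------------------------------

    def checkpoint(self, path: str):
        """HDF5 dump of the fluid state and vertex positions."""
        import h5py

        with h5py.File(path, "w") as h5:
            h5.attrs["time"] = self.time
            h5.attrs["dx"] = self.lattice.dx
            h5.attrs["tau_lb"] = self.lattice.tau_lb
            h5.create_dataset("f", data=self.lattice.f)
            h5.create_dataset("flags", data=self.lattice.flags)
            h5.create_dataset("tau", data=self.lattice.tau)
            h5.create_dataset("verts", data=self.verts)

    def restore(self, path: str):
        import h5py

        with h5py.File(path, "r") as h5:
            self.time = float(h5.attrs["time"])
            self.lattice.f[:] = h5["f"][...]
            self.lattice.flags[:] = h5["flags"][...]
            self.lattice.tau[:] = h5["tau"][...]
            if not self._packed:
                self._pack()
            self.verts[:] = h5["verts"][...]
        self.lattice._rebuild_neighbors()
        return self
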