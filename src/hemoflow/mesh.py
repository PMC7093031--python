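"""Triangulated cell surfaces: biconcave red blood cells and oblate platelets.

All meshes are closed, consistently outward-oriented triangulations built by
subdividing an icosahedron and mapping it onto the target surface.  Positions
are stored in micrometres.  The reference (stress-free) geometry of a mesh is
frozen at construction time and used by the membrane force model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.integrate import quad

__all__ = [
    "TriMesh",
    "build_rbc_mesh",
    "build_platelet_mesh",
    "biconcave_profile",
    "mesh_volume",
    "mesh_area",
    "write_ply",
    "read_ply",
    "write_legacy_vtk",
]

# Biconcave disc profile (Evans-Fung quartic thickness law).  x = 2r/D is the
# normalised planar radius; the half-thickness is
#   z(x) = alpha * (D/4) * sqrt(1-x^2) * (C0 + C1 x^2 + C2 x^4)
# with alpha chosen once so the 8 um cell encloses 90 um^3.
_EF_C0, _EF_C1, _EF_C2 = 0.207161, 2.002558, -1.122762

#: Subdivision levels of an icosphere and the vertex counts they produce.
_ICOSPHERE_VERTS = {12: 0, 42: 1, 162: 2, 642: 3, 2562: 4}


def _ef_volume_factor() -> float:
    f = lambda x: x * np.sqrt(1.0 - x * x) * (_EF_C0 + _EF_C1 * x**2 + _EF_C2 * x**4)
    integral, _ = quad(f, 0.0, 1.0)
    return integral


_EF_INTEGRAL = _ef_volume_factor()


def _thickness_scale(diameter: float, volume: float = 90.0) -> float:
    """Scale factor on the quartic profile so the cell encloses `volume` um^3
    when built at the nominal 8 um diameter (the factor is diameter-invariant
    relative to the similarity-scaled cell)."""
    v_unscaled = 4.0 * np.pi * (8.0 / 2) ** 2 * (8.0 / 4) * _EF_INTEGRAL
    return volume / v_unscaled


_EF_ALPHA = _thickness_scale(8.0)


def biconcave_profile(r: np.ndarray, diameter: float = 8.0) -> np.ndarray:
    """Half-thickness z(r) [um] of the biconcave disc at planar radius r [um]."""
    x = np.clip(2.0 * np.asarray(r, dtype=float) / diameter, 0.0, 1.0)
    return (
        _EF_ALPHA
        * (diameter / 4.0)
        * np.sqrt(1.0 - x * x)
        * (_EF_C0 + _EF_C1 * x**2 + _EF_C2 * x**4)
    )


@dataclass
class TriMesh:
    """A closed triangulated cell surface with its frozen reference geometry.

    Vertices are in micrometres.  `edges` and the bending quadruples are
    derived from the triangle list at construction.
    """

    vertices: np.ndarray  # (V, 3) um, current positions
    triangles: np.ndarray  # (F, 3) int
    species_label: str = "healthy_rbc"

    edges: np.ndarray = field(init=False)  # (E, 2) int
    #: per interior edge: (i, j, k, l) with shared edge i-j, opposite verts k, l
    bend_quads: np.ndarray = field(init=False)
    reference_edge_lengths: np.ndarray = field(init=False)
    reference_triangle_areas: np.ndarray = field(init=False)
    reference_dihedrals: np.ndarray = field(init=False)
    reference_total_area: float = field(init=False)
    reference_volume: float = field(init=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        tm = trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )
        if not tm.is_watertight:
            raise ValueError("mesh surface is not closed")
        if tm.volume < 0:
            self.triangles = self.triangles[:, ::-1].copy()
            tm = trimesh.Trimesh(
                vertices=self.vertices, faces=self.triangles, process=False
            )
        v, e, f = len(self.vertices), len(tm.edges_unique), len(self.triangles)
        if v - e + f != 2:
            raise ValueError(f"Euler characteristic {v - e + f} != 2")
        self.edges = np.ascontiguousarray(tm.edges_unique, dtype=np.int64)
        self.bend_quads = _bend_quads(self.triangles, tm)
        self._freeze_reference()

    def _freeze_reference(self) -> None:
        self.reference_edge_lengths = edge_lengths(self.vertices, self.edges)
        self.reference_triangle_areas = triangle_areas(self.vertices, self.triangles)
        self.reference_dihedrals = dihedral_angles(self.vertices, self.bend_quads)
        if np.any(self.reference_edge_lengths <= 0):
            raise ValueError("degenerate reference edge")
        if np.any(self.reference_triangle_areas <= 0):
            raise ValueError("degenerate reference triangle")
        self.reference_total_area = float(self.reference_triangle_areas.sum())
        self.reference_volume = mesh_volume(self.vertices, self.triangles)

    # -- current-state geometry ------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def volume(self) -> float:
        """Enclosed volume [um^3] of the current configuration."""
        return mesh_volume(self.vertices, self.triangles)

    def area(self) -> float:
        """Surface area [um^2] of the current configuration."""
        return float(triangle_areas(self.vertices, self.triangles).sum())

    def centroid(self) -> np.ndarray:
        """Area-weighted surface centroid [um]."""
        tri = self.vertices[self.triangles]
        centers = tri.mean(axis=1)
        areas = triangle_areas(self.vertices, self.triangles)
        return (centers * areas[:, None]).sum(axis=0) / areas.sum()

    def mean_edge_length(self) -> float:
        return float(self.reference_edge_lengths.mean())

    def copy(self) -> "TriMesh":
        out = TriMesh.__new__(TriMesh)
        out.__dict__.update(self.__dict__)
        out.vertices = self.vertices.copy()
        return out

    def translated(self, shift) -> "TriMesh":
        out = self.copy()
        out.vertices = out.vertices + np.asarray(shift, dtype=float)
        return out

    def rotated(self, rotation: np.ndarray, about=None) -> "TriMesh":
        """Rigidly rotate about `about` (default: centroid of vertices)."""
        out = self.copy()
        c = out.vertices.mean(axis=0) if about is None else np.asarray(about, float)
        out.vertices = (out.vertices - c) @ np.asarray(rotation).T + c
        return out


def _bend_quads(faces: np.ndarray, tm: trimesh.Trimesh) -> np.ndarray:
    """For every interior edge, the quadruple (i, j, k, l): edge i-j shared by
    triangles (i, j, k) and (j, i, l), windings taken from the face list."""
    adj = tm.face_adjacency
    adj_edges = tm.face_adjacency_edges
    quads = np.empty((len(adj), 4), dtype=np.int64)
    for n, ((fa, fb), (i, j)) in enumerate(zip(adj, adj_edges)):
        tri_a = faces[fa]
        tri_b = faces[fb]
        k = [v for v in tri_a if v != i and v != j][0]
        l = [v for v in tri_b if v != i and v != j][0]
        # orient so that triangle (i, j, k) matches tri_a's winding
        ia = list(tri_a).index(i)
        if tri_a[(ia + 1) % 3] != j:
            i, j = j, i
        quads[n] = (i, j, k, l)
    return quads


# -- geometry primitives (shared with the membrane force model) ---------------


def edge_lengths(verts: np.ndarray, edges: np.ndarray) -> np.ndarray:
    d = verts[edges[:, 0]] - verts[edges[:, 1]]
    return np.sqrt((d * d).sum(axis=1))


def triangle_areas(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    n = np.cross(b - a, c - a)
    return 0.5 * np.sqrt((n * n).sum(axis=1))


def mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume by the divergence theorem (outward winding assumed)."""
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0)


def mesh_area(verts: np.ndarray, faces: np.ndarray) -> float:
    return float(triangle_areas(verts, faces).sum())


def dihedral_angles(verts: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Signed dihedral angle at each interior edge (0 for a flat pair).

    Positive when the surface is locally convex with respect to the
    triangle windings (i, j, k) / (j, i, l).
    """
    xi, xj = verts[quads[:, 0]], verts[quads[:, 1]]
    xk, xl = verts[quads[:, 2]], verts[quads[:, 3]]
    e = xj - xi
    n1 = np.cross(e, xk - xi)
    n2 = np.cross(xl - xi, e)
    elen = np.sqrt((e * e).sum(axis=1))
    cross12 = np.cross(n1, n2)
    sin_t = (cross12 * e).sum(axis=1) / np.maximum(elen, 1e-300)
    cos_t = (n1 * n2).sum(axis=1)
    return np.arctan2(sin_t, cos_t)


# -- builders -----------------------------------------------------------------


def _icosphere(n_vertices: int) -> trimesh.Trimesh:
    if n_vertices not in _ICOSPHERE_VERTS:
        raise ValueError(
            f"n_vertices must be one of {sorted(_ICOSPHERE_VERTS)} "
            "(closed icosphere subdivision counts)"
        )
    return trimesh.creation.icosphere(subdivisions=_ICOSPHERE_VERTS[n_vertices])


def build_rbc_mesh(
    n_vertices: int = 642, diameter: float = 8.0, species_label: str = "healthy_rbc"
) -> TriMesh:
    """Closed biconcave RBC mesh of the given diameter [um].

    The unit icosphere is mapped radially onto the biconcave disc: planar
    coordinates scale with the diameter, the axial coordinate follows the
    quartic thickness profile at the vertex's planar radius.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if n_vertices < 162:
        raise ValueError("RBC mesh needs at least 162 vertices")
    sph = _icosphere(n_vertices)
    s = sph.vertices
    r_cyl = np.sqrt(s[:, 0] ** 2 + s[:, 1] ** 2)
    verts = np.empty_like(s)
    verts[:, 0] = (diameter / 2.0) * s[:, 0]
    verts[:, 1] = (diameter / 2.0) * s[:, 1]
    verts[:, 2] = np.sign(s[:, 2]) * biconcave_profile(
        (diameter / 2.0) * r_cyl, diameter
    )
    return TriMesh(verts, sph.faces, species_label=species_label)


def build_platelet_mesh(
    n_vertices: int = 162,
    diameter: float = 2.4,
    thickness: float = 1.0,
    species_label: str = "platelet",
) -> TriMesh:
    """Closed oblate-ellipsoid platelet mesh (diameter x diameter x thickness, um)."""
    if diameter <= 0 or thickness <= 0:
        raise ValueError("diameter and thickness must be positive")
    if thickness > diameter:
        raise ValueError("thickness must not exceed diameter (oblate ellipsoid)")
    sph = _icosphere(n_vertices)
    verts = sph.vertices * np.array([diameter / 2, diameter / 2, thickness / 2])
    # radial volume correction for the inscribed-polyhedron deficit, so the
    # enclosed volume matches the analytic ellipsoid at any subdivision level
    target = np.pi / 6.0 * diameter**2 * thickness
    verts = verts * (target / mesh_volume(verts, sph.faces)) ** (1.0 / 3.0)
    return TriMesh(verts, sph.faces, species_label=species_label)


# -- I/O ----------------------------------------------------------------------


def write_ply(mesh: TriMesh, path: str) -> None:
    """ASCII PLY snapshot (positions in um)."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    with open(path, "wb") as fh:
        fh.write(trimesh.exchange.ply.export_ply(tm, encoding="ascii"))


def read_ply(path: str, species_label: str = "healthy_rbc") -> TriMesh:
    tm = trimesh.load(path, process=False, force="mesh")
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces), species_label)


def write_legacy_vtk(mesh: TriMesh, path: str) -> None:
    """Legacy-VTK polydata snapshot (ASCII, positions in um)."""
    v, f = mesh.vertices, mesh.triangles
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncell surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} double\n")
        for p in v:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        for t in f:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
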