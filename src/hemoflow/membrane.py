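"""Coarse-grained spectrin-network membrane mechanics.

The membrane response of a cell is the superposition of four conservative
forces derived from a discrete energy on the triangulated surface:

* **link** — stretching/compression of the spectrin network along mesh edges.
  The force magnitude per edge is ``kappa_l * dL / p * [1 + 1/(tau_l^2 - dL^2)]``
  with normal strain ``dL = (L - L0)/L0``; it diverges as ``|dL| -> tau_l``
  (the network reaches its persistence length).
* **bend** — a dihedral-angle restoring force per interior edge with the same
  pole structure applied to the angle deviation from the resting shape.
* **area** — a per-triangle surface response on the relative area deviation,
  again with the pole structure.
* **volume** — a global quasi-incompressibility penalty on the relative
  enclosed-volume deviation, acting along the discrete volume gradient
  (area-weighted outward normals).

All four derive from rotation- and translation-invariant energies, so each is
exactly force- and torque-free over a cell at every configuration.  Mesh
positions are in micrometres; forces are returned in Newtons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .constants import KBT, DEFAULT_CONSTANTS, PhysicalConstants
from .mesh import TriMesh, build_rbc_mesh, dihedral_angles, edge_lengths

__all__ = [
    "CellModelParams",
    "MembraneStabilityError",
    "PRESETS",
    "get_preset",
    "load_params",
    "link_force",
    "response_forces",
    "membrane_forces",
    "patch_young_modulus",
    "solve_area_coefficient",
]

_UM = 1.0e-6  # metres per micrometre


class MembraneStabilityError(RuntimeError):
    """A membrane strain reached the pole of the constitutive law."""


# Area coefficient of the healthy calibration: solved once (see
# solve_area_coefficient) so that the hexagonal-patch test of the healthy
# membrane (kappa_link = 15 kBT) returns the validated 27.82 uN/m surface
# Young's modulus at the default RBC mesh edge length.
DEFAULT_KAPPA_AREA_KBT = 635.56800


@dataclass(frozen=True)
class CellModelParams:
    """Mechanical parameter set of one cell species.

    Stiffness coefficients are stored in Joules; use :func:`get_preset` or
    ``CellModelParams.from_kbt`` to specify them in multiples of kBT.
    ``young_modulus_reported`` [uN/m] is a reference value carried along for
    comparison only — it never enters the dynamics.
    """

    kappa_link: float  # J
    Lambda: float = 1.0  # interior/exterior viscosity ratio
    tau_l: float = 3.0  # relative expansion ratio (pole of the link law)
    p: float = 7.5e-9  # persistence length [m]
    kappa_bend: float = 80.0 * KBT  # J
    kappa_area: float = DEFAULT_KAPPA_AREA_KBT * KBT  # J
    kappa_volume: float = 2.5e7 * KBT  # J (global penalty)
    kappa_area_global: float = 1.2e7 * KBT  # J (whole-cell bilayer area penalty)
    tau_bend: float = np.pi  # pole of the bending law [rad] (complete fold)
    tau_area: float = 1.0  # pole of the area law (triangle collapse/doubling)
    young_modulus_reported: float | None = None  # uN/m
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.kappa_link <= 0 or self.p <= 0:
            raise ValueError("kappa_link and p must be positive")
        if self.tau_l <= 1:
            raise ValueError("tau_l must exceed 1")
        if self.Lambda < 1:
            raise ValueError("Lambda must be >= 1")

    @classmethod
    def from_kbt(cls, kappa_link_kbt: float, **kw) -> "CellModelParams":
        for key in ("kappa_bend", "kappa_area", "kappa_volume"):
            k = key + "_kbt"
            if k in kw:
                kw[key] = kw.pop(k) * KBT
        return cls(kappa_link=kappa_link_kbt * KBT, **kw)


def _make_presets() -> dict:
    common = dict(kappa_area=DEFAULT_KAPPA_AREA_KBT * KBT)
    return {
        "healthy": CellModelParams.from_kbt(
            15.0, Lambda=1.0, young_modulus_reported=27.82, label="healthy", **common
        ),
        "tbhp_0p5": CellModelParams.from_kbt(
            90.0, Lambda=6.0, young_modulus_reported=244.04, label="tbhp_0p5", **common
        ),
        "tbhp_0p75": CellModelParams.from_kbt(
            600.0, Lambda=1.0, young_modulus_reported=808.00, label="tbhp_0p75", **common
        ),
        "platelet": CellModelParams.from_kbt(
            25.0, Lambda=1.0, young_modulus_reported=70.6, label="platelet", **common
        ),
    }


PRESETS = _make_presets()

#: mesh species label used by each preset
SPECIES_OF_PRESET = {
    "healthy": "healthy_rbc",
    "tbhp_0p5": "stiff_rbc_0p5",
    "tbhp_0p75": "stiff_rbc_0p75",
    "platelet": "platelet",
}


def get_preset(name: str) -> CellModelParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}") from None


def load_params(path: str) -> CellModelParams:
    """Load a parameter set from a YAML key-value file.

    Recognised keys: ``preset`` (base preset name) plus any CellModelParams
    field; ``kappa_*_kbt`` variants give stiffnesses in kBT multiples.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    base = get_preset(cfg.pop("preset")) if "preset" in cfg else None
    for key in list(cfg):
        if key.endswith("_kbt"):
            cfg[key[:-4]] = cfg.pop(key) * KBT
    if base is not None:
        return replace(base, **cfg)
    return CellModelParams(**cfg)


# -- constitutive laws (shared by the cell model and the patch test) ----------


def _pole_factor(x: np.ndarray, tau: float) -> np.ndarray:
    return 1.0 + 1.0 / (tau * tau - x * x)

def _strain_energy(x, tau):
    """Antiderivative of x * (1 + 1/(tau^2 - x^2)): the per-unit-stiffness
    strain energy, zero at x = 0."""
    return 0.5 * x * x - 0.5 * np.log((tau * tau - x * x) / (tau * tau))


def _guard_strain(x: np.ndarray, tau: float, what: str, mode: str) -> np.ndarray:
    limit = 0.98 * tau
    bad = np.abs(x) >= limit
    if not np.any(bad):
        return x
    if mode == "raise":
        idx = int(np.argmax(np.abs(x)))
        raise MembraneStabilityError(
            f"{what} strain {x.flat[np.argmax(np.abs(x))]:.3f} at element {idx} "
            f"reached the pole guard 0.98*tau = {limit:.3f}"
        )
    warnings.warn(f"{what} strain clamped at {limit:.3f} on {bad.sum()} elements")
    return np.clip(x, -limit, limit)


def link_force(
    mesh: TriMesh,
    params: CellModelParams,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    mode: str = "raise",
) -> np.ndarray:
    """Spectrin-link force [N] per vertex.

    Each edge applies equal-and-opposite axial forces of magnitude
    ``kappa_l*|dL|/p*[1 + 1/(tau_l^2-dL^2)]`` to its endpoints, restoring the
    reference length.  ``mode='clamp'`` clamps strains at the pole guard
    instead of raising (bulk-run option).
    """
    del constants  # kBT already folded into kappa_link
    e0, e1 = mesh.edges[:, 0], mesh.edges[:, 1]
    d = mesh.vertices[e0] - mesh.vertices[e1]
    L = np.sqrt((d * d).sum(axis=1))
    dL = (L - mesh.reference_edge_lengths) / mesh.reference_edge_lengths
    dL = _guard_strain(dL, params.tau_l, "link", mode)
    g = (params.kappa_link / params.p) * dL * _pole_factor(dL, params.tau_l)
    fvec = -(g / L)[:, None] * d  # on e0; -fvec on e1
    out = np.zeros_like(mesh.vertices)
    np.add.at(out, e0, fvec)
    np.add.at(out, e1, -fvec)
    return out


def _area_gradients(verts, faces):
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    n = np.cross(b - a, c - a)
    nn = np.sqrt((n * n).sum(axis=1))
    areas = 0.5 * nn
    nhat = n / nn[:, None]
    ga = 0.5 * np.cross(nhat, c - b)
    gb = 0.5 * np.cross(nhat, a - c)
    gc = 0.5 * np.cross(nhat, b - a)
    return areas, ga, gb, gc


def response_forces(
    mesh: TriMesh, params: CellModelParams, mode: str = "raise"
) -> np.ndarray:
    """Bending + local-area + volume restoring forces [N] per vertex.

    Zero at the reference configuration; the volume term opposes the sign of
    the enclosed-volume deviation.
    """
    verts, faces = mesh.vertices, mesh.triangles
    out = np.zeros_like(verts)

    # --- local area response -------------------------------------------------
    areas, ga, gb, gc = _area_gradients(verts, faces)
    if np.any(areas <= 0) or not np.all(np.isfinite(areas)):
        raise ValueError("degenerate (zero-area) triangle")
    a0 = mesh.reference_triangle_areas
    dA = (areas - a0) / a0
    dA = _guard_strain(dA, params.tau_area, "area", mode)
    coef = -params.kappa_area * dA * _pole_factor(dA, params.tau_area) / (a0 * _UM)
    # whole-cell area penalty (bilayer total-area incompressibility)
    a_tot0 = mesh.reference_total_area
    d_atot = (areas.sum() - a_tot0) / a_tot0
    coef = coef - params.kappa_area_global * d_atot / (a_tot0 * _UM)
    np.add.at(out, faces[:, 0], coef[:, None] * ga)
    np.add.at(out, faces[:, 1], coef[:, None] * gb)
    np.add.at(out, faces[:, 2], coef[:, None] * gc)

    # --- bending response ----------------------------------------------------
    q = mesh.bend_quads
    xi, xj, xk, xl = verts[q[:, 0]], verts[q[:, 1]], verts[q[:, 2]], verts[q[:, 3]]
    e = xj - xi
    elen2 = (e * e).sum(axis=1)
    elen = np.sqrt(elen2)
    n1 = np.cross(e, xk - xi)
    n2 = np.cross(xl - xi, e)
    N1 = n1 / (n1 * n1).sum(axis=1)[:, None]
    N2 = n2 / (n2 * n2).sum(axis=1)[:, None]
    sin_t = (np.cross(n1, n2) * e).sum(axis=1) / elen
    cos_t = (n1 * n2).sum(axis=1)
    theta = np.arctan2(sin_t, cos_t)
    dth = theta - mesh.reference_dihedrals
    dth = _guard_strain(dth, params.tau_bend, "bend", mode)
    moment = -params.kappa_bend * dth * _pole_factor(dth, params.tau_bend) / _UM
    # dihedral-angle gradients (validated against finite differences)
    gk = -elen[:, None] * N1
    gl = -elen[:, None] * N2
    ak = ((xk - xj) * e).sum(axis=1) / elen2
    al = ((xl - xj) * e).sum(axis=1) / elen2
    bk = ((xk - xi) * e).sum(axis=1) / elen2
    bl = ((xl - xi) * e).sum(axis=1) / elen2
    gi = -elen[:, None] * (ak[:, None] * N1 + al[:, None] * N2)
    gj = elen[:, None] * (bk[:, None] * N1 + bl[:, None] * N2)
    np.add.at(out, q[:, 0], moment[:, None] * gi)
    np.add.at(out, q[:, 1], moment[:, None] * gj)
    np.add.at(out, q[:, 2], moment[:, None] * gk)
    np.add.at(out, q[:, 3], moment[:, None] * gl)

    # --- volume quasi-incompressibility --------------------------------------
    v0 = mesh.reference_volume
    dV = (mesh.volume() - v0) / v0
    coef_v = -params.kappa_volume * dV / (v0 * _UM)
    pa, pb, pc = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    np.add.at(out, faces[:, 0], coef_v * np.cross(pb, pc) / 6.0)
    np.add.at(out, faces[:, 1], coef_v * np.cross(pc, pa) / 6.0)
    np.add.at(out, faces[:, 2], coef_v * np.cross(pa, pb) / 6.0)
    return out


def membrane_forces(
    mesh: TriMesh, params: CellModelParams, mode: str = "raise"
) -> np.ndarray:
    """Total membrane force [N] per vertex: link + bend + area + volume."""
    return link_force(mesh, params, mode=mode) + response_forces(
        mesh, params, mode=mode
    )


# -- hexagonal-patch surface Young's modulus ----------------------------------

_PATCH_EDGE_UM: float | None = None


def default_patch_edge_um() -> float:
    """Mean edge length [um] of the default 642-vertex, 8 um RBC mesh."""
    global _PATCH_EDGE_UM
    if _PATCH_EDGE_UM is None:
        _PATCH_EDGE_UM = build_rbc_mesh(642, 8.0).mean_edge_length()
    return _PATCH_EDGE_UM


def _patch_geometry(edge_um: float):
    ang = np.deg2rad(np.arange(6) * 60.0)
    ref = np.zeros((7, 2))
    ref[1:, 0] = edge_um * np.cos(ang)
    ref[1:, 1] = edge_um * np.sin(ang)
    edges = np.array([(0, i) for i in range(1, 7)] + [(i, i % 6 + 1) for i in range(1, 7)])
    # tiling weights: perimeter edges are shared by two patches when the
    # hexagon tiles the lattice, so they count half; triangles are interior
    w_edge = np.array([1.0] * 6 + [0.5] * 6)
    tris = np.array([(0, i, i % 6 + 1) for i in range(1, 7)])
    area0 = 6.0 * np.sqrt(3.0) / 4.0 * edge_um**2  # um^2
    return ref, edges, w_edge, tris, area0


def _patch_energy(dof, eps, params, ref, edges, w_edge, tris):
    """In-plane patch energy [J]; boundary x-coordinates prescribed at
    (1+eps)*x0, all other in-plane coordinates free."""
    v = ref.copy()
    v[1:, 0] = ref[1:, 0] * (1.0 + eps)
    v[1:, 1] = dof[:6]
    v[0, 0] = dof[6]
    v[0, 1] = dof[7]
    d = v[edges[:, 0]] - v[edges[:, 1]]
    L = np.sqrt((d * d).sum(axis=1))
    d0 = ref[edges[:, 0]] - ref[edges[:, 1]]
    L0 = np.sqrt((d0 * d0).sum(axis=1))
    dL = (L - L0) / L0
    if np.any(np.abs(dL) >= params.tau_l):
        return np.inf
    u_link = (params.kappa_link * L0 * _UM / params.p) * _strain_energy(dL, params.tau_l)
    a, b, c = v[tris[:, 0]], v[tris[:, 1]], v[tris[:, 2]]
    cr = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    area = 0.5 * np.abs(cr)
    a, b, c = ref[tris[:, 0]], ref[tris[:, 1]], ref[tris[:, 2]]
    cr0 = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    dA = (area - 0.5 * np.abs(cr0)) / (0.5 * np.abs(cr0))
    u_area = params.kappa_area * _strain_energy(dA, params.tau_area)
    return float((w_edge * u_link).sum() + u_area.sum())


def patch_young_modulus(
    params: CellModelParams,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    edge_um: float | None = None,
) -> float:
    """Surface Young's modulus [uN/m] from quasi-static uniaxial stretch of a
    single regular hexagonal membrane patch.

    The patch is one centre vertex and six boundary vertices forming six
    equilateral triangles at the mean RBC mesh edge length.  A uniaxial strain
    is prescribed on the boundary x-coordinates; all remaining in-plane
    coordinates relax quasi-statically (lateral contraction is free).  Link
    and area energies enter with periodic-tiling weights so the measured
    tension-vs-strain slope is that of the extended membrane lattice.  The
    small-strain slope is Richardson-extrapolated from strains of 0.5% and 1%.
    """
    del constants
    if edge_um is None:
        edge_um = default_patch_edge_um()
    ref, edges, w_edge, tris, area0 = _patch_geometry(edge_um)
    scale = max(params.kappa_link, params.kappa_area) * _UM / params.p

    def u_min(eps: float) -> float:
        x0 = np.concatenate([ref[1:, 1] * (1.0 - eps / 3.0), [0.0, 0.0]])
        # gradient scale at strain eps is ~ scale*eps J/um; accept when the
        # residual is 4 orders below that
        res = minimize(
            _patch_energy,
            x0,
            args=(eps, params, ref, edges, w_edge, tris),
            method="BFGS",
            options={"gtol": 1e-6 * scale * abs(eps), "maxiter": 500},
        )
        gnorm = float(np.max(np.abs(res.jac)))
        if not np.isfinite(res.fun) or gnorm > 1e-4 * scale * abs(eps):
            raise RuntimeError(
                f"patch relaxation did not converge: |grad| = {gnorm:.3e} J/um"
            )
        return float(res.fun)

    moduli = []
    for eps in (0.005, 0.01):
        c2 = (u_min(eps) + u_min(-eps)) / (2.0 * eps * eps)  # J
        moduli.append(2.0 * c2 / (area0 * _UM * _UM))  # N/m
    e1, e2 = 0.005, 0.01
    extrap = (moduli[0] * e2**2 - moduli[1] * e1**2) / (e2**2 - e1**2)
    return float(extrap * 1.0e6)  # uN/m


def solve_area_coefficient(
    target_uN_per_m: float = 27.82,
    kappa_link_kbt: float = 15.0,
    edge_um: float | None = None,
) -> float:
    """Area coefficient [kBT] such that the hexagonal-patch test of the given
    link coefficient returns the target surface Young's modulus.  Used once to
    fix the healthy calibration shipped in the presets."""
    from scipy.optimize import brentq

    def f(ka_kbt):
        p = CellModelParams.from_kbt(kappa_link_kbt, kappa_area=ka_kbt * KBT)
        return patch_young_modulus(p, edge_um=edge_um) - target_uN_per_m

    return float(brentq(f, 1e-3, 5e4, xtol=1e-6))
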