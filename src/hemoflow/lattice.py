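"""Discrete-velocity fluid solver: D3Q19 lattice, BGK relaxation, Guo body
forcing, halfway bounce-back walls (optionally moving), per-node relaxation
time for interior viscosity contrast.

Unit system
-----------
The lattice works in lattice units (dx = dt = rho0 = 1, cs^2 = 1/3).  The
physical spacing ``dx`` [m] is chosen by the caller; the time step follows
from the relaxation time and the plasma viscosity through
``nu = (tau - 1/2)/3 * dx^2 / dt``.  Conversions:

* velocity: ``u_phys = u_lb * dx/dt``
* force per node: ``F_lb = F_N * dt^2 / (rho * dx^4)``
* force density: ``G_lb = G * dt^2 * dx / (rho * dx^2)`` (per-node body force)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "FluidLattice",
    "ShearBoxConfig",
    "StabilityError",
    "collide_stream",
    "apply_shear_walls",
    "set_viscosity_contrast",
    "C19",
    "W19",
    "OPP19",
]

FLUID, WALL = 0, 1


class StabilityError(RuntimeError):
    pass


def _build_stencil():
    c = [(0, 0, 0)]
    for d in range(3):
        for s in (1, -1):
            v = [0, 0, 0]
            v[d] = s
            c.append(tuple(v))
    for d1 in range(3):
        for d2 in range(d1 + 1, 3):
            for s1 in (1, -1):
                for s2 in (1, -1):
                    v = [0, 0, 0]
                    v[d1], v[d2] = s1, s2
                    c.append(tuple(v))
    c = np.array(c, dtype=np.int64)
    w = np.empty(19)
    for i, v in enumerate(c):
        n = np.abs(v).sum()
        w[i] = 1 / 3 if n == 0 else (1 / 18 if n == 1 else 1 / 36)
    opp = np.array([int(np.nonzero((c == -v).all(axis=1))[0][0]) for v in c])
    return c, w, opp


C19, W19, OPP19 = _build_stencil()
_C = C19.astype(np.float64)


@njit(cache=True)
def _lbm_step(f, f_new, nbr, flags, tau, wall_u, force, u_out, rho_out, C, W, OPP):
    n_nodes = f.shape[0]
    min_rho = 1.0e30
    for n in range(n_nodes):
        if flags[n] == 1:  # wall
            continue
        rho = 0.0
        mx = 0.0
        my = 0.0
        mz = 0.0
        for i in range(19):
            fi = f[n, i]
            rho += fi
            mx += fi * C[i, 0]
            my += fi * C[i, 1]
            mz += fi * C[i, 2]
        if rho < min_rho:
            min_rho = rho
        fx = force[n, 0]
        fy = force[n, 1]
        fz = force[n, 2]
        ux = (mx + 0.5 * fx) / rho
        uy = (my + 0.5 * fy) / rho
        uz = (mz + 0.5 * fz) / rho
        u_out[n, 0] = ux
        u_out[n, 1] = uy
        u_out[n, 2] = uz
        rho_out[n] = rho
        usq = ux * ux + uy * uy + uz * uz
        omega = 1.0 / tau[n]
        uf = ux * fx + uy * fy + uz * fz
        for i in range(19):
            cu = C[i, 0] * ux + C[i, 1] * uy + C[i, 2] * uz
            cf = C[i, 0] * fx + C[i, 1] * fy + C[i, 2] * fz
            feq = W[i] * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)
            si = W[i] * (3.0 * (cf - uf) + 9.0 * cu * cf)
            fpost = f[n, i] * (1.0 - omega) + omega * feq + (1.0 - 0.5 * omega) * si
            t = nbr[n, i]
            if t >= 0:
                f_new[t, i] = fpost
            else:
                w = -t - 1  # wall node hit: halfway bounce-back
                cw = (
                    C[i, 0] * wall_u[w, 0]
                    + C[i, 1] * wall_u[w, 1]
                    + C[i, 2] * wall_u[w, 2]
                )
                f_new[n, OPP[i]] = fpost - 6.0 * W[i] * cw
    return min_rho


@dataclass
class ShearBoxConfig:
    """Plane-Couette box: moving walls at -Y and +Y."""

    box_um: tuple  # (Lx, H, Lz) um
    shear_rate: float  # 1/s

    @property
    def wall_speed(self) -> float:
        """+-V_x [m/s] at the +-Y walls; gammadot = 2 V_x / H."""
        return 0.5 * self.shear_rate * self.box_um[1] * 1e-6


class FluidLattice:
    """Fluid state on a D3Q19 grid with explicit lattice<->SI conversion."""

    def __init__(
        self,
        shape: tuple,
        dx: float,
        tau_lb: float = 1.1,
        constants: PhysicalConstants = DEFAULT_CONSTANTS,
        periodic=(True, True, True),
    ):
        if not 0.5 < tau_lb <= 2.0:
            raise ValueError("plasma relaxation time must lie in (0.5, 2]")
        self.shape = tuple(int(s) for s in shape)
        self.nx, self.ny, self.nz = self.shape
        self.n_nodes = self.nx * self.ny * self.nz
        self.dx = float(dx)
        self.tau_lb = float(tau_lb)
        self.constants = constants
        self.nu = constants.plasma_kinematic_viscosity
        self.rho_phys = constants.plasma_density
        # dt follows from nu_lb = (tau - 1/2)/3 = nu * dt / dx^2
        self.dt = (tau_lb - 0.5) / 3.0 * dx * dx / self.nu
        self.periodic = tuple(periodic)

        self.f = np.tile(W19, (self.n_nodes, 1))
        self.f_tmp = np.empty_like(self.f)
        self.flags = np.zeros(self.n_nodes, dtype=np.uint8)
        self.tau = np.full(self.n_nodes, tau_lb)
        self.wall_u = np.zeros((self.n_nodes, 3))
        self.force = np.zeros((self.n_nodes, 3))  # lattice units, per node
        self.body_force = np.zeros(3)  # lattice units, applied to fluid nodes
        self.u = np.zeros((self.n_nodes, 3))
        self.rho = np.ones(self.n_nodes)
        self._nbr = None
        self.step_count = 0

    # -- index helpers ---------------------------------------------------------

    def node_index(self, ix, iy, iz):
        return (ix * self.ny + iy) * self.nz + iz

    def grid_coordinates(self):
        ix, iy, iz = np.meshgrid(
            np.arange(self.nx), np.arange(self.ny), np.arange(self.nz), indexing="ij"
        )
        return ix.ravel(), iy.ravel(), iz.ravel()

    def _rebuild_neighbors(self):
        ix, iy, iz = self.grid_coordinates()
        nbr = np.empty((self.n_nodes, 19), dtype=np.int64)
        for i, (cx, cy, cz) in enumerate(C19):
            tx, ty, tz = ix + cx, iy + cy, iz + cz
            for t, n, per in ((tx, self.nx, self.periodic[0]),
                              (ty, self.ny, self.periodic[1]),
                              (tz, self.nz, self.periodic[2])):
                if per:
                    t %= n
                else:
                    np.clip(t, 0, n - 1, out=t)
            target = (tx * self.ny + ty) * self.nz + tz
            hit_wall = self.flags[target] == WALL
            nbr[:, i] = np.where(hit_wall, -target - 1, target)
        self._nbr = nbr

    # -- conversions -----------------------------------------------------------

    @property
    def velocity_scale(self) -> float:
        """dx/dt [m/s] per lattice velocity unit."""
        return self.dx / self.dt

    def force_to_lattice(self, f_newton):
        """Per-vertex/node force [N] -> lattice units."""
        return np.asarray(f_newton) * self.dt**2 / (self.rho_phys * self.dx**4)

    def body_force_density(self, g_si):
        """Set a uniform body force from a force density [N/m^3]."""
        g = np.asarray(g_si, dtype=float)
        self.body_force = g * self.dx**3 * self.dt**2 / (self.rho_phys * self.dx**4)

    # -- state -----------------------------------------------------------------

    def initialize_velocity(self, u_phys):
        """Set equilibrium populations at density 1 and the given uniform or
        per-node physical velocity [m/s]."""
        u = np.asarray(u_phys, dtype=float) / self.velocity_scale
        if u.ndim == 1:
            u = np.broadcast_to(u, (self.n_nodes, 3))
        cu = u @ _C.T
        usq = (u * u).sum(axis=1)
        self.f = W19[None, :] * (1 + 3 * cu + 4.5 * cu**2 - 1.5 * usq[:, None])
        self.f[self.flags == WALL] = W19

    def velocity_field(self):
        """(nx, ny, nz, 3) velocity [m/s] from the last step's moments."""
        return (self.u * self.velocity_scale).reshape(self.shape + (3,))

    def density_field(self):
        return self.rho.reshape(self.shape)

    def fluid_mask(self):
        return (self.flags != WALL).reshape(self.shape)

    def total_momentum(self):
        """Lattice-unit momentum of fluid nodes (first moment of f)."""
        mom = self.f @ _C
        return mom[self.flags != WALL].sum(axis=0)

    def step(self, n_steps: int = 1):
        if self._nbr is None:
            self._rebuild_neighbors()
        fluid = self.flags != WALL
        for _ in range(n_steps):
            force = self.force.copy()
            force[fluid] += self.body_force
            min_rho = _lbm_step(
                self.f,
                self.f_tmp,
                self._nbr,
                self.flags,
                self.tau,
                self.wall_u,
                force,
                self.u,
                self.rho,
                _C,
                W19,
                OPP19,
            )
            self.f, self.f_tmp = self.f_tmp, self.f
            self.step_count += 1
            if not (min_rho > 0) or not np.isfinite(min_rho):
                raise StabilityError(
                    f"negative or non-finite density at step {self.step_count}"
                )
            umax2 = float(np.max(self.u[fluid, 0] ** 2 + self.u[fluid, 1] ** 2
                                 + self.u[fluid, 2] ** 2))
            if not (umax2 < 0.25):  # Mach bound; also catches NaN
                raise StabilityError(
                    f"lattice velocity {np.sqrt(umax2):.3f} exceeded the "
                    f"stability bound 0.5 at step {self.step_count}"
                )
        return self

    # -- constructors ----------------------------------------------------------

    @classmethod
    def periodic_box(cls, box_um, dx_um=0.5, tau_lb=1.1, constants=DEFAULT_CONSTANTS):
        shape = tuple(max(int(round(b / dx_um)), 1) for b in box_um)
        return cls(shape, dx_um * 1e-6, tau_lb, constants)

    @classmethod
    def couette(
        cls, config: ShearBoxConfig, dx_um=0.5, tau_lb=1.1, constants=DEFAULT_CONSTANTS
    ):
        lx, h, lz = config.box_um
        shape = (
            max(int(round(lx / dx_um)), 1),
            int(round(h / dx_um)) + 2,
            max(int(round(lz / dx_um)), 1),
        )
        lat = cls(shape, dx_um * 1e-6, tau_lb, constants, periodic=(True, False, True))
        apply_shear_walls(lat, config)
        return lat

    @classmethod
    def tube(
        cls,
        radius_um,
        length_um,
        dx_um=0.5,
        tau_lb=1.1,
        constants=DEFAULT_CONSTANTS,
    ):
        """Periodic tube along x; staircase wall where the node-centre radius
        exceeds R + 0.05 dx.  Halfway bounce-back places the hydrodynamic
        boundary about midway between the outermost fluid ring and the wall
        ring; the small offset centres that boundary on R (validated against
        the Poiseuille closed form)."""
        n_span = 2 * int(np.ceil(radius_um / dx_um)) + 3
        shape = (max(int(round(length_um / dx_um)), 1), n_span, n_span)
        lat = cls(shape, dx_um * 1e-6, tau_lb, constants, periodic=(True, False, False))
        center = (n_span - 1) / 2.0
        _, iy, iz = lat.grid_coordinates()
        r = np.sqrt((iy - center) ** 2 + (iz - center) ** 2) * dx_um
        lat.flags[r > radius_um + 0.05 * dx_um] = WALL
        lat.axis_center_um = (center * dx_um, center * dx_um)
        lat.tube_radius_um = float(radius_um)
        lat._rebuild_neighbors()
        return lat


def export_velocity_csv(lattice: FluidLattice, path: str) -> None:
    """Velocity field [m/s] as tidy CSV (ix, iy, iz, ux, uy, uz)."""
    import pandas as pd

    ix, iy, iz = lattice.grid_coordinates()
    u = lattice.u * lattice.velocity_scale
    pd.DataFrame(
        {"ix": ix, "iy": iy, "iz": iz, "ux": u[:, 0], "uy": u[:, 1], "uz": u[:, 2]}
    ).to_csv(path, index=False)


def export_velocity_vtk(lattice: FluidLattice, path: str) -> None:
    """Velocity field as a legacy-VTK ASCII structured-points dataset."""
    nx, ny, nz = lattice.shape
    u = (lattice.u * lattice.velocity_scale).reshape(nx, ny, nz, 3)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nvelocity\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {lattice.dx} {lattice.dx} {lattice.dx}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write("VECTORS velocity double\n")
        # legacy VTK structured points iterate x fastest
        for k in range(nz):
            for j in range(ny):
                for i in range(nx):
                    v = u[i, j, k]
                    fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")


def collide_stream(lattice: FluidLattice, n_steps: int = 1) -> FluidLattice:
    """Advance the fluid by BGK collision + streaming steps."""
    return lattice.step(n_steps)


def apply_shear_walls(lattice: FluidLattice, config: ShearBoxConfig) -> FluidLattice:
    """Moving-wall (bounce-back with momentum correction) boundaries at the
    -Y and +Y faces; the cell-free steady state is linear Couette flow."""
    v_lb = config.wall_speed / lattice.velocity_scale
    if abs(v_lb) > 0.1:
        raise StabilityError(
            f"wall speed {v_lb:.3f} lattice units exceeds the 0.1 stability bound"
        )
    if lattice.periodic[1]:
        raise ValueError("shear walls need a non-periodic Y direction")
    _, iy, _ = lattice.grid_coordinates()
    lo, hi = iy == 0, iy == lattice.ny - 1
    lattice.flags[lo | hi] = WALL
    lattice.wall_u[lo, 0] = -v_lb
    lattice.wall_u[hi, 0] = +v_lb
    lattice._rebuild_neighbors()
    return lattice


def set_viscosity_contrast(lattice: FluidLattice, meshes, lambdas) -> FluidLattice:
    """Assign interior nodes of each closed mesh the relaxation time of
    ``Lambda x`` plasma viscosity; exterior nodes keep the plasma value.

    Overlapping interiors resolve to the union (each node set once).  Note the
    plasma stability bound tau <= 2 applies to exterior nodes; interior nodes
    under strong contrast may exceed it.
    """
    from .voxel import inside_mask

    lattice.tau[:] = lattice.tau_lb
    dx_um = lattice.dx * 1e6
    xs = np.arange(lattice.nx) * dx_um
    ys = np.arange(lattice.ny) * dx_um
    zs = np.arange(lattice.nz) * dx_um
    if np.isscalar(lambdas):
        lambdas = [lambdas] * len(meshes)
    for mesh, lam in zip(meshes, lambdas):
        if lam == 1.0:
            continue
        mask = inside_mask(mesh.vertices, mesh.triangles, xs, ys, zs).ravel()
        mask &= lattice.flags != WALL
        lattice.tau[mask] = 0.5 + lam * (lattice.tau_lb - 0.5)
    return lattice
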