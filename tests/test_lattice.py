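"""Fluid solver validation: fixed points, momentum bookkeeping, Couette and
Poiseuille closed forms, Galilean invariance, viscosity contrast."""

import numpy as np
import pytest

from hemoflow.constants import DEFAULT_CONSTANTS
from hemoflow.lattice import (
    WALL,
    FluidLattice,
    ShearBoxConfig,
    StabilityError,
    apply_shear_walls,
    collide_stream,
    set_viscosity_contrast,
)
from hemoflow.mesh import build_platelet_mesh


def test_rest_fluid_is_fixed_point():
    lat = FluidLattice.periodic_box((4, 4, 4), dx_um=1.0)
    f0 = lat.f.copy()
    collide_stream(lat, 5)
    assert np.allclose(lat.f, f0, atol=1e-15)
    assert np.allclose(lat.velocity_field(), 0.0)


def test_body_force_momentum_bookkeeping():
    lat = FluidLattice.periodic_box((4, 4, 4), dx_um=1.0)
    g = np.array([2.0e-4, 0.0, 0.0])  # lattice units per node
    lat.body_force = g
    p_prev = lat.total_momentum()
    for _ in range(10):
        lat.step()
        p = lat.total_momentum()
        gain = p - p_prev
        expected = g * (lat.flags != WALL).sum()
        assert np.allclose(gain, expected, rtol=1e-10, atol=1e-14)
        p_prev = p


def test_momentum_conserved_without_forcing():
    lat = FluidLattice.periodic_box((6, 6, 6), dx_um=1.0)
    rng = np.random.default_rng(0)
    u0 = rng.normal(0, 1e-3, (lat.n_nodes, 3)) * lat.velocity_scale
    lat.initialize_velocity(u0)
    p0 = lat.total_momentum()
    lat.step(50)
    assert np.allclose(lat.total_momentum(), p0, atol=1e-12)


def test_couette_closed_form():
    cfg = ShearBoxConfig(box_um=(2.0, 20.0, 2.0), shear_rate=1000.0)
    lat = FluidLattice.couette(cfg, dx_um=0.5)
    lat.step(20000)
    ux = lat.velocity_field()[0, 1:-1, 0, 0]
    h = 20e-6
    y = (np.arange(1, lat.ny - 1) - 0.5) * 0.5e-6  # distance from lower wall
    expected = 1000.0 * (y - h / 2)
    assert np.abs(ux - expected).max() / np.abs(expected).max() < 0.01
    mid = len(ux) // 2
    grad = np.gradient(ux, 0.5e-6)
    assert abs(ux[mid - 1] + ux[mid]) / 2 < 1e-6 * np.abs(ux).max() + 1e-12
    assert grad[mid] == pytest.approx(1000.0, rel=0.01)


def test_zero_shear_stays_at_rest():
    cfg = ShearBoxConfig(box_um=(2.0, 10.0, 2.0), shear_rate=0.0)
    lat = FluidLattice.couette(cfg, dx_um=0.5)
    lat.step(200)
    assert np.abs(lat.velocity_field()).max() < 1e-15


def test_shear_stress_conversion():
    # tau = gammadot * eta * rho at 1000/s for plasma constants
    c = DEFAULT_CONSTANTS
    assert 1000.0 * c.plasma_kinematic_viscosity * c.plasma_density == pytest.approx(
        1.1275
    )


def test_poiseuille_tube_within_two_percent():
    lat = FluidLattice.tube(10.0, 2.0, dx_um=0.5)
    mu = DEFAULT_CONSTANTS.plasma_dynamic_viscosity
    R = 10e-6
    G = 2 * mu * 2000.0 / R  # wall shear 2000/s
    lat.body_force_density([G, 0, 0])
    lat.step(8000)
    u = lat.velocity_field()[:, :, :, 0].mean(axis=0)
    center = (lat.ny - 1) / 2.0
    iy, iz = np.meshgrid(np.arange(lat.ny), np.arange(lat.nz), indexing="ij")
    r = np.sqrt((iy - center) ** 2 + (iz - center) ** 2) * 0.5e-6
    analytic = G * (R**2 - r**2) / (4 * mu)
    umax = G * R**2 / (4 * mu)
    mask = r < 0.95 * R
    assert np.abs(u[mask] - analytic[mask]).max() / umax < 0.02


def test_flat_channel_poiseuille_convergence_order():
    """Plane-Poiseuille error decays with order >= 1.8 when dx halves (flat
    walls isolate the discretisation order from staircase geometry error)."""
    errors = {}
    for dx in (1.0, 0.5):
        cfg = ShearBoxConfig(box_um=(2 * dx, 20.0, 2 * dx), shear_rate=0.0)
        lat = FluidLattice.couette(cfg, dx_um=dx)
        mu = DEFAULT_CONSTANTS.plasma_dynamic_viscosity
        h = 20e-6
        G = 8 * mu * 1e-3 / h**2  # u_max = 1 mm/s
        lat.body_force_density([G, 0, 0])
        lat.step(int(25000 / dx**2))
        ux = lat.velocity_field()[0, 1:-1, 0, 0]
        y = (np.arange(1, lat.ny - 1) - 0.5) * dx * 1e-6
        analytic = G / (2 * mu) * y * (h - y)
        errors[dx] = np.abs(ux - analytic).max() / analytic.max()
    order = np.log2(errors[1.0] / errors[0.5])
    assert order >= 1.8


def test_galilean_shift():
    rng = np.random.default_rng(1)
    base = rng.normal(0, 2e-4, (6 * 6 * 6, 3))
    shift = np.array([1e-3, 0, 0])
    results = []
    for extra in (np.zeros(3), shift):
        lat = FluidLattice.periodic_box((6, 6, 6), dx_um=1.0)
        lat.initialize_velocity((base + extra) * lat.velocity_scale)
        lat.step(30)
        results.append(lat.u.copy())
    diff = results[1] - results[0]
    assert np.abs(diff - shift).max() < 1e-8


def test_wall_speed_stability_guard():
    cfg = ShearBoxConfig(box_um=(2.0, 20.0, 2.0), shear_rate=3e6)
    with pytest.raises(StabilityError):
        FluidLattice.couette(cfg, dx_um=0.5)


def test_relaxation_time_bounds():
    with pytest.raises(ValueError):
        FluidLattice((4, 4, 4), dx=0.5e-6, tau_lb=0.4)
    with pytest.raises(ValueError):
        FluidLattice((4, 4, 4), dx=0.5e-6, tau_lb=2.5)


def test_blowup_raises_stability_error():
    cfg = ShearBoxConfig(box_um=(4.0, 8.0, 4.0), shear_rate=0.0)
    lat = FluidLattice.couette(cfg, dx_um=1.0)
    lat.body_force = np.array([0.5, 0, 0])  # absurd lattice forcing
    with pytest.raises(StabilityError):
        lat.step(2000)


def test_derived_timestep_follows_viscosity_relation():
    lat = FluidLattice.periodic_box((4, 4, 4), dx_um=0.5, tau_lb=1.1)
    nu_lb = (1.1 - 0.5) / 3
    assert lat.dt == pytest.approx(nu_lb * (0.5e-6) ** 2 / 1.1e-6)


def test_viscosity_contrast_identity_and_voxel_count():
    lat = FluidLattice.periodic_box((20, 20, 20), dx_um=1.0)
    sphere = build_platelet_mesh(642, 8.0, 8.0).translated([10.0, 10.0, 10.0])
    set_viscosity_contrast(lat, [sphere], 1.0)
    assert np.all(lat.tau == lat.tau_lb)
    set_viscosity_contrast(lat, [sphere], 6.0)
    tagged = (lat.tau != lat.tau_lb).sum()
    expected = sphere.volume()  # voxels of 1 um^3
    assert tagged == pytest.approx(expected, rel=0.05)
    assert np.allclose(np.unique(lat.tau), [lat.tau_lb, 0.5 + 6.0 * 0.6])


def test_viscosity_contrast_union_of_overlapping_cells():
    lat = FluidLattice.periodic_box((20, 20, 20), dx_um=1.0)
    s1 = build_platelet_mesh(162, 6.0, 6.0).translated([9.0, 10.0, 10.0])
    s2 = build_platelet_mesh(162, 6.0, 6.0).translated([12.0, 10.0, 10.0])
    set_viscosity_contrast(lat, [s1, s2], [6.0, 6.0])
    tagged = (lat.tau != lat.tau_lb).sum()
    assert tagged < s1.volume() + s2.volume()  # union, not double counting
    assert len(np.unique(lat.tau)) == 2
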