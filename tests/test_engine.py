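"""Coupling engine: packed-kernel correctness, action-reaction across the
immersed boundary, advection volume conservation, checkpointing."""

import numpy as np
import pytest

from hemoflow.engine import Simulation
from hemoflow.ibm import ibm_spread
from hemoflow.lattice import FluidLattice, ShearBoxConfig
from hemoflow.membrane import get_preset, membrane_forces
from hemoflow.mesh import build_platelet_mesh, build_rbc_mesh

HEALTHY = get_preset("healthy")


def shear_sim(h=16.0, rate=0.0, dx=1.0):
    cfg = ShearBoxConfig(box_um=(20.0, h, 14.0), shear_rate=rate)
    lat = FluidLattice.couette(cfg, dx_um=dx, tau_lb=1.4)
    return Simulation(lat)


def test_packed_kernel_matches_reference_membrane_forces():
    """The numba packed-array membrane kernel agrees with the vectorised
    reference implementation to round-off on a distorted multi-cell state."""
    rng = np.random.default_rng(7)
    sim2 = shear_sim()
    refs = []
    for shift in ([6.0, 8.0, 7.0], [13.0, 8.0, 7.0]):
        m = build_rbc_mesh(162, 8.0).translated(shift)
        refs.append(m)
        sim2.add_cell(m, HEALTHY)
    sim2._pack()
    sim2.verts += rng.normal(0, 0.04, sim2.verts.shape)
    f_kernel = sim2.membrane_forces().copy()
    f_ref = []
    for m, sl in zip(refs, sim2._vert_slices):
        mm = m.copy()
        mm.vertices = sim2.verts[sl].copy()
        f_ref.append(membrane_forces(mm, HEALTHY))
    f_ref = np.concatenate(f_ref)
    assert np.allclose(f_kernel, f_ref, atol=1e-12 * np.abs(f_ref).max())


def test_contact_forces_are_pairwise_balanced():
    sim = shear_sim()
    a = build_rbc_mesh(162, 8.0).translated([8.0, 8.0, 7.0])
    b = build_rbc_mesh(162, 8.0).translated([11.0, 8.5, 7.0])  # overlapping
    sim.add_cell(a, HEALTHY)
    sim.add_cell(b, HEALTHY)
    f = sim.compute_forces()
    # membrane terms are zero at reference shape; only contact remains
    assert np.abs(f).max() > 0
    assert np.abs(f.sum(axis=0)).max() < 1e-12 * np.abs(f).sum()


def test_action_reaction_across_ibm_coupling():
    """The total force spread onto the lattice equals the total membrane
    force (per component) to relative 1e-12."""
    sim = shear_sim(rate=500.0)
    m = build_rbc_mesh(162, 8.0).translated([10.0, 8.0, 7.0])
    sim.add_cell(m, HEALTHY)
    sim.step(50)
    forces = sim.compute_forces()
    lat = sim.lattice
    lat.force[:] = 0.0
    scale = lat.dt**2 / (lat.rho_phys * lat.dx**4)
    ibm_spread(forces * scale, sim.verts / (lat.dx * 1e6), lat)
    total_spread = lat.force.sum(axis=0)
    total_membrane = forces.sum(axis=0) * scale
    norm = np.abs(forces).sum() * scale
    assert np.abs(total_spread - total_membrane).max() < 1e-12 * norm


def test_rigid_advection_conserves_volume():
    """A force-free rigid mesh advected with the interpolated velocity keeps
    its volume within 0.5% over 1e4 steps of uniform flow."""
    lat = FluidLattice.periodic_box((16, 12, 12), dx_um=1.0, tau_lb=1.4)
    lat.initialize_velocity(np.array([3e-3, 0.0, 0.0]))
    sim = Simulation(lat)
    sphere = build_platelet_mesh(162, 5.0, 5.0).translated([8.0, 6.0, 6.0])
    params = get_preset("platelet")
    sim.add_cell(sphere, params)
    sim._pack()
    v0 = sim.cell_volumes()[0]
    # advect without membrane forcing: zero out force path by monkeypatching
    sim.compute_forces = lambda: sim.forces.__setitem__(slice(None), 0.0) or sim.forces
    sim.step(10000)
    assert abs(sim.cell_volumes()[0] / v0 - 1.0) < 0.005


def test_volume_drift_under_forced_dynamics_below_one_percent():
    sim = shear_sim(rate=1000.0)
    m = build_rbc_mesh(162, 8.0).translated([10.0, 8.0, 7.0])
    sim.add_cell(m, HEALTHY)
    n = int(3.0 / (1000.0 * sim.lattice.dt))  # strain 3
    sim.step(n)
    assert np.abs(sim.volume_drift()).max() < 0.01
    assert np.abs(sim.area_drift()).max() < 0.02


def test_checkpoint_roundtrip(tmp_path):
    sim = shear_sim(rate=500.0)
    m = build_rbc_mesh(162, 8.0).translated([10.0, 8.0, 7.0])
    sim.add_cell(m, HEALTHY)
    sim.step(200)
    path = str(tmp_path / "chk.h5")
    sim.checkpoint(path)
    verts = sim.verts.copy()
    f = sim.lattice.f.copy()
    sim.step(100)
    sim.restore(path)
    assert np.array_equal(sim.verts, verts)
    assert np.array_equal(sim.lattice.f, f)
    # deterministic continuation: restored run matches uninterrupted one
    sim.step(100)
    sim2 = shear_sim(rate=500.0)
    sim2.add_cell(build_rbc_mesh(162, 8.0).translated([10.0, 8.0, 7.0]), HEALTHY)
    sim2.step(300)
    assert np.allclose(sim.verts, sim2.verts, atol=1e-10)
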