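"""Rheology estimators against generator ground truth and voxel oracles."""

import numpy as np
import pytest

from hemoflow.analysis import (
    ConcentrationProfile,
    RadialBinning,
    TrajectoryEnsemble,
    cfl_width,
    margination_index,
    radial_diffusivity,
    volume_fraction_profile,
)
from hemoflow.mesh import build_platelet_mesh, build_rbc_mesh
from hemoflow.synthetic import gen_brownian_tracks, gen_radial_profile


def test_binning_tiles_radius():
    b = RadialBinning.for_radius(50.0)
    assert b.n_bins == 7
    assert b.edges[0] == 0 and b.edges[-1] == 50.0
    assert np.allclose(b.widths, 50 / 7)
    # centres close to the published full-scale bin centres
    assert np.allclose(
        b.centers, [3.6, 10.9, 18.2, 25.5, 32.8, 40.0, 47.4], atol=1.1
    )
    assert b.annulus_volumes().sum() == pytest.approx(np.pi * 50.0**2)


def test_diffusivity_recovers_brownian_ground_truth():
    ens = gen_brownian_tracks(n_tracks=200, diffusivity=1.0, seed=11)
    prof = radial_diffusivity(ens, RadialBinning.for_radius(50.0), 5e-4, 0.4)
    d = prof.d_rr["healthy_rbc"]
    # pooled over bins, weighted by counts
    n = prof.counts["healthy_rbc"]
    pooled = np.nansum(d * n) / n.sum()
    assert pooled == pytest.approx(1.0, rel=0.05)


def test_diffusivity_zero_for_deterministic_drift():
    times = np.arange(0, 0.4, 2.5e-4)
    pos = np.zeros((10, len(times), 3))
    pos[:, :, 1] = 10.0 + np.linspace(0, 1.0, len(times))  # slow drift
    ens = TrajectoryEnsemble(times, pos, np.array(["healthy_rbc"] * 10))
    prof = radial_diffusivity(ens, RadialBinning.for_radius(50.0), 5e-4, 0.3)
    d = np.nanmax(list(prof.d_rr.values())[0])
    # drift bias bound: (v*dt)^2/(2 dt) with v ~ 2.5 um/s
    assert d < (2.5 * 5e-4) ** 2 / (2 * 5e-4) * 1.01


def test_diffusivity_window_insensitive_for_brownian_input():
    ens = gen_brownian_tracks(n_tracks=200, diffusivity=1.0, seed=7)
    bins = RadialBinning.for_radius(50.0)
    d1 = radial_diffusivity(ens, bins, 5e-4, 0.4)
    d2 = radial_diffusivity(ens, bins, 1e-3, 0.4)
    n1, n2 = d1.counts["healthy_rbc"], d2.counts["healthy_rbc"]
    p1 = np.nansum(d1.d_rr["healthy_rbc"] * n1) / n1.sum()
    p2 = np.nansum(d2.d_rr["healthy_rbc"] * n2) / n2.sum()
    assert p2 == pytest.approx(p1, rel=0.05)


def test_diffusivity_requires_resolved_window():
    ens = gen_brownian_tracks(n_tracks=5, dt_s=4e-4, seed=0)
    with pytest.raises(ValueError):
        radial_diffusivity(ens, RadialBinning.for_radius(50.0), window_s=5e-4)


def test_diffusivity_flags_empty_bins():
    ens = gen_brownian_tracks(n_tracks=20, diffusivity=0.5, radius_um=10.0, seed=3)
    # bins extend far beyond the walk's wall at 10 um
    prof = radial_diffusivity(ens, RadialBinning.for_radius(50.0), 5e-4, 0.4)
    d = prof.d_rr["healthy_rbc"]
    assert np.isnan(d[-1])
    assert prof.counts["healthy_rbc"][-1] == 0


def test_cfl_width_recovers_constructed_truth():
    pos, labels, truth = gen_radial_profile(
        n_rbc=4000, n_platelets=0, radius_um=50.0, cfl_um=5.0, seed=5
    )
    got = cfl_width((pos, labels), wall_radius_um=50.0)
    assert got["healthy_rbc"] == pytest.approx(5.0, abs=50 / 7 / 2)


def test_cfl_width_empty_and_touching_cases():
    # no cells: CFL equals the wall radius
    got = cfl_width((np.empty((0, 3)), np.empty(0, dtype=object)), 25.0)
    assert got == {}
    # a ring of spherical cells touching the wall in every sector
    ball = build_platelet_mesh(162, 8.0, 8.0, species_label="healthy_rbc")
    R = 25.0
    meshes = []
    for ang in np.linspace(0, 2 * np.pi, 12, endpoint=False):
        c = (R - 4.0) * np.array([0.0, np.cos(ang), np.sin(ang)])
        meshes.append(ball.translated(c))
    got = cfl_width([meshes], R)
    assert got["healthy_rbc"] == pytest.approx(0.0, abs=0.15)


def test_margination_index_identity_and_scaling():
    # 10 bins put a bin edge exactly at the wall-band boundary (45 um)
    bins = RadialBinning.for_radius(50.0, n_bins=10)
    pos, labels, _ = gen_radial_profile(
        n_rbc=0, n_platelets=30000, platelet_excess=1.0, cfl_um=0.0, seed=2
    )
    ref = ConcentrationProfile.from_points(pos, labels, bins)
    assert margination_index(ref, 5.0, ref) == pytest.approx(1.0)
    pos3, labels3, _ = gen_radial_profile(
        n_rbc=0, n_platelets=30000, platelet_excess=3.0, cfl_um=0.0, seed=4
    )
    prof3 = ConcentrationProfile.from_points(pos3, labels3, bins)
    idx = margination_index(prof3, 5.0, ref)
    assert idx == pytest.approx(3.0, rel=0.05)


def test_margination_index_zero_when_wall_band_empty():
    bins = RadialBinning.for_radius(50.0)
    pos, labels, _ = gen_radial_profile(
        n_rbc=0, n_platelets=5000, platelet_excess=1.0, seed=1
    )
    ref = ConcentrationProfile.from_points(pos, labels, bins)
    r = np.sqrt(pos[:, 1] ** 2 + pos[:, 2] ** 2)
    inner = pos[r < 35.0]
    prof = ConcentrationProfile.from_points(inner, labels[: len(inner)], bins)
    assert margination_index(prof, 5.0, ref) == pytest.approx(0.0, abs=1e-12)


def test_volume_fraction_voxel_oracle_sphere():
    sphere = build_platelet_mesh(642, diameter=4.0, thickness=4.0)
    sphere = sphere.translated([5.0, 0.0, 0.0])
    bins = RadialBinning.for_radius(21.0, n_bins=3)  # sphere inside bin 0 (r<7)
    prof = volume_fraction_profile(
        [sphere], bins, dx_um=0.35, x_range=(0.0, 10.0)
    )
    frac = prof.fractions["platelet"]
    bin_volume = np.pi * 7.0**2 * 10.0
    expected = sphere.volume() / bin_volume
    assert frac[0] == pytest.approx(expected, rel=0.05)
    assert frac[1] == pytest.approx(0.0, abs=1e-6)


def test_cplt_normalisation():
    bins = RadialBinning.for_radius(50.0)
    pos, labels, _ = gen_radial_profile(
        n_rbc=0, n_platelets=40000, platelet_excess=1.0, cfl_um=0.0, seed=9
    )
    prof = ConcentrationProfile.from_points(pos, labels, bins)
    c = prof.c_plt()
    vols = bins.annulus_volumes()
    assert (c * vols).sum() / vols.sum() == pytest.approx(1.0, abs=1e-6)
    assert np.allclose(c, 1.0, atol=0.15)  # uniform placement


def test_generator_determinism():
    a = gen_brownian_tracks(n_tracks=10, seed=123)
    b = gen_brownian_tracks(n_tracks=10, seed=123)
    assert np.array_equal(a.positions, b.positions)
    c = gen_brownian_tracks(n_tracks=10, diffusivity=0.0, seed=1)
    assert np.all(c.positions[:, :, 1] == c.positions[:, :1, 1])
    with pytest.raises(ValueError):
        gen_brownian_tracks(diffusivity=-1.0)
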