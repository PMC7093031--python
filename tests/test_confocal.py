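"""Beer-Lambert depth correction and the plate-channel wall shear formula."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemoflow.confocal import (
    AbsorbanceSpectrum,
    PlateChannelSpec,
    ZStackProfile,
    correct_zstack,
    plate_wall_shear,
    transmittance_per_depth,
    wall_concentration,
)
from hemoflow.synthetic import flat_spectrum, gen_zstack_signal


def test_transmittance_definition():
    spec = flat_spectrum(1.0, path_length_mm=3.108)
    assert transmittance_per_depth(spec, 660, 0.0) == pytest.approx(1.0)
    assert transmittance_per_depth(spec, 660, 3108.0) == pytest.approx(0.1)
    assert transmittance_per_depth(spec, 660, 3108.0 / 2) == pytest.approx(10 ** -0.5)
    zero = flat_spectrum(0.0)
    depths = np.linspace(0, 5000, 7)
    assert np.allclose(transmittance_per_depth(zero, 660, depths), 1.0)


def test_transmittance_monotone_decreasing():
    spec = flat_spectrum(0.7)
    d = np.linspace(0, 2000, 50)
    t = transmittance_per_depth(spec, 660, d)
    assert t[0] == pytest.approx(1.0)
    assert np.all(np.diff(t) < 0)


def test_wavelength_interpolation_and_range():
    spec = AbsorbanceSpectrum(np.array([600.0, 700.0]), np.array([1.0, 3.0]))
    assert spec.at(650.0) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        spec.at(550.0)
    with pytest.raises(ValueError):
        AbsorbanceSpectrum(np.array([700.0, 600.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError):
        AbsorbanceSpectrum(np.array([600.0, 700.0]), np.array([-1.0, 1.0]))


def test_zero_absorbance_correction_is_identity():
    profile, truth, spectrum, _ = gen_zstack_signal(
        lambda h: 1.0 + 0.01 * h, absorbance=0.0, noise_sd=0.0
    )
    corrected = correct_zstack(profile, spectrum)
    assert np.allclose(corrected.intensity, profile.intensity)


def test_correction_inverts_synthetic_attenuation():
    profile, truth, spectrum, _ = gen_zstack_signal(
        lambda h: 2.0 + np.sin(h / 17.0), absorbance=1.3, noise_sd=0.0
    )
    # attenuation dims the signal away from the objective side
    ratio = profile.intensity / truth
    assert ratio[-1] > ratio[0]
    corrected = correct_zstack(profile, spectrum)
    assert np.allclose(corrected.intensity, truth, rtol=1e-10)


def test_flipping_objective_side_mirrors_correction():
    heights = np.arange(0.0, 101.0, 2.0)
    flat = np.ones_like(heights)
    spec = flat_spectrum(1.0)
    top = ZStackProfile(heights, flat, objective_at_top=True)
    bottom = ZStackProfile(heights, flat, objective_at_top=False)
    c_top = correct_zstack(top, spec)
    c_bottom = correct_zstack(bottom, spec)
    assert np.allclose(c_top.intensity, c_bottom.intensity[::-1])


@settings(max_examples=40, deadline=None)
@given(
    absorbance=st.floats(0.0, 4.0),
    amp=st.floats(0.1, 10.0),
    tilt=st.floats(-0.005, 0.02),
)
def test_correction_roundtrip_property(absorbance, amp, tilt):
    """correct_zstack inverts the synthetic Beer-Lambert attenuation for any
    positive profile and any non-negative absorbance."""
    profile, truth, spectrum, _ = gen_zstack_signal(
        lambda h: amp * (1.0 + tilt * h), absorbance=absorbance, noise_sd=0.0
    )
    corrected = correct_zstack(profile, spectrum)
    assert np.allclose(corrected.intensity, truth, rtol=1e-9)


def test_low_transmittance_flagged_not_divided():
    profile, truth, spectrum, _ = gen_zstack_signal(
        lambda h: np.ones_like(h), absorbance=300.0, noise_sd=0.0
    )
    with pytest.warns(UserWarning):
        corrected = correct_zstack(profile, spectrum)
    assert corrected.unreliable.any()
    flagged = corrected.unreliable
    assert np.allclose(corrected.intensity[flagged], profile.intensity[flagged])


def test_wall_concentration_region_mean():
    heights = np.arange(0.0, 101.0, 2.0)
    vals = np.linspace(0, 1, len(heights))
    prof = ZStackProfile(heights, vals, objective_at_top=True)
    top3 = prof.intensity[-3:].mean()
    assert wall_concentration(prof, region_width_um=4.0) == pytest.approx(top3)
    flat = ZStackProfile(heights, np.full_like(heights, 2.5))
    assert wall_concentration(flat, 5.0) == pytest.approx(2.5)
    assert wall_concentration(flat, 5.0, reference=flat) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        wall_concentration(flat, 200.0)


def test_plate_wall_shear_closed_form():
    spec = PlateChannelSpec(
        q_ul_per_min=500.0, height_mm=0.1, width_mm=5.0, viscosity_pa_s=0.00076
    )
    gammadot, tau_w = plate_wall_shear(spec)
    assert gammadot == pytest.approx(1000.0, rel=1e-12)
    assert tau_w == pytest.approx(0.76, rel=1e-12)
    double = PlateChannelSpec(1000.0, 0.1, 5.0, 0.00076)
    assert plate_wall_shear(double)[0] == pytest.approx(2 * gammadot)


def test_plate_wall_shear_unit_invariance():
    a = PlateChannelSpec(500.0, 0.1, 5.0, 0.00076)
    b = PlateChannelSpec.from_si(500e-9 / 60.0, 1e-4, 5e-3, 0.00076)
    assert plate_wall_shear(a)[0] == pytest.approx(plate_wall_shear(b)[0], rel=1e-12)
    with pytest.raises(ValueError):
        PlateChannelSpec(-1.0, 0.1, 5.0, 0.00076)
    with pytest.warns(UserWarning):
        PlateChannelSpec(500.0, 1.0, 5.0, 0.00076)  # b/a < 10
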