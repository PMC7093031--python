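"""Ground-truth-known synthetic inputs for the analysis pipeline.

Every generator stores its parameters in the output (`ground_truth`), is
reproducible from a seed, and is shaped so that the matching estimator
recovers the stored truth:

* Brownian radial tracks with prescribed (possibly position-dependent)
  diffusivity, reflecting at the axis and the wall — oracle for
  :func:`hemoflow.analysis.radial_diffusivity`.  The radial coordinate is
  generated directly as a 1-D walk, so the scalar-r MSD estimator is free of
  the geometric bias a 2-D walk would introduce.
* Radial position ensembles with a prescribed cell-free-layer width and
  near-wall platelet excess — oracle for cfl_width and margination_index.
* Depth-attenuated Z-stack signals following Beer-Lambert decay — oracle for
  correct_zstack.
"""

from __future__ import annotations

import numpy as np

from .analysis import TrajectoryEnsemble
from .confocal import AbsorbanceSpectrum, ZStackProfile, transmittance_per_depth

__all__ = [
    "gen_brownian_tracks",
    "gen_radial_profile",
    "gen_zstack_signal",
    "flat_spectrum",
]


def gen_brownian_tracks(
    n_tracks: int = 200,
    duration_s: float = 0.4,
    dt_s: float = 2.5e-4,
    diffusivity=1.0,
    radius_um: float = 50.0,
    seed: int = 0,
    species: str = "healthy_rbc",
) -> TrajectoryEnsemble:
    """Radial Brownian tracks: dr ~ Normal(0, 2 D(r) dt), reflected at the
    axis (r=0) and the wall (r=R).

    `diffusivity` [um^2/s] is a constant or a callable D(r).
    """
    d_fun = diffusivity if callable(diffusivity) else (lambda r: np.full_like(r, diffusivity))
    test = np.asarray(d_fun(np.linspace(0, radius_um, 5)), dtype=float)
    if np.any(test < 0):
        raise ValueError("diffusivity must be non-negative")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration_s / dt_s))
    times = np.arange(n_steps + 1) * dt_s
    r = np.empty((n_tracks, n_steps + 1))
    r[:, 0] = rng.uniform(0.0, radius_um, size=n_tracks)
    for t in range(n_steps):
        d_here = np.asarray(d_fun(r[:, t]), dtype=float)
        step = rng.normal(0.0, 1.0, size=n_tracks) * np.sqrt(2.0 * d_here * dt_s)
        rn = r[:, t] + step
        # reflecting boundaries at 0 and R (fold back)
        rn = np.abs(rn)
        rn = np.where(rn > radius_um, 2 * radius_um - rn, rn)
        r[:, t + 1] = np.clip(rn, 0.0, radius_um)
    positions = np.zeros((n_tracks, n_steps + 1, 3))
    positions[:, :, 1] = r  # radial coordinate carried on the y axis
    return TrajectoryEnsemble(
        times=times,
        positions=positions,
        species=np.full(n_tracks, species, dtype=object),
        ground_truth={
            "kind": "brownian_tracks",
            "diffusivity": diffusivity if not callable(diffusivity) else "callable",
            "radius_um": radius_um,
            "dt_s": dt_s,
            "seed": seed,
        },
    )


def gen_radial_profile(
    n_rbc: int = 2000,
    n_platelets: int = 2000,
    radius_um: float = 50.0,
    cfl_um: float = 5.0,
    platelet_excess: float = 3.0,
    wall_band_um: float = 5.0,
    length_um: float = 100.0,
    seed: int = 0,
):
    """Scattered cell positions with a prescribed cell-free layer and
    near-wall platelet excess.

    RBC centres are uniform in the annulus area for r < R - cfl and absent
    beyond.  Platelets are placed at a uniform base density everywhere
    (n_platelets over the full cross-section) with additional platelets drawn
    in the wall band [R - w, R] so the band density is `platelet_excess`
    times the base density; an excess of 1 adds nothing.

    Returns (positions (N,3) um, labels (N,), ground_truth dict).
    """
    if not 0 <= cfl_um < radius_um:
        raise ValueError("cfl width must lie in [0, R)")
    if platelet_excess < 1:
        raise ValueError("platelet_excess must be >= 1")
    rng = np.random.default_rng(seed)

    def uniform_annulus(n, r0, r1):
        u = rng.uniform(r0**2, r1**2, size=n)
        return np.sqrt(u)

    r_rbc = uniform_annulus(n_rbc, 0.0, radius_um - cfl_um)
    r_w = radius_um - wall_band_um
    a_band_frac = (radius_um**2 - r_w**2) / radius_um**2
    n_extra = rng.poisson((platelet_excess - 1.0) * n_platelets * a_band_frac)
    r_plt = np.concatenate(
        [
            uniform_annulus(n_platelets, 0.0, radius_um),
            uniform_annulus(n_extra, r_w, radius_um),
        ]
    )
    n_platelets = n_platelets + n_extra
    radii = np.concatenate([r_rbc, r_plt])
    theta = rng.uniform(0, 2 * np.pi, size=len(radii))
    pos = np.column_stack(
        [
            rng.uniform(0, length_um, size=len(radii)),
            radii * np.cos(theta),
            radii * np.sin(theta),
        ]
    )
    labels = np.array(
        ["healthy_rbc"] * n_rbc + ["platelet"] * n_platelets, dtype=object
    )
    truth = {
        "kind": "radial_profile",
        "cfl_um": cfl_um,
        "platelet_excess": platelet_excess,
        "wall_band_um": wall_band_um,
        "radius_um": radius_um,
        "seed": seed,
    }
    return pos, labels, truth


def flat_spectrum(absorbance: float, path_length_mm: float = 3.108) -> AbsorbanceSpectrum:
    """Wavelength-independent absorbance over 600-700 nm (synthetic)."""
    wl = np.array([600.0, 700.0])
    return AbsorbanceSpectrum(wl, np.array([absorbance, absorbance]), path_length_mm)


def gen_zstack_signal(
    true_profile,
    absorbance: float = 1.0,
    channel_height_um: float = 100.0,
    dz_um: float = 2.0,
    noise_sd: float = 0.0,
    path_length_mm: float = 3.108,
    objective_at_top: bool = True,
    emission_nm: float = 660.0,
    seed: int = 0,
):
    """Depth-attenuated fluorescence Z-stack.

    ``raw(h) = true(h) * 10^(-A * path(h) / L) + Normal(0, noise_sd)`` with
    path(h) the optical distance from the objective-side wall.

    `true_profile` is a callable of height or an array on the height grid.
    Returns (ZStackProfile raw, true intensities, AbsorbanceSpectrum, truth).
    """
    rng = np.random.default_rng(seed)
    heights = np.arange(0.0, channel_height_um + dz_um / 2, dz_um)
    truth_vals = (
        np.asarray(true_profile, dtype=float)
        if not callable(true_profile)
        else np.asarray(true_profile(heights), dtype=float)
    )
    spectrum = flat_spectrum(absorbance, path_length_mm)
    path = (channel_height_um - heights) if objective_at_top else heights
    t = np.asarray(transmittance_per_depth(spectrum, emission_nm, path))
    raw = truth_vals * t + rng.normal(0.0, noise_sd, size=len(heights))
    profile = ZStackProfile(
        heights,
        raw,
        channel_height_um=channel_height_um,
        objective_at_top=objective_at_top,
    )
    gt = {
        "kind": "zstack_signal",
        "absorbance": absorbance,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return profile, truth_vals, spectrum, gt
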