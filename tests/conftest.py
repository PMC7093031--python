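"""Session-scoped fixtures for the coupled-simulation studies.

The collision and tube-flow runs are the expensive part of the suite; they
are executed once per session here and shared by the acceptance tests and
the conservation checks.
"""

import numpy as np
import pytest

from hemoflow.analysis import RadialBinning, cfl_width, radial_diffusivity, volume_fraction_profile
from hemoflow.experiments import (
    CollisionConfig,
    SuspensionSpec,
    run_channel_flow,
    run_pair_collision,
)

#: desk-scale tube study conditions (see docs/methods.md)
TUBE_RADIUS = 8.5
TUBE_LENGTH = 18.0
TUBE_DURATION = 0.010
TUBE_SEEDS = (0, 1, 2, 3, 4)


@pytest.fixture(scope="session")
def heterogeneous_collisions():
    """Healthy vs 0.75 mM stiff pair: all 10 replicate configurations."""
    cfg = CollisionConfig(species_pair=("healthy_rbc", "stiff_rbc_0p75"))
    return run_pair_collision(cfg)


@pytest.fixture(scope="session")
def homogeneous_collisions():
    """healthy-healthy and stiff-stiff pairs over the five orientations.

    The five position-swapped configurations of a homogeneous pair are exact
    point-symmetry images of the unswapped ones (verified by
    test_homogeneous_swap_is_point_symmetric), so the five runs here carry
    the full ten-configuration content per pair.
    """
    out = {}
    for key, pair in (
        ("hh", ("healthy_rbc", "healthy_rbc")),
        ("ss", ("stiff_rbc_0p75", "stiff_rbc_0p75")),
    ):
        cfg = CollisionConfig(species_pair=pair, swap_initial_positions=False)
        out[key] = run_pair_collision(cfg)
    return out


@pytest.fixture(scope="session")
def tube_study():
    """Reduced-tube suspension runs: stiff fractions {0, 0.5, 1} x 5 seeds.

    Returns {(seed, fraction): dict of observables}.
    """
    bins = RadialBinning.for_radius(TUBE_RADIUS)
    results = {}
    for seed in TUBE_SEEDS:
        for frac in (0.0, 0.5, 1.0):
            spec = SuspensionSpec(
                radius_um=TUBE_RADIUS,
                length_um=TUBE_LENGTH,
                stiff_fraction=frac,
                dx_um=1.4,
                seed=seed,
            )
            res = run_channel_flow(spec, duration_s=TUBE_DURATION)
            late = [s for t, s in res.snapshots if t > TUBE_DURATION / 2]
            # time-averaged concentration profile over the trailing snapshots
            profs = [
                volume_fraction_profile(
                    frame,
                    bins,
                    dx_um=spec.dx_um / 2,
                    axis_center=res.axis_center_um,
                    x_range=(0.0, TUBE_LENGTH),
                )
                for frame in late
            ]
            species = sorted({sp for p in profs for sp in p.fractions})
            from hemoflow.analysis import ConcentrationProfile

            prof = ConcentrationProfile(
                bins,
                {
                    sp: np.mean(
                        [p.fractions.get(sp, np.zeros(bins.n_bins)) for p in profs],
                        axis=0,
                    )
                    for sp in species
                },
            )
            diff = radial_diffusivity(
                res.ensemble, bins, window_s=5e-4, duration_s=TUBE_DURATION
            )
            results[(seed, frac)] = {
                "cfl": cfl_width(late, TUBE_RADIUS, axis_center=res.axis_center_um),
                "profile": prof,
                "diffusivity": diff,
                "tube_hematocrit": res.tube_hematocrit,
                "discharge_hematocrit": res.discharge_hematocrit,
                "volume_drift": None,
            }
    results["bins"] = bins
    return results
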