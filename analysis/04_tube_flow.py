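#!/usr/bin/env python
"""Reduced-tube suspension study: hematocrit profiles, cell-free layer,
radial diffusivity and platelet margination versus the stiff RBC fraction.

For each stiff fraction and seed, packs a 30% hematocrit suspension with
platelets into the periodic tube, drives it at a 1000 1/s wall shear rate,
and computes from the trailing half of the run:

* CFL width per RBC species (azimuthal-sector minimum gap, time averaged)
* radial volume-fraction profiles and the normalized platelet profile
* radial diffusivity D_rr per species in seven radial bins
* the near-wall platelet concentration, normalized to the healthy-only run
  of the same seed (the margination index)
"""

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import numpy as np
import pandas as pd

from hemoflow.analysis import (
    ConcentrationProfile,
    RadialBinning,
    cfl_width,
    margination_index,
    radial_diffusivity,
    volume_fraction_profile,
)
from hemoflow.experiments import SuspensionSpec, run_channel_flow


def study(stiff_fractions, seeds, radius=9.0, length=20.0, duration=0.012):
    bins = RadialBinning.for_radius(radius)
    rows_cfl, rows_diff, rows_prof, rows_marg = [], [], [], []
    wall_ref = {}
    for seed in seeds:
        for frac in stiff_fractions:
            spec = SuspensionSpec(
                radius_um=radius,
                length_um=length,
                stiff_fraction=frac,
                dx_um=1.4,
                seed=seed,
            )
            res = run_channel_flow(spec, duration_s=duration)
            late = [s for t, s in res.snapshots if t > duration / 2]
            cfl = cfl_width(late, radius, axis_center=res.axis_center_um)
            for sp, v in cfl.items():
                rows_cfl.append(
                    {"stiff_fraction": frac, "seed": seed, "species": sp, "cfl_um": v}
                )
            prof = volume_fraction_profile(
                late[-1], bins, dx_um=spec.dx_um / 2,
                axis_center=res.axis_center_um, x_range=(0.0, length),
            )
            for sp, f in prof.fractions.items():
                for c, v in zip(bins.centers, f):
                    rows_prof.append(
                        {
                            "stiff_fraction": frac,
                            "seed": seed,
                            "species": sp,
                            "bin_center_um": c,
                            "volume_fraction": v,
                        }
                    )
            diff = radial_diffusivity(
                res.ensemble, bins, window_s=5e-4, duration_s=duration / 2
            )
            for sp, d in diff.d_rr.items():
                for c, v, n in zip(bins.centers, d, diff.counts[sp]):
                    rows_diff.append(
                        {
                            "stiff_fraction": frac,
                            "seed": seed,
                            "species": sp,
                            "bin_center_um": c,
                            "d_rr_um2_s": v,
                            "n_windows": n,
                        }
                    )
            key = (seed, frac)
            wall_ref[key] = prof
            print(
                f"seed {seed} stiff {frac}: tubeH {res.tube_hematocrit:.3f} "
                f"dischargeH {res.discharge_hematocrit:.3f} cfl {cfl}",
                flush=True,
            )
        for frac in stiff_fractions:
            if frac == 0.0:
                continue
            idx = margination_index(
                wall_ref[(seed, frac)], 4.0, wall_ref[(seed, 0.0)]
            )
            rows_marg.append(
                {"stiff_fraction": frac, "seed": seed, "margination_index": idx}
            )
    return rows_cfl, rows_diff, rows_prof, rows_marg


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seeds", type=int, nargs="*", default=[0, 1, 2, 3, 4])
    ap.add_argument("--fractions", type=float, nargs="*", default=[0.0, 0.5, 1.0])
    ap.add_argument("--duration", type=float, default=0.012)
    args = ap.parse_args()
    cfl, diff, prof, marg = study(args.fractions, args.seeds, duration=args.duration)
    out = os.path.join(os.path.dirname(__file__), "..", "results")
    os.makedirs(out, exist_ok=True)
    pd.DataFrame(cfl).to_csv(os.path.join(out, "tube_cfl.csv"), index=False)
    pd.DataFrame(diff).to_csv(os.path.join(out, "tube_diffusivity.csv"), index=False)
    pd.DataFrame(prof).to_csv(os.path.join(out, "tube_profiles.csv"), index=False)
    pd.DataFrame(marg).to_csv(os.path.join(out, "tube_margination.csv"), index=False)
    cdf = pd.DataFrame(cfl)
    rbc = cdf[cdf.species.str.endswith("rbc") | cdf.species.str.startswith("stiff")]
    print("\nmean CFL by stiff fraction (RBC species):")
    print(rbc.groupby(["stiff_fraction", "species"]).cfl_um.mean())
    if marg:
        print("\nmargination index vs healthy-only:")
        print(pd.DataFrame(marg).groupby("stiff_fraction").margination_index.mean())


if __name__ == "__main__":
    main()
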