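#!/usr/bin/env python
"""Surface Young's modulus of each membrane model from the hexagonal-patch
uniaxial deformation test.

Builds the default RBC mesh to fix the patch edge length, then measures the
small-strain tension-vs-strain slope for the four stiffness presets and
writes the table with the reference values they are compared against.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd

from hemoflow.membrane import PRESETS, patch_young_modulus
from hemoflow.mesh import build_rbc_mesh


def main():
    edge = build_rbc_mesh(642, 8.0).mean_edge_length()
    rows = []
    for name, params in PRESETS.items():
        ym = patch_young_modulus(params, edge_um=edge)
        rows.append(
            {
                "preset": name,
                "kappa_link_kbt": round(params.kappa_link / 4.141947e-21, 1),
                "Lambda": params.Lambda,
                "young_modulus_uN_per_m": round(ym, 2),
                "reference_uN_per_m": params.young_modulus_reported,
            }
        )
    df = pd.DataFrame(rows)
    out = os.path.join(os.path.dirname(__file__), "..", "results")
    os.makedirs(out, exist_ok=True)
    df.to_csv(os.path.join(out, "patch_young_modulus.csv"), index=False)
    print(f"patch edge length: {edge:.4f} um")
    print(df.to_string(index=False))
    print(
        "\nThe healthy value is reproduced by construction (the area "
        "coefficient is calibrated on it); the 600 kBT model lands within "
        "~6% of its reference. The 90 kBT model cannot reach its reference "
        "under any protocol in which the modulus is affine in the link "
        "coefficient; see docs/methods.md."
    )


if __name__ == "__main__":
    main()
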