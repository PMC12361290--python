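#!/usr/bin/env python
"""Validate the two thickness-measurement routes on known geometry.

Route A (surface pair): normal-ray distance on concentric spheres with
a known 2.000 mm shell.  Route B (profile deconvolution): two-step
blurred-intensity model fitted to forward-simulated profiles, noiseless
and at 2% noise.  Writes results/thickness_validation.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from casm.mesh import TriangleMesh                        # noqa: E402
from casm.thickness import (                              # noqa: E402
    fit_profile_model,
    synthesize_profile,
    thickness_from_surface_pair,
)

OUT = ROOT / "results"


def main():
    OUT.mkdir(exist_ok=True)
    rows = []

    outer = trimesh.creation.icosphere(4, radius=40.0)
    inner = trimesh.creation.icosphere(5, radius=38.0)
    f = thickness_from_surface_pair(TriangleMesh(outer.vertices, outer.faces),
                                    TriangleMesh(inner.vertices, inner.faces))
    rows.append({
        "check": "concentric_spheres_2mm",
        "n": int(len(f.values)),
        "mean_mm": float(f.values.mean()),
        "max_abs_error_mm": float(np.abs(f.values - 2.0).max()),
    })

    p = synthesize_profile(2.5, x_outer=1.0, levels=(10, 100, 30),
                           sigma=0.4, spacing=0.25)
    fit = fit_profile_model(p, (0.1, 1.5), seed=0)
    rows.append({
        "check": "profile_noiseless",
        "n": 1,
        "mean_mm": fit.thickness,
        "max_abs_error_mm": max(abs(fit.x_outer - 1.0),
                                abs(fit.x_inner - 3.5)),
    })

    errs = []
    for seed in range(100):
        pn = synthesize_profile(2.5, x_outer=1.0, levels=(10, 100, 30),
                                sigma=0.4, spacing=0.25,
                                noise_sd=0.02 * 90, rng=seed)
        fn = fit_profile_model(pn, (0.1, 1.5), seed=seed)
        errs.append(max(abs(fn.x_outer - 1.0), abs(fn.x_inner - 3.5)))
    rows.append({
        "check": "profile_2pct_noise_100reps",
        "n": 100,
        "mean_mm": float(np.mean(errs)),
        "max_abs_error_mm": float(np.max(errs)),
    })

    df = pd.DataFrame(rows)
    df.to_csv(OUT / "thickness_validation.csv", index=False)
    print(df.to_string(index=False))
    print("\nsphere shell measured to "
          f"{rows[0]['max_abs_error_mm'] * 1000:.2f} um; noiseless profile "
          f"interfaces to {rows[1]['max_abs_error_mm'] * 1000:.2f} um; at 2% "
          f"noise the mean interface error is {rows[2]['mean_mm'] * 1000:.1f} um "
          "(the information-theoretic floor at this spacing is ~12 um).")


if __name__ == "__main__":
    main()
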