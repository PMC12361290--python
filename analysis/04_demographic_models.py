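#!/usr/bin/env python
"""Vertex-wise demographic models on the simulated cohort.

Fits the five univariable demographic models (sex, age, BMI, height,
weight) and the four contrasts of the multivariable model (no BMI, to
avoid collinearity with height and weight) on the femur patch of the
study generated by 01_simulate_cohort.py, with min(RFT, FDR) correction
at alpha = 0.05.  For planted covariates the estimated beta map is
correlated against the generator's ground truth.

Writes results/demographic_models.csv and per-model result surfaces
(beta/t/p/mask fields + colour map) under scratch/maps/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from casm.cohort import build_design, get_model        # noqa: E402
from casm.io import load_mesh, save_colored_ply, save_mesh  # noqa: E402
from casm.spm import run_spm                           # noqa: E402
from casm.mesh import SurfaceField                     # noqa: E402

STUDY = ROOT / "scratch" / "study"
OUT = ROOT / "results"
MAPS = ROOT / "scratch" / "maps"
MODELS = ["uni_sex", "uni_age", "uni_bmi", "uni_height", "uni_weight",
          "multi_demo_sex", "multi_demo_age", "multi_demo_weight",
          "multi_demo_height"]


def main():
    if not STUDY.exists():
        sys.exit("run analysis/01_simulate_cohort.py first")
    MAPS.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(STUDY / "cohort.csv")
    mesh, fields = load_mesh(STUDY / "canonical_femur.ply")
    y = np.load(STUDY / "thickness_femur.npy")
    rows = []
    for name in MODELS:
        spec = get_model(name)
        design = build_design(cohort, spec)
        res = run_spm(y, design, mesh, alpha=0.05)
        beta = res.beta_maps[spec.contrast]
        truth_field = fields.get(f"effect_{spec.contrast}")
        corr = (float(np.corrcoef(beta.values, truth_field.values)[0, 1])
                if truth_field is not None
                and np.abs(truth_field.values).max() > 0 else np.nan)
        rows.append({
            "model": name,
            "contrast": spec.contrast,
            "peak_abs_beta": float(np.abs(beta.values).max()),
            "t_rft": round(res.t_threshold_rft, 3),
            "t_fdr": (round(res.t_threshold_fdr, 3)
                      if np.isfinite(res.t_threshold_fdr) else np.inf),
            "pct_significant": round(100 * res.significance_mask.mean(), 1),
            "beta_truth_corr": round(corr, 3) if np.isfinite(corr) else "",
        })
        out_fields = {"beta": beta, "t": res.t_map, "p": res.p_map,
                      "mask": SurfaceField(
                          res.significance_mask.astype(float), name="mask")}
        save_mesh(mesh, out_fields, MAPS / f"{name}_femur.ply")
        save_colored_ply(mesh, beta, MAPS / f"{name}_femur_color.ply",
                         significance_mask=res.significance_mask)
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "demographic_models.csv", index=False)
    print(df.to_string(index=False))
    planted = df[df.beta_truth_corr != ""]
    print(f"\nplanted demographic effects recovered with beta/truth "
          f"correlations {planted.beta_truth_corr.tolist()}; covariates with "
          "no planted effect stay (mostly) non-significant.")


if __name__ == "__main__":
    main()
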