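# casm — cartilage surface mapping with vertex-wise statistics

`casm` is an analysis pipeline for whole-joint cartilage morphometry in
knee osteoarthritis. Instead of averaging cartilage thickness over
predefined anatomical subregions, it measures thickness at every vertex
of triangulated femoral and tibial surface patches, registers all
subjects to canonical template surfaces, and maps where thickness
depends on demographics (sex, age, BMI, height, weight), radiographic
grades (Kellgren-Lawrence, joint-space narrowing) and MRI pathology
grades (MOAKS meniscal extrusion, bone marrow lesions, osteophytes) —
with principled control of the tens of thousands of spatial tests this
entails. It is written for imaging scientists and methodologists who
want a tested, fully synthetic-validatable implementation of this kind
of surface-statistics pipeline.

## What it computes

Per vertex v of a canonical surface, an ordinary-least-squares general
linear model across n subjects,

    y(v) = X β(v) + ε(v),
    t(v) = c'β̂(v) / sqrt( c'(X'X)⁻¹c · σ̂²(v) ),   df = n − p,

and a two-sided significance mask |t(v)| ≥ t*, where t* is the
**minimum** (less conservative) of two corrected thresholds:

* the **random-field-theory** peak threshold — the smallest t at which
  the expected Euler characteristic of the excursion set,
  Σ_d R_d·ρ_d(t, df), drops to α/2 per tail, with resels R_d estimated
  from the residuals' spatial roughness (FWHM = sqrt(4 ln 2 / λ̄)) and
  the patch geometry (R2 = area/FWHM², R1 = boundary/2FWHM, R0 = χ);
* the **Benjamini–Hochberg FDR** threshold on the two-sided vertex
  p-values, expressed on the |t| scale.

Upstream of the statistics, the package measures thickness (normal-ray
distance between outer and inner cartilage surfaces, or model-based
deconvolution of 1-D intensity profiles via a two-interface
Gaussian-blurred step model), and registers subjects to the template
(closed-form similarity + iterative closest point, then thin-plate
spline refinement, then barycentric field transfer). A synthetic-data
module generates template patches, cohorts with the documented
demographic and pathology marginals, and thickness fields with planted,
recoverable effect maps. See `docs/methods.md` for the full account.

## Worked example

Simulate a 287-subject cohort with a planted sex effect (0.5 mm peak in
the trochlear region, smooth 0.3 mm noise) and fit the multivariable
demographic model:

```python
import numpy as np
from casm.synthetic import CohortSpec, simulate_cohort_dataset
from casm.cohort import build_design, get_model
from casm.spm import run_spm

ds = simulate_cohort_dataset(CohortSpec(n_subjects=287),
                             scenario="demographics", seed=42,
                             patches=("femur",), n_vertices=1000)
design = build_design(ds.cohort, get_model("multi_demo_sex"))
res = run_spm(ds.thickness_matrices["femur"], design, ds.canonical["femur"])

print(f"subjects: {design.n_subjects}, vertices analysed: "
      f"{int(res.analysis_mask.sum())}, df = {res.df}")
print(f"residual smoothness FWHM = {res.fwhm_est:.2f} mm, "
      f"resels = ({res.resels[0]:.0f}, {res.resels[1]:.1f}, {res.resels[2]:.1f})")
print(f"t thresholds: RFT {res.t_threshold_rft:.2f}, "
      f"FDR {res.t_threshold_fdr:.2f}, final {res.t_threshold_final:.2f}")
beta = res.beta_maps["sex"].values
truth = ds.effects.effects["sex"]["femur"]
print(f"peak sex effect: {beta.max():.2f} mm (planted peak 0.50 mm)")
print(f"significant vertices: {res.significance_mask.sum()} "
      f"({100 * res.significance_mask.mean():.0f}%)")
print(f"correlation with planted effect map: "
      f"{np.corrcoef(beta, truth)[0, 1]:.3f}")
```

Output:

```
subjects: 287, vertices analysed: 1008, df = 282
residual smoothness FWHM = 6.74 mm, resels = (1, 18.6, 91.3)
t thresholds: RFT 4.05, FDR 2.08, final 2.08
peak sex effect: 0.52 mm (planted peak 0.50 mm)
significant vertices: 795 (79%)
correlation with planted effect map: 0.917
```

Reading this: the error field's spatial correlation is ≈6.7 mm FWHM, so
the ~1,000 vertex tests amount to ≈91 independent 2-D resolution
elements; here the FDR threshold (|t| ≥ 2.08) is the less conservative
of the two corrections and defines the mask. The estimated sex effect
peaks at 0.52 mm of extra cartilage in men versus the 0.50 mm planted,
and the β̂ map correlates 0.92 with the ground-truth effect map.
`casm.io.save_colored_ply` exports such maps with non-significant
regions washed out, the usual rendering convention.

The numbered scripts under `analysis/` run the full study at desk
scale — cohort simulation, thickness-measurement validation,
registration round-trips, the demographic and pathology model
catalogues, and error-control simulations — each writing its tables
under `results/` (bulky intermediates go to `scratch/`). Run them in
order:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_measure_thickness.py
...
```

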