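# Methods

`casm` implements cartilage surface mapping (CaSM) with vertex-wise
statistical parametric mapping (SPM) for knee-joint surfaces, together
with a synthetic-data generator that plays the role of the MRI cohort so
that every stage can be validated against known ground truth.

## Surfaces and thickness measurement

The primary objects are open triangulated patches of the femoral and
tibial articular surfaces (femur, medial tibia, lateral tibia), in mm,
right-handed coordinates. No voxel grid is modelled: segmentation of MRI
volumes is upstream of this package and out of scope.

Thickness is measured per vertex of the outer cartilage surface by one
of two routes:

* **Surface pair.** A ray is cast from each outer vertex along the
  inward angle-weighted vertex normal; thickness is the distance to the
  first intersection with the inner (cartilage–bone) surface. Rays that
  miss within `max_thickness` (default 10 mm, a physiologic ceiling for
  knee cartilage) fall back to the unsigned closest-point distance; the
  origin is offset by 1e-6 mm to avoid self-intersection. Angle
  weighting of face normals is robust to irregular triangulations; its
  discretisation bias is first-order in edge length and below 1e-3 of a
  unit normal on a finely tessellated sphere.

* **Profile deconvolution.** When only image intensities along the
  normal are available, a two-interface blurred-step model is fitted to
  each 1-D profile:

      y(x) = L_out + (L_cart − L_out)·Φ((x − x_outer)/σ)
                   + (L_bone − L_cart)·Φ((x − x_inner)/σ),

  with Φ the standard normal CDF and a single PSF scale σ shared by
  both interfaces (one scanner). Thickness is `x_inner − x_outer`.
  Fitting is bounded least squares with seeded multi-start
  initialisation over candidate interface pairs taken from the
  profile's gradient extrema. When one step's amplitude falls below 5%
  of the profile's dynamic range its interface position is
  unidentifiable; the fit collapses it onto the resolvable interface,
  which encodes denuded bone (outside→bone in a single step) as
  thickness 0. Unresolvable or non-converged fits are reported as
  thickness 0 with a quality flag rather than missing, so cohort
  matrices stay complete and downstream models may choose to exclude
  flagged vertices.

  Precision limit: for a blurred step of amplitude A sampled at spacing
  Δ with noise s, the Cramér–Rao bound on the interface-position SD is
  approximately `s·sqrt(2√π·Δ·σ)/A`. At the validation conditions
  (A = 90/70, σ = 0.4 mm, Δ = 0.25 mm, s = 1.8) this is 12–15 µm; the
  fitter is tested to stay within 1.5× of it. Sub-pixel tolerances
  tighter than this bound are not achievable by any unbiased estimator.

## Registration to the canonical template

Each subject patch is registered to a canonical (template) patch of the
same type by

1. a closed-form similarity transform (Umeyama; reflections are never
   returned) refined by iterative closest point — vertex-to-vertex
   iterations first, then vertex-to-surface iterations, which remove
   the tessellation bias of nearest-vertex pairing;
2. a 3-D thin-plate-spline (TPS) warp fitted to `n_control` (default
   400) farthest-point-sampled canonical control points paired with
   their current closest points on the subject surface, re-fitted for
   `iterations` (default 5) rounds;
3. closest-point projection of every warped canonical vertex onto the
   subject mesh, yielding a face index and barycentric weights.

The TPS linear system uses the conditionally positive-definite form of
the 3-D biharmonic kernel (−r) with Tikhonov weight λ on the kernel
block (default 1e-3 × mesh diameter); weights are stored negated so
evaluation follows the common U(r) = +r convention. With λ = 0 the warp
interpolates landmarks exactly and reproduces affine maps with zero
kernel weights; bending energy is non-negative and decreases
monotonically in λ.

Fields are pulled canonical ← subject by barycentric interpolation,
which keeps transferred values inside the subject field's range.
Correspondences whose closest-point distance exceeds 3× the subject's
median edge length are marked missing (extrapolation guard). A caveat
inherent to geometry-only registration: tangential sliding on smooth,
featureless regions is unobservable (the aperture problem), so
transferred-field accuracy is reported as RMS over vertices; worst-case
single-vertex errors can be a few times larger.

## Vertex-wise general linear models

For each vertex v across n subjects, ordinary least squares

    y(v) = X β(v) + ε(v),   t(v) = c'β̂(v) / sqrt(c'(X'X)⁻¹c · σ̂²(v)),

with two-sided p-values on n − p degrees of freedom. Vertices missing
in any subject are dropped for all subjects (complete-vertex analysis)
and statistics run per patch; this is the simple, conservative choice.

Multiple-comparison control combines two corrected thresholds on |t|
and takes their minimum (the less conservative), the convention of
SurfStat-style surface statistics:

* **Random field theory (peak-level).** Residuals are normalised to
  unit norm across subjects; squared differences across mesh edges,
  divided by squared edge length and pooled, estimate the roughness λ̄
  of a unit-variance error field, giving FWHM = sqrt(4 ln 2 / λ̄).
  Resel counts follow from geometry: R2 = area/FWHM², R1 =
  boundary/(2·FWHM), R0 = Euler characteristic (computed on the
  retained sub-mesh). The threshold is the smallest t at which the
  expected Euler characteristic Σ R_d·ρ_d(t, ν) of the excursion set
  falls to α/2 per tail, with the standard t-field EC densities,
  solved by bisection to 1e-6. This estimator is consistent for smooth
  fields (construct-and-recover at 8 mm FWHM is tested to 20%); its
  white-noise limit is FWHM = h·sqrt(2 ln 2) for mean edge length h —
  a convention-dependent value, since white noise is not a smooth
  field.
* **False discovery rate.** Benjamini–Hochberg step-up on the
  two-sided vertex p-values at q = α (delegated to statsmodels and
  cross-checked in tests against exhaustive enumeration), expressed as
  the smallest rejected |t|; +∞ when nothing is rejected.

Inference is two-sided throughout (effect maps show increases and
decreases); ordinal grades enter as numeric covariates so every slope
reads "mm per grade increase". Pre-smoothing of thickness maps before
the GLM is available (`smoothing_fwhm`) but OFF by default; the
smoothing operator is an explicit graph-Laplacian diffusion step
x → x − αLx (α = 0.5/max degree), which conserves the field mean
exactly and excludes masked vertices.

## Model catalogue

The catalogue mirrors a standard knee-OA covariate analysis: five
univariable demographic models (sex, age, BMI, height, weight); one
multivariable demographic model over sex, age, weight, height (BMI
omitted for collinearity with height and weight), with each covariate
in turn as contrast; compartmental pathology models (KL grade, medial
and lateral joint-space narrowing, and MOAKS meniscal extrusion, bone
marrow lesions and osteophytes per compartment), all adjusted for sex,
age and height; joint-space-narrowing sensitivity models additionally
adjusted for ipsilateral meniscal extrusion (medial↔medial,
lateral↔lateral); and binary presence/absence variants per MOAKS
subregion, excluded when fewer than 20 subjects are affected. MOAKS
compartment scores are the maximum over the compartment's subregions.
Sex is coded male = 1 / female = 0, so positive sex slopes mean thicker
cartilage in men. KL is accepted on 0–4. An exploratory radiographic-OA
binary model (KL ≥ 2) is included and flagged as such.

## Synthetic data generator

The generator defines the study conditions; it emulates the structure
of the cohort, not its images.

* **Canonical patches.** Parametric surfaces triangulated by Delaunay
  over a jittered grid: the femur is a saddle-like open sheet with two
  condylar bumps and an anterior trochlear groove; tibiae are domed
  elliptical discs. Disc topology, min triangle angle > 15°,
  edge-length CV < 0.5, deterministic per seed. Named regions
  (trochlea, medial/lateral femur, anterior femur, tibial centres) are
  smooth Gaussian bumps in the parametric frame — synthetic analogues,
  not anatomical claims.
* **Cohort.** Demographics are normal with the documented defaults
  (n = 287; 64/287 male; age 66.4 ± 7.1 y; BMI 28.0 ± 5.2; height
  167.1 ± 10.0 cm; weight 78.2 ± 15.8 kg). Height and weight are
  shifted by sex (defaults +8 cm, +10 kg, male−female) in a
  mean-preserving way, so overall means stay at their configured
  values while demographic collinearity is realistic. KL grades are
  multinomial with counts (54, 76, 63, 84, 10)/287; joint-space
  narrowing and MOAKS compartment involvement are Bernoulli at the
  documented prevalences with conditional grade distribution
  (0.5, 0.3, 0.2) over 1–3. Subregion scores are constructed so their
  maximum equals the drawn compartmental grade; the anterior lateral
  meniscus is configured rare (propensity factor 0.25) so the
  fewer-than-20 exclusion rule is exercised at n = 287, as happens in
  real cohorts. BMI is drawn independently rather than derived as
  weight/height², a simplification that leaves the BMI-collinearity
  rationale qualitative.
* **Thickness fields.** thickness = clip₀(baseline + Σ effect_k·(x_k −
  ref_k) + ε). The baseline is a smooth 1.5–2.5 mm map, thinner
  medially. Covariates are centred at cohort-typical references (age
  66.4, height 167.1, weight 78.2, BMI 28, sex 0), which keeps the
  baseline interpretable and thickness positive without changing any
  slope. Effect maps are regional bumps whose **total** per-covariate
  peak matches the published magnitudes (sex 0.5 mm; age 0.035 mm/y;
  height 0.025 mm/cm; KL ±0.2, JSN −0.4/−0.5, extrusion −0.3/−0.4,
  BMLs −0.32/−0.35/−0.14, osteophytes −0.24 local with +0.3 anterior
  femur, all per grade). Noise ε is white Gaussian diffused to FWHM
  3× the mean edge length and rescaled to SD 0.3 mm — chosen so
  recovery at n = 287 is attainable but not trivial. The clip fraction
  is reported and is ≈0 at defaults.
* **Geometry.** Subjects are the canonical mesh pushed through a random
  similarity (scale 0.9–1.1, rotation ±10°, translation ±5 mm) plus a
  random smooth TPS bend (10 control points, 2 mm RMS amplitude);
  connectivity is preserved, so vertex i of the subject corresponds to
  canonical vertex i — the ground truth for registration validation.
  Optionally, per-vertex intensity profiles are emitted from the
  deconvolution forward model at the true thickness.

All randomness flows from one root seed through named substreams
(cohort, geometry, noise, profiles), so every dataset is reproducible
bit-for-bit.

What passing tests on this generator do **not** show: robustness to
segmentation error, intensity inhomogeneity, denuded-area prevalence,
non-Gaussian noise, or anatomical shape variation beyond smooth
similarity+TPS deformations. Results on real cohorts additionally
depend on the upstream segmentation pipeline.

## Problem sizes and numerical choices

Validation experiments run at desk scale: 1,000-vertex patches for
cohort statistics (n = 100–287 subjects), 2,000 vertices for geometric
oracles, 200 replicates for the family-wise-error simulation, 10 seeds
for effect-recovery. Family-wise error of the combined min(RFT, FDR)
mask at α = 0.05 measures ≈0.03–0.06 over 200 null cohorts (bound
0.081 at two Monte-Carlo SEs); the planted 0.5 mm sex effect at
n = 287 is recovered with median β̂/truth correlation ≈0.92 and full
coverage of the strongly-affected region.

Other numerical details: meshes are validated (index ranges, area
> 1e-12 mm², edge-manifold, single component) on load; bisection
tolerance for the RFT threshold is 1e-6; TPS systems raise a
degeneracy error (suggesting λ > 0) on coplanar landmarks; the GLM
treats RSS below 1e-20 of the data scale as an exact fit (t = 0)
rather than dividing by round-off; missing data propagates as explicit
boolean masks, never sentinels.

## Known limitations

* Peak-level RFT only; no cluster-extent inference.
* No mixed-effects or longitudinal models, and no interaction terms.
* Ordinal grades as linear covariates is an interpretable but strong
  assumption; no dummy coding of grade levels is offered.
* The canonical template is an input (or synthetic); groupwise template
  construction is out of scope.
* OBJ I/O carries geometry only; binary PLY is little-endian only.
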