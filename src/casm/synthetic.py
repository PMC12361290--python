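"""Synthetic canonical surfaces, subject geometry, cohort covariates and
thickness fields with known ground truth.

The generator emulates the structure of a knee-osteoarthritis imaging
cohort at desk scale: femur-like and tibia-like template patches, a
covariate table whose marginals follow the published cohort overview
(n=287; 22% male; age 66.4 +/- 7.1 y; BMI 28.0 +/- 5.2; height
167.1 +/- 10.0 cm; weight 78.2 +/- 15.8 kg; compartment pathology
prevalences), per-subject smooth geometric deformations, and thickness
fields built as

    thickness(v) = clip_0( baseline(v)
                           + sum_k effect_k(v) * (x_k - ref_k)
                           + eps(v) )

with eps smooth Gaussian noise.  Effect maps are smooth regional bumps
whose default peak amplitudes follow the published effect magnitudes
(e.g. up to 0.5 mm male-vs-female).  Every stage of the measurement and
inference pipeline can be validated against these ground truths.

All randomness flows from a single root seed through named substreams
(cohort, geometry, noise, profiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .cohort import ALL_SUBREGION_COLUMNS, MOAKS_SUBREGIONS, validate_cohort
from .mesh import SurfaceField, TriangleMesh, smooth_field
from .registration import SimilarityTransform, farthest_point_sample, tps_apply, tps_fit
from .thickness import synthesize_profile

SCENARIOS = ("null", "demographics", "pathology", "custom")


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child stream of the root seed."""
    h = int.from_bytes(name.encode(), "little") % (2 ** 32)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(h,)))


# ---------------------------------------------------------------------------
# canonical patches
# ---------------------------------------------------------------------------

# physical extents, mm
_FEMUR_SIZE = (70.0, 55.0)
_TIBIA_SIZE = (32.0, 42.0)


def make_canonical_patch(patch_label: str, n_vertices: int = 1000,
                         seed: int = 0) -> TriangleMesh:
    """Deterministic template patch with an irregular triangulation.

    The femur patch is an open saddle-like sheet with two condylar
    bumps and an anterior trochlear groove; the tibial patches are
    gently domed elliptical discs.  Interior grid nodes are jittered
    (bounded, seeded) before Delaunay triangulation in the parameter
    plane, giving irregular but quality-bounded triangles; the result
    has disc topology.
    """
    if n_vertices < 200:
        raise ValueError("canonical patches need at least 200 vertices")
    rng = _substream(seed, f"patch:{patch_label}")
    if patch_label == "femur":
        uv = _jittered_rect_grid(n_vertices, rng)
        xyz = _femur_surface(uv)
    elif patch_label in ("medial_tibia", "lateral_tibia"):
        uv = _jittered_disc_grid(n_vertices, rng)
        xyz = _tibia_surface(uv, patch_label)
    else:
        raise ValueError(f"unknown patch label {patch_label!r}")
    tri = Delaunay(uv)
    faces = tri.simplices.astype(np.int64)
    # orient all faces counter-clockwise in the parameter plane -> +z normals
    p = uv[faces]
    area2 = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
             - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    flip = area2 < 0
    faces[flip] = faces[flip][:, ::-1]
    mesh = TriangleMesh(xyz, faces, patch_label=patch_label)
    return mesh.validate()


def _jittered_rect_grid(n_vertices, rng, jitter=0.22):
    aspect = _FEMUR_SIZE[0] / _FEMUR_SIZE[1]
    ny = max(3, int(np.sqrt(n_vertices / aspect)))
    nx = max(3, int(np.ceil(n_vertices / ny)))
    u, v = np.meshgrid(np.linspace(0, 1, nx), np.linspace(0, 1, ny))
    uv = np.column_stack([u.ravel(), v.ravel()])
    interior = (uv[:, 0] > 0) & (uv[:, 0] < 1) & (uv[:, 1] > 0) & (uv[:, 1] < 1)
    h = np.array([1.0 / (nx - 1), 1.0 / (ny - 1)])
    uv[interior] += rng.uniform(-jitter, jitter, (interior.sum(), 2)) * h
    return uv


def _jittered_disc_grid(n_vertices, rng, jitter=0.22):
    # hexagonal-ish grid clipped to the unit disc
    n_grid = int(np.ceil(np.sqrt(n_vertices * 4 / np.pi)))
    lin = np.linspace(-1, 1, n_grid)
    u, v = np.meshgrid(lin, lin)
    u = u + np.tile([0.0, 1.0 / (n_grid - 1)], (n_grid + 1) // 2)[:n_grid][:, None] * 0.5
    uv = np.column_stack([u.ravel(), v.ravel()])
    h = 2.0 / (n_grid - 1)
    r = np.linalg.norm(uv, axis=1)
    keep = r <= 1.0 - 0.75 * h          # clearance to the rim ring
    uv = uv[keep]
    interior = np.linalg.norm(uv, axis=1) < 1.0 - 1.8 * h
    uv[interior] += rng.uniform(-jitter, jitter, (interior.sum(), 2)) * h
    # ring of boundary points at roughly the grid spacing
    n_rim = max(16, int(np.ceil(2.0 * np.pi / h)))
    ang = np.linspace(0, 2 * np.pi, n_rim, endpoint=False)
    rim = np.column_stack([np.cos(ang), np.sin(ang)])
    return np.vstack([uv, rim])


def _femur_surface(uv):
    """Saddle sheet: two posterior condyles plus an anterior groove."""
    u, v = uv[:, 0], uv[:, 1]
    x = (u - 0.5) * _FEMUR_SIZE[0]
    y = (v - 0.5) * _FEMUR_SIZE[1]
    z = (
        9.0 * np.exp(-(((u - 0.28) / 0.16) ** 2 + ((v - 0.70) / 0.22) ** 2))
        + 9.0 * np.exp(-(((u - 0.72) / 0.16) ** 2 + ((v - 0.70) / 0.22) ** 2))
        - 5.0 * np.exp(-(((u - 0.5) / 0.10) ** 2 + ((v - 0.25) / 0.28) ** 2))
        + 3.0 * np.sin(np.pi * u) * (1 - v)
    )
    return np.column_stack([x, y, z])


def _tibia_surface(uv, patch_label):
    u, v = uv[:, 0], uv[:, 1]
    a, b = _TIBIA_SIZE[0] / 2, _TIBIA_SIZE[1] / 2
    x = u * a
    y = v * b
    r2 = u ** 2 + v ** 2
    dome = 4.0 if patch_label == "medial_tibia" else 5.0
    z = -dome * (1.0 - r2) - 1.5 * np.exp(-((u / 0.5) ** 2 + (v / 0.5) ** 2))
    offset = -50.0 if patch_label == "medial_tibia" else 50.0
    return np.column_stack([x + offset, y, z])


def patch_parameters(mesh: TriangleMesh) -> np.ndarray:
    """Recover normalised parametric coordinates (u, v) from geometry.

    The canonical surfaces use affine (x, y) parameterisations, so the
    in-plane coordinates invert exactly; regions for effect maps are
    defined in this (u, v) frame.
    """
    x, y = mesh.vertices[:, 0], mesh.vertices[:, 1]
    if mesh.patch_label == "femur":
        return np.column_stack([x / _FEMUR_SIZE[0] + 0.5, y / _FEMUR_SIZE[1] + 0.5])
    offset = -50.0 if mesh.patch_label == "medial_tibia" else 50.0
    return np.column_stack([(x - offset) / (_TIBIA_SIZE[0] / 2),
                            y / (_TIBIA_SIZE[1] / 2)])


# regions as smooth bumps in the parameter frame; synthetic analogues of
# anatomical names, not anatomical claims
def _bump(uv, center, width):
    d2 = ((uv[:, 0] - center[0]) / width[0]) ** 2 \
        + ((uv[:, 1] - center[1]) / width[1]) ** 2
    return np.exp(-d2)


_REGION_DEFS = {
    "femur": {
        "trochlea": ((0.5, 0.25), (0.28, 0.26)),
        "anterior_femur": ((0.5, 0.30), (0.30, 0.25)),
        "medial_femur": ((0.25, 0.65), (0.18, 0.25)),
        "lateral_femur": ((0.75, 0.65), (0.18, 0.25)),
        "global": None,
    },
    "medial_tibia": {
        "medial_tibia_center": ((0.0, 0.0), (0.55, 0.55)),
        "global": None,
    },
    "lateral_tibia": {
        "lateral_tibia_center": ((0.0, 0.0), (0.55, 0.55)),
        "global": None,
    },
}


def region_weight(mesh: TriangleMesh, region: str) -> np.ndarray:
    """Smooth [0, 1] membership of each vertex in a named region."""
    defs = _REGION_DEFS[mesh.patch_label]
    known = {r for patch in _REGION_DEFS.values() for r in patch}
    if region not in known:
        raise ValueError(f"unknown region {region!r}; known: {sorted(known)}")
    if region not in defs:
        return np.zeros(mesh.n_vertices)
    if defs[region] is None:
        return np.ones(mesh.n_vertices)
    center, width = defs[region]
    return _bump(patch_parameters(mesh), center, width)


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Distributional knobs of the synthetic cohort.

    Defaults reproduce the published cohort overview: 287 subjects,
    64/287 male, age 66.4 +/- 7.1 years, BMI 28.0 +/- 5.2 kg/m^2,
    height 167.1 +/- 10.0 cm, weight 78.2 +/- 15.8 kg,
    Kellgren-Lawrence counts (54, 76, 63, 84, 10), joint-space
    narrowing present in 132/287 (medial) and 43/287 (lateral) knees,
    and MOAKS compartment prevalences per the same table.  The height
    shift between sexes is applied mean-preservingly, so the overall
    height mean stays at its configured value.
    """

    n_subjects: int = 287
    prop_male: float = 64 / 287
    age_mean: float = 66.4
    age_sd: float = 7.1
    bmi_mean: float = 28.0
    bmi_sd: float = 5.2
    height_mean: float = 167.1
    height_sd: float = 10.0
    weight_mean: float = 78.2
    weight_sd: float = 15.8
    sex_height_shift: float = 8.0        # cm, male minus female
    sex_weight_shift: float = 10.0       # kg, male minus female
    kl_probs: tuple = (54 / 287, 76 / 287, 63 / 287, 84 / 287, 10 / 287)
    jsn_prevalence: tuple = (132 / 287, 43 / 287)          # medial, lateral
    pathology_prevalence: dict = field(default_factory=lambda: {
        "extrusion_medial": 168 / 287,
        "extrusion_lateral": 44 / 287,
        "bml_medial": 99 / 287,
        "bml_lateral": 68 / 287,
        "bml_pf": 162 / 287,
        "ost_medial": 225 / 287,
        "ost_lateral": 182 / 287,
        "ost_pf": 190 / 287,
    })
    grade_probs: tuple = (0.5, 0.3, 0.2)  # P(grade = 1, 2, 3 | present)
    # subregions whose involvement is disproportionately rare (the
    # anterior lateral meniscus is the classic example); their carrier
    # and co-involvement propensities are scaled down by this factor
    rare_subregions: tuple = ("extrusion_lateral_anterior",)
    rare_factor: float = 0.25
    seed: int = 0

    def __post_init__(self):
        for p in (self.prop_male, *self.kl_probs, *self.jsn_prevalence,
                  *self.pathology_prevalence.values(), *self.grade_probs):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for sd in (self.age_sd, self.bmi_sd, self.height_sd, self.weight_sd):
            if sd <= 0:
                raise ValueError("SDs must be > 0")
        if abs(sum(self.kl_probs) - 1) > 1e-9:
            raise ValueError("KL probabilities must sum to 1")
        if abs(sum(self.grade_probs) - 1) > 1e-9:
            raise ValueError("conditional grade probabilities must sum to 1")


def sample_cohort(spec: CohortSpec | None = None,
                  n_subjects: int | None = None,
                  seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort covariate table from the spec's distributions.

    Demographics are normal (height and weight shifted by sex around
    the configured overall means); grades are drawn per compartment
    prevalence, with subregion scores constructed so their maximum
    equals the drawn compartmental grade.
    """
    spec = spec or CohortSpec()
    if n_subjects is not None or seed is not None:
        spec = replace(spec,
                       n_subjects=n_subjects or spec.n_subjects,
                       seed=spec.seed if seed is None else seed)
    n = spec.n_subjects
    rng = _substream(spec.seed, "cohort")
    sex = (rng.uniform(size=n) < spec.prop_male).astype(int)
    dev = sex - spec.prop_male                      # mean-zero shift carrier
    height = rng.normal(spec.height_mean, spec.height_sd, n) \
        + spec.sex_height_shift * dev
    weight = rng.normal(spec.weight_mean, spec.weight_sd, n) \
        + spec.sex_weight_shift * dev
    data = {
        "sex": sex,
        "age": rng.normal(spec.age_mean, spec.age_sd, n),
        "bmi": rng.normal(spec.bmi_mean, spec.bmi_sd, n),
        "height": height,
        "weight": weight,
        "kl_grade": rng.choice(5, size=n, p=spec.kl_probs),
    }
    grade_support = np.array([1, 2, 3])
    for side, prev in zip(("medial", "lateral"), spec.jsn_prevalence):
        present = rng.uniform(size=n) < prev
        g = np.where(present, rng.choice(grade_support, size=n,
                                         p=spec.grade_probs), 0)
        data[f"jsn_{side}"] = g
    for comp, cols in MOAKS_SUBREGIONS.items():
        prev = spec.pathology_prevalence[comp]
        present = rng.uniform(size=n) < prev
        gmax = np.where(present, rng.choice(grade_support, size=n,
                                            p=spec.grade_probs), 0)
        k = len(cols)
        propensity = np.array([
            spec.rare_factor if c in spec.rare_subregions else 1.0
            for c in cols])
        carrier = rng.choice(k, size=n, p=propensity / propensity.sum())
        scores = np.zeros((n, k), dtype=int)
        # non-carrier subregions: co-involved with prob 0.4 (scaled for
        # rare subregions), grade <= compartment max
        extra = rng.uniform(size=(n, k)) < 0.4 * propensity
        for j in range(k):
            cap = np.maximum(gmax, 1)
            draw = 1 + (rng.uniform(size=n) * cap).astype(int)
            scores[:, j] = np.where(extra[:, j], np.minimum(draw, gmax), 0)
        scores[np.arange(n), carrier] = gmax
        for j, c in enumerate(cols):
            data[c] = scores[:, j]
    frame = pd.DataFrame(data)
    frame.insert(0, "subject_id", [f"S{i:05d}" for i in range(n)])
    validate_cohort(frame)
    return frame


# ---------------------------------------------------------------------------
# effect maps
# ---------------------------------------------------------------------------

@dataclass
class EffectMapSet:
    """Ground-truth spatial effects (per patch), mm per covariate unit.

    ``references`` centre each covariate so the baseline map stays the
    cohort-typical thickness; the linear predictor uses
    ``effect_k * (x_k - ref_k)``.  Slopes are unaffected by centring.
    """

    baseline: dict                    # patch -> (V,) mm
    effects: dict                     # covariate -> patch -> (V,) mm/unit
    references: dict                  # covariate -> reference value
    noise_sd: float = 0.3             # mm
    noise_fwhm_factor: float = 3.0    # x mean edge length
    clip_fraction: float = 0.0

    def covariates(self):
        return list(self.effects)

    def linear_predictor(self, patch: str, row: dict) -> np.ndarray:
        out = self.baseline[patch].copy()
        for cov, maps in self.effects.items():
            x = _covariate_value(row, cov)
            out += maps[patch] * (x - self.references.get(cov, 0.0))
        return out


def _covariate_value(row: dict, cov: str) -> float:
    """Raw covariate, or the compartmental (max) MOAKS grade."""
    if cov in row:
        return float(row[cov])
    if cov in MOAKS_SUBREGIONS:
        return float(max(row[c] for c in MOAKS_SUBREGIONS[cov]))
    raise KeyError(f"covariate {cov!r} not in cohort row")


# published peak magnitudes (mm per covariate unit) used as defaults;
# bump amplitudes are chosen so the *total* per-covariate map peaks at
# the published figure where regions overlap
_DEMOGRAPHIC_EFFECTS = {
    # covariate: list of (region, amplitude mm per unit)
    "sex": [("trochlea", 0.4), ("global", 0.1)],          # peak 0.5 total
    "age": [("trochlea", -0.035), ("medial_tibia_center", -0.02),
            ("lateral_tibia_center", -0.02)],
    "height": [("medial_femur", 0.015), ("global", 0.01)],  # peak 0.025
    "weight": [],
    "bmi": [],
}

_PATHOLOGY_EFFECTS = {
    "kl_grade": [("medial_femur", -0.2), ("medial_tibia_center", -0.2),
                 ("lateral_tibia_center", -0.2), ("anterior_femur", 0.2)],
    "jsn_medial": [("medial_femur", -0.4), ("medial_tibia_center", -0.4)],
    "jsn_lateral": [("lateral_femur", -0.5), ("lateral_tibia_center", -0.5)],
    "extrusion_medial": [("medial_femur", -0.3), ("medial_tibia_center", -0.3),
                         ("anterior_femur", 0.1)],
    "extrusion_lateral": [("lateral_femur", -0.4), ("lateral_tibia_center", -0.4),
                          ("anterior_femur", 0.1)],
    "bml_medial": [("medial_femur", -0.32), ("medial_tibia_center", -0.32)],
    "bml_lateral": [("lateral_femur", -0.35), ("lateral_tibia_center", -0.35)],
    "bml_pf": [("trochlea", -0.14)],
    "ost_medial": [("medial_femur", -0.24), ("anterior_femur", 0.3)],
    "ost_lateral": [("lateral_femur", -0.24), ("anterior_femur", 0.3)],
    "ost_pf": [("trochlea", -0.24), ("anterior_femur", 0.3)],
}

_REFERENCES = {"sex": 0.0, "age": 66.4, "bmi": 28.0, "height": 167.1,
               "weight": 78.2}


def _baseline_map(mesh: TriangleMesh) -> np.ndarray:
    """Smooth 1.5-2.5 mm baseline, thinner on the medial side."""
    uv = patch_parameters(mesh)
    if mesh.patch_label == "femur":
        base = 2.1 - 0.5 * _bump(uv, (0.22, 0.70), (0.25, 0.30)) \
            + 0.4 * region_weight(mesh, "trochlea") \
            + 0.2 * region_weight(mesh, "lateral_femur")
    elif mesh.patch_label == "medial_tibia":
        base = 1.9 - 0.4 * _bump(uv, (-0.4, 0.0), (0.5, 0.7)) \
            + 0.4 * _bump(uv, (0.2, 0.0), (0.6, 0.6))
    else:
        base = 2.1 + 0.5 * _bump(uv, (0.0, 0.0), (0.6, 0.6))
    return base


def make_effect_maps(canonical_meshes: dict, scenario: str = "demographics",
                     seed: int = 0, custom_effects: dict | None = None,
                     noise_sd: float = 0.3,
                     noise_fwhm_factor: float = 3.0,
                     amplitude_overrides: dict | None = None) -> EffectMapSet:
    """Baseline and per-covariate effect maps for a scenario.

    ``null`` produces identically-zero effects; ``demographics`` and
    ``pathology`` place smooth regional bumps with peak amplitudes
    defaulting to the published per-unit magnitudes; ``custom`` takes
    an explicit {covariate: [(region, amplitude), ...]} mapping.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "null":
        recipe = {}
    elif scenario == "demographics":
        recipe = dict(_DEMOGRAPHIC_EFFECTS)
    elif scenario == "pathology":
        recipe = dict(_PATHOLOGY_EFFECTS)
    else:
        recipe = dict(custom_effects or {})
    if amplitude_overrides:
        for cov, spec_list in amplitude_overrides.items():
            recipe[cov] = spec_list
    baseline = {p: _baseline_map(m) for p, m in canonical_meshes.items()}
    effects = {}
    for cov, placements in recipe.items():
        effects[cov] = {}
        for p, m in canonical_meshes.items():
            em = np.zeros(m.n_vertices)
            for region, amp in placements:
                em += amp * region_weight(m, region)
            effects[cov][p] = em
    refs = {c: _REFERENCES.get(c, 0.0) for c in effects}
    return EffectMapSet(baseline=baseline, effects=effects, references=refs,
                        noise_sd=noise_sd, noise_fwhm_factor=noise_fwhm_factor)


# ---------------------------------------------------------------------------
# subject simulation
# ---------------------------------------------------------------------------

def _smooth_noise(mesh: TriangleMesh, n_fields: int, sd: float,
                  fwhm_factor: float, rng) -> np.ndarray:
    """(n_fields, V) spatially correlated Gaussian noise at target SD."""
    v = mesh.n_vertices
    white = rng.standard_normal((n_fields, v))
    if fwhm_factor <= 0 or sd == 0:
        return sd * white
    fwhm = fwhm_factor * mesh.mean_edge_length
    from .mesh import _diffusion_operator, smoothing_iterations
    op, alpha, d_mean = _diffusion_operator(mesh, np.zeros(v, dtype=bool))
    k = smoothing_iterations(mesh, fwhm, alpha, d_mean)
    x = white.T
    for _ in range(k):
        x = op @ x
    x = x.T
    scale = x.std()
    return sd * x / max(scale, 1e-12)


@dataclass
class SubjectSample:
    """One simulated subject: geometry + true thickness per patch."""

    meshes: dict                    # patch -> TriangleMesh (subject frame)
    thickness: dict                 # patch -> SurfaceField (subject vertices)
    true_similarity: SimilarityTransform
    profiles: dict | None = None    # patch -> list of IntensityProfile


def simulate_subject(canonical_meshes: dict, covariate_row, effects: EffectMapSet,
                     geometry_jitter: dict | None = None, seed: int = 0,
                     with_profiles: bool = False,
                     noise: bool = True) -> SubjectSample:
    """Forward-model one subject.

    True thickness is the clipped linear predictor plus smooth noise,
    carried on the subject's vertices; the subject mesh is the canonical
    mesh pushed through a random similarity plus a random smooth
    thin-plate-spline bend (amplitude ``tps_amplitude`` mm).  Because
    the warp preserves connectivity, vertex i of the subject corresponds
    to canonical vertex i — the ground truth for registration tests.
    """
    jit = {"scale": (0.9, 1.1), "rot_deg": 10.0, "trans_mm": 5.0,
           "tps_amplitude": 2.0, "tps_controls": 10}
    jit.update(geometry_jitter or {})
    rng_geo = _substream(seed, "geometry")
    rng_noise = _substream(seed, "noise")

    s = rng_geo.uniform(*jit["scale"])
    ang = np.deg2rad(rng_geo.uniform(-jit["rot_deg"], jit["rot_deg"], 3))
    rot = _euler(ang)
    t = rng_geo.uniform(-jit["trans_mm"], jit["trans_mm"], 3)
    sim = SimilarityTransform(s, rot, t)

    meshes, thick, profiles = {}, {}, ({} if with_profiles else None)
    for patch, mesh in canonical_meshes.items():
        verts = sim.apply(mesh.vertices)
        amp = jit["tps_amplitude"]
        if amp > 0:
            ctrl_idx = farthest_point_sample(verts, jit["tps_controls"],
                                             seed=int(rng_geo.integers(2 ** 31)))
            ctrl = verts[ctrl_idx]
            disp = rng_geo.normal(0.0, amp / np.sqrt(3), ctrl.shape)
            warp = tps_fit(ctrl, ctrl + disp,
                           lambda_reg=1e-3 * mesh.diameter)
            verts = tps_apply(warp, verts)
        meshes[patch] = TriangleMesh(verts, mesh.faces, patch_label=patch)

        tval = effects.linear_predictor(patch, covariate_row)
        if noise and effects.noise_sd > 0:
            tval = tval + _smooth_noise(mesh, 1, effects.noise_sd,
                                        effects.noise_fwhm_factor,
                                        rng_noise)[0]
        clip = tval < 0
        effects.clip_fraction = float(clip.mean())
        tval = np.clip(tval, 0.0, None)
        thick[patch] = SurfaceField(tval, units="mm", name="thickness_mm")
        if with_profiles:
            rng_prof = _substream(seed, f"profiles:{patch}")
            profiles[patch] = [
                synthesize_profile(ti, rng=rng_prof) for ti in tval
            ]
    return SubjectSample(meshes=meshes, thickness=thick, true_similarity=sim,
                         profiles=profiles)


def _euler(angles):
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


# ---------------------------------------------------------------------------
# cohort-level composition
# ---------------------------------------------------------------------------

@dataclass
class CohortDataset:
    """A simulated cohort, either vertex-aligned or with raw subject geometry."""

    cohort: pd.DataFrame
    canonical: dict                       # patch -> TriangleMesh
    effects: EffectMapSet
    thickness_matrices: dict | None = None   # patch -> (n, V) mm, aligned
    subjects: list | None = None             # list of SubjectSample


def simulate_cohort_dataset(spec: CohortSpec | None = None,
                            scenario: str = "demographics",
                            seed: int = 0,
                            patches: tuple = ("femur",),
                            n_vertices: int = 1000,
                            aligned: bool = True,
                            geometry_jitter: dict | None = None,
                            noise_sd: float = 0.3,
                            noise_fwhm_factor: float = 3.0,
                            amplitude_overrides: dict | None = None,
                            with_profiles: bool = False) -> CohortDataset:
    """Generate a full synthetic study; deterministic given the seed.

    ``aligned=True`` evaluates thickness directly on canonical vertices
    (a (n_subjects, V) matrix per patch), exercising the statistics in
    isolation; ``aligned=False`` emits per-subject warped meshes with
    thickness on subject vertices, exercising registration too.
    """
    spec = replace(spec or CohortSpec(), seed=seed)
    cohort = sample_cohort(spec)
    canonical = {p: make_canonical_patch(p, n_vertices, seed=seed)
                 for p in patches}
    effects = make_effect_maps(canonical, scenario, seed=seed,
                               noise_sd=noise_sd,
                               noise_fwhm_factor=noise_fwhm_factor,
                               amplitude_overrides=amplitude_overrides)
    n = spec.n_subjects
    if aligned:
        rng_noise = _substream(seed, "noise")
        mats = {}
        clip_total = 0.0
        for p, mesh in canonical.items():
            pred = np.stack([
                effects.linear_predictor(p, row)
                for row in cohort.to_dict("records")
            ])
            if noise_sd > 0:
                pred = pred + _smooth_noise(mesh, n, noise_sd,
                                            noise_fwhm_factor, rng_noise)
            clip_total += float((pred < 0).mean())
            mats[p] = np.clip(pred, 0.0, None)
        effects.clip_fraction = clip_total / max(len(canonical), 1)
        return CohortDataset(cohort, canonical, effects,
                             thickness_matrices=mats)
    subjects = [
        simulate_subject(canonical, row, effects,
                         geometry_jitter=geometry_jitter,
                         seed=int(_substream(seed, f"subject:{i}").integers(2 ** 31)),
                         with_profiles=with_profiles)
        for i, row in enumerate(cohort.to_dict("records"))
    ]
    return CohortDataset(cohort, canonical, effects, subjects=subjects)
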