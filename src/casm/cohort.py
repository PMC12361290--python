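"""Cohort covariate engineering and the catalogue of fitted models.

The cohort table carries, per subject: demographics (sex coded male=1 /
female=0, age in years, BMI kg/m^2, height cm, weight kg), radiographic
grades (Kellgren-Lawrence 0-4, OARSI joint-space narrowing 0-3 per
tibiofemoral side) and MOAKS 0-3 grades per anatomical subregion for
meniscal extrusion, bone marrow lesions (BMLs) and osteophytes.

Grades enter the models numerically, so every slope reads "mm per grade
increase".  Where MOAKS scores several subregions per compartment, the
compartmental grade is the maximum subregion score; subregional
analyses instead binarise presence/absence and are skipped when fewer
than 20 subjects are affected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spm import DesignMatrix

# sentinel returned when a binary subregional covariate affects < min subjects
EXCLUDED = "EXCLUDED"

MIN_AFFECTED = 20

DEMOGRAPHICS = ("sex", "age", "bmi", "height", "weight")

# MOAKS subregion column layout (names follow the MOAKS compartment
# subdivision: patellofemoral PF, medial/lateral tibiofemoral TF)
MOAKS_SUBREGIONS = {
    "extrusion_medial": ["extrusion_medial_anterior", "extrusion_medial_exterior"],
    "extrusion_lateral": ["extrusion_lateral_anterior", "extrusion_lateral_exterior"],
    "bml_pf": [
        "bml_pf_medial_patella", "bml_pf_lateral_patella",
        "bml_pf_medial_anterior_femur", "bml_pf_lateral_anterior_femur",
    ],
    "bml_medial": [
        "bml_med_central_femur", "bml_med_posterior_femur",
        "bml_med_anterior_tibia", "bml_med_central_tibia",
        "bml_med_posterior_tibia",
    ],
    "bml_lateral": [
        "bml_lat_central_femur", "bml_lat_posterior_femur",
        "bml_lat_anterior_tibia", "bml_lat_central_tibia",
        "bml_lat_posterior_tibia",
    ],
    "ost_pf": [
        "ost_pf_medial_patella_superior", "ost_pf_medial_patella_inferior",
        "ost_pf_lateral_patella_superior", "ost_pf_lateral_patella_inferior",
        "ost_pf_medial_trochlea", "ost_pf_lateral_trochlea",
    ],
    "ost_medial": [
        "ost_med_central_femur", "ost_med_posterior_femur", "ost_med_tibia",
    ],
    "ost_lateral": [
        "ost_lat_central_femur", "ost_lat_posterior_femur", "ost_lat_tibia",
    ],
}

RADIOGRAPHIC = ("kl_grade", "jsn_medial", "jsn_lateral")

GRADE_RANGES = {"kl_grade": (0, 4)}    # all other grades are 0-3
_DEFAULT_GRADE_RANGE = (0, 3)

ALL_SUBREGION_COLUMNS = [c for cols in MOAKS_SUBREGIONS.values() for c in cols]
ALL_COLUMNS = list(DEMOGRAPHICS) + list(RADIOGRAPHIC) + ALL_SUBREGION_COLUMNS


def validate_cohort(frame: pd.DataFrame) -> pd.DataFrame:
    """Check column presence, grade ranges and missing demographics."""
    missing_cols = [c for c in ALL_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks columns: {missing_cols}")
    demo = frame[list(DEMOGRAPHICS)]
    if demo.isna().any().any():
        raise ValueError("missing demographics for modeled subjects")
    if not frame["sex"].isin([0, 1]).all():
        raise ValueError("sex must be coded male=1 / female=0")
    for col in list(RADIOGRAPHIC) + ALL_SUBREGION_COLUMNS:
        lo, hi = GRADE_RANGES.get(col, _DEFAULT_GRADE_RANGE)
        v = frame[col]
        if ((v < lo) | (v > hi)).any():
            raise ValueError(f"grades in {col!r} outside [{lo}, {hi}]")
    return frame


def compartment_max_score(subregion_scores) -> np.ndarray:
    """Compartmental grade = maximum subregion score (per subject).

    Accepts a (n_subjects, n_subregions) array or DataFrame slice.
    """
    arr = np.asarray(subregion_scores, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] == 0:
        raise ValueError("compartment has no subregion scores")
    if ((arr < 0) | (arr > 4)).any():
        raise ValueError("subregion scores outside the graded range")
    return arr.max(axis=1)


def binarize_subregion(scores, min_affected: int = MIN_AFFECTED):
    """Presence/absence covariate for one subregion, or EXCLUDED.

    Returns the 0/1 vector (score > 0) unless fewer than ``min_affected``
    subjects are affected, in which case the EXCLUDED sentinel is
    returned — subregional analyses on such rare pathologies would lean
    on too small a group.
    """
    s = np.asarray(scores, dtype=np.float64)
    binary = (s > 0).astype(np.float64)
    if binary.sum() < min_affected:
        return EXCLUDED
    return binary


@dataclass(frozen=True)
class ModelSpec:
    """One vertex-wise model: covariate list, contrast, recoding rule."""

    name: str
    covariates: tuple            # ordered, starting with "intercept"
    contrast: str
    adjustment_set: tuple = ()
    recoding: str = "raw"        # raw | compartment_max | binary_presence
    exploratory: bool = False

    def __post_init__(self):
        if self.contrast not in self.covariates:
            raise ValueError(f"{self.name}: contrast not among covariates")
        if not set(self.adjustment_set) <= set(self.covariates):
            raise ValueError(f"{self.name}: adjustment set not among covariates")


_PATHOLOGY_ADJUST = ("sex", "age", "height")

PATHOLOGY_CONTRASTS = (
    "kl_grade", "jsn_medial", "jsn_lateral",
    "extrusion_medial", "extrusion_lateral",
    "bml_medial", "bml_lateral", "bml_pf",
    "ost_medial", "ost_lateral", "ost_pf",
)


def model_catalogue() -> list:
    """The full set of model specifications fitted by the analysis.

    (a) univariable demographic models; (b) the multivariable
    demographic model over sex, age, weight and height (BMI dropped for
    collinearity with height and weight), one entry per contrast;
    (c) compartmental pathology models adjusted for sex, age and height;
    (d) joint-space-narrowing sensitivity models additionally adjusted
    for ipsilateral meniscal extrusion; (e) binary subregional variants,
    subject to the fewer-than-20-affected exclusion at design-build
    time; plus an exploratory radiographic-OA (KL >= 2) binary model.
    """
    specs = []
    for c in DEMOGRAPHICS:
        specs.append(ModelSpec(
            name=f"uni_{c}", covariates=("intercept", c), contrast=c))
    multi_cov = ("intercept", "sex", "age", "weight", "height")
    for c in ("sex", "age", "weight", "height"):
        specs.append(ModelSpec(
            name=f"multi_demo_{c}", covariates=multi_cov, contrast=c,
            adjustment_set=tuple(x for x in multi_cov[1:] if x != c)))
    for c in PATHOLOGY_CONTRASTS:
        recode = "compartment_max" if c in MOAKS_SUBREGIONS else "raw"
        specs.append(ModelSpec(
            name=c,
            covariates=("intercept", *_PATHOLOGY_ADJUST, c),
            contrast=c,
            adjustment_set=_PATHOLOGY_ADJUST,
            recoding=recode))
    # JSN sensitivity: additionally adjust for ipsilateral meniscal extrusion
    for side in ("medial", "lateral"):
        ext = f"extrusion_{side}"
        jsn = f"jsn_{side}"
        specs.append(ModelSpec(
            name=f"{jsn}_adj_extrusion",
            covariates=("intercept", *_PATHOLOGY_ADJUST, ext, jsn),
            contrast=jsn,
            adjustment_set=(*_PATHOLOGY_ADJUST, ext),
            recoding="compartment_max"))
    for comp, subregions in MOAKS_SUBREGIONS.items():
        for sub in subregions:
            specs.append(ModelSpec(
                name=f"binary_{sub}",
                covariates=("intercept", *_PATHOLOGY_ADJUST, sub),
                contrast=sub,
                adjustment_set=_PATHOLOGY_ADJUST,
                recoding="binary_presence"))
    specs.append(ModelSpec(
        name="roa", covariates=("intercept", *_PATHOLOGY_ADJUST, "roa"),
        contrast="roa", adjustment_set=_PATHOLOGY_ADJUST,
        recoding="raw", exploratory=True))
    return specs


def get_model(name: str) -> ModelSpec:
    for spec in model_catalogue():
        if spec.name == name:
            return spec
    raise KeyError(f"no model named {name!r} in the catalogue")


def build_design(frame: pd.DataFrame, spec: ModelSpec,
                 min_affected: int = MIN_AFFECTED):
    """Materialise a DesignMatrix for one model on a cohort table.

    Applies the spec's recoding (compartmental maxima, binarisation,
    the KL >= 2 radiographic-OA cut) before assembling columns.
    Returns EXCLUDED when a binary subregional covariate affects fewer
    than ``min_affected`` subjects.
    """
    work = frame.copy()
    for comp, cols in MOAKS_SUBREGIONS.items():
        if comp in spec.covariates:
            work[comp] = compartment_max_score(work[cols].to_numpy())
    if spec.recoding == "binary_presence":
        b = binarize_subregion(work[spec.contrast].to_numpy(), min_affected)
        if b is EXCLUDED:
            return EXCLUDED
        work[spec.contrast] = b
    if "roa" in spec.covariates:
        work["roa"] = (work["kl_grade"] >= 2).astype(float)
    return DesignMatrix.from_frame(work, spec.covariates[1:], spec.contrast)
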