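"""Cohort-level validation experiments on synthetic ground truth.

These are the standard operating checks for a surface-statistics
pipeline: family-wise error under the global null, and recovery of a
planted spatial effect at the study's sample size.  Both are driven by
a single root seed and are shared by the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np

from .cohort import build_design, get_model
from .spm import DesignMatrix, run_spm
from .synthetic import CohortSpec, simulate_cohort_dataset


def null_fwer_experiment(n_replicates: int = 200, n_subjects: int = 100,
                         n_vertices: int = 1000, noise_sd: float = 0.3,
                         noise_fwhm_factor: float = 3.0,
                         alpha: float = 0.05, seed: int = 1) -> dict:
    """Fraction of null cohorts with any vertex passing min(RFT, FDR).

    Each replicate simulates a cohort with *no* true effects (smooth
    Gaussian noise only) and tests an uninformative covariate.  Under
    valid family-wise control the fraction of replicates with a
    non-empty significance mask stays at or below alpha up to
    Monte-Carlo error.
    """
    n_any = 0
    for r in range(n_replicates):
        rep_seed = int((seed * 100_003 + r) % (2 ** 31))
        ds = simulate_cohort_dataset(
            CohortSpec(n_subjects=n_subjects), scenario="null",
            seed=rep_seed, patches=("femur",), n_vertices=n_vertices,
            noise_sd=noise_sd, noise_fwhm_factor=noise_fwhm_factor)
        rng = np.random.default_rng(rep_seed + 1)
        cov = rng.standard_normal(n_subjects)
        design = DesignMatrix(
            np.column_stack([np.ones(n_subjects), cov]),
            ("intercept", "noise_covariate"), "noise_covariate")
        res = run_spm(ds.thickness_matrices["femur"], design,
                      ds.canonical["femur"], alpha=alpha)
        n_any += bool(res.significance_mask.any())
    return {
        "fwer": n_any / n_replicates,
        "n_replicates": n_replicates,
        "bound": alpha + 2 * np.sqrt(alpha * (1 - alpha) / n_replicates),
    }


def effect_recovery_experiment(n_seeds: int = 10, n_subjects: int = 287,
                               n_vertices: int = 1000,
                               noise_sd: float = 0.3,
                               contrast: str = "sex",
                               model: str = "multi_demo_sex",
                               seed: int = 1) -> dict:
    """Recovery of the planted demographic effect maps at cohort scale.

    For each seed, a demographics-scenario cohort is simulated, the
    corresponding multivariable model fitted, and the estimated
    contrast beta map compared with the generator's ground-truth map:
    Pearson correlation, plus the fraction of strongly-affected
    vertices (above half the peak effect) inside the significance mask.
    """
    cors, overlaps = [], []
    for s in range(n_seeds):
        rep_seed = int((seed * 99_991 + s) % (2 ** 31))
        ds = simulate_cohort_dataset(
            CohortSpec(n_subjects=n_subjects), scenario="demographics",
            seed=rep_seed, patches=("femur",), n_vertices=n_vertices,
            noise_sd=noise_sd)
        design = build_design(ds.cohort, get_model(model))
        res = run_spm(ds.thickness_matrices["femur"], design,
                      ds.canonical["femur"])
        truth = ds.effects.effects[contrast]["femur"]
        beta = res.beta_maps[contrast].values
        cors.append(float(np.corrcoef(beta, truth)[0, 1]))
        strong = np.abs(truth) > 0.5 * np.abs(truth).max()
        overlaps.append(float((res.significance_mask & strong).sum()
                              / max(strong.sum(), 1)))
    return {
        "correlations": cors,
        "median_correlation": float(np.median(cors)),
        "overlaps": overlaps,
        "median_overlap": float(np.median(overlaps)),
        "n_seeds": n_seeds,
    }
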