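"""End-to-end orchestration: simulate -> measure -> register -> SPM -> export.

One run = one output directory containing the canonical surfaces with
result fields (PLY + colour PLY), per-subject registration reports,
the cohort-average thickness and SD maps, per-model JSON summaries and
a manifest (config, seeds) sufficient to reproduce the run
bit-identically on the same platform.

The analysis scripts under ``analysis/`` are thin drivers over this
module; ``run_pipeline`` is the single entry point they share.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as mesh_io
from .cohort import EXCLUDED, build_design, get_model, model_catalogue
from .mesh import SurfaceField, smooth_field
from .registration import register_to_canonical, registration_report, transfer_field
from .spm import run_spm
from .synthetic import CohortSpec, simulate_cohort_dataset

log = logging.getLogger("casm.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full run (synthetic input)."""

    out_dir: str
    seed: int = 0
    n_subjects: int = 287
    n_vertices: int = 1000
    patches: tuple = ("femur",)
    scenario: str = "demographics"
    models: tuple = ("uni_sex",)
    alpha: float = 0.05
    smoothing_fwhm: float = 0.0          # mm; 0 = no pre-smoothing (default)
    use_registration: bool = False       # False: vertex-aligned simulation
    noise_sd: float = 0.3
    noise_fwhm_factor: float = 3.0
    registration: dict = field(default_factory=lambda: {
        "n_control": 400, "iterations": 5})

    def validate(self):
        if not 0 < self.alpha < 1:
            raise PipelineError("config: alpha must be in (0, 1)")
        if self.smoothing_fwhm < 0:
            raise PipelineError("config: smoothing_fwhm must be >= 0")
        known = {m.name for m in model_catalogue()}
        bad = [m for m in self.models if m not in known]
        if bad:
            raise PipelineError(f"config: unknown model names {bad}")
        return self

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["patches"] = tuple(raw.get("patches", ("femur",)))
        raw["models"] = tuple(raw.get("models", ("uni_sex",)))
        return cls(**raw).validate()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:                 # noqa: BLE001
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("simulate")
def _simulate(cfg: RunConfig):
    from dataclasses import replace
    spec = replace(CohortSpec(), n_subjects=cfg.n_subjects)
    return simulate_cohort_dataset(
        spec, scenario=cfg.scenario, seed=cfg.seed, patches=cfg.patches,
        n_vertices=cfg.n_vertices, aligned=not cfg.use_registration,
        noise_sd=cfg.noise_sd, noise_fwhm_factor=cfg.noise_fwhm_factor)


@_stage("register")
def _register(cfg: RunConfig, dataset, out: Path):
    """Register every subject and assemble canonical-aligned matrices."""
    mats, reports = {}, []
    for patch, canonical in dataset.canonical.items():
        cols = []
        for i, subj in enumerate(dataset.subjects):
            res = register_to_canonical(
                subj.meshes[patch], canonical, seed=cfg.seed + i,
                **cfg.registration)
            reports.append({"subject": i, "patch": patch,
                            **registration_report(res)})
            f = transfer_field(subj.thickness[patch], subj.meshes[patch],
                               res["correspondence"])
            col = np.where(f.missing_mask, np.nan, f.values)
            cols.append(col)
        mats[patch] = np.stack(cols)
    (out / "registration_reports.json").write_text(
        json.dumps(reports, indent=1))
    n_missing = sum(int(np.isnan(m).sum()) for m in mats.values())
    log.info("registration: %d subjects, %d missing correspondences",
             len(dataset.subjects), n_missing)
    return mats


@_stage("spm")
def _run_models(cfg: RunConfig, dataset, mats, out: Path):
    summaries = {}
    for name in cfg.models:
        spec = get_model(name)
        design = build_design(dataset.cohort, spec)
        if design is EXCLUDED:
            log.info("model %s excluded by the n<20 rule", name)
            summaries[name] = {"excluded": True}
            continue
        per_patch = {}
        for patch, mesh in dataset.canonical.items():
            y = mats[patch]
            if cfg.smoothing_fwhm > 0:
                y = np.stack([
                    smooth_field(SurfaceField(row, "mm"), mesh,
                                 cfg.smoothing_fwhm).values
                    for row in y])
            res = run_spm(y, design, mesh, alpha=cfg.alpha,
                          missing_matrix=np.isnan(mats[patch]))
            per_patch[patch] = res
            _export_result(res, mesh, out / f"{name}_{patch}")
        summaries[name] = {p: r.summary() for p, r in per_patch.items()}
    (out / "model_summaries.json").write_text(json.dumps(summaries, indent=1))
    return summaries


def _export_result(res, mesh, stem: Path):
    fields = {
        "beta": res.beta_maps[res.design.contrast_name],
        "t": res.t_map,
        "p": res.p_map,
        "mask": SurfaceField(res.significance_mask.astype(float),
                             name="mask"),
    }
    mesh_io.save_mesh(mesh, fields, str(stem) + ".ply", format="ply")
    mesh_io.save_colored_ply(mesh, fields["beta"], str(stem) + "_color.ply",
                             significance_mask=res.significance_mask)
    sidecar = res.summary()
    Path(str(stem) + ".json").write_text(json.dumps(sidecar, indent=1))


@_stage("average_maps")
def _cohort_maps(dataset, mats, out: Path):
    """Cohort mean thickness and its SD on the canonical surfaces."""
    for patch, mesh in dataset.canonical.items():
        y = mats[patch]
        mean = np.nanmean(y, axis=0)
        sd = np.nanstd(y, axis=0, ddof=1)
        fields = {
            "mean_thickness_mm": SurfaceField(mean, "mm",
                                              name="mean_thickness_mm"),
            "sd_thickness_mm": SurfaceField(sd, "mm", name="sd_thickness_mm"),
        }
        mesh_io.save_mesh(mesh, fields, out / f"cohort_{patch}.ply",
                          format="ply")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the model summaries.

    Any stage error aborts with a stage-named PipelineError; partial
    outputs are kept next to a FAILED marker file.
    """
    cfg = config.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        dataset = _simulate(cfg)
        dataset.cohort.to_csv(out / "cohort.csv", index=False)
        for patch, mesh in dataset.canonical.items():
            mesh_io.save_mesh(mesh, None, out / f"canonical_{patch}.ply",
                              format="ply")
        if cfg.use_registration:
            mats = _register(cfg, dataset, out)
        else:
            mats = dataset.thickness_matrices
        _cohort_maps(dataset, mats, out)
        summaries = _run_models(cfg, dataset, mats, out)
    except Exception:
        (out / "FAILED").write_text("see logs")
        raise
    manifest = {
        "config": {**asdict(cfg), "patches": list(cfg.patches),
                   "models": list(cfg.models)},
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return summaries
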