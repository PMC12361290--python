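"""Vertex-wise general linear models with random-field-theory and FDR
multiple-comparison control (statistical parametric mapping on surfaces).

For each canonical vertex v the model is

    y(v) = X beta(v) + e(v),      e ~ N(0, sigma^2(v) I)

fitted by ordinary least squares across subjects; the contrast of
interest c gives a t-field t(v) = c'beta / sqrt(c'(X'X)^-1 c sigma^2).
Two corrected thresholds are computed on |t|:

* the random-field-theory peak threshold, the smallest t at which the
  expected Euler characteristic of the excursion set of a smooth
  t-field with the estimated resel counts drops to the (per-tail)
  level, and
* the Benjamini-Hochberg FDR threshold on the two-sided vertex
  p-values;

the final threshold is the minimum (less conservative) of the two, the
convention of the SurfStat surface-statistics tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .mesh import SurfaceField, TriangleMesh, mesh_metrics


class DesignError(ValueError):
    """The design matrix is unusable (rank deficiency, bad contrast...)."""


@dataclass(frozen=True)
class DesignMatrix:
    """Subjects-by-covariates design with a named contrast column.

    The first column is expected to be an all-ones intercept; ordinal
    grades enter as plain numeric columns (per-grade-increase slopes).
    """

    matrix: np.ndarray
    columns: tuple
    contrast_name: str

    def __post_init__(self):
        x = np.asarray(self.matrix, dtype=np.float64)
        object.__setattr__(self, "matrix", x)
        object.__setattr__(self, "columns", tuple(self.columns))
        if x.ndim != 2 or x.shape[1] != len(self.columns):
            raise DesignError("matrix shape does not match column names")
        if self.contrast_name not in self.columns:
            raise DesignError(f"contrast {self.contrast_name!r} not in columns")
        if "intercept" not in self.columns:
            raise DesignError("design must contain an intercept column")
        n, p = x.shape
        if n <= p + 1:
            raise DesignError(f"need n > p + 1 subjects (n={n}, p={p})")
        rank = np.linalg.matrix_rank(x)
        if rank < p:
            bad = _collinear_columns(x, self.columns)
            raise DesignError(f"design is rank deficient; collinear columns: {bad}")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_params(self) -> int:
        return self.matrix.shape[1]

    @property
    def contrast(self) -> np.ndarray:
        c = np.zeros(self.n_params)
        c[self.columns.index(self.contrast_name)] = 1.0
        return c

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, covariates, contrast: str):
        """Build from a cohort table; an intercept column is prepended."""
        cols = ["intercept"] + [c for c in covariates if c != "intercept"]
        x = np.column_stack(
            [np.ones(len(frame))]
            + [frame[c].to_numpy(dtype=np.float64) for c in cols[1:]]
        )
        return cls(x, cols, contrast)


def _collinear_columns(x, names):
    """Name columns involved in the rank deficiency (diagnostic only)."""
    bad = []
    for j in range(x.shape[1]):
        others = np.delete(x, j, axis=1)
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(x):
            bad.append(names[j])
    return bad or list(names)


@dataclass
class SPMResult:
    """Everything run_spm produces for one patch and one contrast."""

    design: DesignMatrix
    beta_maps: dict
    t_map: SurfaceField
    p_map: SurfaceField
    df: int
    sigma2: np.ndarray
    fwhm_est: float
    resels: tuple
    t_threshold_rft: float
    t_threshold_fdr: float
    alpha: float
    analysis_mask: np.ndarray          # vertices retained for analysis
    residuals: np.ndarray | None = None

    @property
    def t_threshold_final(self) -> float:
        return min(self.t_threshold_rft, self.t_threshold_fdr)

    @property
    def significance_mask(self) -> np.ndarray:
        t = self.t_map.values
        mask = np.zeros(len(t), dtype=bool)
        ok = ~self.t_map.missing_mask
        mask[ok] = np.abs(t[ok]) >= self.t_threshold_final
        return mask

    def summary(self) -> dict:
        return {
            "contrast": self.design.contrast_name,
            "columns": list(self.design.columns),
            "n_subjects": self.design.n_subjects,
            "df": self.df,
            "fwhm_mm": self.fwhm_est,
            "resels": list(self.resels),
            "t_threshold_rft": self.t_threshold_rft,
            "t_threshold_fdr": self.t_threshold_fdr,
            "t_threshold_final": self.t_threshold_final,
            "alpha": self.alpha,
            "n_significant": int(self.significance_mask.sum()),
            "n_analyzed": int(self.analysis_mask.sum()),
        }


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------

def fit_vertex_glm(thickness_matrix: np.ndarray, design: DesignMatrix):
    """Ordinary least squares at every vertex simultaneously.

    Parameters
    ----------
    thickness_matrix : (n_subjects, n_vertices) array, mm
    design : DesignMatrix with the contrast of interest

    Returns a dict with ``beta`` (p, V), ``residuals`` (n, V),
    ``sigma2`` (V,), ``t`` (V,), ``p`` (V,) and ``df``.
    """
    y = np.asarray(thickness_matrix, dtype=np.float64)
    x = design.matrix
    if y.ndim != 2 or y.shape[0] != design.n_subjects:
        raise DesignError(
            f"thickness matrix has {y.shape[0]} rows for "
            f"{design.n_subjects} design rows")
    n, p = x.shape
    df = n - p
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    c = design.contrast
    denom_scale = float(c @ xtx_inv @ c)
    # zero-variance guard: RSS at round-off scale means a perfect fit
    scale = np.einsum("ij,ij->j", y, y) / n + 1.0
    degenerate = sigma2 <= 1e-20 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (c @ beta) / np.sqrt(denom_scale * sigma2)
    t = np.where(degenerate, 0.0, t)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return {"beta": beta, "residuals": resid, "sigma2": sigma2,
            "t": t, "p": pvals, "df": df}


# ---------------------------------------------------------------------------
# smoothness (resels)
# ---------------------------------------------------------------------------

def estimate_smoothness(residual_matrix: np.ndarray, mesh: TriangleMesh,
                        vertex_mask: np.ndarray | None = None):
    """Residual-based FWHM and resel counts of the error field.

    Residuals are normalised per vertex to unit norm across subjects;
    for each retained edge the squared difference of the normalised
    residuals, divided by the squared edge length, estimates the local
    roughness; pooling over edges and subjects gives the average
    gradient variance lambda of a unit-variance error field, from which

        FWHM = sqrt(4 ln 2 / lambda)

    (the Gaussian-autocorrelation relation).  Resels of the retained
    surface: R2 = area / FWHM^2, R1 = boundary / (2 FWHM),
    R0 = Euler characteristic.
    """
    r = np.asarray(residual_matrix, dtype=np.float64)
    if vertex_mask is None:
        vertex_mask = np.ones(mesh.n_vertices, dtype=bool)
    norms = np.linalg.norm(r, axis=0)
    if not (norms[vertex_mask] > 0).any():
        raise DesignError("zero-variance residuals everywhere; smoothness undefined")
    sub = _submesh_metrics(mesh, vertex_mask)
    edges, lengths = sub["edges"], sub["edge_lengths"]
    good = (norms[edges[:, 0]] > 0) & (norms[edges[:, 1]] > 0)
    edges, lengths = edges[good], lengths[good]
    if len(edges) == 0:
        raise DesignError("no usable edges for smoothness estimation")
    u = np.where(norms > 0, 1.0, 0.0)[None, :] * r / np.where(norms > 0, norms, 1.0)
    diff2 = ((u[:, edges[:, 0]] - u[:, edges[:, 1]]) ** 2).sum(axis=0)
    lam = float(np.mean(diff2 / lengths ** 2))
    if lam <= 0:
        raise DesignError("degenerate (perfectly smooth) residual field")
    fwhm = float(np.sqrt(4.0 * np.log(2.0) / lam))
    return fwhm, resel_counts(mesh, fwhm, vertex_mask)


def resel_counts(mesh: TriangleMesh, fwhm: float,
                 vertex_mask: np.ndarray | None = None) -> tuple:
    """(R0, R1, R2) of a surface at a given smoothness FWHM (mm)."""
    if vertex_mask is None:
        vertex_mask = np.ones(mesh.n_vertices, dtype=bool)
    sub = _submesh_metrics(mesh, vertex_mask)
    return (
        float(sub["euler_characteristic"]),
        sub["boundary_length"] / (2.0 * fwhm),
        sub["total_area"] / fwhm ** 2,
    )


def _submesh_metrics(mesh: TriangleMesh, vertex_mask: np.ndarray) -> dict:
    """mesh_metrics restricted to faces whose vertices are all retained."""
    if vertex_mask.all():
        return mesh_metrics(mesh)
    keep_faces = vertex_mask[mesh.faces].all(axis=1)
    sub = TriangleMesh(mesh.vertices, mesh.faces[keep_faces])
    m = mesh_metrics(sub)
    # isolated vertices (retained but no face) shouldn't count towards V
    used = np.zeros(mesh.n_vertices, dtype=bool)
    used[sub.faces.ravel()] = True
    m["euler_characteristic"] = int(used.sum() - len(sub.edges) + sub.n_faces)
    return m


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def ec_density_t(t: float, d: int, df: int) -> float:
    """Euler-characteristic densities of a t random field (Worsley).

    d = 0, 1, 2; unit-FWHM (resel) parameterisation.
    """
    t = float(t)
    if d == 0:
        return float(stats.t.sf(t, df))
    base = (1.0 + t * t / df) ** (-0.5 * (df - 1.0))
    if d == 1:
        return float(np.sqrt(4.0 * np.log(2.0)) / (2.0 * np.pi) * base)
    if d == 2:
        c = (4.0 * np.log(2.0)) / (2.0 * np.pi) ** 1.5
        gam = np.exp(special.gammaln((df + 1.0) / 2.0)
                     - special.gammaln(df / 2.0)) / np.sqrt(df / 2.0)
        return float(c * gam * t * base)
    raise ValueError("d must be 0, 1 or 2")


def expected_euler_characteristic(t: float, resels, df: int) -> float:
    return sum(r * ec_density_t(t, d, df) for d, r in enumerate(resels))


def rft_threshold(df: int, resels, alpha: float = 0.05,
                  two_sided: bool = True) -> float:
    """Peak t threshold from the expected Euler characteristic.

    Smallest t >= 0 with E[EC](t) <= alpha_tail, alpha_tail = alpha/2
    for two-sided inference; solved by bisection to 1e-6.  With resels
    (1, 0, 0) this reduces to the ordinary Student quantile.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    a_tail = alpha / 2.0 if two_sided else alpha
    fn = lambda t: expected_euler_characteristic(t, resels, df) - a_tail

    lo = 0.0
    if fn(lo) <= 0:
        return 0.0
    hi = 10.0
    while fn(hi) > 0 and hi < 1e6:
        hi *= 2.0
    return float(optimize.brentq(fn, lo, hi, xtol=1e-6))


def fdr_threshold(p_map: np.ndarray, t_map: np.ndarray, q: float = 0.05,
                  missing_mask: np.ndarray | None = None) -> float:
    """Benjamini-Hochberg step-up threshold expressed on the |t| scale.

    Runs BH at level q over the non-missing vertex p-values and returns
    the smallest |t| among rejected vertices (so ``|t| >= threshold``
    reproduces the BH rejection set); +inf when nothing is rejected.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_map, dtype=np.float64)
    t = np.asarray(t_map, dtype=np.float64)
    ok = np.isfinite(p)
    if missing_mask is not None:
        ok &= ~np.asarray(missing_mask, dtype=bool)
    if not ok.any():
        return np.inf
    reject, *_ = multipletests(p[ok], alpha=q, method="fdr_bh")
    if not reject.any():
        return np.inf
    return float(np.abs(t[ok][reject]).min())


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def run_spm(thickness_matrix: np.ndarray, design: DesignMatrix,
            mesh: TriangleMesh, alpha: float = 0.05,
            missing_matrix: np.ndarray | None = None,
            keep_residuals: bool = False) -> SPMResult:
    """Full vertex-wise analysis of one patch for one contrast.

    Vertices missing in *any* subject are dropped for all subjects
    (complete-vertex analysis) and the resels are computed on the
    retained sub-mesh.  Statistics run per patch; callers concatenate
    patches for display.
    """
    y = np.asarray(thickness_matrix, dtype=np.float64)
    if y.shape[1] != mesh.n_vertices:
        raise DesignError(
            f"thickness matrix has {y.shape[1]} vertex columns for a mesh "
            f"with {mesh.n_vertices} vertices")
    if missing_matrix is not None:
        vertex_mask = ~np.asarray(missing_matrix, dtype=bool).any(axis=0)
    else:
        vertex_mask = ~np.isnan(y).any(axis=0)
    if not vertex_mask.any():
        raise DesignError("no complete vertices to analyse")

    fit = fit_vertex_glm(y[:, vertex_mask], design)
    resid_full = np.zeros((design.n_subjects, mesh.n_vertices))
    resid_full[:, vertex_mask] = fit["residuals"]
    fwhm, resels = estimate_smoothness(resid_full, mesh, vertex_mask)
    t_rft = rft_threshold(fit["df"], resels, alpha=alpha, two_sided=True)
    t_fdr = fdr_threshold(fit["p"], fit["t"], q=alpha)

    nv = mesh.n_vertices
    miss = ~vertex_mask

    def expand(arr, units, name):
        full = np.zeros(nv)
        full[vertex_mask] = arr
        return SurfaceField(full, units=units, missing_mask=miss.copy(), name=name)

    beta_maps = {
        col: expand(fit["beta"][j], "mm_per_unit", f"beta_{col}")
        for j, col in enumerate(design.columns)
    }
    t_map = expand(fit["t"], "t", "t")
    p_full = np.ones(nv)
    p_full[vertex_mask] = fit["p"]
    p_map = SurfaceField(p_full, units="p", missing_mask=miss.copy(), name="p")
    sigma2 = np.full(nv, np.nan)
    sigma2[vertex_mask] = fit["sigma2"]

    return SPMResult(
        design=design,
        beta_maps=beta_maps,
        t_map=t_map,
        p_map=p_map,
        df=fit["df"],
        sigma2=sigma2,
        fwhm_est=fwhm,
        resels=resels,
        t_threshold_rft=t_rft,
        t_threshold_fdr=t_fdr,
        alpha=alpha,
        analysis_mask=vertex_mask,
        residuals=fit["residuals"] if keep_residuals else None,
    )
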