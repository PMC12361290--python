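"""Subject-to-canonical surface registration and field transfer.

Each subject patch is aligned to the canonical template with a
closed-form similarity transform (iterated closest point), then warped
with a thin-plate spline fitted to corresponding control points, and
finally every canonical vertex is assigned a location on the subject
surface (face + barycentric coordinates) so per-vertex fields can be
pulled onto the template.  Vertex-aligned cohort matrices are what the
vertex-wise statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import MeshValidationError, SurfaceField, SurfaceLocator, TriangleMesh


class DegenerateGeometryError(ValueError):
    """Point configuration too degenerate for the requested fit."""


# ---------------------------------------------------------------------------
# similarity (Umeyama)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityTransform:
    """x -> scale * rotation @ x + translation."""

    scale: float
    rotation: np.ndarray        # (3,3), proper orthonormal
    translation: np.ndarray     # (3,)

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64).ravel()
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if self.scale <= 0:
            raise ValueError("similarity scale must be > 0")
        if np.abs(r.T @ r - np.eye(3)).max() > 1e-8:
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(points) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, np.eye(3), np.zeros(3))

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self ∘ other (apply ``other`` first)."""
        return SimilarityTransform(
            self.scale * other.scale,
            self.rotation @ other.rotation,
            self.scale * self.rotation @ other.translation + self.translation,
        )


def similarity_align(source_points, target_points) -> tuple:
    """Closed-form least-squares similarity (Umeyama).

    Minimises sum ||s R x_i + t - y_i||^2 over proper rotations R,
    scale s > 0 and translation t.  Reflections are never returned:
    when the optimal orthogonal map is improper, the last singular
    direction is flipped, giving the best proper rotation.

    Returns ``(SimilarityTransform, rms_residual)``.
    """
    x = np.asarray(source_points, dtype=np.float64)
    y = np.asarray(target_points, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("source and target must be matching (n, 3) arrays")
    n = len(x)
    if n < 3:
        raise DegenerateGeometryError("need at least 3 point pairs")
    mx, my = x.mean(0), y.mean(0)
    xc, yc = x - mx, y - my
    cov = yc.T @ xc / n
    u, d, vt = np.linalg.svd(cov)
    if np.linalg.matrix_rank(cov, tol=1e-12 * max(d[0], 1.0)) < 2:
        raise DegenerateGeometryError("point configuration is (near-)collinear")
    s_fix = np.ones(3)
    if np.linalg.det(u) * np.linalg.det(vt) < 0:
        s_fix[-1] = -1.0
    rot = u @ np.diag(s_fix) @ vt
    var_x = (xc ** 2).sum() / n
    scale = float((d * s_fix).sum() / var_x)
    if scale <= 0:
        raise DegenerateGeometryError("optimal scale is non-positive")
    t = my - scale * rot @ mx
    tf = SimilarityTransform(scale, rot, t)
    rms = float(np.sqrt(np.mean(np.sum((tf.apply(x) - y) ** 2, axis=1))))
    return tf, rms


# ---------------------------------------------------------------------------
# thin-plate spline, 3-D kernel U(r) = r
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TPSWarp:
    """f(x) = A [x;1] + sum_i w_i U(||x - c_i||), U(r) = r."""

    control_points: np.ndarray   # (n, 3)
    kernel_weights: np.ndarray   # (n, 3)
    affine: np.ndarray           # (3, 4)
    lambda_reg: float = 0.0

    def bending_energy(self) -> float:
        """Bending energy of the warp, summed over components.

        The 3-D biharmonic kernel is conditionally positive definite in
        its -r form, so the energy is w^T (-r) w evaluated with the
        stored (+r-convention) weights; non-negative on the side-
        condition subspace.
        """
        r = np.linalg.norm(
            self.control_points[:, None, :] - self.control_points[None, :, :],
            axis=2)
        return float(-np.einsum("ic,ij,jc->", self.kernel_weights, r,
                                self.kernel_weights))


def tps_fit(source_landmarks, target_landmarks, lambda_reg: float = 0.0) -> TPSWarp:
    """Fit the 3-D thin-plate spline mapping sources onto targets.

    Solves the bordered system  [[K + lam*I, P], [P^T, 0]] [W; A] =
    [Y; 0]  with the conditionally-positive kernel K_ij = -||c_i - c_j||
    and P = [x, 1]; weights are stored negated so evaluation uses the
    U(r) = +r convention.  The side conditions P^T W = 0 make the kernel
    part orthogonal to affine functions, so with lambda=0 the warp
    interpolates, and affine target data yield zero kernel weights;
    lambda > 0 trades landmark fidelity against bending energy.
    """
    src = np.asarray(source_landmarks, dtype=np.float64)
    tgt = np.asarray(target_landmarks, dtype=np.float64)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("landmark arrays must be matching (n, 3)")
    n = len(src)
    if n < 4:
        raise DegenerateGeometryError("TPS needs at least 4 landmarks")
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be >= 0")
    k = -np.linalg.norm(src[:, None, :] - src[None, :, :], axis=2)
    p = np.hstack([src, np.ones((n, 1))])
    a = np.zeros((n + 4, n + 4))
    a[:n, :n] = k + lambda_reg * np.eye(n)
    a[:n, n:] = p
    a[n:, :n] = p.T
    b = np.vstack([tgt, np.zeros((4, 3))])
    try:
        sol = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError(
            "singular TPS system (coplanar landmarks?); try lambda_reg > 0"
        ) from exc
    w, aff = sol[:n], sol[n:]
    cond_resid = np.abs(p.T @ w).max()
    if not np.isfinite(cond_resid) or cond_resid > 1e-6 * max(1.0, np.abs(tgt).max()):
        raise DegenerateGeometryError(
            "TPS side conditions violated (ill-conditioned landmark set); "
            "try lambda_reg > 0")
    # affine stored as (3, 4) acting on [x; 1]; weights negated for +r
    affine = np.hstack([aff[:3].T, aff[3][:, None]])
    return TPSWarp(src.copy(), -w, affine, lambda_reg)


def tps_apply(warp: TPSWarp, points) -> np.ndarray:
    """Evaluate the warp at arbitrary points."""
    x = np.atleast_2d(np.asarray(points, dtype=np.float64))
    r = np.linalg.norm(x[:, None, :] - warp.control_points[None, :, :], axis=2)
    out = x @ warp.affine[:, :3].T + warp.affine[:, 3] + r @ warp.kernel_weights
    return out


# ---------------------------------------------------------------------------
# correspondence + field transfer
# ---------------------------------------------------------------------------

@dataclass
class Correspondence:
    """Location of each canonical vertex on the subject surface."""

    face_indices: np.ndarray     # (n,), -1 where missing
    barycentric: np.ndarray      # (n, 3), convex weights
    missing: np.ndarray          # (n,) bool

    def __post_init__(self):
        ok = ~self.missing
        b = self.barycentric[ok]
        if b.size and (b.min() < -1e-9 or np.abs(b.sum(1) - 1).max() > 1e-9):
            raise ValueError("barycentric weights must be convex")


def transfer_field(subject_field: SurfaceField, subject_mesh: TriangleMesh,
                   correspondence: Correspondence) -> SurfaceField:
    """Pull a subject field onto canonical vertices by barycentric interpolation.

    Canonical vertices whose correspondence is missing, or whose
    corresponded triangle touches a missing subject value, are missing
    in the result.  Barycentric convexity keeps transferred values
    inside the subject field's range.
    """
    subject_field.check_against(subject_mesh)
    n = len(correspondence.face_indices)
    vals = np.zeros(n)
    missing = correspondence.missing.copy()
    ok = ~missing
    faces = subject_mesh.faces[correspondence.face_indices[ok]]
    corner_vals = subject_field.values[faces]
    corner_missing = subject_field.missing_mask[faces].any(axis=1)
    vals[ok] = np.einsum("ij,ij->i", correspondence.barycentric[ok], corner_vals)
    idx = np.where(ok)[0]
    missing[idx[corner_missing]] = True
    vals[missing] = 0.0
    return SurfaceField(vals, units=subject_field.units, missing_mask=missing,
                        name=subject_field.name)


# ---------------------------------------------------------------------------
# full pipeline: similarity ICP + iterated TPS refinement
# ---------------------------------------------------------------------------

def farthest_point_sample(points: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Indices of a seeded farthest-point subsample (first point random)."""
    pts = np.asarray(points)
    n = min(n, len(pts))
    rng = np.random.default_rng(seed)
    chosen = np.empty(n, dtype=np.int64)
    chosen[0] = rng.integers(len(pts))
    d = np.linalg.norm(pts - pts[chosen[0]], axis=1)
    for i in range(1, n):
        chosen[i] = int(np.argmax(d))
        d = np.minimum(d, np.linalg.norm(pts - pts[chosen[i]], axis=1))
    return chosen


def _icp_similarity(subject: TriangleMesh, canonical: TriangleMesh,
                    seed: int, locator: SurfaceLocator | None = None,
                    n_sample: int = 500, max_iter: int = 50,
                    n_surface_iter: int = 300, tol: float = 1e-10):
    """Iterative closest point with a similarity model, canonical -> subject.

    Coarse vertex-to-vertex iterations first (cheap), then a few
    vertex-to-surface iterations to remove the tessellation bias of
    nearest-vertex pairing.
    """
    can_idx = farthest_point_sample(canonical.vertices, n_sample, seed)
    can_pts = canonical.vertices[can_idx]
    tree = cKDTree(subject.vertices)
    tf = SimilarityTransform.identity()
    prev = np.inf
    for _ in range(max_iter):
        moved = tf.apply(can_pts)
        d, j = tree.query(moved)
        tf, _ = similarity_align(can_pts, subject.vertices[j])
        rms = float(np.sqrt(np.mean(d ** 2)))
        if abs(prev - rms) < tol * max(rms, 1.0):
            break
        prev = rms
    locator = locator or SurfaceLocator(subject)
    rms = prev
    prev = np.inf
    for _ in range(n_surface_iter):
        moved = tf.apply(can_pts)
        cp, d, _, _ = locator.closest_point(moved)
        tf, _ = similarity_align(can_pts, cp)
        rms = float(np.sqrt(np.mean(d ** 2)))
        if abs(prev - rms) < tol * max(rms, 1.0):
            break
        prev = rms
    return tf, rms


def register_to_canonical(subject_mesh: TriangleMesh,
                          canonical_mesh: TriangleMesh,
                          n_control: int = 400,
                          iterations: int = 5,
                          lambda_reg: float | None = None,
                          seed: int = 0,
                          rms_warn_threshold: float = 1.0):
    """Register a subject patch to the canonical template.

    1. similarity initialisation: ICP over a seeded farthest-point
       subsample of canonical vertices;
    2. TPS refinement: ``n_control`` farthest-point control points on
       the canonical surface paired with their current closest points on
       the subject surface; the warp (canonical -> subject) is refitted
       ``iterations`` times;
    3. correspondence: each warped canonical vertex is projected to its
       closest point on the subject mesh (face + barycentric weights);
       projections farther than 3x the subject's median edge length are
       marked missing (extrapolation guard).

    ``lambda_reg`` defaults to 1e-3 x canonical mesh diameter.  Returns
    a dict with the similarity, warp, correspondence, residual RMS (mm,
    mean canonical-to-subject distance after warp), and a
    ``converged`` flag (False when RMS exceeds ``rms_warn_threshold``).
    """
    if subject_mesh.patch_label != canonical_mesh.patch_label:
        raise MeshValidationError(
            f"patch mismatch: subject {subject_mesh.patch_label!r} vs "
            f"canonical {canonical_mesh.patch_label!r}")
    if lambda_reg is None:
        lambda_reg = 1e-3 * canonical_mesh.diameter

    locator = SurfaceLocator(subject_mesh)
    tf, _ = _icp_similarity(subject_mesh, canonical_mesh, seed, locator=locator)

    ctrl_idx = farthest_point_sample(canonical_mesh.vertices, n_control, seed + 1)
    ctrl = canonical_mesh.vertices[ctrl_idx]
    current = tf.apply(ctrl)
    warp = None
    for _ in range(max(1, iterations)):
        targets, _, _, _ = locator.closest_point(current)
        warp = tps_fit(ctrl, targets, lambda_reg=lambda_reg)
        current = tps_apply(warp, ctrl)

    warped_vertices = tps_apply(warp, canonical_mesh.vertices)
    cp, dist, face_idx, bary = locator.closest_point(warped_vertices)
    guard = 3.0 * float(np.median(subject_mesh.edge_lengths))
    missing = dist > guard
    corr = Correspondence(
        face_indices=np.where(missing, -1, face_idx),
        barycentric=np.where(missing[:, None], 0.0, bary),
        missing=missing,
    )
    rms = float(np.sqrt(np.mean(dist[~missing] ** 2))) if (~missing).any() else np.inf
    return {
        "similarity": tf,
        "warp": warp,
        "correspondence": corr,
        "residual_rms": rms,
        "fraction_missing": float(missing.mean()),
        "converged": rms <= rms_warn_threshold,
    }


def registration_report(result: dict) -> dict:
    """JSON-serialisable per-subject registration summary."""
    tf = result["similarity"]
    return {
        "scale": tf.scale,
        "rotation": tf.rotation.tolist(),
        "translation": tf.translation.tolist(),
        "residual_rms_mm": result["residual_rms"],
        "fraction_missing": result["fraction_missing"],
        "converged": bool(result["converged"]),
    }
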