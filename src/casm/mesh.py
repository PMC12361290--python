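"""Triangle-mesh containers and differential-geometry utilities.

The primary objects of the pipeline are open triangulated patches of the
articular surfaces (femur, medial tibia, lateral tibia) with per-vertex
scalar fields (cartilage thickness in mm, t-statistics, p-values).  All
coordinates are millimetres in a right-handed frame; no voxel grid is
modelled anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

PATCH_LABELS = ("femur", "medial_tibia", "lateral_tibia")

# areas below this (mm^2) count as degenerate triangles
_DEGENERATE_AREA = 1e-12


class MeshValidationError(ValueError):
    """A mesh or field violates a structural invariant."""


@dataclass(frozen=True)
class TriangleMesh:
    """An open or closed triangulated surface patch.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices, counter-clockwise winding
        seen from the outside.
    patch_label : one of ``femur``, ``medial_tibia``, ``lateral_tibia``,
        or ``None`` for anonymous test geometry.
    """

    vertices: np.ndarray
    faces: np.ndarray
    patch_label: str | None = None

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshValidationError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshValidationError(f"faces must be (m, 3), got {f.shape}")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        if self.patch_label is not None and self.patch_label not in PATCH_LABELS:
            raise MeshValidationError(
                f"patch_label must be one of {PATCH_LABELS}, got {self.patch_label!r}"
            )

    # -- basic sizes ----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    # -- validation -----------------------------------------------------
    def validate(self) -> "TriangleMesh":
        """Check structural invariants, raising MeshValidationError.

        Checks: index range, non-degenerate triangles, edge-manifoldness
        (every edge on at most two faces) and single connectedness.
        Returns self so it can be chained.
        """
        f = self.faces
        if f.size and (f.min() < 0 or f.max() >= self.n_vertices):
            bad = np.where((f < 0) | (f >= self.n_vertices))[0][0]
            raise MeshValidationError(
                f"face {bad} references vertex index outside [0, {self.n_vertices})"
            )
        repeated = (
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        )
        if repeated.any():
            raise MeshValidationError(
                f"face {np.where(repeated)[0][0]} repeats a vertex index"
            )
        areas = self.face_areas
        if (areas <= _DEGENERATE_AREA).any():
            raise MeshValidationError(
                f"face {int(np.argmin(areas))} has (near-)zero area"
            )
        counts = self._edge_face_counts
        if (counts > 2).any():
            raise MeshValidationError("non-manifold edge shared by more than 2 faces")
        n_comp = sparse.csgraph.connected_components(
            self.vertex_adjacency, directed=False, return_labels=False
        )
        if n_comp > 1:
            raise MeshValidationError(f"mesh has {n_comp} connected components")
        return self

    # -- combinatorics --------------------------------------------------
    @cached_property
    def edges(self) -> np.ndarray:
        """Unique undirected edges, (E, 2), sorted pairs."""
        e = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        return np.unique(e, axis=0)

    @cached_property
    def _edge_face_counts(self) -> np.ndarray:
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return counts

    @cached_property
    def boundary_edges(self) -> np.ndarray:
        """Edges incident to exactly one face."""
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    @cached_property
    def vertex_adjacency(self) -> sparse.csr_matrix:
        """Symmetric 0/1 vertex-adjacency matrix."""
        e = self.edges
        n = self.n_vertices
        data = np.ones(len(e), dtype=np.float64)
        a = sparse.coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n))
        return (a + a.T).tocsr()

    @cached_property
    def edge_lengths(self) -> np.ndarray:
        e = self.edges
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    @property
    def mean_edge_length(self) -> float:
        return float(self.edge_lengths.mean())

    # -- geometry -------------------------------------------------------
    @cached_property
    def face_normals(self) -> np.ndarray:
        """Unit face normals following the winding order."""
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.where(norm > 0, norm, 1.0)

    @cached_property
    def face_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    @property
    def diameter(self) -> float:
        """Length of the bounding-box diagonal (mm)."""
        return float(np.linalg.norm(self.vertices.max(0) - self.vertices.min(0)))

    def transformed(self, fn) -> "TriangleMesh":
        """Return a copy with vertices mapped through ``fn`` (points -> points)."""
        return replace(self, vertices=np.asarray(fn(self.vertices), dtype=np.float64))


@dataclass
class SurfaceField:
    """Per-vertex scalar values bound to a mesh.

    Missing data is carried as an explicit boolean mask, never as
    sentinel values; a masked entry's numeric value is undefined.
    """

    values: np.ndarray
    units: str = "dimensionless"
    missing_mask: np.ndarray | None = None
    name: str = "field"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool).ravel()
            if self.missing_mask.shape != self.values.shape:
                raise MeshValidationError("missing_mask length != values length")

    def check_against(self, mesh: TriangleMesh) -> "SurfaceField":
        if len(self.values) != mesh.n_vertices:
            raise MeshValidationError(
                f"field has {len(self.values)} values for a mesh with "
                f"{mesh.n_vertices} vertices"
            )
        ok = ~self.missing_mask
        if self.units == "p" and ok.any():
            v = self.values[ok]
            if (v < 0).any() or (v > 1).any():
                raise MeshValidationError("p-value field outside [0, 1]")
        if self.units == "mm" and ok.any() and (self.values[ok] < 0).any():
            raise MeshValidationError("thickness field has negative values")
        return self

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())


# ---------------------------------------------------------------------------
# differential-geometry operations
# ---------------------------------------------------------------------------

def vertex_normals(mesh: TriangleMesh) -> SurfaceField | np.ndarray:
    """Angle-weighted per-vertex unit normals.

    Each incident face normal is weighted by the triangle's interior
    angle at the vertex, which is robust to irregular triangulations.
    Isolated vertices (no incident face) get a NaN normal and are
    reported via the returned mask.

    Returns
    -------
    normals : (n, 3) array of unit vectors (NaN rows where undefined)
    missing : (n,) bool array, True for isolated vertices
    """
    v, f = mesh.vertices, mesh.faces
    fn = mesh.face_normals
    acc = np.zeros_like(v)
    for corner in range(3):
        i = f[:, corner]
        a = v[f[:, (corner + 1) % 3]] - v[i]
        b = v[f[:, (corner + 2) % 3]] - v[i]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        cosang = np.einsum("ij,ij->i", a, b) / np.maximum(na * nb, 1e-300)
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(acc, i, fn * ang[:, None])
    norm = np.linalg.norm(acc, axis=1)
    missing = norm == 0.0
    out = np.full_like(acc, np.nan)
    out[~missing] = acc[~missing] / norm[~missing, None]
    return out, missing


def mesh_metrics(mesh: TriangleMesh) -> dict:
    """Area, edge lengths, boundary length and Euler characteristic.

    These are the geometric inputs to resel estimation: R2 uses the
    total area, R1 the boundary length, R0 the Euler characteristic.
    """
    boundary = mesh.boundary_edges
    boundary_length = float(
        np.linalg.norm(
            mesh.vertices[boundary[:, 0]] - mesh.vertices[boundary[:, 1]], axis=1
        ).sum()
    ) if len(boundary) else 0.0
    return {
        "total_area": float(mesh.face_areas.sum()),
        "edges": mesh.edges,
        "edge_lengths": mesh.edge_lengths,
        "boundary_length": boundary_length,
        "euler_characteristic": int(
            mesh.n_vertices - len(mesh.edges) + mesh.n_faces
        ),
    }


def _diffusion_operator(mesh: TriangleMesh, missing: np.ndarray):
    """One smoothing step ``x -> x - alpha*L*x`` on the non-missing subgraph.

    The graph Laplacian L = D - A is symmetric with zero column sums, so
    every step conserves the field sum (hence mean) exactly; alpha is
    0.5/max_degree, inside the stability region.  Edges touching missing
    vertices are removed entirely.  Returns (operator, alpha, mean degree
    of the retained subgraph).
    """
    adj = mesh.vertex_adjacency.copy()
    if missing.any():
        keep = sparse.diags((~missing).astype(np.float64))
        adj = keep @ adj @ keep
    deg = np.asarray(adj.sum(axis=1)).ravel()
    d_max = deg.max() if deg.size else 1.0
    alpha = 0.5 / max(d_max, 1.0)
    lap = sparse.diags(deg) - adj
    n = mesh.n_vertices
    op = (sparse.eye(n) - alpha * lap).tocsr()
    active = deg > 0
    d_mean = float(deg[active].mean()) if active.any() else 0.0
    return op, alpha, d_mean


def smoothing_iterations(mesh: TriangleMesh, fwhm: float,
                         alpha: float, d_mean: float) -> int:
    """Diffusion steps needed for an effective Gaussian kernel of given FWHM.

    One step spreads mass alpha to each of ~d neighbours one edge (h mm)
    away; averaging cos^2 over in-plane directions, the per-dimension
    kernel variance grows by alpha*d*h^2/2 per step, so after k steps
    FWHM ~ sqrt(8 ln 2 * k * alpha * d / 2) * h.  Solve for k.
    """
    if fwhm <= 0 or d_mean <= 0:
        return 0
    h = mesh.mean_edge_length
    k = fwhm ** 2 / (4.0 * np.log(2.0) * alpha * d_mean * h ** 2)
    return max(1, int(round(k)))


def smooth_field(field: SurfaceField, mesh: TriangleMesh, fwhm: float) -> SurfaceField:
    """Diffusion smoothing on the mesh graph to an approximate FWHM (mm).

    ``fwhm=0`` is the identity.  Missing vertices are excluded from all
    averages and stay missing.  The Laplacian step conserves the field
    mean over non-missing vertices to round-off.
    """
    if fwhm < 0:
        raise MeshValidationError("fwhm must be >= 0")
    field.check_against(mesh)
    op, alpha, d_mean = _diffusion_operator(mesh, field.missing_mask)
    k = smoothing_iterations(mesh, fwhm, alpha, d_mean)
    if k == 0:
        return SurfaceField(field.values.copy(), field.units,
                            field.missing_mask.copy(), field.name)
    x = np.where(field.missing_mask, 0.0, field.values)
    for _ in range(k):
        x = op @ x
    x[field.missing_mask] = np.nan
    return SurfaceField(x, field.units, field.missing_mask.copy(), field.name)


# ---------------------------------------------------------------------------
# spatial queries (ray casting + closest point), used by thickness and
# registration.  Pure numpy/scipy; candidate triangles are prefiltered
# with a k-d tree on triangle centroids.
# ---------------------------------------------------------------------------

class SurfaceLocator:
    """Closest-point and first-hit ray queries against a triangle mesh."""

    def __init__(self, mesh: TriangleMesh, n_candidates: int = 16):
        self.mesh = mesh
        tri = mesh.vertices[mesh.faces]
        self._tri = tri
        self._centroids = tri.mean(axis=1)
        self._tree = cKDTree(self._centroids)
        # max circumscribed radius, used to pad candidate searches
        self._tri_radius = float(
            np.linalg.norm(tri - self._centroids[:, None, :], axis=2).max()
        )
        self.n_candidates = min(n_candidates, mesh.n_faces)

    # -- closest point --------------------------------------------------
    def closest_point(self, points: np.ndarray):
        """Exact closest point among k-d-tree candidate triangles.

        Returns (closest_points (n,3), distances (n,), face_indices (n,),
        barycentric (n,3)).
        """
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        _, cand = self._tree.query(points, k=self.n_candidates)
        cand = np.atleast_2d(cand)
        n, k = cand.shape
        tri = self._tri[cand.ravel()]                     # (n*k, 3, 3)
        q = np.repeat(points, k, axis=0)                  # (n*k, 3)
        cp, bary = _closest_point_on_triangles(q, tri)
        d = np.linalg.norm(cp - q, axis=1).reshape(n, k)
        best = np.argmin(d, axis=1)
        rows = np.arange(n)
        flat = rows * k + best
        return (
            cp[flat],
            d[rows, best],
            cand[rows, best],
            bary[flat],
        )

    # -- ray casting ----------------------------------------------------
    def ray_first_hit(self, origins: np.ndarray, directions: np.ndarray,
                      max_distance: float, eps: float = 1e-6):
        """First intersection along each (unit-direction) ray.

        ``eps`` offsets ray origins forward to avoid self-intersection
        with the originating surface.  Returns (distances, hit_mask);
        misses get distance NaN.

        Candidate triangles are gathered by ball queries around points
        sampled along each ray (guaranteed to cover every triangle the
        ray can cross within ``max_distance``); the Moller-Trumbore test
        then runs on the flat (ray, triangle) pair list.
        """
        origins = np.asarray(origins, dtype=np.float64) + eps * directions
        directions = np.asarray(directions, dtype=np.float64)
        n_rays = len(origins)
        step = max(self._tri_radius, max_distance / 64.0)
        n_steps = int(np.ceil(max_distance / step)) + 1
        ts = np.linspace(0.0, max_distance, n_steps)
        samples = origins[:, None, :] + ts[None, :, None] * directions[:, None, :]
        radius = 0.5 * (ts[1] - ts[0] if n_steps > 1 else max_distance) \
            + self._tri_radius * 1.001
        hits = self._tree.query_ball_point(samples.reshape(-1, 3), r=radius)
        ray_idx, tri_idx = [], []
        for flat, cand in enumerate(hits):
            if cand:
                ray_idx.append(np.full(len(cand), flat // n_steps))
                tri_idx.append(np.asarray(cand))
        dist = np.full(n_rays, np.nan)
        if not ray_idx:
            return dist, np.isfinite(dist)
        ray_idx = np.concatenate(ray_idx)
        tri_idx = np.concatenate(tri_idx)
        pairs = np.unique(np.column_stack([ray_idx, tri_idx]), axis=0)
        ray_idx, tri_idx = pairs[:, 0], pairs[:, 1]
        m = self.mesh
        v0 = m.vertices[m.faces[tri_idx, 0]]
        e1 = m.vertices[m.faces[tri_idx, 1]] - v0
        e2 = m.vertices[m.faces[tri_idx, 2]] - v0
        o = origins[ray_idx]
        d = directions[ray_idx]
        pvec = np.cross(d, e2)
        det = np.einsum("ij,ij->i", pvec, e1)
        ok = np.abs(det) > 1e-12
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = o - v0
        u = np.einsum("ij,ij->i", tvec, pvec) * inv
        qvec = np.cross(tvec, e1)
        vv = np.einsum("ij,ij->i", d, qvec) * inv
        t = np.einsum("ij,ij->i", e2, qvec) * inv
        hit = ok & (u >= -1e-12) & (vv >= -1e-12) & (u + vv <= 1 + 1e-12) \
            & (t > 0) & (t <= max_distance)
        t = np.where(hit, t, np.inf)
        best = np.full(n_rays, np.inf)
        np.minimum.at(best, ray_idx, t)
        good = np.isfinite(best)
        dist[good] = best[good] + eps
        return dist, np.isfinite(dist)


def _closest_point_on_triangles(p: np.ndarray, tri: np.ndarray):
    """Vectorised closest point on each triangle for paired queries.

    Standard region-classification algorithm (Ericson, Real-Time
    Collision Detection).  Returns closest points and barycentric
    coordinates, both (n, 3).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp_ = p - c
    d5 = np.einsum("ij,ij->i", ab, cp_)
    d6 = np.einsum("ij,ij->i", ac, cp_)

    n = len(p)
    bary = np.zeros((n, 3))
    done = np.zeros(n, dtype=bool)

    reg = (d1 <= 0) & (d2 <= 0)                       # vertex a
    bary[reg] = (1, 0, 0); done |= reg
    reg = ~done & (d3 >= 0) & (d4 <= d3)              # vertex b
    bary[reg] = (0, 1, 0); done |= reg
    reg = ~done & (d6 >= 0) & (d5 <= d6)              # vertex c
    bary[reg] = (0, 0, 1); done |= reg

    vc = d1 * d4 - d3 * d2
    reg = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)   # edge ab
    t = np.divide(d1, d1 - d3, out=np.zeros(n), where=(d1 - d3) != 0)
    bary[reg, 0] = 1 - t[reg]; bary[reg, 1] = t[reg]; done |= reg

    vb = d5 * d2 - d1 * d6
    reg = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)   # edge ac
    t = np.divide(d2, d2 - d6, out=np.zeros(n), where=(d2 - d6) != 0)
    bary[reg, 0] = 1 - t[reg]; bary[reg, 2] = t[reg]; done |= reg

    va = d3 * d6 - d5 * d4
    reg = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)   # edge bc
    den = (d4 - d3) + (d5 - d6)
    t = np.divide(d4 - d3, den, out=np.zeros(n), where=den != 0)
    bary[reg, 1] = 1 - t[reg]; bary[reg, 2] = t[reg]; done |= reg

    inner = ~done                                      # interior
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1.0 / 3)
        w = np.where(denom != 0, vc / denom, 1.0 / 3)
    bary[inner, 0] = 1 - v[inner] - w[inner]
    bary[inner, 1] = v[inner]
    bary[inner, 2] = w[inner]

    points = bary[:, 0, None] * a + bary[:, 1, None] * b + bary[:, 2, None] * c
    return points, bary
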