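"""Similarity alignment, thin-plate splines and subject registration."""

import numpy as np
import pytest
from scipy import optimize

from casm.mesh import SurfaceField, TriangleMesh
from casm.registration import (
    Correspondence,
    DegenerateGeometryError,
    SimilarityTransform,
    farthest_point_sample,
    register_to_canonical,
    similarity_align,
    transfer_field,
    tps_apply,
    tps_fit,
)
from casm.synthetic import make_canonical_patch, make_effect_maps, sample_cohort, simulate_subject


def rotation_about_z(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0],
                     [np.sin(a), np.cos(a), 0],
                     [0, 0, 1]])


class TestSimilarity:
    def test_identity_on_identical_clouds(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((30, 3))
        tf, rms = similarity_align(x, x)
        assert rms < 1e-12
        assert tf.scale == pytest.approx(1.0, abs=1e-12)
        assert np.abs(tf.rotation - np.eye(3)).max() < 1e-12

    def test_construct_and_recover(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((50, 3)) * 10
        rot = rotation_about_z(30.0)
        truth = SimilarityTransform(1.3, rot, np.array([5.0, -2.0, 1.0]))
        tf, rms = similarity_align(x, truth.apply(x))
        assert rms < 1e-8
        assert tf.scale == pytest.approx(1.3, abs=1e-8)
        assert np.abs(tf.rotation - rot).max() < 1e-8
        assert np.abs(tf.translation - truth.translation).max() < 1e-8

    def test_reflection_never_returned(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((40, 3))
        mirrored = x * [-1, 1, 1]
        tf, rms = similarity_align(x, mirrored)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-10)
        assert rms > 0.1

    def test_collinear_points_rejected(self):
        t = np.linspace(0, 1, 10)
        line = np.column_stack([t, 2 * t, 3 * t])
        with pytest.raises(DegenerateGeometryError):
            similarity_align(line, line + 1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_optimizer(self, seed):
        """Closed form equals direct nonlinear minimisation of the LS cost."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((12, 3)) * 5
        y = rng.standard_normal((12, 3)) * 5 + x  # partially structured

        def resid(p):
            s = np.exp(p[0])
            w = p[1:4]
            theta = np.linalg.norm(w)
            if theta < 1e-12:
                rot = np.eye(3)
            else:
                k = w / theta
                kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]],
                               [-k[1], k[0], 0]])
                rot = np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * kx @ kx
            return (s * x @ rot.T + p[4:] - y).ravel()

        best = None
        for trial in range(4):
            p0 = np.concatenate([[0.0], rng.normal(0, 0.5, 3),
                                 rng.normal(0, 1, 3)])
            sol = optimize.least_squares(resid, p0, xtol=1e-14, ftol=1e-14)
            c = np.sum(sol.fun ** 2)
            if best is None or c < best:
                best = c
        tf, rms = similarity_align(x, y)
        closed = rms ** 2 * len(x)
        assert closed <= best + 1e-5 * max(best, 1.0)


class TestTPS:
    def _landmarks(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return rng.standard_normal((n, 3)) * 10

    def test_interpolates_exactly_at_zero_lambda(self):
        src = self._landmarks()
        rng = np.random.default_rng(1)
        tgt = src + rng.normal(0, 2, src.shape)
        warp = tps_fit(src, tgt, lambda_reg=0.0)
        assert np.abs(tps_apply(warp, src) - tgt).max() < 1e-8

    def test_affine_data_gives_zero_kernel_weights(self):
        src = self._landmarks()
        a = np.array([[1.2, 0.1, 0.0], [0.0, 0.9, 0.2], [-0.1, 0.0, 1.1]])
        tgt = src @ a.T + [1.0, -2.0, 3.0]
        warp = tps_fit(src, tgt, lambda_reg=0.0)
        assert np.abs(warp.kernel_weights).max() < 1e-8
        # and the affine part reproduces the map on new points
        rng = np.random.default_rng(2)
        new = rng.standard_normal((15, 3)) * 8
        assert np.abs(tps_apply(warp, new) - (new @ a.T + [1, -2, 3])).max() < 1e-8

    def test_side_conditions_hold(self):
        src = self._landmarks(30, seed=3)
        rng = np.random.default_rng(4)
        tgt = src + rng.normal(0, 1.5, src.shape)
        warp = tps_fit(src, tgt, lambda_reg=0.1)
        p = np.hstack([src, np.ones((len(src), 1))])
        assert np.abs(p.T @ warp.kernel_weights).max() < 1e-8

    def test_bending_energy_decreases_with_lambda(self):
        src = self._landmarks(25, seed=5)
        rng = np.random.default_rng(6)
        tgt = src + rng.normal(0, 2, src.shape)
        energies = [tps_fit(src, tgt, lam).bending_energy()
                    for lam in (0.0, 0.1, 1.0, 10.0, 100.0, 1000.0)]
        assert all(e >= -1e-9 for e in energies)
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_large_lambda_tends_to_affine(self):
        src = self._landmarks(25, seed=7)
        rng = np.random.default_rng(8)
        tgt = src + rng.normal(0, 2, src.shape)
        warp = tps_fit(src, tgt, lambda_reg=1e6)
        # kernel contribution negligible relative to the data scale
        r = np.linalg.norm(src[:, None] - src[None], axis=2)
        assert np.abs(r @ warp.kernel_weights).max() < 1e-2

    def test_coplanar_landmarks_rejected_at_zero_lambda(self):
        rng = np.random.default_rng(9)
        src = rng.standard_normal((12, 3))
        src[:, 2] = 0.0
        with pytest.raises(DegenerateGeometryError, match="lambda"):
            tps_fit(src, src + 0.5, lambda_reg=0.0)

    def test_identity_fit_applies_as_identity(self):
        src = self._landmarks(15, seed=10)
        warp = tps_fit(src, src, lambda_reg=0.0)
        rng = np.random.default_rng(11)
        pts = rng.standard_normal((20, 3)) * 5
        assert np.abs(tps_apply(warp, pts) - pts).max() < 1e-9


@pytest.fixture(scope="module")
def canonical():
    return make_canonical_patch("femur", 900, seed=21)


def _make_subject(canonical, seed, tps_amplitude, scale=(0.9, 1.1)):
    eff = make_effect_maps({"femur": canonical}, "null", seed=seed)
    row = sample_cohort(n_subjects=1, seed=seed).iloc[0].to_dict()
    return simulate_subject(
        {"femur": canonical}, row, eff,
        geometry_jitter={"tps_amplitude": tps_amplitude, "scale": scale},
        seed=seed, noise=False)


class TestRegisterToCanonical:
    def test_identical_meshes_register_trivially(self, canonical):
        res = register_to_canonical(canonical, canonical, seed=0,
                                    n_control=200, iterations=3)
        assert res["residual_rms"] < 1e-6
        assert res["converged"]

    def test_known_similarity_recovered(self, canonical):
        truth = SimilarityTransform(1.1, rotation_about_z(12.0),
                                    np.array([4.0, -3.0, 2.0]))
        subject = TriangleMesh(truth.apply(canonical.vertices),
                               canonical.faces, patch_label="femur")
        res = register_to_canonical(subject, canonical, seed=0)
        assert res["residual_rms"] < 0.01
        assert res["similarity"].scale == pytest.approx(1.1, abs=1e-3)

    def test_synthetic_tps_deformation_recovered(self, canonical):
        subj = _make_subject(canonical, seed=33, tps_amplitude=2.0)
        res = register_to_canonical(subj.meshes["femur"], canonical, seed=0)
        assert res["residual_rms"] < 0.1
        # smooth test field transfers with small error; canonical vertex i
        # corresponds to subject vertex i by construction
        sm = subj.meshes["femur"]
        vals = 2.0 + np.sin(sm.vertices[:, 0] / 25.0)
        f = SurfaceField(vals, units="dimensionless")
        g = transfer_field(f, sm, res["correspondence"])
        ok = ~g.missing_mask
        assert ok.mean() > 0.95
        err = g.values[ok] - vals[ok]
        assert np.sqrt(np.mean(err ** 2)) < 0.05

    def test_equivariance_small_prerotation(self, canonical):
        subj = _make_subject(canonical, seed=40, tps_amplitude=1.0,
                             scale=(1.0, 1.0))
        base = register_to_canonical(subj.meshes["femur"], canonical, seed=0)
        rot = rotation_about_z(4.0)
        rotated = TriangleMesh(subj.meshes["femur"].vertices @ rot.T,
                               subj.meshes["femur"].faces, patch_label="femur")
        again = register_to_canonical(rotated, canonical, seed=0)
        assert again["residual_rms"] == pytest.approx(
            base["residual_rms"], abs=1e-6)

    def test_patch_mismatch_rejected(self, canonical):
        tib = make_canonical_patch("medial_tibia", 300, seed=1)
        with pytest.raises(Exception, match="patch"):
            register_to_canonical(tib, canonical, seed=0)


class TestTransferField:
    def _identity_corr(self, mesh):
        # each canonical vertex sits on a face containing it with weight 1
        face_of = np.full(mesh.n_vertices, -1)
        weight = np.zeros((mesh.n_vertices, 3))
        for fi, face in enumerate(mesh.faces):
            for k, v in enumerate(face):
                if face_of[v] == -1:
                    face_of[v] = fi
                    weight[v] = np.eye(3)[k]
        return Correspondence(face_of, weight,
                              missing=face_of == -1)

    def test_constant_field_preserved(self, canonical):
        corr = self._identity_corr(canonical)
        f = SurfaceField(np.full(canonical.n_vertices, 3.7))
        g = transfer_field(f, canonical, corr)
        assert np.abs(g.values[~g.missing_mask] - 3.7).max() < 1e-12

    def test_identity_correspondence_copies_exactly(self, canonical):
        corr = self._identity_corr(canonical)
        rng = np.random.default_rng(5)
        f = SurfaceField(rng.standard_normal(canonical.n_vertices))
        g = transfer_field(f, canonical, corr)
        ok = ~g.missing_mask
        np.testing.assert_array_equal(g.values[ok], f.values[ok])

    def test_linear_field_barycentric_exact(self, canonical):
        subj = _make_subject(canonical, seed=50, tps_amplitude=1.5)
        sm = subj.meshes["femur"]
        res = register_to_canonical(sm, canonical, seed=0)
        a = np.array([0.01, -0.02, 0.03])
        f = SurfaceField(sm.vertices @ a)
        g = transfer_field(f, sm, res["correspondence"])
        corr = res["correspondence"]
        ok = ~g.missing_mask
        # expected: linear functional at the corresponded surface point
        faces = sm.faces[corr.face_indices[ok]]
        pts = np.einsum("ij,ijk->ik", corr.barycentric[ok],
                        sm.vertices[faces])
        assert np.abs(g.values[ok] - pts @ a).max() < 1e-6

    def test_transfer_respects_bounds(self, canonical):
        subj = _make_subject(canonical, seed=60, tps_amplitude=2.0)
        sm = subj.meshes["femur"]
        res = register_to_canonical(sm, canonical, seed=0)
        rng = np.random.default_rng(6)
        f = SurfaceField(rng.uniform(1.0, 3.0, sm.n_vertices))
        g = transfer_field(f, sm, res["correspondence"])
        ok = ~g.missing_mask
        assert g.values[ok].min() >= f.values.min() - 1e-12
        assert g.values[ok].max() <= f.values.max() + 1e-12


def test_farthest_point_sample_spreads(canonical):
    idx = farthest_point_sample(canonical.vertices, 50, seed=0)
    assert len(np.unique(idx)) == 50
    pts = canonical.vertices[idx]
    d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
    np.fill_diagonal(d, np.inf)
    # minimum pairwise separation is a decent fraction of the diameter
    assert d.min() > 0.03 * canonical.diameter
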