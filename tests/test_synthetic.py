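"""Synthetic cohort, geometry and thickness-field generator."""

import numpy as np
import pytest

from casm.mesh import mesh_metrics
from casm.spm import estimate_smoothness
from casm.synthetic import (
    CohortSpec,
    make_canonical_patch,
    make_effect_maps,
    patch_parameters,
    region_weight,
    sample_cohort,
    simulate_cohort_dataset,
    simulate_subject,
)


class TestCanonicalPatches:
    @pytest.mark.parametrize("label,n", [("femur", 2000), ("medial_tibia", 800),
                                         ("lateral_tibia", 500)])
    def test_disc_topology_single_boundary(self, label, n):
        import networkx as nx

        m = make_canonical_patch(label, n, seed=0)
        assert mesh_metrics(m)["euler_characteristic"] == 1
        g = nx.Graph(m.boundary_edges.tolist())
        assert nx.number_connected_components(g) == 1

    def test_deterministic_given_seed(self):
        a = make_canonical_patch("femur", 700, seed=9)
        b = make_canonical_patch("femur", 700, seed=9)
        np.testing.assert_array_equal(a.vertices, b.vertices)
        np.testing.assert_array_equal(a.faces, b.faces)
        c = make_canonical_patch("femur", 700, seed=10)
        assert np.abs(a.vertices - c.vertices).max() > 0

    @pytest.mark.parametrize("label", ["femur", "medial_tibia"])
    def test_triangulation_quality(self, label):
        m = make_canonical_patch(label, 900, seed=3)
        el = m.edge_lengths
        assert el.std() / el.mean() < 0.5
        tri = m.vertices[m.faces]
        mins = []
        for c in range(3):
            a = tri[:, (c + 1) % 3] - tri[:, c]
            b = tri[:, (c + 2) % 3] - tri[:, c]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
            mins.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        assert np.min(mins) > 15.0

    def test_vertex_count_rejected_below_minimum(self):
        with pytest.raises(ValueError, match="200"):
            make_canonical_patch("femur", 50, seed=0)

    def test_parameters_invert_in_plane(self):
        m = make_canonical_patch("femur", 500, seed=1)
        uv = patch_parameters(m)
        assert uv.min() >= -1.5 and uv.max() <= 1.5


class TestSampleCohort:
    def test_moments_converge_to_spec(self):
        df = sample_cohort(n_subjects=100_000, seed=1)
        spec = CohortSpec()
        assert abs(df.age.mean() - spec.age_mean) < 0.1
        assert abs(df.sex.mean() - spec.prop_male) < 0.005
        assert abs(df.height.mean() - spec.height_mean) < 0.15
        assert abs(df.weight.mean() - spec.weight_mean) < 0.2
        # prevalence of compartment pathology matches the configured table
        from casm.cohort import MOAKS_SUBREGIONS, compartment_max_score

        for comp, prev in spec.pathology_prevalence.items():
            got = (compartment_max_score(
                df[MOAKS_SUBREGIONS[comp]].to_numpy()) > 0).mean()
            assert abs(got - prev) < 0.01, comp

    def test_sex_shift_preserves_overall_height_mean(self):
        spec = CohortSpec(sex_height_shift=12.0)
        df = sample_cohort(spec, n_subjects=100_000, seed=2)
        assert abs(df.height.mean() - spec.height_mean) < 0.15
        male = df[df.sex == 1].height.mean()
        female = df[df.sex == 0].height.mean()
        assert male - female == pytest.approx(12.0, abs=0.5)

    def test_zero_prevalence_means_no_pathology(self):
        spec = CohortSpec(pathology_prevalence={
            k: 0.0 for k in CohortSpec().pathology_prevalence})
        df = sample_cohort(spec, n_subjects=500, seed=3)
        from casm.cohort import ALL_SUBREGION_COLUMNS

        assert (df[ALL_SUBREGION_COLUMNS].to_numpy() == 0).all()

    def test_same_seed_identical(self):
        a = sample_cohort(n_subjects=300, seed=4)
        b = sample_cohort(n_subjects=300, seed=4)
        assert a.equals(b)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="probabilities"):
            CohortSpec(prop_male=1.5)
        with pytest.raises(ValueError, match="SD"):
            CohortSpec(age_sd=-1)


@pytest.fixture(scope="module")
def meshes():
    return {"femur": make_canonical_patch("femur", 800, seed=7),
            "medial_tibia": make_canonical_patch("medial_tibia", 400, seed=7)}


class TestEffectMaps:

    def test_null_scenario_all_zero(self, meshes):
        eff = make_effect_maps(meshes, "null", seed=0)
        assert eff.effects == {}

    def test_sex_effect_peaks_at_half_millimetre(self, meshes):
        eff = make_effect_maps(meshes, "demographics", seed=0)
        peak = max(eff.effects["sex"][p].max() for p in meshes)
        assert peak == pytest.approx(0.5, rel=0.1)

    def test_baseline_in_physiologic_band(self, meshes):
        eff = make_effect_maps(meshes, "demographics", seed=0)
        for p in meshes:
            assert eff.baseline[p].min() > 1.2
            assert eff.baseline[p].max() < 2.8

    def test_unknown_region_rejected(self, meshes):
        with pytest.raises(ValueError, match="unknown region"):
            region_weight(meshes["femur"], "acetabulum")

    def test_effect_bump_width_matches_definition(self, meshes):
        """Half-max width of the trochlear bump ~ its parametric extent."""
        m = meshes["femur"]
        w = region_weight(m, "trochlea")
        uv = patch_parameters(m)
        inside = w >= 0.5
        # half-max ellipse of exp(-d2) is d2 = ln 2
        d2 = ((uv[:, 0] - 0.5) / 0.28) ** 2 + ((uv[:, 1] - 0.25) / 0.26) ** 2
        np.testing.assert_array_equal(inside, d2 <= np.log(2))
        assert 0.01 < inside.mean() < 0.5


@pytest.fixture(scope="module")
def setup():
    meshes = {"femur": make_canonical_patch("femur", 600, seed=13)}
    eff = make_effect_maps(meshes, "demographics", seed=13)
    row = sample_cohort(n_subjects=1, seed=13).iloc[0].to_dict()
    return meshes, eff, row


class TestSimulateSubject:

    def test_zero_jitter_zero_noise_null_reproduces_canonical(self):
        meshes = {"femur": make_canonical_patch("femur", 600, seed=13)}
        eff = make_effect_maps(meshes, "null", seed=13)
        row = sample_cohort(n_subjects=1, seed=13).iloc[0].to_dict()
        s = simulate_subject(meshes, row, eff, seed=1, noise=False,
                             geometry_jitter={"scale": (1.0, 1.0),
                                              "rot_deg": 0.0, "trans_mm": 0.0,
                                              "tps_amplitude": 0.0})
        np.testing.assert_allclose(s.meshes["femur"].vertices,
                                   meshes["femur"].vertices, atol=1e-12)
        np.testing.assert_allclose(s.thickness["femur"].values,
                                   eff.baseline["femur"], atol=1e-12)

    def test_noise_free_thickness_is_linear_predictor(self, setup):
        meshes, eff, row = setup
        s = simulate_subject(meshes, row, eff, seed=2, noise=False)
        expect = eff.linear_predictor("femur", row).clip(0)
        np.testing.assert_allclose(s.thickness["femur"].values, expect,
                                   atol=1e-12)

    def test_geometry_jitter_moves_vertices(self, setup):
        meshes, eff, row = setup
        s = simulate_subject(meshes, row, eff, seed=3, noise=False)
        assert np.abs(s.meshes["femur"].vertices
                      - meshes["femur"].vertices).max() > 0.5

    def test_profiles_encode_true_thickness(self, setup):
        from casm.thickness import fit_profile_model

        meshes, eff, row = setup
        s = simulate_subject(meshes, row, eff, seed=4, noise=False,
                             with_profiles=True)
        profs = s.profiles["femur"]
        truth = s.thickness["femur"].values
        errs = []
        for i in range(0, 60, 3):
            fit = fit_profile_model(profs[i], (0.1, 1.5), seed=i)
            errs.append(fit.thickness - truth[i])
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse < 0.05


class TestSimulateCohortDataset:
    def test_aligned_matrix_shape_and_completeness(self):
        ds = simulate_cohort_dataset(CohortSpec(n_subjects=50), "null",
                                     seed=5, patches=("femur",),
                                     n_vertices=400)
        y = ds.thickness_matrices["femur"]
        assert y.shape == (50, ds.canonical["femur"].n_vertices)
        assert np.isfinite(y).all()
        assert (y >= 0).all()

    def test_demographics_scenario_only_demographic_effects(self):
        ds = simulate_cohort_dataset(CohortSpec(n_subjects=30), "demographics",
                                     seed=6, patches=("femur",),
                                     n_vertices=400)
        assert set(ds.effects.effects) <= {"sex", "age", "bmi", "height",
                                           "weight"}
        assert any(np.abs(m["femur"]).max() > 0
                   for m in ds.effects.effects.values())

    def test_same_seed_identical_dataset(self):
        a = simulate_cohort_dataset(CohortSpec(n_subjects=20), "demographics",
                                    seed=7, patches=("femur",), n_vertices=300)
        b = simulate_cohort_dataset(CohortSpec(n_subjects=20), "demographics",
                                    seed=7, patches=("femur",), n_vertices=300)
        assert a.cohort.equals(b.cohort)
        np.testing.assert_array_equal(a.thickness_matrices["femur"],
                                      b.thickness_matrices["femur"])

    def test_clip_fraction_small_at_defaults(self):
        ds = simulate_cohort_dataset(CohortSpec(n_subjects=100), "pathology",
                                     seed=8, patches=("femur",),
                                     n_vertices=500)
        assert ds.effects.clip_fraction < 0.01

    def test_noise_smoothness_near_requested(self):
        ds = simulate_cohort_dataset(CohortSpec(n_subjects=80), "null",
                                     seed=9, patches=("femur",),
                                     n_vertices=900)
        mesh = ds.canonical["femur"]
        y = ds.thickness_matrices["femur"]
        resid = y - y.mean(axis=0)
        fwhm, _ = estimate_smoothness(resid, mesh)
        target = 3.0 * mesh.mean_edge_length
        assert abs(fwhm - target) / target < 0.25

    def test_subject_mode_emits_geometry(self):
        ds = simulate_cohort_dataset(CohortSpec(n_subjects=3), "null",
                                     seed=10, patches=("femur",),
                                     n_vertices=300, aligned=False)
        assert ds.thickness_matrices is None
        assert len(ds.subjects) == 3
        for s in ds.subjects:
            assert s.meshes["femur"].n_vertices == \
                ds.canonical["femur"].n_vertices
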