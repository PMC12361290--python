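"""Vertex-wise GLM, smoothness estimation and corrected thresholds."""

import numpy as np
import pytest
from scipy import stats

from casm.mesh import SurfaceField, smooth_field
from casm.spm import (
    DesignError,
    DesignMatrix,
    estimate_smoothness,
    expected_euler_characteristic,
    fdr_threshold,
    fit_vertex_glm,
    resel_counts,
    rft_threshold,
    run_spm,
)
from casm.synthetic import make_canonical_patch

from conftest import dense_flat_grid


def design_with_noise_covariate(n, seed=0):
    rng = np.random.default_rng(seed)
    x = np.column_stack([np.ones(n), rng.standard_normal(n)])
    return DesignMatrix(x, ("intercept", "cov"), "cov")


class TestDesignMatrix:
    def test_rank_deficiency_names_columns(self):
        n = 30
        rng = np.random.default_rng(0)
        a = rng.standard_normal(n)
        x = np.column_stack([np.ones(n), a, 2 * a])
        with pytest.raises(DesignError, match="collinear"):
            DesignMatrix(x, ("intercept", "a", "a2"), "a")

    def test_missing_intercept_rejected(self):
        with pytest.raises(DesignError, match="intercept"):
            DesignMatrix(np.random.default_rng(0).standard_normal((20, 2)),
                         ("a", "b"), "a")

    def test_too_few_subjects_rejected(self):
        x = np.column_stack([np.ones(4), np.arange(4), np.arange(4) ** 2])
        with pytest.raises(DesignError, match="n > p"):
            DesignMatrix(x, ("intercept", "a", "b"), "a")


class TestGLM:
    def test_constant_thickness_noise_covariate(self):
        n = 20
        d = design_with_noise_covariate(n)
        y = np.full((n, 50), 2.0)
        fit = fit_vertex_glm(y, d)
        assert np.abs(fit["beta"][0] - 2.0).max() < 1e-12
        assert np.abs(fit["t"]).max() < 1e-6

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_textbook_normal_equations(self, seed):
        """Vectorised GLM equals explicit per-vertex OLS to 1e-10."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 30))
        p = int(rng.integers(2, 5))
        x = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        cols = tuple(["intercept"] + [f"c{j}" for j in range(1, p)])
        d = DesignMatrix(x, cols, cols[-1])
        y = rng.standard_normal((n, 10))
        fit = fit_vertex_glm(y, d)
        c = d.contrast
        xtx_inv = np.linalg.inv(x.T @ x)
        for v in range(y.shape[1]):
            beta = xtx_inv @ x.T @ y[:, v]
            rss = np.sum((y[:, v] - x @ beta) ** 2)
            s2 = rss / (n - p)
            t = c @ beta / np.sqrt(c @ xtx_inv @ c * s2)
            assert np.abs(fit["beta"][:, v] - beta).max() < 1e-10
            assert fit["t"][v] == pytest.approx(t, abs=1e-10)
            assert fit["p"][v] == pytest.approx(
                2 * stats.t.sf(abs(t), n - p), abs=1e-12)

    def test_simulation_with_known_effect(self):
        rng = np.random.default_rng(7)
        n, nv = 200, 300
        cov = rng.standard_normal(n)
        x = np.column_stack([np.ones(n), cov])
        d = DesignMatrix(x, ("intercept", "cov"), "cov")
        y = 2.0 + 0.5 * cov[:, None] + rng.normal(0, 0.1, (n, nv))
        fit = fit_vertex_glm(y, d)
        se = np.sqrt(d.contrast @ np.linalg.inv(x.T @ x) @ d.contrast
                     * fit["sigma2"])
        within = np.abs(fit["beta"][1] - 0.5) <= 3 * se
        assert within.mean() >= 0.95


class TestSmoothness:
    def test_white_noise_limit(self):
        """Unit-norm residual roughness of i.i.d. noise: FWHM = h*sqrt(2 ln 2).

        White noise has edge-difference variance 2 per unit-variance
        field, so lambda = 2/h^2 and FWHM = sqrt(4 ln 2 / lambda).
        """
        mesh = dense_flat_grid(30, extent=29.0)   # h = 1 exactly on axis edges
        h = mesh.mean_edge_length
        expected = h * np.sqrt(2 * np.log(2))
        rng = np.random.default_rng(0)
        ests = []
        for _ in range(20):
            r = rng.standard_normal((12, mesh.n_vertices))
            fwhm, _ = estimate_smoothness(r, mesh)
            ests.append(fwhm)
        assert abs(np.mean(ests) - expected) / expected < 0.25

    def test_recovers_known_smoothness(self):
        """Construct-and-recover: fields smoothed to 8 mm FWHM."""
        mesh = dense_flat_grid(45, extent=88.0)   # 2 mm edges
        target = 8.0
        rng = np.random.default_rng(1)
        r = np.stack([
            smooth_field(SurfaceField(rng.standard_normal(mesh.n_vertices)),
                         mesh, fwhm=target).values
            for _ in range(20)
        ])
        fwhm, resels = estimate_smoothness(r, mesh)
        assert abs(fwhm - target) / target < 0.2

    def test_resels_scale_with_area(self):
        mesh = dense_flat_grid(20, extent=10.0)
        double = dense_flat_grid(20, extent=10.0 * np.sqrt(2))
        r0a, r1a, r2a = resel_counts(mesh, fwhm=4.0)
        r0b, r1b, r2b = resel_counts(double, fwhm=4.0)
        assert r2b == pytest.approx(2 * r2a, rel=1e-9)
        assert r1b == pytest.approx(np.sqrt(2) * r1a, rel=1e-9)
        assert r0a == r0b == 1

    def test_zero_variance_residuals_rejected(self):
        mesh = dense_flat_grid(10)
        with pytest.raises(DesignError):
            estimate_smoothness(np.zeros((8, mesh.n_vertices)), mesh)


class TestRFT:
    def test_zero_dimensional_limit_is_student_quantile(self):
        df = 25
        for alpha in (0.05, 0.01):
            thr = rft_threshold(df, (1.0, 0.0, 0.0), alpha=alpha,
                                two_sided=True)
            assert thr == pytest.approx(stats.t.isf(alpha / 2, df), abs=1e-5)

    def test_threshold_increases_with_resel_count(self):
        df = 30
        thresholds = [rft_threshold(df, (1.0, 5.0, r2), alpha=0.05)
                      for r2 in np.linspace(10, 500, 10)]
        assert all(b > a for a, b in zip(thresholds, thresholds[1:]))

    def test_expected_ec_at_threshold_equals_alpha_tail(self):
        df, resels, alpha = 40, (1.0, 10.0, 80.0), 0.05
        thr = rft_threshold(df, resels, alpha=alpha, two_sided=True)
        assert expected_euler_characteristic(thr, resels, df) == pytest.approx(
            alpha / 2, abs=1e-5)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            rft_threshold(10, (1, 0, 0), alpha=1.5)


class TestFDR:
    def test_no_rejection_gives_infinite_threshold(self):
        p = np.full(100, 0.9)
        t = np.random.default_rng(0).standard_normal(100)
        assert fdr_threshold(p, t, q=0.05) == np.inf

    def test_hand_computed_example(self):
        # BH on (0.001, 0.008, 0.039, 0.041, 0.6) at q=0.05:
        # largest k with p_(k) <= k*0.05/5 is k=2 -> reject first two
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.6])
        t = np.array([5.0, 4.0, 2.2, 2.1, 0.5])
        thr = fdr_threshold(p, t, q=0.05)
        assert thr == pytest.approx(4.0)
        assert (np.abs(t) >= thr).sum() == 2

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_bh_oracle(self, seed):
        """Step-up equals checking every k explicitly."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(5, 200))
        p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
        df = 20
        t = stats.t.isf(p / 2, df)
        q = 0.05
        # brute force: all k from largest to smallest
        order = np.argsort(p)
        k_star = 0
        for k in range(m, 0, -1):
            if p[order[k - 1]] <= k * q / m:
                k_star = k
                break
        thr = fdr_threshold(p, t, q=q)
        if k_star == 0:
            assert thr == np.inf
        else:
            rejected = np.abs(t) >= thr
            assert rejected.sum() == k_star
            assert rejected[order[:k_star]].all()

    def test_missing_vertices_ignored(self):
        p = np.array([1e-6, 0.5, 0.5, 1e-9])
        t = np.array([8.0, 1.0, 1.0, 10.0])
        missing = np.array([False, False, False, True])
        thr = fdr_threshold(p, t, q=0.05, missing_mask=missing)
        assert thr == pytest.approx(8.0)


@pytest.fixture(scope="module")
def patch():
    return make_canonical_patch("femur", 600, seed=5)


class TestRunSPM:

    def test_intercept_contrast_constant_thickness(self, patch):
        n = 30
        rng = np.random.default_rng(2)
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        d = DesignMatrix(x, ("intercept", "cov"), "intercept")
        y = 2.0 + rng.normal(0, 1e-4, (n, patch.n_vertices))
        res = run_spm(y, d, patch)
        assert res.significance_mask.all()
        assert np.abs(res.beta_maps["intercept"].values - 2.0).max() < 1e-2

    def test_min_threshold_and_mask_consistency(self, patch):
        n = 60
        rng = np.random.default_rng(3)
        cov = rng.standard_normal(n)
        x = np.column_stack([np.ones(n), cov])
        d = DesignMatrix(x, ("intercept", "cov"), "cov")
        y = 2.0 + 0.4 * cov[:, None] * (patch.vertices[:, 0] > 0) \
            + rng.normal(0, 0.3, (n, patch.n_vertices))
        res = run_spm(y, d, patch)
        assert res.t_threshold_final == min(res.t_threshold_rft,
                                            res.t_threshold_fdr)
        expect = np.abs(res.t_map.values) >= res.t_threshold_final
        np.testing.assert_array_equal(res.significance_mask, expect)
        # RFT-corrected threshold can never undercut the pointwise quantile
        assert res.t_threshold_rft >= stats.t.isf(0.025, res.df)

    def test_missing_vertices_dropped_for_everyone(self, patch):
        n = 25
        d = design_with_noise_covariate(n, seed=4)
        rng = np.random.default_rng(5)
        y = 2.0 + rng.normal(0, 0.2, (n, patch.n_vertices))
        y[3, :40] = np.nan
        res = run_spm(y, d, patch)
        assert (~res.analysis_mask[:40]).all()
        assert res.t_map.missing_mask[:40].all()
        assert res.analysis_mask[40:].all()

    def test_permutation_destroys_planted_significance(self, patch):
        n = 80
        rng = np.random.default_rng(6)
        cov = rng.standard_normal(n)
        x = np.column_stack([np.ones(n), cov])
        d = DesignMatrix(x, ("intercept", "cov"), "cov")
        effect = 0.5 * (patch.vertices[:, 1] > 0)
        y = 2.0 + cov[:, None] * effect + rng.normal(0, 0.3,
                                                     (n, patch.n_vertices))
        res = run_spm(y, d, patch)
        assert res.significance_mask.any()
        destroyed = 0
        reps = 10
        for r in range(reps):
            perm = rng.permutation(n)
            xp = np.column_stack([np.ones(n), cov[perm]])
            dp = DesignMatrix(xp, ("intercept", "cov"), "cov")
            rp = run_spm(y, dp, patch)
            destroyed += not rp.significance_mask.any()
        assert destroyed >= 0.9 * reps
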