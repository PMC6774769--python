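"""Single-Gaussian and mixture skin models: closed-form fits, EM steps,
likelihood monotonicity, parameter recovery and probability maps."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from skinmesh import skinmodel as sk
from skinmesh.colorspace import ChrominanceImage
from skinmesh.synthetic import sample_mixture


class TestSingleGaussian:
    def test_four_point_square_fit(self):
        X = np.array([[0.0, 0], [2, 0], [0, 2], [2, 2]])
        p = sk.fit_sgm(X)
        np.testing.assert_allclose(p.mu, [1, 1])
        np.testing.assert_allclose(p.sigma, np.eye(2))

    def test_identical_points_regularised(self):
        p = sk.fit_sgm(np.tile([0.3, 0.7], (10, 1)))
        np.testing.assert_allclose(p.mu, [0.3, 0.7])
        assert np.linalg.eigvalsh(p.sigma)[0] > 0  # ridge applied

    def test_monte_carlo_recovery(self, rng):
        mu, sigma = np.array([1.0, -2.0]), np.array([[2.0, 0.6], [0.6, 1.0]])
        X = rng.multivariate_normal(mu, sigma, size=10_000)
        p = sk.fit_sgm(X)
        se = np.sqrt(np.diag(sigma) / len(X))
        assert np.all(np.abs(p.mu - mu) < 3 * se)
        assert np.all(np.abs(p.sigma - sigma) < 0.1)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            sk.fit_sgm(np.array([[0.0, 0], [1, 1]]))

    @pytest.mark.parametrize(
        "x, expected",
        [((1.0, 1.0), 0.0), ((4.0, 5.0), 25.0)],
    )
    def test_mahalanobis_identity_cov(self, x, expected):
        p = sk.SGMParams([1.0, 1.0], np.eye(2))
        assert sk.mahalanobis_sq(np.array(x), p) == pytest.approx(expected)

    def test_mahalanobis_matches_explicit_2x2_inverse(self, rng):
        A = rng.random((2, 2))
        sigma = A @ A.T + 0.5 * np.eye(2)
        p = sk.SGMParams(rng.random(2), sigma)
        x = rng.random(2)
        (a, b), (c, d) = sigma
        inv = np.array([[d, -b], [-c, a]]) / (a * d - b * c)
        diff = x - p.mu
        assert sk.mahalanobis_sq(x, p) == pytest.approx(diff @ inv @ diff)

    def test_pdf_peak_identity_cov(self):
        p = sk.SGMParams([0.0, 0.0], np.eye(2))
        assert sk.sgm_pdf(np.zeros(2), p) == pytest.approx(1 / (2 * np.pi))

    def test_pdf_matches_scipy_and_integrates_to_one(self, rng):
        mu = rng.random(2)
        A = rng.random((2, 2))
        sigma = A @ A.T + 0.3 * np.eye(2)
        p = sk.SGMParams(mu, sigma)
        pts = rng.random((50, 2)) * 4 - 2
        np.testing.assert_allclose(
            sk.sgm_pdf(pts, p), multivariate_normal(mu, sigma).pdf(pts), rtol=1e-10
        )
        half = 6 * np.sqrt(np.diag(sigma).max())
        g = np.linspace(-half, half, 400)
        xx, yy = np.meshgrid(mu[0] + g, mu[1] + g)
        grid = np.stack([xx.ravel(), yy.ravel()], axis=1)
        integral = sk.sgm_pdf(grid, p).sum() * (g[1] - g[0]) ** 2
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_covariance_scaling_quarters_peak(self):
        p1 = sk.SGMParams([0.0, 0.0], np.eye(2))
        p4 = sk.SGMParams([0.0, 0.0], 4 * np.eye(2))
        assert sk.sgm_pdf(np.zeros(2), p4) == pytest.approx(
            sk.sgm_pdf(np.zeros(2), p1) / 4
        )


class TestMixtureDensity:
    def test_single_component_collapses_to_gaussian(self, rng):
        mu, sigma = rng.random(2), np.eye(2) * 0.5
        g = sk.GMMParams([1.0], [mu], [sigma])
        x = rng.random((20, 2))
        np.testing.assert_allclose(
            sk.gmm_pdf(x, g), sk.sgm_pdf(x, sk.SGMParams(mu, sigma)), rtol=1e-12
        )

    def test_well_separated_peak_is_half_component_peak(self, separated_mixture):
        peak = sk.gmm_pdf(np.array([0.0, 0.0]), separated_mixture)
        assert peak == pytest.approx(0.5 / (2 * np.pi), rel=1e-8)

    def test_density_dominates_each_weighted_component(self, rng, separated_mixture):
        x = rng.random((30, 2)) * 8 - 1
        total = sk.gmm_pdf(x, separated_mixture)
        for j in range(2):
            comp = sk.sgm_pdf(
                x,
                sk.SGMParams(
                    separated_mixture.means[j], separated_mixture.covariances[j]
                ),
            )
            assert np.all(total >= separated_mixture.priors[j] * comp - 1e-15)

    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            sk.GMMParams([0.7, 0.7], [[0, 0], [1, 1]], [np.eye(2)] * 2)


class TestEMSteps:
    def test_histogram_init_finds_distant_modes(self, separated_mixture):
        X, _ = sample_mixture(separated_mixture, 4000, seed=7)
        init = sk.init_gmm(X, 2)
        bin_width = max(np.ptp(X[:, 0]), np.ptp(X[:, 1])) / 64
        order = np.argsort(init.means[:, 0])
        for found, true in zip(init.means[order], [[0, 0], [5, 5]]):
            assert np.abs(np.asarray(found) - true).max() < 2 * bin_width

    def test_init_single_component_at_mean_bin(self, rng):
        X = rng.normal(size=(2000, 2))
        init = sk.init_gmm(X, 1)
        assert np.abs(init.means[0] - X.mean(axis=0)).max() < 0.5

    def test_init_deterministic(self, separated_mixture):
        X, _ = sample_mixture(separated_mixture, 1000, seed=3)
        a, b = sk.init_gmm(X, 2, seed=1), sk.init_gmm(X, 2, seed=1)
        np.testing.assert_array_equal(a.means, b.means)

    def test_init_rejects_excess_components(self):
        X = np.tile([0.5, 0.5], (100, 1))
        with pytest.raises(ValueError, match="reduce the component count"):
            sk.init_gmm(X, 3)

    def test_e_step_single_component_all_ones(self, rng):
        g = sk.GMMParams([1.0], [[0, 0]], [np.eye(2)])
        h = sk.em_e_step(rng.random((15, 2)), g)
        np.testing.assert_allclose(h, 1.0)

    def test_e_step_identical_components_uniform(self, rng):
        g = sk.GMMParams([0.25] * 4, [[0, 0]] * 4, [np.eye(2)] * 4)
        h = sk.em_e_step(rng.random((15, 2)), g)
        np.testing.assert_allclose(h, 0.25)

    def test_e_step_dominant_component(self):
        g = sk.GMMParams(
            [0.5, 0.5], [[0, 0], [5, 5]], [np.eye(2) * 1e-4, np.eye(2) * 1e-4]
        )
        h = sk.em_e_step(np.array([[0.0, 0.0]]), g)
        assert h[0, 0] == pytest.approx(1.0)

    def test_e_step_rows_normalised_even_for_remote_points(self, separated_mixture):
        h = sk.em_e_step(np.array([[500.0, -500.0]]), separated_mixture)
        np.testing.assert_allclose(h.sum(axis=1), 1.0, atol=1e-9)

    def test_m_step_single_column_reproduces_sgm(self, rng):
        X = rng.random((50, 2))
        g = sk.em_m_step(X, np.ones((50, 1)))
        p = sk.fit_sgm(X)
        np.testing.assert_allclose(g.means[0], p.mu, atol=1e-12)
        np.testing.assert_allclose(g.covariances[0], p.sigma, atol=1e-12)

    def test_m_step_hard_assignment_partitions(self, rng):
        X = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(8, 1, (60, 2))])
        h = np.zeros((100, 2))
        h[:40, 0] = 1
        h[40:, 1] = 1
        g = sk.em_m_step(X, h)
        for j, sl in enumerate((slice(0, 40), slice(40, 100))):
            p = sk.fit_sgm(X[sl])
            np.testing.assert_allclose(g.means[j], p.mu, atol=1e-12)
            np.testing.assert_allclose(g.covariances[j], p.sigma, atol=1e-10)
        assert g.priors.sum() == pytest.approx(1.0, abs=1e-12)


class TestEMFit:
    def test_loglike_trace_non_decreasing(self, rng):
        for _ in range(5):
            X = rng.random((300, 2)) * rng.integers(1, 5)
            _, trace = sk.fit_gmm(X, 3, max_iter=30)
            assert np.all(np.diff(trace) >= -1e-8)

    def test_j1_equals_single_gaussian(self, rng):
        X = rng.normal(size=(400, 2))
        res = sk.GaussianMixtureModel(X, 1).fit()
        p = sk.fit_sgm(X)
        np.testing.assert_allclose(res.means[0], p.mu, atol=1e-9)
        np.testing.assert_allclose(res.covariances[0], p.sigma, atol=1e-9)
        assert res.priors[0] == pytest.approx(1.0, abs=1e-12)

    def test_two_component_recovery(self, separated_mixture):
        X, _ = sample_mixture(separated_mixture, 5000, seed=11)
        res = sk.GaussianMixtureModel(X, 2).fit(seed=11)
        m = res.means[np.argsort(res.means[:, 0])]
        assert np.linalg.norm(m[0] - [0, 0]) < 0.15
        assert np.linalg.norm(m[1] - [5, 5]) < 0.15
        assert np.all(np.abs(res.priors - 0.5) < 0.05)

    def test_max_iter_respected(self, separated_mixture):
        X, _ = sample_mixture(separated_mixture, 800, seed=2)
        _, trace = sk.fit_gmm(X, 2, max_iter=5, tol=0.0)
        assert len(trace) == 6  # 5 iteration entries + final value

    def test_loglike_agrees_with_reference_em(self, separated_mixture):
        # Independent oracle: score the same parameters with sklearn.
        from sklearn.mixture import GaussianMixture

        X, _ = sample_mixture(separated_mixture, 2000, seed=4)
        g, _ = sk.fit_gmm(X, 2, max_iter=50, seed=4)
        ref = GaussianMixture(n_components=2, covariance_type="full")
        ref.weights_ = g.priors
        ref.means_ = g.means
        ref.precisions_cholesky_ = np.array(
            [np.linalg.inv(np.linalg.cholesky(c)).T for c in g.covariances]
        )
        assert sk.gmm_loglike(X, g) == pytest.approx(
            ref.score(X) * len(X), rel=1e-9
        )

    def test_density_integrates_to_one(self, separated_mixture):
        g = 12.0
        axis = np.linspace(-6, 11, 500)
        xx, yy = np.meshgrid(axis, axis)
        pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
        integral = sk.gmm_pdf(pts, separated_mixture).sum() * (axis[1] - axis[0]) ** 2
        assert integral == pytest.approx(1.0, abs=1e-3)


class TestProbabilityMaps:
    def _image(self, values):
        return ChrominanceImage(np.asarray(values, dtype=float), "lab")

    def test_uniform_image_at_model_mean_is_maximal(self, rng):
        res = sk.SingleGaussianModel(
            rng.normal([10, 10], 1, (500, 2)), space_tag="lab"
        ).fit()
        img = self._image(np.tile(res.mu, (4, 5, 1)))
        pm = res.probability_map(img)
        np.testing.assert_allclose(pm.values, 1.0)

    def test_skin_region_scores_above_background(self, rng, separated_mixture):
        skin = sk.SingleGaussianModel(
            rng.normal([0, 0], 1, (500, 2)), space_tag="lab"
        ).fit()
        img_vals = np.zeros((10, 10, 2))
        img_vals[:, 5:] = [5.0, 5.0]
        pm = skin.probability_map(self._image(img_vals))
        assert pm.values[:, :5].mean() > pm.values[:, 5:].mean()

    def test_posterior_variant_bounded(self, rng):
        skin = sk.SingleGaussianModel(rng.normal(0, 1, (300, 2)), space_tag="lab").fit()
        bg = sk.SingleGaussianModel(rng.normal(4, 1, (300, 2)), space_tag="lab").fit()
        pm = skin.probability_map(self._image(rng.normal(2, 3, (8, 8, 2))), bg)
        assert pm.kind == "posterior"
        assert np.all((pm.values >= 0) & (pm.values <= 1))

    def test_space_tag_mismatch_rejected(self, rng):
        res = sk.SingleGaussianModel(rng.random((100, 2)), space_tag="hsv").fit()
        with pytest.raises(ValueError, match="does not match"):
            res.probability_map(self._image(np.zeros((2, 2, 2))))

    def test_threshold_edges(self):
        pm = sk.ProbabilityMap(np.array([[0.5, 0.6]]), "lab")
        assert sk.threshold_map(pm, 0.0).all()
        assert not sk.threshold_map(pm, 0.7).any()
        np.testing.assert_array_equal(sk.threshold_map(pm, 0.55), [[False, True]])

    def test_serialisation_round_trip(self, tmp_path, rng, separated_mixture):
        X, _ = sample_mixture(separated_mixture, 1000, seed=5)
        res = sk.GaussianMixtureModel(X, 2, space_tag="lab").fit(seed=5)
        path = tmp_path / "model.yaml"
        res.save(path)
        loaded = sk.load_results(path)
        pts = rng.random((10, 2)) * 6
        np.testing.assert_allclose(loaded.pdf(pts), res.pdf(pts), rtol=1e-8)
        assert loaded.space_tag == "lab"
        assert loaded.peak_density == pytest.approx(res.peak_density)


class TestSummaries:
    def test_summary_mentions_key_quantities(self, rng):
        res = sk.SingleGaussianModel(rng.random((100, 2)), space_tag="lab").fit()
        text = res.summary()
        assert "Single Gaussian" in text and "lab" in text
        res2 = sk.GaussianMixtureModel(rng.random((200, 2)), 2).fit()
        text2 = res2.summary()
        assert "EM iterations" in text2 and "prior" in text2
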