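"""Likelihood, posterior weights, and the MLE / MAP / MMSE estimators."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import bayespose as bp
from bayespose.estimators import TemplateCache
from bayespose.forward_model import Observation, PolarImage2D
from bayespose.so3 import geodesic_distance_many, grid_from_samples


def on_grid_observation(phantom, grid, node, sigma, seed=0):
    clean = bp.rotate_volume(phantom, grid.nodes[node]).grid
    rng = np.random.default_rng(seed)
    return Observation(clean + rng.normal(0, sigma, clean.shape), sigma, "subtomogram-3d")


class TestNegativeLogLikelihood:
    def test_zero_residual_leaves_gaussian_constant(self, phantom24, grid300):
        g = grid300.nodes[17]
        clean = bp.rotate_volume(phantom24, g).grid
        sigma = 0.8
        y = Observation(clean, sigma, "subtomogram-3d")
        d = clean.size
        expected = 0.5 * d * np.log(2 * np.pi * sigma**2)
        assert bp.negative_log_likelihood(y, phantom24, g) == pytest.approx(expected)

    def test_orthogonal_perturbation_adds_energy_term(self, phantom24, grid300):
        g = grid300.nodes[3]
        clean = bp.rotate_volume(phantom24, g).grid
        delta = np.zeros_like(clean)
        delta[0, 0, 0] = 2.0  # phantom vanishes at the corner: orthogonal
        assert clean[0, 0, 0] == 0.0
        sigma = 0.5
        base = bp.negative_log_likelihood(Observation(clean, sigma, "subtomogram-3d"), phantom24, g)
        pert = bp.negative_log_likelihood(
            Observation(clean + delta, sigma, "subtomogram-3d"), phantom24, g
        )
        assert pert - base == pytest.approx(4.0 / (2 * sigma**2))

    def test_matches_gaussian_density_on_toy(self):
        """3-pixel polar toy: value equals -log N(y; template, sigma^2 I)."""
        template = PolarImage2D(np.array([[1.0, 2.0, 0.5]]))
        y = Observation(np.array([[1.2, 1.8, 0.6]]), 0.7, "polar-2d")
        got = bp.negative_log_likelihood(y, template, 0)
        expected = -multivariate_normal(
            mean=template.grid.ravel(), cov=0.49 * np.eye(3)
        ).logpdf(y.data.ravel())
        assert got == pytest.approx(expected, rel=1e-12)


class TestPosteriorWeights:
    def test_prior_recovery_at_infinite_noise(self, phantom24):
        grid = bp.build_so3_quadrature(40)
        prior = bp.PriorSO3.igso3(0.5)
        y = Observation(phantom24.grid, 1e6, "subtomogram-3d")
        w = bp.posterior_weights(y, phantom24, grid, prior)
        expected = grid.weights * prior.density(grid.nodes)
        expected /= expected.sum()
        np.testing.assert_allclose(w.weights, expected, atol=1e-4)

    def test_one_hot_in_noiseless_limit(self, phantom24, grid300, cache24):
        node = 42
        clean = bp.rotate_volume(phantom24, grid300.nodes[node]).grid
        y = Observation(clean, 1e-3, "subtomogram-3d")
        w = bp.posterior_weights(y, phantom24, grid300, cache=cache24)
        assert np.argmax(w.weights) == node
        assert w.weights[node] > 0.999

    def test_matches_extended_precision_brute_force(self, phantom24):
        """L = 12 toy against naive unnormalized products in long double."""
        nodes = bp.sample_uniform_rotations(12, seed=8)
        grid = grid_from_samples(nodes)
        sigma = phantom24.grid.std() * 2
        y = bp.add_noise(bp.rotate_volume(phantom24, nodes[4]), sigma, seed=9)
        w = bp.posterior_weights(y, phantom24, grid)
        resid = np.array(
            [np.sum((y.data - bp.rotate_volume(phantom24, g).grid) ** 2) for g in nodes],
            dtype=np.longdouble,
        )
        raw = np.exp(-(resid - resid.min()) / (2 * np.longdouble(sigma) ** 2)) / 12
        expected = (raw / raw.sum()).astype(float)
        np.testing.assert_allclose(w.weights, expected, atol=1e-10)

    def test_no_nan_at_tiny_sigma(self, phantom24, grid300, cache24):
        y = Observation(bp.rotate_volume(phantom24, grid300.nodes[5]).grid, 1e-6, "subtomogram-3d")
        w = bp.posterior_weights(y, phantom24, grid300, cache=cache24)
        assert np.all(np.isfinite(w.weights))
        assert w.weights.sum() == pytest.approx(1.0)

    def test_rejects_nan_observation(self, phantom24, grid300, cache24):
        bad = phantom24.grid.copy()
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            bp.posterior_weights(
                Observation(bad, 1.0, "subtomogram-3d"), phantom24, grid300, cache=cache24
            )


class TestMLE:
    def test_recovers_grid_node_noiselessly(self, phantom24, grid300, cache24):
        node = 7
        clean = bp.rotate_volume(phantom24, grid300.nodes[node]).grid
        y = Observation(clean, 1e-6, "subtomogram-3d")
        res = bp.estimate_mle(y, phantom24, grid300, cache=cache24)
        assert res.node_index == node
        np.testing.assert_array_equal(res.g_hat, grid300.nodes[node])

    def test_prior_free(self, phantom24, grid300, cache24):
        """MLE coincides with MAP under the uniform prior (equal weights)."""
        for seed in range(20):
            g = bp.sample_uniform_rotations(1, seed=seed)[0]
            y = bp.add_noise(bp.rotate_volume(phantom24, g), 0.1, seed=seed)
            mle = bp.estimate_mle(y, phantom24, grid300, cache=cache24)
            map_ = bp.estimate_map(y, phantom24, grid300, bp.PriorSO3.uniform(), cache=cache24)
            assert mle.node_index == map_.node_index

    def test_high_snr_error_bounded_by_covering_radius(self, phantom24, grid300, cache24):
        # the covering radius is itself a Monte-Carlo estimate (max over
        # probes), so allow a 5% slack on the bound
        cover = grid300.covering_radius(4000)
        for seed in range(5):
            g = bp.sample_uniform_rotations(1, seed=100 + seed)[0]
            sigma = bp.sigma_for_snr(phantom24.grid, 1e4)
            y = bp.add_noise(bp.rotate_volume(phantom24, g), sigma, seed=seed)
            res = bp.estimate_mle(y, phantom24, grid300, cache=cache24)
            assert bp.geodesic_distance(res.g_hat, g) <= 1.05 * cover


class TestMAP:
    def test_infinite_noise_returns_prior_mode(self, phantom24):
        grid = bp.build_so3_quadrature(60)
        prior = bp.PriorSO3.igso3(0.4)
        y = Observation(phantom24.grid, 1e7, "subtomogram-3d")
        res = bp.estimate_map(y, phantom24, grid, prior)
        expected = np.argmax(grid.weights * prior.density(grid.nodes))
        assert res.node_index == expected

    def test_matches_brute_force_argmax(self, phantom24):
        nodes = bp.sample_uniform_rotations(12, seed=21)
        grid = grid_from_samples(nodes)
        prior = bp.PriorSO3.igso3(0.8)
        sigma = phantom24.grid.std()
        y = bp.add_noise(bp.rotate_volume(phantom24, nodes[2]), sigma, seed=22)
        res = bp.estimate_map(y, phantom24, grid, prior)
        logits = [
            np.log(grid.weights[l] * prior.density(nodes[l]))
            - np.sum((y.data - bp.rotate_volume(phantom24, nodes[l]).grid) ** 2) / (2 * sigma**2)
            for l in range(12)
        ]
        assert res.node_index == int(np.argmax(logits))


class TestMMSE:
    def test_one_hot_weights_return_node(self, phantom24, grid300, cache24):
        node = 19
        clean = bp.rotate_volume(phantom24, grid300.nodes[node]).grid
        y = Observation(clean, 1e-4, "subtomogram-3d")
        res = bp.estimate_mmse(y, phantom24, grid300, cache=cache24)
        assert bp.geodesic_distance(res.g_hat, grid300.nodes[node]) < 1e-6
        assert res.pre_projection is not None
        np.testing.assert_allclose(
            res.g_hat, bp.procrustes_project(res.pre_projection), atol=1e-12
        )

    def test_symmetric_average_projects_to_identity(self):
        """Equal weights on rotations by +/- theta about z average to the identity."""
        from scipy.spatial.transform import Rotation as R

        theta = 0.7
        gp = R.from_euler("z", theta).as_matrix()
        gm = R.from_euler("z", -theta).as_matrix()
        E = 0.5 * gp + 0.5 * gm
        np.testing.assert_allclose(bp.procrustes_project(E), np.eye(3), atol=1e-12)

    def test_matches_bayes_risk_brute_force(self, phantom24):
        """The Procrustes-projected posterior mean minimizes the posterior
        expected squared chordal loss over a dense rotation search."""
        nodes = bp.sample_uniform_rotations(24, seed=31)
        grid = grid_from_samples(nodes)
        sigma = phantom24.grid.std() * 3
        y = bp.add_noise(bp.rotate_volume(phantom24, nodes[0]), sigma, seed=32)
        res = bp.estimate_mmse(y, phantom24, grid)
        w = res.weights_ref.weights
        search = bp.sample_uniform_rotations(100000, seed=33)
        # sum_l w_l ||g - g_l||_F^2 = 6 - 2 tr(g^T E): minimized by max trace
        scores = np.einsum("sij,ij->s", search, res.pre_projection)
        g_bf = search[np.argmax(scores)]
        spacing = grid_from_samples(search).covering_radius(500)
        assert bp.geodesic_distance(res.g_hat, g_bf) <= spacing + 1e-9

    def test_risk_not_worse_than_mle_at_low_snr(self, phantom24, grid300, cache24):
        """Paired low-SNR trials: mean squared chordal error of MMSE below MLE
        (the loss the posterior mean optimizes)."""
        from bayespose.harness import _draw_trials, batch_pose_errors

        sigma = bp.sigma_for_snr(phantom24.grid, 1e-2)
        g_true, clean, noise = _draw_trials(
            phantom24, bp.PriorSO3.uniform(), 400, 77, "subtomogram-3d"
        )
        errs = batch_pose_errors(
            g_true, clean + sigma * noise, sigma, cache24, grid300,
            ("mle", "mmse"), bp.PriorSO3.uniform(),
        )
        sq_chordal = {m: np.mean((2 * np.sqrt(2) * np.sin(e / 2)) ** 2) for m, e in errs.items()}
        assert sq_chordal["mmse"] < sq_chordal["mle"]


class TestBackRotation:
    def test_one_hot_weights_invert_single_node(self, phantom24, grid300, cache24):
        node = 11
        g = grid300.nodes[node]
        clean = bp.rotate_volume(phantom24, g).grid
        y = Observation(clean, 1e-4, "subtomogram-3d")
        back = bp.mmse_back_rotate(y, phantom24, grid300, cache=cache24)
        expected = bp.rotate_volume(bp.Volume3D(clean), g.T).grid
        assert np.linalg.norm(back - expected) / np.linalg.norm(expected) < 1e-6

    def test_uniform_weights_average_over_cyclic_group(self):
        img = bp.make_polar_phantom(16, 8, seed=1)
        grid = bp.build_cyclic_grid(8)
        y = Observation(img.grid, 1e9, "polar-2d")  # flat posterior
        back = bp.mmse_back_rotate(y, img, grid)
        np.testing.assert_allclose(back - back[:, :1], 0.0, atol=1e-9)  # constant over angles

    def test_matches_naive_weighted_sum_on_polar_toy(self):
        img = bp.make_polar_phantom(12, 8, seed=2)
        grid = bp.build_cyclic_grid(8)
        y = bp.add_noise(img, 0.5, seed=3, model="polar-2d")
        w = bp.posterior_weights(y, img, grid)
        naive = sum(
            wk * np.roll(y.data, -k, axis=1) for k, wk in enumerate(w.weights)
        )
        back = bp.mmse_back_rotate(y, img, grid, weights=w)
        np.testing.assert_allclose(back, naive, atol=1e-12)

    def test_projection_model_unsupported(self, phantom24, grid300):
        y = Observation(bp.project_volume(phantom24), 1.0, "projection-2d")
        with pytest.raises(ValueError):
            bp.mmse_back_rotate(y, phantom24, grid300)


class TestFastPolarCorrelations:
    def test_self_template_minimum_at_zero(self):
        img = bp.make_polar_phantom(32, 30, seed=4)
        r = bp.fast_polar_correlations(img, img)
        assert np.argmin(r) == 0 and r[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_direct_loop(self, rng):
        y = PolarImage2D(rng.normal(size=(20, 30)))
        t = PolarImage2D(rng.normal(size=(20, 30)))
        fast = bp.fast_polar_correlations(y, t)
        direct = np.array(
            [np.sum((y.grid - np.roll(t.grid, k, axis=1)) ** 2) for k in range(30)]
        )
        np.testing.assert_allclose(fast, direct, rtol=1e-8)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bp.fast_polar_correlations(
                bp.make_polar_phantom(8, 10, seed=0), bp.make_polar_phantom(8, 12, seed=0)
            )


class TestEquivariance:
    def test_mmse_uniform_prior_global_rotation_equivariance(self, phantom24):
        """Rotating the grid, observation and truth together rotates the MMSE
        estimate accordingly (within interpolation error)."""
        nodes = bp.sample_uniform_rotations(64, seed=41)
        grid = grid_from_samples(nodes)
        g_true = nodes[10]
        sigma = bp.sigma_for_snr(phantom24.grid, 1.0)
        y = bp.add_noise(bp.rotate_volume(phantom24, g_true), sigma, seed=42)
        res = bp.estimate_mmse(y, phantom24, grid)
        h = bp.sample_uniform_rotations(1, seed=43)[0]
        grid_h = grid_from_samples(np.einsum("ij,ljk->lik", h, nodes))
        y_h = Observation(
            bp.rotate_volume(bp.Volume3D(y.data), h).grid, y.sigma, "subtomogram-3d"
        )
        res_h = bp.estimate_mmse(y_h, phantom24, grid_h)
        assert bp.geodesic_distance(res_h.g_hat, h @ res.g_hat) < 0.2
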