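"""Rotation metrics, Procrustes projection, quadrature and SO(3) priors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation as R
from scipy.stats import kstest, ks_2samp

import bayespose as bp
from bayespose.so3 import (
    DegenerateProjectionError,
    InvalidRotationError,
    check_rotation,
    euler_zyz_deg_from_matrix,
    geodesic_distance_many,
    haar_angle_density,
    matrix_from_quaternion,
    procrustes_project_many,
    quaternion_from_matrix,
)


def rotvec(axis, angle):
    axis = np.asarray(axis, dtype=float)
    return R.from_rotvec(axis / np.linalg.norm(axis) * angle).as_matrix()


class TestMetrics:
    def test_identity_distances_are_zero(self):
        assert bp.chordal_distance(np.eye(3), np.eye(3)) == 0.0
        assert bp.geodesic_distance(np.eye(3), np.eye(3)) == 0.0

    def test_half_turn_attains_chordal_maximum(self):
        g = rotvec([0, 0, 1], np.pi)
        assert bp.chordal_distance(np.eye(3), g) == pytest.approx(2 * np.sqrt(2), abs=1e-12)

    def test_geodesic_equals_rotation_angle(self):
        for axis in ([1, 0, 0], [0, 1, 0], [1, 1, 1]):
            g = rotvec(axis, np.pi / 2)
            assert bp.geodesic_distance(np.eye(3), g) == pytest.approx(np.pi / 2, abs=1e-12)

    def test_chordal_geodesic_identity(self, random_rotation_pairs):
        """d_F = 2*sqrt(2)*sin(d_G/2) holds exactly for arbitrary pairs."""
        for g1, g2 in zip(*random_rotation_pairs):
            dF = bp.chordal_distance(g1, g2)
            dG = bp.geodesic_distance(g1, g2)
            assert dF == pytest.approx(2 * np.sqrt(2) * np.sin(dG / 2), abs=1e-10)

    def test_bi_invariance(self, random_rotation_pairs):
        g1s, g2s = random_rotation_pairs
        hs = bp.sample_uniform_rotations(10, seed=5)
        for g1, g2, h in zip(g1s, g2s, hs):
            assert bp.chordal_distance(h @ g1, h @ g2) == pytest.approx(
                bp.chordal_distance(g1, g2), abs=1e-10
            )
            assert bp.geodesic_distance(h @ g1, h @ g2) == pytest.approx(
                bp.geodesic_distance(g1, g2), abs=1e-10
            )

    def test_small_angle_ratio_approaches_sqrt2(self):
        g1 = bp.sample_uniform_rotations(1, seed=2)[0]
        g2 = g1 @ rotvec([1, 2, 3], 1e-4)
        ratio = bp.chordal_distance(g1, g2) / bp.geodesic_distance(g1, g2)
        assert ratio == pytest.approx(np.sqrt(2), abs=1e-6)

    def test_rejects_non_rotation(self):
        with pytest.raises(InvalidRotationError):
            bp.chordal_distance(np.eye(3) * 2, np.eye(3))
        with pytest.raises(InvalidRotationError):
            bp.geodesic_distance(-np.eye(3), np.eye(3))  # det = -1


class TestProcrustes:
    def test_rotation_is_fixed_point(self):
        g = bp.sample_uniform_rotations(1, seed=3)[0]
        np.testing.assert_allclose(bp.procrustes_project(g), g, atol=1e-12)

    def test_positive_scaling_invariance(self):
        np.testing.assert_allclose(bp.procrustes_project(2 * np.eye(3)), np.eye(3), atol=1e-12)

    def test_beats_grid_search(self, rng):
        """Projection must beat every rotation in a dense grid (Frobenius)."""
        grid = bp.sample_uniform_rotations(20000, seed=9)
        for _ in range(20):
            A = rng.normal(size=(3, 3))
            p = bp.procrustes_project(A)
            d_p = np.linalg.norm(A - p)
            d_grid = np.linalg.norm(A[None] - grid, axis=(1, 2)).min()
            assert d_p <= d_grid + 1e-12

    def test_degenerate_raises_and_fallback(self):
        A = np.outer([1.0, 0, 0], [1.0, 0, 0])  # rank 1: two zero singular values
        with pytest.raises(DegenerateProjectionError):
            bp.procrustes_project(A)
        fb = np.eye(3)
        np.testing.assert_array_equal(bp.procrustes_project(A, fallback=fb), fb)

    def test_result_is_proper_rotation_even_with_reflection(self, rng):
        # matrices with negative determinant exercise the sign flip
        for _ in range(20):
            A = rng.normal(size=(3, 3))
            if np.linalg.det(A) > 0:
                A[:, 0] *= -1
            check_rotation(bp.procrustes_project(A))

    def test_batched_matches_single(self, rng):
        A = rng.normal(size=(15, 3, 3))
        batch = procrustes_project_many(A)
        for a, b in zip(A, batch):
            np.testing.assert_allclose(bp.procrustes_project(a), b, atol=1e-10)


class TestQuadrature:
    def test_single_node_is_identity(self):
        grid = bp.build_so3_quadrature(1)
        assert len(grid) == 1
        np.testing.assert_array_equal(grid.nodes[0], np.eye(3))
        assert grid.weights[0] == 1.0

    @pytest.mark.parametrize("L", [10, 300, 1000])
    def test_weights_normalized_and_nodes_valid(self, L):
        grid = bp.build_so3_quadrature(L)
        assert abs(grid.weights.sum() - 1.0) < 1e-10
        for g in grid.nodes[:: max(1, len(grid) // 20)]:
            check_rotation(g)

    def test_haar_first_moment_vanishes(self):
        grid = bp.build_so3_quadrature(300)
        m = np.einsum("l,lij->ij", grid.weights, grid.nodes)
        assert np.abs(m).max() < 0.05

    def test_cyclic_grid_closure(self):
        grid = bp.build_cyclic_grid(12)
        g1, g5 = grid.nodes[1], grid.nodes[5]
        np.testing.assert_allclose(g1 @ g5, grid.nodes[6], atol=1e-12)

    def test_covering_radius_shrinks_with_L(self):
        r_small = bp.build_so3_quadrature(100).covering_radius(500)
        r_big = bp.build_so3_quadrature(2000).covering_radius(500)
        assert r_big < r_small


class TestHaarSampling:
    def test_deterministic(self):
        a = bp.sample_uniform_rotations(5, seed=42)
        b = bp.sample_uniform_rotations(5, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_first_moment(self):
        rs = bp.sample_uniform_rotations(100000, seed=1)
        assert np.abs(rs.mean(axis=0)).max() < 0.02

    def test_angle_marginal_matches_haar(self):
        rs = bp.sample_uniform_rotations(10000, seed=2)
        ang = geodesic_distance_many(np.broadcast_to(np.eye(3), rs.shape), rs)
        # CDF of (1-cos w)/pi is (w - sin w)/pi
        stat = kstest(ang, lambda w: (w - np.sin(w)) / np.pi)
        assert stat.pvalue > 0.01


class TestIGSO3:
    def test_density_normalized(self):
        w = np.linspace(0, np.pi, 4001)
        for eta in (0.05, 0.5, 10.0):
            f = bp.igso3_angle_density(w, eta)
            assert np.trapezoid(f, w) == pytest.approx(1.0, abs=1e-6)

    def test_large_eta_approaches_haar(self):
        w = np.linspace(0, np.pi, 1001)
        f = bp.igso3_angle_density(w, 10.0)
        assert np.abs(f - haar_angle_density(w)).max() < 1e-3

    def test_small_eta_concentrates_near_zero(self):
        w = np.linspace(0, np.pi, 8001)
        f = bp.igso3_angle_density(w, 0.05)
        mass = np.trapezoid(np.where(w <= 0.3, f, 0.0), w)
        assert mass > 0.99

    def test_invalid_eta(self):
        with pytest.raises(ValueError):
            bp.igso3_angle_density(0.5, -1.0)
        with pytest.raises(ValueError):
            bp.igso3_sample(10, 0.0, seed=0)

    def test_sample_concentration(self):
        rs = bp.igso3_sample(10000, eta=0.05, seed=3)
        ang = geodesic_distance_many(np.broadcast_to(np.eye(3), rs.shape), rs)
        assert ang.mean() < 0.15

    def test_large_eta_sample_indistinguishable_from_haar(self):
        a = bp.igso3_sample(10000, eta=10.0, seed=4)
        b = bp.sample_uniform_rotations(10000, seed=5)
        ang_a = geodesic_distance_many(np.broadcast_to(np.eye(3), a.shape), a)
        ang_b = geodesic_distance_many(np.broadcast_to(np.eye(3), b.shape), b)
        assert ks_2samp(ang_a, ang_b).pvalue > 0.01

    def test_sample_reproducible(self):
        np.testing.assert_array_equal(
            bp.igso3_sample(7, eta=0.3, seed=6), bp.igso3_sample(7, eta=0.3, seed=6)
        )

    def test_prior_density_ratio_sane(self):
        prior = bp.PriorSO3.igso3(0.3)
        small = R.from_rotvec([0.05, 0, 0]).as_matrix()
        large = R.from_rotvec([0, 0, 3.0]).as_matrix()
        assert prior.density(small) > prior.density(large)
        uni = bp.PriorSO3.uniform()
        assert uni.density(small) == 1.0


class TestParameterizations:
    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_quaternion_round_trip(self, seed):
        g = bp.sample_uniform_rotations(1, seed=seed)[0]
        q = quaternion_from_matrix(g)
        assert q[0] >= 0 and np.linalg.norm(q) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(matrix_from_quaternion(q), g, atol=1e-10)

    def test_euler_zyz_matches_scipy_convention(self):
        g = R.from_euler("ZYZ", [10, 20, 30], degrees=True).as_matrix()
        np.testing.assert_allclose(euler_zyz_deg_from_matrix(g), [10, 20, 30], atol=1e-9)
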