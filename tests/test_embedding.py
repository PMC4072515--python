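"""Classical and non-metric MDS, S-cone identification, rotation."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from conelearn.embedding import (
    AmbiguousClusterError,
    Embedding,
    NonmetricMDS,
    RotationError,
    classical_mds,
    identify_s_cones,
    nmds,
    rotate_embedding,
    stress1,
)


def _euclidean_d(coords):
    return squareform(pdist(coords))


def _procrustes_residual(a, b):
    """RMS misfit after optimal rigid alignment (rotation+reflection)."""
    from scipy.linalg import orthogonal_procrustes

    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    r, _ = orthogonal_procrustes(a, b)
    return float(np.sqrt(np.mean(np.sum((a @ r - b) ** 2, axis=1))))


class TestClassicalMDS:
    def test_two_points_at_distance_two_land_on_plus_minus_one(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        coords = classical_mds(d, dim=1)
        assert sorted(coords[:, 0]) == pytest.approx([-1.0, 1.0])

    def test_equilateral_triangle_embeds_equilaterally(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords = classical_mds(d, dim=2)
        embedded = pdist(coords)
        np.testing.assert_allclose(embedded, np.ones(3), rtol=1e-10)

    def test_exact_recovery_of_a_euclidean_configuration(self, rng):
        truth = rng.standard_normal((15, 3))
        coords = classical_mds(_euclidean_d(truth), dim=3)
        assert _procrustes_residual(coords, truth) < 1e-8

    def test_deterministic_sign_convention(self, rng):
        d = _euclidean_d(rng.standard_normal((8, 3)))
        a = classical_mds(d)
        b = classical_mds(d)
        np.testing.assert_array_equal(a, b)

    def test_rank_deficient_input_pads_with_zeros(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            coords = classical_mds(d, dim=3)
        assert np.all(coords[:, 1:] == 0)


class TestNonmetricMDS:
    def test_euclidean_input_reaches_near_zero_stress(self, rng):
        truth = rng.standard_normal((20, 3))
        emb = nmds(_euclidean_d(truth), dim=3)
        assert emb.stress < 1e-4

    def test_stress_history_is_monotone_nonincreasing(self, rng):
        for trial in range(3):
            n = 10
            d = squareform(rng.random(n * (n - 1) // 2) + 0.1)
            emb = nmds(d, dim=3)
            assert np.all(np.diff(emb.stress_history) <= 1e-12)

    def test_optimizer_improves_on_classical_start(self, rng):
        n = 10
        d = squareform(rng.random(n * (n - 1) // 2) + 0.1)
        init_stress = stress1(d, classical_mds(d, 3))
        emb = nmds(d, dim=3)
        assert emb.stress <= init_stress + 1e-12

    def test_stress_invariant_to_monotone_transform_of_dissimilarities(self, rng):
        """Only the rank order of the input matters, so d and d**2 lead to
        the same achievable stress."""
        truth = rng.standard_normal((12, 3))
        d = _euclidean_d(truth) + 0.05 * squareform(rng.random(12 * 11 // 2))
        s_lin = nmds(d, dim=3, n_init=4, random_state=0).stress
        s_sq = nmds(d**2, dim=3, n_init=4, random_state=0).stress
        assert abs(s_lin - s_sq) < 1e-3

    def test_matches_multirestart_smacof_reference_on_small_instances(self, rng):
        """Independent oracle: scikit-learn's non-metric SMACOF with many
        random restarts, scored with the same STRESS1 formula."""
        from sklearn.manifold import smacof

        for n in (8, 12):
            d = squareform(rng.random(n * (n - 1) // 2) + 0.2)
            mine = nmds(d, dim=3, n_init=32, random_state=0, max_iter=500, tol=1e-9)
            coords_ref, _ = smacof(
                d,
                metric=False,
                n_components=3,
                n_init=32,
                max_iter=500,
                eps=1e-9,
                random_state=0,
                normalized_stress=True,
            )
            ref = stress1(d, coords_ref)
            assert mine.stress <= ref + 1e-3

    def test_nonfinite_input_rejected(self):
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            nmds(d)

    def test_result_is_deterministic(self, rng):
        d = _euclidean_d(rng.standard_normal((9, 3)))
        a = nmds(d)
        b = nmds(d)
        np.testing.assert_array_equal(a.coords, b.coords)


class TestIdentifySCones:
    def test_minority_blob_is_returned(self, rng):
        big = rng.standard_normal((376, 3)) * 0.5
        small = rng.standard_normal((24, 3)) * 0.5 + np.array([8.0, 0.0, 0.0])
        coords = np.vstack([big, small])
        mask = identify_s_cones(coords, seed=0)
        assert mask.sum() == 24
        assert np.all(np.flatnonzero(mask) >= 376)

    def test_equal_clusters_raise_instead_of_guessing(self):
        a = np.tile([[0.0, 0.0, 0.0]], (10, 1)) + np.arange(10)[:, None] * 1e-3
        b = a + np.array([5.0, 0.0, 0.0])
        with pytest.raises(AmbiguousClusterError):
            identify_s_cones(np.vstack([a, b]), seed=0)

    def test_fixed_seed_is_deterministic(self, rng):
        coords = rng.standard_normal((40, 3))
        coords[:5] += 6.0
        a = identify_s_cones(coords, seed=1)
        b = identify_s_cones(coords, seed=1)
        np.testing.assert_array_equal(a, b)


class TestRotation:
    @staticmethod
    def _embedding(coords):
        return Embedding(coords=coords, stress=0.0, iterations=1, converged=True)

    def test_already_aligned_input_is_unchanged(self, rng):
        coords = rng.standard_normal((30, 3))
        s_mask = np.zeros(30, bool)
        s_mask[:4] = True
        coords[s_mask] -= np.array([10.0, 0.0, 0.0])
        coords[s_mask, 1:] = coords[~s_mask][:4, 1:]  # no off-axis separation
        sep = coords[s_mask].mean(0) - coords[~s_mask].mean(0)
        coords[s_mask, 1] -= sep[1]
        coords[s_mask, 2] -= sep[2]
        out = rotate_embedding(self._embedding(coords), s_mask)
        np.testing.assert_allclose(out.coords, coords, atol=1e-10)

    def test_axis3_separation_moves_to_axis1(self, rng):
        coords = rng.standard_normal((50, 3)) * 0.1
        s_mask = np.zeros(50, bool)
        s_mask[:6] = True
        coords[s_mask, 2] -= 7.0
        out = rotate_embedding(self._embedding(coords), s_mask)
        sep = out.coords[s_mask].mean(0) - out.coords[~s_mask].mean(0)
        assert sep[0] < 0  # S cones on the negative spectral side
        assert abs(sep[1]) < 1e-10 and abs(sep[2]) < 1e-10

    def test_pairwise_distances_preserved(self, rng):
        coords = rng.standard_normal((25, 3))
        s_mask = np.zeros(25, bool)
        s_mask[::5] = True
        out = rotate_embedding(self._embedding(coords), s_mask)
        np.testing.assert_allclose(pdist(out.coords), pdist(coords), rtol=1e-12)

    def test_degenerate_separation_raises(self, rng):
        coords = rng.standard_normal((10, 3))
        coords[:5] = coords[5:]  # identical means
        with pytest.raises(RotationError):
            rotate_embedding(self._embedding(coords), np.arange(10) < 5)
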