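"""Cone responses: spectral integration, surround opponency, noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conelearn.mosaic import ConeClassSpec, build_mosaic
from conelearn.responses import (
    ResponseBatch,
    SurroundSpec,
    add_noise,
    gather_responses,
    opponent_response,
    project_scene,
    raw_response,
    sensitivity_matrix,
    surround_matrix,
    surround_weights,
)
from conelearn.scenes import DEFAULT_WAVELENGTHS, HyperspectralImage, SceneModel, generate_scene
from conelearn.spectra import standard_set


class TestRawResponse:
    def test_zero_patch_gives_zero_responses(self, lm_mosaic, fundamentals):
        patch = np.zeros((10, 10, 33))
        batch = raw_response(patch, lm_mosaic, fundamentals)
        assert np.array_equal(batch.values, np.zeros((100, 1)))

    def test_flat_unit_patch_gives_sensitivity_sums(self, lm_mosaic, fundamentals):
        patch = np.ones((10, 10, 33))
        batch = raw_response(patch, lm_mosaic, fundamentals)
        expected = sensitivity_matrix(lm_mosaic, fundamentals).sum(axis=1)
        np.testing.assert_allclose(batch.values[:, 0], expected, rtol=1e-12)

    def test_same_class_same_spectrum_same_response(self, lm_mosaic, fundamentals):
        rng = np.random.default_rng(0)
        spectrum = rng.random(33)
        patch = np.tile(spectrum, (10, 10, 1))
        values = raw_response(patch, lm_mosaic, fundamentals).values[:, 0]
        labels = lm_mosaic.label_vector
        for name in ("L", "M", "S"):
            vals = values[labels == name]
            if vals.size:
                assert np.ptp(vals) < 1e-12

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.0, 50.0))
    def test_linearity_in_the_stimulus(self, scale, lm_mosaic, fundamentals):
        rng = np.random.default_rng(7)
        patch = rng.random((10, 10, 33))
        base = raw_response(patch, lm_mosaic, fundamentals).values
        scaled = raw_response(scale * patch, lm_mosaic, fundamentals).values
        np.testing.assert_allclose(scaled, scale * base, rtol=1e-9, atol=1e-12)

    def test_band_mismatch_rejected(self, lm_mosaic, fundamentals):
        with pytest.raises(ValueError, match="bands"):
            raw_response(np.ones((10, 10, 31)), lm_mosaic, fundamentals)

    def test_undersized_patch_rejected(self, lm_mosaic, fundamentals):
        with pytest.raises(ValueError, match="too small"):
            raw_response(np.ones((6, 6, 33)), lm_mosaic, fundamentals)

    def test_stride_picks_spaced_pixels(self, fundamentals):
        mosaic = build_mosaic(4, [ConeClassSpec("L", 558.9)], [1.0], s_fraction=0.0, seed=0)
        rng = np.random.default_rng(3)
        patch = rng.random((7, 7, 33))
        v2 = raw_response(patch, mosaic, fundamentals, stride=2).values[:, 0]
        v1 = raw_response(patch[::2, ::2], mosaic, fundamentals, stride=1).values[:, 0]
        np.testing.assert_allclose(v2, v1, rtol=1e-12)


class TestSurround:
    def test_uniform_weights_sum_to_quarter_everywhere(self, lm_mosaic):
        W = surround_matrix(lm_mosaic, SurroundSpec(mode="uniform"))
        np.testing.assert_allclose(W.sum(axis=1), 0.25, atol=1e-10)

    def test_symmetric_neighbors_get_equal_weights(self, lm_mosaic):
        w = surround_weights(lm_mosaic, (5, 5), SurroundSpec(mode="uniform", support_radius=3.0))
        for (dr, dc), val in w.items():
            assert val == pytest.approx(w[(-dr, -dc)], rel=1e-12)
            # Gaussian falls with distance
        assert w[(0, 1)] > w[(0, 3)]

    def test_selective_mode_skips_same_class_and_s(self):
        mosaic = build_mosaic(
            8,
            [ConeClassSpec("L", 558.9), ConeClassSpec("M", 530.0)],
            [1, 1],
            s_fraction=0.06,
            seed=2,
        )
        spec = SurroundSpec(mode="cone_selective")
        W = surround_matrix(mosaic, spec)
        labels = mosaic.label_vector
        nz = np.nonzero(W)
        for i, j in zip(*nz):
            assert labels[j] != "S"
            if labels[i] != "S":
                assert labels[j] != labels[i]

    def test_selective_mode_with_no_eligible_neighbors_is_empty(self):
        """An L cone in an all-L mosaic has no opposite-type neighbor, hence
        no surround at all."""
        mosaic = build_mosaic(6, [ConeClassSpec("L", 558.9)], [1.0], s_fraction=0.0, seed=0)
        w = surround_weights(mosaic, (3, 3), SurroundSpec(mode="cone_selective"))
        assert w == {}

    def test_mode_none_has_no_weight_map(self, lm_mosaic):
        with pytest.raises(ValueError):
            surround_weights(lm_mosaic, (1, 1), SurroundSpec(mode="none"))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mode": "weird"},
            {"mode": "uniform", "sigma": 0.0},
            {"mode": "uniform", "total_weight": 1.0},
        ],
    )
    def test_invalid_specs(self, kwargs):
        with pytest.raises(ValueError):
            SurroundSpec(**kwargs)


class TestOpponent:
    def test_mode_none_is_identity(self, lm_mosaic, fundamentals):
        patch = np.random.default_rng(0).random((10, 10, 33))
        batch = raw_response(patch, lm_mosaic, fundamentals)
        out = opponent_response(batch, SurroundSpec(mode="none"))
        np.testing.assert_array_equal(out.values, batch.values)

    def test_zero_total_weight_is_identity(self, lm_mosaic, fundamentals):
        patch = np.random.default_rng(0).random((10, 10, 33))
        batch = raw_response(patch, lm_mosaic, fundamentals)
        out = opponent_response(batch, SurroundSpec(mode="uniform", total_weight=0.0))
        np.testing.assert_array_equal(out.values, batch.values)

    def test_uniform_patch_single_class_scales_by_three_quarters(self, fundamentals):
        """On a one-class mosaic viewing a spatially uniform patch, every
        neighbor response equals the center's, so subtracting a surround of
        total weight 0.25 scales each response by exactly 0.75."""
        mosaic = build_mosaic(6, [ConeClassSpec("L", 558.9)], [1.0], s_fraction=0.0, seed=0)
        patch = np.tile(np.linspace(0.5, 1.5, 33), (6, 6, 1))
        batch = raw_response(patch, mosaic, fundamentals)
        out = opponent_response(batch, SurroundSpec(mode="uniform"))
        np.testing.assert_allclose(out.values, 0.75 * batch.values, rtol=1e-10)


class TestNoise:
    def _batch(self, lm_mosaic, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        values = 1.0 + 0.2 * rng.random((lm_mosaic.n_cones, n))
        return ResponseBatch(values, lm_mosaic)

    def test_zero_fraction_is_identity(self, lm_mosaic):
        batch = self._batch(lm_mosaic)
        out = add_noise(batch, 0.0, seed=1)
        np.testing.assert_array_equal(out.values, batch.values)

    def test_noise_sigma_tracks_patch_mean(self, lm_mosaic):
        """At 10^4 patches the added noise standard deviation converges to
        fraction * per-patch mean response."""
        batch = self._batch(lm_mosaic, n=10_000)
        out = add_noise(batch, 0.05, seed=2)
        added = out.values - batch.values
        ratio = added.std(axis=0) / (0.05 * batch.values.mean(axis=0))
        assert abs(ratio.mean() - 1.0) < 0.01

    def test_seeded_reproducibility(self, lm_mosaic):
        batch = self._batch(lm_mosaic, n=50)
        a = add_noise(batch, 0.01, seed=3)
        b = add_noise(batch, 0.01, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_negative_fraction_rejected(self, lm_mosaic):
        with pytest.raises(ValueError):
            add_noise(self._batch(lm_mosaic, n=5), -0.01, seed=0)


def test_gather_matches_per_patch_raw_response(lm_mosaic, fundamentals):
    """The projection fast path reproduces raw_response patch by patch."""
    scene = generate_scene(SceneModel(size=32, seed=5))
    class_order = sorted(lm_mosaic.lambda_max)
    proj = project_scene(scene, fundamentals, class_order)
    img_idx = np.zeros(4, dtype=int)
    rows = np.array([0, 3, 7, 20])
    cols = np.array([1, 5, 0, 18])
    fast = gather_responses([proj], lm_mosaic, class_order, img_idx, rows, cols)
    for k, (r, c) in enumerate(zip(rows, cols)):
        patch = scene.cube[r : r + 10, c : c + 10, :]
        slow = raw_response(patch, lm_mosaic, fundamentals).values[:, 0]
        np.testing.assert_allclose(fast[:, k], slow, rtol=1e-12)
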