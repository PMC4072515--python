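"""Scene synthesis, transforms, sampling, and container I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conelearn.scenes import (
    DEFAULT_WAVELENGTHS,
    HyperspectralImage,
    SceneError,
    SceneModel,
    blur_image,
    extrapolate_bands,
    generate_scene,
    read_cube,
    sample_patches,
    write_cube,
)


class TestGenerate:
    def test_zero_contrast_gives_constant_cube(self):
        img = generate_scene(SceneModel(size=16, contrast=0.0, mean_level=2.5))
        assert np.array_equal(img.cube, np.full((16, 16, 33), 2.5))

    def test_fixed_seed_is_bit_identical(self):
        a = generate_scene(SceneModel(size=24, seed=7))
        b = generate_scene(SceneModel(size=24, seed=7))
        assert np.array_equal(a.cube, b.cube)
        c = generate_scene(SceneModel(size=24, seed=8))
        assert not np.array_equal(a.cube, c.cube)

    def test_cube_is_nonnegative_and_on_grid(self):
        img = generate_scene(SceneModel(size=20, seed=0))
        assert np.all(img.cube >= 0)
        assert np.array_equal(img.wavelengths, DEFAULT_WAVELENGTHS)
        assert img.is_full_grid

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"size": 0},
            {"size": -3},
            {"size": 8, "spectral_corr_scale": 0.0},
            {"size": 8, "spectral_corr_scale": -10.0},
            {"size": 8, "contrast": -0.1},
            {"size": 8, "luminance_weight": 1.0},
        ],
    )
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(SceneError):
            SceneModel(**kwargs)

    def test_ensemble_correlations_decay_in_space_and_wavelength(self):
        """Over 50 scenes: correlation falls with pixel distance at fixed
        band, and with wavelength separation at fixed distance."""
        same_d1, same_d8, cross_d1 = [], [], []
        for seed in range(50):
            cube = generate_scene(SceneModel(size=32, seed=seed)).cube
            band = cube[:, :, 16]
            same_d1.append(np.corrcoef(band[:, :-1].ravel(), band[:, 1:].ravel())[0, 1])
            same_d8.append(np.corrcoef(band[:, :-8].ravel(), band[:, 8:].ravel())[0, 1])
            cross_d1.append(
                np.corrcoef(cube[:, :-1, 0].ravel(), cube[:, 1:, 32].ravel())[0, 1]
            )
        assert np.mean(same_d1) > np.mean(same_d8)  # spatial decay
        assert np.mean(same_d1) > np.mean(cross_d1)  # spectral decay at d=1


class TestExtrapolate:
    @staticmethod
    def _cube_from_spectrum(wavelengths, fn):
        spec = fn(np.asarray(wavelengths, float))
        cube = np.tile(spec, (4, 5, 1))
        return HyperspectralImage(wavelengths, cube)

    @pytest.mark.parametrize(
        "fn",
        [
            lambda lam: 1e-4 * (lam - 380) ** 2 + 0.5,  # quadratic
            lambda lam: 0.01 * lam,  # linear
            lambda lam: np.full_like(lam, 3.0),  # constant
        ],
        ids=["quadratic", "linear", "constant"],
    )
    def test_polynomial_spectra_recovered_exactly(self, fn):
        truncated = self._cube_from_spectrum(DEFAULT_WAVELENGTHS[2:], fn)
        full = extrapolate_bands(truncated)
        expected = self._cube_from_spectrum(DEFAULT_WAVELENGTHS, fn)
        np.testing.assert_allclose(full.cube, expected.cube, rtol=1e-10)
        # pre-existing bands are untouched
        np.testing.assert_array_equal(full.cube[:, :, 2:], truncated.cube)

    def test_missing_high_end_bands(self):
        truncated = self._cube_from_spectrum(
            DEFAULT_WAVELENGTHS[:-2], lambda lam: 0.02 * lam + 1
        )
        full = extrapolate_bands(truncated)
        np.testing.assert_allclose(
            full.cube[:, :, -1], 0.02 * DEFAULT_WAVELENGTHS[-1] + 1
        )

    def test_negative_extrapolations_are_clamped(self):
        # a linear spectrum hitting zero at 420 nm extrapolates negative below
        truncated = self._cube_from_spectrum(
            DEFAULT_WAVELENGTHS[2:], lambda lam: 0.1 * (lam - 420.0)
        )
        full = extrapolate_bands(truncated)
        assert np.all(full.cube >= 0)
        assert np.all(full.cube[:, :, 0] == 0.0)  # -2.0 clamped to 0
        assert np.all(full.cube[:, :, 1] == 0.0)  # -1.0 clamped to 0

    def test_interior_gap_rejected(self):
        grid = np.concatenate([DEFAULT_WAVELENGTHS[:5], DEFAULT_WAVELENGTHS[7:]])
        with pytest.raises(SceneError, match="uniform"):
            # non-uniform grid cannot even be constructed
            HyperspectralImage(grid, np.ones((2, 2, grid.size)))
        # a uniform sub-grid whose step skips bands is an interior-gap layout
        coarse = HyperspectralImage(
            DEFAULT_WAVELENGTHS[::2], np.ones((2, 2, 17))
        )
        with pytest.raises(SceneError, match="interior"):
            extrapolate_bands(coarse)


class TestBlur:
    def test_sigma_zero_is_identity(self, tiny_scenes):
        img = tiny_scenes[0]
        out = blur_image(img, 0.0)
        np.testing.assert_array_equal(out.cube, img.cube)

    def test_constant_cube_unchanged(self):
        img = HyperspectralImage(DEFAULT_WAVELENGTHS, np.full((12, 12, 33), 4.0))
        out = blur_image(img, 3.0)
        np.testing.assert_allclose(out.cube, img.cube, rtol=1e-12)

    def test_delta_spreads_to_gaussian_with_matching_std(self):
        cube = np.zeros((65, 65, 33))
        cube[32, 32, :] = 1.0
        out = blur_image(HyperspectralImage(DEFAULT_WAVELENGTHS, cube), 4.0)
        band = out.cube[:, :, 0]
        xs = np.arange(65) - 32
        total = band.sum()
        var_x = (band.sum(axis=0) * xs**2).sum() / total
        assert abs(np.sqrt(var_x) - 4.0) < 0.05
        assert abs(total - 1.0) < 1e-6  # per-band sum preserved

    def test_negative_sigma_rejected(self, tiny_scenes):
        with pytest.raises(SceneError):
            blur_image(tiny_scenes[0], -1.0)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(perm_seed=st.integers(0, 10_000))
    def test_blur_commutes_with_band_permutation(self, perm_seed):
        """Blur acts spatially only, so shuffling bands first or last is the
        same."""
        rng = np.random.default_rng(perm_seed)
        cube = rng.random((10, 10, 33))
        perm = rng.permutation(33)
        img = HyperspectralImage(DEFAULT_WAVELENGTHS, cube)
        blurred_then_perm = blur_image(img, 2.0).cube[:, :, perm]
        perm_then_blurred = blur_image(
            HyperspectralImage(DEFAULT_WAVELENGTHS, cube[:, :, perm]), 2.0
        ).cube
        np.testing.assert_allclose(blurred_then_perm, perm_then_blurred, rtol=1e-12)


class TestSamplePatches:
    def test_zero_patches_is_empty(self, tiny_scenes):
        assert list(sample_patches(tiny_scenes, 8, 0, seed=0)) == []

    def test_exact_count_and_shape(self, tiny_scenes):
        patches = list(sample_patches(tiny_scenes, 8, 17, seed=0))
        assert len(patches) == 17
        assert all(p.shape == (8, 8, 33) for p in patches)

    def test_single_offset_returns_whole_image(self, tiny_scenes):
        img = tiny_scenes[0]
        for patch in sample_patches([img], 32, 5, seed=1):
            np.testing.assert_array_equal(patch, img.cube)

    def test_seeded_reproducibility(self, tiny_scenes):
        a = list(sample_patches(tiny_scenes, 10, 8, seed=42))
        b = list(sample_patches(tiny_scenes, 10, 8, seed=42))
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa, pb)

    def test_oversized_patch_rejected(self, tiny_scenes):
        with pytest.raises(SceneError):
            list(sample_patches(tiny_scenes, 40, 1, seed=0))


class TestIO:
    @pytest.mark.parametrize("name", ["cube.raw", "cube.npz"], ids=["envi", "npz"])
    def test_roundtrip_is_lossless(self, tmp_path, name, tiny_scenes):
        img = tiny_scenes[1]
        path = tmp_path / name
        write_cube(img, path)
        back = read_cube(path)
        np.testing.assert_array_equal(back.cube, img.cube)
        np.testing.assert_array_equal(back.wavelengths, img.wavelengths)

    def test_truncated_grid_is_readable_and_flagged(self, tmp_path):
        """A 31-band cube (420-720 nm) reads fine but is not on the full
        grid, signalling that band extrapolation is needed."""
        grid = DEFAULT_WAVELENGTHS[2:]
        img = HyperspectralImage(grid, np.random.default_rng(0).random((6, 6, 31)))
        path = tmp_path / "trunc.raw"
        write_cube(img, path)
        back = read_cube(path)
        assert back.n_bands == 31
        assert not back.is_full_grid
        assert extrapolate_bands(back).is_full_grid

    def test_missing_wavelength_metadata_is_an_error(self, tmp_path, tiny_scenes):
        path = tmp_path / "bad.raw"
        write_cube(tiny_scenes[0], path)
        hdr = path.with_suffix(".raw.hdr")
        text = "\n".join(
            line for line in hdr.read_text().splitlines() if not line.startswith("wavelength =")
        )
        hdr.write_text(text)
        with pytest.raises(SceneError, match="wavelength"):
            read_cube(path)

    def test_missing_header_is_an_error(self, tmp_path):
        raw = tmp_path / "orphan.raw"
        raw.write_bytes(b"\x00" * 64)
        with pytest.raises(SceneError, match="header"):
            read_cube(raw)
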