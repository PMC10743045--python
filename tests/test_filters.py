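"""Preprocessing chain: normalization, resampling, LoG, wavelet, discretization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radrobust.filters import (
    ExtractionConfig,
    SUBBAND_LABELS,
    derive_images,
    discretize,
    log_filter,
    normalize_image,
    resample_to_isotropic,
    wavelet_reconstruct,
    wavelet_subbands,
)


class TestNormalize:
    def test_zero_mean_unit_population_sd(self):
        rng = np.random.default_rng(0)
        img = rng.random((8, 8, 8)) * 7 + 3
        out = normalize_image(img, scale=1.0)
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1.0) < 1e-9

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.random((6, 6, 6))
        np.testing.assert_allclose(normalize_image(img), normalize_image(3.5 * img + 11.0), atol=1e-12)

    def test_three_values_population_sd_convention(self):
        out = normalize_image(np.array([[[1.0, 2.0, 3.0]]]))
        np.testing.assert_allclose(out.ravel(), [-1.224744871, 0.0, 1.224744871], atol=1e-6)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            normalize_image(np.ones((4, 4, 4)))


class TestResample:
    def test_identity_grid_preserves_values(self):
        rng = np.random.default_rng(2)
        img = rng.random((10, 10, 10))
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[3:7, 3:7, 3:7] = True
        out_img, out_mask = resample_to_isotropic(img, mask, (2.0, 2.0, 2.0), (2.0, 2.0, 2.0))
        np.testing.assert_allclose(out_img, img, atol=1e-6)
        np.testing.assert_array_equal(out_mask, mask)

    def test_fine_sphere_volume_preserved(self):
        # 1 mm grid, radius 10 mm sphere -> resampled to 2 mm
        x, y, z = np.meshgrid(*[np.arange(28.0)] * 3, indexing="ij")
        mask = ((x - 13.5) ** 2 + (y - 13.5) ** 2 + (z - 13.5) ** 2) <= 100.0
        img = mask.astype(float)
        _, out_mask = resample_to_isotropic(img, mask, (1.0, 1.0, 1.0), (2.0, 2.0, 2.0))
        analytic = 4.0 / 3.0 * np.pi * 1000.0
        assert abs(out_mask.sum() * 8.0 - analytic) / analytic < 0.15

    def test_anisotropic_input_lands_on_exact_target_grid(self):
        rng = np.random.default_rng(3)
        img = rng.random((12, 12, 10))
        mask = np.zeros_like(img, dtype=bool)
        mask[4:8, 4:8, 4:7] = True
        out_img, out_mask = resample_to_isotropic(img, mask, (2.73, 2.73, 3.27), (2.0, 2.0, 2.0))
        expected_shape = tuple(
            int(np.ceil(n * s / 2.0)) for n, s in zip((12, 12, 10), (2.73, 2.73, 3.27))
        )
        assert out_img.shape == expected_shape == out_mask.shape

    def test_emptying_mask_errors(self):
        img = np.zeros((4, 4, 4))
        mask = np.zeros((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError):
            resample_to_isotropic(img, mask, (1.0, 1.0, 1.0), (2.0, 2.0, 2.0))


class TestLoG:
    def test_constant_image_zero_response(self):
        out = log_filter(np.full((10, 10, 10), 5.0), 2.0, (2.0, 2.0, 2.0))
        np.testing.assert_allclose(out.volume, 0.0, atol=1e-10)

    def test_default_config_has_ten_scales(self):
        cfg = ExtractionConfig()
        assert len(cfg.log_sigmas) == 10
        ders = derive_images(np.random.default_rng(0).random((8, 8, 8)), (2.0, 2.0, 2.0), cfg)
        assert sum(d.kind == "log" for d in ders) == 10
        assert len(ders) == 19

    def test_bright_voxel_gives_response_minimum(self):
        img = np.zeros((11, 11, 11))
        img[5, 5, 5] = 1.0
        out = log_filter(img, 2.0, (2.0, 2.0, 2.0))  # sigma = 1 voxel
        assert np.argmin(out.volume) == np.ravel_multi_index((5, 5, 5), img.shape)

    def test_blob_scale_selectivity(self):
        # scale-normalized response at a Gaussian blob peaks at an interior sigma
        x, y, z = np.meshgrid(*[np.arange(24.0) * 2.0] * 3, indexing="ij")
        blob = np.exp(-((x - 23) ** 2 + (y - 23) ** 2 + (z - 23) ** 2) / (2 * 4.0**2))
        center = (12, 12, 12)
        resp = [abs(log_filter(blob, s, (2.0, 2.0, 2.0)).volume[center]) for s in (1.0, 2.0, 4.0, 8.0, 16.0)]
        assert np.argmax(resp) not in (0, len(resp) - 1)

    def test_sub_voxel_sigma_warns(self):
        with pytest.warns(UserWarning, match="below half a voxel"):
            log_filter(np.zeros((6, 6, 6)), 0.5, (2.0, 2.0, 2.0))


class TestWavelet:
    def test_constant_zeroes_every_highpass_band(self):
        subs = wavelet_subbands(np.full((12, 12, 12), 3.0))
        for s in subs:
            if "H" in s.parameter:
                np.testing.assert_allclose(s.volume, 0.0, atol=1e-9)

    def test_eight_distinct_labels_same_grid(self):
        img = np.random.default_rng(4).random((10, 9, 8))
        subs = wavelet_subbands(img)
        assert len(subs) == 8
        assert {s.parameter for s in subs} == set(SUBBAND_LABELS)
        assert all(s.volume.shape == img.shape for s in subs)

    def test_perfect_reconstruction(self):
        img = np.random.default_rng(5).normal(size=(20, 18, 16))
        rec = wavelet_reconstruct(img)
        assert np.max(np.abs(rec - img)) / np.max(np.abs(img)) < 1e-6

    def test_low_frequency_energy_concentrates_in_lll(self):
        n = 32
        x, y, z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        img = np.cos(2 * np.pi * x / n) * np.cos(2 * np.pi * y / n) * np.cos(2 * np.pi * z / n)
        energies = {s.parameter: float(np.sum(s.volume**2)) for s in wavelet_subbands(img)}
        lll = energies.pop("LLL")
        assert all(lll > e for e in energies.values())


class TestDiscretize:
    def test_constant_input_single_level(self):
        np.testing.assert_array_equal(discretize(np.full(5, 2.2), 0.25), np.ones(5, dtype=int))

    def test_worked_example(self):
        np.testing.assert_array_equal(
            discretize(np.array([0.0, 0.1, 0.26, 0.5]), 0.25), [1, 1, 2, 3]
        )

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(-1e3, 1e3), st.integers(0, 10_000))
    def test_shift_invariance(self, shift, seed):
        values = np.random.default_rng(seed).random(20) * 5
        np.testing.assert_array_equal(
            discretize(values, 0.25), discretize(values + shift, 0.25)
        )

    def test_level_one_attained_and_level_count(self):
        rng = np.random.default_rng(6)
        values = rng.random(100) * 3
        levels = discretize(values, 0.25)
        assert levels.min() == 1
        assert levels.max() == int(np.floor((values.max() - values.min()) / 0.25)) + 1
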