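"""Roughness, PSD / fractal dimension, porosity and feature sizing."""

import math

import numpy as np
import pytest

from mesocell.errors import ParameterError
from mesocell.nuclei_graph import ImageGrid
from mesocell.surface_topography import (
    PSDResult,
    SurfaceField,
    feature_size_stats,
    fractal_dimension,
    porosity,
    power_spectrum,
    roughness_Ra,
    segment_pores,
)
from mesocell.synthetic_data import (
    SurfaceSynthesisParams,
    porous_to_grayscale,
    simulate_fractal_surface,
    simulate_porous_image,
)


class TestRoughness:
    def test_flat_surface_is_zero(self):
        assert roughness_Ra(SurfaceField(np.full((32, 32), 5.0))) == pytest.approx(0.0, abs=1e-12)

    def test_tilted_plane_is_zero_after_detrend(self):
        y, x = np.mgrid[0:64, 0:64]
        assert roughness_Ra(SurfaceField(0.3 * x - 0.1 * y + 2.0)) == pytest.approx(0.0, abs=1e-9)

    def test_sine_surface_closed_form(self):
        amp = 5.0
        x = np.linspace(0, 20 * np.pi, 1024, endpoint=False)
        surface = SurfaceField(np.tile(amp * np.sin(x), (64, 1)))
        assert roughness_Ra(surface) == pytest.approx(2 * amp / np.pi, rel=0.01)

    def test_matches_direct_summation(self, rng):
        h = rng.normal(size=(10, 12))
        got = roughness_Ra(SurfaceField(h))
        # independently written oracle: explicit plane fit + direct summation
        y, x = np.mgrid[0:10, 0:12]
        A = np.column_stack([x.ravel(), y.ravel(), np.ones(h.size)])
        coef, *_ = np.linalg.lstsq(A, h.ravel(), rcond=None)
        want = np.abs(h - (A @ coef).reshape(h.shape)).mean()
        assert got == pytest.approx(want, abs=1e-12)

    def test_linear_in_amplitude(self, rng):
        h = rng.normal(size=(32, 32))
        assert roughness_Ra(SurfaceField(3.5 * h)) == pytest.approx(
            3.5 * roughness_Ra(SurfaceField(h)), rel=1e-12
        )


class TestPowerSpectrum:
    def test_single_cosine_concentrates_power(self):
        n = 128
        x = np.arange(n)
        surface = SurfaceField(np.tile(np.cos(2 * np.pi * 16 * x / n), (n, 1)))
        psd = power_spectrum(surface)
        peak_bin = np.argmax(psd.power)
        # the mode at 16 cycles/um falls in the winning bin
        assert psd.spatial_frequencies[peak_bin] == pytest.approx(16.0, rel=0.25)
        assert psd.power[peak_bin] > 100 * np.median(psd.power)

    def test_parseval_within_one_percent(self, rng):
        h = rng.normal(0, 2.0, (256, 256))
        psd = power_spectrum(SurfaceField(h))
        var = (h - h.mean()).var()
        assert psd.total_power == pytest.approx(var, rel=0.01)

    def test_white_noise_spectrum_flat(self):
        slopes = []
        for seed in range(10):
            h = np.random.default_rng(seed).normal(size=(128, 128))
            res = fractal_dimension(power_spectrum(SurfaceField(h)))
            slopes.append(res.slope)
        assert max(abs(s) for s in slopes) < 0.3

    def test_non_square_zero_padded(self, rng):
        with pytest.warns(UserWarning, match="non-square"):
            psd = power_spectrum(SurfaceField(rng.normal(size=(64, 96))))
        assert psd.spatial_frequencies.size > 0

    def test_too_small_grid_rejected(self):
        with pytest.raises(ParameterError):
            power_spectrum(SurfaceField(np.zeros((8, 8))))


class TestFractalDimension:
    @staticmethod
    def power_law_psd(beta, n_bins=24):
        f = np.geomspace(1.0, 100.0, n_bins)
        return PSDResult(
            spatial_frequencies=f,
            power=f**-beta,
            mode_counts=np.full(n_bins, 50),
            total_power=1.0,
            ra_nm=1.0,
            nyquist=200.0,
        )

    def test_slope_inversion_convention(self):
        # beta = 3.04 corresponds to Df = (8 - 3.04)/2 = 2.48
        res = fractal_dimension(self.power_law_psd(3.04), fit_band=(1.0, 100.0))
        assert res.df == pytest.approx(2.48, abs=1e-9)
        assert not res.low_confidence

    def test_smooth_limit_clamped(self):
        res = fractal_dimension(self.power_law_psd(4.5), fit_band=(1.0, 100.0))
        assert res.df == 2.0

    def test_poor_power_law_flagged(self, rng):
        f = np.geomspace(1.0, 100.0, 24)
        psd = PSDResult(f, np.exp(rng.normal(0, 2.0, 24)), np.full(24, 50), 1.0, 1.0, 200.0)
        assert fractal_dimension(psd, fit_band=(1.0, 100.0)).low_confidence

    def test_round_trip_through_synthesis(self):
        for target in (2.15, 2.48):
            errs = []
            for seed in range(5):
                surf = simulate_fractal_surface(
                    SurfaceSynthesisParams(target_df=target, grid_n=256, seed=seed)
                )
                res = fractal_dimension(power_spectrum(surf))
                errs.append(abs(res.df - target))
            assert np.median(errs) < 0.1

    def test_narrow_band_rejected(self):
        with pytest.raises(ParameterError):
            fractal_dimension(self.power_law_psd(3.0, n_bins=8), fit_band=(1.0, 1.5))


class TestPorosity:
    def test_all_void_and_half_void(self):
        assert porosity(np.ones((10, 10), dtype=np.uint8)) == 1.0
        half = np.zeros((10, 10), dtype=np.uint8)
        half[:5] = 1
        assert porosity(half) == 0.5

    def test_non_binary_rejected(self):
        with pytest.raises(ParameterError, match="segment_pores"):
            porosity(np.full((5, 5), 0.5))

    @pytest.mark.parametrize("target", [0.12, 0.40])
    def test_planted_fraction_round_trip(self, target):
        img = simulate_porous_image(target, seed=7)
        assert porosity(img) == pytest.approx(target, abs=0.02)

    def test_extremes_exact(self):
        assert porosity(simulate_porous_image(0.0, seed=0)) == 0.0
        assert porosity(simulate_porous_image(1.0, seed=0)) == 1.0


class TestSegmentPores:
    def test_bimodal_image_recovers_planted_mask(self, rng):
        truth = rng.random((60, 60)) < 0.3
        img = np.where(truth, 0.2, 0.8) + rng.normal(0, 0.02, (60, 60))
        mask = segment_pores(ImageGrid(img, 1.0))
        assert np.array_equal(mask.astype(bool), truth)

    def test_invert_flag_symmetry(self, rng):
        truth = rng.random((40, 40)) < 0.3
        img = np.where(truth, 0.2, 0.8)
        dark_void = segment_pores(ImageGrid(img, 1.0))
        bright_void = segment_pores(ImageGrid(1.0 - img, 1.0), invert=True)
        assert np.array_equal(dark_void, bright_void)

    def test_grayscale_round_trip(self):
        binary = simulate_porous_image(0.12, seed=5)
        gray = porous_to_grayscale(binary, seed=5)
        p = porosity(segment_pores(gray))
        assert p == pytest.approx(0.12, abs=0.03)

    def test_constant_image_rejected(self):
        with pytest.raises(ParameterError):
            segment_pores(ImageGrid(np.full((10, 10), 3.0), 1.0))


class TestFeatureSizeStats:
    @staticmethod
    def stamp_disk(mask, cy, cx, radius):
        yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = 1

    def test_single_disk_diameter(self):
        mask = np.zeros((64, 64), dtype=np.uint8)
        self.stamp_disk(mask, 32, 32, 10)
        stats = feature_size_stats(mask, pixel_size_nm=1.0)
        assert stats.count == 1
        assert stats.mean_diameter == pytest.approx(20.0, rel=0.03)

    def test_planted_equal_disks(self):
        mask = np.zeros((200, 200), dtype=np.uint8)
        centers = [(20 + 30 * i, 20 + 30 * j) for i in range(6) for j in range(6)]
        for cy, cx in centers:
            self.stamp_disk(mask, cy, cx, 5)
        stats = feature_size_stats(mask, pixel_size_nm=2.0)
        assert stats.count > 25
        assert stats.mean_diameter == pytest.approx(2 * 2.0 * 5, rel=0.03)
        assert stats.sd_diameter < 0.05 * stats.mean_diameter

    def test_border_components_excluded(self):
        mask = np.zeros((50, 50), dtype=np.uint8)
        self.stamp_disk(mask, 0, 25, 8)      # touches the top border
        self.stamp_disk(mask, 30, 25, 5)
        assert feature_size_stats(mask, 1.0).count == 1

    def test_touching_disks_merge(self):
        mask = np.zeros((60, 60), dtype=np.uint8)
        self.stamp_disk(mask, 30, 25, 6)
        self.stamp_disk(mask, 30, 33, 6)
        assert feature_size_stats(mask, 1.0).count == 1

    def test_empty_mask_flagged(self):
        stats = feature_size_stats(np.zeros((20, 20), dtype=np.uint8), 1.0)
        assert stats.count == 0
        assert math.isnan(stats.mean_diameter)
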