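"""SERS map normalization, PCA, clustering and the integrin loading ratio."""

import numpy as np
import pytest
from sklearn.metrics import rand_score

from mesocell.errors import ParameterError
from mesocell.sers_chemometrics import (
    PCAModel,
    SpectralMap,
    area_normalize,
    band_intensity_map,
    cluster_pixels,
    fit_pca,
    loading_ratio,
)
from mesocell.synthetic_data import (
    ADHESION_PEAKS,
    SpectralPeak,
    default_wavenumber_axis,
    simulate_sers_map,
)


def flat_map(value=1.0, n_px=8, n_w=101):
    w = np.linspace(700.0, 3250.0, n_w)
    return SpectralMap(w, np.full((n_px, n_w), value), (2, n_px // 2))


class TestAreaNormalize:
    def test_constant_spectrum_becomes_inverse_span(self):
        smap = area_normalize(flat_map(value=4.2))
        assert np.allclose(smap.spectra, 1.0 / (3250.0 - 700.0))

    def test_scale_invariance(self):
        base, _ = simulate_sers_map(grid_shape=(2, 4), noise_sd=0.0, seed=0)
        scaled = SpectralMap(base.wavenumbers, 7.0 * base.spectra, base.grid_shape)
        assert np.allclose(
            area_normalize(base).spectra, area_normalize(scaled).spectra, atol=1e-12
        )

    def test_unit_integrals_after_call(self, rng):
        w = np.linspace(700, 3250, 300)
        smap = SpectralMap(w, rng.random((12, 300)) + 0.1, (3, 4))
        out = area_normalize(smap)
        integrals = np.trapezoid(out.spectra, w, axis=1)
        assert np.allclose(integrals, 1.0, atol=1e-9)

    def test_idempotent(self, rng):
        w = np.linspace(700, 3250, 200)
        smap = SpectralMap(w, rng.random((6, 200)) + 0.1, (2, 3))
        once = area_normalize(smap)
        twice = area_normalize(once)
        assert np.allclose(once.spectra, twice.spectra, atol=1e-12)

    def test_zero_area_spectrum_flagged(self):
        w = np.linspace(700, 3250, 50)
        spectra = np.ones((4, 50))
        spectra[2] = 0.0
        with pytest.warns(UserWarning, match="non-positive area"):
            out = area_normalize(SpectralMap(w, spectra, (2, 2)))
        assert out.bad_pixels == [2]


class TestFitPca:
    def test_planted_rank_two_explained(self, rng):
        w = np.linspace(700, 3250, 400)
        a = np.exp(-0.5 * ((w - 1200) / 60) ** 2)
        b = np.exp(-0.5 * ((w - 2800) / 80) ** 2)
        mix = rng.random((40, 2))
        spectra = mix @ np.stack([a, b]) + rng.normal(0, 1e-5, (40, 400))
        model = fit_pca(SpectralMap(w, spectra, (5, 8)), n_components=5)
        assert model.explained_variance_fraction[:2].sum() > 0.99

    def test_deterministic_loadings(self):
        smap, _ = simulate_sers_map(grid_shape=(4, 4), seed=2)
        m1 = fit_pca(smap, 3)
        m2 = fit_pca(smap, 3)
        assert np.array_equal(m1.loadings, m2.loadings)

    def test_sign_convention(self):
        smap, _ = simulate_sers_map(grid_shape=(4, 4), seed=3)
        model = fit_pca(smap, 3)
        for comp in model.loadings:
            assert comp[np.abs(comp).argmax()] > 0

    def test_explained_fractions_complete(self, rng):
        w = np.linspace(700, 3250, 60)
        smap = SpectralMap(w, rng.random((10, 60)), (2, 5))
        model = fit_pca(smap, n_components=9)
        assert model.explained_variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(model.explained_variance_fraction) <= 1e-12)

    def test_full_reconstruction(self, rng):
        w = np.linspace(700, 3250, 80)
        spectra = rng.random((12, 80))
        smap = SpectralMap(w, spectra, (3, 4))
        model = fit_pca(smap, n_components=11)
        recon = model.scores @ model.loadings + model.mean_spectrum
        rms = np.sqrt(np.mean((recon - spectra) ** 2))
        assert rms < 1e-9

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ParameterError):
            fit_pca(flat_map(n_px=4), n_components=5)


class TestClusterPixels:
    def test_separated_blobs_recovered_exactly(self, rng):
        scores = np.vstack([
            rng.normal(0.0, 0.05, (30, 2)),
            rng.normal(10.0, 0.05, (30, 2)),
        ])
        labels = cluster_pixels(scores, k=2, seed=0)
        truth = np.repeat([0, 1], 30)
        assert rand_score(truth, labels) == 1.0

    def test_seeded_determinism(self, rng):
        scores = rng.normal(size=(50, 3))
        a = cluster_pixels(scores, k=5, seed=4)
        b = cluster_pixels(scores, k=5, seed=4)
        assert np.array_equal(a, b)

    def test_degenerate_scores_single_class(self):
        with pytest.warns(UserWarning, match="single effective class"):
            labels = cluster_pixels(np.ones((20, 2)), k=3, seed=0)
        assert set(labels) == {0}

    def test_grid_reshaping(self, rng):
        labels = cluster_pixels(rng.normal(size=(24, 2)), grid_shape=(4, 6), k=2, seed=0)
        assert labels.shape == (4, 6)


class TestLoadingRatio:
    @staticmethod
    def model_from_loading(loading, w):
        return PCAModel(
            loadings=np.asarray([loading]),
            scores=np.zeros((1, 1)),
            explained_variance_fraction=np.array([1.0]),
            mean_spectrum=np.zeros_like(w),
            wavenumbers=w,
        )

    def test_flat_loading_is_one(self):
        w = np.linspace(700, 3250, 256)
        model = self.model_from_loading(np.full(256, 0.3), w)
        assert loading_ratio(model).r_int == pytest.approx(1.0)

    def test_one_hot_loading_is_axis_length(self):
        w = np.linspace(700, 3250, 256)
        loading = np.zeros(256)
        loading[np.argmin(np.abs(w - 1569))] = 0.7
        model = self.model_from_loading(loading, w)
        assert loading_ratio(model).r_int == pytest.approx(256.0)

    def test_sign_and_scale_invariance(self, rng):
        w = np.linspace(700, 3250, 256)
        loading = rng.normal(size=256)
        r0 = loading_ratio(self.model_from_loading(loading, w)).r_int
        assert loading_ratio(self.model_from_loading(-loading, w)).r_int == pytest.approx(r0)
        assert loading_ratio(self.model_from_loading(5 * loading, w)).r_int == pytest.approx(r0)

    def test_planted_band_dominates_pc1(self):
        smap, _ = simulate_sers_map(seed=0)
        model = fit_pca(area_normalize(smap), 5)
        assert loading_ratio(model, component=0).r_int > 2.0

    def test_target_outside_axis_rejected(self):
        w = np.linspace(1600, 3250, 64)
        model = self.model_from_loading(np.ones(64), w)
        with pytest.raises(ParameterError):
            loading_ratio(model, target=1569.0)


class TestBandIntensityMap:
    def test_planted_region_brighter(self):
        smap, labels = simulate_sers_map(grid_shape=(6, 6), seed=1)
        band = band_intensity_map(smap)
        assert band[labels == 1].mean() > band[labels == 0].mean()

    def test_window_covering_axis_gives_global_max(self):
        smap, _ = simulate_sers_map(grid_shape=(3, 3), seed=2)
        full = band_intensity_map(smap, target=1975.0, window_halfwidth=1e5)
        assert np.allclose(full.ravel(), smap.spectra.max(axis=1))

    def test_zero_spectra_give_zero_map(self):
        w = np.linspace(700, 3250, 256)
        smap = SpectralMap(w, np.zeros((4, 256)), (2, 2))
        assert not band_intensity_map(smap).any()


class TestEndToEnd:
    def test_two_class_map_recovered(self):
        rands = []
        for seed in range(10):
            smap, truth = simulate_sers_map(seed=seed)
            model = fit_pca(area_normalize(smap), 5)
            labels = cluster_pixels(model.scores, k=2, seed=seed)
            rands.append(rand_score(truth.ravel(), labels.ravel()))
        assert min(rands) > 0.9

    def test_adhesion_band_table_is_planted(self):
        smap, labels = simulate_sers_map(grid_shape=(4, 4), noise_sd=0.0, seed=0)
        w = smap.wavenumbers
        idx = np.argmin(np.abs(w - 1569.0))
        mean_a = smap.spectra[labels.ravel() == 1, idx].mean()
        mean_b = smap.spectra[labels.ravel() == 0, idx].mean()
        assert mean_a > mean_b

    def test_single_class_no_peaks_identical_spectra(self):
        smap, _ = simulate_sers_map(
            grid_shape=(3, 3),
            class_layout=np.zeros((3, 3), dtype=int),
            peak_table={0: ()},
            noise_sd=0.0,
            seed=0,
        )
        assert np.allclose(smap.spectra, smap.spectra[0])

    def test_peak_outside_axis_rejected(self):
        with pytest.raises(ParameterError):
            simulate_sers_map(
                grid_shape=(2, 2),
                wavenumbers=default_wavenumber_axis(),
                class_layout=np.zeros((2, 2), dtype=int),
                peak_table={0: (SpectralPeak(5000.0),)},
                seed=0,
            )
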