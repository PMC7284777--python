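"""Chemometric analysis of SERS hyperspectral maps.

A SERS map is a grid of Raman spectra (one per 0.5-um step of the scanning
stage).  The analysis chain is: area normalization of each spectrum (divides
out the slowly varying fluorescence background level), mean-centered PCA,
k-means clustering of the retained component scores into a small number of
chemometric classes, and a loading-ratio statistic that quantifies how
strongly the 1569 1/cm tryptophan band — a fingerprint frequency of integrin
cell-adhesion molecules — drives a principal component:

    r = max |loading| in [target +/- window]  /  mean |loading| over the axis

Flat loadings give r = 1; values well above 1 indicate that the adhesion
band dominates the component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ParameterError

__all__ = [
    "SpectralMap",
    "PCAModel",
    "IntegrinRatio",
    "area_normalize",
    "fit_pca",
    "cluster_pixels",
    "loading_ratio",
    "band_intensity_map",
]

INTEGRIN_BAND_CM1 = 1569.0  # tryptophan band, integrin fingerprint


@dataclass
class SpectralMap:
    """Wavenumber-indexed spectra on a rectangular spatial grid."""

    wavenumbers: np.ndarray       # (W,) cm^-1, strictly increasing
    spectra: np.ndarray           # (pixels, W)
    grid_shape: tuple[int, int]
    stepsize_um: float = 0.5
    bad_pixels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        s = np.asarray(self.spectra, dtype=float)
        if w.ndim != 1 or np.any(np.diff(w) <= 0):
            raise ParameterError("wavenumber axis must be 1-D and strictly increasing")
        if s.ndim != 2 or s.shape[1] != w.size:
            raise ParameterError("spectra must be (pixels, wavenumbers)")
        if s.shape[0] != self.grid_shape[0] * self.grid_shape[1]:
            raise ParameterError(
                f"pixel count {s.shape[0]} != rows*cols {self.grid_shape}"
            )
        self.wavenumbers = w
        self.spectra = s

    @property
    def n_pixels(self) -> int:
        return int(self.spectra.shape[0])


@dataclass
class PCAModel:
    """Principal components of a spectral map."""

    loadings: np.ndarray                    # (components, W), unit norm
    scores: np.ndarray                      # (pixels, components)
    explained_variance_fraction: np.ndarray
    mean_spectrum: np.ndarray
    wavenumbers: np.ndarray


@dataclass(frozen=True)
class IntegrinRatio:
    """Loading-ratio statistic at a fingerprint band."""

    r_int: float
    target_wavenumber: float = INTEGRIN_BAND_CM1
    window_halfwidth: float = 5.0
    component: int = 0


def area_normalize(smap: SpectralMap) -> SpectralMap:
    """Divide each spectrum by its trapezoidal integral over the axis.

    After the call every valid spectrum integrates to 1, removing the
    pixel-to-pixel fluorescence level.  Spectra with non-positive area are
    zeroed, recorded in ``bad_pixels`` and reported through a warning.
    """
    areas = np.trapezoid(smap.spectra, smap.wavenumbers, axis=1)
    bad = np.nonzero(areas <= 0)[0]
    out = np.zeros_like(smap.spectra)
    good = areas > 0
    out[good] = smap.spectra[good] / areas[good, None]
    if bad.size:
        warnings.warn(f"{bad.size} spectra with non-positive area excluded", stacklevel=2)
    return SpectralMap(
        wavenumbers=smap.wavenumbers,
        spectra=out,
        grid_shape=smap.grid_shape,
        stepsize_um=smap.stepsize_um,
        bad_pixels=sorted(set(smap.bad_pixels) | set(int(i) for i in bad)),
    )


def fit_pca(smap: SpectralMap, n_components: int = 5) -> PCAModel:
    """Mean-centered PCA of the spectra.

    The sign of each component is fixed deterministically so that its
    largest-magnitude loading element is positive.
    """
    if smap.n_pixels < n_components:
        raise ParameterError(
            f"need at least {n_components} pixels, got {smap.n_pixels}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(smap.spectra)
    loadings = pca.components_
    flip = np.sign(loadings[np.arange(loadings.shape[0]), np.abs(loadings).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return PCAModel(
        loadings=loadings * flip[:, None],
        scores=scores * flip[None, :],
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        mean_spectrum=pca.mean_.copy(),
        wavenumbers=smap.wavenumbers.copy(),
    )


def cluster_pixels(
    scores: np.ndarray,
    grid_shape: tuple[int, int] | None = None,
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 10,
) -> np.ndarray:
    """K-means clustering of component scores into chemometric classes.

    Returns labels, reshaped to ``grid_shape`` when given.  Best of
    ``n_restarts`` initializations by within-cluster sum of squares.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if scores.shape[0] < k:
        raise ParameterError(f"need at least k={k} pixels, got {scores.shape[0]}")
    if np.unique(scores, axis=0).shape[0] == 1:
        warnings.warn("all scores identical: single effective class", stacklevel=2)
        labels = np.zeros(scores.shape[0], dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(scores)
    if grid_shape is not None:
        labels = labels.reshape(grid_shape)
    return labels


def loading_ratio(
    model: PCAModel,
    component: int = 0,
    target: float = INTEGRIN_BAND_CM1,
    window_halfwidth: float = 5.0,
) -> IntegrinRatio:
    """Ratio of the band loading to the spectrum-wide mean loading.

    Uses absolute loading values (loadings are sign-ambiguous) and the
    maximum within the window, which is robust to axis discretization.
    ``component=0`` is the first principal component.
    """
    w = model.wavenumbers
    if not (w[0] <= target <= w[-1]):
        raise ParameterError(f"target {target} outside axis [{w[0]}, {w[-1]}]")
    in_window = np.abs(w - target) <= window_halfwidth
    if not in_window.any():
        raise ParameterError("window contains no axis points")
    loading = np.abs(model.loadings[component])
    return IntegrinRatio(
        r_int=float(loading[in_window].max() / loading.mean()),
        target_wavenumber=target,
        window_halfwidth=window_halfwidth,
        component=component,
    )


def band_intensity_map(
    smap: SpectralMap, target: float = INTEGRIN_BAND_CM1, window_halfwidth: float = 5.0
) -> np.ndarray:
    """Per-pixel maximum intensity within a band, rendered on the grid."""
    w = smap.wavenumbers
    if not (w[0] <= target <= w[-1]):
        raise ParameterError(f"target {target} outside axis [{w[0]}, {w[-1]}]")
    in_window = np.abs(w - target) <= window_halfwidth
    if not in_window.any():
        raise ParameterError("window contains no axis points")
    return smap.spectra[:, in_window].max(axis=1).reshape(smap.grid_shape)
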