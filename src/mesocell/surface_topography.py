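"""Nanoscale surface-topography metrics.

From AFM-like height maps: arithmetic roughness Ra (mean absolute height
deviation after linear detrending) and the fractal dimension Df of a
self-affine surface, estimated from the radially averaged power spectral
density.  For an isotropic self-affine surface of Hurst exponent H the 2-D
PSD follows a power law P(q) ~ q**(-2*(H+1)-2), and Df = 3 - H, so with
log-log slope -beta of the radially averaged 2-D spectrum::

    Df = (8 - beta) / 2        (clamped to the physical range [2, 3])

From SEM-like micrographs: porosity (void area fraction of a binary image),
an Otsu-threshold segmentation helper, and equivalent-circle particle/pore
size statistics from connected components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import clear_border

from .errors import ParameterError
from .nuclei_graph import ImageGrid

__all__ = [
    "SurfaceField",
    "PSDResult",
    "DfResult",
    "PorosityResult",
    "FeatureSizeStats",
    "roughness_Ra",
    "power_spectrum",
    "fractal_dimension",
    "porosity",
    "segment_pores",
    "feature_size_stats",
]


@dataclass
class SurfaceField:
    """A height map in nanometres over a rectangular extent in micrometres."""

    heights_nm: np.ndarray
    extent_um: tuple[float, float] = (1.0, 1.0)   # (x, y)

    def __post_init__(self) -> None:
        h = np.asarray(self.heights_nm, dtype=float)
        if h.ndim != 2:
            raise ParameterError("heights must be 2-D")
        if not np.all(np.isfinite(h)):
            raise ParameterError("heights must be finite")
        if min(self.extent_um) <= 0:
            raise ParameterError("extent must be positive")
        self.heights_nm = h


@dataclass
class PSDResult:
    """Radially averaged power spectral density of a height map."""

    spatial_frequencies: np.ndarray   # bin-center |q|, cycles/um
    power: np.ndarray                 # mean 2-D power per bin, nm^2
    mode_counts: np.ndarray           # Fourier modes averaged per bin
    total_power: float                # sum of 2-D power ~ variance, nm^2
    ra_nm: float
    nyquist: float                    # cycles/um


@dataclass(frozen=True)
class DfResult:
    """Fractal dimension from the PSD slope."""

    df: float
    slope: float          # fitted log-log slope (= -beta)
    r_squared: float
    low_confidence: bool  # True when the spectrum is a poor power law
    fit_band: tuple[float, float]


@dataclass(frozen=True)
class PorosityResult:
    P: float


@dataclass(frozen=True)
class FeatureSizeStats:
    """Equivalent-circle diameter statistics of connected components."""

    mean_diameter: float
    sd_diameter: float
    count: int


def _detrend_plane(h: np.ndarray) -> np.ndarray:
    """Subtract the least-squares plane a*x + b*y + c."""
    ny, nx = h.shape
    y, x = np.mgrid[0:ny, 0:nx]
    A = np.column_stack([x.ravel(), y.ravel(), np.ones(h.size)])
    coef, *_ = np.linalg.lstsq(A, h.ravel(), rcond=None)
    return h - (A @ coef).reshape(h.shape)


def roughness_Ra(surface: SurfaceField) -> float:
    """Arithmetic average roughness: mean |h - plane| after linear detrend."""
    d = _detrend_plane(surface.heights_nm)
    return float(np.abs(d).mean())


def power_spectrum(surface: SurfaceField, n_bins: int = 32) -> PSDResult:
    """Windowed 2-D periodogram, radially averaged into log-spaced |q| bins.

    The height map is plane-detrended and Hann-windowed; the periodogram is
    normalized so that its total equals the (window-weighted) variance of
    the detrended heights, preserving Parseval's identity up to the
    windowing factor.  Non-square maps are zero-padded to square.
    """
    h = _detrend_plane(surface.heights_nm)
    if min(h.shape) < 16:
        raise ParameterError("grid must be at least 16 x 16")
    ra = float(np.abs(h).mean())

    wy = np.hanning(h.shape[0])
    wx = np.hanning(h.shape[1])
    w = np.outer(wy, wx)
    hw = h * w
    n = max(h.shape)
    if h.shape[0] != h.shape[1]:
        warnings.warn("non-square height map: zero-padding to square", stacklevel=2)
        pad = np.zeros((n, n))
        pad[: h.shape[0], : h.shape[1]] = hw
        hw = pad
    F = np.fft.fft2(hw)
    p2d = np.abs(F) ** 2 / (hw.size * np.sum(w**2))

    dx = surface.extent_um[0] / surface.heights_nm.shape[1]
    dy = surface.extent_um[1] / surface.heights_nm.shape[0]
    qx = np.fft.fftfreq(n, d=dx)
    qy = np.fft.fftfreq(n, d=dy)
    q = np.hypot(*np.meshgrid(qx, qy, indexing="xy"))
    nyq = 0.5 / max(dx, dy)

    qpos = q[q > 0]
    edges = np.geomspace(qpos.min() * 0.999, nyq, n_bins + 1)
    which = np.digitize(q.ravel(), edges) - 1
    power = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    freqs = np.sqrt(edges[:-1] * edges[1:])
    flat = p2d.ravel()
    for b in range(n_bins):
        sel = which == b
        counts[b] = int(sel.sum())
        if counts[b]:
            power[b] = flat[sel].mean()
    ok = np.isfinite(power)
    return PSDResult(
        spatial_frequencies=freqs[ok],
        power=power[ok],
        mode_counts=counts[ok],
        total_power=float(p2d.sum()),
        ra_nm=ra,
        nyquist=nyq,
    )


def fractal_dimension(
    psd: PSDResult, fit_band: tuple[float, float] | None = None
) -> DfResult:
    """Fractal dimension from the log-log slope of the radial PSD.

    Default fit band: drop the two lowest-frequency bins (detrending
    leakage) and the top octave (discretization/noise floor).  Bins are
    weighted by the square root of their Fourier-mode count, the
    inverse-sd weighting for chi-squared periodogram scatter; without it
    the sparse low-frequency bins dominate the fit.  Df is clamped to the
    physical range [2, 3]; a fit with R^2 < 0.8 is flagged as low
    confidence (the surface is then a poor power law).
    """
    f, p = psd.spatial_frequencies, psd.power
    if fit_band is None:
        lo = f[2] if f.size > 2 else f[0]
        hi = psd.nyquist / 2.0
        fit_band = (lo, hi)
    sel = (f >= fit_band[0]) & (f <= fit_band[1]) & (p > 0)
    if sel.sum() < 5:
        raise ParameterError("need at least 5 PSD bins inside the fit band")
    lx, ly = np.log10(f[sel]), np.log10(p[sel])
    wts = np.sqrt(psd.mode_counts[sel].astype(float))
    slope, intercept = np.polyfit(lx, ly, 1, w=wts)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum(wts**2 * (ly - np.average(ly, weights=wts**2)) ** 2)
    r2 = 1.0 - np.sum(wts**2 * resid**2) / ss_tot if ss_tot > 0 else 0.0
    beta = -slope
    df = float(np.clip((8.0 - beta) / 2.0, 2.0, 3.0))
    return DfResult(
        df=df,
        slope=float(slope),
        r_squared=float(r2),
        low_confidence=bool(r2 < 0.8),
        fit_band=tuple(float(v) for v in fit_band),
    )


def porosity(binary: ImageGrid | np.ndarray) -> float:
    """Void fraction of a binary image (void = 1): void pixels / total."""
    arr = binary.intensities if isinstance(binary, ImageGrid) else np.asarray(binary)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ParameterError(
            "porosity expects a binary image (void=1); use segment_pores on grayscale input"
        )
    return float(arr.mean())


def segment_pores(img: ImageGrid | np.ndarray, invert: bool = False) -> np.ndarray:
    """Otsu global threshold of a grayscale micrograph; dark phase = void.

    Returns a binary mask with void pixels set to 1.  ``invert=True``
    treats the bright phase as void instead.
    """
    arr = img.intensities if isinstance(img, ImageGrid) else np.asarray(img, dtype=float)
    if np.unique(arr).size < 2:
        raise ParameterError("constant image cannot be thresholded")
    thr = threshold_otsu(arr)
    mask = arr > thr if invert else arr < thr
    return mask.astype(np.uint8)


def feature_size_stats(mask: np.ndarray, pixel_size_nm: float) -> FeatureSizeStats:
    """Mean +/- sd equivalent-circle diameter of connected components.

    Components use 8-connectivity; per component the diameter is
    2*sqrt(area/pi) scaled by the pixel size.  Components touching the
    image border are excluded to avoid truncation bias; touching features
    merge into one component by construction.
    """
    if pixel_size_nm <= 0:
        raise ParameterError(f"pixel_size must be > 0, got {pixel_size_nm}")
    m = np.asarray(mask).astype(bool)
    labeled = clear_border(label(m, connectivity=2))
    areas = np.array([rp.area for rp in regionprops(labeled)], dtype=float)
    if areas.size == 0:
        return FeatureSizeStats(float("nan"), float("nan"), 0)
    diam = 2.0 * np.sqrt(areas / np.pi) * pixel_size_nm
    sd = float(diam.std(ddof=1)) if diam.size > 1 else 0.0
    return FeatureSizeStats(float(diam.mean()), sd, int(diam.size))
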