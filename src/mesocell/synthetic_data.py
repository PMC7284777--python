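"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its parameters and seed, and returns
the planted ground truth alongside the synthetic observable:

- nuclei micrographs (uniform or Thomas-process clustered layouts, Gaussian
  nucleus blobs, additive Gaussian noise) emulating DAPI confocal images of
  a 1174 x 882 um field at 1.72 um/px;
- first-order release curves with Gaussian measurement noise;
- SERS hyperspectral maps with a smooth fluorescence baseline plus
  class-specific Lorentzian/Gaussian bands, including the 1569 1/cm
  integrin fingerprint;
- self-affine fractal surfaces of prescribed fractal dimension and Ra,
  synthesized spectrally with P(q) ~ q**(-(8 - 2*Df));
- porous binary micrographs of prescribed void fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .nuclei_graph import ImageGrid
from .release_kinetics import ReleaseCurve, ReleaseModelParams, first_order_model
from .sers_chemometrics import SpectralMap
from .surface_topography import SurfaceField

__all__ = [
    "NucleiLayoutParams",
    "default_release_times",
    "default_wavenumber_axis",
    "SurfaceSynthesisParams",
    "SpectralPeak",
    "ADHESION_PEAKS",
    "simulate_nuclei_image",
    "simulate_release_curve",
    "simulate_sers_map",
    "simulate_fractal_surface",
    "simulate_porous_image",
    "porous_to_grayscale",
]


@dataclass(frozen=True)
class NucleiLayoutParams:
    """Layout and rendering parameters for a synthetic nuclei micrograph.

    Field geometry defaults to the confocal region of interest of
    1174 x 882 um imaged at 1.72 um/px.  ``nucleus_radius`` is the sd of
    the Gaussian blob used to render one nucleus; the visible (segmentable)
    nucleus diameter is about 4 sd, so the 3 um default emulates ~12 um
    MCF-7 nuclei.
    Clustered layouts use a Thomas process: ``n_parents`` uniform cluster
    centers, offspring scattered isotropically with sd ``cluster_sd``.
    """

    n_cells: int = 700
    layout: str = "uniform"            # "uniform" | "clustered"
    n_parents: int = 25
    cluster_sd: float = 25.0           # um
    field_width: float = 1174.0        # um
    field_height: float = 882.0        # um
    pixel_size: float = 1.72           # um
    nucleus_radius: float = 3.0        # um (blob sd; visible nucleus ~4*sd)
    blob_amplitude: float = 1.0
    background: float = 0.05
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ParameterError(f"n_cells must be >= 0, got {self.n_cells}")
        if self.layout not in ("uniform", "clustered"):
            raise ParameterError(f"unknown layout {self.layout!r}")
        if self.pixel_size <= 0 or self.field_width <= 0 or self.field_height <= 0:
            raise ParameterError("field dimensions and pixel_size must be > 0")
        if self.layout == "clustered":
            if self.n_parents < 1:
                raise ParameterError("clustered layout needs n_parents >= 1")
            if self.cluster_sd <= 0:
                raise ParameterError("clustered layout needs cluster_sd > 0")
        if self.nucleus_radius <= 0:
            raise ParameterError("nucleus_radius must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SurfaceSynthesisParams:
    """Spectral-synthesis parameters for a self-affine surface."""

    target_df: float = 2.5
    target_ra: float = 5.0     # nm
    grid_n: int = 256          # power of two
    extent_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2.0 <= self.target_df <= 3.0):
            raise ParameterError(f"target_df must be in [2, 3], got {self.target_df}")
        if self.target_ra <= 0:
            raise ParameterError("target_ra must be > 0")
        n = self.grid_n
        if n < 16 or (n & (n - 1)) != 0:
            raise ParameterError(f"grid_n must be a power of two >= 16, got {n}")


@dataclass(frozen=True)
class SpectralPeak:
    """One Raman band: center (cm^-1), FWHM (cm^-1), amplitude, line shape."""

    center: float
    fwhm: float = 15.0
    amplitude: float = 1.0
    shape: str = "lorentzian"   # "lorentzian" | "gaussian"

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        x = wavenumbers - self.center
        if self.shape == "lorentzian":
            hw = self.fwhm / 2.0
            return self.amplitude * hw**2 / (x**2 + hw**2)
        if self.shape == "gaussian":
            sd = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            return self.amplitude * np.exp(-0.5 * (x / sd) ** 2)
        raise ParameterError(f"unknown line shape {self.shape!r}")


#: Fingerprint bands of integrin cell-adhesion molecules; the 1569 1/cm
#: tryptophan band is the diagnostic frequency and is planted strongest.
ADHESION_PEAKS: tuple[SpectralPeak, ...] = (
    SpectralPeak(1126.0, amplitude=0.4),   # C-N stretch
    SpectralPeak(1175.0, amplitude=0.3),   # Tyr/Phe
    SpectralPeak(1306.0, amplitude=0.5),   # amide III
    SpectralPeak(1506.0, amplitude=0.4),   # Phe/His
    SpectralPeak(1569.0, amplitude=1.0),   # tryptophan (integrin marker)
    SpectralPeak(1645.0, amplitude=0.6),   # amide I
)


def _draw_positions(params: NucleiLayoutParams, rng: np.random.Generator) -> np.ndarray:
    w, h = params.field_width, params.field_height
    n = params.n_cells
    if n == 0:
        return np.empty((0, 2))
    if params.layout == "uniform":
        return rng.uniform([0, 0], [w, h], size=(n, 2))
    parents = rng.uniform([0, 0], [w, h], size=(params.n_parents, 2))
    assignment = rng.integers(0, params.n_parents, size=n)
    # rejection-sample offspring so the window edge does not accumulate mass
    pos = np.empty((n, 2))
    for i, parent in enumerate(parents[assignment]):
        while True:
            cand = parent + rng.normal(0.0, params.cluster_sd, size=2)
            if 0 <= cand[0] <= w and 0 <= cand[1] <= h:
                pos[i] = cand
                break
    return pos


def simulate_nuclei_image(params: NucleiLayoutParams) -> tuple[ImageGrid, np.ndarray]:
    """Render a synthetic nuclei micrograph; returns (image, positions).

    Positions are (x, y) in micrometres with origin at the top-left corner,
    x rightward and y downward.  Each nucleus is an isotropic Gaussian blob
    of sd ``nucleus_radius`` and peak ``blob_amplitude`` added onto the
    background; i.i.d. Gaussian noise of sd ``noise_sd`` is added last.
    """
    rng = np.random.default_rng(params.seed)
    positions = _draw_positions(params, rng)
    ny = int(round(params.field_height / params.pixel_size))
    nx = int(round(params.field_width / params.pixel_size))
    img = np.full((ny, nx), float(params.background))
    sigma_px = params.nucleus_radius / params.pixel_size
    half = int(np.ceil(4.0 * sigma_px))
    for x_um, y_um in positions:
        cx = x_um / params.pixel_size
        cy = y_um / params.pixel_size
        x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        xs = np.arange(max(x0, 0), min(x1, nx))
        ys = np.arange(max(y0, 0), min(y1, ny))
        if xs.size == 0 or ys.size == 0:
            continue
        gx = np.exp(-0.5 * ((xs - cx) / sigma_px) ** 2)
        gy = np.exp(-0.5 * ((ys - cy) / sigma_px) ** 2)
        img[np.ix_(ys, xs)] += params.blob_amplitude * np.outer(gy, gx)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    return ImageGrid(img, params.pixel_size), positions


def simulate_release_curve(
    model: ReleaseModelParams,
    times_h,
    noise_sd: float = 0.0,
    seed: int = 0,
    c_load_uM: float | None = None,
    label: str = "",
) -> ReleaseCurve:
    """First-order release observations with additive Gaussian noise."""
    t = np.asarray(times_h, dtype=float)
    if np.any(t < 0):
        raise ParameterError("times must be >= 0")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    c = np.asarray(first_order_model(t, model), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        c = c + rng.normal(0.0, noise_sd, size=c.shape)
    return ReleaseCurve(
        times_h=t,
        concentrations_uM=np.clip(c, 0.0, None),
        c_load_uM=c_load_uM,
        label=label,
    )


def default_release_times(t_max_h: float = 240.0, n_points: int = 30) -> np.ndarray:
    """Default release sampling schedule: dense early, sparse late.

    Release assays sample frequently during the fast initial rise and
    sparsely on the plateau; t = 0 plus a geometric progression out to 10
    days emulates that design and keeps the time constant identifiable.
    """
    return np.concatenate([[0.0], np.geomspace(2.0, t_max_h, n_points - 1)])


def default_wavenumber_axis(step: float = 2.0) -> np.ndarray:
    """Default Raman axis: 700-3250 cm^-1."""
    return np.arange(700.0, 3250.0 + step / 2, step)


def _fluorescence_baseline(wavenumbers: np.ndarray, scale: float) -> np.ndarray:
    """Broad, featureless background emulating cell autofluorescence."""
    w = (wavenumbers - wavenumbers[0]) / (wavenumbers[-1] - wavenumbers[0])
    return scale * (0.6 + 0.8 * np.exp(-0.5 * ((w - 0.35) / 0.3) ** 2) - 0.3 * w)


def simulate_sers_map(
    grid_shape: tuple[int, int] = (16, 16),
    wavenumbers: np.ndarray | None = None,
    class_layout: np.ndarray | None = None,
    peak_table: dict[int, tuple[SpectralPeak, ...]] | None = None,
    baseline_scale: float = 1.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    stepsize_um: float = 0.5,
) -> tuple[SpectralMap, np.ndarray]:
    """Hyperspectral map with planted spectral classes; returns (map, labels).

    ``class_layout`` assigns a class label to every grid pixel (default:
    left half class 0, right half class 1); ``peak_table`` maps labels to
    the bands planted in that class (default: class 1 carries the adhesion
    fingerprint, class 0 only baseline).  Every spectrum is baseline +
    class peaks + Gaussian noise.
    """
    if wavenumbers is None:
        wavenumbers = default_wavenumber_axis()
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    if np.any(np.diff(wavenumbers) <= 0):
        raise ParameterError("wavenumber axis must be strictly increasing")
    rows, cols = grid_shape
    if class_layout is None:
        class_layout = (np.arange(cols)[None, :] >= cols // 2).astype(int)
        class_layout = np.broadcast_to(class_layout, (rows, cols)).copy()
    class_layout = np.asarray(class_layout)
    if class_layout.shape != tuple(grid_shape):
        raise ParameterError("class_layout shape must match grid_shape")
    if peak_table is None:
        peak_table = {0: (), 1: ADHESION_PEAKS}
    for peaks in peak_table.values():
        for pk in peaks:
            if not (wavenumbers[0] <= pk.center <= wavenumbers[-1]):
                raise ParameterError(f"peak center {pk.center} outside axis range")

    baseline = _fluorescence_baseline(wavenumbers, baseline_scale)
    class_spectra = {
        lbl: baseline + sum((pk.profile(wavenumbers) for pk in peaks), np.zeros_like(wavenumbers))
        for lbl, peaks in peak_table.items()
    }
    labels = class_layout.ravel()
    missing = set(np.unique(labels)) - set(class_spectra)
    if missing:
        raise ParameterError(f"class_layout labels {sorted(missing)} missing from peak_table")
    spectra = np.stack([class_spectra[lbl] for lbl in labels])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        spectra = spectra + rng.normal(0.0, noise_sd, size=spectra.shape)
    smap = SpectralMap(
        wavenumbers=wavenumbers,
        spectra=np.clip(spectra, 0.0, None),
        grid_shape=tuple(grid_shape),
        stepsize_um=stepsize_um,
    )
    return smap, class_layout.copy()


def simulate_fractal_surface(params: SurfaceSynthesisParams) -> SurfaceField:
    """Self-affine surface of prescribed fractal dimension and roughness.

    Spectral synthesis: white Gaussian noise is shaped in Fourier space by
    the amplitude filter |q|**(-(8 - 2*Df)/2), giving a 2-D power spectrum
    P(q) ~ q**(-(8 - 2*Df)); the inverse transform is rescaled so the
    measured Ra equals ``target_ra`` exactly (Ra is linear in amplitude).
    """
    n = params.grid_n
    rng = np.random.default_rng(params.seed)
    white = rng.normal(size=(n, n))
    F = np.fft.fft2(white)
    qx = np.fft.fftfreq(n, d=params.extent_um / n)
    q = np.hypot(*np.meshgrid(qx, qx, indexing="xy"))
    amp = np.zeros_like(q)
    nz = q > 0
    exponent = (8.0 - 2.0 * params.target_df) / 2.0
    amp[nz] = q[nz] ** (-exponent)
    h = np.real(np.fft.ifft2(F * amp))
    h -= h.mean()
    # rescale against the same plane-detrended Ra the estimator reports
    from .surface_topography import SurfaceField as _SF, roughness_Ra

    ra = roughness_Ra(_SF(h, (params.extent_um, params.extent_um)))
    if ra > 0:
        h *= params.target_ra / ra
    return SurfaceField(heights_nm=h, extent_um=(params.extent_um, params.extent_um))


def simulate_porous_image(
    target_p: float,
    pore_radius_px: int = 4,
    image_shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    tol: float = 0.005,
) -> ImageGrid:
    """Binary porous micrograph (void = 1) of prescribed void fraction.

    Random disks are stamped as void until the void fraction is within
    ``tol`` of ``target_p``; targets 0 and 1 return exactly solid / void.
    """
    if not (0.0 <= target_p <= 1.0):
        raise ParameterError(f"target_p must be in [0, 1], got {target_p}")
    if pore_radius_px <= 0:
        raise ParameterError(f"pore_radius_px must be > 0, got {pore_radius_px}")
    ny, nx = image_shape
    mask = np.zeros((ny, nx), dtype=np.uint8)
    if target_p == 0.0:
        return ImageGrid(mask, 1.0)
    if target_p == 1.0:
        return ImageGrid(np.ones_like(mask), 1.0)
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:ny, 0:nx]
    r2 = pore_radius_px**2
    for _ in range(100000):
        if abs(mask.mean() - target_p) <= tol or mask.mean() > target_p:
            break
        cy = rng.uniform(0, ny)
        cx = rng.uniform(0, nx)
        mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= r2] = 1
    return ImageGrid(mask, 1.0)


def porous_to_grayscale(
    binary: ImageGrid,
    solid_level: float = 0.75,
    void_level: float = 0.25,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> ImageGrid:
    """Grayscale SEM-like rendering of a binary porous mask (void dark)."""
    arr = np.where(binary.intensities > 0, void_level, solid_level).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        arr = arr + rng.normal(0.0, noise_sd, size=arr.shape)
    return ImageGrid(np.clip(arr, 0.0, 1.0), binary.pixel_size)
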