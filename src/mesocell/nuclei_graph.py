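"""Nuclei detection from fluorescence images.

Converts a DAPI-stained fluorescence micrograph into a set of candidate cell
nodes in three stages:

1. intensity k-means segmentation into ``k`` classes ranked from dark to
   bright, with the ``t`` darkest classes treated as background (DAPI nuclei
   are bright on a dark background; set ``invert=True`` for dark-foreground
   stains);
2. occupancy downsampling: the binary mask is reduced by non-overlapping
   ``r x r`` block means, where ``r**2`` approximates the area of one nucleus
   footprint in pixels, so each block value is the probability that the block
   is occupied by a cell;
3. probability thresholding: blocks with occupancy above ``p_thresh`` become
   graph nodes, positioned at the block center in physical micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from sklearn.cluster import KMeans

from .errors import ParameterError

__all__ = [
    "ImageGrid",
    "SegmentationParams",
    "NodeSet",
    "preprocess_image",
    "segment_image",
    "downsample_occupancy",
    "detect_nodes",
    "detect_nodes_from_image",
]


@dataclass(frozen=True)
class ImageGrid:
    """A 2-D raster with a physical pixel size.

    Parameters
    ----------
    intensities:
        Rectangular array of non-negative intensities (grayscale).
    pixel_size:
        Edge length of one pixel in micrometres.
    """

    intensities: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 2:
            raise ParameterError(f"intensities must be 2-D, got ndim={arr.ndim}")
        if self.pixel_size <= 0:
            raise ParameterError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def field_size_um(self) -> tuple[float, float]:
        """(width, height) of the imaged field in micrometres."""
        h, w = self.intensities.shape
        return (w * self.pixel_size, h * self.pixel_size)


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the segmentation / downsampling / thresholding chain.

    ``r`` should match the linear size of a segmented nucleus footprint in
    pixels (``r**2`` = expected footprint area).  The default corresponds to
    the thresholded footprint of a ~10 um nucleus imaged at 1.72 um/px: the
    bright blob that survives segmentation is wider than the geometric
    nucleus because its dim rim also separates from background.
    """

    k: int = 3
    t: int = 1
    r: int = 6
    p_thresh: float = 0.5
    invert: bool = False
    smooth_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ParameterError(f"k must be >= 2, got {self.k}")
        if not (1 <= self.t < self.k):
            raise ParameterError(f"t must satisfy 1 <= t < k, got t={self.t}, k={self.k}")
        if self.r < 1:
            raise ParameterError(f"r must be >= 1, got {self.r}")
        if not (0 < self.p_thresh <= 1):
            raise ParameterError(f"p_thresh must be in (0, 1], got {self.p_thresh}")


@dataclass
class NodeSet:
    """Detected cell nodes on the downsampled block grid."""

    rows: np.ndarray           # block row indices
    cols: np.ndarray           # block column indices
    x_um: np.ndarray           # block-center x (rightward), micrometres
    y_um: np.ndarray           # block-center y (downward), micrometres
    occupancy: np.ndarray      # full occupancy grid in [0, 1]
    pixel_size: float
    r: int
    image_shape: tuple[int, int]
    p_thresh: float = 0.5
    warnings: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.x_um.size)

    @property
    def positions_um(self) -> np.ndarray:
        """(N, 2) array of (x, y) positions in micrometres."""
        return np.column_stack([self.x_um, self.y_um])

    @property
    def field_size_um(self) -> tuple[float, float]:
        h, w = self.image_shape
        return (w * self.pixel_size, h * self.pixel_size)

    def to_dataframe(self) -> pd.DataFrame:
        occ = self.occupancy[self.rows, self.cols] if self.n else np.array([])
        return pd.DataFrame(
            {
                "node_id": np.arange(self.n),
                "row": self.rows,
                "col": self.cols,
                "x_um": self.x_um,
                "y_um": self.y_um,
                "occupancy": occ,
            }
        )


def preprocess_image(img: ImageGrid, smooth_sd: float = 1.0) -> ImageGrid:
    """Low-pass filter and contrast-stretch an image to [0, 1].

    Gaussian smoothing (sd in pixels) suppresses flat-spectrum additive
    noise; the linear stretch maps the observed intensity range onto [0, 1].
    A constant image maps to all zeros.
    """
    arr = np.asarray(img.intensities, dtype=float)
    if smooth_sd > 0:
        arr = gaussian_filter(arr, sigma=smooth_sd)
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        arr = np.zeros_like(arr)
    return ImageGrid(arr, img.pixel_size)


def _kmeans_1d(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Histogram-weighted 1-D k-means; returns (sorted class edges, centers).

    Quantizing to a fixed histogram makes the clustering deterministic and
    independent of image size.  Initial centers are intensity quantiles.
    """
    counts, edges = np.histogram(values, bins=1024)
    centers_bins = 0.5 * (edges[:-1] + edges[1:])
    nonzero = counts > 0
    pts = centers_bins[nonzero].reshape(-1, 1)
    wts = counts[nonzero].astype(float)
    quantiles = np.quantile(values, np.linspace(0.05, 0.95, k))
    init = np.sort(np.unique(quantiles))
    if init.size < k:
        # spread initial centers over the observed range instead
        init = np.linspace(pts.min(), pts.max(), k)
    km = KMeans(n_clusters=k, init=init.reshape(-1, 1), n_init=1, random_state=0)
    km.fit(pts, sample_weight=wts)
    centers = np.sort(km.cluster_centers_.ravel())
    # 1-D k-means decision boundaries are midpoints of adjacent centers
    boundaries = 0.5 * (centers[:-1] + centers[1:])
    return boundaries, centers


def segment_image(img: ImageGrid, params: SegmentationParams) -> np.ndarray:
    """Binary cell/background mask via 1-D k-means intensity clustering.

    Pixels are clustered into ``k`` intensity classes ranked dark to bright.
    With ``invert=False`` the ``t`` darkest classes are background (0) and
    the rest foreground (1); ``invert=True`` flips the convention for stains
    where the signal is dark.
    """
    pre = preprocess_image(img, params.smooth_sd)
    values = pre.intensities.ravel()
    distinct = np.unique(values)
    if distinct.size == 1:
        warnings.warn("constant image: returning all-zero mask", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    k = params.k
    if distinct.size < k:
        warnings.warn(
            f"only {distinct.size} distinct intensities; reducing k from {k}",
            stacklevel=2,
        )
        k = int(distinct.size)
    boundaries, _ = _kmeans_1d(values, k)
    labels = np.digitize(pre.intensities, boundaries)  # 0 = darkest class
    t = min(params.t, k - 1)
    if params.invert:
        mask = labels < (k - t)
    else:
        mask = labels >= t
    return mask


def downsample_occupancy(mask: np.ndarray, r: int) -> np.ndarray:
    """Non-overlapping r x r block mean of a binary mask (stride r).

    Trailing partial blocks are averaged over their actual pixel count, so
    the block-size-weighted mean of the output equals the foreground
    fraction of the mask exactly.
    """
    if r < 1:
        raise ParameterError(f"r must be >= 1, got {r}")
    m = np.asarray(mask, dtype=float)
    h, w = m.shape
    row_starts = np.arange(0, h, r)
    col_starts = np.arange(0, w, r)
    sums = np.add.reduceat(np.add.reduceat(m, row_starts, axis=0), col_starts, axis=1)
    row_sizes = np.minimum(r, h - row_starts)
    col_sizes = np.minimum(r, w - col_starts)
    return sums / np.outer(row_sizes, col_sizes)


def block_centers_um(
    shape: tuple[int, int], r: int, pixel_size: float
) -> tuple[np.ndarray, np.ndarray]:
    """Physical (x, y) centers of each downsampling block, per grid axis."""
    h, w = shape
    row_starts = np.arange(0, h, r)
    col_starts = np.arange(0, w, r)
    y = (row_starts + np.minimum(r, h - row_starts) / 2.0) * pixel_size
    x = (col_starts + np.minimum(r, w - col_starts) / 2.0) * pixel_size
    return x, y


def detect_nodes(
    occupancy: np.ndarray,
    p_thresh: float,
    pixel_size: float,
    r: int,
    image_shape: tuple[int, int] | None = None,
) -> NodeSet:
    """Threshold the occupancy grid into graph nodes.

    Every block with occupancy strictly above ``p_thresh`` becomes one node
    located at the block center.  An empty node set is a valid result.
    """
    occ = np.asarray(occupancy, dtype=float)
    if occ.min() < 0 or occ.max() > 1:
        raise ParameterError("occupancy values must lie in [0, 1]")
    if image_shape is None:
        image_shape = (occ.shape[0] * r, occ.shape[1] * r)
    rows, cols = np.nonzero(occ > p_thresh)
    x_ax, y_ax = block_centers_um(image_shape, r, pixel_size)
    return NodeSet(
        rows=rows,
        cols=cols,
        x_um=x_ax[cols],
        y_um=y_ax[rows],
        occupancy=occ,
        pixel_size=pixel_size,
        r=r,
        image_shape=tuple(image_shape),
        p_thresh=p_thresh,
    )


def detect_nodes_from_image(img: ImageGrid, params: SegmentationParams) -> NodeSet:
    """Run the full segmentation -> occupancy -> thresholding chain."""
    mask = segment_image(img, params)
    occ = downsample_occupancy(mask, params.r)
    return detect_nodes(occ, params.p_thresh, img.pixel_size, params.r, img.shape)
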