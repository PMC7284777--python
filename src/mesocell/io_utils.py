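"""File formats, provenance and thin reporting utilities.

Conventions: images as TIFF/PNG (16-bit grayscale or float32 TIFF), tables
as tidy CSV with unit-suffixed headers, structured results as JSON with
embedded provenance (parameters, seed, package version), adjacency matrices
as Matrix Market.  Coordinates are 0-based, row-major, origin top-left.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_array
from scipy.stats import ttest_ind

from . import __version__
from .errors import ConfigError
from .nuclei_graph import ImageGrid, NodeSet
from .release_kinetics import ReleaseCurve
from .sers_chemometrics import SpectralMap
from .surface_topography import PSDResult, SurfaceField


def write_image(path: str | Path, img: ImageGrid, dtype: str = "uint16") -> None:
    path = Path(path)
    arr = np.asarray(img.intensities, dtype=float)
    if dtype == "uint16":
        lo, hi = arr.min(), arr.max()
        scaled = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
        out = (scaled * 65535).astype(np.uint16)
    elif dtype == "float32":
        out = arr.astype(np.float32)
    else:
        raise ConfigError(f"unsupported image dtype {dtype!r}")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out, metadata={"pixel_size_um": img.pixel_size})
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, out)
    else:
        raise ConfigError(f"unsupported image format {path.suffix!r}")


def read_image(path: str | Path, pixel_size_um: float = 1.0) -> ImageGrid:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            meta = tf.shaped_metadata or tf.imagej_metadata or {}
            if isinstance(meta, (list, tuple)):
                meta = meta[0] if meta else {}
            pixel_size_um = float(meta.get("pixel_size_um", pixel_size_um))
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    return ImageGrid(np.asarray(arr, dtype=float), pixel_size_um)


def write_nodes_csv(path: str | Path, nodes: NodeSet) -> None:
    nodes.to_dataframe().to_csv(path, index=False)


def write_positions_csv(path: str | Path, positions_um: np.ndarray) -> None:
    pd.DataFrame(positions_um, columns=["x_um", "y_um"]).to_csv(path, index=False)


def read_release_csv(path: str | Path, **kwargs: Any) -> ReleaseCurve:
    df = pd.read_csv(path)
    for col in ("time_h", "concentration_uM"):
        if col not in df.columns:
            raise ConfigError(f"release CSV missing column {col!r} in {path}")
    return ReleaseCurve(
        times_h=df["time_h"].to_numpy(),
        concentrations_uM=df["concentration_uM"].to_numpy(),
        **kwargs,
    )


def write_release_csv(path: str | Path, curve: ReleaseCurve) -> None:
    pd.DataFrame(
        {"time_h": curve.times_h, "concentration_uM": curve.concentrations_uM}
    ).to_csv(path, index=False)


def write_spectra_csv(path: str | Path, smap: SpectralMap) -> None:
    """Spectra as CSV: wavenumber_cm-1 first column, one column per pixel."""
    cols = {"wavenumber_cm-1": smap.wavenumbers}
    for i in range(smap.n_pixels):
        cols[f"px{i:05d}"] = smap.spectra[i]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_spectra_csv(
    path: str | Path, grid_shape: tuple[int, int], stepsize_um: float = 0.5
) -> SpectralMap:
    df = pd.read_csv(path)
    if "wavenumber_cm-1" not in df.columns:
        raise ConfigError(f"spectra CSV missing 'wavenumber_cm-1' column in {path}")
    w = df.pop("wavenumber_cm-1").to_numpy()
    return SpectralMap(
        wavenumbers=w,
        spectra=df.to_numpy().T,
        grid_shape=grid_shape,
        stepsize_um=stepsize_um,
    )


def write_heightmap_csv(path: str | Path, surface: SurfaceField) -> None:
    np.savetxt(path, surface.heights_nm, delimiter=",")


def read_heightmap_csv(
    path: str | Path, extent_um: tuple[float, float] = (1.0, 1.0)
) -> SurfaceField:
    return SurfaceField(np.loadtxt(path, delimiter=","), extent_um)


def write_psd_csv(path: str | Path, psd: PSDResult) -> None:
    pd.DataFrame(
        {"frequency_per_um": psd.spatial_frequencies, "power_nm2": psd.power}
    ).to_csv(path, index=False)


def write_adjacency_mtx(path: str | Path, adjacency: np.ndarray) -> None:
    mmwrite(str(path), csr_array(adjacency.astype(np.int8)))


def read_adjacency_mtx(path: str | Path) -> np.ndarray:
    return np.asarray(mmread(str(path)).todense()).astype(bool)


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def provenance(config: dict[str, Any], seed: int | None = None) -> dict[str, Any]:
    """Provenance block embedded in every structured output."""
    cfg = _to_jsonable(config)
    digest = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    return {"software": "mesocell", "version": __version__, "seed": seed,
            "config": cfg, "config_sha256": digest}


def write_json_report(
    path: str | Path, payload: dict[str, Any], config: dict[str, Any] | None = None,
    seed: int | None = None,
) -> None:
    doc = _to_jsonable(payload)
    doc["provenance"] = provenance(config or {}, seed)
    Path(path).write_text(json.dumps(doc, indent=2, allow_nan=True) + "\n")


def compare_groups(a, b, alpha: float = 0.05) -> dict[str, float | bool]:
    """Two-tailed unpaired Student's t-test between two metric groups.

    Standard reporting utility (equal-variance t-test, normality assumed);
    returns the statistic, p-value and a significance flag at ``alpha``.
    """
    stat, p = ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return {"t_statistic": float(stat), "p_value": float(p), "significant": bool(p < alpha)}
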