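"""Reproducible multi-stage runs driven by a validated configuration.

A :class:`RunConfig` selects pipeline stages and carries every stage
parameter plus one master seed; identical configs produce byte-identical
numeric outputs.  Per-stage seeds are derived deterministically from the
master seed so stages stay independent.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io_utils
from .cell_network import WaxmanParams, analyze_image, field_diagonal
from .errors import ConfigError
from .nuclei_graph import SegmentationParams
from .release_kinetics import (
    ReleaseModelParams,
    fit_release,
    initial_velocity,
    release_efficiency,
)
from .sers_chemometrics import area_normalize, cluster_pixels, fit_pca, loading_ratio
from .surface_topography import (
    fractal_dimension,
    feature_size_stats,
    porosity,
    power_spectrum,
    roughness_Ra,
    segment_pores,
)
from .synthetic_data import (
    NucleiLayoutParams,
    SurfaceSynthesisParams,
    simulate_fractal_surface,
    simulate_nuclei_image,
    simulate_porous_image,
    simulate_release_curve,
    simulate_sers_map,
)

ALL_STAGES = (
    "nuclei_network",
    "release",
    "sers",
    "surface",
    "porosity",
)


def _filter_kwargs(cls: type, section: str, kwargs: dict[str, Any]) -> dict[str, Any]:
    known = {f.name for f in fields(cls)}
    unknown = set(kwargs) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in config section {section!r}; "
            f"known keys: {sorted(known)}"
        )
    return kwargs


@dataclass
class RunConfig:
    """Validated configuration of a full synthetic-pipeline run."""

    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    outdir: str = "mesocell_out"
    nuclei: dict[str, Any] = field(default_factory=dict)
    segmentation: dict[str, Any] = field(default_factory=dict)
    waxman: dict[str, Any] = field(default_factory=dict)
    null_reps: int = 20
    release_model: dict[str, Any] = field(default_factory=lambda: {"cs": 4.94, "tau": 46.0})
    release_times_h: list[float] = field(default_factory=lambda: list(
        np.concatenate([[0.0], np.geomspace(2.0, 240.0, 29)])))
    release_noise_sd: float = 0.1
    c_load_uM: float = 30.0
    sers: dict[str, Any] = field(default_factory=dict)
    n_components: int = 5
    n_classes: int = 5
    surface: dict[str, Any] = field(default_factory=dict)
    porous_target_p: float = 0.12
    verbosity: int = 1

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ConfigError(f"unknown stage(s) {sorted(bad)}; known: {list(ALL_STAGES)}")
        _filter_kwargs(NucleiLayoutParams, "nuclei", self.nuclei)
        _filter_kwargs(SegmentationParams, "segmentation", self.segmentation)
        _filter_kwargs(WaxmanParams, "waxman", self.waxman)
        _filter_kwargs(ReleaseModelParams, "release_model", self.release_model)
        _filter_kwargs(SurfaceSynthesisParams, "surface", self.surface)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(
                f"unknown config key(s) {sorted(unknown)}; known keys: {sorted(known)}"
            )
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(io_utils._to_jsonable(asdict(self))))


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the selected stages on synthetic inputs; write a report.

    Returns the consolidated report dictionary (also written to
    ``<outdir>/report.json`` with provenance).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: config.seed + 1000 * i for i, s in enumerate(ALL_STAGES)}
    report: dict[str, Any] = {}

    if "nuclei_network" in config.stages:
        params = NucleiLayoutParams(**{**config.nuclei, "seed": seeds["nuclei_network"]})
        img, truth = simulate_nuclei_image(params)
        io_utils.write_image(out / "nuclei.tif", img)
        io_utils.write_positions_csv(out / "nuclei_truth.csv", truth)
        seg = SegmentationParams(**config.segmentation)
        waxman = (
            WaxmanParams(**config.waxman)
            if "L" in config.waxman
            else WaxmanParams(**{**config.waxman, "L": field_diagonal(*img.field_size_um)})
        )
        metrics = analyze_image(
            img, seg, waxman, reps=config.null_reps, seed=seeds["nuclei_network"]
        )
        report["nuclei_network"] = {"n_planted": int(truth.shape[0]), **metrics.to_dict()}

    if "release" in config.stages:
        model = ReleaseModelParams(**config.release_model)
        curve = simulate_release_curve(
            model,
            config.release_times_h,
            noise_sd=config.release_noise_sd,
            seed=seeds["release"],
            c_load_uM=config.c_load_uM,
        )
        io_utils.write_release_csv(out / "release.csv", curve)
        fit = fit_release(curve)
        _, eff = release_efficiency(fit.params, config.c_load_uM)
        report["release"] = {
            "true": asdict(model),
            "fit": asdict(fit.params),
            "rss": fit.rss,
            "converged": fit.converged,
            "initial_velocity_uM_per_h": initial_velocity(fit.params),
            "asymptotic_efficiency": eff,
        }

    if "sers" in config.stages:
        smap, labels = simulate_sers_map(seed=seeds["sers"], **config.sers)
        io_utils.write_spectra_csv(out / "sers_spectra.csv", smap)
        norm = area_normalize(smap)
        model = fit_pca(norm, n_components=config.n_components)
        classes = cluster_pixels(
            model.scores, grid_shape=smap.grid_shape, k=config.n_classes,
            seed=seeds["sers"],
        )
        ratio = loading_ratio(model)
        np.savetxt(out / "sers_classes.csv", classes, fmt="%d", delimiter=",")
        report["sers"] = {
            "explained_variance_fraction": model.explained_variance_fraction,
            "r_int": ratio.r_int,
            "n_classes_found": int(np.unique(classes).size),
        }

    if "surface" in config.stages:
        sparams = SurfaceSynthesisParams(**{**config.surface, "seed": seeds["surface"]})
        surf = simulate_fractal_surface(sparams)
        io_utils.write_heightmap_csv(out / "surface_nm.csv", surf)
        psd = power_spectrum(surf)
        io_utils.write_psd_csv(out / "surface_psd.csv", psd)
        dfres = fractal_dimension(psd)
        report["surface"] = {
            "target_df": sparams.target_df,
            "df": dfres.df,
            "r_squared": dfres.r_squared,
            "low_confidence": dfres.low_confidence,
            "ra_nm": roughness_Ra(surf),
            "target_ra_nm": sparams.target_ra,
        }

    if "porosity" in config.stages:
        binary = simulate_porous_image(config.porous_target_p, seed=seeds["porosity"])
        io_utils.write_image(out / "porous.tif", binary)
        p = porosity(binary)
        from .synthetic_data import porous_to_grayscale

        gray = porous_to_grayscale(binary, seed=seeds["porosity"])
        p_seg = porosity(segment_pores(gray))
        sizes = feature_size_stats(binary.intensities, pixel_size_nm=1.0)
        report["porosity"] = {
            "target_P": config.porous_target_p,
            "P_direct": p,
            "P_from_grayscale": p_seg,
            "pore_mean_diameter_px": sizes.mean_diameter,
            "pore_count": sizes.count,
        }

    io_utils.write_json_report(
        out / "report.json", report, config=asdict(config), seed=config.seed
    )
    return report
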