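"""High-level orchestration: simulated studies and method comparison.

These helpers wire the modules together the way the CLI and the
reproduction script use them: simulate the phantom study, fit the MV→kV
calibration from a simulated rod phantom, and run any of the four
correction methods (fusion prior, LIMAR, NMAR, NMAR-MV) on one kV/MV pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import CalibrationCurve, apply_calibration, fit_calibration, rod_samples
from .config import PipelineConfig
from .fusion import segment_metal
from .grid import ImageGrid
from .io import save_image_fixture
from .mar import limar, mar_correct, nmar, nmar_prior_from_limar
from .metrics import region_metrics, standard_regions
from .phantom import Circle, PhantomSpec, calibration_phantom, default_phantom, rasterize
from .physics import default_kv_acquisition, default_mv_acquisition
from .projection import Sinogram
from .register import resample_to_grid
from .simulate import simulate_acquisition


@dataclass
class SimulatedStudy:
    """One simulated phantom experiment: ground truth plus both scans."""

    spec: PhantomSpec
    truth: ImageGrid  # theoretical CT image at kV
    kv: ImageGrid
    mv: ImageGrid
    sino_kv: Sinogram
    sino_mv: Sinogram
    seed: int


def simulate_study(cfg: PipelineConfig | None = None) -> SimulatedStudy:
    cfg = cfg or PipelineConfig()
    sim = cfg.simulator
    spec = default_phantom()
    shape = (sim.grid_size, sim.grid_size)
    truth = rasterize(spec, shape, sim.pixel_spacing_mm, "kV")
    kv_acq = default_kv_acquisition(
        incident_photons_per_bin=sim.kv_photons_per_bin, views=sim.views
    )
    mv_acq = default_mv_acquisition(
        incident_photons_per_bin=sim.mv_photons_per_bin,
        detector_blur_sigma=sim.mv_detector_blur_mm,
        views=sim.views,
    )
    kv, sino_kv = simulate_acquisition(spec, kv_acq, sim.seed, shape, sim.pixel_spacing_mm)
    mv, sino_mv = simulate_acquisition(
        spec, mv_acq, sim.seed + 1, shape, sim.pixel_spacing_mm
    )
    return SimulatedStudy(
        spec=spec, truth=truth, kv=kv, mv=mv, sino_kv=sino_kv, sino_mv=sino_mv,
        seed=sim.seed,
    )


def calibration_rod_masks(
    spec: PhantomSpec, grid: ImageGrid, erode_fraction: float = 0.6
) -> list[np.ndarray]:
    """Boolean mask per rod, eroded to avoid partial-volume boundary pixels."""
    yy, xx = grid.coords()
    x_cm, y_cm = xx / 10.0, yy / 10.0
    masks = []
    for shape in spec.shapes:
        if isinstance(shape, Circle) and shape.material.startswith("rod"):
            inner = Circle(shape.center, shape.radius * erode_fraction, shape.material)
            masks.append(inner.contains(x_cm, y_cm))
    return masks


def fit_calibration_from_simulation(cfg: PipelineConfig | None = None) -> CalibrationCurve:
    """Scan the rod phantom at both energies and fit the piecewise-linear map."""
    cfg = cfg or PipelineConfig()
    sim = cfg.simulator
    spec = calibration_phantom(cfg.calibration.n_rods)
    shape = (sim.grid_size, sim.grid_size)
    # the 30 cm cylinder needs a slightly wider field of view than the study
    spacing = max(sim.pixel_spacing_mm, 310.0 / sim.grid_size)
    kv_acq = default_kv_acquisition(
        incident_photons_per_bin=sim.kv_photons_per_bin, views=sim.views
    )
    mv_acq = default_mv_acquisition(
        incident_photons_per_bin=sim.mv_photons_per_bin,
        detector_blur_sigma=sim.mv_detector_blur_mm,
        views=sim.views,
    )
    kv, _ = simulate_acquisition(spec, kv_acq, sim.seed + 2, shape, spacing)
    mv, _ = simulate_acquisition(spec, mv_acq, sim.seed + 3, shape, spacing)
    masks = calibration_rod_masks(spec, kv)
    return fit_calibration(rod_samples(kv, mv, masks))


def correct_pair(
    i_kv: ImageGrid,
    i_mv: ImageGrid,
    cfg: PipelineConfig | None = None,
    sino_kv: Sinogram | None = None,
    calibration: CalibrationCurve | None = None,
) -> tuple[ImageGrid, dict[str, ImageGrid]]:
    """Run the configured MAR method on one kV/MV pair.

    Returns (corrected image, image-domain intermediates). LIMAR and NMAR
    use only the kV data; NMAR-MV and the fusion method use the MV image as
    (part of) the prior.
    """
    cfg = cfg or PipelineConfig()
    fus, mar = cfg.fusion, cfg.mar
    method = mar.method
    if method == "fusion":
        result = mar_correct(
            i_kv, i_mv, sino_kv=sino_kv, calibration=calibration,
            register=mar.do_register, threshold_hu=fus.threshold_hu,
            r_lo=fus.r_lo, r_hi=fus.r_hi, sigma_mm=fus.sigma_mm,
            fill_hu=fus.fill_hu, filter_name=mar.filter_name,
            trace_epsilon_cm=mar.trace_epsilon_cm,
        )
        inter = {"pseudo_mv": result.pseudo_mv}
        if result.fused is not None:
            inter["fused"] = result.fused
            inter["prior"] = result.prior
        return result.corrected, inter

    if method == "limar":
        metal = segment_metal(i_kv, fus.threshold_hu)
        corrected = limar(i_kv, metal, sino_kv=sino_kv, filter_name=mar.filter_name)
        return corrected, {}

    pseudo = i_mv if i_mv.same_grid(i_kv) else resample_to_grid(i_mv, i_kv)
    if calibration is not None:
        pseudo = apply_calibration(pseudo, calibration)

    if method == "nmar":
        metal = segment_metal(i_kv, fus.threshold_hu)
        pre = limar(i_kv, metal, sino_kv=sino_kv, filter_name=mar.filter_name)
        prior = nmar_prior_from_limar(pre)
        corrected = nmar(i_kv, metal, prior, sino_kv=sino_kv, filter_name=mar.filter_name)
        return corrected, {"limar_preprocess": pre, "prior": prior}

    if method == "nmar-mv":
        metal = segment_metal(pseudo, fus.threshold_hu)
        corrected = nmar(
            i_kv, metal, pseudo, sino_kv=sino_kv,
            filter_name=mar.filter_name, metal_source=pseudo,
        )
        return corrected, {"pseudo_mv": pseudo, "prior": pseudo}

    raise ValueError(f"unknown MAR method {method!r}")


def compare_methods(
    cfg: PipelineConfig | None = None, outdir: Path | None = None
) -> pd.DataFrame:
    """Simulate once, run all four methods, and tabulate region metrics."""
    cfg = cfg or PipelineConfig()
    study = simulate_study(cfg)
    curve = fit_calibration_from_simulation(cfg)
    regions = standard_regions(
        study.spec, study.truth,
        cfg.evaluation.band_width_mm, cfg.evaluation.metal_margin_mm,
    )
    frames = []
    images = {"uncorrected": study.kv}
    for method in ("fusion", "limar", "nmar", "nmar-mv"):
        method_cfg = cfg.model_copy(deep=True)
        method_cfg.mar.method = method
        corrected, _ = correct_pair(
            study.kv, study.mv, method_cfg, sino_kv=study.sino_kv, calibration=curve
        )
        images[method] = corrected
    for name, image in images.items():
        table = region_metrics(image, study.truth, regions)
        table.insert(0, "method", name)
        frames.append(table)
        if outdir is not None:
            save_image_fixture(Path(outdir) / f"{name}.npz", image)
    if outdir is not None:
        save_image_fixture(Path(outdir) / "truth.npz", study.truth)
    return pd.concat(frames, ignore_index=True)
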