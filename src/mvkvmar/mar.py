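"""Sinogram-domain metal artifact reduction and baseline methods.

The correction pipeline: segment metal in the MV image, forward project the
metal-only image to find the metal trace (the corrupted sinogram bins),
forward project the fused prior to obtain surrogate data, replace the trace
with the surrogate plus a linear blend of the boundary offsets so the
corrected sinogram is continuous with the measured data at both segment
ends, reconstruct with FBP, and re-insert the metal.

For a per-view trace segment occupying bins jj+1 .. jj+D (boundary bins jj
and jj+D+1 just outside the trace), the corrected projection is

    P_cor(b) = P_prior(b)
             + [ (jj+D+1-b) * (P_kv(jj)   - P_prior(jj))
               + (b-jj)     * (P_kv(jj+D+1) - P_prior(jj+D+1)) ] / (D+1)

Bins outside the trace are left bit-identical to the measured data. LIMAR
is the same blend with a zero prior (plain linear interpolation across the
trace); NMAR normalizes the measured sinogram by a prior's sinogram before
interpolating and multiplies back afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .calibrate import CalibrationCurve, apply_calibration
from .fusion import (
    MetalMask,
    WeightMaps,
    compute_weights,
    fuse,
    make_prior,
    segment_metal,
)
from .grid import ImageGrid, require_same_grid
from .physics import METAL_THRESHOLD_HU
from .projection import ProjectionGeometry, Sinogram, fbp, forward_project, project_mu
from .register import resample_to_grid, rigid_register

logger = logging.getLogger(__name__)


@dataclass
class TraceMask:
    """Metal trace in sinogram space with per-view run-length segments.

    ``segments`` holds (view, start, stop) with start..stop the inclusive
    bin range inside the trace; boundary bins start-1 and stop+1 (when they
    exist) are outside the mask.
    """

    mask: np.ndarray
    segments: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "TraceMask":
        mask = np.asarray(mask, dtype=bool)
        segments = []
        for view in range(mask.shape[0]):
            row = mask[view]
            edges = np.flatnonzero(np.diff(np.concatenate(([0], row.view(np.int8), [0]))))
            for start, stop in zip(edges[::2], edges[1::2] - 1):
                segments.append((view, int(start), int(stop)))
        return cls(mask=mask, segments=segments)


def metal_trace(
    metal: MetalMask,
    geometry: ProjectionGeometry,
    epsilon_cm: float | None = None,
) -> TraceMask:
    """Sinogram bins whose rays cross more metal than a small path epsilon.

    Default epsilon is half the pixel diagonal, which suppresses grazing
    rays that would otherwise yield unstable one-pixel segments.
    """
    spacing_cm = geometry.detector_spacing_mm / 10.0
    if epsilon_cm is None:
        epsilon_cm = 0.5 * np.sqrt(2.0) * spacing_cm
    path_cm = project_mu(metal.mask.astype(float), geometry)  # cm of metal per ray
    return TraceMask.from_mask(path_cm > epsilon_cm)


def replace_trace(p_kv: Sinogram, p_prior: Sinogram, trace: TraceMask) -> Sinogram:
    """Surrogate replacement with boundary-continuous linear blending.

    Segments touching a detector edge (no boundary bin on that side) fall
    back to a one-sided constant offset and are logged.
    """
    if p_kv.values.shape != p_prior.values.shape:
        raise ValueError("kV and prior sinograms have different shapes")
    if trace.mask.shape != p_kv.values.shape:
        raise ValueError("trace mask does not match the sinogram shape")
    n_bins = p_kv.n_bins
    out = p_kv.values.copy()
    for view, start, stop in trace.segments:
        kv_row = p_kv.values[view]
        pr_row = p_prior.values[view]
        b = np.arange(start, stop + 1)
        jj, right = start - 1, stop + 1
        if jj >= 0 and right < n_bins:
            d = stop - start + 1
            off_l = kv_row[jj] - pr_row[jj]
            off_r = kv_row[right] - pr_row[right]
            blend = ((right - b) * off_l + (b - jj) * off_r) / (d + 1)
        elif right < n_bins:
            logger.debug("view %d: segment touches left detector edge", view)
            blend = kv_row[right] - pr_row[right]
        elif jj >= 0:
            logger.debug("view %d: segment touches right detector edge", view)
            blend = kv_row[jj] - pr_row[jj]
        else:
            logger.debug("view %d: segment spans the whole detector", view)
            blend = 0.0
        out[view, start : stop + 1] = pr_row[b] + blend
    return p_kv.with_values(out)


def interpolate_trace(p_kv: Sinogram, trace: TraceMask) -> Sinogram:
    """Linear interpolation across each trace segment (the LIMAR surrogate)."""
    zero = p_kv.with_values(np.zeros_like(p_kv.values))
    return replace_trace(p_kv, zero, trace)


def reinsert_metal(
    reconstruction: ImageGrid, metal_source: ImageGrid, metal: MetalMask
) -> ImageGrid:
    """Overwrite metal pixels of the reconstruction with the source's values."""
    require_same_grid(reconstruction, metal_source)
    values = reconstruction.values.copy()
    values[metal.mask] = metal_source.values[metal.mask]
    return reconstruction.with_values(values)


def _measured_or_synthesized(
    i_kv: ImageGrid, geometry: ProjectionGeometry, sino_kv: Sinogram | None
) -> tuple[Sinogram, bool]:
    if sino_kv is not None:
        return sino_kv, True
    return forward_project(i_kv, geometry), False


def limar(
    i_kv: ImageGrid,
    metal: MetalMask,
    geometry: ProjectionGeometry | None = None,
    sino_kv: Sinogram | None = None,
    filter_name: str = "ramp",
) -> ImageGrid:
    """Linear-interpolation MAR: kV data only, no prior."""
    if geometry is None:
        geometry = ProjectionGeometry.for_image(i_kv) if sino_kv is None else sino_kv.geometry
    p_kv, _ = _measured_or_synthesized(i_kv, geometry, sino_kv)
    if metal.empty:
        return _match_grid(fbp(p_kv, filter_name), i_kv)
    trace = metal_trace(metal, geometry)
    corrected = interpolate_trace(p_kv, trace)
    recon = _match_grid(fbp(corrected, filter_name), i_kv)
    return reinsert_metal(recon, i_kv, metal)


def nmar(
    i_kv: ImageGrid,
    metal: MetalMask,
    prior: ImageGrid,
    geometry: ProjectionGeometry | None = None,
    epsilon: float = 1e-2,
    sino_kv: Sinogram | None = None,
    filter_name: str = "ramp",
    metal_source: ImageGrid | None = None,
) -> ImageGrid:
    """Normalized MAR: interpolate the prior-normalized sinogram.

    With a prior segmented from the LIMAR image this is the classic NMAR
    baseline; passing the registered pseudo-kV MV image as ``prior`` (and as
    ``metal_source``) gives the NMAR-MV variant.
    """
    if geometry is None:
        geometry = ProjectionGeometry.for_image(i_kv) if sino_kv is None else sino_kv.geometry
    p_kv, _ = _measured_or_synthesized(i_kv, geometry, sino_kv)
    if metal.empty:
        return _match_grid(fbp(p_kv, filter_name), i_kv)
    p_prior = forward_project(prior, geometry)
    corrected = nmar_replace(p_kv, p_prior, metal_trace(metal, geometry), epsilon)
    recon = _match_grid(fbp(corrected, filter_name), i_kv)
    return reinsert_metal(recon, metal_source if metal_source is not None else i_kv, metal)


def nmar_replace(
    p_kv: Sinogram, p_prior: Sinogram, trace: TraceMask, epsilon: float = 1e-2
) -> Sinogram:
    """Normalize by the (floored) prior sinogram, interpolate, denormalize."""
    floor = np.maximum(p_prior.values, epsilon)
    norm = p_kv.with_values(p_kv.values / floor)
    interp = interpolate_trace(norm, trace)
    out = p_kv.values.copy()
    out[trace.mask] = (interp.values * floor)[trace.mask]
    return p_kv.with_values(out)


def nmar_prior_from_limar(
    limar_image: ImageGrid,
    air_below_hu: float = -500.0,
    bone_above_hu: float = 500.0,
) -> ImageGrid:
    """Tissue-class prior for classic NMAR: air and soft tissue flattened to
    their class means, dense pixels (>= bone threshold) kept as-is."""
    v = limar_image.values
    out = v.copy()
    air = v < air_below_hu
    soft = (v >= air_below_hu) & (v < bone_above_hu)
    if air.any():
        out[air] = v[air].mean()
    if soft.any():
        out[soft] = v[soft].mean()
    return limar_image.with_values(out)


def _match_grid(recon: ImageGrid, like: ImageGrid) -> ImageGrid:
    return ImageGrid(
        values=recon.values,
        pixel_spacing=like.pixel_spacing,
        origin=like.origin,
        bit_depth_range=like.bit_depth_range,
    )


@dataclass
class MARResult:
    """Corrected image plus every intermediate of the pipeline."""

    corrected: ImageGrid
    pseudo_mv: ImageGrid
    metal: MetalMask
    weights: WeightMaps | None
    fused: ImageGrid | None
    prior: ImageGrid | None
    sino_kv: Sinogram
    sino_prior: Sinogram | None
    sino_corrected: Sinogram
    trace: TraceMask | None
    used_measured_sinogram: bool


def mar_correct(
    i_kv: ImageGrid,
    i_mv: ImageGrid,
    geometry: ProjectionGeometry | None = None,
    sino_kv: Sinogram | None = None,
    calibration: CalibrationCurve | None = None,
    register: bool = False,
    threshold_hu: float = METAL_THRESHOLD_HU,
    r_lo: float = 0.05,
    r_hi: float = 0.40,
    sigma_mm: float = 60.0,
    fill_hu: float = 0.0,
    filter_name: str = "ramp",
    trace_epsilon_cm: float | None = None,
    min_metal_area_px: int = 0,
    fixed_metal_hu: float | None = None,
) -> MARResult:
    """Full kV+MV fusion-prior correction of one slice.

    Stages: resample MV onto the kV grid → HU calibration to pseudo-kV →
    (optional) rigid registration → metal segmentation in the MV image →
    weighted fusion → prior (metal set to ``fill_hu``) → forward projection →
    trace replacement → FBP → metal re-insertion (MV values, or a fixed HU
    when ``fixed_metal_hu`` is given). With an empty metal mask the result
    degenerates to the plain FBP round trip of the kV data.
    """
    logger.info("stage: resample MV onto kV grid")
    pseudo = i_mv if i_mv.same_grid(i_kv) else resample_to_grid(i_mv, i_kv)
    if calibration is not None:
        logger.info("stage: apply MV->pseudo-kV calibration")
        pseudo = apply_calibration(pseudo, calibration)
    if register:
        logger.info("stage: rigid registration")
        _, pseudo = rigid_register(pseudo, i_kv, metal_threshold=threshold_hu)

    logger.info("stage: metal segmentation (threshold %.0f HU)", threshold_hu)
    metal = segment_metal(pseudo, threshold_hu, min_area_px=min_metal_area_px)

    if geometry is None:
        geometry = ProjectionGeometry.for_image(i_kv) if sino_kv is None else sino_kv.geometry
    p_kv, measured = _measured_or_synthesized(i_kv, geometry, sino_kv)
    logger.info("stage: kV sinogram (%s)", "measured" if measured else "synthesized")

    if metal.empty:
        logger.info("no metal found: returning plain FBP round trip")
        recon = _match_grid(fbp(p_kv, filter_name), i_kv)
        return MARResult(
            corrected=recon, pseudo_mv=pseudo, metal=metal, weights=None,
            fused=None, prior=None, sino_kv=p_kv, sino_prior=None,
            sino_corrected=p_kv, trace=None, used_measured_sinogram=measured,
        )

    logger.info("stage: fusion weights and prior image")
    weights = compute_weights(i_kv, pseudo, metal, r_lo, r_hi, sigma_mm)
    fused = fuse(i_kv, pseudo, weights)
    prior = make_prior(fused, metal, fill_hu)

    logger.info("stage: trace replacement")
    trace = metal_trace(metal, geometry, trace_epsilon_cm)
    p_prior = forward_project(prior, geometry)
    p_cor = replace_trace(p_kv, p_prior, trace)

    logger.info("stage: FBP and metal re-insertion")
    recon = _match_grid(fbp(p_cor, filter_name), i_kv)
    if fixed_metal_hu is not None:
        source = pseudo.with_values(np.full(pseudo.shape, float(fixed_metal_hu)))
    else:
        source = pseudo
    corrected = reinsert_metal(recon, source, metal)
    return MARResult(
        corrected=corrected, pseudo_mv=pseudo, metal=metal, weights=weights,
        fused=fused, prior=prior, sino_kv=p_kv, sino_prior=p_prior,
        sino_corrected=p_cor, trace=trace, used_measured_sinogram=measured,
    )
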