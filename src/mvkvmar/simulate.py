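"""Polychromatic CT acquisition simulator.

Simulates the two scans the correction pipeline consumes:

* a 120 kVp diagnostic scan whose polychromatic beam hardens and whose
  detector photon-starves behind ~5 cm of steel, producing the classic dark
  streaks along the metal's long axis, bright bands along its short axis,
  and a filled-in (lost) central hole;
* a megavoltage cone-beam scan whose high-energy beam penetrates the metal
  (hole resolved, CT numbers near truth) at the cost of markedly higher
  noise and a blurred detector.

Transmitted intensity per bin is sum_E S(E) * N0 * exp(-integral mu(E) dl),
detector blur is applied to the intensity, Poisson counting noise is drawn
from the given seed, zero counts are clamped to a small floor before the
log, and the projection p = -ln(I / N0) is reconstructed by FBP at the
spectrum's effective energy.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .grid import ImageGrid
from .phantom import PhantomSpec, rasterize_labels
from .physics import WATER, AcquisitionModel
from .projection import ProjectionGeometry, Sinogram, fbp, project_mu


def material_mu_map(
    spec: PhantomSpec,
    energy_kev: float,
    grid_shape: tuple[int, int],
    pixel_spacing_mm: float | tuple[float, float],
) -> np.ndarray:
    """Linear attenuation map (1/cm) at one energy from the material models."""
    index, labels, _ = rasterize_labels(spec, grid_shape, pixel_spacing_mm)
    mu = np.zeros(grid_shape)
    for i, label in enumerate(labels):
        mat = spec.materials[label].material
        mu[index == i] = mat.mu(energy_kev)
    return mu


def simulate_acquisition(
    spec: PhantomSpec,
    acq: AcquisitionModel,
    seed: int,
    grid_shape: tuple[int, int] = (512, 512),
    pixel_spacing_mm: float | tuple[float, float] = 0.59,
    noise: bool = True,
    count_floor: float = 0.5,
) -> tuple[ImageGrid, Sinogram]:
    """Simulate one scan; returns (FBP reconstruction, measured sinogram).

    Deterministic for a fixed (spec, acq, seed, grid) tuple. ``noise=False``
    disables Poisson sampling (ideal detector), which together with a
    single-line spectrum gives the noise-free monochromatic round trip used
    to validate the projector/FBP pair.
    """
    if acq.incident_photons_per_bin <= 0:
        raise ValueError("incident photon count must be positive")
    spacing = (
        (float(pixel_spacing_mm), float(pixel_spacing_mm))
        if np.isscalar(pixel_spacing_mm)
        else tuple(map(float, pixel_spacing_mm))
    )
    mu_ref = float(WATER.mu(acq.effective_energy_kev))
    geometry = ProjectionGeometry(
        angles_deg=np.linspace(0.0, 180.0, acq.views, endpoint=False),
        detector_spacing_mm=spacing[0],
        image_shape=grid_shape,
        mu_water_ref=mu_ref,
    )

    n0 = float(acq.incident_photons_per_bin)
    intensity = np.zeros((geometry.n_views, geometry.n_bins))
    for energy, weight in acq.spectrum:
        mu_map = material_mu_map(spec, energy, grid_shape, spacing)
        line_integrals = project_mu(mu_map, geometry)
        intensity += weight * n0 * np.exp(-line_integrals)

    if acq.detector_blur_sigma > 0:
        sigma_bins = acq.detector_blur_sigma / geometry.detector_spacing_mm
        intensity = gaussian_filter1d(intensity, sigma_bins, axis=1)

    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(intensity).astype(float)
    else:
        counts = intensity
    counts = np.maximum(counts, count_floor)  # photon starvation clamp

    projections = -np.log(counts / n0)
    sino = Sinogram(values=projections, geometry=geometry)
    recon = fbp(sino)
    recon = ImageGrid(values=recon.values, pixel_spacing=spacing)
    return recon, sino
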