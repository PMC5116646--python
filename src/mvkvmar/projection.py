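"""Parallel-beam forward projection and filtered back projection.

Projection geometry follows the reconstruction convention of this package:
views uniformly spaced over 180 degrees, detector bins spanning the image
diagonal at one bin per pixel. Images are exchanged in HU; internally they
are mapped to linear attenuation via the affine water-equivalent scaling

    mu = mu_ref * (1 + HU / 1000)          [1/cm]

so sinograms hold dimensionless line integrals (1/cm x cm) directly
comparable with the simulator's measured -ln(I/I0) projections. FBP inverts
the same scaling, so a zero sinogram reconstructs to uniform air (-1000 HU).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import radon, iradon

from .grid import ImageGrid
from .physics import WATER, REFERENCE_KEV

#: default attenuation reference: water at the kV reference energy, 1/cm
MU_WATER_REF = float(WATER.mu(REFERENCE_KEV))

FILTERS = ("ramp", "shepp-logan", "hann")


def detector_bins_for(shape: tuple[int, int]) -> int:
    """Number of detector bins skimage's projector uses for a square grid."""
    return int(np.ceil(np.sqrt(2) * max(shape)))


@dataclass(frozen=True)
class ProjectionGeometry:
    """Acquisition geometry shared by all sinograms of one scan."""

    angles_deg: np.ndarray
    detector_spacing_mm: float
    image_shape: tuple[int, int]
    mu_water_ref: float = MU_WATER_REF

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles_deg", np.asarray(self.angles_deg, dtype=float))
        d = np.diff(self.angles_deg)
        if self.angles_deg.size < 2 or np.any(d <= 0):
            raise ValueError("angles must be strictly increasing, >= 2 views")
        if self.angles_deg[-1] - self.angles_deg[0] >= 360.0:
            raise ValueError("angular span must be < 360 degrees")

    @property
    def n_views(self) -> int:
        return int(self.angles_deg.size)

    @property
    def n_bins(self) -> int:
        return detector_bins_for(self.image_shape)

    @classmethod
    def for_image(
        cls, image: ImageGrid, n_views: int = 180, mu_water_ref: float = MU_WATER_REF
    ) -> "ProjectionGeometry":
        return cls(
            angles_deg=np.linspace(0.0, 180.0, n_views, endpoint=False),
            detector_spacing_mm=float(image.pixel_spacing[0]),
            image_shape=image.shape,
            mu_water_ref=mu_water_ref,
        )


@dataclass
class Sinogram:
    """Projection data: m views x n detector bins.

    ``values[a, b]`` is the line integral at view ``a``, bin ``b``; the flat
    index convention k = (a-1)*n + b of the trace-replacement formulas
    corresponds to C-order flattening of this array.
    """

    values: np.ndarray
    geometry: ProjectionGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("sinogram values must be 2D (views x bins)")
        if self.values.shape[0] != self.geometry.n_views:
            raise ValueError("sinogram rows must match the number of views")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")

    @property
    def n_views(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "Sinogram":
        return Sinogram(values=np.asarray(values, dtype=float), geometry=self.geometry)


def project_mu(mu_map: np.ndarray, geometry: ProjectionGeometry) -> np.ndarray:
    """Line integrals (dimensionless) of a 1/cm attenuation map."""
    spacing_cm = geometry.detector_spacing_mm / 10.0
    sino = radon(mu_map, theta=geometry.angles_deg, circle=False) * spacing_cm
    return sino.T  # (views, bins)


def forward_project(image: ImageGrid, geometry: ProjectionGeometry | None = None) -> Sinogram:
    """Forward project an HU image through the mu scaling."""
    if geometry is None:
        geometry = ProjectionGeometry.for_image(image)
    if geometry.image_shape != image.shape:
        raise ValueError("geometry was built for a different image shape")
    mu = geometry.mu_water_ref * (1.0 + image.values / 1000.0)
    np.clip(mu, 0.0, None, out=mu)
    return Sinogram(values=project_mu(mu, geometry), geometry=geometry)


def fbp(sino: Sinogram, filter_name: str = "ramp") -> ImageGrid:
    """Filtered back projection of a sinogram back to an HU image."""
    if filter_name not in FILTERS:
        raise ValueError(f"filter must be one of {FILTERS}")
    geom = sino.geometry
    spacing_cm = geom.detector_spacing_mm / 10.0
    mu = iradon(
        sino.values.T / spacing_cm,
        theta=geom.angles_deg,
        circle=False,
        filter_name=filter_name,
        output_size=max(geom.image_shape),
    )
    hu = 1000.0 * (mu / geom.mu_water_ref - 1.0)
    return ImageGrid(
        values=hu,
        pixel_spacing=(geom.detector_spacing_mm, geom.detector_spacing_mm),
    )
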