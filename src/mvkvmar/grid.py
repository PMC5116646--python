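"""2D CT slice container in Hounsfield units.

All image-domain operations in this package exchange :class:`ImageGrid`
objects: a 2D HU array plus the physical metadata (pixel spacing, origin)
needed to relate array indices to positions in the scanner frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: HU range representable by conventional 12-bit CT reconstruction.
STANDARD_RANGE: tuple[float, float] = (-1024.0, 3071.0)
#: Extended 16-bit range needed to represent metal HU faithfully.
EXTENDED_RANGE: tuple[float, float] = (-32768.0, 32767.0)


@dataclass
class ImageGrid:
    """A single axial CT slice in HU (water = 0, air = −1000).

    Parameters
    ----------
    values :
        2D float array of CT numbers.
    pixel_spacing :
        (row, col) pixel size in mm; strictly positive.
    origin :
        Physical (row, col) position in mm of the center of pixel (0, 0).
        By default the grid is centered on the scanner isocenter.
    bit_depth_range :
        Representable HU range. Either the standard 12-bit range
        (−1024, 3071) or an extended range that contains it.
    """

    values: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    origin: tuple[float, float] | None = None
    bit_depth_range: tuple[float, float] = EXTENDED_RANGE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ImageGrid values must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ImageGrid values must be finite")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError("pixel_spacing components must be > 0")
        lo, hi = self.bit_depth_range
        if (lo, hi) != STANDARD_RANGE and not (
            lo <= STANDARD_RANGE[0] and hi >= STANDARD_RANGE[1]
        ):
            raise ValueError(
                "bit_depth_range must be the 12-bit (-1024, 3071) range or an "
                "extended range containing it"
            )
        if self.origin is None:
            r, c = self.values.shape
            self.origin = (
                -0.5 * (r - 1) * self.pixel_spacing[0],
                -0.5 * (c - 1) * self.pixel_spacing[1],
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (y, x) coordinates in mm of every pixel center.

        Returns two 2D arrays following the (row, col) axis convention:
        ``y`` grows with row index, ``x`` with column index.
        """
        r, c = self.values.shape
        y = self.origin[0] + np.arange(r) * self.pixel_spacing[0]
        x = self.origin[1] + np.arange(c) * self.pixel_spacing[1]
        return np.meshgrid(y, x, indexing="ij")

    def same_grid(self, other: "ImageGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.pixel_spacing, other.pixel_spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_values(self, values: np.ndarray) -> "ImageGrid":
        """Copy of this grid carrying new HU values on the same geometry."""
        return replace(self, values=np.asarray(values, dtype=float))


def require_same_grid(a: ImageGrid, b: ImageGrid) -> None:
    if not a.same_grid(b):
        raise ValueError(
            f"images are not on the same grid: {a.shape}@{a.pixel_spacing} vs "
            f"{b.shape}@{b.pixel_spacing}"
        )
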