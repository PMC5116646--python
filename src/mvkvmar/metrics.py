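"""Artifact metrics: percentage-difference maps, line profiles, region stats.

The dark streaks along the metal's long axis and the bright bands along its
short axis are quantified over geometric regions derived from the phantom
specification: 1 cm-wide bands along each metal axis (metal excluded), the
central hole disk, the metal itself, and a far-field annulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import ImageGrid, require_same_grid
from .phantom import Circle, Ellipse, PhantomSpec


@dataclass
class RegionSpec:
    """A named evaluation region given directly as a boolean mask."""

    label: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def percent_diff_map(test: ImageGrid, reference: ImageGrid) -> np.ndarray:
    """Signed percentage difference d = 100 (t - t̄) / t̄.

    Reference pixels equal to zero use a denominator of 1, keeping the map
    finite; positive values mark bright artifacts, negative values dark
    ones.
    """
    require_same_grid(test, reference)
    ref = reference.values
    den = np.where(ref == 0.0, 1.0, ref)
    return 100.0 * (test.values - ref) / den


def line_profile(
    image: ImageGrid, orientation: str, through: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """HU along the full row/column through a physical (y, x) point in mm.

    Returns (positions_mm, values); default point is the grid center.
    """
    if orientation not in ("horizontal", "vertical"):
        raise ValueError("orientation must be 'horizontal' or 'vertical'")
    r, c = image.shape
    if through is None:
        through = (
            image.origin[0] + 0.5 * (r - 1) * image.pixel_spacing[0],
            image.origin[1] + 0.5 * (c - 1) * image.pixel_spacing[1],
        )
    row = round((through[0] - image.origin[0]) / image.pixel_spacing[0])
    col = round((through[1] - image.origin[1]) / image.pixel_spacing[1])
    if not (0 <= row < r and 0 <= col < c):
        raise IndexError("profile point lies outside the image grid")
    if orientation == "horizontal":
        pos = image.origin[1] + np.arange(c) * image.pixel_spacing[1]
        return pos, image.values[row, :].copy()
    pos = image.origin[0] + np.arange(r) * image.pixel_spacing[0]
    return pos, image.values[:, col].copy()


def region_metrics(
    test: ImageGrid, reference: ImageGrid, regions: list[RegionSpec]
) -> pd.DataFrame:
    """Per-region MAE / mean signed error / max abs error of (test − reference)."""
    require_same_grid(test, reference)
    rows = []
    for region in regions:
        if not region.mask.any():
            import warnings

            warnings.warn(f"region {region.label!r} is empty; skipped")
            continue
        err = (test.values - reference.values)[region.mask]
        rows.append(
            {
                "region": region.label,
                "n_pixels": int(region.mask.sum()),
                "mae_hu": float(np.abs(err).mean()),
                "mean_err_hu": float(err.mean()),
                "max_abs_err_hu": float(np.abs(err).max()),
            }
        )
    return pd.DataFrame(rows, columns=["region", "n_pixels", "mae_hu", "mean_err_hu", "max_abs_err_hu"])


def _find_metal_and_hole(spec: PhantomSpec) -> tuple[Ellipse | Circle, Circle | None]:
    metal = None
    hole = None
    for shape in spec.shapes:
        if shape.material == "steel":
            metal = shape
        elif metal is not None and shape.material == "air" and hole is None:
            hole = shape
    if metal is None:
        raise ValueError("phantom has no steel shape to derive regions from")
    return metal, hole


def standard_regions(
    spec: PhantomSpec,
    grid: ImageGrid,
    band_width_mm: float = 10.0,
    metal_margin_mm: float = 2.0,
) -> list[RegionSpec]:
    """Geometric artifact regions for a phantom with one elliptical insert.

    * ``long_axis_band`` / ``short_axis_band``: bands of the given width
      along the metal's axes, inside the body, excluding metal plus a small
      safety margin — the dark- and bright-artifact zones;
    * ``hole``: the central air hole (slightly eroded so boundary pixels do
      not dilute the mean);
    * ``metal``: the steel minus the hole;
    * ``far_field``: an annulus well away from the metal.
    """
    metal, hole = _find_metal_and_hole(spec)
    yy, xx = grid.coords()  # mm
    x_cm, y_cm = xx / 10.0, yy / 10.0
    inside_body = spec.body.contains(x_cm, y_cm)

    th = math.radians(getattr(metal, "rotation_deg", 0.0))
    cx, cy = metal.center
    u = (x_cm - cx) * math.cos(th) + (y_cm - cy) * math.sin(th)
    v = -(x_cm - cx) * math.sin(th) + (y_cm - cy) * math.cos(th)

    if isinstance(metal, Ellipse):
        a, b = metal.axes[0] / 2.0, metal.axes[1] / 2.0
    else:
        a = b = metal.radius
    margin = metal_margin_mm / 10.0
    near_metal = (u / (a + margin)) ** 2 + (v / (b + margin)) ** 2 <= 1.0
    metal_mask = metal.contains(x_cm, y_cm)
    half_band = band_width_mm / 20.0  # cm

    regions = [
        RegionSpec("long_axis_band", inside_body & (np.abs(v) <= half_band) & ~near_metal),
        RegionSpec("short_axis_band", inside_body & (np.abs(u) <= half_band) & ~near_metal),
    ]
    if hole is not None:
        r_in = 0.8 * hole.radius
        hole_mask = (x_cm - hole.center[0]) ** 2 + (y_cm - hole.center[1]) ** 2 <= r_in**2
        regions.append(RegionSpec("hole", hole_mask))
        metal_mask = metal_mask & ~hole.contains(x_cm, y_cm)
    regions.append(RegionSpec("metal", metal_mask))

    body_r = spec.body.radius if isinstance(spec.body, Circle) else max(a, b) * 3
    rr = np.sqrt((x_cm - cx) ** 2 + (y_cm - cy) ** 2)
    regions.append(
        RegionSpec("far_field", inside_body & (rr >= 0.6 * body_r) & (rr <= 0.85 * body_r))
    )
    return regions
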