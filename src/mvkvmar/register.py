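"""Resampling and rigid registration of the MV image onto the kV grid.

The MV cone-beam scan is acquired with its own field of view and couch
position, so before fusion it is (1) bilinearly resampled in physical
coordinates onto the kV pixel grid and (2) rigidly aligned by a
deterministic coarse-to-fine search over (tx, ty, theta) minimizing the
mean-squared HU difference. Metal pixels can be masked out of the metric,
since artifacts differ between the two modalities and would bias it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import ImageGrid, require_same_grid

AIR_HU = -1000.0


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """In-plane rigid motion: translation (row, col) in mm and rotation in
    degrees about the grid center."""

    translation: tuple[float, float] = (0.0, 0.0)
    rotation_deg: float = 0.0

    def inverse(self) -> "RigidTransform":
        th = math.radians(-self.rotation_deg)
        ty, tx = self.translation
        # inverse of x -> R x + t is x -> R^-1 (x - t)
        ity = -(ty * math.cos(th) - tx * math.sin(th))
        itx = -(ty * math.sin(th) + tx * math.cos(th))
        return RigidTransform(translation=(ity, itx), rotation_deg=-self.rotation_deg)

    def to_json(self) -> str:
        return json.dumps(
            {"translation_mm": list(self.translation), "rotation_deg": self.rotation_deg}
        )

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        d = json.loads(text)
        return cls(translation=tuple(d["translation_mm"]), rotation_deg=d["rotation_deg"])


def resample_to_grid(moving: ImageGrid, target: ImageGrid) -> ImageGrid:
    """Bilinear resampling in physical mm coordinates onto the target grid.

    Pixels of the target grid that fall outside the moving image's field of
    view are filled with air (-1000 HU).
    """
    yy, xx = target.coords()
    rows = (yy - moving.origin[0]) / moving.pixel_spacing[0]
    cols = (xx - moving.origin[1]) / moving.pixel_spacing[1]
    values = ndimage.map_coordinates(
        moving.values, [rows, cols], order=1, mode="constant", cval=AIR_HU
    )
    return ImageGrid(
        values=values,
        pixel_spacing=target.pixel_spacing,
        origin=target.origin,
        bit_depth_range=moving.bit_depth_range,
    )


def apply_rigid(image: ImageGrid, transform: RigidTransform) -> ImageGrid:
    """Apply the transform (rotation about grid center, then translation)."""
    th = math.radians(transform.rotation_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    r, c = image.shape
    center = np.array([0.5 * (r - 1), 0.5 * (c - 1)])
    spacing = np.asarray(image.pixel_spacing)
    shift_px = np.asarray(transform.translation) / spacing
    # map_coordinates pulls values: output(x) = input(R^-1 (x - c - t) + c)
    inv = rot.T
    offset = center - inv @ (center + shift_px)
    values = ndimage.affine_transform(
        image.values, inv, offset=offset, order=1, mode="constant", cval=AIR_HU
    )
    return image.with_values(values)


def _mse(a: np.ndarray, b: np.ndarray, keep: np.ndarray | None) -> float:
    d = a - b
    if keep is not None:
        if not np.any(keep):
            raise RegistrationError("empty overlap: no pixels left to compare")
        d = d[keep]
    return float(np.mean(d * d))


def rigid_register(
    moving: ImageGrid,
    fixed: ImageGrid,
    max_translation_mm: float = 10.0,
    max_rotation_deg: float = 10.0,
    coarse_step_mm: float = 2.0,
    coarse_step_deg: float = 2.0,
    fine_step_mm: float = 0.1,
    fine_step_deg: float = 0.1,
    metal_threshold: float | None = None,
) -> tuple[RigidTransform, ImageGrid]:
    """Recover the rigid motion aligning ``moving`` to ``fixed``.

    Exhaustive coarse grid over (ty, tx, theta) followed by a pattern search
    that repeatedly halves the step down to (fine_step_mm, fine_step_deg).
    Deterministic; for identical inputs the optimum is the identity. When a
    metal threshold is given, pixels at or above it in either image are
    excluded from the metric.
    """
    require_same_grid(moving, fixed)
    keep = None
    if metal_threshold is not None:
        keep = (fixed.values < metal_threshold) & (moving.values < metal_threshold)

    def cost(ty: float, tx: float, th: float) -> float:
        moved = apply_rigid(moving, RigidTransform((ty, tx), th))
        return _mse(moved.values, fixed.values, keep)

    best = (0.0, 0.0, 0.0)
    best_cost = cost(*best)
    t_grid = np.arange(-max_translation_mm, max_translation_mm + 1e-9, coarse_step_mm)
    r_grid = np.arange(-max_rotation_deg, max_rotation_deg + 1e-9, coarse_step_deg)
    for ty in t_grid:
        for tx in t_grid:
            for th in r_grid:
                c = cost(ty, tx, th)
                if c < best_cost - 1e-12:
                    best_cost, best = c, (float(ty), float(tx), float(th))

    step_t, step_r = coarse_step_mm / 2.0, coarse_step_deg / 2.0
    while step_t >= fine_step_mm / 2.0 or step_r >= fine_step_deg / 2.0:
        improved = True
        while improved:
            improved = False
            ty0, tx0, th0 = best
            for dty, dtx, dth in (
                (step_t, 0, 0), (-step_t, 0, 0),
                (0, step_t, 0), (0, -step_t, 0),
                (0, 0, step_r), (0, 0, -step_r),
            ):
                cand = (ty0 + dty, tx0 + dtx, th0 + dth)
                c = cost(*cand)
                if c < best_cost - 1e-12:
                    best_cost, best, improved = c, cand, True
        step_t, step_r = step_t / 2.0, step_r / 2.0

    transform = RigidTransform(translation=(best[0], best[1]), rotation_deg=best[2])
    return transform, apply_rigid(moving, transform)
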