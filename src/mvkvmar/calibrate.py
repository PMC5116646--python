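"""Piecewise-linear HU calibration from MV to pseudo-kV.

The linear attenuation coefficient of a material differs between a
megavoltage and a kilovoltage beam, so MV CT numbers cannot be fused with
kV CT numbers directly. The mapping is measured on a calibration cylinder
holding tissue-density rods: the mean MV and kV CT number of each rod gives
one knot of a monotone piecewise-linear curve, evaluated by linear
interpolation between knots and linear continuation beyond the outermost
knots (clamping would destroy the pseudo-kV value of metal, which lies far
above the densest rod).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .grid import ImageGrid


class DegenerateFitError(ValueError):
    """Calibration pairs do not define a function of HU_MV."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone piecewise-linear map HU_MV -> HU_kV defined by knots."""

    knots: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.knots) < 2:
            raise DegenerateFitError("need at least 2 calibration pairs")
        mv = np.array([k[0] for k in self.knots])
        if np.any(np.diff(mv) <= 0):
            raise DegenerateFitError("HU_MV knots must be strictly increasing")

    def __call__(self, hu_mv: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(hu_mv, dtype=float)
        xs = np.array([k[0] for k in self.knots])
        ys = np.array([k[1] for k in self.knots])
        out = np.interp(x, xs, ys)
        # linear continuation beyond the end knots
        lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        out = np.where(x < xs[0], ys[0] + (x - xs[0]) * lo_slope, out)
        out = np.where(x > xs[-1], ys[-1] + (x - xs[-1]) * hi_slope, out)
        return out if out.ndim else float(out)

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("hu_mv,hu_kv\n")
        for mv, kv in self.knots:
            buf.write(f"{mv},{kv}\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "CalibrationCurve":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        pairs = [tuple(float(v) for v in ln.split(",")) for ln in lines[1:]]
        return cls(knots=tuple(pairs))


def identity_curve() -> CalibrationCurve:
    return CalibrationCurve(knots=((-1000.0, -1000.0), (3000.0, 3000.0)))


def fit_calibration(paired_samples: list[tuple[float, float]]) -> CalibrationCurve:
    """Build the curve from per-rod (mean HU_MV, mean HU_kV) pairs."""
    if len(paired_samples) < 2:
        raise DegenerateFitError("need at least 2 calibration pairs")
    ordered = sorted((float(a), float(b)) for a, b in paired_samples)
    mv = [a for a, _ in ordered]
    if len(set(mv)) != len(mv):
        raise DegenerateFitError("duplicate HU_MV values in calibration pairs")
    return CalibrationCurve(knots=tuple(ordered))


def apply_calibration(image: ImageGrid, curve: CalibrationCurve) -> ImageGrid:
    """Per-pixel evaluation of the curve; grid metadata unchanged."""
    return image.with_values(curve(image.values))


def rod_samples(
    kv_image: ImageGrid,
    mv_image: ImageGrid,
    rod_masks: list[np.ndarray],
) -> list[tuple[float, float]]:
    """Mean (HU_MV, HU_kV) over each rod mask, the raw calibration pairs."""
    pairs = []
    for mask in rod_masks:
        pairs.append((float(mv_image.values[mask].mean()), float(kv_image.values[mask].mean())))
    return pairs
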