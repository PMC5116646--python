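"""Vector phantom specifications and ground-truth rasterization.

A phantom is described by analytic primitives (ellipses, circles,
rectangles) in physical centimeters, each tagged with a material. The
default phantom mirrors the imaging experiment this package models: a
water-equivalent body holding an elliptical stainless-steel insert
(long axis 4.97 cm, short axis 3.58 cm, density 7.8 g/cm^3) with a central
cylindrical air hole of 1.81 cm diameter, plus tissue rods away from the
metal for line-profile checks. Rasterizing the spec yields the
"theoretical CT image": the artifact-free HU ground truth against which
corrections are scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import ImageGrid
from .physics import MATERIALS, Material, AttenuationModel, _WATER_MODEL, _BONE_MODEL

KV_REFERENCE_KEV = 70.0
MV_REFERENCE_KEV = 1500.0


class GeometryError(ValueError):
    """Phantom geometry impossible or inconsistent with the target grid."""


@dataclass(frozen=True)
class Ellipse:
    """center (x, y) in cm; axes are FULL axis lengths (long, short) in cm."""

    center: tuple[float, float]
    axes: tuple[float, float]
    rotation_deg: float = 0.0
    material: str = "water"

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        th = math.radians(self.rotation_deg)
        dx, dy = x - self.center[0], y - self.center[1]
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        a, b = self.axes[0] / 2.0, self.axes[1] / 2.0
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def outline(self, n: int = 64) -> np.ndarray:
        t = np.linspace(0, 2 * math.pi, n, endpoint=False)
        a, b = self.axes[0] / 2.0, self.axes[1] / 2.0
        th = math.radians(self.rotation_deg)
        u, v = a * np.cos(t), b * np.sin(t)
        x = self.center[0] + u * math.cos(th) - v * math.sin(th)
        y = self.center[1] + u * math.sin(th) + v * math.cos(th)
        return np.stack([x, y], axis=1)

    def area(self) -> float:
        return math.pi * self.axes[0] * self.axes[1] / 4.0


@dataclass(frozen=True)
class Circle:
    center: tuple[float, float]
    radius: float
    material: str = "water"

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2 <= self.radius**2

    def outline(self, n: int = 64) -> np.ndarray:
        t = np.linspace(0, 2 * math.pi, n, endpoint=False)
        return np.stack(
            [self.center[0] + self.radius * np.cos(t), self.center[1] + self.radius * np.sin(t)],
            axis=1,
        )

    def area(self) -> float:
        return math.pi * self.radius**2


@dataclass(frozen=True)
class Rectangle:
    center: tuple[float, float]
    size: tuple[float, float]  # (width, height) cm
    rotation_deg: float = 0.0
    material: str = "water"

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        th = math.radians(self.rotation_deg)
        dx, dy = x - self.center[0], y - self.center[1]
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        return (np.abs(u) <= self.size[0] / 2.0) & (np.abs(v) <= self.size[1] / 2.0)

    def outline(self, n: int = 64) -> np.ndarray:
        w, h = self.size[0] / 2.0, self.size[1] / 2.0
        t = np.linspace(0, 4, n, endpoint=False)
        pts = []
        corners = [(-w, -h), (w, -h), (w, h), (-w, h)]
        for s in t:
            i = int(s) % 4
            f = s - int(s)
            x0, y0 = corners[i]
            x1, y1 = corners[(i + 1) % 4]
            pts.append((x0 + f * (x1 - x0), y0 + f * (y1 - y0)))
        th = math.radians(self.rotation_deg)
        arr = np.asarray(pts)
        x = self.center[0] + arr[:, 0] * math.cos(th) - arr[:, 1] * math.sin(th)
        y = self.center[1] + arr[:, 0] * math.sin(th) + arr[:, 1] * math.cos(th)
        return np.stack([x, y], axis=1)

    def area(self) -> float:
        return self.size[0] * self.size[1]


Shape = Ellipse | Circle | Rectangle


@dataclass(frozen=True)
class PhantomMaterial:
    """Material entry of a phantom: physics model plus optional HU overrides."""

    material: Material
    hu_kv: float | None = None
    hu_mv: float | None = None

    @property
    def density(self) -> float:
        return self.material.density

    def hu(self, energy_label: str) -> float:
        if energy_label == "kV":
            return self.hu_kv if self.hu_kv is not None else self.material.hu(KV_REFERENCE_KEV)
        if energy_label == "MV":
            return self.hu_mv if self.hu_mv is not None else self.material.hu(MV_REFERENCE_KEV)
        raise ValueError("energy_label must be 'kV' or 'MV'")


def _default_materials() -> dict[str, PhantomMaterial]:
    out = {name: PhantomMaterial(mat) for name, mat in MATERIALS.items()}
    # the central pinhole is air by definition of the HU scale
    out["air"] = PhantomMaterial(MATERIALS["air"], hu_kv=-1000.0, hu_mv=-1000.0)
    return out


@dataclass
class PhantomSpec:
    """Ordered analytic shapes inside an outer body boundary.

    Later shapes are drawn on top of earlier ones; the body is drawn first.
    All coordinates and sizes are in cm.
    """

    body: Shape
    shapes: list[Shape] = field(default_factory=list)
    materials: dict[str, PhantomMaterial] = field(default_factory=_default_materials)

    def __post_init__(self) -> None:
        for shape in [self.body, *self.shapes]:
            if shape.material not in self.materials:
                raise GeometryError(f"unknown material {shape.material!r}")
        for shape in self.shapes:
            pts = shape.outline(96)
            if not np.all(self.body.contains(pts[:, 0], pts[:, 1])):
                raise GeometryError(f"shape {shape} extends outside the body boundary")

    def hu_of(self, label: str, energy_label: str) -> float:
        return self.materials[label].hu(energy_label)


def default_phantom() -> PhantomSpec:
    """The verification phantom with the elliptical steel insert.

    Circular 24 cm water body; steel ellipse 4.97 x 3.58 cm (long axis
    horizontal) with a centered 1.81 cm diameter air hole; a bone and an
    adipose rod on the horizontal midline far from the metal and a bone rod
    on the vertical midline, so center-line profiles cross tissue structures
    on both sides of the metal.
    """
    body = Circle(center=(0.0, 0.0), radius=12.0, material="water")
    shapes = [
        Ellipse(center=(0.0, 0.0), axes=(4.97, 3.58), rotation_deg=0.0, material="steel"),
        Circle(center=(0.0, 0.0), radius=1.81 / 2.0, material="air"),
        Circle(center=(8.5, 0.0), radius=1.0, material="bone"),
        Circle(center=(-8.5, 0.0), radius=1.0, material="adipose"),
        Circle(center=(0.0, 8.5), radius=1.0, material="bone"),
        Circle(center=(0.0, -8.5), radius=1.0, material="muscle"),
    ]
    return PhantomSpec(body=body, shapes=shapes)


def calibration_phantom(n_rods: int = 5) -> PhantomSpec:
    """30 cm calibration cylinder with density rods for the HU mapping.

    Rods span lung-like (0.30 g/cm^3) to bone-like (1.60 g/cm^3) density on a
    ring; their kV and MV CT numbers diverge toward the dense end, which is
    what makes the piecewise-linear MV→kV calibration curve non-trivial.
    """
    if n_rods < 2:
        raise GeometryError("need at least 2 rods to define a calibration curve")
    ring_radius = 10.0
    rod_radius = 1.5
    # chord spacing between adjacent rod centers must exceed one diameter
    if n_rods > 2 and 2 * ring_radius * math.sin(math.pi / n_rods) <= 2 * rod_radius:
        raise GeometryError(f"{n_rods} rods of radius {rod_radius} cm overlap on the ring")
    materials = _default_materials()
    shapes = []
    densities = np.linspace(0.30, 1.60, n_rods)
    for i, (d, angle) in enumerate(zip(densities, np.linspace(0, 2 * math.pi, n_rods, endpoint=False))):
        # blend water-like and bone-like mass attenuation as density rises
        t = float(np.clip((d - 1.0) / 0.6, 0.0, 1.0))
        model = AttenuationModel(
            a=(1 - t) * _WATER_MODEL.a + t * _BONE_MODEL.a,
            b=(1 - t) * _WATER_MODEL.b + t * _BONE_MODEL.b,
        )
        name = f"rod{i}"
        materials[name] = PhantomMaterial(Material(name, float(d), model))
        shapes.append(
            Circle(
                center=(ring_radius * math.cos(angle), ring_radius * math.sin(angle)),
                radius=rod_radius,
                material=name,
            )
        )
    body = Circle(center=(0.0, 0.0), radius=15.0, material="water")
    return PhantomSpec(body=body, shapes=shapes, materials=materials)


def _grid_coords_cm(
    grid_shape: tuple[int, int], pixel_spacing_mm: float | tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    if np.isscalar(pixel_spacing_mm):
        spacing = (float(pixel_spacing_mm), float(pixel_spacing_mm))
    else:
        spacing = (float(pixel_spacing_mm[0]), float(pixel_spacing_mm[1]))
    r, c = grid_shape
    y = (np.arange(r) - 0.5 * (r - 1)) * spacing[0] / 10.0  # cm
    x = (np.arange(c) - 0.5 * (c - 1)) * spacing[1] / 10.0
    yy, xx = np.meshgrid(y, x, indexing="ij")
    return xx, yy, spacing


def rasterize_labels(
    spec: PhantomSpec,
    grid_shape: tuple[int, int] = (512, 512),
    pixel_spacing_mm: float | tuple[float, float] = 0.59,
) -> tuple[np.ndarray, list[str | None], tuple[float, float]]:
    """Material-label index map: -1 outside the body, else index into labels."""
    xx, yy, spacing = _grid_coords_cm(grid_shape, pixel_spacing_mm)
    half_fov = (grid_shape[0] * spacing[0] / 20.0, grid_shape[1] * spacing[1] / 20.0)
    pts = spec.body.outline(96)
    if np.any(np.abs(pts[:, 0]) > half_fov[1]) or np.any(np.abs(pts[:, 1]) > half_fov[0]):
        raise GeometryError("phantom body exceeds the requested grid field of view")
    labels: list[str | None] = []
    index = np.full(grid_shape, -1, dtype=int)
    for shape in [spec.body, *spec.shapes]:
        if shape.material not in labels:
            labels.append(shape.material)
        index[shape.contains(xx, yy)] = labels.index(shape.material)
    return index, labels, spacing


def rasterize(
    spec: PhantomSpec,
    grid_shape: tuple[int, int] = (512, 512),
    pixel_spacing_mm: float | tuple[float, float] = 0.59,
    energy_label: str = "kV",
) -> ImageGrid:
    """Ground-truth HU image: topmost shape wins at each pixel center.

    Pixels outside the body are air (−1000 HU). This is the theoretical CT
    image used as the reference for artifact metrics.
    """
    index, labels, spacing = rasterize_labels(spec, grid_shape, pixel_spacing_mm)
    values = np.full(grid_shape, -1000.0)
    for i, label in enumerate(labels):
        values[index == i] = spec.hu_of(label, energy_label)
    return ImageGrid(values=values, pixel_spacing=spacing)
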