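"""X-ray attenuation physics for the scanner simulator.

Each material carries a two-term parametric attenuation model

    mu(E) / rho = a * (E0 / E)^3  +  b * kn(E) / kn(E0)

whose first term mimics the photoelectric cross section (steep ~E^-3 decay,
dominant for steel at diagnostic energies) and whose second follows the
Klein–Nishina total Compton cross section (dominant for tissue and for any
material at megavoltage energies). The coefficients (a, b) are solved from
two (energy, mass-attenuation) anchor points per material, so water comes
out near 0.19 cm^-1 at 70 keV and steel is strongly energy dependent: this
is the minimal physics that produces beam hardening and photon starvation
behind metal without tabulated cross sections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ELECTRON_REST_KEV = 511.0
REFERENCE_KEV = 70.0  # anchor energy for the parametric model


def klein_nishina(energy_kev: np.ndarray | float) -> np.ndarray | float:
    """Total Klein–Nishina cross section per electron (relative units)."""
    a = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_KEV
    term1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log1p(2 * a) / a)
    term2 = np.log1p(2 * a) / (2 * a)
    term3 = -(1 + 3 * a) / (1 + 2 * a) ** 2
    return term1 + term2 + term3


@dataclass(frozen=True)
class AttenuationModel:
    """Mass attenuation mu/rho(E) in cm^2/g from photoelectric + Compton terms."""

    a: float  # photoelectric-like coefficient at E0, cm^2/g
    b: float  # Compton-like coefficient at E0, cm^2/g

    def mass_attenuation(self, energy_kev: np.ndarray | float) -> np.ndarray | float:
        e = np.asarray(energy_kev, dtype=float)
        pe = (REFERENCE_KEV / e) ** 3
        compton = klein_nishina(e) / klein_nishina(REFERENCE_KEV)
        return self.a * pe + self.b * compton

    @classmethod
    def from_anchors(
        cls, p1: tuple[float, float], p2: tuple[float, float]
    ) -> "AttenuationModel":
        """Solve (a, b) so mu/rho matches two (energy keV, cm^2/g) anchors."""
        (e1, m1), (e2, m2) = p1, p2
        kn0 = klein_nishina(REFERENCE_KEV)
        mat = np.array(
            [
                [(REFERENCE_KEV / e1) ** 3, klein_nishina(e1) / kn0],
                [(REFERENCE_KEV / e2) ** 3, klein_nishina(e2) / kn0],
            ]
        )
        a, b = np.linalg.solve(mat, np.array([m1, m2]))
        return cls(a=float(a), b=float(b))


@dataclass(frozen=True)
class Material:
    """A scannable material: density plus its attenuation model."""

    name: str
    density: float  # g/cm^3
    attenuation: AttenuationModel

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"material {self.name!r}: density must be > 0")

    def mu(self, energy_kev: np.ndarray | float) -> np.ndarray | float:
        """Linear attenuation coefficient in 1/cm."""
        return self.density * self.attenuation.mass_attenuation(energy_kev)

    def hu(self, energy_kev: float) -> float:
        """CT number at a given energy relative to water."""
        return float(1000.0 * (self.mu(energy_kev) / WATER.mu(energy_kev) - 1.0))


# Anchor points loosely follow published mass-attenuation values for water
# and iron; tissues reuse the water model at their own density.
_WATER_MODEL = AttenuationModel.from_anchors((70.0, 0.193), (1000.0, 0.0707))
_BONE_MODEL = AttenuationModel.from_anchors((70.0, 0.260), (1000.0, 0.0657))
_STEEL_MODEL = AttenuationModel.from_anchors((70.0, 0.830), (1000.0, 0.0599))

WATER = Material("water", 1.0, _WATER_MODEL)

MATERIALS: dict[str, Material] = {
    "air": Material("air", 1.2e-3, _WATER_MODEL),
    "lung": Material("lung", 0.30, _WATER_MODEL),
    "adipose": Material("adipose", 0.92, _WATER_MODEL),
    "water": WATER,
    "muscle": Material("muscle", 1.05, _WATER_MODEL),
    "bone": Material("bone", 1.60, _BONE_MODEL),
    "steel": Material("steel", 7.8, _STEEL_MODEL),
}

#: HU at or above which a pixel is treated as metal (paper threshold).
METAL_THRESHOLD_HU = 3000.0


@dataclass
class AcquisitionModel:
    """Scanner model for one simulated acquisition.

    mode
        'kV' for a polychromatic diagnostic beam (>= 3 spectrum points) or
        'MV' for a single effective megavoltage energy.
    spectrum
        list of (energy keV, relative fluence); fluences are normalized to 1.
    incident_photons_per_bin
        unattenuated detector counts per bin; lower values increase noise and
        photon starvation behind metal.
    detector_blur_sigma
        Gaussian detector blur (mm) applied along the detector row; models
        the lower spatial resolution of the MV flat panel.
    views, bins
        number of projection angles over 180 deg and detector bins; bins may
        be None to let the projector size the detector to the grid diagonal.
    """

    mode: str
    spectrum: list[tuple[float, float]]
    incident_photons_per_bin: float
    detector_blur_sigma: float = 0.0
    views: int = 180
    bins: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("kV", "MV"):
            raise ValueError("mode must be 'kV' or 'MV'")
        if self.incident_photons_per_bin <= 0:
            raise ValueError("incident_photons_per_bin must be > 0")
        if self.views < 2 or (self.bins is not None and self.bins < 2):
            raise ValueError("need at least 2 views and 2 bins")
        if self.mode == "kV" and len(self.spectrum) < 3:
            raise ValueError("kV mode needs a polychromatic spectrum (>= 3 points)")
        if self.mode == "MV" and len(self.spectrum) != 1:
            raise ValueError("MV mode uses a single effective energy")
        total = sum(w for _, w in self.spectrum)
        if total <= 0:
            raise ValueError("spectrum fluences must have positive sum")
        self.spectrum = [(float(e), float(w) / total) for e, w in self.spectrum]

    @property
    def effective_energy_kev(self) -> float:
        """Fluence-weighted mean energy; the reconstruction reference."""
        return sum(e * w for e, w in self.spectrum)


def default_kv_acquisition(**overrides) -> AcquisitionModel:
    """120 kVp diagnostic scan: polychromatic, high flux, sharp detector."""
    params = dict(
        mode="kV",
        spectrum=[(45.0, 0.25), (60.0, 0.45), (80.0, 0.25), (100.0, 0.05)],
        incident_photons_per_bin=1e5,
        detector_blur_sigma=0.0,
        views=180,
    )
    params.update(overrides)
    return AcquisitionModel(**params)


def default_mv_acquisition(**overrides) -> AcquisitionModel:
    """Megavoltage cone-beam scan: penetrates metal, noisy, blurred detector."""
    params = dict(
        mode="MV",
        spectrum=[(1500.0, 1.0)],
        incident_photons_per_bin=8e3,
        detector_blur_sigma=1.5,
        views=180,
    )
    params.update(overrides)
    return AcquisitionModel(**params)


def hu_to_mu(
    values: np.ndarray,
    energy_kev: float,
    metal_material: Material | None = MATERIALS["steel"],
    metal_threshold: float = METAL_THRESHOLD_HU,
) -> np.ndarray:
    """Convert an HU array to linear attenuation (1/cm) at one energy.

    Non-metal pixels use the water-equivalent scaling
    mu = mu_water(E) * (1 + HU/1000). Pixels at or above the metal threshold
    use the metal material's model, scaled by their HU relative to the
    metal's nominal kV CT number, so metal keeps its strong energy dependence
    (kV mu >> MV mu). Negative results are clipped to zero.
    """
    if energy_kev <= 0:
        raise ValueError("energy must be > 0")
    values = np.asarray(values, dtype=float)
    mu = WATER.mu(energy_kev) * (1.0 + values / 1000.0)
    if metal_material is not None:
        metal = values >= metal_threshold
        if np.any(metal):
            nominal_hu = metal_material.hu(REFERENCE_KEV)
            scale = values[metal] / nominal_hu
            mu[metal] = metal_material.mu(energy_kev) * scale
    return np.clip(mu, 0.0, None)
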