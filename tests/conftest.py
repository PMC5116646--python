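"""Shared fixtures: one seeded simulated study reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import mvkvmar as m

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

STUDY_SEED = 1
STUDY_GRID = 256
STUDY_SPACING_MM = 1.18  # 30.2 cm field of view, as in the 512 x 0.59 mm scans


def study_config(seed: int = STUDY_SEED, grid: int = STUDY_GRID) -> m.PipelineConfig:
    cfg = m.PipelineConfig()
    cfg.simulator.seed = seed
    cfg.simulator.grid_size = grid
    cfg.simulator.pixel_spacing_mm = STUDY_SPACING_MM * STUDY_GRID / grid
    return cfg


@pytest.fixture(scope="session")
def phantom_spec() -> m.PhantomSpec:
    return m.default_phantom()


@pytest.fixture(scope="session")
def study() -> m.SimulatedStudy:
    """The seeded 256^2 phantom experiment used by the acceptance checks."""
    return m.simulate_study(study_config())


@pytest.fixture(scope="session")
def calibration_curve() -> m.CalibrationCurve:
    return m.fit_calibration_from_simulation(study_config())


@pytest.fixture(scope="session")
def regions(study) -> dict[str, np.ndarray]:
    return {r.label: r.mask for r in m.standard_regions(study.spec, study.truth)}


@pytest.fixture(scope="session")
def fusion_corrected(study, calibration_curve) -> m.MARResult:
    return m.mar_correct(
        study.kv, study.mv, sino_kv=study.sino_kv, calibration=calibration_curve
    )


@pytest.fixture(scope="session")
def small_image() -> m.ImageGrid:
    """Small smooth image for registration / resampling tests."""
    from scipy.ndimage import gaussian_filter

    spec = m.default_phantom()
    img = m.rasterize(spec, (128, 128), 2.36, "kV")
    smooth = gaussian_filter(np.clip(img.values, -1000, 2000), 2.0)
    return img.with_values(smooth)


# ------------------------------------------------------------------ oracle

def brute_force_replace(
    p_kv: np.ndarray, p_prior: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Independent scalar reimplementation of trace replacement.

    Walks every view bin-by-bin, finds maximal runs of masked bins, and
    applies the surrogate-plus-boundary-blend formula one bin at a time.
    Kept deliberately loop-based so it shares no code with the package.
    """
    m_views, n_bins = p_kv.shape
    out = p_kv.copy()
    for a in range(m_views):
        b = 0
        while b < n_bins:
            if not mask[a, b]:
                b += 1
                continue
            start = b
            while b < n_bins and mask[a, b]:
                b += 1
            stop = b - 1
            jj, right = start - 1, stop + 1
            d = stop - start + 1
            for bb in range(start, stop + 1):
                if jj >= 0 and right < n_bins:
                    blend = (
                        (right - bb) * (p_kv[a, jj] - p_prior[a, jj])
                        + (bb - jj) * (p_kv[a, right] - p_prior[a, right])
                    ) / (d + 1)
                elif right < n_bins:
                    blend = p_kv[a, right] - p_prior[a, right]
                elif jj >= 0:
                    blend = p_kv[a, jj] - p_prior[a, jj]
                else:
                    blend = 0.0
                out[a, bb] = p_prior[a, bb] + blend
    return out


def random_sinogram_case(rng: np.random.Generator):
    """One random small (values, prior, mask) triple for the oracle tests."""
    m_views = int(rng.integers(2, 17))
    n_bins = int(rng.integers(4, 17))
    p_kv = rng.normal(0, 5, size=(m_views, n_bins))
    p_prior = rng.normal(0, 5, size=(m_views, n_bins))
    mask = rng.random((m_views, n_bins)) < 0.3
    return p_kv, p_prior, mask


def as_sinogram(values: np.ndarray) -> "m.Sinogram":
    """Wrap a hand-built (views x bins) array in a Sinogram for the tests."""
    values = np.asarray(values, dtype=float)
    geom = m.ProjectionGeometry(
        angles_deg=np.linspace(0, 180, values.shape[0], endpoint=False),
        detector_spacing_mm=1.0,
        image_shape=(max(2, int(np.ceil(values.shape[1] / np.sqrt(2)))),) * 2,
    )
    return m.Sinogram(values=values, geometry=geom)
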