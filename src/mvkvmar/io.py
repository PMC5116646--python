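"""File formats: DICOM CT slices and portable array fixtures.

Images travel either as single-slice DICOM CT files (HU recovered through
RescaleSlope/RescaleIntercept on read; written as 16-bit signed pixels so
the extended metal HU range survives) or as compressed ``.npz`` fixtures
with a JSON metadata sidecar, which also carry sinograms and weight maps.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .grid import ImageGrid
from .projection import ProjectionGeometry, Sinogram


# ---------------------------------------------------------------- fixtures

def save_image_fixture(path: str | Path, image: ImageGrid) -> None:
    path = Path(path)
    np.savez_compressed(path, values=image.values)
    meta = {
        "kind": "image",
        "pixel_spacing_mm": list(image.pixel_spacing),
        "origin_mm": list(image.origin),
        "bit_depth_range": list(image.bit_depth_range),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_image_fixture(path: str | Path) -> ImageGrid:
    path = Path(path)
    values = np.load(path)["values"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return ImageGrid(
        values=values,
        pixel_spacing=tuple(meta["pixel_spacing_mm"]),
        origin=tuple(meta["origin_mm"]),
        bit_depth_range=tuple(meta["bit_depth_range"]),
    )


def save_sinogram_fixture(path: str | Path, sino: Sinogram) -> None:
    path = Path(path)
    np.savez_compressed(path, values=sino.values, angles_deg=sino.geometry.angles_deg)
    meta = {
        "kind": "sinogram",
        "detector_spacing_mm": sino.geometry.detector_spacing_mm,
        "image_shape": list(sino.geometry.image_shape),
        "mu_water_ref": sino.geometry.mu_water_ref,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_sinogram_fixture(path: str | Path) -> Sinogram:
    path = Path(path)
    data = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    geometry = ProjectionGeometry(
        angles_deg=data["angles_deg"],
        detector_spacing_mm=meta["detector_spacing_mm"],
        image_shape=tuple(meta["image_shape"]),
        mu_water_ref=meta["mu_water_ref"],
    )
    return Sinogram(values=data["values"], geometry=geometry)


# ------------------------------------------------------------------ DICOM

def save_dicom(path: str | Path, image: ImageGrid) -> None:
    """Write one CT slice as 16-bit signed DICOM with identity rescale."""
    values = np.clip(np.rint(image.values), -32768, 32767).astype(np.int16)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = image.shape
    ds.PixelSpacing = [str(image.pixel_spacing[0]), str(image.pixel_spacing[1])]
    ds.ImagePositionPatient = [str(image.origin[1]), str(image.origin[0]), "0"]
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = "0"
    ds.PixelData = values.tobytes()
    ds.save_as(Path(path), enforce_file_format=True)


def load_dicom(path: str | Path) -> ImageGrid:
    """Read one CT slice, applying RescaleSlope/RescaleIntercept."""
    ds = pydicom.dcmread(Path(path))
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    values = ds.pixel_array.astype(float) * slope + intercept
    spacing = tuple(float(s) for s in getattr(ds, "PixelSpacing", [1.0, 1.0]))
    pos = getattr(ds, "ImagePositionPatient", None)
    origin = (float(pos[1]), float(pos[0])) if pos is not None else None
    return ImageGrid(values=values, pixel_spacing=spacing, origin=origin)


def load_image(path: str | Path) -> ImageGrid:
    """Dispatch on extension: .dcm → DICOM, .npz → fixture."""
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        return load_dicom(path)
    if path.suffix.lower() == ".npz":
        return load_image_fixture(path)
    raise ValueError(f"unsupported image format: {path.suffix!r} ({path})")
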