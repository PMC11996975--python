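"""Reading and writing image stacks: DICOM series and a raw container.

The raw container (``.npy`` voxels + JSON sidecar with spacings) is
lossless and round-trips bit-identically; the DICOM writer quantizes HU
to signed 16-bit integers with an identity rescale, as scanners do.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .phantom import ImageStack

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# Raw container
# ---------------------------------------------------------------------------

def write_raw(stack: ImageStack, path: PathLike) -> None:
    """Write ``<path>.npy`` (float64 voxels) and ``<path>.json`` (spacings)."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), stack.voxels)
    sidecar = {
        "pixel_spacing_mm": list(stack.pixel_spacing_mm),
        "slice_spacing_mm": stack.slice_spacing_mm,
        "nominal_slice_thickness_mm": stack.nominal_slice_thickness_mm,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_raw(path: PathLike) -> ImageStack:
    path = Path(path)
    voxels = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return ImageStack(voxels, tuple(meta["pixel_spacing_mm"]),
                      meta["slice_spacing_mm"],
                      meta.get("nominal_slice_thickness_mm", 1.0))


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def write_dicom_series(stack: ImageStack, directory: PathLike) -> None:
    """Write one CT Image Storage file per slice (int16 HU, rescale 1/0)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    dx, dy = stack.pixel_spacing_mm
    for k in range(stack.n_slices):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = CTImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, round(k * stack.slice_spacing_mm, 6)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [dy, dx]
        ds.SliceThickness = stack.nominal_slice_thickness_mm
        ds.SpacingBetweenSlices = stack.slice_spacing_mm
        ds.Rows, ds.Columns = stack.shape_yx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.PixelData = np.rint(stack.voxels[k]).astype(np.int16).tobytes()
        ds.save_as(directory / f"slice_{k:04d}.dcm", enforce_file_format=True)


def read_dicom_series(directory: PathLike) -> ImageStack:
    """Read a CT series, sort by z, apply HU rescale, validate spacing."""
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise ValueError(f"no DICOM files found in {directory}")
    datasets = [pydicom.dcmread(f) for f in files]
    for ds, f in zip(datasets, files):
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError(f"{f.name}: missing HU rescale tags")
    datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    spacings = {tuple(float(v) for v in d.PixelSpacing) for d in datasets}
    if len(spacings) > 1:
        raise ValueError(f"mixed in-plane pixel spacing in series: {spacings}")
    dyx = next(iter(spacings))
    z = np.array([float(d.ImagePositionPatient[2]) for d in datasets])
    if len(z) > 1:
        gaps = np.diff(z)
        dz = float(np.median(gaps))
        bad = np.flatnonzero(np.abs(gaps - dz) > 1e-3 * max(dz, 1e-6))
        if bad.size:
            raise ValueError(
                f"non-uniform slice spacing: gap of {gaps[bad[0]]:.4g} mm "
                f"between z = {z[bad[0]]:.4g} and {z[bad[0] + 1]:.4g} mm "
                f"(expected {dz:.4g} mm)")
    else:
        dz = float(datasets[0].get("SpacingBetweenSlices",
                                   datasets[0].get("SliceThickness", 1.0)))
    voxels = np.stack([
        d.pixel_array.astype(float) * float(d.RescaleSlope) + float(d.RescaleIntercept)
        for d in datasets])
    return ImageStack(voxels, (dyx[1], dyx[0]), dz,
                      float(datasets[0].get("SliceThickness", dz)))
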