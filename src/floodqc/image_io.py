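"""Read and write flood-field images as DICOM NM files or plain CSV matrices.

A flood-field image is the raw input of every uniformity analysis: a 2-D
count matrix acquired by irradiating the uncollimated detector with a distant
point source. DICOM is the interchange format used by scanners and QC tools;
the CSV dialect is a human-diffable fixture format that also holds real-valued
(smoothed) matrices, which DICOM deliberately refuses.

Conventions: row index = image row (y), column index = x, 0-based throughout.
``total_counts`` is always recomputed from the pixel data, never trusted from
file metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import FormatError, MetadataError

__all__ = [
    "FloodImage",
    "read_flood_dicom",
    "write_flood_dicom",
    "read_counts_csv",
    "write_counts_csv",
]

_NM_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.20"


@dataclass
class FloodImage:
    """A 2-D count matrix with pixel spacing and acquisition metadata.

    Parameters
    ----------
    counts
        Non-negative 2-D array. Raw acquisitions are integer-valued; smoothed
        images are real-valued.
    pixel_spacing_mm
        (row, column) pixel spacing in millimetres, both strictly positive.
    detector_id
        Free-text detector label (e.g. "D1").
    meta
        Free-form key/value metadata (provenance, simulation parameters...).

    ``total_counts`` is derived from ``counts`` on construction.
    """

    counts: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    detector_id: str = ""
    meta: dict[str, Any] = field(default_factory=dict)
    total_counts: float = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2:
            raise FormatError(f"counts must be 2-D, got shape {counts.shape}")
        if not np.isfinite(counts).all():
            raise FormatError("counts contain non-finite values")
        if (counts < 0).any():
            raise FormatError("counts contain negative values")
        r, c = (float(x) for x in self.pixel_spacing_mm)
        if r <= 0 or c <= 0:
            raise MetadataError(f"pixel_spacing_mm must be positive, got ({r}, {c})")
        self.counts = counts
        self.pixel_spacing_mm = (r, c)
        self.total_counts = float(counts.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def write_flood_dicom(img: FloodImage, path: str | Path) -> Path:
    """Write a raw (integer-valued) flood image as a single-frame DICOM NM file.

    Counts must be exactly integral and representable as unsigned 16- or
    32-bit integers; smoothed (real-valued) images are refused — use
    :func:`write_counts_csv` for those.
    """
    path = Path(path)
    arr = img.counts
    if not np.array_equal(arr, np.floor(arr)):
        raise FormatError(
            "counts are not integral; DICOM export is restricted to raw count "
            "matrices (write smoothed images as CSV)"
        )
    vmax = arr.max(initial=0.0)
    if vmax < 2**16:
        pixel = arr.astype(np.uint16)
        bits = 16
    elif vmax < 2**32:
        pixel = arr.astype(np.uint32)
        bits = 32
    else:
        raise FormatError(f"max count {vmax} exceeds 32-bit unsigned range")

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = _NM_IMAGE_STORAGE
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = _NM_IMAGE_STORAGE
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "NM"
    ds.StationName = img.detector_id[:16]
    ds.Rows, ds.Columns = pixel.shape
    ds.PixelSpacing = [f"{img.pixel_spacing_mm[0]:.6f}", f"{img.pixel_spacing_mm[1]:.6f}"]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = bits
    ds.BitsStored = bits
    ds.HighBit = bits - 1
    ds.PixelRepresentation = 0
    ds.PixelData = pixel.tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def read_flood_dicom(path: str | Path) -> FloodImage:
    """Read a single-frame DICOM image into a :class:`FloodImage`.

    Accepts any single-frame image carrying pixel data and a pixel-spacing
    attribute (``PixelSpacing``, falling back to ``ImagerPixelSpacing``, as
    both occur in vendor NM exports). Rescale slope/intercept are applied if
    present; ``total_counts`` is recomputed from the pixels.
    """
    path = Path(path)
    ds = pydicom.dcmread(path)
    if "PixelData" not in ds:
        raise FormatError(f"{path}: no PixelData element")
    arr = np.asarray(ds.pixel_array, dtype=float)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-frame 2-D image, got shape {arr.shape}")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    if slope != 1.0 or intercept != 0.0:
        arr = arr * slope + intercept

    spacing = getattr(ds, "PixelSpacing", None)
    attr = "PixelSpacing"
    if spacing is None:
        spacing = getattr(ds, "ImagerPixelSpacing", None)
        attr = "ImagerPixelSpacing"
    if spacing is None:
        raise MetadataError(
            f"{path}: neither PixelSpacing nor ImagerPixelSpacing is present"
        )
    r, c = (float(s) for s in spacing)
    if r <= 0 or c <= 0:
        raise MetadataError(f"{path}: {attr} has non-positive component ({r}, {c})")
    return FloodImage(
        counts=arr,
        pixel_spacing_mm=(r, c),
        detector_id=str(getattr(ds, "StationName", "")),
        meta={"source": str(path), "format": "dicom"},
    )


def write_counts_csv(img: FloodImage, path: str | Path) -> Path:
    """Write a flood image as a comma-separated matrix with a spacing header.

    The dialect: "#" starts a comment; the header line
    ``## spacing_mm=<row>,<col>`` carries the pixel spacing; values are
    printed at 17 significant digits so real-valued (smoothed) matrices
    round-trip losslessly.
    """
    path = Path(path)
    r, c = img.pixel_spacing_mm
    with open(path, "w") as fh:
        fh.write(f"## spacing_mm={r:.17g},{c:.17g}\n")
        if img.detector_id:
            fh.write(f"## detector_id={img.detector_id}\n")
        np.savetxt(fh, img.counts, delimiter=",", fmt="%.17g")
    return path


def read_counts_csv(path: str | Path) -> FloodImage:
    """Read the CSV fixture dialect written by :func:`write_counts_csv`."""
    path = Path(path)
    spacing: tuple[float, float] | None = None
    detector_id = ""
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("spacing_mm="):
                    parts = body.removeprefix("spacing_mm=").split(",")
                    if len(parts) != 2:
                        raise FormatError(f"{path}:{lineno}: malformed spacing header")
                    spacing = (float(parts[0]), float(parts[1]))
                elif body.startswith("detector_id="):
                    detector_id = body.removeprefix("detector_id=")
                continue
            try:
                rows.append([float(tok) for tok in line.split(",")])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric entry ({exc})") from exc
    if not rows:
        raise FormatError(f"{path}: no data rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    if spacing is None:
        raise MetadataError(f"{path}: missing '## spacing_mm=<r>,<c>' header")
    return FloodImage(
        counts=np.array(rows, dtype=float),
        pixel_spacing_mm=spacing,
        detector_id=detector_id,
        meta={"source": str(path), "format": "csv"},
    )
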