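"""Reading/writing CT slices (DICOM) and masks (PNG), and the dataset split.

On-disk conventions: masks are 8-bit grayscale PNG with foreground 255 and
background 0 (any nonzero pixel reads back as 1); CT slices are single-frame
DICOM with stored uint16 pixels and RescaleSlope/RescaleIntercept metadata
(HU = stored * slope + intercept).  Coordinates are row-major, origin
top-left, 0-based.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "CTSlice",
    "DatasetSplit",
    "read_dicom_slice",
    "write_dicom_slice",
    "read_mask_png",
    "write_mask_png",
    "split_dataset",
]


@dataclass
class CTSlice:
    stored_pixels: np.ndarray        # 2-D integer array
    rescale_slope: float
    rescale_intercept: float
    pixel_spacing: tuple[float, float]  # mm (row, col)
    slice_thickness: float              # mm
    case_id: str

    @property
    def hu(self) -> np.ndarray:
        return self.stored_pixels * self.rescale_slope + self.rescale_intercept


@dataclass
class DatasetSplit:
    train: list[str]
    validation: list[str]
    test: list[str]


def _det_uid(tag: str) -> str:
    """Deterministic UID from a string tag, so identical writes are byte-identical."""
    h = int(hashlib.sha256(tag.encode()).hexdigest()[:30], 16)
    return f"1.2.826.0.1.3680043.8.498.{h % 10**30}"


def write_dicom_slice(hu_image: np.ndarray, path, case_id: str = "case",
                      pixel_spacing=(1.0, 1.0), slice_thickness: float = 5.0,
                      rescale_intercept: float = -1024.0) -> None:
    """Write an HU-valued image as a single-frame CT DICOM.

    Stored pixels are uint16 with slope 1: stored = round(HU - intercept),
    clipped to [0, 65535].  All UIDs/dates are derived deterministically from
    `case_id` so repeated writes are reproducible.
    """
    stored = np.clip(np.round(np.asarray(hu_image, dtype=np.float64)
                              - rescale_intercept), 0, 65535).astype(np.uint16)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = _det_uid(f"{case_id}/sop")
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = _det_uid(f"{case_id}/series")
    ds.StudyInstanceUID = _det_uid(f"{case_id}/study")
    ds.Modality = "CT"
    ds.PatientID = case_id
    ds.PatientName = case_id
    ds.Rows, ds.Columns = stored.shape
    ds.PixelSpacing = [f"{pixel_spacing[0]:g}", f"{pixel_spacing[1]:g}"]
    ds.SliceThickness = f"{slice_thickness:g}"
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = f"{rescale_intercept:g}"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_dicom_slice(path) -> CTSlice:
    """Read a single-frame CT DICOM into a CTSlice.

    Missing rescale tags default to slope 1 / intercept 0 with a logged
    warning; unreadable files raise ValueError naming the path.
    """
    try:
        ds = pydicom.dcmread(str(path))
        pixels = ds.pixel_array
    except Exception as exc:
        raise ValueError(f"cannot read DICOM slice from {path}: {exc}") from exc
    if pixels.ndim != 2:
        raise ValueError(f"{path}: expected a single-frame 2-D image, "
                         f"got shape {pixels.shape}")
    slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
    if not hasattr(ds, "RescaleSlope"):
        logger.warning("%s: missing RescaleSlope, defaulting to 1", path)
    intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
    if not hasattr(ds, "RescaleIntercept"):
        logger.warning("%s: missing RescaleIntercept, defaulting to 0", path)
    spacing = getattr(ds, "PixelSpacing", [1.0, 1.0])
    thickness = float(getattr(ds, "SliceThickness", 1.0) or 1.0)
    case_id = str(getattr(ds, "PatientID", "") or Path(path).stem)
    return CTSlice(pixels, slope, intercept,
                   (float(spacing[0]), float(spacing[1])), thickness, case_id)


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a binary mask as 8-bit grayscale PNG (foreground 255)."""
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask must be binary {0,1}")
    Image.fromarray((m.astype(np.uint8) * 255)).save(str(path), format="PNG")


def read_mask_png(path) -> np.ndarray:
    """Read a PNG mask; any pixel > 0 maps to 1. RGB input is converted via
    luminance (with a warning) before thresholding."""
    img = Image.open(str(path))
    if img.mode not in ("L", "I", "I;16", "1"):
        logger.warning("%s: non-grayscale mask (%s), converting via luminance",
                       path, img.mode)
        img = img.convert("L")
    arr = np.asarray(img)
    return (arr > 0).astype(np.uint8)


def split_dataset(case_ids: list[str], ratios=(6, 1, 1), seed: int = 0) -> DatasetSplit:
    """Shuffle case ids and partition by `ratios` with largest-remainder rounding.

    The split is by case, so all slices belonging to a case stay together.
    Each partition receives at least its floor share; 80 cases at (6,1,1)
    yield exactly 60/10/10.
    """
    n = len(case_ids)
    if n < len(ratios):
        raise ValueError(f"need at least {len(ratios)} cases, got {n}")
    rng = np.random.default_rng(seed)
    order = [case_ids[i] for i in rng.permutation(n)]
    total = sum(ratios)
    quotas = [n * r / total for r in ratios]
    sizes = [math.floor(q) for q in quotas]
    remainders = sorted(range(len(ratios)), key=lambda i: quotas[i] - sizes[i],
                        reverse=True)
    for i in remainders[: n - sum(sizes)]:
        sizes[i] += 1
    a, b = sizes[0], sizes[0] + sizes[1]
    return DatasetSplit(order[:a], order[a:b], order[b:])
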