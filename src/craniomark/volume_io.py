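"""DICOM series ingestion and voxel-stack preprocessing.

Axial CT slices are read as raw stored values (no rescale slope/intercept
is applied — bone segmentation thresholds the stored integers directly).
Slices are ordered caudal-first, a calibration cross can be burnt into the
most caudal slice as a fiducial, and fixed-shape {0,1} stacks are built by
area-compressing then thresholding each slice and stacking bottom-up into
a zero template.

Array conventions
-----------------
A slice pixel array is indexed ``[row, col]`` = ``[y, x]``; a voxel stack
is indexed ``[y, x, z]`` with z = 0 the most caudal slice.  Landmark
coordinates are ``(x, y, z)`` in pixel units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .config import PipelineConfig
from .errors import CapacityError, FormatError, InputError, ParameterError

# acquisition-protocol constants: 512 px span 500 mm
IN_PLANE_MM = 500.0 / 512.0
SLICE_MM = 5.0


@dataclass
class RawSlice:
    """One axial CT slice of raw stored values."""

    pixels: np.ndarray  # (rows, cols) non-negative integers
    slice_position: float  # physical z in mm
    order_index: int  # position in the caudal->cranial sequence

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise FormatError(f"slice must be square 2D, got shape {self.pixels.shape}")
        if np.any(self.pixels < 0):
            raise FormatError("stored CT values must be non-negative")


@dataclass
class CaseVolume:
    """Ordered caudal->cranial stack of raw slices with physical spacing."""

    case_id: str
    slices: list[RawSlice]
    in_plane_spacing_mm: float = IN_PLANE_MM
    slice_interval_mm: float = SLICE_MM

    def __post_init__(self) -> None:
        if not self.slices:
            raise InputError("a case needs at least one slice")
        shapes = {s.pixels.shape for s in self.slices}
        if len(shapes) != 1:
            raise FormatError(f"inconsistent slice dimensions: {sorted(shapes)}")
        idx = [s.order_index for s in self.slices]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise FormatError("order_index must increase cranially")

    @property
    def image_size(self) -> int:
        return self.slices[0].pixels.shape[0]

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def z_step_px(self) -> float:
        return self.slice_interval_mm / self.in_plane_spacing_mm

    def pixel_array(self) -> np.ndarray:
        """All slices as one (rows, cols, z) array, z caudal-first."""
        return np.stack([s.pixels for s in self.slices], axis=-1)


@dataclass
class BinaryStack:
    """Fixed-shape {0,1} voxel array — a network input.

    ``window`` records the crop placement tying local to global
    coordinates; ``None`` marks a whole-volume (phase 1) stack.
    ``scale`` is the in-plane compression factor relative to the original
    frame (1.0 for crops, e.g. 96/512 for the compressed phase-1 stack).
    """

    voxels: np.ndarray  # (rows, cols, depth) of {0,1}
    window: Optional["CropWindow"] = None  # noqa: F821 - defined in cropper
    scale: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if not np.isin(v, (0, 1)).all():
            raise FormatError("binary stack must contain only {0,1}")
        self.voxels = v


# ----------------------------------------------------------------------
# DICOM reading / writing


def load_series(directory: str | Path) -> CaseVolume:
    """Read a directory of axial DICOM slices into a caudal-first volume.

    Slices are sorted by physical slice position (ImagePositionPatient z,
    falling back to SliceLocation), ascending, so index 0 is the most
    caudal; ties are broken by instance number.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise InputError(f"no parseable DICOM files in {directory}")

    def zpos(ds) -> float:
        if getattr(ds, "ImagePositionPatient", None) is not None:
            return float(ds.ImagePositionPatient[2])
        if getattr(ds, "SliceLocation", None) is not None:
            return float(ds.SliceLocation)
        raise FormatError("slice lacks a position tag (ImagePositionPatient/SliceLocation)")

    datasets.sort(key=lambda ds: (zpos(ds), int(getattr(ds, "InstanceNumber", 0))))

    spacing = getattr(datasets[0], "PixelSpacing", None)
    if spacing is None:
        raise FormatError("missing PixelSpacing tag")
    in_plane = float(spacing[0])

    z0, z1 = zpos(datasets[0]), zpos(datasets[-1])
    interval = (z1 - z0) / (len(datasets) - 1) if len(datasets) > 1 else SLICE_MM

    shape0 = (int(datasets[0].Rows), int(datasets[0].Columns))
    slices = []
    for i, ds in enumerate(datasets):
        if (int(ds.Rows), int(ds.Columns)) != shape0:
            raise FormatError(
                f"inconsistent slice dimensions: {(int(ds.Rows), int(ds.Columns))} vs {shape0}"
            )
        slices.append(RawSlice(ds.pixel_array.astype(np.int32), zpos(ds), i))
    return CaseVolume(
        case_id=directory.name,
        slices=slices,
        in_plane_spacing_mm=in_plane,
        slice_interval_mm=abs(interval) if len(datasets) > 1 else SLICE_MM,
    )


def write_series(volume: CaseVolume, directory: str | Path) -> list[Path]:
    """Write a volume as a minimal valid DICOM slice series."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid(entropy_srcs=[volume.case_id])
    paths = []
    for s in volume.slices:
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(
            entropy_srcs=[volume.case_id, str(s.order_index)]
        )
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.PatientID = volume.case_id
        ds.InstanceNumber = s.order_index + 1
        ds.Rows, ds.Columns = s.pixels.shape
        ds.PixelSpacing = [volume.in_plane_spacing_mm, volume.in_plane_spacing_mm]
        ds.SliceThickness = volume.slice_interval_mm
        ds.ImagePositionPatient = [0.0, 0.0, float(s.slice_position)]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = s.pixels.astype(np.uint16).tobytes()
        path = directory / f"{volume.case_id}_{s.order_index:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


# ----------------------------------------------------------------------
# preprocessing


def add_calibration_cross(
    volume: CaseVolume, value: int = 4000, index: int = 255
) -> CaseVolume:
    """Burn a fiducial cross into the most caudal slice.

    Every pixel in row ``index`` and column ``index`` of slice 0 is set to
    ``value``; all other slices are untouched.  Returns a new volume.
    """
    caudal = volume.slices[0]
    if caudal.pixels.shape[0] <= index or caudal.pixels.shape[1] <= index:
        raise IndexError(
            f"slice of shape {caudal.pixels.shape} has no row/column {index}"
        )
    pixels = caudal.pixels.copy()
    pixels[index, :] = value
    pixels[:, index] = value
    new_slices = [dataclasses.replace(caudal, pixels=pixels)] + [
        dataclasses.replace(s) for s in volume.slices[1:]
    ]
    return dataclasses.replace(volume, slices=new_slices)


def binarize(image: np.ndarray, threshold: int = 1100) -> np.ndarray:
    """Segment bone: 1 where stored value >= threshold, else 0 (uint8)."""
    return (np.asarray(image) >= threshold).astype(np.uint8)


def _area_resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) row-stochastic matrix of cell-overlap weights.

    Output cell i covers the interval [i*r, (i+1)*r) with r = n_in/n_out;
    its value is the overlap-weighted mean of the input cells it spans.
    """
    r = n_in / n_out
    w = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo, hi = i * r, (i + 1) * r
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, n_in)):
            w[i, j] = min(hi, j + 1) - max(lo, j)
    return w / r


def compress_slice(image: np.ndarray, target_size: int = 96) -> np.ndarray:
    """Area-weighted (box) resampling of a square slice.

    Exactly preserves constants and is the identity when sizes match.
    """
    if target_size <= 0:
        raise ParameterError("target_size must be positive")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise FormatError(f"expected a square 2D image, got {image.shape}")
    n = image.shape[0]
    if n == target_size:
        return image.copy()
    a = _area_resize_matrix(n, target_size)
    return a @ image @ a.T


def build_phase1_stack(
    volume: CaseVolume,
    width: int = 96,
    depth: int = 81,
    threshold: int = 1100,
) -> BinaryStack:
    """Compress, binarize and stack all slices bottom-up into a zero template.

    Slice i (caudal-first) occupies depth index i; depth indices beyond
    the slice count stay zero.
    """
    if volume.n_slices > depth:
        raise CapacityError(
            f"case has {volume.n_slices} slices but the template depth is {depth}"
        )
    voxels = np.zeros((width, width, depth), dtype=np.uint8)
    for i, s in enumerate(volume.slices):
        voxels[:, :, i] = binarize(compress_slice(s.pixels, width), threshold)
    return BinaryStack(voxels=voxels, window=None, scale=width / volume.image_size)


# ----------------------------------------------------------------------
# unit conversions (pixel units; 1 px = 500/512 mm at full scale)


def px_to_mm(value, in_plane_mm: float = IN_PLANE_MM):
    """Pixels -> millimetres."""
    return np.asarray(value, dtype=np.float64) * in_plane_mm


def mm_to_px(value, in_plane_mm: float = IN_PLANE_MM):
    """Millimetres -> pixels (exact inverse of :func:`px_to_mm`)."""
    return np.asarray(value, dtype=np.float64) / in_plane_mm


def slice_to_zpx(index, slice_mm: float = SLICE_MM, in_plane_mm: float = IN_PLANE_MM):
    """Slice index -> z coordinate in pixel units (slices sit 5.12 px apart)."""
    return np.asarray(index, dtype=np.float64) * slice_mm / in_plane_mm


def stack_from_config(volume: CaseVolume, config: PipelineConfig) -> BinaryStack:
    """Phase-1 stack per the pipeline configuration."""
    return build_phase1_stack(
        volume, width=config.phase1_size, depth=config.depth, threshold=config.threshold
    )
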