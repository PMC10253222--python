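"""Crop-window algebra, shift-grid augmentation, and coordinate remapping.

Refinement phases operate on fixed-width windows cropped from the
original-resolution slices, binarized and stacked over the full z extent.
The window origin (the global (x, y) of the crop's corner) is recorded so
local predictions remap exactly to the global frame:

    global = origin + local          (x and y; z is always global)

Training data are augmented on a half-open Cartesian shift lattice
[-max_shift, +max_shift) stepped by ``step`` in both axes; the regression
target moves opposite to the shift, so an unshifted crop of width w has
target (w/2, w/2, z).  The half-open convention gives (2*max_shift/step)^2
offsets per case — 36 for both the (30, 10) and (15, 5) grids, hence
90 x 36 = 3240 examples per landmark at full scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .errors import InputError, ParameterError
from .landmarks import LandmarkTable, code_index
from .volume_io import BinaryStack, CaseVolume, binarize


@dataclass(frozen=True)
class CropWindow:
    """Integer placement of a crop in the original pixel frame."""

    origin: tuple[int, int]  # (x0, y0) global px; may be negative
    width: int
    depth: int

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ParameterError("window width must be positive")


@dataclass(frozen=True)
class ShiftGrid:
    """Half-open Cartesian lattice of (dx, dy) augmentation offsets."""

    max_shift: int
    step: int
    offsets: tuple[tuple[int, int], ...] = field(default=(), compare=False)

    def __len__(self) -> int:
        return len(self.offsets)


def make_shift_grid(max_shift: int, step: int) -> ShiftGrid:
    """Offsets [-max_shift, +max_shift) x same, stepped by ``step``."""
    if step <= 0:
        raise ParameterError("step must be positive")
    if max_shift % step != 0:
        raise ParameterError(f"max_shift {max_shift} is not divisible by step {step}")
    axis = range(-max_shift, max_shift, step)
    offsets = tuple((dx, dy) for dx in axis for dy in axis)
    return ShiftGrid(max_shift=max_shift, step=step, offsets=offsets)


def _binary_volume(volume: CaseVolume, threshold: int) -> np.ndarray:
    """(rows, cols, z) uint8 bone mask at original resolution."""
    return binarize(volume.pixel_array(), threshold)


def _crop_from_binary(
    bone: np.ndarray, origin: tuple[int, int], width: int, depth: int
) -> np.ndarray:
    """Zero-padded window [y0:y0+w, x0:x0+w] padded to ``depth`` slices."""
    h, w_img, nz = bone.shape
    x0, y0 = origin
    out = np.zeros((width, width, depth), dtype=np.uint8)
    ys0, ys1 = max(y0, 0), min(y0 + width, h)
    xs0, xs1 = max(x0, 0), min(x0 + width, w_img)
    if ys0 < ys1 and xs0 < xs1:
        out[ys0 - y0 : ys1 - y0, xs0 - x0 : xs1 - x0, : min(nz, depth)] = bone[
            ys0:ys1, xs0:xs1, : min(nz, depth)
        ]
    return out


def window_for_center(center: tuple[float, float], width: int, depth: int) -> CropWindow:
    """Window whose origin is round(center) - width/2 on each axis."""
    if width % 2:
        raise ParameterError("crop width must be even")
    cx, cy = center
    if not (np.isfinite(cx) and np.isfinite(cy)):
        raise InputError("crop center must be finite")
    origin = (int(round(cx)) - width // 2, int(round(cy)) - width // 2)
    return CropWindow(origin=origin, width=width, depth=depth)


def crop_stack(
    volume: CaseVolume,
    center: tuple[float, float],
    width: int,
    depth: int = 81,
    threshold: int = 1100,
    _bone: np.ndarray | None = None,
) -> tuple[BinaryStack, CropWindow]:
    """Binarized, zero-padded crop of the full z extent around ``center``.

    Out-of-frame regions are zero-filled, so windows may straddle or even
    leave the image borders without error.
    """
    window = window_for_center(center, width, depth)
    bone = _bone if _bone is not None else _binary_volume(volume, threshold)
    voxels = _crop_from_binary(bone, window.origin, width, depth)
    return BinaryStack(voxels=voxels, window=window, scale=1.0), window


def local_target(landmark, window: CropWindow) -> np.ndarray:
    """(x_local, y_local, z_global) regression target for a window."""
    x, y, z = landmark
    return np.array([x - window.origin[0], y - window.origin[1], z], dtype=np.float64)


def remap_to_global(local_pred, window: CropWindow) -> np.ndarray:
    """Exact inverse of :func:`local_target` on x and y; z passes through."""
    x, y, z = local_pred
    return np.array([x + window.origin[0], y + window.origin[1], z], dtype=np.float64)


@dataclass
class TrainingExample:
    """One network input/target pair."""

    stack: BinaryStack
    target: np.ndarray
    case_id: str = ""
    landmark: str = ""


def build_refinement_dataset(
    cases: list[CaseVolume],
    tables: list[LandmarkTable],
    landmark_code: str,
    width: int,
    grid: ShiftGrid,
    depth: int = 81,
    threshold: int = 1100,
) -> list[TrainingExample]:
    """Shift-augmented crop dataset for one landmark.

    Yields ``len(cases) * len(grid)`` examples; each crop is centered on
    the true landmark displaced by the grid offset, and its target is the
    landmark in the crop's local frame (z stays global).
    """
    if len(cases) != len(tables):
        raise InputError("cases and tables must align")
    idx = code_index(landmark_code)
    examples: list[TrainingExample] = []
    for volume, table in zip(cases, tables):
        if volume.case_id != table.case_id:
            raise InputError(
                f"case mismatch: volume {volume.case_id!r} vs table {table.case_id!r}"
            )
        lm = table.points[idx]
        bone = _binary_volume(volume, threshold)
        for dx, dy in grid.offsets:
            stack, window = crop_stack(
                volume,
                (lm[0] + dx, lm[1] + dy),
                width,
                depth=depth,
                threshold=threshold,
                _bone=bone,
            )
            examples.append(
                TrainingExample(
                    stack=stack,
                    target=local_target(lm, window),
                    case_id=volume.case_id,
                    landmark=landmark_code,
                )
            )
    return examples


def build_phase1_dataset(
    cases: list[CaseVolume],
    tables: list[LandmarkTable],
    width: int = 96,
    depth: int = 81,
    threshold: int = 1100,
) -> list[TrainingExample]:
    """Whole-volume dataset: compressed stacks vs all 48 global coordinates."""
    from .volume_io import build_phase1_stack

    if len(cases) != len(tables):
        raise InputError("cases and tables must align")
    examples = []
    for volume, table in zip(cases, tables):
        if volume.case_id != table.case_id:
            raise InputError("case order mismatch between volumes and tables")
        stack = build_phase1_stack(volume, width=width, depth=depth, threshold=threshold)
        examples.append(
            TrainingExample(
                stack=stack, target=table.points.ravel().copy(), case_id=volume.case_id
            )
        )
    return examples


# ----------------------------------------------------------------------
# HDF5 serialization


def save_dataset(examples: list[TrainingExample], path: str | Path) -> None:
    """Persist (stack, target, window, case_id, landmark) records."""
    if not examples:
        raise InputError("nothing to save")
    stacks = np.stack([e.stack.voxels for e in examples]).astype(np.uint8)
    targets = np.stack([e.target for e in examples])
    origins = np.array(
        [e.stack.window.origin if e.stack.window else (0, 0) for e in examples],
        dtype=np.int64,
    )
    with h5py.File(path, "w") as fh:
        fh.create_dataset("stack", data=stacks, compression="gzip", compression_opts=1)
        fh.create_dataset("target", data=targets)
        fh.create_dataset("window_origin", data=origins)
        fh.create_dataset(
            "case_id", data=np.array([e.case_id for e in examples], dtype="S32")
        )
        fh.create_dataset(
            "landmark", data=np.array([e.landmark for e in examples], dtype="S8")
        )


def load_dataset(path: str | Path) -> list[TrainingExample]:
    with h5py.File(path, "r") as fh:
        stacks = fh["stack"][:]
        targets = fh["target"][:]
        origins = fh["window_origin"][:]
        case_ids = [s.decode() for s in fh["case_id"][:]]
        codes = [s.decode() for s in fh["landmark"][:]]
    examples = []
    for vox, tgt, org, cid, code in zip(stacks, targets, origins, case_ids, codes):
        window = CropWindow(
            origin=(int(org[0]), int(org[1])), width=vox.shape[1], depth=vox.shape[2]
        )
        examples.append(
            TrainingExample(
                stack=BinaryStack(voxels=vox, window=window, scale=1.0),
                target=np.asarray(tgt, dtype=np.float64),
                case_id=cid,
                landmark=code,
            )
        )
    return examples
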