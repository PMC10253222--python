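"""Pipeline configuration.

Two presets ship with the package:

* :meth:`PipelineConfig.full_scale` — the geometry of the source imaging
  protocol: 512 × 512 px axial slices (512 px = 500 mm), 5 mm slice
  interval, at most 81 slices per case, whole-volume input compressed to
  96 × 96, refinement crops of 100 and 50 px, shift-grid augmentation of
  ±30 px step 10 (phase 2) and ±15 px step 5 (phase 3).

* :meth:`PipelineConfig.desk_scale` — the same geometry shrunk by 512/96
  in-plane so that the full three-phase system trains on one CPU in
  minutes.  The z-step stays 5.12 px at both scales because the slice
  interval is scaled together with the in-plane spacing.

All coordinates, including z, are kept in pixel units (1 px = 500/512 mm
at full scale); axial slices therefore sit at multiples of
``slice_mm / in_plane_mm`` = 5.12 px.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass(frozen=True)
class NetConfig:
    """Architecture knobs for the regression networks.

    ``blocks``/``block_type`` describe the residual trunk; the default
    bottleneck layout (3, 4, 6, 3) gives the classic 50-layer residual
    network (1 stem conv + 48 block convs + 1 linear head).
    ``width_scale`` multiplies every channel count, so small values give
    desk-trainable variants of the same architecture.
    """

    blocks: tuple[int, ...] = (3, 4, 6, 3)
    block_type: str = "bottleneck"  # "bottleneck" | "basic"
    base_channels: int = 64
    width_scale: float = 1.0
    head: str = "avgpool"  # "avgpool" | "flatten"
    learning_rate: float = 1e-3


@dataclass(frozen=True)
class PhaseTraining:
    batch_size: int
    epochs: int


@dataclass(frozen=True)
class PipelineConfig:
    # in-plane geometry
    image_size: int = 512
    in_plane_mm: float = 500.0 / 512.0
    slice_mm: float = 5.0
    depth: int = 81  # z capacity of the stacking template

    # preprocessing
    threshold: int = 1100
    cross_value: int = 4000
    cross_index: int = 255
    apply_cross: bool = True

    # phase geometry
    phase1_size: int = 96
    phase2_width: int = 100
    phase3_width: int = 50
    phase2_shift: tuple[int, int] = (30, 10)  # (max_shift, step)
    phase3_shift: tuple[int, int] = (15, 5)

    # networks / optimisation
    net: NetConfig = field(default_factory=NetConfig)
    phase1_training: PhaseTraining = field(default_factory=lambda: PhaseTraining(8, 150))
    phase2_training: PhaseTraining = field(default_factory=lambda: PhaseTraining(16, 100))
    phase3_training: PhaseTraining = field(default_factory=lambda: PhaseTraining(16, 150))

    def __post_init__(self) -> None:
        if self.image_size <= 0 or self.depth <= 0:
            raise ParameterError("image_size and depth must be positive")
        if self.phase2_width % 2 or self.phase3_width % 2:
            raise ParameterError("crop widths must be even")

    @property
    def z_step_px(self) -> float:
        """Distance between adjacent slices, in pixel units."""
        return self.slice_mm / self.in_plane_mm

    @classmethod
    def full_scale(cls) -> "PipelineConfig":
        return cls()

    @classmethod
    def desk_scale(cls) -> "PipelineConfig":
        """Geometry shrunk by 512/96 with shallow, narrow networks.

        Shift grids keep the half-open Cartesian structure; widths and
        shifts are scaled so the crop-to-head proportions match the
        full-scale setup.  Epoch counts are small because the phantom
        task is far easier than real anatomy.
        """
        return cls(
            image_size=96,
            in_plane_mm=500.0 / 96.0,
            slice_mm=5.0 * 512.0 / 96.0,
            depth=24,
            phase1_size=32,
            phase2_width=24,
            phase3_width=12,
            phase2_shift=(6, 3),
            phase3_shift=(2, 1),
            net=NetConfig(
                blocks=(1,),
                block_type="basic",
                base_channels=16,
                width_scale=0.25,
                head="flatten",
                learning_rate=8e-3,
            ),
            phase1_training=PhaseTraining(8, 15),
            phase2_training=PhaseTraining(16, 12),
            phase3_training=PhaseTraining(16, 12),
        )

    # ------------------------------------------------------------------
    # serialisation
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "net" in d and isinstance(d["net"], dict):
            net = dict(d["net"])
            if "blocks" in net:
                net["blocks"] = tuple(net["blocks"])
            d["net"] = NetConfig(**net)
        for key in ("phase1_training", "phase2_training", "phase3_training"):
            if key in d and isinstance(d[key], dict):
                d[key] = PhaseTraining(**d[key])
        for key in ("phase2_shift", "phase3_shift"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
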