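"""Regression networks for landmark coordinate prediction.

One whole-volume network regresses all 48 coordinates (16 landmarks x 3)
from the compressed binary stack; each refinement phase adds 16
per-landmark networks with 3 outputs, giving 1 + 16 + 16 = 33 trained
models in a complete system.

The architecture is a 3D residual convolutional regressor with a linear
(unbounded) output head: a stride-2 stem convolution, stages of residual
blocks (stride 2 at each stage entry after the first), and either global
average pooling or a flattened feature map feeding the final dense layer.
The default bottleneck layout (3, 4, 6, 3) is the classic 50-layer
residual network; ``width_scale`` shrinks channel counts so desk-scale
variants train on a CPU in seconds.  Training minimises mean squared
error with Adam on per-output standardized targets (the standardization
constants are stored with the weights and inverted at prediction time).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .config import NetConfig
from .errors import FormatError, InputError, ParameterError

PHASE1_OUTPUTS = 48
REFINE_OUTPUTS = 3


@dataclass(frozen=True)
class RegressorSpec:
    """Architecture description of one regression network."""

    input_shape: tuple[int, int, int]  # (W, H, D)
    n_outputs: int = PHASE1_OUTPUTS
    blocks: tuple[int, ...] = (3, 4, 6, 3)
    block_type: str = "bottleneck"  # "bottleneck" | "basic"
    base_channels: int = 64
    width_scale: float = 1.0
    head: str = "avgpool"  # "avgpool" | "flatten"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outputs not in (PHASE1_OUTPUTS, REFINE_OUTPUTS):
            raise ParameterError(f"n_outputs must be 48 or 3, got {self.n_outputs}")
        if any(s <= 0 for s in self.input_shape):
            raise ParameterError("input_shape must be positive")
        if self.width_scale <= 0:
            raise ParameterError("width_scale must be positive")
        if self.block_type not in ("bottleneck", "basic"):
            raise ParameterError(f"unknown block type {self.block_type!r}")
        if self.head not in ("avgpool", "flatten"):
            raise ParameterError(f"unknown head {self.head!r}")

    @classmethod
    def from_net_config(
        cls, input_shape: tuple[int, int, int], n_outputs: int, net: NetConfig, seed: int = 0
    ) -> "RegressorSpec":
        return cls(
            input_shape=tuple(input_shape),
            n_outputs=n_outputs,
            blocks=tuple(net.blocks),
            block_type=net.block_type,
            base_channels=net.base_channels,
            width_scale=net.width_scale,
            head=net.head,
            seed=seed,
        )


@dataclass
class TrainingConfig:
    """Optimisation settings for one network."""

    batch_size: int = 16
    epochs: int = 100
    learning_rate: float = 1e-3
    seed: int = 0


class Regressor:
    """A trained (or trainable) volumetric coordinate regressor."""

    def __init__(self, spec: RegressorSpec):
        self.spec = spec
        self.net = _build_net(spec)
        self.target_mean = np.zeros(spec.n_outputs, dtype=np.float32)
        self.target_std = np.ones(spec.n_outputs, dtype=np.float32)
        self.history: list[float] = []

    @property
    def n_outputs(self) -> int:
        return self.spec.n_outputs

    def params(self) -> list[_nn.Param]:
        return self.net.params()

    def _as_batch(self, stacks) -> np.ndarray:
        x = np.asarray(stacks, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4:
            raise InputError(f"expected (N, H, W, D) stacks, got shape {x.shape}")
        w, h, d = self.spec.input_shape
        if x.shape[1:] != (w, h, d):
            raise InputError(
                f"stack shape {x.shape[1:]} does not match model input {self.spec.input_shape}"
            )
        return x[:, None]  # add channel axis

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def predict(self, stacks, batch_size: int = 16) -> np.ndarray:
        """Deterministic forward pass, de-standardized to coordinate units."""
        x = self._as_batch(stacks)
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self.net.forward(x[i : i + batch_size]))
        y = np.concatenate(outs, axis=0)
        return y * self.target_std + self.target_mean


def _build_net(spec: RegressorSpec) -> _nn.Sequential:
    rng = np.random.default_rng(spec.seed)
    c = max(1, int(round(spec.base_channels * spec.width_scale)))
    n_halvings = 1 + max(0, len(spec.blocks) - 1)  # stem + stage entries
    _nn.check_spatial(spec.input_shape, n_halvings)

    layers: list[_nn.Layer] = [_nn.Conv3D(1, c, 3, 2, rng), _nn.ReLU()]
    shape = tuple(_nn.out_size(s, 2) for s in spec.input_shape)
    cin = c
    for stage, n_blocks in enumerate(spec.blocks):
        cmid = c * 2**stage
        for b in range(n_blocks):
            stride = 2 if (stage > 0 and b == 0) else 1
            if spec.block_type == "bottleneck":
                layers.append(_nn.bottleneck_block(cin, cmid, stride, rng))
                cin = 4 * cmid
            else:
                layers.append(_nn.basic_block(cin, cmid, stride, rng))
                cin = cmid
            if stride == 2:
                shape = tuple(_nn.out_size(s, 2) for s in shape)
    if spec.head == "avgpool":
        layers += [_nn.GlobalAvgPool(), _nn.Dense(cin, spec.n_outputs, rng)]
    else:
        layers += [_nn.Flatten(),
                   _nn.Dense(cin * int(np.prod(shape)), spec.n_outputs, rng)]
    return _nn.Sequential(layers)


def build_regressor(spec: RegressorSpec) -> Regressor:
    """Instantiate a randomly initialised regressor for ``spec``."""
    return Regressor(spec)


def _dataset_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(dataset, "__len__") and len(dataset) == 2 and isinstance(dataset, tuple):
        x, y = dataset
        return np.asarray(x), np.asarray(y, dtype=np.float64)
    stacks = np.stack([e.stack.voxels for e in dataset])
    targets = np.stack([np.asarray(e.target, dtype=np.float64) for e in dataset])
    return stacks, targets


def train(
    model: Regressor,
    dataset,
    config: TrainingConfig,
    out_path: str | Path | None = None,
) -> Path | None:
    """Minimise MSE with Adam; optionally persist the weights.

    ``dataset`` is a list of training examples or an ``(X, Y)`` tuple.
    Targets are standardized per output dimension before optimisation;
    the constants travel with the weights.  The per-epoch training loss
    (standardized scale) is recorded on ``model.history``.
    """
    x, y = _dataset_arrays(dataset)
    if len(x) == 0:
        raise InputError("dataset is empty")
    if y.shape[1] != model.n_outputs:
        raise InputError(
            f"targets have {y.shape[1]} dims but the model outputs {model.n_outputs}"
        )
    xb = model._as_batch(x)
    mean = y.mean(axis=0)
    std = y.std(axis=0)
    std[std < 1e-6] = 1.0
    model.target_mean = mean.astype(np.float32)
    model.target_std = std.astype(np.float32)
    yn = ((y - mean) / std).astype(np.float32)

    rng = np.random.default_rng(config.seed)
    opt = _nn.Adam(model.params(), lr=config.learning_rate)
    n = len(xb)
    model.history = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            sel = order[i : i + config.batch_size]
            opt.zero_grad()
            pred = model.forward(xb[sel])
            loss, grad = _nn.mse_loss(pred, yn[sel])
            model.net.backward(grad)
            opt.step()
            losses.append(loss)
        model.history.append(float(np.mean(losses)))
    if out_path is not None:
        return save_weights(model, out_path)
    return None


# ----------------------------------------------------------------------
# persistence


def save_weights(model: Regressor, path: str | Path) -> Path:
    """Write weights + architecture + target scaler to a single file."""
    path = Path(path)
    meta = {
        "spec": {
            "input_shape": list(model.spec.input_shape),
            "n_outputs": model.spec.n_outputs,
            "blocks": list(model.spec.blocks),
            "block_type": model.spec.block_type,
            "base_channels": model.spec.base_channels,
            "width_scale": model.spec.width_scale,
            "head": model.spec.head,
            "seed": model.spec.seed,
        }
    }
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    arrays["target_mean"] = model.target_mean
    arrays["target_std"] = model.target_std
    buf = io.BytesIO()
    np.savez(buf, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    path.write_bytes(buf.getvalue())
    return path


def load_weights(path: str | Path, expected_spec: RegressorSpec | None = None) -> Regressor:
    """Rebuild a regressor from a weights file; bit-exact predictions."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"weights file {path} does not exist")
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            spec_d = meta["spec"]
            spec = RegressorSpec(
                input_shape=tuple(spec_d["input_shape"]),
                n_outputs=int(spec_d["n_outputs"]),
                blocks=tuple(spec_d["blocks"]),
                block_type=spec_d["block_type"],
                base_channels=int(spec_d["base_channels"]),
                width_scale=float(spec_d["width_scale"]),
                head=spec_d["head"],
                seed=int(spec_d["seed"]),
            )
            model = Regressor(spec)
            params = model.params()
            for i, p in enumerate(params):
                stored = data[f"param_{i}"]
                if stored.shape != p.value.shape:
                    raise FormatError(
                        f"parameter {i} shape {stored.shape} != expected {p.value.shape}"
                    )
                p.value = stored.astype(np.float32)
            model.target_mean = data["target_mean"].astype(np.float32)
            model.target_std = data["target_std"].astype(np.float32)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read weights file {path}: {exc}") from exc
    if expected_spec is not None and spec != expected_spec:
        raise FormatError(f"weights at {path} were built for a different spec")
    return model
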