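"""ResNet-style 1-D CNN for binary spectrum classification.

The network is an initial strided convolution ("stem"), six residual blocks
of four convolutions each, and a fully connected two-logit head.  Every
convolution uses kernel size 5; downsampling by stride 2 happens once in the
stem and once in the first convolution of each block, so a 1174-point
spectrum is reduced through 587 -> 294 -> 147 -> 74 -> 37 -> 19 -> 10
feature points before the head.  Batch normalization follows every
convolution; shortcuts use a strided 1x1 projection whenever shape changes.

Parameters are addressable by named groups — ``stem``, ``block_1`` ..
``block_6``, ``head`` — plus the cross-cutting set of all batch-norm affine
parameters.  Group-wise addressing is what selective fine-tuning (freeze the
first half, adapt the rest) and test-time adaptation (update head + batch
norms only) rely on.

With the default configuration (100 channels throughout) the model has
1,268,702 parameters, a deliberate ~1.25M budget that keeps the capacity of
the network in the regime where multi-domain pre-training is worthwhile but
single-CPU training remains feasible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn.functional import softmax
from .nn.layers import BatchNorm1d, Conv1d, Flatten, Linear, ReLU

__all__ = [
    "ModelConfig",
    "Resnet1D",
    "build_model",
    "count_parameters",
    "predict_proba",
    "shape_trace",
    "save_checkpoint",
    "load_checkpoint",
    "CHECKPOINT_FORMAT_VERSION",
]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``block_channels`` gives the channel width of each residual block; the
    default keeps 100 channels everywhere, which realises the ~1.25M
    parameter budget.  A 64-filter variant is available by passing
    ``initial_filters=64, block_channels=(64,)*6``.
    """

    input_length: int = 1174
    initial_filters: int = 100
    block_channels: tuple[int, ...] = (100, 100, 100, 100, 100, 100)
    kernel_size: int = 5
    downsample_stride: int = 2
    convs_per_block: int = 4
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.kernel_size % 2 != 1:
            raise ValueError(f"kernel_size must be odd, got {self.kernel_size}")
        if self.downsample_stride < 1:
            raise ValueError("downsample_stride must be >= 1")
        if self.convs_per_block < 1:
            raise ValueError("convs_per_block must be >= 1")
        if len(self.block_channels) < 1:
            raise ValueError("need at least one residual block")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        n_stages = 1 + self.n_blocks  # stem + one downsampling conv per block
        min_len = self.downsample_stride**n_stages
        if self.input_length < min_len:
            raise ValueError(
                f"input_length {self.input_length} too short for {n_stages} "
                f"stride-{self.downsample_stride} stages; minimum is {min_len}"
            )

    @property
    def n_blocks(self) -> int:
        return len(self.block_channels)


def shape_trace(config: ModelConfig) -> list[int]:
    """Feature lengths after the stem and after each block.

    Each stride-``s`` stage maps length ``L`` to ``ceil(L / s)``.
    """
    s = config.downsample_stride
    lengths = [config.input_length]
    for _ in range(1 + config.n_blocks):
        lengths.append(-(-lengths[-1] // s))
    return lengths


class _ResBlock:
    """Four convolutions with a projection shortcut; downsamples on entry."""

    def __init__(
        self,
        in_channels: int,
        channels: int,
        kernel_size: int,
        stride: int,
        n_convs: int,
        rng: np.random.Generator,
    ) -> None:
        self.convs = [Conv1d(in_channels, channels, kernel_size, stride=stride, rng=rng)]
        self.convs += [
            Conv1d(channels, channels, kernel_size, stride=1, rng=rng)
            for _ in range(n_convs - 1)
        ]
        self.bns = [BatchNorm1d(channels) for _ in range(n_convs)]
        self.relus = [ReLU() for _ in range(n_convs - 1)]
        self.final_relu = ReLU()
        if stride != 1 or in_channels != channels:
            self.shortcut_conv: Conv1d | None = Conv1d(
                in_channels, channels, 1, stride=stride, rng=rng
            )
            self.shortcut_bn: BatchNorm1d | None = BatchNorm1d(channels)
        else:
            self.shortcut_conv = None
            self.shortcut_bn = None

    def named_layers(self) -> list[tuple[str, object]]:
        out: list[tuple[str, object]] = []
        for i, (cv, bn) in enumerate(zip(self.convs, self.bns), start=1):
            out.append((f"conv{i}", cv))
            out.append((f"bn{i}", bn))
        if self.shortcut_conv is not None:
            out.append(("shortcut_conv", self.shortcut_conv))
            out.append(("shortcut_bn", self.shortcut_bn))
        return out

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = x
        last = len(self.convs) - 1
        for i, (cv, bn) in enumerate(zip(self.convs, self.bns)):
            h = bn.forward(cv.forward(h, training), training)
            if i < last:
                h = self.relus[i].forward(h, training)
        if self.shortcut_conv is not None:
            sc = self.shortcut_bn.forward(self.shortcut_conv.forward(x, training), training)
        else:
            sc = x
        return self.final_relu.forward(h + sc, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.final_relu.backward(grad)
        g_main = grad
        last = len(self.convs) - 1
        for i in range(last, -1, -1):
            if i < last:
                g_main = self.relus[i].backward(g_main)
            g_main = self.bns[i].backward(g_main)
            g_main = self.convs[i].backward(g_main)
        if self.shortcut_conv is not None:
            g_sc = self.shortcut_conv.backward(self.shortcut_bn.backward(grad))
        else:
            g_sc = grad
        return g_main + g_sc


class Resnet1D:
    """The assembled network with named parameter groups."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        k = config.kernel_size
        s = config.downsample_stride

        self.stem_conv = Conv1d(1, config.initial_filters, k, stride=s, rng=rng)
        self.stem_bn = BatchNorm1d(config.initial_filters)
        self.stem_relu = ReLU()

        self.blocks: list[_ResBlock] = []
        in_ch = config.initial_filters
        for ch in config.block_channels:
            self.blocks.append(_ResBlock(in_ch, ch, k, s, config.convs_per_block, rng))
            in_ch = ch

        final_len = shape_trace(config)[-1]
        self.flatten = Flatten()
        self.fc = Linear(in_ch * final_len, config.n_classes, rng=rng)

        # name -> layer, and group -> parameter names
        self._layers: dict[str, object] = {"stem.conv": self.stem_conv, "stem.bn": self.stem_bn}
        for bi, block in enumerate(self.blocks, start=1):
            for lname, layer in block.named_layers():
                self._layers[f"block_{bi}.{lname}"] = layer
        self._layers["head.fc"] = self.fc

        self.group_order = ["stem"] + [f"block_{i}" for i in range(1, config.n_blocks + 1)] + ["head"]
        self.group_map: dict[str, list[str]] = {g: [] for g in self.group_order}
        for lname, layer in self._layers.items():
            group = lname.split(".", 1)[0]
            if group.startswith("block"):
                group = lname.split(".", 1)[0]
            for pkey in layer.params:
                self.group_map[group].append(f"{lname}.{pkey}")

        #: Names currently receiving optimizer updates; training routines
        #: narrow this set to implement freezing.
        self.trainable_names: set[str] = set(self.parameters())

    # ---------------------------------------------------------------- params
    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{lname}.{k}": layer.params[k]
            for lname, layer in self._layers.items()
            for k in layer.params
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {
            f"{lname}.{k}": layer.grads[k]
            for lname, layer in self._layers.items()
            for k in layer.grads
        }

    def buffers(self) -> dict[str, np.ndarray]:
        return {
            f"{lname}.{k}": layer.buffers[k]
            for lname, layer in self._layers.items()
            for k in layer.buffers
        }

    def batchnorm_param_names(self) -> set[str]:
        return {
            f"{lname}.{k}"
            for lname, layer in self._layers.items()
            if isinstance(layer, BatchNorm1d)
            for k in layer.params
        }

    def zero_grad(self) -> None:
        for layer in self._layers.values():
            layer.grads.clear()

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {f"param:{k}": v.copy() for k, v in self.parameters().items()}
        out.update({f"buffer:{k}": v.copy() for k, v in self.buffers().items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        buffers = self.buffers()
        for key, value in state.items():
            kind, name = key.split(":", 1)
            target = params[name] if kind == "param" else buffers[name]
            if target.shape != value.shape:
                raise ValueError(f"shape mismatch for {name}: {target.shape} vs {value.shape}")
            target[...] = value

    # --------------------------------------------------------------- forward
    def _as_batch(self, spectra: np.ndarray) -> np.ndarray:
        x = np.asarray(spectra, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[2] != self.config.input_length:
            raise ValueError(
                f"expected spectra of length {self.config.input_length}, got {x.shape[2]}"
            )
        return x

    def forward(self, spectra: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits of shape ``(N, n_classes)``."""
        h = self._as_batch(spectra)
        h = self.stem_relu.forward(
            self.stem_bn.forward(self.stem_conv.forward(h, training), training), training
        )
        for block in self.blocks:
            h = block.forward(h, training)
        return self.fc.forward(self.flatten.forward(h, training), training)

    def backward(self, grad_logits: np.ndarray, needed_groups: set[str] | None = None) -> None:
        """Backpropagate, optionally stopping once all needed parameter
        groups have received gradients (frozen early layers then cost
        nothing)."""
        if needed_groups is None:
            earliest = 0
        else:
            unknown = set(needed_groups) - set(self.group_order)
            if unknown:
                raise ValueError(f"unknown parameter groups: {sorted(unknown)}")
            earliest = min(self.group_order.index(g) for g in needed_groups)
        g = self.flatten.backward(self.fc.backward(grad_logits))
        if earliest > self.config.n_blocks:  # head only
            return
        for bi in range(len(self.blocks), 0, -1):
            g = self.blocks[bi - 1].backward(g)
            if earliest == bi:
                return
        self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(g)))

    def predict_proba(self, spectra: np.ndarray) -> np.ndarray:
        """Class probabilities in evaluation mode (stored normalization
        statistics; no state is mutated)."""
        return softmax(self.forward(spectra, training=False))

    def copy(self) -> "Resnet1D":
        clone = Resnet1D(self.config, seed=0)
        clone.load_state_dict(self.state_dict())
        clone.trainable_names = set(self.trainable_names)
        return clone


def build_model(config: ModelConfig | None = None, seed: int = 0) -> Resnet1D:
    """Deterministically initialize a model from its configuration."""
    return Resnet1D(config or ModelConfig(), seed=seed)


def count_parameters(model: Resnet1D, trainable_only: bool = False) -> int:
    params = model.parameters()
    names = model.trainable_names if trainable_only else set(params)
    return int(sum(params[n].size for n in names))


def predict_proba(model: Resnet1D, spectra: np.ndarray) -> np.ndarray:
    return model.predict_proba(spectra)


def save_checkpoint(model: Resnet1D, path) -> None:
    """Single-file checkpoint: weights + buffers + config + group map."""
    from pathlib import Path

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": asdict(model.config),
        "group_map": model.group_map,
    }
    arrays = {k.replace(":", "__"): v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, config: ModelConfig | None = None) -> Resnet1D:
    """Rebuild a model from a checkpoint; an explicitly passed config must
    match the stored one field by field."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        stored = ModelConfig(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in meta["config"].items()
            }
        )
        if config is not None and config != stored:
            diffs = [
                f
                for f in asdict(stored)
                if getattr(stored, f) != getattr(config, f)
            ]
            raise ValueError(f"checkpoint config mismatch in fields: {diffs}")
        model = Resnet1D(stored, seed=0)
        state = {
            k.replace("__", ":", 1): data[k] for k in data.files if k != "__meta__"
        }
        model.load_state_dict(state)
        model._checkpoint_meta = meta  # group-name map retained for audits
    return model
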