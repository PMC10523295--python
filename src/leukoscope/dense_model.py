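"""Dense-connectivity convolutional classifier.

Within a dense block every layer receives the concatenation of the block
input and all previous layer outputs, so layer l sees k0_block + (l-1)*k
channels (k the growth rate) and an L-layer block realizes L(L+1)/2 direct
connections instead of L. Contrast with residual networks, which combine a
layer's input and output by *addition* — concatenation keeps earlier features
verbatim in the stream instead of merging them, at the cost of channel growth
that the transition layers (1x1 compression conv + 2x2 average pooling)
periodically rein in.

Each dense layer uses the bottleneck recipe: BN -> ReLU -> 1x1 conv (4k
channels) -> BN -> ReLU -> 3x3 conv (k channels). The stem is a 3x3
convolution followed by BN/ReLU and 2x2 max pooling; the head is global
average pooling into a linear map onto the class scores. The head is
replaceable (transfer-style: keep every feature layer, re-initialize only the
final fully connected layer, optionally freezing the backbone).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .cells import CLASS_NAMES, CellClass


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class DenseNetConfig:
    initial_channels: int = 16          # stem output channels (k0)
    growth_rate: int = 8                # k: channels appended per dense layer
    block_layout: tuple[int, ...] = (2, 2)
    transition_compression: float = 0.5
    n_classes: int = 4
    input_side: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_channels < 1 or self.growth_rate < 1 or self.n_classes < 1:
            raise ConfigurationError("channel counts and n_classes must be >= 1")
        if not self.block_layout or any(l < 1 for l in self.block_layout):
            raise ConfigurationError("block_layout needs >= 1 layer per block")
        if not 0.0 < self.transition_compression <= 1.0:
            raise ConfigurationError("transition_compression must be in (0, 1]")
        if self.input_side < 8:
            raise ConfigurationError("input_side must be >= 8")
        object.__setattr__(self, "block_layout", tuple(int(l) for l in self.block_layout))


#: Published DenseNet-161 layout (for building the full-scale architecture).
DENSENET_161 = DenseNetConfig(initial_channels=96, growth_rate=48,
                              block_layout=(6, 12, 36, 24),
                              transition_compression=0.5,
                              n_classes=1000, input_side=244)


def count_dense_connections(n_layers: int) -> int:
    """Direct connections in an L-layer dense block: L(L+1)/2."""
    if n_layers < 1:
        raise ValueError(f"n_layers must be >= 1, got {n_layers}")
    return n_layers * (n_layers + 1) // 2


class DenseLayer:
    """BN-ReLU-1x1(4k)-BN-ReLU-3x3(k) bottleneck unit."""

    def __init__(self, c_in: int, growth: int, rng: np.random.Generator, name: str):
        inter = 4 * growth
        self.bn1 = nn.BatchNorm2d(c_in, name=f"{name}.bn1")
        self.relu1 = nn.ReLU()
        self.conv1 = nn.Conv2d(c_in, inter, 1, rng, pad=0, name=f"{name}.conv1")
        self.bn2 = nn.BatchNorm2d(inter, name=f"{name}.bn2")
        self.relu2 = nn.ReLU()
        self.conv2 = nn.Conv2d(inter, growth, 3, rng, pad=1, name=f"{name}.conv2")
        self.stages = [self.bn1, self.relu1, self.conv1, self.bn2, self.relu2, self.conv2]

    def params(self):
        return [p for s in self.stages for p in s.params()]

    def forward(self, x, train):
        for s in self.stages:
            x = s.forward(x, train)
        return x

    def backward(self, grad):
        for s in reversed(self.stages):
            grad = s.backward(grad)
        return grad


class DenseBlock:
    """Concatenative block: output channels = c_in + L * growth."""

    def __init__(self, c_in: int, n_layers: int, growth: int,
                 rng: np.random.Generator, name: str):
        self.c_in = c_in
        self.growth = growth
        self.layers = [DenseLayer(c_in + l * growth, growth, rng, f"{name}.layer{l}")
                       for l in range(n_layers)]
        self.c_out = c_in + n_layers * growth

    def params(self):
        return [p for l in self.layers for p in l.params()]

    @property
    def layer_input_channels(self) -> list[int]:
        return [self.c_in + l * self.growth for l in range(len(self.layers))]

    def forward(self, x, train):
        feats = [x]
        for layer in self.layers:
            y = layer.forward(np.concatenate(feats, axis=1), train)
            feats.append(y)
        self._sizes = [f.shape[1] for f in feats]
        return np.concatenate(feats, axis=1)

    def backward(self, grad):
        # split the output gradient into per-feature slices, then fold each
        # layer's input gradient back onto the earlier slices it consumed
        sizes = self._sizes
        bounds = np.cumsum([0] + sizes)
        grads = [grad[:, bounds[i]:bounds[i + 1]].copy() for i in range(len(sizes))]
        for l in reversed(range(len(self.layers))):
            gin = self.layers[l].backward(grads[l + 1])
            ofs = 0
            for i in range(l + 1):
                grads[i] += gin[:, ofs:ofs + sizes[i]]
                ofs += sizes[i]
        return grads[0]


class Transition:
    """BN-ReLU-1x1 compression conv, then 2x2 average pooling."""

    def __init__(self, c_in: int, compression: float, rng: np.random.Generator, name: str):
        self.c_out = max(1, int(np.floor(c_in * compression)))
        self.bn = nn.BatchNorm2d(c_in, name=f"{name}.bn")
        self.relu = nn.ReLU()
        self.conv = nn.Conv2d(c_in, self.c_out, 1, rng, pad=0, name=f"{name}.conv")
        self.pool = nn.AvgPool2d(2)
        self.stages = [self.bn, self.relu, self.conv, self.pool]

    def params(self):
        return [p for s in self.stages for p in s.params()]

    def forward(self, x, train):
        for s in self.stages:
            x = s.forward(x, train)
        return x

    def backward(self, grad):
        for s in reversed(self.stages):
            grad = s.backward(grad)
        return grad


@dataclass
class Prediction:
    probabilities: np.ndarray  # (n_classes,) summing to 1
    predicted_class: CellClass


class Model:
    """Built dense-connectivity classifier with a replaceable head."""

    def __init__(self, config: DenseNetConfig):
        self.config = config
        self.class_names = tuple(CLASS_NAMES[:config.n_classes]) \
            if config.n_classes <= len(CLASS_NAMES) else tuple(
                f"class_{i}" for i in range(config.n_classes))
        if config.n_classes == len(CLASS_NAMES):
            self.class_names = CLASS_NAMES
        rng = np.random.default_rng(config.seed)

        side = config.input_side
        self.stem_conv = nn.Conv2d(3, config.initial_channels, 3, rng, name="stem.conv")
        self.stem_bn = nn.BatchNorm2d(config.initial_channels, name="stem.bn")
        self.stem_relu = nn.ReLU()
        self.stem_pool = nn.MaxPool2d(2)
        side //= 2

        self.blocks: list[DenseBlock] = []
        self.transitions: list[Transition] = []
        c = config.initial_channels
        for b, n_layers in enumerate(config.block_layout):
            if side < 1:
                raise ConfigurationError(
                    f"block {b}: spatial size collapsed to {side} at input_side "
                    f"{config.input_side}; reduce the number of blocks/transitions"
                )
            block = DenseBlock(c, n_layers, config.growth_rate, rng, f"block{b}")
            self.blocks.append(block)
            c = block.c_out
            if b < len(config.block_layout) - 1:
                tr = Transition(c, config.transition_compression, rng, f"trans{b}")
                self.transitions.append(tr)
                c = tr.c_out
                side //= 2
        if side < 1:
            raise ConfigurationError(
                f"block {len(config.block_layout) - 1}: spatial size collapsed "
                f"at input_side {config.input_side}"
            )

        self.final_bn = nn.BatchNorm2d(c, name="final.bn")
        self.final_relu = nn.ReLU()
        self.pool = nn.GlobalAvgPool()
        self.feature_channels = c
        self.head = nn.Linear(c, config.n_classes, rng, name="head")
        self.frozen_backbone = False

    # -- parameter access ---------------------------------------------------
    def backbone_parameters(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        ps += self.stem_conv.params() + self.stem_bn.params()
        for b in self.blocks:
            ps += b.params()
        for t in self.transitions:
            ps += t.params()
        ps += self.final_bn.params()
        return ps

    def head_parameters(self) -> list[nn.Param]:
        return self.head.params()

    def parameters(self) -> list[nn.Param]:
        return self.backbone_parameters() + self.head_parameters()

    def trainable_parameters(self) -> list[nn.Param]:
        return self.head_parameters() if self.frozen_backbone else self.parameters()

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, 3, S, S) float array; returns (N, n_classes) logits."""
        x = np.ascontiguousarray(x, dtype=nn.DTYPE)
        x = self.stem_pool.forward(
            self.stem_relu.forward(
                self.stem_bn.forward(self.stem_conv.forward(x, train), train), train), train)
        for b, block in enumerate(self.blocks):
            x = block.forward(x, train)
            if b < len(self.transitions):
                x = self.transitions[b].forward(x, train)
        x = self.final_relu.forward(self.final_bn.forward(x, train), train)
        x = self.pool.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        if self.frozen_backbone:
            return
        g = self.pool.backward(g)
        g = self.final_bn.backward(self.final_relu.backward(g))
        for b in reversed(range(len(self.blocks))):
            if b < len(self.transitions):
                g = self.transitions[b].backward(g)
            g = self.blocks[b].backward(g)
        g = self.stem_pool.backward(g)
        g = self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(g)))


def build_model(config: DenseNetConfig) -> Model:
    return Model(config)


def replace_head(model: Model, n_classes: int, freeze: bool = False,
                 seed: int | None = None) -> Model:
    """Swap the final fully connected layer for a fresh n_classes head.

    Every feature-extraction parameter is left bit-identical; only the head
    is re-initialized. With ``freeze=True`` subsequent training updates the
    head alone.
    """
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")
    rng = np.random.default_rng(model.config.seed if seed is None else seed)
    model.head = nn.Linear(model.feature_channels, n_classes, rng, name="head")
    model.config = DenseNetConfig(**{**asdict(model.config), "n_classes": n_classes})
    model.class_names = CLASS_NAMES if n_classes == len(CLASS_NAMES) else tuple(
        f"class_{i}" for i in range(n_classes))
    model.frozen_backbone = bool(freeze)
    return model


def _as_batch(images, input_side: int) -> np.ndarray:
    arr = np.asarray(images, dtype=float)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[3] != 3:
        raise ValueError(f"expected (N, H, W, 3) images, got shape {arr.shape}")
    if arr.shape[1] != input_side or arr.shape[2] != input_side:
        raise ValueError(
            f"expected {input_side}x{input_side} inputs, got {arr.shape[1]}x{arr.shape[2]}"
        )
    return arr.transpose(0, 3, 1, 2)


def predict(model: Model, images) -> list[Prediction]:
    """Evaluation-mode class probabilities (softmax over head scores)."""
    x = _as_batch(images, model.config.input_side)
    logits = model.forward(x, train=False)
    probs = nn.softmax(logits.astype(np.float64))
    out = []
    for p in probs:
        idx = int(np.argmax(p))
        cls = CellClass.from_index(idx) if model.config.n_classes == len(CLASS_NAMES) \
            else CellClass.from_index(min(idx, len(CLASS_NAMES) - 1))
        out.append(Prediction(probabilities=p, predicted_class=cls))
    return out


def predict_proba(model: Model, images, batch_size: int = 64) -> np.ndarray:
    """Batched evaluation-mode probabilities as an (N, n_classes) array."""
    x = _as_batch(images, model.config.input_side)
    chunks = []
    for i in range(0, x.shape[0], batch_size):
        logits = model.forward(x[i:i + batch_size], train=False)
        chunks.append(nn.softmax(logits.astype(np.float64)))
    return np.concatenate(chunks, axis=0)


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(model: Model, path: str | Path) -> None:
    """Save parameters + running stats as .npz with a JSON config sidecar."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for p in model.parameters():
        arrays[p.name] = p.value
    for i, bn in enumerate(_all_batchnorms(model)):
        arrays[f"__running_mean_{i}"] = bn.running_mean
        arrays[f"__running_var_{i}"] = bn.running_var
    np.savez(path, **arrays)
    sidecar = path.with_suffix(path.suffix + ".json")
    cfg = asdict(model.config)
    cfg["block_layout"] = list(cfg["block_layout"])
    sidecar.write_text(json.dumps({
        "config": cfg,
        "class_names": list(model.class_names),
        "frozen_backbone": model.frozen_backbone,
    }, indent=2))


def load_checkpoint(path: str | Path) -> Model:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    cfg = meta["config"]
    cfg["block_layout"] = tuple(cfg["block_layout"])
    model = Model(DenseNetConfig(**cfg))
    model.frozen_backbone = bool(meta.get("frozen_backbone", False))
    with np.load(path) as data:
        for p in model.parameters():
            p.value = np.ascontiguousarray(data[p.name], dtype=nn.DTYPE)
            p.grad = np.zeros_like(p.value)
        for i, bn in enumerate(_all_batchnorms(model)):
            bn.running_mean = data[f"__running_mean_{i}"].astype(nn.DTYPE)
            bn.running_var = data[f"__running_var_{i}"].astype(nn.DTYPE)
    return model


def _all_batchnorms(model: Model):
    bns = [model.stem_bn]
    for b in model.blocks:
        for l in b.layers:
            bns += [l.bn1, l.bn2]
    for t in model.transitions:
        bns.append(t.bn)
    bns.append(model.final_bn)
    return bns
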