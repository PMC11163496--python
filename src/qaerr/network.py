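"""The hybrid CNN + shifted-window-attention classifier.

Architecture (serial CNN -> transformer):

1. **Stem** — a Convolution-BatchNorm-ReLU (CBR) cluster with a 7x7 kernel
   encoding the multi-channel QA maps into low-level features.
2. **RCA stages** — residual channel-attention bottleneck blocks: a 1x1 CBR
   expands the feature dimension, a strided 3x3 CBR extracts features at
   lower resolution, a squeeze-and-excitation gate reweights channels, and
   a 1x1 projection closes the residual.
3. **Attention stages** — tokens are linearly patch-embedded and passed
   through pairs of regular / shifted window multi-head self-attention
   blocks; patch merging between stages halves resolution and doubles the
   embedding dimension.
4. **Head** — layer norm, global average pooling, and a linear 5-class
   classifier; softmax yields the predicted error-family probabilities.

The stage plan (widths, depths, window size) is configuration, not
doctrine: :func:`full_config` operates on 224x224 inputs, and
:func:`desk_config` is a slim profile for 96x96 inputs that trains in
minutes on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from qaerr.nn.autograd import Tensor
from qaerr.nn.attention import PatchMerging, SwinBlock
from qaerr.nn.layers import (
    BatchNorm2d,
    Conv2d,
    LayerNorm,
    Linear,
    Module,
    Sequential,
)


@dataclass(frozen=True)
class NetConfig:
    """Hybrid-network hyperparameters.

    ``rca_stages`` rows are (out_channels, n_blocks, downsample_stride);
    ``attention_stages`` rows are (embed_dim, depth, n_heads, window_size),
    with patch merging inserted between consecutive stages (each stage
    after the first must double the previous embedding dimension).
    """

    input_size: int = 224
    in_channels: int = 3
    stem_channels: int = 32
    stem_kernel: int = 7
    stem_stride: int = 1
    rca_stages: tuple[tuple[int, int, int], ...] = ((64, 1, 2), (128, 1, 2), (256, 1, 2))
    bottleneck_ratio: float = 2.0
    attention_stages: tuple[tuple[int, int, int, int], ...] = ((256, 2, 8, 7), (512, 2, 8, 7))
    mlp_ratio: float = 4.0
    n_classes: int = 5
    dropout: float = 0.0
    droppath: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        size = self.input_size // self.stem_stride
        for _, _, stride in self.rca_stages:
            size //= stride
        for i, (dim, _, heads, ws) in enumerate(self.attention_stages):
            if i > 0:
                if dim != 2 * self.attention_stages[i - 1][0]:
                    raise ValueError("patch merging doubles the embedding dim")
                size //= 2
            if size % ws:
                raise ValueError(
                    f"window size {ws} does not divide stage size {size}")
            if dim % heads:
                raise ValueError("embed dim must be divisible by n_heads")


def full_config(in_channels: int = 3, seed: int = 0) -> NetConfig:
    """224x224 profile mirroring the published input resolution."""
    return NetConfig(in_channels=in_channels, seed=seed)


def desk_config(in_channels: int = 3, seed: int = 0) -> NetConfig:
    """Slim 96x96 profile for CPU-scale experiments."""
    return NetConfig(
        input_size=96,
        in_channels=in_channels,
        stem_channels=8,
        stem_stride=2,
        rca_stages=((16, 1, 2), (32, 1, 2)),
        bottleneck_ratio=1.0,
        attention_stages=((32, 2, 4, 6), (64, 2, 4, 6)),
        mlp_ratio=2.0,
        droppath=0.05,
        seed=seed,
    )


class CBR(Module):
    """Convolution -> BatchNorm -> ReLU."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class ChannelAttention(Module):
    """Squeeze-and-excitation gate: global pool -> bottleneck -> sigmoid."""

    def __init__(self, n_ch: int, rng: np.random.Generator, reduction: int = 4):
        super().__init__()
        hidden = max(n_ch // reduction, 4)
        self.fc1 = Linear(n_ch, hidden, rng=rng)
        self.fc2 = Linear(hidden, n_ch, rng=rng)

    def gate(self, x: Tensor) -> Tensor:
        squeeze = x.mean(axis=(2, 3))          # (N, C)
        return self.fc2(self.fc1(squeeze).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        return x * self.gate(x).reshape(n, c, 1, 1)


class RCABlock(Module):
    """Residual channel-attention bottleneck block."""

    def __init__(self, in_ch: int, out_ch: int, stride: int,
                 bottleneck_ratio: float, rng: np.random.Generator):
        super().__init__()
        mid = max(int(out_ch * bottleneck_ratio), 4)
        self.expand = CBR(in_ch, mid, 1, 1, rng)
        self.spatial = CBR(mid, mid, 3, stride, rng)
        self.se = ChannelAttention(mid, rng)
        self.project = Conv2d(mid, out_ch, 1, 1, bias=False, rng=rng)
        self.project_bn = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.shortcut = Conv2d(in_ch, out_ch, 1, stride, bias=False, rng=rng)
            self.shortcut_bn = BatchNorm2d(out_ch)
        else:
            self.shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.project_bn(self.project(self.se(self.spatial(self.expand(x)))))
        idt = x if self.shortcut is None else self.shortcut_bn(self.shortcut(x))
        return (y + idt).relu()


class HybridNet(Module):
    """Hybrid CNN + windowed-attention classifier over QA map stacks."""

    def __init__(self, config: NetConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)

        self.stem = CBR(config.in_channels, config.stem_channels,
                        config.stem_kernel, config.stem_stride, rng)

        blocks = []
        ch = config.stem_channels
        size = config.input_size // config.stem_stride
        for out_ch, n_blocks, stride in config.rca_stages:
            for b in range(n_blocks):
                s = stride if b == 0 else 1
                blocks.append(RCABlock(ch, out_ch, s, config.bottleneck_ratio, rng))
                ch = out_ch
                size //= s
        self.rca = Sequential(*blocks)

        first_dim = config.attention_stages[0][0]
        self.patch_embed = Linear(ch, first_dim, rng=rng)

        stages: list[Module] = []
        for i, (dim, depth, heads, ws) in enumerate(config.attention_stages):
            if i > 0:
                stages.append(PatchMerging(config.attention_stages[i - 1][0], rng))
                size //= 2
            for d in range(depth):
                shift = 0 if d % 2 == 0 else ws // 2
                stages.append(SwinBlock(dim, size, heads, ws, shift,
                                        config.mlp_ratio, config.dropout,
                                        config.droppath, rng))
        self.attention = Sequential(*stages)
        final_dim = config.attention_stages[-1][0]
        self.norm = LayerNorm(final_dim)
        self.head = Linear(final_dim, config.n_classes, rng=rng)

    def features(self, x: Tensor) -> Tensor:
        """Penultimate pooled feature vector, (N, final_dim)."""
        y = self.rca(self.stem(x))
        n = y.shape[0]
        tokens = y.transpose(0, 2, 3, 1)
        tokens = self.patch_embed(tokens)
        tokens = self.attention(tokens)
        return self.norm(tokens).reshape(n, -1, tokens.shape[-1]).mean(axis=1)

    def forward(self, x: Tensor) -> Tensor:
        """Logits (N, n_classes) for an NCHW input batch."""
        return self.head(self.features(x))

    def predict_proba(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Inference-mode class probabilities for (N, C, H, W) images."""
        was_training = self.training
        self.eval()
        out = []
        for i in range(0, images.shape[0], batch_size):
            logits = self.forward(Tensor(images[i:i + batch_size]))
            out.append(logits.softmax(axis=-1).data)
        self.train(was_training)
        return np.concatenate(out, axis=0)

    def embed(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Inference-mode penultimate features for visualization."""
        was_training = self.training
        self.eval()
        out = []
        for i in range(0, images.shape[0], batch_size):
            out.append(self.features(Tensor(images[i:i + batch_size])).data)
        self.train(was_training)
        return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: HybridNet, path: str | Path) -> None:
    """NPZ checkpoint with the NetConfig embedded as JSON."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path: str | Path) -> HybridNet:
    with np.load(path) as data:
        cfg_doc = json.loads(bytes(data["__config__"].tobytes()).decode())
        for seq_key in ("rca_stages", "attention_stages"):
            cfg_doc[seq_key] = tuple(tuple(row) for row in cfg_doc[seq_key])
        model = HybridNet(NetConfig(**cfg_doc))
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
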