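"""Shifted-window multi-head self-attention blocks.

Feature maps are partitioned into non-overlapping square windows; attention
is computed within each window (W-MSA).  Alternating blocks cyclically
shift the map by half a window before partitioning (SW-MSA) so information
crosses window boundaries; an additive attention mask keeps queries from
attending across the wrap-around seam.  Patch merging concatenates 2x2
neighborhoods and linearly projects them, halving resolution and doubling
the embedding dimension.
"""

from __future__ import annotations

import numpy as np

from qaerr.nn.autograd import Tensor
from qaerr.nn.layers import DropPath, Dropout, LayerNorm, Linear, Module


def window_partition(x: Tensor, ws: int) -> Tensor:
    """(B, H, W, C) -> (B * nWindows, ws*ws, C)."""
    b, h, w, c = x.shape
    x = x.reshape(b, h // ws, ws, w // ws, ws, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b * (h // ws) * (w // ws), ws * ws, c)


def window_reverse(x: Tensor, ws: int, b: int, h: int, w: int) -> Tensor:
    c = x.shape[-1]
    x = x.reshape(b, h // ws, w // ws, ws, ws, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, h, w, c)


def shift_attn_mask(h: int, w: int, ws: int, shift: int) -> np.ndarray:
    """Additive mask (nWindows, T, T) blocking cross-seam attention."""
    img = np.zeros((h, w))
    cnt = 0
    for hs in (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)):
        for wsl in (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)):
            img[hs, wsl] = cnt
            cnt += 1
    win = img.reshape(h // ws, ws, w // ws, ws).transpose(0, 2, 1, 3)
    win = win.reshape(-1, ws * ws)
    diff = win[:, None, :] - win[:, :, None]
    return np.where(diff != 0, -1e4, 0.0).astype(np.float32)


class WindowAttention(Module):
    """Multi-head self-attention within windows of ``ws x ws`` tokens."""

    def __init__(self, dim: int, n_heads: int, ws: int,
                 rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim = dim
        self.n_heads = n_heads
        self.ws = ws
        self.scale = (dim // n_heads) ** -0.5
        self.qkv = Linear(dim, 3 * dim, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        bw_, t, c = x.shape
        h = self.n_heads
        hd = c // h
        qkv = self.qkv(x)  # (B', T, 3C)
        q = qkv[:, :, 0 * c:1 * c].reshape(bw_, t, h, hd).transpose(0, 2, 1, 3)
        k = qkv[:, :, 1 * c:2 * c].reshape(bw_, t, h, hd).transpose(0, 2, 1, 3)
        v = qkv[:, :, 2 * c:3 * c].reshape(bw_, t, h, hd).transpose(0, 2, 1, 3)
        attn = (q * self.scale) @ k.transpose(0, 1, 3, 2)  # (B', h, T, T)
        if mask is not None:
            nw = mask.shape[0]
            attn = attn.reshape(bw_ // nw, nw, h, t, t) + Tensor(
                mask[None, :, None, :, :])
            attn = attn.reshape(bw_, h, t, t)
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(bw_, t, c)
        return self.proj(out)


class Mlp(Module):
    def __init__(self, dim: int, ratio: float, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        hidden = int(dim * ratio)
        self.fc1 = Linear(dim, hidden, rng=rng)
        self.fc2 = Linear(hidden, dim, rng=rng)
        self.drop = Dropout(dropout, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.drop(self.fc2(self.drop(self.fc1(x).gelu())))


class SwinBlock(Module):
    """Pre-norm transformer block with (shifted-)window attention."""

    def __init__(self, dim: int, input_hw: int, n_heads: int, ws: int,
                 shift: int, mlp_ratio: float, dropout: float,
                 droppath: float, rng: np.random.Generator):
        super().__init__()
        if input_hw % ws:
            raise ValueError(f"window size {ws} does not divide {input_hw}")
        self.hw = input_hw
        self.ws = ws
        self.shift = shift
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, n_heads, ws, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, mlp_ratio, dropout, rng)
        self.droppath = DropPath(droppath, rng=rng)
        self.mask = (shift_attn_mask(input_hw, input_hw, ws, shift)
                     if shift else None)

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, H, W, C) token map."""
        b, h, w, c = x.shape
        y = self.norm1(x)
        if self.shift:
            y = y.roll((-self.shift, -self.shift), (1, 2))
        y = window_partition(y, self.ws)
        y = self.attn(y, self.mask)
        y = window_reverse(y, self.ws, b, h, w)
        if self.shift:
            y = y.roll((self.shift, self.shift), (1, 2))
        x = x + self.droppath(y)
        x = x + self.droppath(self.mlp(self.norm2(x)))
        return x


class PatchMerging(Module):
    """2x2 token concatenation + linear projection: (H, W, C) -> (H/2, W/2, 2C)."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.norm = LayerNorm(4 * dim)
        self.reduce = Linear(4 * dim, 2 * dim, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        x = x.reshape(b, h // 2, 2, w // 2, 2, c)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(b, h // 2, w // 2, 4 * c)
        return self.reduce(self.norm(x))
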