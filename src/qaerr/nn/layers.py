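"""Neural-network layers built on the autodiff tensor.

Convolution uses im2col/col2im with explicit gradients; batch and layer
normalization are composed from differentiable primitives so their
backward passes come for free.  Weight initialization: Kaiming for
convolutions, truncated normal (sigma 0.02) for linear/attention weights.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from qaerr.nn.autograd import Tensor


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std)


class Module:
    """Minimal module system: named parameters, submodules, train/eval."""

    def __init__(self) -> None:
        self._params: OrderedDict[str, Tensor] = OrderedDict()
        self._modules: OrderedDict[str, Module] = OrderedDict()
        self._buffers: OrderedDict[str, np.ndarray] = OrderedDict()
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", OrderedDict())[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for mn, m in self._modules.items():
            out.extend(m.named_parameters(prefix + mn + "."))
        return out

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = [(prefix + n, b) for n, b in self._buffers.items()]
        for mn, m in self._modules.items():
            out.extend(m.named_buffers(prefix + mn + "."))
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        state.update({n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters():
            p.data = state[n].astype(np.float32).copy()
        for holder, name, _ in self._iter_buffer_slots():
            key = name
            if key in state:
                holder._buffers[key.split(".")[-1]][...] = state[key]

    def _iter_buffer_slots(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield self, prefix + n, b
        for mn, m in self._modules.items():
            yield from m._iter_buffer_slots(prefix + mn + ".")

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    n, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (n, c, kh, kw, oh, ow),
        (s0, s1, s2, s3, s2 * stride, s3 * stride))
    return np.ascontiguousarray(cols).reshape(n, c * kh * kw, oh * ow)


def _col2im(dcols: np.ndarray, xshape, kh: int, kw: int, stride: int) -> np.ndarray:
    n, c, h, w = xshape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    dcols = dcols.reshape(n, c, kh, kw, oh, ow)
    dx = np.zeros(xshape, dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + oh * stride:stride, j:j + ow * stride:stride] += \
                dcols[:, :, i, j]
    return dx


class Conv2d(Module):
    """2-D convolution (NCHW), symmetric zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.kernel = kernel
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        k, s, p = self.kernel, self.stride, self.padding
        xd = x.data
        if p:
            xd = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)))
        n, c, h, wd = xd.shape
        oh = (h - k) // s + 1
        ow = (wd - k) // s + 1
        cols = _im2col(xd, k, k, s)                      # (n, c*k*k, oh*ow)
        wmat = w.data.reshape(w.data.shape[0], -1)       # (O, c*k*k)
        out = np.matmul(wmat, cols).reshape(n, -1, oh, ow)
        if b is not None:
            out = out + b.data[None, :, None, None]
        padded_shape = xd.shape

        def bw(g):
            gm = g.reshape(n, g.shape[1], oh * ow)       # (n, O, L)
            if w.requires_grad:
                dw = np.einsum("nol,nkl->ok", gm, cols)
                w._accum(dw.reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dcols = np.matmul(wmat.T[None], gm)      # (n, c*k*k, L)
                dxp = _col2im(dcols, padded_shape, k, k, s)
                if p:
                    dxp = dxp[:, :, p:-p, p:-p]
                x._accum(dxp)

        parents = (x, w) if b is None else (x, w, b)
        return Tensor._make(out, parents, bw)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(trunc_normal(rng, (in_f, out_f)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel, NCHW layout."""

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(n_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch), requires_grad=True)
        self._buffers["running_mean"] = np.zeros(n_ch, dtype=np.float32)
        self._buffers["running_var"] = np.ones(n_ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= (1 - m)
            self._buffers["running_mean"] += m * mu.data.ravel()
            self._buffers["running_var"] *= (1 - m)
            self._buffers["running_var"] += m * var.data.ravel()
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = self._buffers["running_mean"].reshape(1, -1, 1, 1)
            var = self._buffers["running_var"].reshape(1, -1, 1, 1)
            xhat = (x + (-mu)) * (1.0 / np.sqrt(var + self.eps))
        return g * xhat + b


class LayerNorm(Module):
    """Layer normalization over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return self.gamma * xhat + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class DropPath(Module):
    """Stochastic depth: drop a residual branch per sample."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        shape = (x.shape[0],) + (1,) * (len(x.shape) - 1)
        mask = (self.rng.random(shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)
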