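"""Minimal numpy neural-network core with reverse-mode gradients.

Implements exactly the layers the two similarity calculators need —
linear, layer norm, multi-head self-attention, 2-D convolution, batch
norm, max pooling, residual blocks — each as a module with an explicit
``forward``/``backward`` pair, plus an Adam optimizer. Shapes follow the
(batch, channel, height, width) convention for images and
(batch, tokens, features) for sequences. All arithmetic is float64;
gradient correctness is pinned down by finite-difference tests.
"""

from __future__ import annotations

from typing import Dict, Iterable, List

import numpy as np


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    def params(self) -> List[Param]:
        out: List[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def buffers(self) -> List[tuple]:
        """Non-trainable state (e.g. batch-norm running statistics)."""
        out: List[tuple] = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.buffers())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.buffers())
        for name in getattr(self, "_buffer_names", ()):
            out.append((self, name))
        return out

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {f"p{i}": p.value for i, p in enumerate(self.params())}
        for j, (mod, name) in enumerate(self.buffers()):
            state[f"b{j}"] = getattr(mod, name)
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"p{i}"]
        for j, (mod, name) in enumerate(self.buffers()):
            if f"b{j}" in state:
                setattr(mod, name, np.array(state[f"b{j}"]))


# ---------------------------------------------------------------- dense

class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / d_in)
        self.w = Param(rng.normal(0, scale, (d_in, d_out)), "w")
        self.b = Param(np.zeros(d_out), "b")

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.w.grad += x2.T @ d2
        self.b.grad += d2.sum(axis=0)
        return dout @ self.w.value.T


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(dim), "gamma")
        self.beta = Param(np.zeros(dim), "beta")
        self.eps = eps

    def forward(self, x, train=False):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dout):
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += (dout * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
        self.beta.grad += dout.reshape(-1, dout.shape[-1]).sum(axis=0)
        dxhat = dout * self.gamma.value
        n = xhat.shape[-1]
        return inv * (dxhat - dxhat.mean(axis=-1, keepdims=True)
                      - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True))


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadSelfAttention(Module):
    """Standard scaled-dot-product self-attention over token sequences."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator) -> None:
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.dim = dim
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def _split(self, x):  # (B, T, D) -> (B, H, T, d)
        b, t, _ = x.shape
        return x.reshape(b, t, self.heads, -1).transpose(0, 2, 1, 3)

    def _merge(self, x):  # (B, H, T, d) -> (B, T, D)
        b, h, t, d = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, t, h * d)

    def forward(self, x, train=False):
        qkv = self.qkv.forward(x)
        q, k, v = np.split(qkv, 3, axis=-1)
        q, k, v = self._split(q), self._split(k), self._split(v)
        scale = 1.0 / np.sqrt(q.shape[-1])
        att = _softmax(np.einsum("bhtd,bhsd->bhts", q, k) * scale)
        out = np.einsum("bhts,bhsd->bhtd", att, v)
        self._cache = (q, k, v, att, scale)
        return self.proj.forward(self._merge(out))

    def backward(self, dout):
        q, k, v, att, scale = self._cache
        dmerged = self.proj.backward(dout)
        do = self._split(dmerged)
        datt = np.einsum("bhtd,bhsd->bhts", do, v)
        dv = np.einsum("bhts,bhtd->bhsd", att, do)
        ds = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
        dq = np.einsum("bhts,bhsd->bhtd", ds, k) * scale
        dk = np.einsum("bhts,bhtd->bhsd", ds, q) * scale
        dqkv = np.concatenate([self._merge(dq), self._merge(dk), self._merge(dv)],
                              axis=-1)
        return self.qkv.backward(dqkv)


class TransformerBlock(Module):
    """Pre-norm encoder block: x + MHSA(LN(x)); x + MLP(LN(x))."""

    def __init__(self, dim: int, heads: int, mlp_ratio: int,
                 rng: np.random.Generator) -> None:
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_ratio * dim, rng)
        self.act = ReLU()
        self.fc2 = Linear(mlp_ratio * dim, dim, rng)

    def forward(self, x, train=False):
        x = x + self.attn.forward(self.ln1.forward(x), train)
        x = x + self.fc2.forward(self.act.forward(self.fc1.forward(
            self.ln2.forward(x), train), train), train)
        return x

    def backward(self, dout):
        d = self.ln2.backward(self.fc1.backward(self.act.backward(
            self.fc2.backward(dout))))
        dout = dout + d
        d = self.ln1.backward(self.attn.backward(dout))
        return dout + d


# ---------------------------------------------------------------- conv

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (x.shape[2] - kh) // stride + 1
    ow = (x.shape[3] - kw) // stride + 1
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, (b, c, oh, ow, kh, kw),
        (s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]))
    return windows.reshape(b, c, oh * ow, kh * kw), (oh, ow, x.shape)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel, stride: int, pad: int,
                 rng: np.random.Generator) -> None:
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        scale = np.sqrt(2.0 / (c_in * kh * kw))
        self.w = Param(rng.normal(0, scale, (c_out, c_in, kh, kw)), "w")
        self.b = Param(np.zeros(c_out), "b")
        self.stride, self.pad = stride, pad

    def forward(self, x, train=False):
        co, ci, kh, kw = self.w.value.shape
        cols, (oh, ow, padded_shape) = _im2col(x, kh, kw, self.stride, self.pad)
        self._cols = cols.reshape(x.shape[0], ci, oh * ow, kh * kw)
        self._meta = (x.shape, oh, ow, padded_shape)
        out = np.einsum("bcpk,ock->bop", self._cols,
                        self.w.value.reshape(co, ci, kh * kw))
        out += self.b.value[None, :, None]
        return out.reshape(x.shape[0], co, oh, ow)

    def backward(self, dout):
        (xb, xc, xh, xw), oh, ow, padded_shape = self._meta
        co, ci, kh, kw = self.w.value.shape
        d = dout.reshape(xb, co, oh * ow)
        self.w.grad += np.einsum("bop,bcpk->ock", d, self._cols).reshape(
            co, ci, kh, kw)
        self.b.grad += d.sum(axis=(0, 2))
        dcols = np.einsum("bop,ock->bcpk", d, self.w.value.reshape(co, ci, kh * kw))
        # scatter-add columns back to the (padded) input
        dx = np.zeros(padded_shape)
        dcols = dcols.reshape(xb, ci, oh, ow, kh, kw)
        for i in range(kh):
            for j in range(kw):
                dx[:, :, i:i + oh * self.stride:self.stride,
                   j:j + ow * self.stride:self.stride] += dcols[:, :, :, :, i, j]
        if self.pad:
            dx = dx[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dx


class BatchNorm2d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(channels), "gamma")
        self.beta = Param(np.zeros(channels), "beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train=False):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout):
        xhat, inv, train, shape = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        if not train:
            return dxhat * inv[None, :, None, None]
        n = shape[0] * shape[2] * shape[3]
        mean_d = dxhat.mean(axis=(0, 2, 3))[None, :, None, None]
        mean_dx = (dxhat * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        return inv[None, :, None, None] * (dxhat - mean_d - xhat * mean_dx)


class MaxPool2x2(Module):
    def forward(self, x, train=False):
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout):
        b, c, h, w = self._shape
        dflat = np.zeros((b, c, h // 2, w // 2, 4))
        np.put_along_axis(dflat, self._arg[..., None], dout[..., None], axis=-1)
        return dflat.reshape(b, c, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(b, c, h, w)


class BasicBlock(Module):
    """Residual block: out = ReLU(BN(conv(ReLU(BN(conv(x))))) + shortcut(x))."""

    def __init__(self, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator) -> None:
        self.conv1 = Conv2d(c_in, c_out, 3, stride, 1, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, 1, 1, rng)
        self.bn2 = BatchNorm2d(c_out)
        self.downsample = None
        if stride != 1 or c_in != c_out:
            self.downsample = Conv2d(c_in, c_out, 1, stride, 0, rng)
        self.relu_out = ReLU()

    def forward(self, x, train=False):
        branch = self.bn2.forward(self.conv2.forward(self.relu1.forward(
            self.bn1.forward(self.conv1.forward(x, train), train), train), train), train)
        short = x if self.downsample is None else self.downsample.forward(x, train)
        return self.relu_out.forward(branch + short, train)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dbranch = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(d)))))
        dshort = d if self.downsample is None else self.downsample.backward(d)
        return dbranch + dshort


# ---------------------------------------------------------------- optimizer

class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: Iterable[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
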