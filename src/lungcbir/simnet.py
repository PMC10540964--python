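"""The two-layer similarity calculator and its training loop.

* The contour-similarity (CS) calculator is a small vision transformer
  over CI-block vectors: each same-position block of the two stacked
  slices is flattened and concatenated into one token, and self-attention
  learns which blocks (in practice, the lobe outline) carry the contour
  signal. The attention weights realize the contextual-linkage weighting
  of the block vectors.

* The detail-similarity (DS) calculator is a residual convolutional
  network — a stem convolution plus four residual basic blocks — whose
  terminal fully-connected layer is replaced by a full-spatial-extent
  convolution, keeping the head sensitive to WHERE bright structures sit,
  not only to their pooled presence.

Both emit a single logit; the probability of "similar" is its sigmoid,
and training minimizes the binary cross-entropy of Eq-style form
loss = mean(-y log g(s) - (1-y) log(1-g(s))) with Adam.

The fused retrieval score is SScore = alpha*SimC + (1-alpha)*SimD, and
the retrieval distance is its complement 1 - SScore.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np

from . import nn
from .pairs import PairSample, pairs_to_arrays

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class NetConfig:
    """Architecture and training hyper-parameters (tiny by default; the
    mechanism is size-independent and 512-scale only changes widths)."""

    image_size: int = 64
    block_size: int = 8
    embed_dim: int = 64
    depth: int = 2
    heads: int = 2
    widths: Tuple[int, int, int, int] = (16, 32, 64, 128)
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 10
    seed: int = 0
    hu_offset: float = 1000.0
    hu_scale: float = 1.0 / 1050.0

    def validate(self) -> None:
        if self.image_size % self.block_size:
            raise ConfigurationError("image_size must be divisible by block_size")
        if self.embed_dim % self.heads:
            raise ConfigurationError("embed_dim must be divisible by heads")
        if self.learning_rate < 0:
            raise ConfigurationError("learning_rate must be >= 0")
        if self.image_size % 16:
            raise ConfigurationError("image_size must be divisible by 16 "
                                     "(stem pool + three stride-2 blocks)")


@dataclass(frozen=True)
class ScoreFusionConfig:
    """Weight of contour similarity in the fused score."""

    alpha: float = 0.5

    def validate(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")


def sigmoid(x):
    """Numerically stable logistic function 1/(1+e^-x)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def pair_loss(logits, labels) -> float:
    """Mean binary cross-entropy of sigmoid(logit) against {0,1} labels."""
    logits = np.atleast_1d(np.asarray(logits, dtype=float))
    labels = np.atleast_1d(np.asarray(labels, dtype=float))
    if logits.shape != labels.shape:
        raise ValidationError("logits and labels must have equal length")
    if logits.size == 0:
        raise ValidationError("empty batch")
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValidationError("labels must be 0 or 1")
    p = np.clip(sigmoid(logits), 1e-12, 1.0 - 1e-12)
    return float(np.mean(-labels * np.log(p) - (1 - labels) * np.log(1 - p)))


# ------------------------------------------------------------ CS calculator

class ContourNet(nn.Module):
    """ViT-style pair classifier over concatenated CI-block tokens."""

    def __init__(self, config: NetConfig) -> None:
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        bs = config.block_size
        self.n_patches = (config.image_size // bs) ** 2
        self.embed = nn.Linear(2 * bs * bs, config.embed_dim, rng)
        self.pos = nn.Param(rng.normal(0, 0.02, (self.n_patches, config.embed_dim)),
                            "pos")
        self.blocks = [nn.TransformerBlock(config.embed_dim, config.heads, 2, rng)
                       for _ in range(config.depth)]
        self.ln = nn.LayerNorm(config.embed_dim)
        self.head = nn.Linear(config.embed_dim, 1, rng)

    def _patchify(self, x: np.ndarray) -> np.ndarray:
        # (B, 2, H, W) -> (B, k, 2*bs*bs): token j concatenates the two
        # slices' j-th blocks, exactly the CIB vector (vec_1j, vec_2j)
        b, c, h, w = x.shape
        bs = self.config.block_size
        xr = x.reshape(b, c, h // bs, bs, w // bs, bs)
        return xr.transpose(0, 2, 4, 1, 3, 5).reshape(b, self.n_patches, c * bs * bs)

    def _unpatchify_grad(self, d: np.ndarray, shape) -> np.ndarray:
        b, c, h, w = shape
        bs = self.config.block_size
        return d.reshape(b, h // bs, w // bs, c, bs, bs).transpose(
            0, 3, 1, 4, 2, 5).reshape(b, c, h, w)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[None]
        self._in_shape = x.shape
        x = (x + self.config.hu_offset) * self.config.hu_scale
        t = self.embed.forward(self._patchify(x)) + self.pos.value
        for blk in self.blocks:
            t = blk.forward(t, train)
        t = self.ln.forward(t.mean(axis=1))
        self._tokens = t.shape
        return self.head.forward(t)[:, 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.head.backward(dout[:, None])
        d = self.ln.backward(d)
        d = np.repeat(d[:, None, :], self.n_patches, axis=1) / self.n_patches
        for blk in reversed(self.blocks):
            d = blk.backward(d)
        self.pos.grad += d.sum(axis=0)
        d = self.embed.backward(d)
        return self._unpatchify_grad(d, self._in_shape) * self.config.hu_scale


# ------------------------------------------------------------ DS calculator

class DetailNet(nn.Module):
    """Residual conv pair classifier: stem + four basic blocks + conv head.

    ``head_mode='conv'`` (default) reduces the final feature map with a
    full-extent valid convolution — weights differ per spatial position,
    so the logit depends on where structures are. ``head_mode='gap'`` is
    the global-average-pooling ablation used in tests.
    """

    def __init__(self, config: NetConfig, head_mode: str = "conv") -> None:
        config.validate()
        if head_mode not in ("conv", "gap"):
            raise ConfigurationError(f"unknown head_mode {head_mode!r}")
        self.config = config
        self.head_mode = head_mode
        rng = np.random.default_rng(config.seed + 1)
        w0, w1, w2, w3 = config.widths
        self.conv1 = nn.Conv2d(2, w0, 3, 1, 1, rng)
        self.bn1 = nn.BatchNorm2d(w0)
        self.relu = nn.ReLU()
        self.pool = nn.MaxPool2x2()
        self.blocks = [
            nn.BasicBlock(w0, w0, 1, rng),
            nn.BasicBlock(w0, w1, 2, rng),
            nn.BasicBlock(w1, w2, 2, rng),
            nn.BasicBlock(w2, w3, 2, rng),
        ]
        final = config.image_size // 16
        if head_mode == "conv":
            self.head = nn.Conv2d(w3, 1, (final, final), 1, 0, rng)
        else:
            self.head = nn.Linear(w3, 1, rng)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[None]
        x = (x + self.config.hu_offset) * self.config.hu_scale
        h = self.pool.forward(self.relu.forward(self.bn1.forward(
            self.conv1.forward(x, train), train), train), train)
        for blk in self.blocks:
            h = blk.forward(h, train)
        if self.head_mode == "conv":
            return self.head.forward(h)[:, 0, 0, 0]
        self._gap_shape = h.shape
        return self.head.forward(h.mean(axis=(2, 3)))[:, 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.head_mode == "conv":
            d = self.head.backward(dout[:, None, None, None])
        else:
            d = self.head.backward(dout[:, None])
            b, c, hh, ww = self._gap_shape
            d = np.broadcast_to(d[:, :, None, None], (b, c, hh, ww)) / (hh * ww)
        for blk in reversed(self.blocks):
            d = blk.backward(d)
        d = self.conv1.backward(self.bn1.backward(self.relu.backward(
            self.pool.backward(d))))
        return d * self.config.hu_scale


def build_cs_calculator(config: NetConfig) -> ContourNet:
    return ContourNet(config)


def build_ds_calculator(config: NetConfig, head_mode: str = "conv") -> DetailNet:
    return DetailNet(config, head_mode=head_mode)


# ------------------------------------------------------------ training

def train_calculator(model: nn.Module, pairs: Sequence[PairSample],
                     config: NetConfig) -> Tuple[nn.Module, List[float]]:
    """Minimize the pair cross-entropy with Adam; returns per-epoch means.

    Deterministic given ``config.seed`` (pure numpy, no backend
    nondeterminism).
    """
    if len(pairs) == 0:
        raise ValidationError("empty training set")
    x, y = pairs_to_arrays(pairs)
    rng = np.random.default_rng(config.seed + 7)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    history: List[float] = []
    n = len(pairs)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb, train=True)
            total += pair_loss(logits, yb) * len(idx)
            # d loss / d logit for BCE-with-logits: (g(s) - y) / batch
            dlogit = (sigmoid(logits) - yb) / len(idx)
            opt.zero_grad()
            model.backward(dlogit)
            opt.step()
        history.append(total / n)   # sample-weighted epoch mean
    return model, history


# ------------------------------------------------------------ scoring

def identity_alignment(ci1: np.ndarray, ci2: np.ndarray):
    """No-op pose-alignment hook.

    Scoring assumes the two slices are grid-aligned (true for phantom
    stacks and resampled CT). A learned affine spatial transformer can
    be plugged in here to normalize scale/rotation before scoring.
    """
    return ci1, ci2


def _score(model: nn.Module, ci1: np.ndarray, ci2: np.ndarray,
           aligner=identity_alignment) -> float:
    a, b = np.asarray(ci1, float), np.asarray(ci2, float)
    if a.shape != b.shape:
        raise ValidationError(f"slice shapes differ: {a.shape} vs {b.shape}")
    a, b = aligner(a, b)
    logit = model.forward(np.stack([a, b])[None], train=False)
    return float(sigmoid(logit[0]))


def sim_c(model: ContourNet, ci1, ci2, aligner=identity_alignment) -> float:
    """Contour similarity in [0, 1]."""
    return _score(model, ci1, ci2, aligner)


def sim_d(model: DetailNet, ci1, ci2, aligner=identity_alignment) -> float:
    """Detail similarity in [0, 1] (expects parenchyma-masked slices)."""
    return _score(model, ci1, ci2, aligner)


def sscore(ci1, ci2, cs_model: ContourNet, ds_model: DetailNet,
           fusion: ScoreFusionConfig = ScoreFusionConfig()) -> float:
    """Fused similarity alpha*SimC + (1-alpha)*SimD."""
    fusion.validate()
    a = fusion.alpha
    if a == 1.0:
        return sim_c(cs_model, ci1, ci2)
    if a == 0.0:
        return sim_d(ds_model, ci1, ci2)
    return a * sim_c(cs_model, ci1, ci2) + (1 - a) * sim_d(ds_model, ci1, ci2)


def distance(ci1, ci2, cs_model: ContourNet, ds_model: DetailNet,
             fusion: ScoreFusionConfig = ScoreFusionConfig()) -> float:
    """Retrieval distance: the complement 1 - SScore (0 = identical)."""
    return 1.0 - sscore(ci1, ci2, cs_model, ds_model, fusion)


def batched_logits(model: nn.Module, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Eval-mode logits over a (N, 2, H, W) stack, in batches."""
    return np.concatenate([model.forward(x[i:i + batch_size], train=False)
                           for i in range(0, len(x), batch_size)])


# ------------------------------------------------------------ checkpoints

def save_checkpoint(path, model: nn.Module, kind: str) -> None:
    path = Path(path)
    np.savez_compressed(path, **model.state_dict())
    sidecar = {"kind": kind, "config": asdict(model.config)}
    if isinstance(model, DetailNet):
        sidecar["head_mode"] = model.head_mode
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path) -> nn.Module:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = meta["config"]
    cfg["widths"] = tuple(cfg["widths"])
    config = NetConfig(**cfg)
    if meta["kind"] == "cs":
        model: nn.Module = ContourNet(config)
    else:
        model = DetailNet(config, head_mode=meta.get("head_mode", "conv"))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        model.load_state_dict(dict(z.items()))
    return model
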