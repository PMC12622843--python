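"""Global-local feature modulation (GLFN) blocks and ContraNorm.

GLFN refines a D-channel feature map in two stages. GLS attention splits
the channels in half: the first half passes through a global-context
branch (per-position scores from a 1x1 projection, softmax over
positions, a weighted channel sum giving a context vector that an MLP
maps back and adds residually), the second through a local gated branch
(a cascade of 1x1 convolutions around a 3x3 depthwise convolution whose
sigmoid output gates the features); the halves are concatenated and
fused by a 1x1 convolution. The PCFN feed-forward then normalizes,
expands with a 1x1 convolution + GELU, applies a 3x3 convolution to only
a fraction of the hidden channels (partial convolution), and projects
back with a residual connection.

ContraNorm counteracts over-smoothing by subtracting a
similarity-weighted combination of the features before layer
normalization:

    H_t = LN(H_b - (s / tau) * softmax(H_b H_b^T) H_b)

applied independently per sample over the set of sampled points.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .autodiff import (Conv2d, LayerNorm, Linear, Module, Tensor, concatenate,
                       layer_norm)


@dataclass
class GLFNConfig:
    """Channel layout of one GLFN block."""

    channels: int
    mlp_hidden: Optional[int] = None      # GS-attention MLP width; default D/2
    pcfn_hidden_ratio: float = 2.0
    pcfn_split_ratio: float = 0.5
    pcfn_residual: bool = True

    def __post_init__(self):
        if self.channels % 2:
            raise ValueError("GLFN channel count must be even for the half split")
        if self.pcfn_hidden_ratio <= 0 or not 0 < self.pcfn_split_ratio < 1:
            raise ValueError("PCFN ratios must be positive (split in (0,1))")
        if int(self.channels * self.pcfn_hidden_ratio) < 2:
            raise ValueError("PCFN hidden width must be >= 2")


@dataclass
class ContraNormParams:
    """Scale ('stride') s and temperature tau of the contrastive term."""

    s: float = 0.1
    tau: float = 1.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.s < 0:
            raise ValueError("s must be >= 0")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def channel_split(f) -> Tuple[Tensor, Tensor]:
    """Split a (B, D, H, W) feature map into its first and second D/2 channels."""
    f = _as_tensor(f)
    d = f.shape[1]
    if d % 2:
        raise ValueError("channel count must be even")
    return f[:, : d // 2], f[:, d // 2:]


class GSAttention(Module):
    """Global spatial attention: softmax-weighted context vector + residual.

    A 1x1 projection scores every spatial position; the softmax over
    positions weights a channel-wise sum of the input, producing a
    permutation-invariant global context vector. A two-layer MLP (ReLU +
    layer normalization between the layers) maps it back to the channel
    width and the result is broadcast-added to the input.
    """

    def __init__(self, channels: int, hidden: Optional[int] = None, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = hidden or channels
        self.score = Conv2d(channels, 1, 1, rng=rng)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.norm = LayerNorm(hidden, axis=-1)
        # zero-init output layer: the branch starts as an identity and
        # the attention contribution grows during training
        self.fc2 = Linear(hidden, channels, rng=rng)
        self.fc2.weight.data[:] = 0.0

    def __call__(self, f1) -> Tensor:
        f1 = _as_tensor(f1)
        B, C, H, W = f1.shape
        scores = self.score(f1).reshape(B, H * W)
        weights = scores.softmax(axis=1)                      # sum to 1 over S
        flat = f1.reshape(B, C, H * W)
        context = (flat * weights.reshape(B, 1, H * W)).sum(axis=2)   # (B, C)
        out = self.fc2(self.norm(self.fc1(context).relu()))
        return f1 + out.reshape(B, C, 1, 1)

    def attention_weights(self, f1) -> np.ndarray:
        f1 = _as_tensor(f1)
        B, C, H, W = f1.shape
        return self.score(f1).reshape(B, H * W).softmax(axis=1).data


class LSAttention(Module):
    """Local spatial attention: sigmoid gate from a depthwise conv cascade.

    Fc = 1x1 (to a 4x channel bottleneck) -> 1x1 -> 3x3 depthwise -> 1x1
    (back to full width); gate = sigmoid(1x1(Fc(F2)) + F2); the output is
    gate * F2 + F2, so it lies between F2 and 2*F2 for non-negative F2.
    """

    def __init__(self, channels: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        mid = max(1, channels // 4)
        self.c1 = Conv2d(channels, mid, 1, rng=rng)
        self.c2 = Conv2d(mid, mid, 1, rng=rng)
        self.dw = Conv2d(mid, mid, 3, rng=rng, padding="same", groups=mid)
        self.c3 = Conv2d(mid, channels, 1, rng=rng)
        # gate starts nearly closed so the block begins as an identity
        self.gate_proj = Conv2d(channels, channels, 1, rng=rng)
        self.gate_proj.bias.data[:] = -4.0

    def __call__(self, f2) -> Tensor:
        f2 = _as_tensor(f2)
        fc = self.c3(self.dw(self.c2(self.c1(f2))))
        gate = (self.gate_proj(fc) + f2).sigmoid()
        return gate * f2 + f2

    def gate_values(self, f2) -> np.ndarray:
        f2 = _as_tensor(f2)
        fc = self.c3(self.dw(self.c2(self.c1(f2))))
        return (self.gate_proj(fc) + f2).sigmoid().data


class GLSAttention(Module):
    """Half-split into global and local branches, concatenated and fused 1x1."""

    def __init__(self, cfg: GLFNConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        half = cfg.channels // 2
        self.gs = GSAttention(half, cfg.mlp_hidden, rng=rng)
        self.ls = LSAttention(half, rng=rng)
        # identity-initialized fusion keeps the split-transform-concat
        # path an identity at the start of training
        self.fuse = Conv2d(cfg.channels, cfg.channels, 1, rng=rng)
        self.fuse.weight.data[:] = np.eye(cfg.channels)[:, :, None, None]

    def __call__(self, f) -> Tensor:
        f1, f2 = channel_split(_as_tensor(f))
        return self.fuse(concatenate([self.gs(f1), self.ls(f2)], axis=1))


class PCFN(Module):
    """Partial-convolution feed-forward network with residual connection."""

    def __init__(self, cfg: GLFNConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        d = cfg.channels
        hidden = int(d * cfg.pcfn_hidden_ratio)
        self.n_a = max(1, int(round(hidden * cfg.pcfn_split_ratio)))
        self.n_b = hidden - self.n_a
        self.norm = LayerNorm(d, axis=1)
        self.expand = Conv2d(d, hidden, 1, rng=rng)
        self.local = Conv2d(self.n_a, self.n_a, 3, rng=rng, padding="same")
        # zero-init projection: the feed-forward starts as an identity
        self.project = Conv2d(hidden, d, 1, rng=rng)
        self.project.weight.data[:] = 0.0
        self.residual = cfg.pcfn_residual

    def __call__(self, f) -> Tensor:
        f = _as_tensor(f)
        h = self.expand(self.norm(f)).gelu()
        fa, fb = h[:, : self.n_a], h[:, self.n_a:]
        out = self.project(concatenate([self.local(fa).gelu(), fb], axis=1))
        return out + f if self.residual else out


class GLFN(Module):
    """GLS attention followed by the PCFN feed-forward refinement."""

    def __init__(self, cfg: GLFNConfig, rng=None):
        super().__init__()
        self.attention = GLSAttention(cfg, rng=rng)
        self.pcfn = PCFN(cfg, rng=rng)

    def __call__(self, f) -> Tensor:
        return self.pcfn(self.attention(f))


def contranorm(hb: np.ndarray, params: ContraNormParams) -> np.ndarray:
    """Functional ContraNorm on one (N, D) sample, no affine.

    Row-wise softmax of the raw N x N similarity matrix, subtraction of the
    (s/tau)-scaled attention combination, then layer normalization over the
    feature axis.
    """
    hb = np.asarray(hb, dtype=np.float64)
    if hb.ndim != 2:
        raise ValueError("expected an (N, D) feature matrix")
    with np.errstate(over="ignore", invalid="ignore"):
        sim = hb @ hb.T
    if not np.isfinite(sim).all():
        raise ValueError("non-finite similarities")
    sim -= sim.max(axis=1, keepdims=True)
    e = np.exp(sim)
    attn = e / e.sum(axis=1, keepdims=True)
    h = hb - (params.s / params.tau) * (attn @ hb)
    mu = h.mean(axis=1, keepdims=True)
    var = h.var(axis=1, keepdims=True)
    return (h - mu) / np.sqrt(var + 1e-5)


class ContraNorm(Module):
    """ContraNorm over the point axis with learnable LN affine.

    Input (B, D, N); the similarity/softmax runs per sample over the N
    points; normalization (and the affine) act on the feature axis. With
    s = 0 this reduces to plain layer normalization.
    """

    def __init__(self, channels: int, params: Optional[ContraNormParams] = None,
                 eps: float = 1e-5):
        super().__init__()
        self.params = params or ContraNormParams()
        self.ln = LayerNorm(channels, axis=-1, eps=eps)

    def __call__(self, x) -> Tensor:
        x = _as_tensor(x)                         # (B, D, N)
        h = x.transpose(0, 2, 1)                  # (B, N, D)
        if self.params.s != 0.0:
            attn = (h @ h.transpose(0, 2, 1)).softmax(axis=-1)
            h = h - (attn @ h) * (self.params.s / self.params.tau)
        return self.ln(h).transpose(0, 2, 1)
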