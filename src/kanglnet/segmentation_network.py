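"""KAN-GLNet: a PointNet++-style encoder/decoder for plant organ segmentation.

The encoder is a stack of set-abstraction (SA) levels: farthest-point
sampling picks M centers, a ball query gathers up to K in-radius
neighbors per center (ordered by ascending distance, deficits filled by
repeating the nearest), and a small per-group network -- here rebuilt as
KGL-PointNet -- maps the (D+3) x K x M grouped features to per-center
features. KGL-PointNet applies the configured convolution variant at
each of its three layers (the full model places a reverse-bottleneck KAN
convolution at layer 1), optionally refines the K x N grid with a GLFN
block, max-pools over the neighbor axis, and normalizes the per-center
features with ContraNorm (or batch normalization in the baseline). The
decoder mirrors the encoder with feature-propagation (FP) levels using
inverse-distance weighted 3-NN interpolation and skip links, ending in a
per-point classification head.

Because the convolution kernel can be 3 x 3 over the K x N grouped grid
(neighbors ordered by distance), exact neighbor-permutation invariance
is traded for a richer local operator; with kernel size 1 the blocks are
permutation-invariant like the original Min-PointNet.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import (BatchNorm2d, Conv2d, Module, Tensor, concatenate)
from .glfn_blocks import GLFN, ContraNorm, ContraNormParams, GLFNConfig
from .kan_layers import KanConvSpec, RBFGrid, make_conv

CONV_VARIANTS = ("standard", "reverse_bottleneck", "vanilla", "fastkan")


# ---------------------------------------------------------------------------
# Sampling and grouping


def farthest_point_sample(coords: np.ndarray, m: int,
                          start_index: int = 0) -> np.ndarray:
    """Greedy max-min selection of m indices from (N, 3) coords."""
    coords = np.asarray(coords, dtype=np.float64)
    n = len(coords)
    if m > n:
        raise ValueError(f"cannot sample {m} from {n} points")
    sel = np.empty(m, dtype=np.int64)
    sel[0] = start_index
    dist = np.linalg.norm(coords - coords[start_index], axis=1)
    for i in range(1, m):
        sel[i] = int(np.argmax(dist))
        dist = np.minimum(dist, np.linalg.norm(coords - coords[sel[i]], axis=1))
    return sel


def _batched_fps(coords: np.ndarray, m: int) -> np.ndarray:
    """(B, N, 3) -> (B, m) farthest-point indices, start index 0."""
    B, n, _ = coords.shape
    sel = np.zeros((B, m), dtype=np.int64)
    dist = np.linalg.norm(coords - coords[:, :1], axis=2)
    rows = np.arange(B)
    for i in range(1, m):
        sel[:, i] = np.argmax(dist, axis=1)
        newd = np.linalg.norm(coords - coords[rows, sel[:, i]][:, None], axis=2)
        dist = np.minimum(dist, newd)
    return sel


def ball_query_group(coords: np.ndarray, centers: np.ndarray, radius: float,
                     k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Up to k in-radius neighbors per center, nearest first.

    ``coords``: (B, N, 3); ``centers``: (B, M, 3). Returns
    ``(idx, rel)`` with idx (B, M, K) indices into N (deficits repeat the
    nearest neighbor; an empty ball degenerates to the nearest point,
    which for a center taken from the cloud is the center itself) and
    rel (B, M, K, 3) center-relative coordinates.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if k < 1:
        raise ValueError("K must be >= 1")
    d = np.linalg.norm(coords[:, None] - centers[:, :, None], axis=3)  # B,M,N
    if k < d.shape[2]:
        part = np.argpartition(d, k - 1, axis=2)[:, :, :k]
    else:
        part = np.broadcast_to(np.arange(d.shape[2]), d.shape).copy()[:, :, :k]
    dpart = np.take_along_axis(d, part, axis=2)
    inner = np.argsort(dpart, axis=2, kind="stable")
    order = np.take_along_axis(part, inner, axis=2)
    dsort = np.take_along_axis(dpart, inner, axis=2)
    idx = np.where(dsort <= radius, order, order[:, :, :1])
    B = coords.shape[0]
    rel = coords[np.arange(B)[:, None, None], idx] - centers[:, :, None]
    return idx, rel


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SALevel:
    npoint: int
    radius: float
    k: int
    widths: Tuple[int, ...]

    def __post_init__(self):
        self.widths = tuple(self.widths)


@dataclass
class ModelConfig:
    """Architecture description; presets cover the baseline and all variants."""

    sa_levels: List[SALevel]
    fp_levels: List[Tuple[int, ...]]
    head_width: int = 32
    num_classes: int = 2
    in_channels: int = 6                   # xyz (relative) handled separately
    use_contranorm: bool = False
    use_glfn: bool = False
    conv_variants: Tuple[str, str, str] = ("standard", "standard", "standard")
    kan_kernel: int = 3
    rbf_grid_size: int = 8
    expansion: float = 2.0
    contra_s: float = 0.1
    contra_tau: float = 1.0
    points: int = 1024
    seed: int = 0

    def __post_init__(self):
        if not self.sa_levels or not self.fp_levels:
            raise ValueError("need at least one SA and one FP level")
        if len(self.sa_levels) != len(self.fp_levels):
            raise ValueError("fp_levels must mirror sa_levels")
        for v in self.conv_variants:
            if v not in CONV_VARIANTS:
                raise ValueError(f"unknown conv variant {v!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["sa_levels"] = [SALevel(**lv) if isinstance(lv, dict) else SALevel(*lv)
                          for lv in d["sa_levels"]]
        d["fp_levels"] = [tuple(w) for w in d["fp_levels"]]
        d["conv_variants"] = tuple(d["conv_variants"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Blocks


class KGLPointNetBlock(Module):
    """Per-group feature extractor applied on the (D, K, M) grouped grid."""

    def __init__(self, c_in: int, cfg: ModelConfig, widths: Sequence[int],
                 rng: np.random.Generator):
        super().__init__()
        self.layers: List[Module] = []
        self.norms: List[Module] = []
        self.kinds: List[str] = []
        grid = RBFGrid(np.linspace(-2.0, 2.0, cfg.rbf_grid_size))
        prev = c_in
        for i, width in enumerate(widths):
            variant = cfg.conv_variants[i] if i < len(cfg.conv_variants) \
                else "standard"
            if variant == "standard":
                self.layers.append(Conv2d(prev, width, 1, rng=rng))
            else:
                spec = KanConvSpec(variant=variant, k=cfg.kan_kernel,
                                   c_in=prev, c_out=width, grid=grid,
                                   expansion=cfg.expansion, padding="same")
                self.layers.append(make_conv(spec, rng))
            self.norms.append(BatchNorm2d(width))
            self.kinds.append(variant)
            prev = width
        self.glfn = GLFN(GLFNConfig(prev), rng=rng) if cfg.use_glfn else None
        self.out_channels = prev

    def __call__(self, group: Tensor) -> Tensor:
        """(B, D, K, M) grouped features -> (B, D', M) pooled per-center."""
        h = group
        for layer, norm, kind in zip(self.layers, self.norms, self.kinds):
            h = norm(layer(h))
            if kind == "standard":
                h = h.relu()
        if self.glfn is not None:
            h = self.glfn(h)
        return h.max(axis=2)                                     # pool over K


class _PointNorm(Module):
    """Post-SA/FP normalization: ContraNorm when enabled, else batch norm."""

    def __init__(self, channels: int, cfg: ModelConfig):
        super().__init__()
        if cfg.use_contranorm:
            self.norm = ContraNorm(channels,
                                   ContraNormParams(cfg.contra_s, cfg.contra_tau))
            self.is_contra = True
        else:
            self.norm = BatchNorm2d(channels)
            self.is_contra = False

    def __call__(self, x: Tensor) -> Tensor:                      # (B, C, N)
        if self.is_contra:
            return self.norm(x)
        B, C, N = x.shape
        return self.norm(x.reshape(B, C, 1, N)).reshape(B, C, N)


class SAModule(Module):
    def __init__(self, level: SALevel, c_in: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.level = level
        self.block = KGLPointNetBlock(c_in + 3, cfg, level.widths, rng)
        self.post = _PointNorm(self.block.out_channels, cfg)

    def __call__(self, coords: np.ndarray, feats: Tensor):
        B = coords.shape[0]
        sel = _batched_fps(coords, self.level.npoint)
        centers = coords[np.arange(B)[:, None], sel]              # (B, M, 3)
        idx, rel = ball_query_group(coords, centers, self.level.radius,
                                    self.level.k)
        gathered = feats.transpose(0, 2, 1)[
            np.arange(B)[:, None, None], idx]                     # (B, M, K, C)
        grouped = concatenate(
            [Tensor(np.ascontiguousarray(rel.transpose(0, 3, 2, 1))),
             gathered.transpose(0, 3, 2, 1)], axis=1)             # (B, C+3, K, M)
        return centers, self.post(self.block(grouped))


def inverse_distance_interpolate(coords_fine: np.ndarray,
                                 coords_coarse: np.ndarray,
                                 feats_coarse: Tensor) -> Tensor:
    """Inverse-distance weighted 3-NN feature interpolation.

    Maps (B, C, M2) features at coarse positions to (B, C, M1) at fine
    positions; a query coinciding with a coarse point copies that point's
    feature exactly (distance-zero weighting).
    """
    B, M1, _ = coords_fine.shape
    d = np.linalg.norm(coords_fine[:, :, None] - coords_coarse[:, None],
                       axis=3)                                    # (B, M1, M2)
    nn = min(3, coords_coarse.shape[1])
    idx = np.argsort(d, axis=2, kind="stable")[:, :, :nn]
    dn = np.take_along_axis(d, idx, axis=2)
    w = 1.0 / np.maximum(dn, 1e-10)
    w /= w.sum(axis=2, keepdims=True)
    exact = dn[:, :, 0] < 1e-10
    w[exact] = 0.0
    w[exact, 0] = 1.0
    gathered = feats_coarse.transpose(0, 2, 1)[
        np.arange(B)[:, None, None], idx]                         # (B, M1, nn, C)
    interp = (gathered * Tensor(w[..., None])).sum(axis=2)        # (B, M1, C)
    return interp.transpose(0, 2, 1)


class FPModule(Module):
    """Inverse-distance 3-NN interpolation with skip link and shared MLP."""

    def __init__(self, c_coarse: int, c_skip: int, widths: Sequence[int],
                 cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.convs: List[Conv2d] = []
        self.bns: List[BatchNorm2d] = []
        prev = c_coarse + c_skip
        for w in widths:
            self.convs.append(Conv2d(prev, w, 1, rng=rng))
            self.bns.append(BatchNorm2d(w))
            prev = w
        self.post = _PointNorm(prev, cfg)
        self.out_channels = prev

    def __call__(self, coords_fine, coords_coarse, feats_coarse: Tensor,
                 feats_skip: Optional[Tensor]):
        B, M1, _ = coords_fine.shape
        h = inverse_distance_interpolate(coords_fine, coords_coarse,
                                         feats_coarse)            # (B, C, M1)
        if feats_skip is not None:
            h = concatenate([h, feats_skip], axis=1)
        h = h.reshape(B, h.shape[1], 1, M1)
        for conv, bn in zip(self.convs, self.bns):
            h = bn(conv(h)).relu()
        return self.post(h.reshape(B, self.out_channels, M1))


class SegmentationModel(Module):
    """Encoder/decoder point network with a per-point classification head."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        self.sa: List[SAModule] = []
        c = cfg.in_channels
        enc_channels = [c]
        for level in cfg.sa_levels:
            mod = SAModule(level, c, cfg, rng)
            self.sa.append(mod)
            c = mod.block.out_channels
            enc_channels.append(c)
        self.fp: List[FPModule] = []
        for i, widths in enumerate(cfg.fp_levels):
            lvl = len(cfg.sa_levels) - 1 - i          # decode from deepest
            skip = enc_channels[lvl]
            mod = FPModule(c, skip, widths, cfg, rng)
            self.fp.append(mod)
            c = mod.out_channels
        self.head1 = Conv2d(c, cfg.head_width, 1, rng=rng)
        self.head_bn = BatchNorm2d(cfg.head_width)
        self.head2 = Conv2d(cfg.head_width, cfg.num_classes, 1, rng=rng)

    def __call__(self, coords: np.ndarray, feats) -> Tensor:
        """coords (B, N, 3), feats (B, C_in, N) -> logits (B, classes, N)."""
        feats = feats if isinstance(feats, Tensor) else Tensor(feats)
        if feats.shape[1] != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} input "
                             f"feature channels, got {feats.shape[1]}")
        coords_stack = [coords]
        feats_stack = [feats]
        for sa in self.sa:
            c_next, f_next = sa(coords_stack[-1], feats_stack[-1])
            coords_stack.append(c_next)
            feats_stack.append(f_next)
        h = feats_stack[-1]
        pos = len(coords_stack) - 1
        for fp in self.fp:
            h = fp(coords_stack[pos - 1], coords_stack[pos], h,
                   feats_stack[pos - 1])
            pos -= 1
        B, C, N = h.shape
        h = self.head_bn(self.head1(h.reshape(B, C, 1, N))).relu()
        return self.head2(h).reshape(B, self.config.num_classes, N)


def count_parameters(model: Module) -> int:
    """Exact count of learnable scalars."""
    return model.num_parameters()


# ---------------------------------------------------------------------------
# Presets


def _tiny_levels():
    return ([SALevel(256, 0.25, 16, (16, 16, 32)),
             SALevel(64, 0.5, 16, (32, 32, 64))],
            [(48, 32), (32, 32)])


def _reference_levels():
    return ([SALevel(1024, 0.1, 32, (32, 32, 64)),
             SALevel(256, 0.2, 32, (64, 64, 128)),
             SALevel(64, 0.4, 32, (128, 128, 256)),
             SALevel(16, 0.8, 32, (256, 256, 512))],
            [(256, 256), (256, 256), (256, 128), (128, 128, 128)])


def build_model(cfg: ModelConfig) -> SegmentationModel:
    return SegmentationModel(cfg)


def make_config(preset: str = "kan_glnet_full", size: str = "tiny",
                seed: int = 0, *, use_contranorm: Optional[bool] = None,
                use_glfn: Optional[bool] = None,
                conv_variants: Optional[Tuple[str, str, str]] = None,
                points: Optional[int] = None) -> ModelConfig:
    """Named model variants.

    ``baseline_pointnet2``: shared-MLP blocks, batch norm everywhere.
    ``kan_glnet_full``: reverse-bottleneck KAN at layer 1 + GLFN + ContraNorm.
    Ablation combinations and conv-position variants are reachable through
    the keyword overrides.
    """
    sa, fp = _tiny_levels() if size == "tiny" else _reference_levels()
    presets = {
        "baseline_pointnet2": dict(use_contranorm=False, use_glfn=False,
                                   conv_variants=("standard",) * 3),
        "kan_glnet_full": dict(use_contranorm=True, use_glfn=True,
                               conv_variants=("reverse_bottleneck",
                                              "standard", "standard")),
    }
    if preset not in presets:
        raise ValueError(f"unknown preset {preset!r}")
    kw = presets[preset]
    if use_contranorm is not None:
        kw["use_contranorm"] = use_contranorm
    if use_glfn is not None:
        kw["use_glfn"] = use_glfn
    if conv_variants is not None:
        kw["conv_variants"] = tuple(conv_variants)
    cfg = ModelConfig(sa_levels=sa, fp_levels=fp, seed=seed,
                      points=points or (1024 if size == "tiny" else 4096),
                      **kw)
    return cfg


def ablation_config(contranorm: bool, glfn: bool, rb_kan: bool,
                    size: str = "tiny", seed: int = 0) -> ModelConfig:
    """One row of the module-combination ablation grid."""
    variants = ("reverse_bottleneck", "standard", "standard") if rb_kan \
        else ("standard",) * 3
    return make_config("baseline_pointnet2", size=size, seed=seed,
                       use_contranorm=contranorm, use_glfn=glfn,
                       conv_variants=variants)


def forward_segment(model: SegmentationModel, coords: np.ndarray,
                    colors: np.ndarray, seed: int = 0) -> np.ndarray:
    """Per-point class logits (N, classes) for one cloud of any size.

    The cloud is processed in seeded random chunks of the configured point
    count (the last chunk padded by resampling); every point receives
    exactly one prediction.
    """
    n = len(coords)
    pts = model.config.points
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    logits = np.zeros((n, model.config.num_classes))
    model.eval()
    for start in range(0, n, pts):
        chunk = order[start:start + pts]
        pad = pts - len(chunk)
        idx = np.concatenate([chunk, rng.choice(n, pad)]) if pad else chunk
        c = coords[idx][None]
        f = np.concatenate([coords[idx], colors[idx]], axis=1).T[None]
        out = model(c, f).data[0].T                              # (pts, C)
        logits[chunk] = out[: len(chunk)]
    return logits
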