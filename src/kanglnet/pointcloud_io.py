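"""Plant point-cloud containers, PLY I/O, preprocessing and augmentation.

A plant scan is carried as a :class:`PointCloud` (N x 3 coordinates plus
N x 3 RGB colors in [0, 1]) or a :class:`LabeledCloud` which adds a
per-point semantic class (0 = stem, 1 = silique) and an optional positive
silique-instance id. Preprocessing mirrors the usual reconstruction
cleanup chain: radius / statistical outlier filters, uniform
downsampling into the 20k-30k point working regime, and unit-sphere
normalization. Augmentation and the train/val/test split follow the
protocol used for small plant datasets: split first, then expand each
subset with random dropout, Z-rotation, isotropic scaling and Y-flips.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import ply as _ply

SEM_STEM = 0
SEM_SILIQUE = 1


class ParameterError(ValueError):
    """Raised for out-of-contract filter or split parameters."""


class EmptyCloudError(ValueError):
    """Raised when a PLY file contains no vertices."""


@dataclass
class PointCloud:
    """N x 3 coordinates with N x 3 RGB colors in [0, 1]."""

    coords: np.ndarray
    colors: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an N x 3 array")
        if self.colors is None:
            self.colors = np.full_like(self.coords, 0.5)
        self.colors = np.asarray(self.colors, dtype=np.float64)
        if self.colors.shape != self.coords.shape:
            raise ValueError("colors must match coords shape")
        if not (np.isfinite(self.coords).all() and np.isfinite(self.colors).all()):
            raise ValueError("coordinates and colors must be finite")
        if len(self.colors) and (self.colors.min() < 0 or self.colors.max() > 1):
            raise ValueError("colors must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.coords)

    def select(self, index) -> "PointCloud":
        return PointCloud(self.coords[index], self.colors[index])


@dataclass
class LabeledCloud:
    """A PointCloud plus per-point semantic class and optional instance id.

    ``semantic`` values are in {0, 1}; ``instance`` ids are > 0 exactly on
    silique points (0 elsewhere) when present.
    """

    cloud: PointCloud
    semantic: Optional[np.ndarray] = None
    instance: Optional[np.ndarray] = None

    def __post_init__(self):
        n = len(self.cloud)
        if self.semantic is not None:
            self.semantic = np.asarray(self.semantic, dtype=np.int64)
            if self.semantic.shape != (n,):
                raise ValueError("semantic labels must be length N")
            if not np.isin(self.semantic, (SEM_STEM, SEM_SILIQUE)).all():
                raise ValueError("semantic values must be 0 (stem) or 1 (silique)")
        if self.instance is not None:
            if self.semantic is None:
                raise ValueError("instance ids require semantic labels")
            self.instance = np.asarray(self.instance, dtype=np.int64)
            if self.instance.shape != (n,):
                raise ValueError("instance ids must be length N")
            if ((self.instance > 0) & (self.semantic != SEM_SILIQUE)).any():
                raise ValueError("instance id > 0 only allowed on silique points")

    def __len__(self) -> int:
        return len(self.cloud)

    def select(self, index) -> "LabeledCloud":
        return LabeledCloud(
            self.cloud.select(index),
            None if self.semantic is None else self.semantic[index],
            None if self.instance is None else self.instance[index],
        )


@dataclass
class AugmentConfig:
    """Random augmentation draw ranges (one draw per generated copy)."""

    dropout_max: float = 0.30
    rot_z_range: float = 180.0          # degrees, symmetric about 0
    scale_range: tuple = (0.9, 1.1)
    flip_y_prob: float = 0.20
    copies: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout_max < 1:
            raise ParameterError("dropout_max must be in [0, 1)")
        if min(self.scale_range) <= 0:
            raise ParameterError("scale_range must be positive")
        if not 0 <= self.flip_y_prob <= 1:
            raise ParameterError("flip_y_prob must be a probability")


@dataclass
class SplitSpec:
    """Train/val/test ratio spec, normalized to sum 1."""

    ratios: tuple = (7.0, 1.0, 2.0)
    seed: int = 0

    def __post_init__(self):
        r = np.asarray(self.ratios, dtype=float)
        if r.shape != (3,) or (r < 0).any() or r.sum() == 0:
            raise ParameterError("ratios must be three non-negative reals, not all zero")
        self.ratios = tuple(r / r.sum())


# ---------------------------------------------------------------------------
# PLY I/O


def read_ply(path) -> LabeledCloud:
    """Read a PLY point cloud with optional color and label properties.

    8-bit colors are rescaled to [0, 1]. Semantic labels are read from a
    ``label`` vertex property or, failing that, a ``<path>.labels`` sidecar
    text file (one integer per line); instance ids from an ``instance``
    property or ``<path>.instances`` sidecar.
    """
    verts = _ply.read_ply_vertices(path)
    names = verts.dtype.names
    for axis in ("x", "y", "z"):
        if axis not in names:
            raise _ply.PLYFormatError(f"PLY missing required '{axis}' property")
    if verts.shape[0] == 0:
        raise EmptyCloudError(f"{path}: zero vertices")
    coords = np.stack([verts["x"], verts["y"], verts["z"]], axis=1).astype(np.float64)
    if all(c in names for c in ("red", "green", "blue")):
        cols = np.stack([verts["red"], verts["green"], verts["blue"]], axis=1)
        colors = cols.astype(np.float64)
        if verts.dtype["red"].kind == "u":
            colors /= 255.0
        colors = np.clip(colors, 0.0, 1.0)
    else:
        colors = None
    semantic = verts["label"].astype(np.int64) if "label" in names else None
    instance = verts["instance"].astype(np.int64) if "instance" in names else None
    if semantic is None:
        sidecar = str(path) + ".labels"
        try:
            semantic = np.loadtxt(sidecar, dtype=np.int64, ndmin=1)
        except OSError:
            semantic = None
    if semantic is not None and instance is None:
        sidecar = str(path) + ".instances"
        try:
            instance = np.loadtxt(sidecar, dtype=np.int64, ndmin=1)
        except OSError:
            instance = None
    return LabeledCloud(PointCloud(coords, colors), semantic, instance)


def write_ply(labeled: LabeledCloud, path) -> None:
    """Write a LabeledCloud as binary PLY; labels become integer properties."""
    n = len(labeled)
    fields = [("x", "<f4"), ("y", "<f4"), ("z", "<f4"),
              ("red", "u1"), ("green", "u1"), ("blue", "u1")]
    if labeled.semantic is not None:
        fields.append(("label", "<i4"))
    if labeled.instance is not None:
        fields.append(("instance", "<i4"))
    arr = np.empty(n, dtype=np.dtype(fields))
    arr["x"], arr["y"], arr["z"] = labeled.cloud.coords.T.astype(np.float32)
    rgb = np.clip(np.round(labeled.cloud.colors * 255.0), 0, 255).astype(np.uint8)
    arr["red"], arr["green"], arr["blue"] = rgb.T
    if labeled.semantic is not None:
        arr["label"] = labeled.semantic
    if labeled.instance is not None:
        arr["instance"] = labeled.instance
    _ply.write_ply_vertices(path, arr)


# ---------------------------------------------------------------------------
# Filters and conditioning


def statistical_outlier_removal(cloud: PointCloud, k: int = 16,
                                std_ratio: float = 2.0):
    """Drop points whose mean k-NN distance is > global mean + ratio * std.

    Returns ``(kept_cloud, removed_indices)`` with input order preserved
    among kept points.
    """
    n = len(cloud)
    if k >= n:
        raise ParameterError(f"k={k} must be < N={n}")
    if std_ratio <= 0:
        raise ParameterError("std_ratio must be > 0")
    tree = cKDTree(cloud.coords)
    dists, _ = tree.query(cloud.coords, k=k + 1)  # first neighbor is self
    mean_d = dists[:, 1:].mean(axis=1)
    thresh = mean_d.mean() + std_ratio * mean_d.std()
    keep = mean_d <= thresh
    removed = np.flatnonzero(~keep)
    return cloud.select(keep), removed


def radius_outlier_removal(cloud: PointCloud, radius: float,
                           min_neighbors: int = 1) -> PointCloud:
    """Keep points with at least ``min_neighbors`` others within ``radius``."""
    if radius <= 0:
        raise ParameterError("radius must be > 0")
    if min_neighbors < 1:
        raise ParameterError("min_neighbors must be >= 1")
    tree = cKDTree(cloud.coords)
    counts = np.asarray(tree.query_ball_point(
        cloud.coords, radius, return_length=True))
    return cloud.select(counts - 1 >= min_neighbors)  # exclude self


def uniform_downsample(obj, target_min: int, target_max: int):
    """Keep every s-th point with s = ceil(N / target_max), order preserved.

    Accepts a PointCloud or LabeledCloud; no-op when N already in range.
    """
    n = len(obj)
    if target_min > target_max:
        raise ParameterError("target_min must be <= target_max")
    if n < target_min:
        raise ParameterError(f"cloud of {n} points below target_min={target_min}")
    if n <= target_max:
        return obj
    s = int(np.ceil(n / target_max))
    idx = np.arange(0, n, s)
    if len(idx) < target_min:
        raise ParameterError("infeasible downsampling range for this cloud")
    return obj.select(idx)


def normalize_cloud(cloud: PointCloud):
    """Center on the centroid and scale by the max point norm.

    Returns ``(normalized_cloud, centroid, scale)`` so results computed in
    the normalized frame can be mapped back (e.g. clustering radii).
    """
    centroid = cloud.coords.mean(axis=0)
    centered = cloud.coords - centroid
    scale = float(np.linalg.norm(centered, axis=1).max())
    if scale == 0.0:
        scale = 1.0
    return PointCloud(centered / scale, cloud.colors), centroid, scale


# ---------------------------------------------------------------------------
# Augmentation and splitting


def augment_cloud(labeled: LabeledCloud, cfg: AugmentConfig,
                  rng: np.random.Generator) -> LabeledCloud:
    """One random augmented copy: dropout, Z-rotation, scale, optional Y-flip.

    The dropout fraction is drawn uniformly in [0, dropout_max] and removes
    floor(fraction * N) points; labels are removed in lockstep.
    """
    n = len(labeled)
    frac = rng.uniform(0.0, cfg.dropout_max) if cfg.dropout_max > 0 else 0.0
    n_drop = int(np.floor(frac * n))
    if n - n_drop < 2:
        raise ParameterError("dropout would leave fewer than 2 points")
    out = labeled
    if n_drop > 0:
        keep = np.sort(rng.choice(n, size=n - n_drop, replace=False))
        out = out.select(keep)
    theta = np.deg2rad(rng.uniform(-cfg.rot_z_range, cfg.rot_z_range))
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    scale = rng.uniform(*cfg.scale_range)
    coords = (out.cloud.coords @ rot.T) * scale
    if rng.uniform() < cfg.flip_y_prob:
        coords = coords * np.array([1.0, -1.0, 1.0])
    return LabeledCloud(PointCloud(coords, out.cloud.colors),
                        out.semantic, out.instance)


def augment_dataset(clouds: Sequence[LabeledCloud], cfg: AugmentConfig):
    """Replace each cloud by ``cfg.copies`` independent augmented copies."""
    rng = np.random.default_rng(cfg.seed)
    out = []
    for cl in clouds:
        for _ in range(cfg.copies):
            out.append(augment_cloud(cl, cfg, rng))
    return out


def split_dataset(clouds: Sequence, spec: SplitSpec):
    """Shuffle and split into train/val/test by rounded ratios.

    Splitting happens before any augmentation; subsets are disjoint and
    exhaustive, and membership is deterministic given ``spec.seed``.
    """
    n = len(clouds)
    if n < 10:
        raise ParameterError("need at least 10 clouds to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    r = np.asarray(spec.ratios)
    n_train = int(round(n * r[0]))
    n_val = int(round(n * r[1]))
    n_train = min(n_train, n - 2)
    n_val = max(1, min(n_val, n - n_train - 1))
    train = [clouds[i] for i in order[:n_train]]
    val = [clouds[i] for i in order[n_train:n_train + n_val]]
    test = [clouds[i] for i in order[n_train + n_val:]]
    return train, val, test
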