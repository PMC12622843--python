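"""Silique instance counting: SOR-filtered DBSCAN with grid search.

The counting workflow extracts silique-class points from a semantically
segmented cloud, removes sparse noise with statistical outlier removal
(SOR, k = 16, std_ratio = 2.0 by default), clusters the remainder with
DBSCAN (eps = 0.10, min_samples = 5 by default; eps is interpreted in
the coordinate frame of the preprocessed cloud), and reports the number
of clusters, excluding noise. Without the SOR step, small clumps of
mislabeled points form spurious clusters and inflate the count.

The grid search evaluates the pipeline over eps in [0.05, 0.20] and
min_samples in [1, 15] against ground-truth counts and returns the
parameters minimizing the mean absolute count error, breaking ties
toward larger min_samples (more noise suppression) and then smaller eps
(better separation of adjacent organs).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import DBSCAN

from .pointcloud_io import (LabeledCloud, PointCloud, SEM_SILIQUE,
                            statistical_outlier_removal)


@dataclass
class DBSCANParams:
    eps: float = 0.10
    min_samples: int = 5

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


@dataclass
class ClusterResult:
    """Per-point cluster labels (-1 = noise) with contiguous ids 0..k-1."""

    labels: np.ndarray
    n_clusters: int
    params: DBSCANParams

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        ids = np.unique(self.labels[self.labels >= 0])
        if len(ids) != self.n_clusters or \
                (len(ids) and (ids != np.arange(len(ids))).any()):
            raise ValueError("cluster ids must be contiguous 0..n_clusters-1")


@dataclass
class GridSearchSpec:
    eps_values: Sequence[float] = field(
        default_factory=lambda: np.round(np.arange(0.05, 0.201, 0.01), 3))
    min_samples_values: Sequence[int] = field(
        default_factory=lambda: range(1, 16))

    def __post_init__(self):
        self.eps_values = [float(e) for e in self.eps_values]
        self.min_samples_values = [int(m) for m in self.min_samples_values]
        if not self.eps_values or not self.min_samples_values:
            raise ValueError("grid must be non-empty")


@dataclass
class CountResult:
    count: int
    clusters: ClusterResult
    kept_indices: np.ndarray        # indices into the original cloud
    sor_removed: np.ndarray         # original indices removed by SOR
    noise_indices: np.ndarray       # original indices labeled noise by DBSCAN


def extract_class_points(labeled: LabeledCloud, class_id: int
                         ) -> Tuple[Optional[PointCloud], np.ndarray]:
    """Subset cloud of one semantic class plus back-mapping indices."""
    if labeled.semantic is None:
        raise ValueError("semantic labels required")
    if class_id not in (0, 1):
        warnings.warn(f"class_id {class_id} outside {{0, 1}}; empty subset")
    idx = np.flatnonzero(labeled.semantic == class_id)
    if len(idx) == 0:
        return None, idx
    return labeled.cloud.select(idx), idx


def dbscan_cluster(cloud: PointCloud, params: DBSCANParams) -> ClusterResult:
    """Standard DBSCAN semantics; cluster ids renumbered by first occurrence."""
    raw = DBSCAN(eps=params.eps, min_samples=params.min_samples).fit_predict(
        cloud.coords)
    labels = np.full(len(raw), -1, dtype=np.int64)
    next_id = 0
    remap = {}
    for i, lab in enumerate(raw):
        if lab < 0:
            continue
        if lab not in remap:
            remap[lab] = next_id
            next_id += 1
        labels[i] = remap[lab]
    return ClusterResult(labels, next_id, params)


def count_instances(labeled: LabeledCloud,
                    dbscan: DBSCANParams | None = None,
                    sor_k: int = 16, sor_std: float = 2.0,
                    use_sor: bool = True) -> CountResult:
    """Silique points -> (optional SOR) -> DBSCAN -> cluster count.

    Noise points and SOR-removed points are reported separately through
    the returned :class:`CountResult`.
    """
    dbscan = dbscan or DBSCANParams()
    subset, idx = extract_class_points(labeled, SEM_SILIQUE)
    if subset is None:
        empty = np.empty(0, dtype=np.int64)
        return CountResult(0, ClusterResult(empty, 0, dbscan), empty, empty,
                           empty)
    if use_sor and len(subset) > sor_k:
        kept_cloud, removed_local = statistical_outlier_removal(
            subset, k=sor_k, std_ratio=sor_std)
        keep_mask = np.ones(len(subset), dtype=bool)
        keep_mask[removed_local] = False
        kept_idx = idx[keep_mask]
        sor_removed = idx[removed_local]
    else:
        kept_cloud, kept_idx = subset, idx
        sor_removed = np.empty(0, dtype=np.int64)
    result = dbscan_cluster(kept_cloud, dbscan)
    noise = kept_idx[result.labels < 0]
    return CountResult(result.n_clusters, result, kept_idx, sor_removed, noise)


def parameter_grid_search(plants: Sequence[Tuple[LabeledCloud, int]],
                          spec: GridSearchSpec | None = None,
                          sor_k: int = 16, sor_std: float = 2.0
                          ) -> Tuple[DBSCANParams, np.ndarray]:
    """Mean |count error| over the (eps, min_samples) grid.

    ``plants`` is a sequence of (labeled cloud, ground-truth count).
    Returns the best parameters and the full score grid of shape
    (len(eps_values), len(min_samples_values)). SOR filtering does not
    depend on the grid parameters, so it is applied once per cloud.
    """
    spec = spec or GridSearchSpec()
    if not plants:
        raise ValueError("need at least one cloud with a known count")
    filtered = []
    truths = []
    for labeled, truth in plants:
        subset, _ = extract_class_points(labeled, SEM_SILIQUE)
        if subset is not None and len(subset) > sor_k:
            subset, _ = statistical_outlier_removal(subset, k=sor_k,
                                                    std_ratio=sor_std)
        filtered.append(subset)
        truths.append(truth)
    grid = np.zeros((len(spec.eps_values), len(spec.min_samples_values)))
    for i, eps in enumerate(spec.eps_values):
        for j, ms in enumerate(spec.min_samples_values):
            errs = []
            for subset, truth in zip(filtered, truths):
                count = 0 if subset is None else dbscan_cluster(
                    subset, DBSCANParams(eps, ms)).n_clusters
                errs.append(abs(count - truth))
            grid[i, j] = float(np.mean(errs))
    # argmin with ties broken by larger min_samples, then smaller eps
    best = None
    for i, eps in enumerate(spec.eps_values):
        for j, ms in enumerate(spec.min_samples_values):
            key = (grid[i, j], -ms, eps)
            if best is None or key < best[0]:
                best = (key, DBSCANParams(eps, ms))
    return best[1], grid
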