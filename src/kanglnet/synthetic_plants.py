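"""Seeded synthetic canola-like plants for testing, training and calibration.

A plant is a branching stem skeleton carrying elongated silique capsules:
the main stem is a noisy vertical polyline, branches arc outward and
upward from it, and each silique is a tapered prolate capsule on a short
pedicel near a branch. Geometry is parametric rather than botanically
simulated; it is calibrated to the observable statistics that matter
downstream -- a 20k-30k point budget per plant, instance counts spanning
the high-yield range, crowded but separable capsules whose inter-surface
gaps straddle the clustering radius eps = 0.10, and heterogeneous
point density (reconstruction-like) so density-based clustering has a
genuine operating window:

* non-twin capsule pairs keep a surface gap of at least
  0.30 - 0.40 * overlap_level (about 0.14 at the default crowding);
* a quarter of the capsules are "twin" pods placed at gaps of
  0.13-0.17, which merge only when the clustering radius is too large;
* per-capsule surface density is drawn log-uniformly over a wide range
  and each capsule has a sparser waist at its middle (the replum
  constriction), so overly small radii fragment sparse capsules and
  overly large neighbor-count thresholds erode or split them.

Noise emulates reconstruction and segmentation artifacts: Gaussian
coordinate jitter, plus silique-labeled outliers in three flavors --
small mislabeled clumps sitting on the stem/branch surface (the
segmentation-error false clusters that break counting without SOR),
sparse uniform points in an inflated bounding box, and tiny floater
specks. All outliers are flagged and carry instance id 0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .pointcloud_io import (LabeledCloud, PointCloud, SEM_SILIQUE, SEM_STEM,
                            uniform_downsample)


@dataclass
class PlantSpec:
    """Generation parameters for one synthetic plant."""

    n_siliques: Optional[int] = None          # None: draw 50-300
    silique_length: Tuple[float, float] = (0.30, 0.50)
    silique_radius: Tuple[float, float] = (0.022, 0.035)
    branch_levels: int = 2
    points_per_silique: Optional[Tuple[int, int]] = None   # None: density-based
    points_per_stem_unit: Optional[float] = None           # None: fill budget
    silique_density: Tuple[float, float] = (900.0, 1300.0)  # points / unit^2
    small_pod_fraction: float = 0.05      # immature pods of 8-14 points
    jitter_sigma: float = 0.006
    outlier_fraction: float = 0.01
    overlap_level: float = 0.4
    total_points: int = 24000
    seed: int = 0

    def __post_init__(self):
        if self.n_siliques is not None and self.n_siliques < 1:
            raise ValueError("n_siliques must be >= 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if not 0 <= self.overlap_level <= 1:
            raise ValueError("overlap_level must be in [0, 1]")


@dataclass
class SyntheticPlant:
    labeled: LabeledCloud
    true_count: int
    outlier_mask: np.ndarray

    def __post_init__(self):
        self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
        if self.outlier_mask.shape != (len(self.labeled),):
            raise ValueError("outlier_mask must be length N")
        ids = self.labeled.instance
        if ids is not None:
            distinct = len(np.unique(ids[ids > 0]))
            if distinct != self.true_count:
                raise ValueError("true_count must equal distinct instance ids")


# ---------------------------------------------------------------------------
# Geometry helpers


def _segment_distances(p0, p1, q0s, q1s):
    """Min distance between segment (p0,p1) and each segment (q0s[i],q1s[i])."""
    q0s = np.atleast_2d(q0s)
    q1s = np.atleast_2d(q1s)
    d1 = p1 - p0
    d2 = q1s - q0s
    r = p0 - q0s
    a = float(d1 @ d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)                 # d2 . r
    c = np.einsum("j,ij->i", d1, r)                  # d1 . r
    b = np.einsum("j,ij->i", d1, d2)
    denom = a * e - b * b
    s = np.where(denom > 1e-12, np.clip((b * f - c * e) / np.where(
        denom > 1e-12, denom, 1.0), 0.0, 1.0), 0.0)
    t = np.where(e > 1e-12, np.clip((b * s + f) / np.where(
        e > 1e-12, e, 1.0), 0.0, 1.0), 0.0)
    # re-clamp s for clamped t
    s = np.clip(np.where(a > 1e-12, (b * t - c) / max(a, 1e-12), 0.0), 0.0, 1.0)
    closest_p = p0 + s[:, None] * d1
    closest_q = q0s + t[:, None] * d2
    return np.linalg.norm(closest_p - closest_q, axis=1)


def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _perp_basis(axis):
    a = _unit(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else \
        np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(a, helper))
    return u, np.cross(a, u)


def _sample_cylinder(rng, start, end, radius, n):
    t = rng.uniform(0, 1, n)
    axis = end - start
    u, v = _perp_basis(axis)
    phi = rng.uniform(0, 2 * np.pi, n)
    rr = radius * np.sqrt(rng.uniform(0.2, 1.0, n))
    return (start + t[:, None] * axis
            + rr[:, None] * (np.cos(phi)[:, None] * u
                             + np.sin(phi)[:, None] * v))


def _sample_capsule(rng, p0, axis_dir, length, radius, n, waist_len=0.13,
                    waist_factor=0.35):
    """Tapered capsule surface points with a sparser middle waist."""
    half = min(0.3, waist_len / (2.0 * length))
    t = np.empty(0)
    while len(t) < n:                       # rejection-sample waist density dip
        cand = rng.uniform(0, 1, max(16, 2 * n))
        keep = ~((np.abs(cand - 0.5) < half)
                 & (rng.uniform(0, 1, len(cand)) > waist_factor))
        t = np.concatenate([t, cand[keep]])
    t = t[:n]
    taper = (1.0 - (2.0 * t - 1.0) ** 2) ** 0.25     # ellipsoidal-ish profile
    u, v = _perp_basis(axis_dir)
    phi = rng.uniform(0, 2 * np.pi, n)
    rr = radius * taper
    return (p0 + t[:, None] * (length * _unit(axis_dir))
            + rr[:, None] * (np.cos(phi)[:, None] * u
                             + np.sin(phi)[:, None] * v))


# ---------------------------------------------------------------------------
# Generation


def _build_skeleton(rng, n_branches, height=2.2, levels=2):
    """Main stem + branch polylines; returns list of (start, end) segments
    per structure and per-branch attachment frames."""
    stem_pts = [np.array([0.0, 0.0, 0.0])]
    z = 0.0
    drift = np.zeros(2)
    while z < height:
        z += height / 12.0
        drift += rng.normal(0, 0.015, 2)
        stem_pts.append(np.array([drift[0], drift[1], z]))
    stem = np.array(stem_pts)
    golden = np.pi * (3 - np.sqrt(5))
    branches = []
    for b in range(n_branches):
        hfrac = rng.uniform(0.35, 0.95)
        base_idx = min(int(hfrac * (len(stem) - 1)), len(stem) - 2)
        base = stem[base_idx] + (stem[base_idx + 1] - stem[base_idx]) * \
            rng.uniform(0, 1)
        az = b * golden + rng.normal(0, 0.3)
        elev = rng.uniform(np.deg2rad(25), np.deg2rad(70))
        direction = np.array([np.cos(az) * np.sin(elev),
                              np.sin(az) * np.sin(elev), np.cos(elev)])
        pts = [base.copy()]
        d = direction.copy()
        seg = 0.18
        for _ in range(rng.integers(10, 16)):
            d = _unit(d + np.array([0, 0, 0.06]) + rng.normal(0, 0.05, 3))
            pts.append(pts[-1] + d * seg)
        branches.append(np.array(pts))
    return stem, branches


def _arc_points(poly, fracs):
    """Points along a polyline at given arc-length fractions, with tangents."""
    seg = np.diff(poly, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0], np.cumsum(lens)])
    targets = np.asarray(fracs) * cum[-1]
    idx = np.clip(np.searchsorted(cum, targets) - 1, 0, len(seg) - 1)
    local = (targets - cum[idx]) / np.maximum(lens[idx], 1e-12)
    pts = poly[idx] + local[:, None] * seg[idx]
    return pts, seg[idx] / np.maximum(lens[idx], 1e-12)[:, None]


def _place_siliques(rng, spec: PlantSpec, branches, gap_min):
    """Rejection-place capsules near branches; returns per-silique geometry."""
    n = spec.n_siliques
    n_pods = 0 if spec.small_pod_fraction <= 0 or n < 8 else \
        min(n - 1, max(2, int(round(spec.small_pod_fraction * n))))
    placed = []           # dicts with p0, p1, axis, length, radius
    q0 = np.empty((0, 3))
    q1 = np.empty((0, 3))
    radii = np.empty(0)
    for i in range(n):
        pod = i >= n - n_pods            # immature pods placed last (need hosts)
        if pod:
            length = rng.uniform(0.08, 0.12)
            radius = 0.02
        else:
            length = rng.uniform(*spec.silique_length)
            radius = rng.uniform(*spec.silique_radius)
        twin = (not pod) and len(placed) > 0 and rng.uniform() < 0.25
        accepted = False
        relax = 1.0
        anchor = None
        for attempt in range(600):
            if twin and attempt >= 40:
                twin = False      # fall back to a regular placement
            if pod:
                # immature pod beside a mature host near the raceme tip
                hosts = [c for c in placed if not c.get("pod")]
                ref = hosts[rng.integers(0, len(hosts))]
                gap = rng.uniform(0.14, 0.18)
                u, v = _perp_basis(ref["axis"])
                phi = rng.uniform(0, 2 * np.pi)
                offset = (np.cos(phi) * u + np.sin(phi) * v) * \
                    (ref["radius"] + radius + gap)
                tfrac = rng.uniform(0.6, 1.0)       # toward the host's tip
                p0 = ref["p0"] + ref["axis"] * (tfrac * ref["length"]) + offset
                axis = _unit(ref["axis"] + rng.normal(0, 0.3, 3))
                anchor = None
                floor = 0.115
            elif twin:
                ref = placed[rng.integers(0, len(placed))]
                gap = rng.uniform(0.135, 0.175)
                u, v = _perp_basis(ref["axis"])
                phi = rng.uniform(0, 2 * np.pi)
                offset = (np.cos(phi) * u + np.sin(phi) * v) * \
                    (ref["radius"] + radius + gap)
                p0 = ref["p0"] + offset + ref["axis"] * rng.uniform(-0.1, 0.1)
                axis = _unit(ref["axis"] + rng.normal(0, 0.12, 3))
                anchor = None
                floor = 0.115
            else:
                branch = branches[rng.integers(0, len(branches))]
                frac = rng.uniform(0.2, 1.0)
                (anchor,), (tangent,) = _arc_points(branch, [frac])
                u, v = _perp_basis(tangent)
                phi = rng.uniform(0, 2 * np.pi)
                out_dir = _unit(np.cos(phi) * u + np.sin(phi) * v
                                + tangent * rng.uniform(0.4, 1.6))
                pedicel = rng.uniform(0.08, 0.22 + 0.10 * relax_deficit(relax))
                p0 = anchor + out_dir * pedicel
                axis = _unit(out_dir + rng.normal(0, 0.25, 3))
                floor = max(0.105, gap_min * relax)
            p1 = p0 + axis * length
            if len(q0):
                d = _segment_distances(p0, p1, q0, q1) - radii - radius
                if d.min() < floor:
                    if attempt % 8 == 7:
                        relax *= 0.93
                    continue
            placed.append(dict(p0=p0, p1=p1, axis=axis, length=length,
                               radius=radius, pod=pod,
                               anchor=anchor,
                               pedicel_end=p0))
            q0 = np.vstack([q0, p0])
            q1 = np.vstack([q1, p1])
            radii = np.append(radii, radius)
            accepted = True
            break
        if not accepted:
            raise ValueError("infeasible geometry: cannot place silique "
                             "(capsules too large for the plant)")
    return placed


def relax_deficit(relax: float) -> float:
    """0 while placement is easy, growing toward 1 as the floor relaxes."""
    return float(np.clip((1.0 - relax) * 4.0, 0.0, 1.0))


def generate_plant(spec: PlantSpec) -> SyntheticPlant:
    """Generate one labeled plant with ground-truth instances and noise flags."""
    rng = np.random.default_rng(spec.seed)
    n_sil = spec.n_siliques if spec.n_siliques is not None \
        else int(rng.integers(50, 301))
    spec = PlantSpec(**{**spec.__dict__, "n_siliques": n_sil})
    max_len = spec.silique_length[1]
    if max_len > 2.2:
        raise ValueError("infeasible geometry: silique longer than the plant")
    n_branches = max(1, math.ceil(n_sil / 9))
    stem, branches = _build_skeleton(rng, n_branches,
                                     height=2.2 + 0.005 * n_sil,
                                     levels=spec.branch_levels)
    gap_min = max(0.02, 0.30 - 0.40 * spec.overlap_level)
    placed = _place_siliques(rng, spec, branches, gap_min)

    # silique surface points
    sil_pts, sil_ids = [], []
    for i, cap in enumerate(placed):
        area = 2 * np.pi * cap["radius"] * cap["length"]
        if cap["pod"]:
            # immature pods carry exactly 8 points: an isolated n-point
            # blob survives DBSCAN iff min_samples <= n, so the pods pin
            # the largest usable neighbor threshold at 8
            npts = 8
        elif spec.points_per_silique is not None:
            npts = int(rng.integers(spec.points_per_silique[0],
                                    spec.points_per_silique[1] + 1))
        else:
            lo, hi = spec.silique_density
            dens = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            npts = max(8, int(round(dens * area)))
        pts = _sample_capsule(rng, cap["p0"], cap["axis"], cap["length"],
                              cap["radius"], npts,
                              waist_factor=1.0 if cap["pod"] else 0.35)
        sil_pts.append(pts)
        sil_ids.append(np.full(npts, i + 1))
    sil_pts = np.concatenate(sil_pts)
    sil_ids = np.concatenate(sil_ids)

    # stem, branch and pedicel points fill the remaining budget
    skeleton = [(stem, 0.032)] + [(b, 0.02) for b in branches]
    seg_list = []
    for poly, rad in skeleton:
        for a, b in zip(poly[:-1], poly[1:]):
            seg_list.append((a, b, rad))
    for cap in placed:
        if cap["anchor"] is not None:
            seg_list.append((cap["anchor"], cap["pedicel_end"], 0.008))
    seg_lens = np.array([np.linalg.norm(b - a) for a, b, _ in seg_list])
    total_len = seg_lens.sum()
    if spec.points_per_stem_unit is not None:
        ppu = spec.points_per_stem_unit
    else:
        budget = max(1500, spec.total_points - len(sil_pts))
        ppu = np.clip(budget / total_len, 60.0, 1400.0)
    stem_pts = []
    for (a, b, rad), ln in zip(seg_list, seg_lens):
        k = rng.poisson(ppu * ln)
        if k:
            stem_pts.append(_sample_cylinder(rng, a, b, rad, k))
    stem_pts = np.concatenate(stem_pts) if stem_pts else \
        np.zeros((0, 3))

    coords = np.concatenate([stem_pts, sil_pts])
    semantic = np.concatenate([np.zeros(len(stem_pts), dtype=np.int64),
                               np.ones(len(sil_pts), dtype=np.int64)])
    instance = np.concatenate([np.zeros(len(stem_pts), dtype=np.int64),
                               sil_ids]).astype(np.int64)
    coords = coords + rng.normal(0, spec.jitter_sigma, coords.shape)
    outlier = np.zeros(len(coords), dtype=bool)

    # noise: mislabeled clumps on the skeleton + uniform strays + floaters
    n_out = int(np.floor(spec.outlier_fraction * len(coords)))
    if n_out:
        stem_top = max(b[2] for a, b, r in seg_list if r > 0.03)
        stem_segs = [(a, b, r) for (a, b, r) in seg_list
                     if r > 0.03 and 0.5 * (a[2] + b[2]) < 0.6 * stem_top]
        o_pts = _make_outliers(rng, n_out, coords, seg_list,
                               clump_segs=stem_segs or None,
                               anchor_pts=sil_pts)
        coords = np.concatenate([coords, o_pts])
        semantic = np.concatenate([semantic,
                                   np.ones(len(o_pts), dtype=np.int64)])
        instance = np.concatenate([instance,
                                   np.zeros(len(o_pts), dtype=np.int64)])
        outlier = np.concatenate([outlier, np.ones(len(o_pts), dtype=bool)])

    colors = _colorize(rng, semantic)
    order = rng.permutation(len(coords))
    labeled = LabeledCloud(PointCloud(coords[order], colors[order]),
                           semantic[order], instance[order])
    return SyntheticPlant(labeled, true_count=n_sil,
                          outlier_mask=outlier[order])


def _make_outliers(rng, n_out, coords, seg_list, clump_segs=None,
                   anchor_pts=None):
    """Sparse silique-labeled noise: stem-adjacent clumps, strays, floaters.

    All components are rejection-sampled to stay clear of the plant surface
    (they emulate sparse acquisition/segmentation residue, not in-canopy
    points), which is what makes them statistically removable."""
    from scipy.spatial import cKDTree
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    span = hi - lo
    tree = cKDTree(coords)

    def sparse_centers(k, dmin, dmax=np.inf):
        out = []
        tries = 0
        while len(out) < k and tries < 60:
            cand = lo + rng.uniform(0, 1, (4 * k, 3)) * span
            d, _ = tree.query(cand)
            ok = (d >= dmin) & (d <= dmax)
            out.extend(cand[ok][: k - len(out)])
            tries += 1
        return out

    pts = []
    remaining = n_out
    clump_segs = clump_segs if clump_segs else seg_list
    # ~6% ghost pairs: two-point specks hovering just beyond clustering
    # range of an organ surface (near-surface reconstruction ghosts)
    anchors = anchor_pts if anchor_pts is not None and len(anchor_pts) \
        else coords
    pair_budget = max(2, int(n_out * 0.06))
    while pair_budget > 1 and remaining > 1:
        for _ in range(40):
            base = anchors[rng.integers(0, len(anchors))]
            center = base + _unit(rng.normal(0, 1, 3)) * rng.uniform(0.14, 0.17)
            d, _ = tree.query(center)
            if 0.125 <= d <= 0.19:
                break
        else:
            break
        pts.append(center + rng.normal(0, 0.008, (2, 3)))
        remaining -= 2
        pair_budget -= 2
    # ~60% clumps of 5-8 points hovering off the main stem, where
    # segmentation errors concentrate and the silique cloud is sparse;
    # clump centers keep mutual distance so they stay small and sparse
    clump_centers = []
    while remaining > n_out * 0.40:
        size = min(int(rng.integers(5, 9)), remaining)
        placed_center = None
        for _ in range(60):
            a, b, rad = clump_segs[rng.integers(0, len(clump_segs))]
            base = a + rng.uniform(0, 1) * (b - a)
            direction = _unit(rng.normal(0, 1, 3) * np.array([1.0, 1.0, 0.35]))
            center = base + direction * (rad + rng.uniform(0.45, 0.85))
            d, _ = tree.query(center)
            if not 0.40 <= d <= 1.2:
                continue
            if clump_centers and np.min(np.linalg.norm(
                    np.asarray(clump_centers) - center, axis=1)) < 0.45:
                continue
            placed_center = center
            break
        if placed_center is None:
            break                        # shell saturated; rest become singles
        clump_centers.append(placed_center)
        pts.append(placed_center + rng.normal(0, 0.025, (size, 3)))
        remaining -= size
    # ~15% floater specks of 2-4 points
    floater_budget = int(n_out * 0.15)
    centers = sparse_centers(max(1, floater_budget // 3), 0.18)
    for center in centers:
        if floater_budget <= 0 or remaining <= 0:
            break
        size = min(int(rng.integers(2, 5)), remaining)
        pts.append(center + rng.normal(0, 0.012, (size, 3)))
        remaining -= size
        floater_budget -= size
    # rest: sparse singles in the bounding box
    if remaining > 0:
        singles = sparse_centers(remaining, 0.16)
        if len(singles) < remaining:
            singles.extend(lo + rng.uniform(0, 1, (remaining - len(singles), 3))
                           * span)
        pts.append(np.asarray(singles))
    return np.concatenate(pts)[:n_out]


def _colorize(rng, semantic):
    """Greens for stem, yellow-browns for siliques, with realistic noise."""
    n = len(semantic)
    base = np.where(semantic[:, None] == SEM_STEM,
                    np.array([0.42, 0.47, 0.18]),
                    np.array([0.70, 0.60, 0.24]))
    shift = rng.normal(0, 0.04, 3)              # per-plant illumination shift
    colors = base + shift + rng.normal(0, 0.08, (n, 3))
    # color bleed: some points take the other organ's palette
    bleed = rng.uniform(size=n) < 0.08
    flipped = np.where(semantic[:, None] == SEM_STEM,
                       np.array([0.70, 0.60, 0.24]),
                       np.array([0.42, 0.47, 0.18]))
    colors[bleed] = flipped[bleed] + shift + rng.normal(0, 0.08, (bleed.sum(), 3))
    return np.clip(colors, 0.0, 1.0)


def inject_outliers(labeled: LabeledCloud, fraction: float,
                    seed: int = 0) -> SyntheticPlant:
    """Add floor(fraction * N) silique-labeled noise points, flagged.

    The mixture mirrors the generator's own noise model (mislabeled
    near-structure clumps, uniform strays, floater specks), the worst case
    for counting.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(labeled)
    n_out = int(np.floor(fraction * n))
    base_mask = np.zeros(n, dtype=bool)
    if n_out == 0:
        true_count = 0 if labeled.instance is None else \
            len(np.unique(labeled.instance[labeled.instance > 0]))
        return SyntheticPlant(labeled, true_count, base_mask)
    coords = labeled.cloud.coords
    stem_pts = coords[labeled.semantic == SEM_STEM] if labeled.semantic is not None \
        else coords
    if len(stem_pts) < 2:
        stem_pts = coords
    seg_idx = rng.integers(0, len(stem_pts) - 1, size=64)
    seg_list = [(stem_pts[i], stem_pts[i] + rng.normal(0, 0.02, 3), 0.03)
                for i in seg_idx]
    sil_anchor = coords[labeled.semantic == SEM_SILIQUE] \
        if labeled.semantic is not None else None
    o_pts = _make_outliers(rng, n_out, coords, seg_list,
                           anchor_pts=sil_anchor)
    o_colors = _colorize(rng, np.ones(len(o_pts), dtype=np.int64))
    new = LabeledCloud(
        PointCloud(np.concatenate([coords, o_pts]),
                   np.concatenate([labeled.cloud.colors, o_colors])),
        np.concatenate([labeled.semantic,
                        np.ones(len(o_pts), dtype=np.int64)]),
        None if labeled.instance is None else
        np.concatenate([labeled.instance,
                        np.zeros(len(o_pts), dtype=np.int64)]))
    mask = np.concatenate([base_mask, np.ones(len(o_pts), dtype=bool)])
    true_count = 0 if new.instance is None else \
        len(np.unique(new.instance[new.instance > 0]))
    return SyntheticPlant(new, true_count, mask)


def generate_dataset(n_plants: int, seed: int = 0,
                     count_range: Tuple[int, int] = (50, 300),
                     overlap_level: float = 0.4,
                     outlier_fraction: float = 0.01,
                     spec: Optional[PlantSpec] = None
                     ) -> Tuple[List[SyntheticPlant], pd.DataFrame]:
    """Generate plants with per-plant specs drawn from ranges plus a manifest.

    Every plant is kept within the 20k-30k-point working regime (uniform
    downsampling if generation overshoots).
    """
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    rng = np.random.default_rng(seed)
    template = spec.__dict__ if spec is not None else {}
    plants, rows = [], []
    for i in range(n_plants):
        pseed = int(rng.integers(0, 2 ** 31 - 1))
        n_sil = int(rng.integers(count_range[0], count_range[1] + 1))
        pspec = PlantSpec(**{**template,
                             "n_siliques": n_sil,
                             "overlap_level": overlap_level,
                             "outlier_fraction": outlier_fraction,
                             "seed": pseed})
        plant = generate_plant(pspec)
        if len(plant.labeled) > 30000:
            keep = np.arange(0, len(plant.labeled),
                             int(np.ceil(len(plant.labeled) / 30000)))
            plant = SyntheticPlant(plant.labeled.select(keep),
                                   plant.true_count,
                                   plant.outlier_mask[keep])
        plants.append(plant)
        rows.append(dict(plant_id=i, seed=pseed, n_siliques=n_sil,
                         true_count=plant.true_count,
                         n_points=len(plant.labeled)))
    return plants, pd.DataFrame(rows)


def generate_segmentation_dataset(n_plants: int, seed: int = 0,
                                  count_range: Tuple[int, int] = (25, 45),
                                  total_points: int = 4500
                                  ) -> List[LabeledCloud]:
    """Small labeled plants for desk-scale segmentation training.

    Fewer but larger, well-sampled capsules so each silique stays
    recognizable after subsampling to ~1k points, with a realistic
    silique-dominated canopy (~60/40 silique/stem point split). The
    density calibration that matters for clustering is irrelevant here,
    only labels, colors and geometry are.
    """
    rng = np.random.default_rng(seed)
    clouds = []
    for _ in range(n_plants):
        pspec = PlantSpec(
            n_siliques=int(rng.integers(count_range[0], count_range[1] + 1)),
            silique_length=(0.5, 0.8),
            silique_radius=(0.035, 0.05),
            silique_density=(250.0, 450.0),
            small_pod_fraction=0.0,
            total_points=total_points,
            outlier_fraction=0.0,
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        clouds.append(generate_plant(pspec).labeled)
    return clouds
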