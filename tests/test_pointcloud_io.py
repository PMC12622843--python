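import numpy as np
import pytest
from scipy.spatial.distance import cdist

from kanglnet import ply
from kanglnet.pointcloud_io import (AugmentConfig, EmptyCloudError,
                                    LabeledCloud, ParameterError, PointCloud,
                                    SplitSpec, augment_cloud, augment_dataset,
                                    normalize_cloud, radius_outlier_removal,
                                    read_ply, split_dataset,
                                    statistical_outlier_removal,
                                    uniform_downsample, write_ply)


def brute_force_sor(coords, k, std_ratio):
    """Independent SOR oracle: full pairwise-distance kNN means."""
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    knn = np.sort(d, axis=1)[:, :k]
    mean_d = knn.mean(axis=1)
    thresh = mean_d.mean() + std_ratio * mean_d.std()
    return mean_d <= thresh


class TestPlyIO:
    def test_roundtrip_coords_and_labels(self, tmp_path, labeled_cloud):
        path = tmp_path / "c.ply"
        write_ply(labeled_cloud, path)
        back = read_ply(path)
        np.testing.assert_allclose(back.cloud.coords, labeled_cloud.cloud.coords,
                                   atol=1e-6)  # single-precision storage
        np.testing.assert_array_equal(back.semantic, labeled_cloud.semantic)
        np.testing.assert_array_equal(back.instance, labeled_cloud.instance)
        assert 0 <= back.cloud.colors.min() and back.cloud.colors.max() <= 1

    def test_single_vertex_cloud(self, tmp_path):
        lc = LabeledCloud(PointCloud([[1.0, 2.0, 3.0]], [[0.5, 0.5, 0.5]]))
        path = tmp_path / "one.ply"
        write_ply(lc, path)
        assert len(read_ply(path)) == 1

    def test_ascii_dialect_with_uchar_colors(self, tmp_path):
        path = tmp_path / "a.ply"
        path.write_text(
            "ply\nformat ascii 1.0\nelement vertex 2\n"
            "property float x\nproperty float y\nproperty float z\n"
            "property uchar red\nproperty uchar green\nproperty uchar blue\n"
            "end_header\n0 0 0 255 0 0\n1 1 1 0 128 0\n")
        lc = read_ply(path)
        assert len(lc) == 2
        np.testing.assert_allclose(lc.cloud.colors[0], [1.0, 0.0, 0.0])

    def test_missing_x_property_raises(self, tmp_path):
        path = tmp_path / "bad.ply"
        path.write_text("ply\nformat ascii 1.0\nelement vertex 1\n"
                        "property float y\nproperty float z\n"
                        "end_header\n0 0\n")
        with pytest.raises(ply.PLYFormatError):
            read_ply(path)

    def test_zero_vertices_raises(self, tmp_path):
        path = tmp_path / "empty.ply"
        path.write_text("ply\nformat ascii 1.0\nelement vertex 0\n"
                        "property float x\nproperty float y\n"
                        "property float z\nend_header\n")
        with pytest.raises(EmptyCloudError):
            read_ply(path)

    def test_sidecar_labels(self, tmp_path, labeled_cloud):
        path = tmp_path / "s.ply"
        write_ply(LabeledCloud(labeled_cloud.cloud), path)
        (tmp_path / "s.ply.labels").write_text(
            "\n".join(map(str, labeled_cloud.semantic)))
        back = read_ply(path)
        np.testing.assert_array_equal(back.semantic, labeled_cloud.semantic)


class TestStatisticalOutlierRemoval:
    def test_far_point_removed_from_lattice(self):
        grid = np.stack(np.meshgrid(*[np.arange(5)] * 2, [0.0]),
                        -1).reshape(-1, 3).astype(float)
        coords = np.vstack([grid, [[100.0, 100.0, 0.0]]])
        cloud = PointCloud(coords, np.full_like(coords, 0.5))
        kept, removed = statistical_outlier_removal(cloud, k=8, std_ratio=2.0)
        assert list(removed) == [len(coords) - 1]
        oracle = brute_force_sor(coords, 8, 2.0)
        assert len(kept) == oracle.sum()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        coords = np.vstack([r.normal(size=(150, 3)),
                            r.normal(size=(10, 3)) * 8])
        cloud = PointCloud(coords, np.full_like(coords, 0.5))
        kept, removed = statistical_outlier_removal(cloud, k=12, std_ratio=1.5)
        oracle = brute_force_sor(coords, 12, 1.5)
        np.testing.assert_array_equal(np.flatnonzero(~oracle), removed)

    def test_huge_std_ratio_is_identity(self, labeled_cloud):
        kept, removed = statistical_outlier_removal(labeled_cloud.cloud,
                                                    k=8, std_ratio=1e9)
        assert len(removed) == 0 and len(kept) == len(labeled_cloud)

    def test_k_at_least_n_raises(self):
        cloud = PointCloud(np.zeros((5, 3)) + np.arange(5)[:, None],
                           np.full((5, 3), 0.5))
        with pytest.raises(ParameterError):
            statistical_outlier_removal(cloud, k=5)


class TestRadiusOutlierRemoval:
    def test_isolated_point_removed(self):
        coords = np.vstack([np.random.default_rng(0).normal(size=(50, 3)) * 0.1,
                            [[50.0, 0.0, 0.0]]])
        cloud = PointCloud(coords, np.full_like(coords, 0.5))
        out = radius_outlier_removal(cloud, radius=1.0, min_neighbors=1)
        assert len(out) == 50

    def test_dense_blob_identity(self, labeled_cloud):
        out = radius_outlier_removal(labeled_cloud.cloud, radius=100.0,
                                     min_neighbors=1)
        assert len(out) == len(labeled_cloud)

    def test_ring_spaced_above_radius_all_removed(self):
        # 12 points on a circle; chord between neighbors just above radius
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        chord = 2 * np.sin(np.pi / 12)
        coords = np.stack([np.cos(theta), np.sin(theta),
                           np.zeros(12)], axis=1)
        cloud = PointCloud(coords, np.full_like(coords, 0.5))
        out = radius_outlier_removal(cloud, radius=chord * 0.99,
                                     min_neighbors=1)
        assert len(out.coords) == 0 or len(out) == 0

    def test_nonpositive_radius_raises(self, labeled_cloud):
        with pytest.raises(ParameterError):
            radius_outlier_removal(labeled_cloud.cloud, radius=0.0)


class TestUniformDownsample:
    def test_forced_stride_keeps_every_fifth(self):
        coords = np.arange(300).reshape(100, 3).astype(float)
        cloud = PointCloud(coords, np.full_like(coords, 0.5))
        out = uniform_downsample(cloud, 10, 20)
        assert len(out) == 20
        np.testing.assert_array_equal(out.coords[:3, 0], [0, 15, 30])

    def test_large_cloud_lands_in_range(self):
        n = 250_000
        coords = np.random.default_rng(1).normal(size=(n, 3))
        cloud = PointCloud(coords, np.full_like(coords, 0.5))
        out = uniform_downsample(cloud, 20_000, 30_000)
        assert 20_000 <= len(out) <= 30_000

    def test_in_range_is_identity(self, labeled_cloud):
        assert uniform_downsample(labeled_cloud, 10, 500) is labeled_cloud

    def test_order_preserved(self):
        coords = np.arange(300).reshape(100, 3).astype(float)
        cloud = PointCloud(coords, np.full_like(coords, 0.5))
        out = uniform_downsample(cloud, 10, 33)
        assert (np.diff(out.coords[:, 0]) > 0).all()


class TestNormalize:
    def test_centroid_zero_and_unit_norm(self, labeled_cloud):
        out, centroid, scale = normalize_cloud(labeled_cloud.cloud)
        assert np.abs(out.coords.mean(axis=0)).max() < 1e-6
        assert abs(np.linalg.norm(out.coords, axis=1).max() - 1.0) < 1e-9
        np.testing.assert_allclose(out.coords * scale + centroid,
                                   labeled_cloud.cloud.coords)

    def test_idempotent(self, labeled_cloud):
        once, _, _ = normalize_cloud(labeled_cloud.cloud)
        twice, _, scale = normalize_cloud(once)
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-9)

    def test_degenerate_identical_points(self):
        cloud = PointCloud(np.ones((4, 3)), np.full((4, 3), 0.5))
        out, _, scale = normalize_cloud(cloud)
        assert scale == 1.0 and np.isfinite(out.coords).all()


class TestAugment:
    def test_identity_config(self, labeled_cloud, rng):
        cfg = AugmentConfig(dropout_max=0.0, rot_z_range=0.0,
                            scale_range=(1.0, 1.0), flip_y_prob=0.0)
        out = augment_cloud(labeled_cloud, cfg, rng)
        np.testing.assert_allclose(out.cloud.coords, labeled_cloud.cloud.coords)
        np.testing.assert_array_equal(out.semantic, labeled_cloud.semantic)

    def test_z_rotation_is_isometry(self, labeled_cloud, rng):
        cfg = AugmentConfig(dropout_max=0.0, scale_range=(1.0, 1.0),
                            flip_y_prob=0.0)
        out = augment_cloud(labeled_cloud, cfg, rng)
        np.testing.assert_allclose(out.cloud.coords[:, 2],
                                   labeled_cloud.cloud.coords[:, 2])
        a = cdist(out.cloud.coords[:20], out.cloud.coords[:20])
        b = cdist(labeled_cloud.cloud.coords[:20],
                  labeled_cloud.cloud.coords[:20])
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_dropout_floor_rule(self, rng):
        n = 1000
        coords = rng.normal(size=(n, 3))
        lc = LabeledCloud(PointCloud(coords, np.full_like(coords, 0.5)),
                          np.zeros(n, dtype=int))
        cfg = AugmentConfig(dropout_max=0.3, seed=5)
        sample_rng = np.random.default_rng(99)
        frac = np.random.default_rng(99).uniform(0.0, 0.3)   # replay the draw
        out = augment_cloud(lc, cfg, sample_rng)
        assert len(out) == n - int(np.floor(frac * n))

    def test_labels_travel_with_points(self, rng):
        # label i encodes point identity through coordinates
        n = 400
        coords = np.arange(n, dtype=float)[:, None] * [1.0, 0.0, 0.0]
        instance = np.arange(1, n + 1)
        lc = LabeledCloud(PointCloud(coords, np.full((n, 3), 0.5)),
                          np.ones(n, dtype=int), instance)
        cfg = AugmentConfig(dropout_max=0.5, rot_z_range=0.0,
                            scale_range=(1.0, 1.0), flip_y_prob=0.0)
        out = augment_cloud(lc, cfg, rng)
        np.testing.assert_allclose(out.cloud.coords[:, 0], out.instance - 1)


class TestSplit:
    def test_50_clouds_split_35_5_10(self):
        clouds = list(range(50))
        train, val, test = split_dataset(clouds, SplitSpec(seed=0))
        assert (len(train), len(val), len(test)) == (35, 5, 10)

    def test_disjoint_exhaustive_any_seed(self):
        clouds = list(range(37))
        for seed in range(5):
            tr, va, te = split_dataset(clouds, SplitSpec(seed=seed))
            assert sorted(tr + va + te) == clouds

    def test_same_seed_same_membership(self):
        clouds = list(range(23))
        a = split_dataset(clouds, SplitSpec(seed=3))
        b = split_dataset(clouds, SplitSpec(seed=3))
        assert a == b

    def test_augmentation_factor_on_train_split(self, rng):
        n = 35
        clouds = []
        for i in range(n):
            coords = rng.normal(size=(50, 3))
            clouds.append(LabeledCloud(PointCloud(coords,
                                                  np.full_like(coords, 0.5))))
        out = augment_dataset(clouds, AugmentConfig(copies=10, seed=1))
        assert len(out) == 350

    def test_all_zero_ratios_raise(self):
        with pytest.raises(ParameterError):
            SplitSpec(ratios=(0, 0, 0))
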