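import numpy as np
import pytest

from kanglnet.autodiff import Tensor
from kanglnet.segmentation_network import (ModelConfig, SALevel,
                                           ablation_config, ball_query_group,
                                           build_model, count_parameters,
                                           farthest_point_sample,
                                           forward_segment,
                                           inverse_distance_interpolate,
                                           make_config)
from kanglnet.training import cross_entropy


def brute_force_fps(coords, m, start):
    """Independent greedy max-min oracle."""
    chosen = [start]
    for _ in range(m - 1):
        d = np.min([np.linalg.norm(coords - coords[c], axis=1)
                    for c in chosen], axis=0)
        chosen.append(int(np.argmax(d)))
    return chosen


class TestFarthestPointSampling:
    def test_m_equals_n_selects_all(self, rng):
        coords = rng.normal(size=(10, 3))
        sel = farthest_point_sample(coords, 10)
        assert sorted(sel) == list(range(10))

    def test_two_blobs_second_pick_in_other_blob(self, rng):
        a = rng.normal(size=(20, 3)) * 0.1
        b = rng.normal(size=(20, 3)) * 0.1 + 10
        coords = np.vstack([a, b])
        sel = farthest_point_sample(coords, 2, start_index=0)
        assert sel[1] >= 20

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_greedy_oracle(self, seed):
        r = np.random.default_rng(seed)
        coords = r.normal(size=(40, 3))
        sel = farthest_point_sample(coords, 12, start_index=3)
        assert list(sel) == brute_force_fps(coords, 12, 3)

    def test_m_exceeding_n_raises(self, rng):
        with pytest.raises(ValueError):
            farthest_point_sample(rng.normal(size=(5, 3)), 6)


class TestBallQuery:
    def test_isolated_center_repeats_itself(self, rng):
        coords = np.vstack([[0.0, 0.0, 0.0],
                            rng.normal(size=(20, 3)) + 100])[None]
        centers = np.array([[[0.0, 0.0, 0.0]]])
        idx, rel = ball_query_group(coords, centers, radius=1.0, k=8)
        assert (idx[0, 0] == 0).all()
        np.testing.assert_allclose(rel[0, 0], 0.0)

    def test_k1_returns_nearest_in_radius(self, rng):
        coords = rng.normal(size=(1, 50, 3))
        centers = coords[:, :5]
        idx, _ = ball_query_group(coords, centers, radius=10.0, k=1)
        d = np.linalg.norm(coords[0][None] - centers[0][:, None], axis=2)
        np.testing.assert_array_equal(idx[0, :, 0], np.argmin(d, axis=1))

    def test_output_layout(self, rng):
        coords = rng.normal(size=(2, 100, 3))
        centers = coords[:, :16]
        idx, rel = ball_query_group(coords, centers, radius=0.5, k=8)
        assert idx.shape == (2, 16, 8)
        assert rel.shape == (2, 16, 8, 3)

    def test_neighbors_sorted_by_distance(self, rng):
        coords = rng.normal(size=(1, 200, 3))
        centers = coords[:, :4]
        idx, rel = ball_query_group(coords, centers, radius=5.0, k=16)
        d = np.linalg.norm(rel, axis=3)
        assert (np.diff(d, axis=2) >= -1e-12).all()


class TestInterpolation:
    def test_coincident_points_reproduce_features(self, rng):
        coords = rng.normal(size=(2, 30, 3))
        feats = Tensor(rng.normal(size=(2, 5, 30)))
        out = inverse_distance_interpolate(coords, coords, feats)
        np.testing.assert_allclose(out.data, feats.data, atol=1e-12)

    def test_weights_interpolate_between_two_points(self):
        coarse = np.array([[[0.0, 0, 0], [1.0, 0, 0]]])
        fine = np.array([[[0.25, 0, 0]]])
        feats = Tensor(np.array([[[0.0, 1.0]]]))
        out = inverse_distance_interpolate(fine, coarse, feats)
        # inverse-distance weights: (1/.25)/(1/.25+1/.75) = 0.75 -> value .25
        assert out.data[0, 0, 0] == pytest.approx(0.25)


class TestModelAssembly:
    def test_full_preset_forward_smoke(self, rng):
        cfg = make_config("kan_glnet_full", size="tiny", seed=0)
        model = build_model(cfg)
        coords = rng.normal(size=(1, 1024, 3)) * 0.3
        feats = rng.uniform(size=(1, 6, 1024))
        out = model(coords, feats)
        assert out.shape == (1, 2, 1024)
        assert np.isfinite(out.data).all()

    def test_softmax_rows_sum_to_one(self, rng):
        model = build_model(make_config("baseline_pointnet2", seed=0))
        coords = rng.normal(size=(1, 1024, 3)) * 0.3
        feats = rng.uniform(size=(1, 6, 1024))
        probs = model(coords, feats).softmax(axis=1).data
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_fixed_seed_identical_logits(self, rng):
        coords = rng.normal(size=(1, 1024, 3)) * 0.3
        feats = rng.uniform(size=(1, 6, 1024))
        a = build_model(make_config("kan_glnet_full", seed=5))(coords, feats)
        b = build_model(make_config("kan_glnet_full", seed=5))(coords, feats)
        np.testing.assert_array_equal(a.data, b.data)

    def test_disabled_enhancements_reduce_to_baseline(self, rng):
        coords = rng.normal(size=(1, 1024, 3)) * 0.3
        feats = rng.uniform(size=(1, 6, 1024))
        stripped = build_model(make_config(
            "kan_glnet_full", seed=1, use_contranorm=False, use_glfn=False,
            conv_variants=("standard",) * 3))
        baseline = build_model(make_config("baseline_pointnet2", seed=1))
        np.testing.assert_array_equal(stripped(coords, feats).data,
                                      baseline(coords, feats).data)

    def test_duplicated_neighbor_invariance_at_kernel_one(self, rng):
        # max pooling over K makes a repeated neighbor column a no-op when
        # no cross-neighbor kernel mixes columns
        from kanglnet.segmentation_network import KGLPointNetBlock
        cfg = make_config("kan_glnet_full", seed=0, use_glfn=False)
        cfg.kan_kernel = 1
        block = KGLPointNetBlock(9, cfg, (8, 8), np.random.default_rng(0))
        block.eval()
        group = rng.normal(size=(1, 9, 4, 6))
        extended = np.concatenate([group, group[:, :, -1:, :]], axis=2)
        a = block(Tensor(group)).data
        b = block(Tensor(extended)).data
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_forward_backward_finite_gradients(self, rng):
        cfg = make_config("kan_glnet_full", seed=0)
        model = build_model(cfg)
        coords = rng.normal(size=(2, 1024, 3)) * 0.3
        feats = rng.uniform(size=(2, 6, 1024))
        labels = rng.integers(0, 2, (2, 1024))
        loss = cross_entropy(model(coords, feats), labels)
        loss.backward()
        for p in model.parameters():
            assert p.grad is not None and np.isfinite(p.grad).all()

    def test_forward_segment_covers_all_points(self, rng):
        model = build_model(make_config("baseline_pointnet2", seed=0))
        coords = rng.normal(size=(2500, 3)) * 0.3
        colors = rng.uniform(size=(2500, 3))
        logits = forward_segment(model, coords, colors, seed=1)
        assert logits.shape == (2500, 2)
        assert np.isfinite(logits).all() and (np.abs(logits).sum(axis=1) > 0).all()


class TestParameterCounting:
    def test_minimal_config_hand_tally(self):
        cfg = ModelConfig(sa_levels=[SALevel(8, 0.5, 4, (4, 8))],
                          fp_levels=[(8,)], head_width=4, num_classes=2,
                          seed=0)
        model = build_model(cfg)
        # SA block: conv (6+3)->4 (36+4) + BN 8; conv 4->8 (32+8) + BN 16
        # post-SA BN: 16
        # FP: conv (8+6)->8 (112+8) + BN 16; post-FP BN 16
        # head: conv 8->4 (32+4) + BN 8; conv 4->2 (8+2)
        expected = (36 + 4 + 8) + (32 + 8 + 16) + 16 \
            + (112 + 8 + 16) + 16 + (32 + 4 + 8) + (8 + 2)
        assert count_parameters(model) == expected

    def test_module_combination_ordering(self):
        base = count_parameters(build_model(ablation_config(False, False, False)))
        glfn = count_parameters(build_model(ablation_config(False, True, False)))
        full = count_parameters(build_model(ablation_config(False, True, True)))
        assert base < glfn < full

    def test_contranorm_matches_baseline_count(self):
        base = build_model(ablation_config(False, False, False))
        contra = build_model(ablation_config(True, False, False))
        # ContraNorm carries only the LN affine, like the BN it replaces
        assert count_parameters(base) == count_parameters(contra)

    def test_reverse_bottleneck_below_fastkan_at_conv1(self):
        rb = build_model(make_config(
            "kan_glnet_full", use_contranorm=False, use_glfn=False,
            conv_variants=("reverse_bottleneck", "standard", "standard")))
        fk = build_model(make_config(
            "kan_glnet_full", use_contranorm=False, use_glfn=False,
            conv_variants=("fastkan", "standard", "standard")))
        assert count_parameters(rb) < count_parameters(fk)

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = make_config("kan_glnet_full", size="tiny", seed=3)
        path = tmp_path / "model.yaml"
        cfg.to_yaml(path)
        from kanglnet.segmentation_network import ModelConfig
        back = ModelConfig.from_yaml(path)
        assert back == cfg

    def test_count_invariant_to_input(self, rng):
        model = build_model(make_config("baseline_pointnet2", seed=0))
        before = count_parameters(model)
        model(rng.normal(size=(1, 1024, 3)), rng.uniform(size=(1, 6, 1024)))
        assert count_parameters(model) == before
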