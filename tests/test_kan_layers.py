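import numpy as np
import pytest

from kanglnet.autodiff import Tensor
from kanglnet.kan_layers import (KANConv2d, KanConvSpec, PhiParams, RBFGrid,
                                 ReverseBottleneckKANConv2d,
                                 conv_parameter_count, make_conv, phi_edge,
                                 rbf_basis, silu)


def eq1_oracle(y, module):
    """Brute-force triple-sum evaluation of the edge-function convolution."""
    spec = module.spec
    G = spec.grid.size
    c, h, w = y.shape[1:]
    ho, wo = h - spec.k + 1, w - spec.k + 1
    out = np.zeros((y.shape[0], spec.c_out, ho, wo))
    for o in range(spec.c_out):
        for i in range(ho):
            for j in range(wo):
                acc = np.zeros(y.shape[0])
                for d in range(c):
                    for a in range(spec.k):
                        for b in range(spec.k):
                            v = y[:, d, i + a, j + b]
                            p = PhiParams(
                                w_b=module.w_base.data[o, d, a, b], w_s=1.0,
                                coeffs=module.w_spline.data[
                                    o, d * G:(d + 1) * G, a, b])
                            acc = acc + phi_edge(v, p, spec.grid)
                out[:, o, i, j] = acc
    return out


class TestEdgeFunctions:
    def test_silu_closed_form(self):
        assert silu(0.0) == 0.0
        assert silu(1.0) == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-7)
        assert silu(1.0) == pytest.approx(0.7310586, abs=1e-6)
        assert silu(50.0) == pytest.approx(50.0)
        assert silu(-50.0) == pytest.approx(0.0, abs=1e-12)

    def test_rbf_at_center_and_one_sigma(self):
        grid = RBFGrid(np.array([-1.0, 0.0, 1.0]), sigma=0.5)
        vals = rbf_basis(0.0, grid)
        assert vals[1] == 1.0
        vals = rbf_basis(0.5, grid)        # one sigma from center 0
        assert vals[1] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_rbf_bounded_and_positive(self, rng):
        x = rng.normal(size=100) * 5
        vals = rbf_basis(x, RBFGrid())
        assert (vals > 0).all() and (vals <= 1).all()

    def test_rbf_max_at_nearest_center(self, rng):
        grid = RBFGrid()
        x = rng.uniform(-2, 2, 50)
        vals = rbf_basis(x, grid)
        nearest = np.argmin(np.abs(x[:, None] - grid.centers), axis=1)
        np.testing.assert_array_equal(np.argmax(vals, axis=1), nearest)

    def test_phi_reductions(self):
        grid = RBFGrid(np.array([0.0]), sigma=1.0)
        x = np.linspace(-2, 2, 9)
        zero = phi_edge(x, PhiParams(0.0, 0.0, [1.0]), grid)
        np.testing.assert_array_equal(zero, 0.0)
        base = phi_edge(x, PhiParams(1.0, 0.0, [1.0]), grid)
        np.testing.assert_allclose(base, silu(x))
        assert phi_edge(np.array(0.0), PhiParams(0.0, 1.0, [1.0]), grid) == 1.0

    def test_phi_linear_in_weights_and_coeffs(self, rng):
        grid = RBFGrid()
        x = rng.normal(size=20)
        c = rng.normal(size=grid.size)
        a = phi_edge(x, PhiParams(2.0, 3.0, c), grid)
        b = 2.0 * phi_edge(x, PhiParams(1.0, 0.0, c), grid) \
            + 3.0 * phi_edge(x, PhiParams(0.0, 1.0, c), grid)
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestKanConvolutions:
    @pytest.mark.parametrize("variant", ["vanilla", "fastkan"])
    def test_matches_triple_sum_oracle(self, variant, rng):
        spec = KanConvSpec(variant=variant, k=3, c_in=4, c_out=3,
                           padding="valid")
        module = KANConv2d(spec, rng)
        y = rng.normal(size=(2, 4, 8, 8))
        np.testing.assert_allclose(module(y).data, eq1_oracle(y, module),
                                   atol=1e-5)

    def test_k1_c1_reduces_to_pointwise_phi(self, rng):
        spec = KanConvSpec(variant="fastkan", k=1, c_in=1, c_out=1,
                           padding="valid")
        module = KANConv2d(spec, rng)
        y = rng.normal(size=(1, 1, 4, 4))
        p = PhiParams(module.w_base.data[0, 0, 0, 0], 1.0,
                      module.w_spline.data[0, :, 0, 0])
        np.testing.assert_allclose(module(y).data[0, 0],
                                   phi_edge(y[0, 0], p, spec.grid), atol=1e-12)

    def test_valid_padding_output_size(self, rng):
        spec = KanConvSpec(variant="fastkan", k=3, c_in=2, c_out=2,
                           padding="valid")
        out = KANConv2d(spec, rng)(rng.normal(size=(1, 2, 5, 6)))
        assert out.shape == (1, 2, 3, 4)

    def test_zero_parameters_zero_output(self, rng):
        spec = KanConvSpec(variant="fastkan", k=3, c_in=2, c_out=2,
                           padding="same")
        module = KANConv2d(spec, rng)
        module.w_base.data[:] = 0.0
        module.w_spline.data[:] = 0.0
        out = module(rng.normal(size=(1, 2, 4, 4)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_reverse_bottleneck_same_padding_shape(self, rng):
        spec = KanConvSpec(variant="reverse_bottleneck", k=3, c_in=4,
                           c_out=6, padding="same")
        out = ReverseBottleneckKANConv2d(spec, rng)(
            rng.normal(size=(2, 4, 16, 10)))
        assert out.shape == (2, 6, 16, 10)

    def test_zero_reduction_leaves_base_branch(self, rng):
        spec = KanConvSpec(variant="reverse_bottleneck", k=3, c_in=3,
                           c_out=4, padding="same")
        module = ReverseBottleneckKANConv2d(spec, rng)
        module.reduce.weight.data[:] = 0.0
        module.reduce.bias.data[:] = 0.0
        y = rng.normal(size=(1, 3, 6, 6))
        np.testing.assert_allclose(
            module(y).data,
            module.base(Tensor(y).silu()).data, atol=1e-12)

    @pytest.mark.parametrize("variant", ["vanilla", "fastkan",
                                         "reverse_bottleneck"])
    def test_finite_difference_gradients(self, variant, rng):
        spec = KanConvSpec(variant=variant, k=3, c_in=2, c_out=2,
                           padding="same")
        module = make_conv(spec, rng)
        x0 = rng.normal(size=(1, 2, 4, 4))
        x = Tensor(x0, requires_grad=True)
        module(x).sum().backward()
        grad = x.grad.copy()
        num = np.zeros_like(x0)
        eps = 1e-6
        it = np.nditer(x0, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            xp = x0.copy()
            xp[i] += eps
            xm = x0.copy()
            xm[i] -= eps
            num[i] = (module(xp).data.sum() - module(xm).data.sum()) / (2 * eps)
        np.testing.assert_allclose(grad, num, atol=1e-4)


class TestParameterCounts:
    @pytest.mark.parametrize("variant", ["vanilla", "fastkan",
                                         "reverse_bottleneck"])
    def test_closed_form_matches_module_enumeration(self, variant, rng):
        spec = KanConvSpec(variant=variant, k=3, c_in=3, c_out=5,
                           padding="same")
        module = make_conv(spec, rng)
        assert module.num_parameters() == conv_parameter_count(spec)

    def test_minimal_vanilla_hand_count(self):
        # one edge: one base weight + G spline coefficients
        spec = KanConvSpec(variant="vanilla", k=1, c_in=1, c_out=1,
                           grid=RBFGrid(np.array([0.0]), 1.0))
        assert conv_parameter_count(spec) == 2

    def test_vanilla_equals_fastkan_at_equal_grid(self):
        a = KanConvSpec(variant="vanilla", k=3, c_in=16, c_out=32)
        b = KanConvSpec(variant="fastkan", k=3, c_in=16, c_out=32)
        assert conv_parameter_count(a) == conv_parameter_count(b)

    def test_monotone_in_every_dimension(self):
        base = dict(variant="fastkan", k=3, c_in=8, c_out=8)
        ref = conv_parameter_count(KanConvSpec(**base))
        for key, val in [("k", 5), ("c_in", 16), ("c_out", 16)]:
            assert conv_parameter_count(KanConvSpec(**{**base, key: val})) > ref
        grid = RBFGrid(np.linspace(-2, 2, 16))
        assert conv_parameter_count(KanConvSpec(**base, grid=grid)) > ref

    @pytest.mark.parametrize("c", [16, 32, 64])
    @pytest.mark.parametrize("e", [1.0, 2.0, 4.0])
    def test_reverse_bottleneck_below_dense_variants(self, c, e):
        rb = KanConvSpec(variant="reverse_bottleneck", k=3, c_in=c, c_out=c,
                         expansion=e)
        dense = KanConvSpec(variant="fastkan", k=3, c_in=c, c_out=c)
        vanilla = KanConvSpec(variant="vanilla", k=3, c_in=c, c_out=c)
        assert conv_parameter_count(rb) < conv_parameter_count(dense)
        assert conv_parameter_count(rb) < conv_parameter_count(vanilla)
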