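"""Kolmogorov-Arnold convolution layers.

A KAN convolution replaces each scalar kernel weight with a learnable
univariate edge function

    phi(x) = w_b * SiLU(x) + w_s * spline(x),

so an output pixel is the triple sum over input channels d and kernel
offsets (a, b) of phi_{a,b,d} applied to the shifted input. The spline
term is a linear combination of Gaussian radial basis bumps
exp(-(x - c_g)^2 / (2 sigma^2)) on a fixed grid of centers (the FastKAN
construction, which approximates the B-spline basis without grid
refitting); the ``vanilla`` and ``fastkan`` variants share this basis
and therefore have identical learnable-parameter counts.

The reverse-bottleneck variant keeps the k x k convolution only on the
SiLU base term and moves the spline into a 1x1 expand -> per-channel
edge function -> 1x1 reduce sandwich, which cuts the parameter count
from O(c_in * c_out * k^2 * G) to O(e * c_in * (c_in + c_out + G)).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .autodiff import Conv2d, Module, Parameter, Tensor, conv2d


def silu(x):
    """SiLU / swish: x / (1 + exp(-x)), elementwise, ndarray in -> ndarray out."""
    x = np.asarray(x, dtype=np.float64)
    return x / (1.0 + np.exp(-x))


@dataclass
class RBFGrid:
    """Grid of Gaussian bump centers with common width sigma.

    Default: 8 centers uniform on [-2, 2] with sigma equal to the grid
    spacing, wide enough to cover post-normalization activations.
    """

    centers: np.ndarray = None
    sigma: float = None

    def __post_init__(self):
        if self.centers is None:
            self.centers = np.linspace(-2.0, 2.0, 8)
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.centers.ndim != 1 or len(self.centers) < 1:
            raise ValueError("centers must be a non-empty 1-D array")
        if len(self.centers) > 1 and (np.diff(self.centers) <= 0).any():
            raise ValueError("centers must be strictly increasing")
        if self.sigma is None:
            self.sigma = float(self.centers[1] - self.centers[0]) \
                if len(self.centers) > 1 else 1.0
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    @property
    def size(self) -> int:
        return len(self.centers)


@dataclass
class PhiParams:
    """Parameters of one edge function phi(x) = w_b b(x) + w_s sum_g c_g r_g(x)."""

    w_b: float
    w_s: float
    coeffs: np.ndarray

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        if not (np.isfinite(self.coeffs).all()
                and np.isfinite([self.w_b, self.w_s]).all()):
            raise ValueError("phi parameters must be finite")


@dataclass
class KanConvSpec:
    """Shape/variant description of one KAN convolution layer."""

    variant: str = "reverse_bottleneck"   # vanilla | fastkan | reverse_bottleneck
    k: int = 3
    c_in: int = 1
    c_out: int = 1
    grid: RBFGrid = field(default_factory=RBFGrid)
    expansion: float = 2.0
    padding: str = "valid"

    def __post_init__(self):
        if self.variant not in ("vanilla", "fastkan", "reverse_bottleneck"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.k < 1 or self.c_in < 1 or self.c_out < 1:
            raise ValueError("kernel and channel sizes must be >= 1")
        if self.expansion < 1:
            raise ValueError("expansion ratio must be >= 1")

    @property
    def expanded(self) -> int:
        return int(round(self.expansion * self.c_in))


def rbf_basis(x, grid: RBFGrid) -> np.ndarray:
    """Evaluate all Gaussian bumps at x; output gains a trailing axis of size G."""
    x = np.asarray(x, dtype=np.float64)
    r = x[..., None] - grid.centers
    return np.exp(-(r ** 2) / (2.0 * grid.sigma ** 2))


def phi_edge(x, p: PhiParams, grid: RBFGrid) -> np.ndarray:
    """Evaluate one edge function phi(x) = w_b SiLU(x) + w_s sum_g c_g r_g(x)."""
    if p.coeffs.shape != (grid.size,):
        raise ValueError("coeffs length must equal grid size")
    return p.w_b * silu(x) + p.w_s * (rbf_basis(x, grid) @ p.coeffs)


def _rbf_tensor(x: Tensor, grid: RBFGrid) -> Tensor:
    """Differentiable RBF expansion: (B, C, H, W) -> (B, C*G, H, W)."""
    B, C, H, W = x.shape
    G = grid.size
    xe = x.reshape(B, C, 1, H, W)
    centers = Tensor(grid.centers.reshape(1, 1, G, 1, 1))
    r = xe - centers
    return ((r * r) * (-0.5 / grid.sigma ** 2)).exp().reshape(B, C * G, H, W)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class KANConv2d(Module):
    """Direct Eq-style KAN convolution (``vanilla`` or ``fastkan`` variant).

    Each of the c_out * c_in * k * k edges carries an independent phi with
    a per-edge base weight and G spline coefficients (the scale w_s is
    absorbed into the coefficients), realized as two convolutions: a k x k
    conv over SiLU(x) plus a k x k conv over the RBF-expanded input.
    """

    def __init__(self, spec: KanConvSpec, rng: Optional[np.random.Generator] = None):
        super().__init__()
        if spec.variant not in ("vanilla", "fastkan"):
            raise ValueError("KANConv2d handles vanilla/fastkan variants")
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        G = spec.grid.size
        scale_b = np.sqrt(2.0 / (spec.c_in * spec.k ** 2))
        scale_s = np.sqrt(2.0 / (spec.c_in * spec.k ** 2 * G))
        self.w_base = Parameter(rng.normal(
            0, scale_b, (spec.c_out, spec.c_in, spec.k, spec.k)))
        self.w_spline = Parameter(rng.normal(
            0, scale_s, (spec.c_out, spec.c_in * G, spec.k, spec.k)))

    def __call__(self, x) -> Tensor:
        x = _as_tensor(x)
        base = conv2d(x.silu(), self.w_base, None, self.spec.padding)
        spline = conv2d(_rbf_tensor(x, self.spec.grid), self.w_spline,
                        None, self.spec.padding)
        return base + spline


class ReverseBottleneckKANConv2d(Module):
    """Reverse-bottleneck KAN convolution.

    Spline branch: 1x1 expand to e*c_in channels, per-expanded-channel edge
    function (base weight w_b[c] on SiLU plus G RBF coefficients), 1x1
    reduce to c_out. Base branch: k x k convolution of SiLU(x) -- exactly
    the summed w_b * b(.) base terms of the edge functions, with the conv
    weights playing the role of the per-edge base weights. Branch outputs
    are summed; 'same' padding preserves the spatial grid.
    """

    def __init__(self, spec: KanConvSpec, rng: Optional[np.random.Generator] = None):
        super().__init__()
        if spec.variant != "reverse_bottleneck":
            raise ValueError("spec.variant must be 'reverse_bottleneck'")
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        ec, G = spec.expanded, spec.grid.size
        self.expand = Conv2d(spec.c_in, ec, 1, rng=rng, bias=True)
        self.w_b = Parameter(np.ones(ec))
        self.coeffs = Parameter(rng.normal(0, np.sqrt(1.0 / G), (ec, G, 1, 1)))
        self.reduce = Conv2d(ec, spec.c_out, 1, rng=rng, bias=True)
        self.base = Conv2d(spec.c_in, spec.c_out, spec.k, rng=rng,
                           padding=spec.padding, bias=False)

    def __call__(self, x) -> Tensor:
        x = _as_tensor(x)
        h = self.expand(x)
        ec, G = self.spec.expanded, self.spec.grid.size
        spline = conv2d(_rbf_tensor(h, self.spec.grid),
                        self.coeffs.reshape(ec, G, 1, 1), None,
                        "same", groups=ec)
        phi = h.silu() * self.w_b.reshape(1, ec, 1, 1) + spline
        return self.reduce(phi) + self.base(x.silu())


class StandardConv2d(Module):
    """Plain shared-weight convolution (the baseline Min-PointNet layer)."""

    def __init__(self, spec_or_cin, c_out=None, k=1, rng=None, padding="same"):
        super().__init__()
        if isinstance(spec_or_cin, KanConvSpec):
            s = spec_or_cin
            c_in, c_out, k, padding = s.c_in, s.c_out, s.k, s.padding
        else:
            c_in = spec_or_cin
        self.conv = Conv2d(c_in, c_out, k, rng=rng, padding=padding, bias=True)

    def __call__(self, x) -> Tensor:
        return self.conv(_as_tensor(x))


def make_conv(spec: KanConvSpec, rng=None) -> Module:
    if spec.variant in ("vanilla", "fastkan"):
        return KANConv2d(spec, rng)
    return ReverseBottleneckKANConv2d(spec, rng)


def conv_parameter_count(spec: KanConvSpec) -> int:
    """Closed-form learnable-scalar count per variant.

    vanilla / fastkan:  c_out * c_in * k^2 * (G + 1)
        (one base weight plus G spline coefficients per edge; the two
         variants differ only in the basis family, not in count)
    reverse_bottleneck: expand (c_in*e*c_in + e*c_in) + per-channel edges
        (e*c_in base weights + e*c_in*G coefficients) + reduce
        (e*c_in*c_out + c_out) + base k x k conv (c_in*c_out*k^2)
    """
    G = spec.grid.size
    if spec.variant in ("vanilla", "fastkan"):
        return spec.c_out * spec.c_in * spec.k ** 2 * (G + 1)
    ec = spec.expanded
    return (spec.c_in * ec + ec            # expand conv + bias
            + ec + ec * G                  # per-channel w_b and coeffs
            + ec * spec.c_out + spec.c_out  # reduce conv + bias
            + spec.c_in * spec.c_out * spec.k ** 2)  # base branch
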