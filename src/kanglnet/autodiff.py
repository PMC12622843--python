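"""Compact reverse-mode autodiff core used by the segmentation network.

A :class:`Tensor` wraps a numpy array and records the operations applied
to it; :meth:`Tensor.backward` walks the tape in reverse topological
order accumulating gradients. The op set is exactly what the KAN / GLFN
point-network needs: broadcast arithmetic, matmul, reshaping, gather,
reductions, the usual activations, and a stride-1 grouped 2-D
convolution implemented as a sum over kernel offsets (kernels here are
1x1 or 3x3, so the offset loop is at most nine fused numpy updates).

Layers follow the familiar Module/Parameter idiom with a recursive
``parameters()`` and a train/eval flag for batch-norm running statistics;
:class:`AdamW` implements decoupled weight decay.
"""
from __future__ import annotations

import math
from typing import Iterable, List, Optional, Sequence

import numpy as np
from scipy.special import erf as _erf

_F = np.float64


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_F)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- graph bookkeeping ------------------------------------------------
    @classmethod
    def _make(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad, own: bool = False):
        """Accumulate a gradient; ``own=True`` promises ``grad`` is a fresh
        array the op will not reuse, allowing copy-free assignment."""
        if self.grad is None:
            self.grad = grad if own else np.array(grad, dtype=_F)
        else:
            self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(t):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self._accum(np.asarray(grad, dtype=_F))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                ga = _unbroadcast(g, self.data.shape)
                self._accum(ga, own=ga is not g)
            if other.requires_grad:
                gb = _unbroadcast(g, other.data.shape)
                other._accum(gb, own=gb is not g)
        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g, own=True)
        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape),
                            own=True)
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape),
                             own=True)
        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            self._accum(g * p * self.data ** (p - 1.0), own=True)
        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape), own=True)
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape), own=True)
        return Tensor._make(out_data, (self, other), bw)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape

        def bw(g):
            self._accum(g.reshape(src))
        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))
        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, key):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full, own=True)
        return Tensor._make(self.data[key], (self,), bw)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy(), own=True)
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), bw)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims=False):
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis),
                                      axis=axis)

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
            self._accum(full, own=True)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)
        return Tensor._make(out_data, (self,), bw)

    # -- activations -----------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data, own=True)
        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data, own=True)
        return Tensor._make(np.log(self.data), (self,), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * s * (1.0 - s), own=True)
        return Tensor._make(s, (self,), bw)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * (s + self.data * s * (1.0 - s)), own=True)
        return Tensor._make(self.data * s, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask, own=True)
        return Tensor._make(self.data * mask, (self,), bw)

    def gelu(self):
        x = self.data
        cdf = 0.5 * (1.0 + _erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)

        def bw(g):
            self._accum(g * (cdf + x * pdf), own=True)
        return Tensor._make(x * cdf, (self,), bw)

    def softmax(self, axis: int):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accum(s * (g - dot), own=True)
        return Tensor._make(s, (self,), bw)


def concatenate(tensors: Sequence[Tensor], axis: int) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, bw)


def take(t: Tensor, idx: np.ndarray, axis: int) -> Tensor:
    """Gather along ``axis`` with integer index array; scatter-add backward."""
    idx = np.asarray(idx)

    def bw(g):
        full = np.zeros_like(t.data)
        # in the output, dims [axis, axis+idx.ndim) index into idx
        g_front = np.moveaxis(g, tuple(range(axis, axis + idx.ndim)),
                              tuple(range(idx.ndim)))
        np.add.at(np.moveaxis(full, axis, 0), idx, g_front)
        t._accum(full, own=True)
    return Tensor._make(np.take(t.data, idx, axis=axis), (t,), bw)


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           padding: str = "same", groups: int = 1) -> Tensor:
    """Stride-1 grouped 2-D convolution, summing over kernel offsets.

    ``x``: (B, C, H, W); ``w``: (C_out, C // groups, kh, kw);
    ``b``: (C_out,) or None. ``padding`` is 'same' or 'valid'.
    """
    B, C, H, W = x.data.shape
    Cout, Cg, kh, kw = w.data.shape
    G = groups
    if C % G or Cout % G or Cg != C // G:
        raise ValueError("inconsistent channel/group configuration")
    if padding == "same":
        ph, pw = (kh - 1) // 2, (kw - 1) // 2
        Ho, Wo = H, W
    elif padding == "valid":
        ph = pw = 0
        Ho, Wo = H - kh + 1, W - kw + 1
        if Ho < 1 or Wo < 1:
            raise ValueError("kernel larger than input under valid padding")
    else:
        raise ValueError(f"unknown padding {padding!r}")
    L = Ho * Wo
    Og = Cout // G
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, kh - 1 - ph), (pw, kw - 1 - pw))) \
        if (kh > 1 or kw > 1) else x.data
    xg = xp.reshape(B, G, Cg, *xp.shape[2:])
    wg = w.data.reshape(G, Og, Cg, kh, kw)
    # per-offset flattened patches; all contractions are batched matmuls
    patches = {}
    out = None
    for a in range(kh):
        for c in range(kw):
            patch = np.ascontiguousarray(
                xg[:, :, :, a:a + Ho, c:c + Wo]).reshape(B, G, Cg, L)
            patches[a, c] = patch
            term = np.matmul(wg[None, :, :, :, a, c], patch)
            out = term if out is None else out + term
    out = out.reshape(B, Cout, Ho, Wo)
    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gg = np.ascontiguousarray(g).reshape(B, G, Og, L)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)), own=True)
        if w.requires_grad:
            gw = np.empty_like(wg)
            for (a, c), patch in patches.items():
                gw[:, :, :, a, c] = np.matmul(
                    gg, patch.swapaxes(-1, -2)).sum(axis=0)
            w._accum(gw.reshape(w.data.shape), own=True)
        if x.requires_grad:
            gxp = np.zeros_like(xg)
            wt = wg.transpose(3, 4, 0, 2, 1)          # (kh, kw, G, Cg, Og)
            for a in range(kh):
                for c in range(kw):
                    gpatch = np.matmul(wt[None, a, c], gg)     # (B,G,Cg,L)
                    gxp[:, :, :, a:a + Ho, c:c + Wo] += \
                        gpatch.reshape(B, G, Cg, Ho, Wo)
            gx = gxp.reshape(xp.shape)
            if kh > 1 or kw > 1:
                gx = np.ascontiguousarray(gx[:, :, ph:ph + H, pw:pw + W])
            x._accum(gx, own=True)
    return Tensor._make(out, parents, bw)


# ---------------------------------------------------------------------------
# Modules


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    def parameters(self) -> List[Parameter]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def modules(self) -> List["Module"]:
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict:
        """Flat name -> array mapping covering parameters and buffers."""
        out = {}

        def walk(mod, prefix):
            for k, v in mod.__dict__.items():
                name = f"{prefix}{k}"
                if isinstance(v, Parameter):
                    out[name] = v.data
                elif isinstance(v, np.ndarray):
                    out[name] = v
                elif isinstance(v, Module):
                    walk(v, name + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{name}.{i}.")
                        elif isinstance(item, Parameter):
                            out[f"{name}.{i}"] = item.data
        walk(self, "")
        return out

    def load_state_dict(self, state: dict):
        def walk(mod, prefix):
            for k, v in mod.__dict__.items():
                name = f"{prefix}{k}"
                if isinstance(v, Parameter):
                    v.data = np.asarray(state[name], dtype=_F).reshape(v.data.shape)
                elif isinstance(v, np.ndarray):
                    mod.__dict__[k] = np.asarray(state[name], dtype=_F).reshape(v.shape)
                elif isinstance(v, Module):
                    walk(v, name + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{name}.{i}.")
                        elif isinstance(item, Parameter):
                            item.data = np.asarray(
                                state[f"{name}.{i}"], dtype=_F
                            ).reshape(item.data.shape)
        walk(self, "")
        return self


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / max(fan_in, 1)), size=shape)


class Conv2d(Module):
    """Stride-1 grouped 2-D convolution layer ('same' or 'valid' padding)."""

    def __init__(self, c_in, c_out, kernel_size=1, rng=None, padding="same",
                 groups=1, bias=True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = kernel_size if isinstance(kernel_size, tuple) else (kernel_size,) * 2
        fan_in = (c_in // groups) * k[0] * k[1]
        self.weight = Parameter(_kaiming(rng, (c_out, c_in // groups, *k), fan_in))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.padding = padding
        self.groups = groups

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.padding, self.groups)


class Linear(Module):
    def __init__(self, n_in, n_out, rng=None, bias=True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, (n_in, n_out), n_in))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        return out if self.bias is None else out + self.bias


class BatchNorm2d(Module):
    """Batch normalization over (B, H, W) per channel with running stats."""

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        sh = (1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = Tensor(self.running_mean.reshape(sh))
            var = Tensor(self.running_var.reshape(sh))
            xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(sh) + self.beta.reshape(sh)


def layer_norm(x: Tensor, axis: int, eps: float = 1e-5) -> Tensor:
    """Plain layer normalization over ``axis`` (no affine)."""
    mu = x.mean(axis=axis, keepdims=True)
    var = ((x - mu) ** 2.0).mean(axis=axis, keepdims=True)
    return (x - mu) * (var + eps) ** -0.5


class LayerNorm(Module):
    """Layer normalization over a chosen axis with learnable affine."""

    def __init__(self, channels, axis=1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.axis = axis
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        sh = [1] * x.ndim
        sh[self.axis] = -1
        xhat = layer_norm(x, self.axis, self.eps)
        return xhat * self.gamma.reshape(sh) + self.beta.reshape(sh)


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: Iterable[Parameter], lr=1e-3, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
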