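"""Reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations that
produced it; calling :meth:`Tensor.backward` propagates gradients to every
tensor created with ``requires_grad=True``.  Only the handful of operations
a convolutional detector needs are provided: 2-D convolution (im2col),
batch normalization, max pooling, nearest-neighbour upsampling, pointwise
activations, addition, concatenation and shape manipulation.

The engine is deliberately eager and array-level: each operation computes
its result immediately with vectorised numpy and stores a closure for the
backward pass.  Gradient correctness of every primitive is checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad=None):
        """Accumulate gradients of ``self`` w.r.t. every reachable leaf.

        ``grad`` seeds the output gradient; it defaults to ones (i.e. the
        gradient of ``self.sum()``).
        """
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        _accumulate(self, np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # interior activations are not inspected after the sweep;
                # drop their gradients to bound peak memory
                if not node.requires_grad:
                    node.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)


def backward_multi(seeded: list[tuple["Tensor", np.ndarray]]) -> None:
    """Backpropagate from several roots in one sweep.

    ``seeded`` pairs each root tensor with its output gradient.  A single
    topological pass over the union graph is much cheaper than one
    :meth:`Tensor.backward` call per root when the roots share most of
    their history (e.g. per-level detector heads over one backbone).
    """
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(t, False) for t, _ in seeded]
    while stack:
        node, done = stack.pop()
        if done:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    for t, g in seeded:
        _accumulate(t, np.asarray(g, dtype=np.float32))
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)
            if not node.requires_grad:
                node.grad = None


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


def _make(data, parents, backward) -> Tensor:
    """Build an op result, attaching the graph only when gradients flow."""
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# convolution


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """Extract sliding patches from padded input; (N, OH*OW, C*kh*kw)."""
    n, c, _, _ = xp.shape
    v = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    v = v[:, :, ::sh, ::sw]  # (N, C, OH, OW, kh, kw)
    oh, ow = v.shape[2], v.shape[3]
    cols = v.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation with square stride/padding, NCHW layout."""
    n, c, h, wd = x.data.shape
    f, cw, kh, kw = w.data.shape
    if cw != c:
        raise ValueError(f"conv2d channel mismatch: input has {c}, weight expects {cw}")
    p, s = padding, stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    cols, oh, ow = _im2col(xp, kh, kw, s, s)
    wm = w.data.reshape(f, c * kh * kw)
    out = cols @ wm.T  # (N, L, F)
    if b is not None:
        out += b.data
    out = out.transpose(0, 2, 1).reshape(n, f, oh, ow)

    def backward(g):
        g3 = g.reshape(n, f, oh * ow).transpose(0, 2, 1)  # (N, L, F)
        if w.requires_grad or w._parents:
            gw = np.tensordot(g3, cols, axes=([0, 1], [0, 1]))
            _accumulate(w, gw.reshape(w.data.shape))
        if b is not None and (b.requires_grad or b._parents):
            _accumulate(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gcols = (g3 @ wm).reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
            hp, wp = h + 2 * p, wd + 2 * p
            gxp = np.zeros((n, c, hp, wp), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += gcols[:, :, i, j]
            _accumulate(x, gxp[:, :, p : p + h, p : p + wd] if p else gxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


# ---------------------------------------------------------------------------
# normalisation and pooling


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation with affine transform.

    Running statistics are plain arrays updated in-place during training and
    used verbatim in inference mode.
    """
    xd = x.data
    if training:
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    std = np.sqrt(var + eps)
    xhat = (xd - mean[None, :, None, None]) / std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad or gamma._parents:
            _accumulate(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad or beta._parents:
            _accumulate(beta, g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            k = (gamma.data / std)[None, :, None, None]
            if training:
                m = float(g.shape[0] * g.shape[2] * g.shape[3])
                gm = g.sum(axis=(0, 2, 3))[None, :, None, None] / m
                gxm = (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None] / m
                _accumulate(x, k * (g - gm - xhat * gxm))
            else:
                _accumulate(x, k * g)

    return _make(out, (x, gamma, beta), backward)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    n, c, h, w = x.data.shape
    k, s, p = kernel, stride, padding
    pad_val = np.float32(-np.inf)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=pad_val) if p else x.data
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    oh, ow = v.shape[2], v.shape[3]
    vflat = v.reshape(n, c, oh, ow, k * k)
    idx = vflat.argmax(axis=-1)
    out = np.take_along_axis(vflat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not (x.requires_grad or x._parents):
            return
        hp, wp = h + 2 * p, w + 2 * p
        gxp = np.zeros((n, c, hp, wp), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                mask = idx == (i * k + j)
                gxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += g * mask
        _accumulate(x, gxp[:, :, p : p + h, p : p + w] if p else gxp)

    return _make(out, (x,), backward)


def upsample_nearest(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Nearest-neighbour resize to ``size`` (used by the top-down pathway)."""
    n, c, h, w = x.data.shape
    oh, ow = size
    rows = (np.arange(oh) * h // oh).astype(np.intp)
    cols = (np.arange(ow) * w // ow).astype(np.intp)
    out = x.data[:, :, rows[:, None], cols[None, :]]

    def backward(g):
        if not (x.requires_grad or x._parents):
            return
        gx = np.zeros((n, c, h, w), dtype=np.float32)
        np.add.at(gx, (slice(None), slice(None), rows[:, None], cols[None, :]), g)
        _accumulate(x, gx)

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# pointwise and structural ops


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g):
        if x.requires_grad or x._parents:
            _accumulate(x, g * mask)

    return _make(out, (x,), backward)


def leaky_relu(x: Tensor, negative_slope: float = 0.01) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, negative_slope * x.data)

    def backward(g):
        if x.requires_grad or x._parents:
            _accumulate(x, g * np.where(mask, 1.0, negative_slope).astype(np.float32))

    return _make(out, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"add shape mismatch: {a.data.shape} vs {b.data.shape}")
    out = a.data + b.data

    def backward(g):
        if a.requires_grad or a._parents:
            _accumulate(a, g)
        if b.requires_grad or b._parents:
            _accumulate(b, g)

    return _make(out, (a, b), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                _accumulate(t, g[tuple(sl)])

    return _make(out, tuple(tensors), backward)


def reshape(x: Tensor, shape) -> Tensor:
    out = x.data.reshape(shape)

    def backward(g):
        if x.requires_grad or x._parents:
            _accumulate(x, g.reshape(x.data.shape))

    return _make(out, (x,), backward)


def transpose(x: Tensor, axes) -> Tensor:
    out = np.ascontiguousarray(x.data.transpose(axes))
    inv = np.argsort(axes)

    def backward(g):
        if x.requires_grad or x._parents:
            _accumulate(x, g.transpose(inv))

    return _make(out, (x,), backward)
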