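"""Reverse-mode autodiff primitives for the 3D segmentation network.

A deliberately small tape-based engine over numpy ``float64`` arrays: enough
to express stride-1 same-padded 3D convolutions, batch normalisation, ELU,
non-overlapping max pooling, nearest-neighbour upsampling, channel
slicing/padding for identity shortcuts, and a fused softmax cross-entropy.
Arrays are batched ``(N, C, Z, Y, X)``. Everything is CPU numpy; determinism
is the floating-point reproducibility of numpy itself.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Parameter",
    "backward",
    "conv3d",
    "add",
    "elu",
    "maxpool3d",
    "upsample_nearest",
    "channel_slice",
    "channel_pad",
    "BatchNorm3d",
    "softmax",
    "softmax_cross_entropy",
    "scale",
    "add_scalars",
    "sum_squares",
    "Adam",
]

# im2col column matrices above this byte count fall back to the loop-over-
# kernel-offsets path (slower per call, O(input) memory).
_IM2COL_BYTE_LIMIT = 192 * 1024 * 1024


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward_fn: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward_fn

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data: np.ndarray) -> None:
        super().__init__(data, requires_grad=True)

    @property
    def size(self) -> int:
        return int(self.data.size)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad or t._parents:
        t.grad = g if t.grad is None else t.grad + g


def backward(root: Tensor) -> None:
    """Backpropagate from a scalar root through the recorded tape."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    root.grad = np.ones_like(root.data)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1 3D convolution with zero 'same' padding (odd kernels only)."""
    xd, wd = x.data, w.data
    n, cin, z, y, xx = xd.shape
    cout, cin_w, kz, ky, kx = wd.shape
    if cin != cin_w:
        raise ValueError(f"input has {cin} channels, kernel expects {cin_w}")
    pz, py, px = kz // 2, ky // 2, kx // 2
    xp = np.pad(xd, ((0, 0), (0, 0), (pz, pz), (py, py), (px, px)))
    v = z * y * xx
    k = cin * kz * ky * kx
    use_cols = n * v * k * 8 <= _IM2COL_BYTE_LIMIT
    wmat = wd.reshape(cout, k)

    if use_cols:
        win = sliding_window_view(xp, (kz, ky, kx), axis=(2, 3, 4))
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(n * v, k)
        out = (cols @ wmat.T).reshape(n, z, y, xx, cout).transpose(0, 4, 1, 2, 3)
    else:
        cols = None
        out = np.zeros((n, cout, z, y, xx))
        for dz in range(kz):
            for dy in range(ky):
                for dx in range(kx):
                    xs = xp[:, :, dz : dz + z, dy : dy + y, dx : dx + xx]
                    part = np.tensordot(wd[:, :, dz, dy, dx], xs, axes=(1, 1))
                    out += part.transpose(1, 0, 2, 3, 4)
    out = out + b.data.reshape(1, cout, 1, 1, 1)

    def _bwd(g: np.ndarray) -> None:
        _accumulate(b, g.sum(axis=(0, 2, 3, 4)))
        gflat = g.transpose(0, 2, 3, 4, 1).reshape(n * v, cout)
        dxp = np.zeros_like(xp)
        if cols is not None:
            _accumulate(w, (gflat.T @ cols).reshape(wd.shape))
            dcols = (gflat @ wmat).reshape(n, z, y, xx, cin, kz, ky, kx)
            for dz in range(kz):
                for dy in range(ky):
                    for dx in range(kx):
                        dxp[:, :, dz : dz + z, dy : dy + y, dx : dx + xx] += (
                            dcols[:, :, :, :, :, dz, dy, dx].transpose(0, 4, 1, 2, 3)
                        )
        else:
            dw = np.empty_like(wd)
            for dz in range(kz):
                for dy in range(ky):
                    for dx in range(kx):
                        xs = xp[:, :, dz : dz + z, dy : dy + y, dx : dx + xx]
                        dw[:, :, dz, dy, dx] = np.tensordot(
                            g, xs, axes=([0, 2, 3, 4], [0, 2, 3, 4])
                        )
                        dxp[:, :, dz : dz + z, dy : dy + y, dx : dx + xx] += np.tensordot(
                            wd[:, :, dz, dy, dx], g, axes=(0, 1)
                        ).transpose(1, 0, 2, 3, 4)
            _accumulate(w, dw)
        dx = dxp[:, :, pz : pz + z, py : py + y, px : px + xx]
        _accumulate(x, dx)

    return Tensor(out, parents=(x, w, b), backward_fn=_bwd)


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def _bwd(g: np.ndarray) -> None:
        _accumulate(a, g)
        _accumulate(b, g)

    return Tensor(out, parents=(a, b), backward_fn=_bwd)


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    pos = x.data > 0
    out = np.where(pos, x.data, alpha * np.expm1(x.data))

    def _bwd(g: np.ndarray) -> None:
        _accumulate(x, g * np.where(pos, 1.0, out + alpha))

    return Tensor(out, parents=(x,), backward_fn=_bwd)


def maxpool3d(x: Tensor, stride: tuple[int, int, int]) -> Tensor:
    """Non-overlapping max pooling; window equals stride per axis."""
    n, c, z, y, xx = x.data.shape
    sz, sy, sx = stride
    for name, dim, s in (("z", z, sz), ("y", y, sy), ("x", xx, sx)):
        if dim % s != 0:
            raise ValueError(
                f"axis {name} extent {dim} not divisible by pooling stride {s}"
            )
    zo, yo, xo = z // sz, y // sy, xx // sx
    xr = x.data.reshape(n, c, zo, sz, yo, sy, xo, sx)
    xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, zo, yo, xo, sz * sy * sx)
    idx = np.argmax(xr, axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def _bwd(g: np.ndarray) -> None:
        dxr = np.zeros((n, c, zo, yo, xo, sz * sy * sx))
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(n, c, zo, yo, xo, sz, sy, sx).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        _accumulate(x, dx.reshape(n, c, z, y, xx))

    return Tensor(out, parents=(x,), backward_fn=_bwd)


def upsample_nearest(x: Tensor, factors: tuple[int, int, int]) -> Tensor:
    fz, fy, fx = factors
    out = np.repeat(np.repeat(np.repeat(x.data, fz, axis=2), fy, axis=3), fx, axis=4)

    def _bwd(g: np.ndarray) -> None:
        n, c, z, y, xx = x.data.shape
        gr = g.reshape(n, c, z, fz, y, fy, xx, fx)
        _accumulate(x, gr.sum(axis=(3, 5, 7)))

    return Tensor(out, parents=(x,), backward_fn=_bwd)


def channel_slice(x: Tensor, channels: int) -> Tensor:
    """Keep the first ``channels`` channels (parameter-free reduction)."""
    out = x.data[:, :channels].copy()

    def _bwd(g: np.ndarray) -> None:
        dx = np.zeros_like(x.data)
        dx[:, :channels] = g
        _accumulate(x, dx)

    return Tensor(out, parents=(x,), backward_fn=_bwd)


def channel_pad(x: Tensor, channels: int) -> Tensor:
    """Zero-pad channels up to ``channels`` (identity-shortcut widening)."""
    n, c = x.data.shape[:2]
    if channels < c:
        raise ValueError(f"cannot pad {c} channels down to {channels}")
    out = np.zeros((n, channels) + x.data.shape[2:])
    out[:, :c] = x.data

    def _bwd(g: np.ndarray) -> None:
        _accumulate(x, g[:, :c])

    return Tensor(out, parents=(x,), backward_fn=_bwd)


class BatchNorm3d:
    """Per-channel batch normalisation with running inference statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    @property
    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        sh = (1, -1, 1, 1, 1)
        if train:
            mean = x.data.mean(axis=(0, 2, 3, 4))
            var = x.data.var(axis=(0, 2, 3, 4))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean.reshape(sh)) * inv_std.reshape(sh)
        out = self.gamma.data.reshape(sh) * xhat + self.beta.data.reshape(sh)
        gamma, beta = self.gamma, self.beta

        if train:
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3] * x.data.shape[4]

            def _bwd(g: np.ndarray) -> None:
                dbeta = g.sum(axis=(0, 2, 3, 4))
                dgamma = (g * xhat).sum(axis=(0, 2, 3, 4))
                _accumulate(beta, dbeta)
                _accumulate(gamma, dgamma)
                coef = (gamma.data * inv_std).reshape(sh)
                dx = coef * (g - (dbeta / m).reshape(sh) - xhat * (dgamma / m).reshape(sh))
                _accumulate(x, dx)

        else:

            def _bwd(g: np.ndarray) -> None:
                _accumulate(beta, g.sum(axis=(0, 2, 3, 4)))
                _accumulate(gamma, (g * xhat).sum(axis=(0, 2, 3, 4)))
                _accumulate(x, g * (gamma.data * inv_std).reshape(sh))

        return Tensor(out, parents=(x, gamma, beta), backward_fn=_bwd)

    def state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean.copy(), "running_var": self.running_var.copy()}


# ---------------------------------------------------------------------------
# loss heads
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean-over-voxels cross-entropy with fused softmax backward.

    ``labels`` is an integer array of shape (N, Z, Y, X) with values in
    [0, C-1]; ``logits`` has shape (N, C, Z, Y, X).
    """
    probs = softmax(logits.data, axis=1)
    n, c, z, y, xx = logits.data.shape
    onehot_idx = labels.astype(np.intp)
    if onehot_idx.shape != (n, z, y, xx):
        raise ValueError(
            f"labels shape {labels.shape} incompatible with logits {logits.data.shape}"
        )
    m = n * z * y * xx
    picked = np.take_along_axis(probs, onehot_idx[:, None], axis=1)[:, 0]
    loss = -np.log(np.clip(picked, 1e-300, None)).sum() / m

    def _bwd(g: np.ndarray) -> None:
        grad = probs.copy()
        np.put_along_axis(grad, onehot_idx[:, None], (picked - 1.0)[:, None], axis=1)
        _accumulate(logits, g * grad / m)

    return Tensor(loss, parents=(logits,), backward_fn=_bwd)


def scale(x: Tensor, c: float) -> Tensor:
    def _bwd(g: np.ndarray) -> None:
        _accumulate(x, g * c)

    return Tensor(x.data * c, parents=(x,), backward_fn=_bwd)


def add_scalars(terms: Sequence[Tensor]) -> Tensor:
    out = sum(t.data for t in terms)

    def _bwd(g: np.ndarray) -> None:
        for t in terms:
            _accumulate(t, g)

    return Tensor(out, parents=tuple(terms), backward_fn=_bwd)


def sum_squares(params: Sequence[Parameter]) -> Tensor:
    out = sum(float((p.data**2).sum()) for p in params)

    def _bwd(g: np.ndarray) -> None:
        for p in params:
            _accumulate(p, g * 2.0 * p.data)

    return Tensor(out, parents=tuple(params), backward_fn=_bwd)


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive moment estimation over a list of parameters."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m += (1.0 - b1) * (p.grad - m)
            v += (1.0 - b2) * (p.grad**2 - v)
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
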