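"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the primitives a small convolutional regression network
needs: dense/convolutional affine maps, batch normalization, SiLU/ReLU,
max/average pooling, channel split/concat and an MSE loss. Gradients are
accumulated by a topological sweep over the recorded op graph, micrograd
style, with float32 storage throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "add",
    "linear",
    "conv2d",
    "batch_norm2d",
    "silu",
    "relu",
    "max_pool2d",
    "global_avg_pool2d",
    "flatten",
    "concat",
    "narrow",
    "mse_loss",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        if self.data.size != 1:
            raise ValueError(f"item() requires a single-element tensor, shape {self.shape}")
        return float(self.data.reshape(-1)[0])

    def _ensure_grad(self) -> np.ndarray:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        return self.grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data
    out = Tensor(out_data)

    def _bw():
        if a.requires_grad or a._parents:
            a._ensure_grad()
            a.grad += out.grad
        if b.requires_grad or b._parents:
            b._ensure_grad()
            b.grad += out.grad

    return _finish(out, (a, b), _bw)


def _finish(out: Tensor, parents, backward) -> Tensor:
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def linear(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """y = x @ w.T + b with x of shape (N, D) and w of shape (F, D)."""
    y = x.data @ w.data.T
    if b is not None:
        y = y + b.data
    out = Tensor(y)

    def _bw():
        g = out.grad
        if w.requires_grad:
            w._ensure_grad()
            w.grad += g.T @ x.data
        if b is not None and b.requires_grad:
            b._ensure_grad()
            b.grad += g.sum(axis=0)
        if x.requires_grad or x._parents:
            x._ensure_grad()
            x.grad += g @ w.data

    parents = (x, w) if b is None else (x, w, b)
    return _finish(out, parents, _bw)


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation. ``w`` has shape (F, C // groups, kh, kw).

    The depthwise case (groups == C == F) is handled without an explicit
    group loop; other group counts fall back to per-group im2col.
    """
    xd, wd = x.data, w.data
    n, c, h, wdt = xd.shape
    f, cg, kh, kw = wd.shape
    s, p = stride, padding
    oh = (h + 2 * p - kh) // s + 1
    ow = (wdt + 2 * p - kw) // s + 1
    if oh < 1 or ow < 1:
        raise ValueError(
            f"conv2d: spatial collapse — input {h}x{wdt} with kernel {kh}, "
            f"stride {s}, padding {p} yields {oh}x{ow}"
        )
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]

    depthwise = groups == c and f == c and cg == 1
    if depthwise:
        out_data = np.einsum("nchwij,cij->nchw", win, wd[:, 0], optimize=True)
        if b is not None:
            out_data = out_data + b.data[None, :, None, None]
        cols = None
        wmat = None
    elif groups == 1:
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n, oh * ow, c * kh * kw
        )
        wmat = wd.reshape(f, -1)
        out_data = (cols @ wmat.T).transpose(0, 2, 1).reshape(n, f, oh, ow)
        if b is not None:
            out_data += b.data[None, :, None, None]
    else:
        cin_g, f_g = c // groups, f // groups
        cols = [
            np.ascontiguousarray(
                win[:, g * cin_g : (g + 1) * cin_g].transpose(0, 2, 3, 1, 4, 5)
            ).reshape(n, oh * ow, cin_g * kh * kw)
            for g in range(groups)
        ]
        wmat = wd.reshape(groups, f_g, -1)
        out_data = np.concatenate(
            [
                (cols[g] @ wmat[g].T).transpose(0, 2, 1).reshape(n, f_g, oh, ow)
                for g in range(groups)
            ],
            axis=1,
        )
        if b is not None:
            out_data += b.data[None, :, None, None]
    out = Tensor(out_data)

    def _col2im(dcols, cin_slice=slice(None)):
        """Scatter (N, OH, OW, Cs, kh, kw) gradients back to padded input."""
        nonlocal gxp
        for i in range(kh):
            for j in range(kw):
                gxp[:, cin_slice, i : i + s * oh : s, j : j + s * ow : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)

    gxp = None

    def _bw():
        nonlocal gxp
        g = out.grad
        need_x = x.requires_grad or x._parents
        if need_x:
            gxp = np.zeros_like(xp)
        if b is not None and b.requires_grad:
            b._ensure_grad()
            b.grad += g.sum(axis=(0, 2, 3))
        if depthwise:
            if w.requires_grad:
                w._ensure_grad()
                w.grad += np.einsum("nchwij,nchw->cij", win, g, optimize=True)[
                    :, None
                ]
            if need_x:
                dcols = np.einsum("nchw,cij->nhwcij", g, wd[:, 0], optimize=True)
                _col2im(dcols)
        elif groups == 1:
            gmat = g.reshape(n, f, oh * ow)
            if w.requires_grad:
                w._ensure_grad()
                w.grad += (
                    np.einsum("nfo,nok->fk", gmat, cols, optimize=True)
                ).reshape(wd.shape)
            if need_x:
                dcols = np.einsum("nfo,fk->nok", gmat, wmat, optimize=True)
                _col2im(dcols.reshape(n, oh, ow, c, kh, kw))
        else:
            cin_g, f_g = c // groups, f // groups
            for grp in range(groups):
                gg = g[:, grp * f_g : (grp + 1) * f_g].reshape(n, f_g, oh * ow)
                if w.requires_grad:
                    w._ensure_grad()
                    w.grad[grp * f_g : (grp + 1) * f_g] += np.einsum(
                        "nfo,nok->fk", gg, cols[grp], optimize=True
                    ).reshape(f_g, cin_g, kh, kw)
                if need_x:
                    dcols = np.einsum("nfo,fk->nok", gg, wmat[grp], optimize=True)
                    _col2im(
                        dcols.reshape(n, oh, ow, cin_g, kh, kw),
                        slice(grp * cin_g, (grp + 1) * cin_g),
                    )
        if need_x:
            x._ensure_grad()
            if p:
                x.grad += gxp[:, :, p : p + h, p : p + wdt]
            else:
                x.grad += gxp
            gxp = None

    parents = (x, w) if b is None else (x, w, b)
    return _finish(out, parents, _bw)


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
    """Channel-wise batch normalization over (N, H, W).

    Running statistics are updated in place during training and used verbatim
    in evaluation mode, so inference is deterministic for fixed weights.
    """
    xd = x.data
    n, c, h, w = xd.shape
    m = n * h * w
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        # unbiased variance for the running estimate, as is conventional
        running_var *= 1.0 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out = Tensor(xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None])

    def _bw():
        g = out.grad
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        if gamma.requires_grad:
            gamma._ensure_grad()
            gamma.grad += dgamma
        if beta.requires_grad:
            beta._ensure_grad()
            beta.grad += dbeta
        if x.requires_grad or x._parents:
            x._ensure_grad()
            k = (gamma.data * inv_std)[None, :, None, None]
            if training:
                x.grad += k * (
                    g
                    - dbeta[None, :, None, None] / m
                    - xhat * dgamma[None, :, None, None] / m
                )
            else:
                x.grad += k * g

    return _finish(out, (x, gamma, beta), _bw)


def silu(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(x.data * s)

    def _bw():
        if x.requires_grad or x._parents:
            x._ensure_grad()
            x.grad += out.grad * (s * (1.0 + x.data * (1.0 - s)))

    return _finish(out, (x,), _bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0))

    def _bw():
        if x.requires_grad or x._parents:
            x._ensure_grad()
            x.grad += out.grad * mask

    return _finish(out, (x,), _bw)


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    s = stride or kernel
    xd = x.data
    n, c, h, w = xd.shape
    if padding:
        xp = np.pad(
            xd,
            ((0, 0), (0, 0), (padding, padding), (padding, padding)),
            constant_values=-np.inf,
        )
    else:
        xp = xd
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::s, ::s]
    n_, c_, oh, ow = win.shape[:4]
    flat = win.reshape(n, c, oh, ow, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0])

    def _bw():
        if not (x.requires_grad or x._parents):
            return
        gxp = np.zeros(xp.shape, dtype=np.float32)
        ni, ci, ohi, owi = np.indices((n, c, oh, ow), sparse=False)
        hi = ohi * s + idx // kernel
        wi = owi * s + idx % kernel
        np.add.at(gxp, (ni, ci, hi, wi), out.grad)
        x._ensure_grad()
        if padding:
            x.grad += gxp[:, :, padding : padding + h, padding : padding + w]
        else:
            x.grad += gxp

    return _finish(out, (x,), _bw)


def global_avg_pool2d(x: Tensor) -> Tensor:
    """Adaptive average pooling to 1x1 spatial size, returned as (N, C)."""
    n, c, h, w = x.data.shape
    out = Tensor(x.data.mean(axis=(2, 3)))

    def _bw():
        if x.requires_grad or x._parents:
            x._ensure_grad()
            x.grad += out.grad[:, :, None, None] / (h * w) * np.ones(
                (n, c, h, w), dtype=np.float32
            )

    return _finish(out, (x,), _bw)


def flatten(x: Tensor) -> Tensor:
    n = x.data.shape[0]
    orig = x.data.shape
    out = Tensor(x.data.reshape(n, -1))

    def _bw():
        if x.requires_grad or x._parents:
            x._ensure_grad()
            x.grad += out.grad.reshape(orig)

    return _finish(out, (x,), _bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents:
                t._ensure_grad()
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t.grad += out.grad[tuple(sl)]

    return _finish(out, tuple(tensors), _bw)


def narrow(x: Tensor, start: int, length: int, axis: int = 1) -> Tensor:
    sl = [slice(None)] * x.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)
    out = Tensor(x.data[sl])

    def _bw():
        if x.requires_grad or x._parents:
            x._ensure_grad()
            x.grad[sl] += out.grad

    return _finish(out, (x,), _bw)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    t = np.asarray(target, dtype=np.float32).reshape(pred.data.shape)
    diff = pred.data - t
    out = Tensor(np.float32(np.mean(diff**2)))

    def _bw():
        if pred.requires_grad or pred._parents:
            pred._ensure_grad()
            pred.grad += out.grad * 2.0 * diff / diff.size

    return _finish(out, (pred,), _bw)
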