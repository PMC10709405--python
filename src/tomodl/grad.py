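"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the unrolled reconstructor needs: 3x3
same-padding convolution (im2col + BLAS matmul), batch normalisation, ReLU,
elementwise arithmetic, a min-max normalisation with subgradients at the
extrema, a conjugate-gradient linear-system solve differentiated through the
implicit-function identity, and a mean-squared-error loss.  Gradients are
accumulated by reverse topological traversal of the recorded tape.

Shapes follow the channels-last (batch, height, width, channels) convention,
which keeps patch extraction for the convolution a set of contiguous block
copies.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "relu", "batch_norm", "minmax_normalize",
           "cg_solve_op", "mse", "Adam"]


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- tape bookkeeping ---------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(grad)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g, other.data.shape))

        return Tensor._make(self.data - other.data, (self, other), bw)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __radd__ = __add__
    __rmul__ = __mul__

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    @property
    def shape(self):
        return self.data.shape

    def item(self):
        return float(self.data)


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- convolution --------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, H, W, C) -> (B*H*W, k*k*C) patches of the zero-padded input."""
    p = k // 2
    b, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    col = np.empty((b, h, w, k * k * c), dtype=x.dtype)
    for ky in range(k):
        for kx in range(k):
            i = (ky * k + kx) * c
            col[..., i:i + c] = xp[:, ky:ky + h, kx:kx + w, :]
    return col.reshape(b * h * w, k * k * c)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padding 2-D convolution (cross-correlation).

    weight: (k, k, C, F); bias: (F,); x: (B, H, W, C) -> (B, H, W, F).
    """
    b, h, w, c = x.data.shape
    k, _, c2, f = weight.data.shape
    assert c == c2, "channel mismatch"
    col = _im2col(x.data, k)
    wmat = weight.data.reshape(k * k * c, f)
    out = (col @ wmat + bias.data).reshape(b, h, w, f)

    def bw(g):
        gmat = g.reshape(b * h * w, f)
        if weight.requires_grad:
            # recompute the patch matrix rather than keeping it on the tape:
            # one extra im2col costs far less than holding B*H*W x k*k*C
            # floats per layer per unrolled iteration
            weight._accum((_im2col(x.data, k).T @ gmat).reshape(k, k, c, f))
        if bias.requires_grad:
            bias._accum(gmat.sum(axis=0))
        if x.requires_grad:
            # dx = conv of g with spatially flipped, channel-transposed kernels
            w_rot = weight.data[::-1, ::-1].transpose(0, 1, 3, 2)
            gcol = _im2col(np.ascontiguousarray(g), k)
            dx = (gcol @ w_rot.reshape(k * k * f, c)).reshape(b, h, w, c)
            x._accum(dx)

    return Tensor._make(out, (x, weight, bias), bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        x._accum(g * mask)

    return Tensor._make(x.data * mask, (x,), bw)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running: dict,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over (B, H, W) for (B, H, W, C) input.

    ``running`` holds ``{"mean": (C,), "var": (C,)}`` updated in training mode
    and used verbatim in inference mode.
    """
    if training:
        mean = x.data.mean(axis=(0, 1, 2))
        var = x.data.var(axis=(0, 1, 2))
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mean
        running["var"] = (1 - momentum) * running["var"] + momentum * var
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mean) * inv
        out = gamma.data * xhat + beta.data

        def bw(grad):
            if gamma.requires_grad:
                gamma._accum((grad * xhat).sum(axis=(0, 1, 2)))
            if beta.requires_grad:
                beta._accum(grad.sum(axis=(0, 1, 2)))
            if x.requires_grad:
                m = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]
                gh = grad * gamma.data
                s1 = gh.sum(axis=(0, 1, 2), keepdims=True)
                s2 = (gh * xhat).sum(axis=(0, 1, 2), keepdims=True)
                dx = (gh - s1 / m - xhat * s2 / m) * inv
                x._accum(dx)

        return Tensor._make(out, (x, gamma, beta), bw)
    # inference: plain affine map with frozen statistics
    inv = 1.0 / np.sqrt(running["var"] + eps)
    scale = gamma.data * inv
    shift = beta.data - gamma.data * running["mean"] * inv
    xhat = (x.data - running["mean"]) * inv
    out = x.data * scale + shift

    def bw_eval(grad):
        if gamma.requires_grad:
            gamma._accum((grad * xhat).sum(axis=(0, 1, 2)))
        if beta.requires_grad:
            beta._accum(grad.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            x._accum(grad * scale)

    return Tensor._make(out, (x, gamma, beta), bw_eval)


# -- reconstruction-specific ops ----------------------------------------------

def minmax_normalize(x: Tensor, mask: np.ndarray, eps: float = 1e-12) -> Tensor:
    """Rescale each (B, H, W, 1) sample to [0, 1] by min-max over ``mask``.

    Pixels outside the mask are set to zero.  A constant sample (range below
    ``eps``) passes through unchanged.  Backward uses subgradients at the
    first argmin/argmax.
    """
    b = x.data.shape[0]
    out = np.zeros_like(x.data)
    info = []
    m3 = mask[..., None]
    midx = np.flatnonzero(mask.ravel())
    for i in range(b):
        v = x.data[i, :, :, 0].ravel()[midx]
        lo, hi = v.min(), v.max()
        if hi - lo < eps:
            out[i] = x.data[i] * m3
            info.append(None)
            continue
        out[i] = (x.data[i] - lo) / (hi - lo) * m3
        info.append((midx[int(v.argmin())], midx[int(v.argmax())], hi - lo))

    def bw(g):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        for i in range(b):
            gi = g[i] * m3
            if info[i] is None:
                dx[i] = gi
                continue
            amin, amax, rng = info[i]
            d = gi / rng
            y = out[i]
            gy = float((gi * y).sum())
            gs = float(gi.sum())
            d_flat = d[:, :, 0].ravel()
            d_flat[amin] += (gy - gs) / rng
            d_flat[amax] += -gy / rng
            dx[i] = d
        x._accum(dx)

    return Tensor._make(out, (x,), bw)


def _cg(matvec, rhs: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Plain conjugate gradients for an SPD operator on flat vectors."""
    x = np.zeros_like(rhs)
    r = rhs.copy()
    p = r.copy()
    rs = float(r @ r)
    bnorm = np.sqrt(float(rhs @ rhs))
    if bnorm == 0.0:
        return x
    for _ in range(max_iter):
        ap = matvec(p)
        alpha = rs / float(p @ ap)
        x += alpha * p
        r -= alpha * ap
        rs_new = float(r @ r)
        if np.sqrt(rs_new) <= tol * bnorm:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x


def cg_solve_op(z: Tensor, atb: np.ndarray, lam: Tensor, matvec_AtA,
                tol: float = 1e-6, max_iter: int = 30) -> Tensor:
    """Differentiable solve of ``(A^T A + lam I) x = atb + lam z`` per sample.

    ``z``: (B, H, W, 1); ``atb``: array of the same shape; ``lam``: scalar
    tensor.  ``matvec_AtA`` maps a flat image vector to ``A^T A v``.  The
    backward pass uses the implicit-function identity: with
    ``M = A^T A + lam I`` and ``s = M^{-1} g``, the gradients are
    ``dL/dz = lam s``, ``dL/d(atb) = s`` and ``dL/dlam = s . (z - x)``.
    """
    lam_v = float(lam.data)
    b, h, w, _ = z.data.shape

    def matvec(v):
        return matvec_AtA(v) + lam_v * v

    xs = np.empty_like(z.data)
    for i in range(b):
        rhs = (atb[i] + lam_v * z.data[i]).ravel()
        xs[i] = _cg(matvec, rhs, tol, max_iter).reshape(h, w, 1)

    def bw(g):
        dlam = 0.0
        dz = np.empty_like(z.data)
        for i in range(b):
            s = _cg(matvec, np.ascontiguousarray(g[i]).ravel(), tol, max_iter)
            dz[i] = (lam_v * s).reshape(h, w, 1)
            if lam.requires_grad:
                dlam += float(s @ (z.data[i] - xs[i]).ravel())
        if z.requires_grad:
            z._accum(dz)
        if lam.requires_grad:
            lam._accum(np.asarray(dlam, dtype=lam.data.dtype))

    return Tensor._make(xs, (z, lam), bw)


def mse(pred: Tensor, target: np.ndarray, reduction: str = "mean") -> Tensor:
    """Squared-error loss; ``sum`` gives the summed squared Euclidean norms,
    ``mean`` the per-element average used for optimisation."""
    diff = pred.data - target
    if reduction == "sum":
        val, scale = float((diff**2).sum()), 2.0
    else:
        val, scale = float((diff**2).mean()), 2.0 / diff.size

    def bw(g):
        pred._accum(g * scale * diff)

    return Tensor._make(np.asarray(val), (pred,), bw)


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
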