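"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just the operations the 3D-CNN decoders need: broadcasting arithmetic,
elementwise nonlinearities, reductions, reshaping/slicing, 3-D
convolution (im2col + matmul), and temporal average pooling. Values are
float32 by default; gradients are accumulated in the same dtype.

The design follows the classic tape-free pattern: every operation builds
an output ``Tensor`` holding a closure that, given the output gradient,
accumulates gradients into its parents; ``Tensor.backward`` walks the
graph in reverse topological order.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _pin_mmap_threshold() -> None:
    """Keep large numpy buffers mmap-backed on glibc.

    Training allocates and frees many multi-megabyte im2col buffers.
    glibc's malloc dynamically raises its mmap threshold after frequent
    mmap frees, after which those buffers are served from the brk heap
    and the freed space is never returned to the OS — resident memory
    then grows by tens of MB per optimizer step. Pinning the threshold
    at its default keeps the buffers mmap-backed and promptly released.
    """
    try:
        import ctypes
        libc = ctypes.CDLL("libc.so.6", use_errno=True)
        M_MMAP_THRESHOLD = -3
        libc.mallopt(M_MMAP_THRESHOLD, 131072)
    except Exception:  # non-glibc platform: harmless to skip
        pass


_pin_mmap_threshold()

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode).

    Inside the context no operation retains parents or backward
    closures, so large intermediates (im2col buffers) are freed as soon
    as each layer's output is computed.
    """

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ---- graph plumbing -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # Iterative post-order traversal. A recursive closure here would
        # reference itself and trap the whole graph in a GC cycle, so
        # hundreds of MB of buffers would outlive the training step.
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            t, expanded = stack.pop()
            if expanded:
                topo.append(t)
                continue
            if id(t) in seen or not t.requires_grad:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._parents:
                stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=DTYPE)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in t._backward(g):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf
                t.grad = g if t.grad is None else t.grad + g
        # non-leaf tensors that still hold gradients (graph roots mid-walk)
        for t in topo:
            if t._backward is None and id(t) in grads:
                g = grads[id(t)]
                t.grad = g if t.grad is None else t.grad + g

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # ---- arithmetic -----------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        a, b = self, Tensor._coerce(other)
        out_data = a.data + b.data
        return Tensor._make(out_data, (a, b), lambda g: [
            (a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape))])

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: [(a, -g)])

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._coerce(other)
        return Tensor._make(a.data * b.data, (a, b), lambda g: [
            (a, _unbroadcast(g * b.data, a.data.shape)),
            (b, _unbroadcast(g * a.data, b.data.shape))])

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._coerce(other)
        return Tensor._make(a.data / b.data, (a, b), lambda g: [
            (a, _unbroadcast(g / b.data, a.data.shape)),
            (b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))])

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def pow(self, exponent: float):
        a, e = self, float(exponent)
        return Tensor._make(a.data ** e, (a,),
                            lambda g: [(a, g * e * a.data ** (e - 1.0))])

    __pow__ = pow

    # ---- elementwise ----------------------------------------------------
    def exp(self):
        a = self
        out = np.exp(a.data)
        return Tensor._make(out, (a,), lambda g: [(a, g * out)])

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: [(a, g / a.data)])

    def sigmoid(self):
        a = self
        from scipy.special import expit
        out = expit(a.data).astype(DTYPE)
        return Tensor._make(out, (a,), lambda g: [(a, g * out * (1.0 - out))])

    def softplus(self):
        """log(1 + exp(x)), numerically stable; gradient is sigmoid(x)."""
        a = self
        from scipy.special import expit
        out = np.logaddexp(0.0, a.data).astype(DTYPE)
        return Tensor._make(out, (a,), lambda g: [(a, g * expit(a.data).astype(DTYPE))])

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: [(a, g * mask)])

    # ---- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = g
            if not keepdims and axis is not None:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a_norm(axes, a.data.ndim)):
                    gg = np.expand_dims(gg, ax)
            return [(a, np.broadcast_to(gg, a.data.shape).astype(DTYPE))]

        return Tensor._make(out, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in a_norm(
                axis if isinstance(axis, tuple) else (axis,), self.data.ndim)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._make(a.data.reshape(shape), (a,),
                            lambda g: [(a, g.reshape(a.data.shape))])

    def __getitem__(self, idx):
        a = self
        out = a.data[idx]

        def backward(g):
            full = np.zeros_like(a.data)
            full[idx] = g
            return [(a, full)]

        return Tensor._make(out, (a,), backward)


def a_norm(axes, ndim):
    return tuple(ax % ndim for ax in axes)


# ---- structured ops -----------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: str = "same") -> Tensor:
    """3-D convolution (cross-correlation), channels-last.

    ``x``: (N, T, H, W, Cin); ``w``: (kt, kh, kw, Cin, Cout);
    ``padding`` 'same' (stride 1, output dims preserved) or 'valid'.
    """
    kt, kh, kw, cin, cout = w.data.shape
    if x.data.shape[-1] != cin:
        raise ValueError(f"input channels {x.data.shape[-1]} != kernel Cin {cin}")
    if padding == "same":
        pt, ph, pw = (kt - 1), (kh - 1), (kw - 1)
        pads = ((0, 0), (pt // 2, pt - pt // 2), (ph // 2, ph - ph // 2),
                (pw // 2, pw - pw // 2), (0, 0))
        xp = np.pad(x.data, pads)
    elif padding == "valid":
        pads = None
        xp = x.data
    else:
        raise ValueError(f"unknown padding {padding!r}")
    n, tp, hp, wp, _ = xp.shape
    ot, oh, ow = tp - kt + 1, hp - kh + 1, wp - kw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kt, kh, kw), axis=(1, 2, 3))
    # win: (N, ot, oh, ow, Cin, kt, kh, kw) -> (..., kt, kh, kw, Cin)
    col = np.ascontiguousarray(win.transpose(0, 1, 2, 3, 5, 6, 7, 4)).reshape(
        n * ot * oh * ow, kt * kh * kw * cin)
    wmat = w.data.reshape(kt * kh * kw * cin, cout)
    out = col @ wmat
    if b is not None:
        out = out + b.data
    out = out.reshape(n, ot, oh, ow, cout)

    def backward(g):
        gflat = g.reshape(n * ot * oh * ow, cout)
        grads = []
        if w.requires_grad:
            grads.append((w, (col.T @ gflat).reshape(w.data.shape)))
        if b is not None and b.requires_grad:
            grads.append((b, gflat.sum(axis=0)))
        if x.requires_grad:
            dcol = (gflat @ wmat.T).reshape(n, ot, oh, ow, kt, kh, kw, cin)
            dxp = np.zeros_like(xp)
            for it in range(kt):
                for ih in range(kh):
                    for iw in range(kw):
                        dxp[:, it:it + ot, ih:ih + oh, iw:iw + ow, :] += \
                            dcol[:, :, :, :, it, ih, iw, :]
            if pads is not None:
                sl = tuple(slice(p0, dim - p1) for (p0, p1), dim in
                           zip(pads, dxp.shape))
                dxp = dxp[sl]
            grads.append((x, dxp))
        return grads

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def avgpool_temporal(x: Tensor, pool: int) -> Tensor:
    """Average pooling over the temporal axis only (kernel pool x 1 x 1)."""
    n, t, h, w, c = x.data.shape
    if t % pool:
        raise ValueError(f"temporal size {t} not divisible by pool {pool}")
    out = x.data.reshape(n, t // pool, pool, h, w, c).mean(axis=2)

    def backward(g):
        gx = np.repeat(g[:, :, None], pool, axis=2).reshape(n, t, h, w, c) / pool
        return [(x, gx.astype(DTYPE))]

    return Tensor._make(out, (x,), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running: dict,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over all non-channel axes.

    ``running`` holds 'mean'/'var' numpy arrays updated in training mode
    and used verbatim in inference mode.
    """
    axes = tuple(range(x.data.ndim - 1))
    if training:
        mu = x.mean(axis=axes, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=axes, keepdims=True)
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu.data.ravel()
        running["var"] = (1 - momentum) * running["var"] + momentum * var.data.ravel()
        inv = (var + eps).pow(-0.5)
        return xc * inv * gamma + beta
    shape = (1,) * (x.data.ndim - 1) + (-1,)
    mu = running["mean"].reshape(shape)
    inv = 1.0 / np.sqrt(running["var"].reshape(shape) + eps)
    return x * Tensor(inv) * gamma + (beta - Tensor(mu * inv) * gamma)
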