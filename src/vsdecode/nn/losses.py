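"""Differentiable training losses: binary cross-entropy and SSIM.

The SSIM loss re-implements the windowed structural-similarity measure
(11x11 Gaussian window, sigma 1.5, K1=0.01, K2=0.03, dynamic range 1) in
autodiff ops so its gradient can drive training; the evaluation module
uses scikit-image's implementation of the same measure as an independent
reference.
"""

from __future__ import annotations

import numpy as np

from .tensor import DTYPE, Tensor, conv3d

__all__ = ["bce_with_logits", "differentiable_ssim", "ssim_loss"]


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from pre-sigmoid logits (stable form).

    BCE(sigmoid(z), t) = softplus(z) - t*z, averaged over all elements.
    """
    t = Tensor(np.asarray(targets, dtype=DTYPE))
    return (logits.softplus() - t * logits).mean()


def _gauss_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    r = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(r ** 2) / (2 * sigma ** 2))
    k2 = np.outer(g, g)
    return (k2 / k2.sum()).astype(DTYPE)


def differentiable_ssim(pred: Tensor, target: np.ndarray, *, win_size: int = 11,
                        sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03,
                        data_range: float = 1.0) -> Tensor:
    """Mean SSIM between predicted and target image batches, (N, H, W).

    Windows are 'valid' (no padding), matching the reference convention of
    evaluating statistics only where the Gaussian window fits entirely.
    """
    if not isinstance(pred, Tensor):
        pred = Tensor(pred)
    tgt = np.asarray(target, dtype=DTYPE)
    if pred.data.shape != tgt.shape:
        raise ValueError(f"shape mismatch {pred.data.shape} vs {tgt.shape}")
    n, h, w = pred.data.shape
    if min(h, w) < win_size:
        raise ValueError("image smaller than the SSIM window")
    kern = Tensor(_gauss_window(win_size, sigma).reshape(1, win_size, win_size, 1, 1))

    def blur(t: Tensor) -> Tensor:
        return conv3d(t, kern, padding="valid")

    x = pred.reshape(n, 1, h, w, 1)
    y = Tensor(tgt.reshape(n, 1, h, w, 1))
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mx, my = blur(x), blur(y)
    mx2, my2, mxy = mx * mx, my * my, mx * my
    sx = blur(x * x) - mx2
    sy = blur(y * y) - my2
    sxy = blur(x * y) - mxy
    num = (2.0 * mxy + c1) * (2.0 * sxy + c2)
    den = (mx2 + my2 + c1) * (sx + sy + c2)
    return (num / den).mean()


def ssim_loss(pred: Tensor, target: np.ndarray, **kw) -> Tensor:
    """1 - mean SSIM, the image-reconstruction training loss."""
    return 1.0 - differentiable_ssim(pred, target, **kw)
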