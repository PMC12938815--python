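"""Synthetic natural-like grayscale images and the photoreceptor-layer prefilter.

The decoding pipeline is trained on grayscale photographs; for a fully
self-contained, reproducible artifact this module generates procedural
stand-ins that keep the two statistical properties the downstream stages
rely on: broadband (1/f-type) spatial spectra and localized luminance
edges. Styles:

``constant``
    Uniform field at a fixed level (diagnostic).
``pink_noise``
    Isotropic Gaussian noise shaped so the radially averaged power
    spectrum falls as ``f**spectral_slope`` (slope -2 approximates the
    natural-image ensemble; slope 0 is white noise).
``blobs``
    Sum of randomly placed 2-D Gaussian bumps of mixed polarity.
``shapes``
    Randomly placed filled rectangles and disks (hard edges).
``mixture``
    Pink-noise texture overlaid with blobs and shapes; the default
    training style.

All generators are deterministic given ``(style, seed, dims)`` and return
luminance in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "GrayImage",
    "ImageStyle",
    "generate_image",
    "photoreceptor_prefilter",
    "read_image",
    "write_image",
]

STYLE_KINDS = ("constant", "pink_noise", "blobs", "shapes", "mixture")


@dataclass(frozen=True)
class ImageStyle:
    """Parameters selecting one procedural image family."""

    kind: str = "mixture"
    spectral_slope: float = -2.0
    level: float = 0.5  # constant style only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in STYLE_KINDS:
            raise ValueError(
                f"unknown image style {self.kind!r}; expected one of {STYLE_KINDS}"
            )


# GrayImage is represented as a float64 ndarray of shape (height, width)
# with values in [0, 1]; a type alias keeps signatures readable.
GrayImage = np.ndarray


def _rescale01(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return np.full_like(img, 0.5)
    return (img - lo) / (hi - lo)


def _pink_noise(rng: np.random.Generator, h: int, w: int, slope: float) -> np.ndarray:
    """Gaussian field with radial power spectrum ~ f**slope."""
    white = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0  # DC untouched (removed below)
    amp = f ** (slope / 2.0)  # power = amp**2 ~ f**slope
    spec = np.fft.fft2(white) * amp
    spec[0, 0] = 0.0
    return np.fft.ifft2(spec).real


def _blobs(rng: np.random.Generator, h: int, w: int, n: int | None = None) -> np.ndarray:
    if n is None:
        n = max(4, (h * w) // 1200)
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.zeros((h, w))
    for _ in range(n):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        sig = rng.uniform(0.03, 0.15) * min(h, w)
        amp = rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 1.0)
        img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2))
    return img


def _shapes(rng: np.random.Generator, h: int, w: int, n: int | None = None) -> np.ndarray:
    if n is None:
        n = max(3, (h * w) // 2000)
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.zeros((h, w))
    for _ in range(n):
        level = rng.uniform(-1.0, 1.0)
        if rng.random() < 0.5:  # rectangle
            y0, x0 = rng.uniform(0, h * 0.8), rng.uniform(0, w * 0.8)
            dy, dx = rng.uniform(0.1, 0.4) * h, rng.uniform(0.1, 0.4) * w
            mask = (yy >= y0) & (yy < y0 + dy) & (xx >= x0) & (xx < x0 + dx)
        else:  # disk
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            r = rng.uniform(0.05, 0.25) * min(h, w)
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 < r**2
        img[mask] += level
    return img


def generate_image(style: ImageStyle, height: int = 120, width: int = 120) -> GrayImage:
    """Generate one deterministic grayscale image in [0, 1].

    Parameters
    ----------
    style
        Image family and seed.
    height, width
        Grid dimensions, each at least 8.
    """
    if height < 8 or width < 8:
        raise ValueError("image dimensions must be at least 8x8")
    if style.kind == "constant":
        if not 0.0 <= style.level <= 1.0:
            raise ValueError("constant level must lie in [0, 1]")
        return np.full((height, width), float(style.level))

    rng = np.random.default_rng(style.seed)
    if style.kind == "pink_noise":
        img = _pink_noise(rng, height, width, style.spectral_slope)
    elif style.kind == "blobs":
        img = _blobs(rng, height, width)
    elif style.kind == "shapes":
        img = _shapes(rng, height, width)
    else:  # mixture
        tex = _pink_noise(rng, height, width, style.spectral_slope)
        tex /= max(np.abs(tex).max(), 1e-12)
        img = 0.6 * tex + 0.8 * _blobs(rng, height, width) + _shapes(rng, height, width)
    return _rescale01(img)


def photoreceptor_prefilter(img: GrayImage, sigma_px: float = 1.0) -> GrayImage:
    """Gaussian spatial low-pass emulating optical blur in the photoreceptor layer.

    Unit DC gain (a constant image passes through unchanged), reflect
    boundary handling, output clipped to [0, 1].
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    out = ndimage.gaussian_filter(np.asarray(img, dtype=float), sigma_px, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def read_image(path) -> GrayImage:
    """Read a PNG/TIFF grayscale image, rescaling 8/16-bit integers to [0, 1]."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse any color axis by luminance average
        arr = arr.mean(axis=-1)
    arr = arr.astype(float)
    if arr.max() > 1.0:
        arr /= 65535.0 if arr.max() > 255.0 else 255.0
    return np.clip(arr, 0.0, 1.0)


def write_image(path, img: GrayImage) -> None:
    """Write a GrayImage as 16-bit PNG/TIFF (by extension)."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    iio.imwrite(path, np.round(arr * 65535).astype(np.uint16))


def resample_image(img: GrayImage, height: int, width: int) -> GrayImage:
    """Resample to the encoder grid (bilinear, anti-aliased on downscale)."""
    from skimage.transform import resize

    out = resize(np.asarray(img, dtype=float), (height, width), order=1,
                 mode="reflect", anti_aliasing=True, preserve_range=True)
    return np.clip(out, 0.0, 1.0)
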