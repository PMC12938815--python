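"""Retinomorphic spike encoder.

Emulates a grid of off-transient alpha retinal ganglion cells. Each unit
sees the stimulus through

1. a *delayed difference-of-Gaussians* spatial filter: a narrow center
   Gaussian minus a wider, temporally delayed surround Gaussian, both
   normalized to unit DC gain so a uniform field drives nothing;
2. a *biphasic temporal filter* (difference of two alpha functions with a
   zero integral), which converts sustained luminance into transient
   drive; and
3. an *Izhikevich spiking neuron* integrating the filtered drive into a
   point-process spike train.

Off polarity is realized by sign-inverting the generator signal, so a
luminance decrement excites. The stimulus protocol is a full-field gray
adaptation period followed by a switch to the target image; spikes are
collected for ``record_ms`` after the switch. The whole encoder is
deterministic — there is no stochastic term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "EncoderConfig",
    "SpikeEvents",
    "SpikeStream",
    "biphasic_kernel",
    "dog_generator_signal",
    "biphasic_filter",
    "izhikevich_step",
    "encode_stream",
    "bin_spikes",
]


def biphasic_kernel(dt_ms: float, tau_fast_ms: float = 10.0,
                    tau_slow_ms: float = 40.0, support_factor: float = 8.0) -> np.ndarray:
    """Zero-sum biphasic kernel: difference of two normalized alpha functions.

    Each alpha function ``t*exp(-t/tau)`` is normalized to unit discrete
    sum before subtraction, so the kernel sums to zero exactly; the peak
    is then scaled to 1.
    """
    n = int(np.ceil(support_factor * tau_slow_ms / dt_ms)) + 1
    t = np.arange(n) * dt_ms
    fast = t * np.exp(-t / tau_fast_ms)
    slow = t * np.exp(-t / tau_slow_ms)
    h = fast / fast.sum() - slow / slow.sum()
    return h / np.abs(h).max()


@dataclass
class EncoderConfig:
    """Retinal-encoder parameters (one set shared by all grid units).

    Izhikevich defaults are the regular-spiking parameter set
    (a=0.02, b=0.2, c=-65, d=8) with the conventional 30 mV peak. The
    ``gain`` scales filtered drive into the neuron's input current and is
    set so a mixture-style image elicits a transient burst of a few
    spikes per unit.
    """

    grid: tuple[int, int] = (120, 120)
    dt_ms: float = 0.5
    center_sigma_px: float = 1.2
    surround_sigma_px: float = 3.0
    surround_delay_ms: float = 5.0
    tau_fast_ms: float = 10.0
    tau_slow_ms: float = 40.0
    gain: float = 50.0
    polarity: str = "off"
    izh_a: float = 0.02
    izh_b: float = 0.2
    izh_c: float = -65.0
    izh_d: float = 8.0
    v_peak: float = 30.0
    temporal_kernel: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        if self.surround_sigma_px <= self.center_sigma_px:
            raise ValueError("surround sigma must exceed center sigma")
        if self.polarity != "off":
            raise ValueError("only off polarity is supported")
        if self.temporal_kernel is None:
            self.temporal_kernel = biphasic_kernel(
                self.dt_ms, self.tau_fast_ms, self.tau_slow_ms)
        if abs(float(np.sum(self.temporal_kernel))) > 1e-9:
            raise ValueError("temporal kernel must sum to zero")


@dataclass
class SpikeEvents:
    """Per-unit sorted spike times (ms, relative to the image switch)."""

    grid: tuple[int, int]
    record_ms: float
    # times[row * cols + col] -> strictly increasing float array
    times: list

    def total_count(self) -> int:
        return int(sum(len(t) for t in self.times))


@dataclass
class SpikeStream:
    """Binary spike-frame stack: (n_frames, rows, cols), 5 ms bins.

    Multiple spikes falling in one bin saturate to 1, keeping the stream
    binary for use as a binary-cross-entropy target.
    """

    frames: np.ndarray
    bin_ms: float = 5.0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _spatial_drive(img: np.ndarray, cfg: EncoderConfig) -> tuple[np.ndarray, np.ndarray]:
    """Center and surround spatial responses (each unit DC gain)."""
    img = np.asarray(img, dtype=float)
    if img.shape != tuple(cfg.grid):
        raise ValueError(f"frame shape {img.shape} does not match grid {cfg.grid}")
    c = ndimage.gaussian_filter(img, cfg.center_sigma_px, mode="reflect")
    s = ndimage.gaussian_filter(img, cfg.surround_sigma_px, mode="reflect")
    return c, s


def dog_generator_signal(frames: np.ndarray, cfg: EncoderConfig) -> np.ndarray:
    """Delayed-DoG generator signal for a stimulus movie.

    ``frames`` has shape (T, rows, cols) sampled at ``cfg.dt_ms``. Returns
    g of the same shape: for off polarity
    ``g(t) = -(Gc * I(t) - Gs * I(t - delay))`` with the surround frozen at
    its first frame for t < delay.
    """
    frames = np.asarray(frames, dtype=float)
    T = frames.shape[0]
    delay_steps = int(round(cfg.surround_delay_ms / cfg.dt_ms))
    center = np.empty_like(frames)
    surround_now = np.empty_like(frames)
    for t in range(T):
        center[t], surround_now[t] = _spatial_drive(frames[t], cfg)
    surround = np.empty_like(frames)
    for t in range(T):
        surround[t] = surround_now[max(t - delay_steps, 0)]
    g = center - surround
    return -g  # off polarity: luminance decrement excites


def biphasic_filter(sig: np.ndarray, cfg: EncoderConfig) -> np.ndarray:
    """Causal convolution with the zero-sum biphasic kernel along axis 0."""
    sig = np.asarray(sig, dtype=float)
    k = cfg.temporal_kernel
    full = signal.fftconvolve(sig, k.reshape((-1,) + (1,) * (sig.ndim - 1)), axes=0)
    return full[: sig.shape[0]]


def izhikevich_step(state: tuple[float, float], input_current: float,
                    dt_ms: float, cfg: EncoderConfig) -> tuple[tuple[float, float], bool]:
    """One forward-Euler Izhikevich update; reset applied after detection.

    v' = 0.04 v^2 + 5 v + 140 - u + I;  u' = a (b v - u).
    A spike is flagged when v reaches ``v_peak``; then v <- c, u <- u + d.
    """
    v, u = state
    if not (np.isfinite(v) and np.isfinite(u)):
        raise FloatingPointError(f"non-finite Izhikevich state v={v} u={u}")
    v_new = v + dt_ms * (0.04 * v * v + 5.0 * v + 140.0 - u + input_current)
    u_new = u + dt_ms * cfg.izh_a * (cfg.izh_b * v - u)
    spiked = v_new >= cfg.v_peak
    if spiked:
        v_new = cfg.izh_c
        u_new = u_new + cfg.izh_d
    return (v_new, u_new), bool(spiked)


def _izhikevich_run(drive: np.ndarray, cfg: EncoderConfig,
                    v0: np.ndarray | None = None, u0: np.ndarray | None = None):
    """Vectorized Izhikevich integration over all units.

    ``drive``: (T, n_units) input current. Returns (spike bool array
    (T, n_units), final v, final u). Spike at step t means v crossed
    v_peak during the update entering step t+1's state.
    """
    T, n = drive.shape
    dt = cfg.dt_ms
    v = np.full(n, -65.0) if v0 is None else v0.copy()
    u = (cfg.izh_b * v) if u0 is None else u0.copy()
    spikes = np.zeros((T, n), dtype=bool)
    for t in range(T):
        v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + drive[t])
        u_new = u + dt * cfg.izh_a * (cfg.izh_b * v - u)
        fired = v_new >= cfg.v_peak
        v_new[fired] = cfg.izh_c
        u_new[fired] += cfg.izh_d
        spikes[t] = fired
        v, u = v_new, u_new
        if not np.all(np.isfinite(v)):
            raise FloatingPointError("non-finite membrane state during integration")
    return spikes, v, u


def encode_stream(image: np.ndarray, cfg: EncoderConfig,
                  gray_ms: float = 200.0, record_ms: float = 150.0,
                  gray_level: float = 0.5) -> SpikeEvents:
    """Encode one image into per-unit spike trains.

    A full-field gray frame at ``gray_level`` is shown for ``gray_ms``
    (letting the temporal filter and neurons settle), then the image; spike
    times are reported relative to the switch, within [0, record_ms).
    """
    image = np.asarray(image, dtype=float)
    rows, cols = cfg.grid
    if image.shape != (rows, cols):
        raise ValueError(f"image shape {image.shape} does not match grid {cfg.grid}")
    dt = cfg.dt_ms
    n_gray = int(round(gray_ms / dt))
    n_rec = int(round(record_ms / dt))

    # Piecewise-constant stimulus: spatial filtering need only touch the
    # two distinct frames; the time axis is assembled afterwards.
    gray = np.full((rows, cols), float(gray_level))
    c_gray, s_gray = _spatial_drive(gray, cfg)
    c_img, s_img = _spatial_drive(image, cfg)
    delay_steps = int(round(cfg.surround_delay_ms / dt))
    T = n_gray + n_rec
    g = np.empty((T, rows * cols))
    g_gray = -(c_gray - s_gray).ravel()            # steady state (zero by DC match)
    g_img = -(c_img - s_img).ravel()               # after surround catches up
    g_trans = -(c_img - s_gray).ravel()            # center switched, surround delayed
    g[:n_gray] = g_gray
    g[n_gray:n_gray + delay_steps] = g_trans
    g[n_gray + delay_steps:] = g_img

    drive = cfg.gain * biphasic_filter(g, cfg)
    spikes, _, _ = _izhikevich_run(drive, cfg)

    rec = spikes[n_gray:]
    times = []
    for idx in range(rows * cols):
        steps = np.nonzero(rec[:, idx])[0]
        times.append(steps * dt)
    return SpikeEvents(grid=(rows, cols), record_ms=record_ms, times=times)


def bin_spikes(events: SpikeEvents, bin_ms: float = 5.0,
               record_ms: float | None = None) -> SpikeStream:
    """Bin spike events into binary frames on half-open intervals.

    Frame k covers [k*bin_ms, (k+1)*bin_ms); any number of events in one
    bin saturates to 1.
    """
    if record_ms is None:
        record_ms = events.record_ms
    n_frames = record_ms / bin_ms
    if abs(n_frames - round(n_frames)) > 1e-9:
        raise ValueError("record_ms must be an exact multiple of bin_ms")
    n_frames = int(round(n_frames))
    rows, cols = events.grid
    frames = np.zeros((n_frames, rows, cols), dtype=np.uint8)
    for idx, t in enumerate(events.times):
        if len(t) == 0:
            continue
        k = np.floor(np.asarray(t) / bin_ms).astype(int)
        k = k[(k >= 0) & (k < n_frames)]
        frames[k, idx // cols, idx % cols] = 1
    return SpikeStream(frames=frames, bin_ms=bin_ms)
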