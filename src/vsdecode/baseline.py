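"""Fixed-frequency stimulation baseline.

Clinical intracortical prostheses commonly deliver an all-or-none,
fixed-frequency pulse train (300 Hz for 166 ms, about 50 pulses) at
electrode sites covering contrast edges of the image. This module
reproduces that strategy inside the simulation loop so it can be
compared with neuromorphic spike-timing stimulation under a matched
total pulse budget: edges are extracted with a Laplacian filter, the
highest-edge pixels are selected until the budget is filled (in whole
trains), every selected pixel receives the identical fixed train, and
the resulting responses are simulated and decoded with the same Wiener
model and Path-2 decoder as the neuromorphic pathway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dataset import VsdStream, downsample_vsd
from .wiener import PulseTrain, WienerModel, simulate_vsd_trace

__all__ = [
    "StimulationPlan", "laplacian_edge_map", "fixed_rate_train",
    "match_pulse_budget", "baseline_pipeline",
]

LAPLACIAN_STENCIL = np.array([[0., 1., 0.], [1., -4., 1.], [0., 1., 0.]])


@dataclass
class StimulationPlan:
    """Set of stimulated pixels, all driven by one identical fixed train."""

    selected_pixels: list          # (row, col) tuples
    train: PulseTrain
    grid: tuple[int, int]

    @property
    def total_pulses(self) -> int:
        return len(self.selected_pixels) * len(self.train.times_ms)

    def mask(self) -> np.ndarray:
        m = np.zeros(self.grid, dtype=np.uint8)
        for r, c in self.selected_pixels:
            m[r, c] = 1
        return m

    def to_json(self) -> str:
        import json
        return json.dumps({
            "grid": list(self.grid),
            "selected_pixels": [list(p) for p in self.selected_pixels],
            "train_times_ms": self.train.times_ms.tolist(),
            "total_pulses": self.total_pulses})

    def write_mask_png(self, path) -> None:
        from .images import write_image
        write_image(path, self.mask().astype(float))


def laplacian_edge_map(img: np.ndarray) -> np.ndarray:
    """|4-neighbor Laplacian| edge strength, reflect boundary."""
    img = np.asarray(img, dtype=float)
    return np.abs(ndimage.convolve(img, LAPLACIAN_STENCIL, mode="reflect"))


def fixed_rate_train(rate_hz: float, duration_ms: float,
                     window_ms: float = 1000.0) -> PulseTrain:
    """Pulses at k/rate for k = 0..round(rate*duration/1000)-1, from t = 0."""
    if rate_hz <= 0 or duration_ms <= 0:
        raise ValueError("rate and duration must be positive")
    n = int(round(rate_hz * duration_ms / 1000.0))
    times = np.arange(n) * (1000.0 / rate_hz)
    times = times[times < duration_ms]
    return PulseTrain(times, max(window_ms, duration_ms))


def match_pulse_budget(edges: np.ndarray, budget: int,
                       pulses_per_train: int) -> list:
    """Top-k edge pixels filling the pulse budget in whole trains.

    Selection is by descending edge strength with row-major tie-breaking;
    returns (row, col) tuples. A budget below one train yields an empty
    selection.
    """
    if budget < 0:
        raise ValueError("budget must be non-negative")
    if pulses_per_train <= 0:
        raise ValueError("pulses_per_train must be positive")
    k = budget // pulses_per_train
    if k == 0:
        import warnings
        warnings.warn("pulse budget smaller than one train; empty plan")
        return []
    flat = np.asarray(edges, dtype=float).ravel()
    # stable sort on negated strengths keeps row-major order among ties
    order = np.argsort(-flat, kind="stable")[:k]
    cols = edges.shape[1]
    return [(int(i) // cols, int(i) % cols) for i in order]


def baseline_pipeline(img: np.ndarray, wiener_model: WienerModel,
                      path2_decoder, *, spike_budget: int,
                      rate_hz: float = 300.0, train_duration_ms: float = 166.0,
                      sim_duration_ms: float = 1000.0, frame_ms: float = 5.0):
    """Fixed-frequency stimulation of one image through the full loop.

    ``spike_budget`` is the total spike count of the neuromorphic
    encoding of the same image, so both strategies spend (up to train
    granularity) the same number of pulses. Returns
    ``(StimulationPlan, VsdStream, decoded image)``.
    """
    from .decoder import decode

    edges = laplacian_edge_map(img)
    train = fixed_rate_train(rate_hz, train_duration_ms, sim_duration_ms)
    pulses_per_train = len(train.times_ms)
    selected = match_pulse_budget(edges, spike_budget, pulses_per_train)
    plan = StimulationPlan(selected_pixels=selected, train=train, grid=img.shape)

    n = int(round(sim_duration_ms / wiener_model.dt_ms))
    baseline_trace = simulate_vsd_trace(PulseTrain(np.array([]), sim_duration_ms),
                                        wiener_model)
    stim_trace = simulate_vsd_trace(train, wiener_model)
    y = np.tile(baseline_trace[:, None, None], (1,) + img.shape)
    for r, c in selected:
        y[:, r, c] = stim_trace
    vsd = VsdStream(downsample_vsd(y, int(round(frame_ms / wiener_model.dt_ms))),
                    frame_ms=frame_ms)
    decoded = decode(path2_decoder, vsd.frames.astype(np.float32))
    return plan, vsd, decoded
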