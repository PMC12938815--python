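"""Matched (image, spike stream, VSD stream) triplet construction and storage.

For each source image the pipeline runs: Gaussian photoreceptor
prefilter -> retinomorphic encoder -> 5 ms spike binning -> per-pixel
upsampling to the 1 ms Wiener-model grid -> VSD simulation -> 5 ms block
averaging. Each pixel is simulated independently (the cortical model has
no spatial coupling). Datasets are persisted in one HDF5 file with
groups ``/images``, ``/spikes``, ``/vsd`` plus a JSON manifest, and every
run is reproducible from the manifest's seed and configuration digest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .encoder import EncoderConfig, SpikeStream, bin_spikes, encode_stream
from .images import ImageStyle, generate_image, photoreceptor_prefilter
from .wiener import PulseTrain, WienerModel, simulate_vsd_pixels

__all__ = [
    "Triplet", "VsdStream", "DatasetManifest",
    "upsample_spike_frames", "downsample_vsd", "build_triplet",
    "make_dataset", "load_dataset", "derive_seed",
]


@dataclass
class VsdStream:
    """Real-valued dT/T0 frame stack (n_frames, rows, cols) at 5 ms frames."""

    frames: np.ndarray
    frame_ms: float = 5.0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class Triplet:
    image: np.ndarray
    spikes: SpikeStream
    vsd: VsdStream

    def __post_init__(self) -> None:
        if self.image.shape != self.spikes.frames.shape[1:] or \
                self.image.shape != self.vsd.frames.shape[1:]:
            raise ValueError("triplet members disagree on spatial dimensions")


@dataclass
class DatasetManifest:
    n_total: int
    n_train: int
    n_test: int
    seed: int
    config_digest: str
    train_indices: list
    test_indices: list

    def __post_init__(self) -> None:
        if self.n_train + self.n_test != self.n_total:
            raise ValueError("train + test must equal total")


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, fanned out from a global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def upsample_spike_frames(spikes: SpikeStream, duration_ms: float = 1000.0):
    """Per-pixel pulse trains on the 1 ms grid: frame k -> pulse at k*bin_ms.

    Returns a list of :class:`~vsdecode.wiener.PulseTrain` in row-major
    pixel order.
    """
    f = spikes.frames
    if not np.isin(f, (0, 1)).all():
        raise ValueError("spike stream must be binary")
    nf, rows, cols = f.shape
    trains = []
    for r in range(rows):
        for c in range(cols):
            ks = np.nonzero(f[:, r, c])[0]
            trains.append(PulseTrain(ks * spikes.bin_ms, duration_ms))
    return trains


def downsample_vsd(trace: np.ndarray, factor: int = 5) -> np.ndarray:
    """Block mean of consecutive ``factor`` samples (1 ms -> 5 ms frames)."""
    trace = np.asarray(trace, dtype=float)
    if trace.shape[0] % factor:
        raise ValueError(f"length {trace.shape[0]} not divisible by {factor}")
    shape = (trace.shape[0] // factor, factor) + trace.shape[1:]
    return trace.reshape(shape).mean(axis=1)


def build_triplet(image: np.ndarray, encoder_cfg: EncoderConfig,
                  wiener_model: WienerModel, *, record_ms: float = 150.0,
                  bin_ms: float = 5.0, sim_duration_ms: float = 1000.0,
                  prefilter_sigma_px: float = 1.0) -> Triplet:
    """Deterministic image -> spikes -> simulated VSD composition."""
    img = photoreceptor_prefilter(image, prefilter_sigma_px)
    events = encode_stream(img, encoder_cfg, record_ms=record_ms)
    spikes = bin_spikes(events, bin_ms=bin_ms)
    y = simulate_vsd_pixels(spikes.frames, bin_ms, wiener_model, sim_duration_ms)
    vsd = VsdStream(downsample_vsd(y, int(round(bin_ms / wiener_model.dt_ms))),
                    frame_ms=bin_ms)
    return Triplet(image=img, spikes=spikes, vsd=vsd)


def _config_digest(encoder_cfg: EncoderConfig, wiener_model: WienerModel,
                   extra: dict) -> str:
    payload = {
        "encoder": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in dataclasses.asdict(encoder_cfg).items()},
        "wiener": wiener_model.to_json_dict(),
        "extra": extra,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def make_dataset(path, n: int, split: tuple[int, int], seed: int,
                 encoder_cfg: EncoderConfig, wiener_model: WienerModel, *,
                 record_ms: float = 150.0, bin_ms: float = 5.0,
                 sim_duration_ms: float = 1000.0, prefilter_sigma_px: float = 1.0,
                 image_style_kind: str = "mixture",
                 spectral_slope: float = -2.0) -> DatasetManifest:
    """Generate ``n`` triplets, split them, and store everything in HDF5.

    Images get per-index derived seeds; the train/test split is a seeded
    shuffle. Rerunning with the same arguments is bit-identical.
    """
    import h5py

    n_train, n_test = split
    if n_train + n_test != n:
        raise ValueError("split sizes must sum to n")
    rows, cols = encoder_cfg.grid
    extra = {"n": n, "split": list(split), "seed": seed, "record_ms": record_ms,
             "bin_ms": bin_ms, "sim_duration_ms": sim_duration_ms,
             "prefilter_sigma_px": prefilter_sigma_px, "style": image_style_kind}
    digest = _config_digest(encoder_cfg, wiener_model, extra)

    perm = np.random.default_rng(derive_seed(seed, "split")).permutation(n)
    train_idx = sorted(int(i) for i in perm[:n_train])
    test_idx = sorted(int(i) for i in perm[n_train:])

    nf_spk = int(round(record_ms / bin_ms))
    nf_vsd = int(round(sim_duration_ms / bin_ms))
    with h5py.File(path, "w") as f:
        d_img = f.create_dataset("images", (n, rows, cols), dtype="f4")
        d_spk = f.create_dataset("spikes", (n, nf_spk, rows, cols), dtype="u1")
        d_vsd = f.create_dataset("vsd", (n, nf_vsd, rows, cols), dtype="f4")
        for i in range(n):
            style = ImageStyle(kind=image_style_kind, spectral_slope=spectral_slope,
                               seed=derive_seed(seed, f"image:{i}"))
            img = generate_image(style, rows, cols)
            trip = build_triplet(img, encoder_cfg, wiener_model,
                                 record_ms=record_ms, bin_ms=bin_ms,
                                 sim_duration_ms=sim_duration_ms,
                                 prefilter_sigma_px=prefilter_sigma_px)
            d_img[i] = trip.image
            d_spk[i] = trip.spikes.frames
            d_vsd[i] = trip.vsd.frames
        manifest = DatasetManifest(n_total=n, n_train=n_train, n_test=n_test,
                                   seed=seed, config_digest=digest,
                                   train_indices=train_idx, test_indices=test_idx)
        f.attrs["manifest"] = json.dumps(dataclasses.asdict(manifest))
    return manifest


def load_dataset(path):
    """Load an HDF5 dataset into memory: (images, spikes, vsd, manifest)."""
    import h5py

    with h5py.File(path, "r") as f:
        images = f["images"][:]
        spikes = f["spikes"][:]
        vsd = f["vsd"][:]
        manifest = DatasetManifest(**json.loads(f.attrs["manifest"]))
    return images, spikes, vsd, manifest
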