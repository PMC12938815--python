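"""3D-CNN decoders and their two-stage training protocol.

Two decoding pathways are provided:

* **Path 1** — spike stream -> image: a 3D-CNN that collapses the
  temporal axis through successive temporal average-pooling stages
  (30 -> 15 -> 5 -> 1 frames at full scale) while preserving the spatial
  grid with 'same'-padded convolutions.
* **Path 2** — VSD stream -> image: a *front-end* block first decodes
  the simulated cortical stream back into per-voxel spike probabilities
  (trained with binary cross-entropy), and the Path-1 architecture is
  reused as the *back-end* spike-to-image block (trained with an SSIM
  loss). The pretrained blocks are then joined and refined by
  alternately re-training one block with the other frozen, under the
  end-to-end SSIM loss, for three rounds.

The ``paper`` preset reproduces the published layer tables exactly
(layer-wise trainable-parameter counts are audited in closed form); the
``desk`` preset is a reduced-width/reduced-frames profile for CPU-scale
experiments.

Convolutions followed by batch normalization carry no bias (the BN shift
makes it redundant); terminal convolutions carry bias. Hidden
activations are ReLU; both block outputs pass through a sigmoid (spike
probabilities, and images in [0, 1]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .nn import (Adam, AvgPool3D, BatchNorm, Conv3D, Sequential, Tensor,
                 bce_with_logits, no_grad, ssim_loss)
from .evaluation import f1_score, ssim

__all__ = [
    "LayerSpec", "DecoderNet", "Path2Net", "TrainConfig",
    "build_backend", "build_frontend", "assemble_path2",
    "pretrain_frontend", "pretrain_backend", "alternating_refinement",
    "decode",
]


@dataclass(frozen=True)
class LayerSpec:
    """Closed-form description of one layer for the parameter-count audit."""

    op: str                      # conv3d | batch_norm | avgpool3d | input
    kernel: tuple = ()
    filters: int = 0
    in_channels: int = 0
    has_bias: bool = False
    activation: str = "linear"
    output_shape: tuple = ()     # (t, h, w, c)

    @property
    def param_count(self) -> int:
        if self.op == "conv3d":
            kt, kh, kw = self.kernel
            n = kt * kh * kw * self.in_channels * self.filters
            return n + (self.filters if self.has_bias else 0)
        if self.op == "batch_norm":
            return 2 * self.filters
        return 0


@dataclass
class DecoderNet:
    """A built network plus its audit ledger."""

    net: Sequential
    specs: list
    role: str
    input_shape: tuple  # (t, h, w, c)

    def audit_param_counts(self) -> list[int]:
        """Closed-form per-layer counts (input layer omitted)."""
        return [s.param_count for s in self.specs if s.op != "input"]

    def framework_param_counts(self) -> list[int]:
        """Counts reported by the layer objects themselves."""
        return [layer.param_count() for layer in self.net.layers]

    def param_count(self) -> int:
        return self.net.param_count()

    def audit_json(self) -> str:
        return json.dumps([{"op": s.op, "kernel": list(s.kernel),
                            "filters": s.filters, "has_bias": s.has_bias,
                            "output_shape": list(s.output_shape),
                            "params": s.param_count} for s in self.specs])

    def save(self, path) -> None:
        """Checkpoint: weights + running stats (npz) with a JSON layer audit."""
        state = self.net.get_state()
        arrays = {}
        for i, item in enumerate(state):
            if isinstance(item, dict):
                for k, v in item.items():
                    arrays[f"running_{i}_{k}"] = v
            else:
                arrays[f"param_{i}"] = item
        np.savez(path, **arrays)
        from pathlib import Path
        Path(str(path) + ".audit.json").write_text(self.audit_json())

    def load(self, path) -> None:
        with np.load(path) as data:
            state: list = []
            i = 0
            while f"param_{i}" in data or any(
                    k.startswith(f"running_{i}_") for k in data.files):
                if f"param_{i}" in data:
                    state.append(data[f"param_{i}"])
                else:
                    state.append({k.split("_", 2)[2]: data[k] for k in data.files
                                  if k.startswith(f"running_{i}_")})
                i += 1
        self.net.set_state(state)


# preset -> (spike frames, vsd frames, grid, backend channels, frontend channels,
#            temporal pools, backend temporal kernels, frontend temporal kernels)
_PRESETS = {
    "paper": dict(spike_frames=30, vsd_frames=200, grid=(120, 120),
                  back_channels=(4, 4, 8, 16, 1), front_channels=(16, 32, 16, 32, 1),
                  pools=(2, 3, 5), back_tk=(30, 30, 15, 5, 1),
                  front_tk=(7, 5, 5, 3, 1)),
    "desk": dict(spike_frames=12, vsd_frames=48, grid=(32, 32),
                 back_channels=(4, 4, 8, 16, 1), front_channels=(4, 8, 4, 8, 1),
                 pools=(2, 3, 2), back_tk=(12, 12, 6, 2, 1),
                 front_tk=(7, 5, 5, 3, 1)),
}


def build_backend(preset: str = "paper", seed: int = 0) -> DecoderNet:
    """Spike-to-image 3D-CNN (Path 1, and the Path-2 back-end).

    Full scale: input 30x120x120x1; conv(30x3x3)x4, conv(30x3x3)x4,
    avgpool(2x1x1), conv(15x3x3)x8, avgpool(3x1x1), conv(5x3x3)x16,
    avgpool(5x1x1), conv(1x3x3)x1 -> 1x120x120x1. All convolutions carry
    bias and 'same' spatial padding.
    """
    p = _PRESETS[preset]
    t, (h, w) = p["spike_frames"], p["grid"]
    c1, c2, c3, c4, c5 = p["back_channels"]
    k1, k2, k3, k4, k5 = p["back_tk"]
    q1, q2, q3 = p["pools"]
    rng = np.random.default_rng(seed)
    layers, specs = [], [LayerSpec("input", output_shape=(t, h, w, 1))]

    def conv(kt, cin, cout, act):
        layers.append(Conv3D((kt, 3, 3), cin, cout, use_bias=True,
                             activation=act, rng=rng))

    conv(k1, 1, c1, "relu")
    specs.append(LayerSpec("conv3d", (k1, 3, 3), c1, 1, True, "relu", (t, h, w, c1)))
    conv(k2, c1, c2, "relu")
    specs.append(LayerSpec("conv3d", (k2, 3, 3), c2, c1, True, "relu", (t, h, w, c2)))
    layers.append(AvgPool3D(q1)); t //= q1
    specs.append(LayerSpec("avgpool3d", (q1, 1, 1), c2, output_shape=(t, h, w, c2)))
    conv(k3, c2, c3, "relu")
    specs.append(LayerSpec("conv3d", (k3, 3, 3), c3, c2, True, "relu", (t, h, w, c3)))
    layers.append(AvgPool3D(q2)); t //= q2
    specs.append(LayerSpec("avgpool3d", (q2, 1, 1), c3, output_shape=(t, h, w, c3)))
    conv(k4, c3, c4, "relu")
    specs.append(LayerSpec("conv3d", (k4, 3, 3), c4, c3, True, "relu", (t, h, w, c4)))
    layers.append(AvgPool3D(q3)); t //= q3
    specs.append(LayerSpec("avgpool3d", (q3, 1, 1), c4, output_shape=(t, h, w, c4)))
    conv(k5, c4, c5, "sigmoid")
    specs.append(LayerSpec("conv3d", (k5, 3, 3), c5, c4, True, "sigmoid",
                           (t, h, w, c5)))
    return DecoderNet(Sequential(layers), specs, "path1_backend",
                      (p["spike_frames"], h, w, 1))


def build_frontend(preset: str = "paper", seed: int = 0) -> DecoderNet:
    """VSD-to-spike 3D-CNN front-end of Path 2.

    Full scale: input 200x120x120x1; four conv+BN pairs with temporal
    kernels 7/5/5/3 and 16/32/16/32 filters, then a 1x1x1 conv with bias
    producing per-voxel spike logits (sigmoid -> probabilities).
    Convolutions followed by BN carry no bias.
    """
    p = _PRESETS[preset]
    t, (h, w) = p["vsd_frames"], p["grid"]
    chans = p["front_channels"]
    tks = p["front_tk"]
    rng = np.random.default_rng(seed + 1)
    layers, specs = [], [LayerSpec("input", output_shape=(t, h, w, 1))]
    cin = 1
    for kt, cout in zip(tks[:-1], chans[:-1]):
        layers.append(Conv3D((kt, 3, 3), cin, cout, use_bias=False,
                             activation="linear", rng=rng))
        specs.append(LayerSpec("conv3d", (kt, 3, 3), cout, cin, False, "linear",
                               (t, h, w, cout)))
        layers.append(BatchNorm(cout))
        specs.append(LayerSpec("batch_norm", (), cout, output_shape=(t, h, w, cout)))
        from .nn import Activation
        layers.append(Activation("relu"))
        cin = cout
    layers.append(Conv3D((tks[-1], 1, 1), cin, chans[-1], use_bias=True,
                         activation="linear", rng=rng))
    specs.append(LayerSpec("conv3d", (tks[-1], 1, 1), chans[-1], cin, True,
                           "sigmoid", (t, h, w, chans[-1])))
    return DecoderNet(Sequential(layers), specs, "path2_frontend", (t, h, w, 1))


@dataclass
class Path2Net:
    """Front-end + back-end composition for VSD -> image decoding.

    The front-end emits spike probabilities over the full VSD window; the
    back-end consumes only the first ``crop_frames`` frames — the window
    in which spikes occur (activity largely dies out within 150 ms at
    full scale).
    """

    front: DecoderNet
    back: DecoderNet
    crop_frames: int

    def __post_init__(self) -> None:
        ft, fh, fw, _ = self.front.specs[-1].output_shape
        bt, bh, bw, _ = self.back.input_shape
        if (fh, fw) != (bh, bw) or self.crop_frames != bt or ft < bt:
            raise ValueError("front-end output incompatible with back-end input")

    def forward(self, vsd: np.ndarray, training: bool = False) -> Tensor:
        logits = self.front.net.forward(Tensor(vsd), training)
        probs = logits.sigmoid()
        cropped = probs[:, :self.crop_frames]
        return self.back.net.forward(cropped, training)

    def parameters(self):
        return self.front.net.parameters() + self.back.net.parameters()

    def param_count(self) -> int:
        return self.front.param_count() + self.back.param_count()


def assemble_path2(front: DecoderNet, back: DecoderNet) -> Path2Net:
    """Connect pretrained blocks; crop the front-end output temporally."""
    return Path2Net(front=front, back=back, crop_frames=back.input_shape[0])


@dataclass
class TrainConfig:
    """Optimization settings for pretraining and refinement.

    The full-scale defaults follow the published protocol: Adam,
    learning rate 1e-4 (pretraining) or 0.5e-4 (refinement), batch size
    2, three refinement rounds, early stopping on F1 (front-end) or SSIM
    (back-end / end-to-end). The desk profile uses proportionally larger
    learning rates because its training runs are two orders of magnitude
    shorter.
    """

    lr_pretrain: float = 1e-4
    lr_refine: float = 0.5e-4
    batch_size: int = 2
    rounds: int = 3
    max_epochs: int = 100
    refine_epochs: int = 10
    patience: int = 10
    min_epochs: int = 10     # floor before patience applies; the F1 monitor
                             # can sit at 0 for the first epochs of an
                             # imbalanced spike target
    min_delta: float = 1e-4
    f1_threshold: float = 0.5
    seed: int = 0

    @classmethod
    def desk(cls, seed: int = 0) -> "TrainConfig":
        return cls(lr_pretrain=3e-3, lr_refine=1.5e-3, max_epochs=16,
                   refine_epochs=2, patience=4, min_epochs=8, seed=seed)


def _batches(n: int, batch: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for i in range(0, n, batch):
        yield idx[i:i + batch]


def _add_channel(x: np.ndarray) -> np.ndarray:
    return np.asarray(x, dtype=np.float32)[..., None]


def pretrain_frontend(front: DecoderNet, vsd: np.ndarray, spikes: np.ndarray,
                      val_vsd: np.ndarray, val_spikes: np.ndarray,
                      cfg: TrainConfig) -> dict:
    """BCE pretraining of the VSD-to-spike block; early stop on val F1.

    Spike targets are zero-padded along time to the VSD frame count
    (spikes only occupy the early frames).
    """
    n, nf_vsd = vsd.shape[0], vsd.shape[1]
    targets = _pad_spikes(spikes, nf_vsd)
    val_targets = _pad_spikes(val_spikes, nf_vsd)
    opt = Adam(front.net.parameters(), lr=cfg.lr_pretrain)
    rng = np.random.default_rng(cfg.seed)
    history = {"loss": [], "val_f1": []}
    best_f1, best_epoch = -np.inf, 0
    for epoch in range(cfg.max_epochs):
        losses = []
        for b in _batches(n, cfg.batch_size, rng):
            opt.zero_grad()
            logits = front.net.forward(Tensor(_add_channel(vsd[b])), training=True)
            loss = bce_with_logits(logits, _add_channel(targets[b]))
            if not np.isfinite(loss.item()):
                raise FloatingPointError("front-end training diverged (NaN loss)")
            loss.backward()
            opt.step()
            losses.append(loss.item())
        probs = frontend_probs(front, val_vsd)
        f1 = f1_score(probs, val_targets, cfg.f1_threshold)
        history["loss"].append(float(np.mean(losses)))
        history["val_f1"].append(f1)
        if f1 > best_f1 + cfg.min_delta:
            best_f1, best_epoch = f1, epoch
        elif epoch + 1 >= cfg.min_epochs and epoch - best_epoch >= cfg.patience:
            break
    return history


def _pad_spikes(spikes: np.ndarray, nf: int) -> np.ndarray:
    out = np.zeros((spikes.shape[0], nf) + spikes.shape[2:], dtype=np.float32)
    out[:, :spikes.shape[1]] = spikes
    return out


def frontend_probs(front: DecoderNet, vsd: np.ndarray,
                   batch: int = 4) -> np.ndarray:
    """Inference-mode spike probabilities, (N, T, H, W)."""
    outs = []
    with no_grad():
        for i in range(0, vsd.shape[0], batch):
            logits = front.net.forward(Tensor(_add_channel(vsd[i:i + batch])),
                                       training=False)
            outs.append(logits.sigmoid().data[..., 0])
    return np.concatenate(outs, axis=0)


def pretrain_backend(back: DecoderNet, spikes: np.ndarray, images: np.ndarray,
                     val_spikes: np.ndarray, val_images: np.ndarray,
                     cfg: TrainConfig) -> dict:
    """SSIM-loss pretraining of the spike-to-image block; early stop on val SSIM."""
    n = spikes.shape[0]
    opt = Adam(back.net.parameters(), lr=cfg.lr_pretrain)
    rng = np.random.default_rng(cfg.seed + 1)
    history = {"loss": [], "val_ssim": []}
    best, best_epoch = -np.inf, 0
    for epoch in range(cfg.max_epochs):
        losses = []
        for b in _batches(n, cfg.batch_size, rng):
            opt.zero_grad()
            pred = _backend_image(back.net.forward(
                Tensor(_add_channel(spikes[b]).astype(np.float32)), training=True))
            loss = ssim_loss(pred, images[b])
            if not np.isfinite(loss.item()):
                raise FloatingPointError("back-end training diverged (NaN loss)")
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val = _mean_ssim(decode_batch(back, val_spikes), val_images)
        history["loss"].append(float(np.mean(losses)))
        history["val_ssim"].append(val)
        if val > best + cfg.min_delta:
            best, best_epoch = val, epoch
        elif epoch + 1 >= cfg.min_epochs and epoch - best_epoch >= cfg.patience:
            break
    return history


def _backend_image(out: Tensor) -> Tensor:
    n, t, h, w, c = out.shape
    return out.reshape(n, h, w)


def _mean_ssim(pred: np.ndarray, truth: np.ndarray) -> float:
    return float(np.mean([ssim(p, t) for p, t in zip(pred, truth)]))


def alternating_refinement(path2: Path2Net, vsd: np.ndarray, images: np.ndarray,
                           val_vsd: np.ndarray, val_images: np.ndarray,
                           cfg: TrainConfig) -> dict:
    """Three rounds of alternating block refinement under end-to-end SSIM loss.

    Each round re-trains the front-end with the back-end frozen, then the
    back-end with the front-end frozen; frozen parameters are verified
    bit-identical across their frozen phase. Each phase monitors
    validation SSIM per epoch and restores the best state seen
    (including the pre-phase state), so a phase can never leave the
    network worse than it found it.
    """
    n = vsd.shape[0]
    rng = np.random.default_rng(cfg.seed + 2)
    history = {"round_val_ssim": [], "initial_val_ssim": _val_ssim(
        path2, val_vsd, val_images)}

    def train_phase(trained, frozen):
        frozen.net.set_trainable(False)
        trained.net.set_trainable(True)
        digest_before = frozen.net.state_digest()
        opt = Adam(trained.net.parameters(), lr=cfg.lr_refine)
        best_val = _val_ssim(path2, val_vsd, val_images)
        best_state = trained.net.get_state()
        for _ in range(cfg.refine_epochs):
            for b in _batches(n, cfg.batch_size, rng):
                opt.zero_grad()
                pred = _backend_image(path2.forward(_add_channel(vsd[b]),
                                                    training=True))
                loss = ssim_loss(pred, images[b])
                if not np.isfinite(loss.item()):
                    raise FloatingPointError("refinement diverged (NaN loss)")
                loss.backward()
                opt.step()
            val = _val_ssim(path2, val_vsd, val_images)
            if val > best_val:
                best_val, best_state = val, trained.net.get_state()
        trained.net.set_state(best_state)
        if frozen.net.state_digest() != digest_before:
            raise RuntimeError("frozen block changed during its frozen phase")
        frozen.net.set_trainable(True)

    for _ in range(cfg.rounds):
        train_phase(path2.front, path2.back)
        train_phase(path2.back, path2.front)
        history["round_val_ssim"].append(_val_ssim(path2, val_vsd, val_images))
    return history


def _val_ssim(path2: Path2Net, vsd: np.ndarray, images: np.ndarray) -> float:
    pred = decode_path2_batch(path2, vsd)
    return _mean_ssim(pred, images)


def decode(net, stream: np.ndarray) -> np.ndarray:
    """Decode a single stream (T, H, W) into a grayscale image in [0, 1]."""
    if isinstance(net, Path2Net):
        return decode_path2_batch(net, stream[None])[0]
    return decode_batch(net, stream[None])[0]


def decode_batch(back: DecoderNet, spikes: np.ndarray, batch: int = 4) -> np.ndarray:
    outs = []
    with no_grad():
        for i in range(0, spikes.shape[0], batch):
            out = back.net.forward(Tensor(_add_channel(spikes[i:i + batch]).astype(
                np.float32)), training=False)
            outs.append(_backend_image(out).data)
    return np.concatenate(outs, axis=0)


def decode_path2_batch(path2: Path2Net, vsd: np.ndarray, batch: int = 4) -> np.ndarray:
    outs = []
    with no_grad():
        for i in range(0, vsd.shape[0], batch):
            out = path2.forward(_add_channel(vsd[i:i + batch]), training=False)
            outs.append(_backend_image(out).data)
    return np.concatenate(outs, axis=0)
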