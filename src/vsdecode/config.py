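"""Run configuration, presets, seed fan-out, and the staged pipeline driver.

A single :class:`RunConfig` ties every stage together. The ``paper``
preset fixes the full-scale study conditions (120x120 grid, 30 spike
frames at 5 ms, 200 VSD frames, 400 triplets split 320/80); the ``desk``
preset is a CPU-scale profile (32x32 grid, 12 spike frames, 48 VSD
frames, 50 triplets split 40/10) with proportionally shortened training.
One global seed fans out to per-stage derived seeds (a hash of seed and
stage name) so each stage is independently reproducible. Artifacts are
stamped with the digest of the configuration that produced them and are
skipped on rerun unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import derive_seed
from .encoder import EncoderConfig
from .wiener import WienerModel

__all__ = ["RunConfig", "run_pipeline", "PIPELINE_STAGES", "default_wiener_model"]

PIPELINE_STAGES = ("make-dataset", "train", "evaluate", "baseline")


def default_wiener_model() -> WienerModel:
    """Wiener model with a plausible cortical impulse response and gain.

    The linear filter is an alpha-like 40 ms rise/decay; the static gain
    is a gently saturating monotone softplus-of-sigmoid producing dT/T0
    values of order 0.1-1 above a small baseline.
    """
    return WienerModel(beta=5.0, p=(1.0, 2.0, 0.5, 0.0, 0.0, 0.0))


@dataclass
class RunConfig:
    preset: str = "desk"
    grid: tuple[int, int] = (32, 32)
    record_ms: float = 60.0
    bin_ms: float = 5.0
    sim_duration_ms: float = 240.0
    n_total: int = 50
    n_train: int = 40
    n_test: int = 10
    prefilter_sigma_px: float = 1.0
    image_style: str = "mixture"
    spectral_slope: float = -2.0
    seed: int = 0
    out_dir: str = "runs/desk"
    encoder: dict = field(default_factory=dict)   # EncoderConfig overrides
    wiener: dict | None = None                    # serialized WienerModel

    @classmethod
    def from_preset(cls, preset: str, seed: int = 0,
                    out_dir: str | None = None) -> "RunConfig":
        if preset == "paper":
            return cls(preset="paper", grid=(120, 120), record_ms=150.0,
                       sim_duration_ms=1000.0, n_total=400, n_train=320,
                       n_test=80, seed=seed, out_dir=out_dir or "runs/paper")
        if preset == "desk":
            return cls(seed=seed, out_dir=out_dir or "runs/desk")
        raise ValueError(f"unknown preset {preset!r}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_train + self.n_test != self.n_total:
            raise ValueError("n_train + n_test must equal n_total")
        if self.preset == "paper" and (self.grid != (120, 120)
                                       or self.record_ms != 150.0
                                       or self.sim_duration_ms != 1000.0):
            raise ValueError("paper preset fixes grid 120x120, 150 ms record, "
                             "1000 ms simulation")

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(grid=tuple(self.grid), **self.encoder)

    def wiener_model(self) -> WienerModel:
        if self.wiener is None:
            return default_wiener_model()
        return WienerModel.from_json_dict(self.wiener)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str)
                              .encode()).hexdigest()

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)


def _stamp(path: Path, cfg: RunConfig) -> None:
    (path.with_suffix(path.suffix + ".provenance.json")).write_text(
        json.dumps({"config_digest": cfg.digest(), "seed": cfg.seed}))


def _is_cached(path: Path, cfg: RunConfig) -> bool:
    prov = path.with_suffix(path.suffix + ".provenance.json")
    if not (path.exists() and prov.exists()):
        return False
    try:
        return json.loads(prov.read_text())["config_digest"] == cfg.digest()
    except (json.JSONDecodeError, KeyError):
        return False


def run_pipeline(cfg: RunConfig, stages=None, force: bool = False,
                 log=print) -> dict:
    """Execute the pipeline stages in dependency order.

    Returns a dict of produced artifact paths and headline numbers.
    Cached artifacts (matching config digest) are skipped unless
    ``force``.
    """
    from . import baseline as bl
    from . import decoder as dec
    from .dataset import load_dataset, make_dataset
    from .evaluation import ssim_summary

    if stages is None:
        stages = PIPELINE_STAGES
    base_log = log

    def log(msg):
        base_log(msg)
        try:
            with open(Path(cfg.out_dir) / "log.jsonl", "a") as fh:
                fh.write(json.dumps({"msg": str(msg),
                                     "config_digest": cfg.digest()}) + "\n")
        except OSError:
            pass
    unknown = set(stages) - set(PIPELINE_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}; "
                         f"valid stages: {list(PIPELINE_STAGES)}")
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    ds_path = out / "dataset.h5"

    if "make-dataset" in stages:
        if _is_cached(ds_path, cfg) and not force:
            log(f"[make-dataset] cached: {ds_path}")
        else:
            log(f"[make-dataset] generating {cfg.n_total} triplets ...")
            make_dataset(ds_path, cfg.n_total, (cfg.n_train, cfg.n_test),
                         cfg.stage_seed("dataset"), cfg.encoder_config(),
                         cfg.wiener_model(), record_ms=cfg.record_ms,
                         bin_ms=cfg.bin_ms, sim_duration_ms=cfg.sim_duration_ms,
                         prefilter_sigma_px=cfg.prefilter_sigma_px,
                         image_style_kind=cfg.image_style,
                         spectral_slope=cfg.spectral_slope)
            _stamp(ds_path, cfg)
        results["dataset"] = str(ds_path)

    needs_training = {"train", "evaluate", "baseline"} & set(stages)
    if needs_training:
        if not ds_path.exists():
            raise FileNotFoundError(
                "stage 'train' requires the dataset artifact; run 'make-dataset'")
        images, spikes, vsd, manifest = load_dataset(ds_path)
        tr, te = manifest.train_indices, manifest.test_indices
        preset = "paper" if cfg.preset == "paper" else "desk"
        tcfg = (dec.TrainConfig(seed=cfg.stage_seed("train"))
                if preset == "paper"
                else dec.TrainConfig.desk(seed=cfg.stage_seed("train")))
        log("[train] pretraining back-end (Path 1) ...")
        back = dec.build_backend(preset, seed=cfg.stage_seed("back"))
        h_back = dec.pretrain_backend(back, spikes[tr], images[tr], spikes[te],
                                      images[te], tcfg)
        log("[train] pretraining front-end ...")
        front = dec.build_frontend(preset, seed=cfg.stage_seed("front"))
        h_front = dec.pretrain_frontend(front, vsd[tr], spikes[tr], vsd[te],
                                        spikes[te], tcfg)
        path2 = dec.assemble_path2(front, back)
        log("[train] alternating refinement ...")
        h_ref = dec.alternating_refinement(path2, vsd[tr], images[tr], vsd[te],
                                           images[te], tcfg)
        results["path1"] = back
        results["path2"] = path2
        results["history"] = {"backend": h_back, "frontend": h_front,
                              "refinement": h_ref}
        results["manifest"] = manifest

        if "evaluate" in stages:
            dec1 = dec.decode_batch(back, np.concatenate([spikes[tr], spikes[te]]))
            dec2 = dec.decode_path2_batch(path2,
                                          np.concatenate([vsd[tr], vsd[te]]))
            originals = np.concatenate([images[tr], images[te]])
            labels = ["train"] * len(tr) + ["test"] * len(te)
            rep1 = ssim_summary(dec1, originals, labels)
            rep2 = ssim_summary(dec2, originals, labels)
            report = {"path1": rep1.to_json_dict(), "path2": rep2.to_json_dict()}
            (out / "eval_report.json").write_text(json.dumps(report, indent=1))
            from .evaluation import plot_report
            plot_report(rep1, out / "path1")
            plot_report(rep2, out / "path2")
            log(f"[evaluate] Path-1 test SSIM {rep1.mean_test:.3f}, "
                f"Path-2 test SSIM {rep2.mean_test:.3f}")
            results["eval_report"] = report

        if "baseline" in stages:
            i = te[0]
            budget = int(spikes[i].sum())
            plan, _, decoded = bl.baseline_pipeline(
                images[i], cfg.wiener_model(), path2,
                spike_budget=budget, sim_duration_ms=cfg.sim_duration_ms,
                frame_ms=cfg.bin_ms)
            np.save(out / "baseline_decoded.npy", decoded)
            (out / "baseline_plan.json").write_text(plan.to_json())
            plan.write_mask_png(out / "baseline_mask.png")
            results["baseline_total_pulses"] = plan.total_pulses
            log(f"[baseline] stimulated {len(plan.selected_pixels)} pixels, "
                f"{plan.total_pulses} pulses (budget {budget})")
    return results
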