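"""Shared fixtures.

The desk-scale end-to-end run (dataset generation, two-stage training
with three refinement rounds, decoding) is expensive, so it is built
once per session and shared by every test that needs trained decoders.
"""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture(scope="session")
def desk_run(tmp_path_factory):
    """Full desk-preset pipeline: dataset, trained Path-1/Path-2, decodings."""
    from vsdecode.config import RunConfig, run_pipeline
    from vsdecode.dataset import load_dataset
    from vsdecode import decoder as dec

    out = tmp_path_factory.mktemp("desk_run")
    cfg = RunConfig.from_preset("desk", seed=1, out_dir=str(out))
    results = run_pipeline(cfg, stages=("make-dataset", "train"),
                           log=lambda *a: None)
    images, spikes, vsd, manifest = load_dataset(results["dataset"])
    tr, te = manifest.train_indices, manifest.test_indices
    back, path2 = results["path1"], results["path2"]
    return {
        "config": cfg,
        "images": images, "spikes": spikes, "vsd": vsd,
        "train_idx": tr, "test_idx": te,
        "path1": back, "path2": path2,
        "history": results["history"],
        "decoded1_test": dec.decode_batch(back, spikes[te]),
        "decoded2_test": dec.decode_path2_batch(path2, vsd[te]),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
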