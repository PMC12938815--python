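# Methods

`vsdecode` simulates the full loop of a neuromorphic intracortical
visual prosthesis — image → retinal spike code → cortical response →
decoded image — entirely in software, so that decoding strategies can be
compared without new physiological recordings. This note documents the
models, the parameters that matter, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Retinomorphic spike encoder

Each unit of a rectangular grid (default 120×120) emulates an
off-transient alpha retinal ganglion cell:

1. **Delayed difference of Gaussians.** The generator signal is
   `g(t) = −(G_c ∗ I(t) − G_s ∗ I(t − δ))`: a center Gaussian
   (σ_c = 1.2 px) minus a delayed (δ = 5 ms), wider surround Gaussian
   (σ_s = 3.0 px). Both kernels are normalized to unit DC gain, so a
   uniform field produces zero drive once the surround catches up. The
   leading sign implements *off* polarity: luminance decrements excite.
2. **Biphasic temporal filter.** A difference of two alpha functions
   (τ_fast = 10 ms, τ_slow = 40 ms), discretely normalized to exact zero
   sum and unit peak. The zero integral makes the response to sustained
   input transient — the defining property of the cell class.
3. **Izhikevich spiking.** Forward-Euler integration (dt = 0.5 ms) of
   `v' = 0.04v² + 5v + 140 − u + I`, `u' = a(bv − u)`, regular-spiking
   parameters (a, b, c, d) = (0.02, 0.2, −65, 8), spike at v ≥ 30 mV
   with post-detection reset.

The stimulus protocol is 200 ms of full-field gray (0.5) followed by the
image; spikes are collected for 150 ms after the switch and binned into
binary 5 ms frames (multiple spikes per bin saturate to 1, keeping the
stream a valid binary-cross-entropy target). The drive gain (default
50) was calibrated once so that a mixture-style image elicits 2–10
spikes per unit within the 150 ms window (measured ≈ 5.4/unit); with
this setting spiking is strongly transient, decaying to near silence by
the end of the window. The encoder is fully deterministic.

The specific receptive-field numbers (σ_c, σ_s, δ, the two τ, gain) are
behavior-level choices: they reproduce the transient off response and a
plausible firing budget rather than a particular fitted cell. All are
exposed in `EncoderConfig`.

## Wiener-system model of cortical VSD responses

The cortical voltage-sensitive-dye response of one pixel to a pulse
train `s(t)` is

    y(t) = f( (k ∗ L_γ ∗ s)(t) ),   L_γ(t) = 1 / (1 + (t/γ)²)

on a 1 ms grid, with γ = 0.25 ms. (The Lorentzian's closed-form FWHM is
2γ = 0.5 ms; descriptions quoting ≈ 0.49 ms reflect discrete sampling.)
The static gain is a modified Softplus,

    f(x) = Softplus_β( p₁·σ(p₂(x − p₃)) + p₄·e^{p₅x} + p₆ ),
    Softplus_β(z) = ln(1 + e^{βz}) / β,

evaluated with `logaddexp` so the large-argument linear asymptote is
exact. Pulses are unit impulses; physical current amplitude is metadata.
Simulation is strictly per pixel — no lateral coupling, recurrence, or
feedback, which is the model's main simplification.

**Identification.** Given pulse trains and measured traces, the filter
is estimated as the cross-correlation between the Lorentzian-filtered
train `w = L_γ ∗ s` and the trace, normalized by Σw² and restricted to
causal lags (default support 300 ms). Both signals are mean-centered
per segment; without centering the resting output f(0) leaks a constant
offset into every lag. The static gain is then fit by multi-start
(≥ 8 seeded starts) least squares of f against the (linear prediction,
trace) scatter. The individual (β, p) values are weakly identifiable —
the fitted *curve* is the contract, and tests assert curve RMSE, not
parameter recovery.

The identification round-trip experiment
(`wiener.identification_roundtrip`) mirrors the scale of the original
physiological derivation: 16 segments of 1.4 s driven by sparse 10 Hz
Poisson trains. On synthetic data from a known monotone model it reaches
filter-recovery r ≈ 0.99 and held-out simulated-vs-truth Pearson
r ≈ 0.97. This is a self-consistency check of the identification code,
not a reproduction of physiological agreement values, which depend on
recordings this package does not ship.

## Dataset construction

A triplet is (prefiltered image, spike stream, VSD stream). Images are
first blurred by a unit-DC Gaussian (σ = 1 px, reflect boundary)
standing in for photoreceptor-layer optics. Spike frames are upsampled
to the 1 ms grid with one pulse at each set frame's onset (k → 5k ms,
consistent with half-open binning); the simulated 1000 ms response is
block-averaged back to 5 ms frames (mean rather than decimation, to
preserve the energy of the slow VSD dynamics). Full scale therefore
yields 30×120×120 binary spikes and 200×120×120 real VSD frames per
image; 400 triplets split 320/80 into train/test by seeded shuffle.
Everything is stored in one HDF5 file with a JSON manifest; regeneration
from the same seed and configuration is bit-identical. VSD streams are
stored raw (including the f(0) baseline); normalization is left to the
decoder's batch-norm layers.

## Decoders

Both pathways are 3D CNNs over (time, height, width, channel), stride 1,
'same' spatial padding at every convolution.

* **Path 1 / back-end (spikes → image):** conv(30×3×3)×4,
  conv(30×3×3)×4, avgpool(2×1×1), conv(15×3×3)×8, avgpool(3×1×1),
  conv(5×3×3)×16, avgpool(5×1×1), conv(1×3×3)×1 — temporal axis
  collapsed 30→15→5→1, output a single 120×120 image. All convolutions
  carry bias (per-layer trainable counts 1084, 4324, 4328, 5776, 145).
* **Path 2 front-end (VSD → spike probabilities):** four conv+batch-norm
  pairs (temporal kernels 7/5/5/3, filters 16/32/16/32, no conv bias —
  the BN shift subsumes it) and a final 1×1×1 conv with bias (counts
  1008, 32, 23040, 64, 23040, 32, 13824, 64, 33). Hidden activations
  are ReLU; both block outputs pass through sigmoids.

The closed-form parameter audit (`DecoderNet.audit_param_counts`) is
checked against the counts reported by the allocated tensors for every
layer.

**Temporal interface.** The front-end emits 200 frames of spike
probability but the back-end consumes 30. Since spiking activity dies
out within the first 150 ms, the composition crops the front-end output
to its first 30 frames (0–150 ms). Cropping was chosen over pooling or
retraining the input layer as the least invasive bridge.

**Training protocol.** Adam, batch size 2. The blocks are pretrained
separately — front-end with binary cross-entropy against spike targets
zero-padded to the VSD frame count, early-stopped on validation F1
(threshold 0.5); back-end with a 1−SSIM loss against the prefiltered
images, early-stopped on validation SSIM. The assembled Path-2 network
is then refined for three rounds of (retrain front-end with back-end
frozen; retrain back-end with front-end frozen) under the end-to-end
SSIM loss; frozen blocks are digest-verified bit-identical across their
frozen phase. Full-scale learning rates are 1e-4 (pretraining) and
0.5e-4 (refinement) — coarse-then-fine. Early-stopping patience is 10
epochs with min-delta 1e-4 at full scale.

The networks run on a small in-package reverse-mode autodiff engine
(`vsdecode.nn`): conv3d via im2col/matmul with an explicit col2im
adjoint, composable batch norm, temporal average pooling, and
numerically stable BCE-from-logits. The SSIM training loss re-derives
the windowed measure (11×11 Gaussian window, σ = 1.5, K₁ = 0.01,
K₂ = 0.03, dynamic range 1, 'valid' windows) in autodiff ops; the
evaluation metric is scikit-image's implementation of the same measure,
giving an independent cross-check between loss and metric. Engine
gradients are verified against central finite differences in the test
suite. Parameters are float32; inference runs in a no-grad mode so no
graph buffers are retained.

## Desk preset

Full-scale training is a GPU-days workload; the `desk` preset is the
CPU-scale profile used by the tests and the acceptance script:
32×32 grid, 12 spike frames (60 ms record), 48 VSD frames (240 ms
simulation), 50 triplets split 40/10, front-end widths reduced to
4/8/4/8/1, temporal pools 2/3/2, learning rates scaled up to 3e-3 /
1.5e-3 because desk runs take two orders of magnitude fewer optimizer
steps, at most 16 pretraining epochs (patience 4) and 2 epochs per
refinement phase. The protocol structure — two-stage pretraining,
three alternating refinement rounds, batch 2, the same losses and
early-stopping monitors — is unchanged. Only a train/test split exists,
so the test fold doubles as the early-stopping validation fold; the
permuted-pair margin criterion is insensitive to this mild conflation. A desk run trains in roughly
ten minutes on one CPU core within ~2.5 GB of memory.

Desk-scale quality is assessed against a *permuted-pair* floor: the mean
SSIM of decoded images against mismatched originals, which captures how
similar any two generated images are by construction. Trained decoders
must beat this floor by at least 0.1 mean SSIM. Absolute SSIM values at
desk scale are not comparable to full-scale values obtained with
photographic images and long training.

## Synthetic images

Stock photographs are replaced by procedural generators (constant, pink
noise with configurable spectral slope, Gaussian blobs, hard-edged
shapes, and their mixture — the default). The mixture preserves the two
properties the pipeline exercises: broadband 1/f-type spectra and
localized contrast edges. It does not emulate photographic semantics,
texture statistics beyond second order, or occlusion structure; passing
desk-scale tests demonstrates that the loop transmits and recovers
spatial contrast structure, not that it reconstructs natural photographs
at any particular fidelity.

## Evaluation conventions

The image mean is removed before Fourier transforms so DC does not
dominate power statistics. Radial profiles use annuli of width 1/N
centered on the DFT frequencies k/N, so discrete gratings fall exactly
on bin centers. Orientation distributions fold conjugate half-planes to
[0°, 180°), exclude DC, and restrict to the Nyquist disk (the square
spectrum's corners exist only at diagonal orientations and would bias
sector sums); 36 sectors by default. Phase-difference profiles use the
power of the *original* image as weights inside each annulus, since
phases of near-zero-power components are noise. Per-image profiles are
averaged across images.

## Fixed-frequency baseline

The comparison strategy mirrors clinical all-or-none stimulation:
|Laplacian| edge strength (4-neighbor stencil, reflect boundary),
selection of the strongest-edge pixels until the per-image pulse budget
(the neuromorphic encoding's total spike count) is filled in whole
trains of 50 pulses (300 Hz × 166 ms, anchored at t = 0), identical
trains at every selected pixel, and the same Wiener model and Path-2
decoder downstream. Top-k selection is used instead of a scalar
threshold because it is the only way to satisfy the budget match exactly
up to train granularity; ties break in row-major order for determinism.
The budget is matched per image.

## Degenerate inputs and edge handling

Zero-variance traces make the Pearson coefficient undefined and raise;
empty pulse trains cannot drive identification and raise; spike streams
must be strictly binary before upsampling; non-finite membrane state
aborts integration with a diagnostic. All spatial filtering uses reflect
boundaries throughout the package.

## Known limitations

The cortical model is per-pixel linear–nonlinear: no lateral
interactions, adaptation, recurrence, or trial-to-trial variability, so
decoding scores here bound what stimulus-locked population components
can carry, not full cortical dynamics. The encoder implements a single
ganglion-cell type without stochastic spiking. Desk-scale SSIMs depend
on the synthetic image ensemble and short training, and are orientation
values only. The identification experiment validates the code path on
synthetic data; agreement with physiology requires measured traces fed
through the same `identify` interface.
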