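"""Reconstruction metrics: SSIM summaries and Fourier-domain analyses.

Beyond per-image SSIM, decoded images are compared with their originals
in the spatial-frequency domain: orientational power distributions,
radially averaged power profiles, and power-weighted phase-difference
profiles. The image mean is removed before every transform so the DC
component does not dominate the power statistics, and orientations are
folded to [0, 180) degrees using the Hermitian symmetry of real-image
spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

__all__ = [
    "EvalReport", "ssim", "ssim_summary", "f1_score",
    "fourier_spectrum", "radial_power_profile",
    "orientational_power_distribution", "phase_difference_profile",
]

SSIM_SETTINGS = dict(data_range=1.0, gaussian_weights=True, sigma=1.5,
                     use_sample_covariance=False, K1=0.01, K2=0.03, win_size=11)


def ssim(a: np.ndarray, b: np.ndarray, **overrides) -> float:
    """Windowed SSIM (11x11 Gaussian window, sigma 1.5, K1/K2 = 0.01/0.03)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    settings = {**SSIM_SETTINGS, **overrides}
    return float(structural_similarity(a, b, **settings))


@dataclass
class EvalReport:
    """Per-split SSIM statistics plus frequency-domain profiles."""

    ssim_train: list = field(default_factory=list)
    ssim_test: list = field(default_factory=list)
    mean_train: float = np.nan
    sd_train: float = np.nan
    mean_test: float = np.nan
    sd_test: float = np.nan
    n_train: int = 0
    n_test: int = 0
    radial_freqs: np.ndarray | None = None
    radial_power: np.ndarray | None = None
    orientation_bins: np.ndarray | None = None
    orientation_power: np.ndarray | None = None
    phase_diff: np.ndarray | None = None

    def to_json_dict(self) -> dict:
        def arr(x):
            return None if x is None else np.asarray(x).tolist()
        return {"ssim_train": list(map(float, self.ssim_train)),
                "ssim_test": list(map(float, self.ssim_test)),
                "mean_train": self.mean_train, "sd_train": self.sd_train,
                "mean_test": self.mean_test, "sd_test": self.sd_test,
                "n_train": self.n_train, "n_test": self.n_test,
                "radial_freqs": arr(self.radial_freqs),
                "radial_power": arr(self.radial_power),
                "orientation_bins": arr(self.orientation_bins),
                "orientation_power": arr(self.orientation_power),
                "phase_diff": arr(self.phase_diff)}


def ssim_summary(decoded, originals, split_labels) -> EvalReport:
    """Per-split mean +/- sample standard deviation of paired SSIMs.

    ``split_labels`` contains 'train'/'test' per pair.
    """
    decoded, originals = list(decoded), list(originals)
    labels = list(split_labels)
    if not (len(decoded) == len(originals) == len(labels)):
        raise ValueError("decoded, originals and split labels must be paired")
    rep = EvalReport()
    for d, o, lab in zip(decoded, originals, labels):
        (rep.ssim_train if lab == "train" else rep.ssim_test).append(ssim(d, o))
    for name, vals in (("train", rep.ssim_train), ("test", rep.ssim_test)):
        if vals:
            setattr(rep, f"mean_{name}", float(np.mean(vals)))
            setattr(rep, f"sd_{name}",
                    float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
        setattr(rep, f"n_{name}", len(vals))
    return rep


def f1_score(pred_probs: np.ndarray, truth: np.ndarray,
             threshold: float = 0.5) -> float:
    """F1 of thresholded predictions: 2TP / (2TP + FP + FN); 0 if undefined."""
    p = np.asarray(pred_probs)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("prediction and truth shapes differ")
    pb = p >= threshold
    tb = t > 0.5
    tp = int(np.sum(pb & tb))
    fp = int(np.sum(pb & ~tb))
    fn = int(np.sum(~pb & tb))
    denom = 2 * tp + fp + fn
    return 0.0 if denom == 0 else 2.0 * tp / denom


def plot_report(report: EvalReport, path_prefix) -> list:
    """Write violin (SSIM distributions) and profile plots as PNGs.

    Returns the list of files written; profiles are skipped when the
    report holds none.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    groups = [(lab, vals) for lab, vals in
              [("train", report.ssim_train), ("test", report.ssim_test)] if vals]
    if groups:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.violinplot([v for _, v in groups], showmeans=True)
        ax.set_xticks(range(1, len(groups) + 1),
                      [f"{lab} (n={len(v)})" for lab, v in groups])
        ax.set_ylabel("SSIM")
        fig.savefig(f"{path_prefix}_ssim_violin.png", dpi=120,
                    bbox_inches="tight")
        plt.close(fig)
        written.append(f"{path_prefix}_ssim_violin.png")
    if report.radial_freqs is not None or report.phase_diff is not None:
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
        if report.radial_freqs is not None:
            axes[0].loglog(report.radial_freqs[1:], report.radial_power[1:])
            axes[0].set_xlabel("spatial frequency (cycles/pixel)")
            axes[0].set_ylabel("radial power")
        if report.phase_diff is not None:
            axes[1].plot(report.radial_freqs, report.phase_diff)
            axes[1].set_xlabel("spatial frequency (cycles/pixel)")
            axes[1].set_ylabel("mean |Δphase| (rad)")
        fig.savefig(f"{path_prefix}_profiles.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(f"{path_prefix}_profiles.png")
    return written


def fourier_spectrum(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centered 2-D DFT power and phase maps after mean removal.

    Returns (power, phase), both fftshifted so DC sits at the center
    pixel; phase lies in (-pi, pi].
    """
    img = np.asarray(img, dtype=float)
    if img.shape[0] != img.shape[1]:
        raise ValueError("square images required for the spectral analyses")
    spec = np.fft.fftshift(np.fft.fft2(img - img.mean()))
    return np.abs(spec) ** 2, np.angle(spec)


def _freq_grid(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    f = np.fft.fftshift(np.fft.fftfreq(n))
    fy, fx = np.meshgrid(f, f, indexing="ij")
    return fx, fy, np.hypot(fx, fy)


def _radial_bins(n: int):
    """Annular bins of width 1/N centered on the discrete frequencies k/N.

    Centering bins on the DFT grid (round-to-nearest) keeps a pure
    grating's power in the bin whose center is exactly its frequency.
    Bins beyond the Nyquist frequency 0.5 are discarded.
    """
    _, _, fr = _freq_grid(n)
    n_bins = n // 2 + 1
    idx = np.minimum(np.round(fr * n).astype(int), n_bins)  # overflow discarded
    centers = np.arange(n_bins) / n
    return idx, centers, n_bins


def radial_power_profile(power: np.ndarray):
    """Mean power in annuli of width 1/N cycles/pixel, from 0 to Nyquist.

    Returns (bin center frequencies, mean power per bin).
    """
    n = power.shape[0]
    idx, centers, n_bins = _radial_bins(n)
    sums = np.bincount(idx.ravel(), weights=power.ravel(), minlength=n_bins + 1)
    counts = np.bincount(idx.ravel(), minlength=n_bins + 1)
    prof = np.divide(sums[:n_bins], counts[:n_bins],
                     out=np.zeros(n_bins), where=counts[:n_bins] > 0)
    return centers, prof


def orientational_power_distribution(power: np.ndarray, n_angle_bins: int = 36):
    """Power summed in angular sectors over [0, 180) degrees.

    Conjugate symmetry folds opposite half-planes together. The mask
    drops the DC component and everything beyond the Nyquist disk: the
    square spectrum's corners exist only at diagonal orientations and
    would bias the distribution. Returns (bin center angles in degrees,
    power per bin).
    """
    n = power.shape[0]
    fx, fy, fr = _freq_grid(n)
    mask = (fr > 0) & (fr <= 0.5)
    ang = np.degrees(np.arctan2(fy, fx)) % 180.0
    idx = np.minimum((ang[mask] / (180.0 / n_angle_bins)).astype(int),
                     n_angle_bins - 1)
    sums = np.bincount(idx, weights=power[mask], minlength=n_angle_bins)
    centers = (np.arange(n_angle_bins) + 0.5) * (180.0 / n_angle_bins)
    return centers, sums


def phase_difference_profile(orig: np.ndarray, decoded: np.ndarray):
    """Power-weighted mean |wrapped phase difference| per radial frequency bin.

    Weights are the original image's spectral power, so bins are not
    dominated by the meaningless phases of near-zero-power components.
    Returns (bin center frequencies, mean |dphase| in radians).
    """
    if np.shape(orig) != np.shape(decoded):
        raise ValueError("images must share dimensions")
    p_o, ph_o = fourier_spectrum(orig)
    _, ph_d = fourier_spectrum(decoded)
    dphi = np.angle(np.exp(1j * (ph_o - ph_d)))  # wrap to (-pi, pi]
    n = p_o.shape[0]
    idx, centers, n_bins = _radial_bins(n)
    w = p_o.ravel()
    num = np.bincount(idx.ravel(), weights=w * np.abs(dphi).ravel(),
                      minlength=n_bins + 1)
    den = np.bincount(idx.ravel(), weights=w, minlength=n_bins + 1)
    prof = np.divide(num[:n_bins], den[:n_bins], out=np.zeros(n_bins),
                     where=den[:n_bins] > 0)
    return centers, prof
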