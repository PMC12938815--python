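"""SSIM metrics, F1, and the Fourier-domain analyses."""

import numpy as np
import pytest

from vsdecode import evaluation as ev


class TestSsim:
    def test_identity(self, rng):
        x = rng.random((32, 32))
        assert ev.ssim(x, x) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a, b = rng.random((32, 32)), rng.random((32, 32))
        assert ev.ssim(a, b) == pytest.approx(ev.ssim(b, a), abs=1e-9)

    def test_inverted_checkerboard_negative(self):
        x = np.indices((32, 32)).sum(axis=0) % 2 * 1.0
        assert ev.ssim(x, 1.0 - x) < 0

    def test_single_window_matches_closed_form(self, rng):
        """3x3 toy pair, one uniform window: direct formula oracle."""
        a = rng.random((3, 3))
        b = rng.random((3, 3))
        got = ev.ssim(a, b, win_size=3, gaussian_weights=False)
        c1, c2 = 0.01 ** 2, 0.03 ** 2
        mx, my = a.mean(), b.mean()
        vx, vy = a.var(), b.var()
        cxy = ((a - mx) * (b - my)).mean()
        want = ((2 * mx * my + c1) * (2 * cxy + c2)) / \
               ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2))
        assert got == pytest.approx(want, abs=1e-10)

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.ssim(np.zeros((8, 8)), np.zeros((9, 9)))


class TestSsimSummary:
    def test_identical_pairs(self, rng):
        imgs = [rng.random((16, 16)) for _ in range(4)]
        rep = ev.ssim_summary(imgs, imgs, ["train", "train", "test", "test"])
        assert rep.mean_train == pytest.approx(1.0)
        assert rep.sd_train == pytest.approx(0.0)
        assert rep.n_train == 2 and rep.n_test == 2

    def test_mean_and_sample_sd(self, monkeypatch):
        vals = iter([0.8, 0.9])
        monkeypatch.setattr(ev, "ssim", lambda a, b: next(vals))
        rep = ev.ssim_summary([None, None], [None, None], ["test", "test"])
        assert rep.mean_test == pytest.approx(0.85)
        assert rep.sd_test == pytest.approx(0.0707, abs=1e-3)

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            ev.ssim_summary([np.zeros((8, 8))], [], ["train"])


def test_plot_report_writes_pngs(tmp_path, rng):
    imgs = [rng.random((16, 16)) for _ in range(4)]
    rep = ev.ssim_summary(imgs, imgs, ["train", "test", "test", "test"])
    rep.radial_freqs, rep.radial_power = ev.radial_power_profile(
        ev.fourier_spectrum(imgs[0])[0])
    _, rep.phase_diff = ev.phase_difference_profile(imgs[0], imgs[1])
    written = ev.plot_report(rep, tmp_path / "rep")
    assert len(written) == 2
    for f in written:
        assert (tmp_path / f.split("/")[-1]).exists()


class TestF1:
    def test_perfect_prediction(self):
        t = np.array([[1, 0], [0, 1]], dtype=float)
        assert ev.f1_score(t, t) == 1.0

    def test_all_zero_prediction(self):
        assert ev.f1_score(np.zeros((3, 3)), np.eye(3)) == 0.0

    def test_empty_case_defined_zero(self):
        assert ev.f1_score(np.zeros((2, 2)), np.zeros((2, 2))) == 0.0

    def test_matches_contingency_bruteforce(self, rng):
        p = rng.random((10, 4, 4))
        t = (rng.random((10, 4, 4)) < 0.4).astype(float)
        got = ev.f1_score(p, t, threshold=0.5)
        tp = fp = fn = 0
        for pi, ti in zip(p.ravel(), t.ravel()):
            pred = pi >= 0.5
            if pred and ti:
                tp += 1
            elif pred and not ti:
                fp += 1
            elif not pred and ti:
                fn += 1
        assert got == pytest.approx(2 * tp / (2 * tp + fp + fn))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import f1_score as sk_f1
        p = rng.random((6, 5, 5))
        t = (rng.random((6, 5, 5)) < 0.3).astype(int)
        got = ev.f1_score(p, t, threshold=0.5)
        want = sk_f1(t.ravel(), (p >= 0.5).astype(int).ravel())
        assert got == pytest.approx(want)


class TestFourier:
    def test_constant_image_zero_power(self):
        power, _ = ev.fourier_spectrum(np.full((16, 16), 0.7))
        assert np.allclose(power, 0.0)

    def test_cosine_concentrates_power(self):
        n = 64
        x = np.arange(n)
        img = 0.5 + 0.4 * np.cos(2 * np.pi * 0.125 * x)[None, :] * np.ones((n, 1))
        power, _ = ev.fourier_spectrum(img)
        # conjugate pair at fx = +-0.125, fy = 0
        iy, ix = np.unravel_index(np.argsort(power.ravel())[-2:], power.shape)
        f = np.fft.fftshift(np.fft.fftfreq(n))
        assert set(np.round(np.abs(f[ix]), 6)) == {0.125}
        assert np.allclose(f[iy], 0.0)
        assert power.sum() == pytest.approx(power[iy, ix].sum(), rel=1e-9)

    def test_parseval_identity(self, rng):
        img = rng.random((32, 32))
        power, _ = ev.fourier_spectrum(img)
        n2 = 32 * 32
        assert power.sum() / n2 ** 2 == pytest.approx(img.var(), rel=1e-6)

    def test_conjugate_symmetry_of_phase(self, rng):
        img = rng.random((16, 16))
        _, phase = ev.fourier_spectrum(img)
        spec = np.fft.fft2(img - img.mean())
        for fy, fx in [(1, 2), (3, 5)]:
            assert np.angle(spec[fy, fx]) == pytest.approx(
                -np.angle(spec[-fy, -fx]), abs=1e-9)

    def test_nonsquare_rejected(self):
        with pytest.raises(ValueError):
            ev.fourier_spectrum(np.zeros((8, 10)))


class TestRadialProfile:
    def test_white_noise_profile_flat(self):
        profs = []
        for seed in range(100):
            img = np.random.default_rng(seed).random((32, 32))
            power, _ = ev.fourier_spectrum(img)
            f, p = ev.radial_power_profile(power)
            profs.append(p)
        mean_prof = np.mean(profs, axis=0)
        f, _ = ev.radial_power_profile(power)
        sel = f >= 0.05
        grand = mean_prof[sel].mean()
        assert np.all(np.abs(mean_prof[sel] - grand) < 0.2 * grand)

    def test_grating_peak_at_its_frequency(self):
        n = 64
        img = np.cos(2 * np.pi * 0.25 * np.arange(n))[None, :] * np.ones((n, 1))
        power, _ = ev.fourier_spectrum(img)
        f, p = ev.radial_power_profile(power)
        assert f[np.argmax(p)] == pytest.approx(0.25, abs=1.0 / n)

    def test_zero_map_zero_profile(self):
        _, p = ev.radial_power_profile(np.zeros((16, 16)))
        assert np.allclose(p, 0.0)


class TestOrientationProfile:
    def test_isotropic_noise_near_uniform(self):
        totals = np.zeros(36)
        for seed in range(100):
            img = np.random.default_rng(seed).standard_normal((128, 128))
            power, _ = ev.fourier_spectrum(img)
            _, p = ev.orientational_power_distribution(power, 36)
            totals += p
        assert totals.max() / totals.min() < 1.5

    def test_vertical_grating_orientation(self):
        n = 64
        img = np.cos(2 * np.pi * 0.2 * np.arange(n))[None, :] * np.ones((n, 1))
        power, _ = ev.fourier_spectrum(img)
        ang, p = ev.orientational_power_distribution(power, 36)
        # variation along x -> power on the fx axis -> angle bin at 0 deg
        assert ang[np.argmax(p)] == pytest.approx(2.5)

    def test_total_power_conserved(self, rng):
        """Sector sums add up to the total power inside the mask
        (DC excluded, Nyquist disk)."""
        img = rng.random((32, 32))
        power, _ = ev.fourier_spectrum(img)
        _, p = ev.orientational_power_distribution(power, 36)
        _, _, fr = ev._freq_grid(32)
        masked_total = power[(fr > 0) & (fr <= 0.5)].sum()
        assert p.sum() == pytest.approx(masked_total, rel=1e-9)


class TestPhaseDifference:
    def test_identical_images_zero_profile(self, rng):
        img = rng.random((32, 32))
        _, prof = ev.phase_difference_profile(img, img)
        assert np.allclose(prof, 0.0)

    def test_shift_theorem_linear_growth(self):
        """1-pixel shift along x: |dphase| = 2*pi*f on a pattern whose
        power lies on the shift axis; matched within 5%."""
        n = 64
        sig = np.random.default_rng(0).standard_normal(n)
        img = np.tile(sig, (n, 1))  # varies along x only
        shifted = np.roll(img, 1, axis=1)
        f, prof = ev.phase_difference_profile(img, shifted)
        sel = (f > 0.05) & (f < 0.45)
        expect = 2 * np.pi * f[sel]
        assert np.all(np.abs(prof[sel] - expect) <= 0.05 * expect)

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.phase_difference_profile(np.zeros((8, 8)), np.zeros((16, 16)))
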