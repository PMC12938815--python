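"""Wiener-system model: kernels, simulation, and identification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vsdecode.wiener import (PulseTrain, WienerModel, estimate_linear_filter,
                             fit_static_nonlinearity, linear_stage,
                             lorentzian_kernel, modified_softplus, pearson_fit,
                             simulate_vsd_trace)


def random_train(rng, rate_hz=10.0, duration_ms=1400.0):
    n = rng.poisson(rate_hz * duration_ms / 1000.0)
    t = np.unique(np.round(np.sort(rng.uniform(0, duration_ms - 1, size=n))))
    return PulseTrain(t, duration_ms)


class TestLorentzian:
    def test_peak_is_one(self):
        L = lorentzian_kernel(0.25, dt_ms=0.25, support_ms=2.0)
        assert L[len(L) // 2] == 1.0

    def test_half_maximum_at_gamma(self):
        # L(+-gamma) = 0.5, i.e. continuous-time FWHM = 2*gamma = 0.5 ms
        L = lorentzian_kernel(0.25, dt_ms=0.25, support_ms=2.0)
        center = len(L) // 2
        assert L[center + 1] == pytest.approx(0.5)  # t = 0.25 ms
        assert L[center - 1] == pytest.approx(0.5)

    def test_sampled_value_direct_evaluation(self):
        L = lorentzian_kernel(0.25, dt_ms=0.05, support_ms=2.0)
        center = len(L) // 2
        assert L[center + 10] == pytest.approx(1.0 / 5.0)  # t = 0.5 ms

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            lorentzian_kernel(0.0)


class TestLinearStage:
    def test_no_pulses_zero_output(self):
        x = linear_stage(PulseTrain(np.array([]), 500.0), WienerModel())
        assert x.shape == (500,)
        assert np.allclose(x, 0.0)

    def test_single_pulse_matches_bruteforce(self):
        """Direct double-sum convolution oracle at 1e-9."""
        model = WienerModel()
        t0 = 100.0
        x = linear_stage(PulseTrain(np.array([t0]), 600.0), model)
        L = lorentzian_kernel(model.gamma_ms, 1.0, model.lorentzian_support_ms)
        half = (len(L) - 1) // 2
        oracle = np.zeros(600)
        for i in range(600):
            acc = 0.0
            for j, lv in enumerate(L):  # Lorentzian-broadened impulse
                tl = int(t0) + j - half
                for m, kv in enumerate(model.k):
                    if tl + m == i:
                        acc += lv * kv
            oracle[i] = acc
        assert np.allclose(x, oracle, atol=1e-9)

    def test_superposition(self):
        model = WienerModel()
        x12 = linear_stage(PulseTrain(np.array([50.0, 300.0]), 800.0), model)
        x1 = linear_stage(PulseTrain(np.array([50.0]), 800.0), model)
        x2 = linear_stage(PulseTrain(np.array([300.0]), 800.0), model)
        assert np.allclose(x12, x1 + x2, atol=1e-9)

    def test_empty_filter_rejected(self):
        with pytest.raises(ValueError):
            linear_stage(PulseTrain(np.array([1.0]), 100.0),
                         WienerModel(k=np.array([])))


class TestModifiedSoftplus:
    def test_zero_inner_argument_gives_log_two(self):
        v = modified_softplus(np.linspace(-5, 5, 11), 1.0, (0, 1, 0, 0, 0, 0))
        assert np.allclose(v, np.log(2.0))

    def test_saturated_sigmoid_linear_asymptote(self):
        v = modified_softplus(5.0, 20.0, (1.0, 1000.0, 0.0, 0.0, 0.0, 0.0))
        assert v == pytest.approx(1.0, abs=1e-4)

    def test_matches_extended_precision_formula(self, rng):
        """High-precision sympy oracle at 1e-10 relative."""
        import sympy as sp

        xs = rng.uniform(-3, 3, size=20)
        for _ in range(5):
            beta = float(rng.uniform(0.5, 20))
            p = rng.uniform(-2, 2, size=6)
            p[1] = abs(p[1])
            got = modified_softplus(xs, beta, tuple(p))
            for x, g in zip(xs, got):
                z = (p[0] / (1 + sp.exp(-p[1] * (sp.Float(x, 30) - p[2])))
                     + p[3] * sp.exp(p[4] * sp.Float(x, 30)) + p[5])
                want = float(sp.log(1 + sp.exp(beta * z)) / beta)
                assert g == pytest.approx(want, rel=1e-10, abs=1e-12)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            modified_softplus(0.0, -1.0, (0, 0, 0, 0, 0, 0))

    @given(st.floats(-50, 50), st.floats(0.1, 100),
           st.lists(st.floats(-3, 3), min_size=6, max_size=6))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_always_finite_and_above_softplus_floor(self, x, beta, p):
        """f stays finite and >= 0 over a wide input/parameter range
        (Softplus of any real argument is positive)."""
        p = list(p)
        p[4] = max(min(p[4], 0.3), -0.3)  # keep exp term representable
        v = float(modified_softplus(x, beta, tuple(p)))
        assert np.isfinite(v)
        assert v >= 0.0


class TestSimulate:
    def test_no_pulses_constant_baseline(self):
        model = WienerModel()
        y = simulate_vsd_trace(PulseTrain(np.array([]), 400.0), model)
        assert np.allclose(y, model.nonlinearity(0.0))

    def test_length_matches_duration(self):
        y = simulate_vsd_trace(PulseTrain(np.array([100.0]), 1000.0), WienerModel())
        assert y.shape == (1000,)

    def test_composition_of_oracles(self, rng):
        model = WienerModel()
        pt = random_train(rng, duration_ms=700.0)
        y = simulate_vsd_trace(pt, model)
        assert np.allclose(y, model.nonlinearity(linear_stage(pt, model)),
                           atol=1e-9)

    def test_translation_equivariance(self):
        model = WienerModel()
        y1 = simulate_vsd_trace(PulseTrain(np.array([100.0]), 1500.0), model)
        y2 = simulate_vsd_trace(PulseTrain(np.array([300.0]), 1500.0), model)
        assert np.allclose(y1[100:800], y2[300:1000], atol=1e-9)

    def test_monotone_nonlinearity_pulse_addition(self):
        """With monotone f and nonnegative filter, adding a pulse never
        lowers the response anywhere."""
        model = WienerModel()  # default k >= 0, monotone f
        y1 = simulate_vsd_trace(PulseTrain(np.array([200.0]), 900.0), model)
        y2 = simulate_vsd_trace(PulseTrain(np.array([200.0, 400.0]), 900.0), model)
        assert np.all(y2 >= y1 - 1e-12)


class TestIdentification:
    def test_filter_recovery_identity_nonlinearity(self):
        """Known k, identity output nonlinearity, sparse random trains:
        cross-correlation recovers the filter with r >= 0.99."""
        rng = np.random.default_rng(2024)
        truth = WienerModel()
        segs = []
        for _ in range(16):
            pt = random_train(rng)
            segs.append((pt, linear_stage(pt, truth)))  # identity f
        k_hat = estimate_linear_filter(segs, support_ms=300.0)
        r = np.corrcoef(k_hat, truth.k)[0, 1]
        assert r >= 0.99

    def test_zero_trace_zero_filter(self):
        pt = PulseTrain(np.array([50.0, 200.0]), 1000.0)
        k = estimate_linear_filter([(pt, np.zeros(1000))])
        assert np.allclose(k, 0.0)

    def test_estimator_linear_in_measurement(self, rng):
        pt = random_train(rng, duration_ms=1000.0)
        y = rng.standard_normal(1000)
        k1 = estimate_linear_filter([(pt, y)])
        k3 = estimate_linear_filter([(pt, 3.0 * y)])
        assert np.allclose(k3, 3.0 * k1, atol=1e-12)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            estimate_linear_filter([(PulseTrain(np.array([]), 100.0),
                                     np.zeros(100))])

    def test_nonlinearity_recovery_from_noisy_data(self):
        """Curve recovered within 2% RMSE of range from 1%-noise samples."""
        rng = np.random.default_rng(7)
        beta_t, p_t = 5.0, (1.0, 2.0, 0.5, 0.0, 0.0, 0.0)
        x = rng.uniform(-1, 3, size=2000)
        y_clean = modified_softplus(x, beta_t, p_t)
        rngn = np.random.default_rng(8)
        y = y_clean + rngn.normal(0, 0.01 * np.ptp(y_clean), size=y_clean.shape)
        beta, p, _ = fit_static_nonlinearity(x, y, seed=0)
        fitted = modified_softplus(x, beta, p)
        rmse = np.sqrt(np.mean((fitted - y_clean) ** 2))
        assert rmse <= 0.02 * np.ptp(y_clean)

    def test_linear_data_fit(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, size=2000)
        y = 0.8 * x + 0.1
        beta, p, resid = fit_static_nonlinearity(x, y, seed=1)
        assert resid <= 1e-3

    def test_constant_data_fit(self):
        x = np.linspace(-1, 1, 500)
        y = np.full(500, 0.3)
        beta, p, resid = fit_static_nonlinearity(x, y, seed=2)
        fitted = modified_softplus(x, beta, p)
        assert np.ptp(fitted) < 1e-4
        assert resid < 1e-4


class TestPearson:
    def test_identical_traces(self, rng):
        y = rng.standard_normal(100)
        assert pearson_fit(y, y) == pytest.approx(1.0)

    def test_negated_trace(self, rng):
        y = rng.standard_normal(100)
        assert pearson_fit(y, -y) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        a = np.array([1.0, 3, 2, 5, 4, 6, 8, 7, 9, 10])
        b = np.array([2.0, 1, 4, 3, 6, 5, 8, 9, 7, 11])
        want = (np.mean(a * b) - a.mean() * b.mean()) / (np.std(a) * np.std(b))
        assert pearson_fit(a, b) == pytest.approx(want, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_fit(np.ones(10), np.arange(10.0))
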