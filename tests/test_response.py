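"""Total system response H, impulse-response power and duration."""

import numpy as np
import pytest

import varxnet as vn
from varxnet.containers import InstabilityError, NeuralTimeSeries, StimulusFeatureSet
from varxnet.response import (
    ImpulseResponseSet,
    companion_spectral_radius,
    compare_B_vs_H,
    compute_H,
    impulse_responses_from_B,
    response_length,
    response_power,
)
from varxnet.simulate import GroundTruthSpec


def _spec(A, B, sd=0.0):
    d_y = A.shape[0]
    return GroundTruthSpec(A_true=A, B_true=B, innovation_sd=np.full(d_y, sd), seed=0)


class TestComputeH:
    def test_no_recurrence_returns_B_padded(self):
        rng = np.random.default_rng(0)
        A = np.zeros((2, 2, 3))
        B = rng.normal(size=(2, 1, 4))
        H = compute_H(_spec(A, B).as_fit(), L=6) if hasattr(GroundTruthSpec, "as_fit") else None
        fit = vn.VARXModelFit(A=A, B=B, sigma2_full=np.zeros(2), residuals=np.zeros((2, 1)),
                              lag_spec=vn.LagSpec(3, 4, 0.0), T_eff=1, fs=60.0)
        H = compute_H(fit, L=6)
        np.testing.assert_array_equal(H.kernels[:, :, :4], B)
        np.testing.assert_array_equal(H.kernels[:, :, 4:], 0.0)

    def test_scalar_geometric_closed_form(self):
        a, b = 0.8, 1.5
        fit = vn.VARXModelFit(
            A=np.array([[[a]]]), B=np.array([[[b]]]), sigma2_full=np.zeros(1),
            residuals=np.zeros((1, 1)), lag_spec=vn.LagSpec(1, 1, 0.0), T_eff=1, fs=60.0,
        )
        H = compute_H(fit, L=20)
        np.testing.assert_allclose(H.kernels[0, 0], b * a ** np.arange(20), atol=1e-12)

    def test_matches_noiseless_simulation_of_impulse(self):
        spec = vn.oscillator_ground_truth(d_y=3, d_x=2, n_a=3, n_b=5, seed=3)
        noiseless = GroundTruthSpec(
            A_true=spec.A_true, B_true=spec.B_true, innovation_sd=np.zeros(3), seed=0
        )
        L = 30
        for j in range(2):
            data = np.zeros((2, L))
            data[j, 0] = 1.0
            x = StimulusFeatureSet(data=data, fs=60.0)
            y = vn.simulate_varx(noiseless, x, seed=0)
            H = compute_H(
                vn.VARXModelFit(A=spec.A_true, B=spec.B_true, sigma2_full=np.zeros(3),
                                residuals=np.zeros((3, 1)), lag_spec=vn.LagSpec(3, 5, 0.0),
                                T_eff=1, fs=60.0),
                L=L,
            )
            np.testing.assert_allclose(y.data, H.kernels[:, j, :], atol=1e-10)

    def test_equals_z_domain_transfer_function(self):
        """Time-domain recursion agrees with (I - A(z))^{-1} B(z) via FFT."""
        spec = vn.oscillator_ground_truth(d_y=3, d_x=2, n_a=3, n_b=5, seed=4)
        A, B = spec.A_true, spec.B_true
        L = 40
        N = 4096
        w = np.exp(-2j * np.pi * np.arange(N) / N)
        H_freq = np.empty((3, 2, N), dtype=complex)
        for k in range(N):
            Az = sum(A[:, :, t] * w[k] ** (t + 1) for t in range(A.shape[2]))
            Bz = sum(B[:, :, t] * w[k] ** t for t in range(B.shape[2]))
            H_freq[:, :, k] = np.linalg.inv(np.eye(3) - Az) @ Bz
        h_time = np.fft.ifft(H_freq, axis=2).real[:, :, :L]
        fit = vn.VARXModelFit(A=A, B=B, sigma2_full=np.zeros(3), residuals=np.zeros((3, 1)),
                              lag_spec=vn.LagSpec(3, 5, 0.0), T_eff=1, fs=60.0)
        np.testing.assert_allclose(compute_H(fit, L=L).kernels, h_time, atol=1e-8)

    def test_unstable_model_raises_with_radius(self):
        A = np.array([[[1.05]]])
        fit = vn.VARXModelFit(A=A, B=np.ones((1, 1, 1)), sigma2_full=np.zeros(1),
                              residuals=np.zeros((1, 1)), lag_spec=vn.LagSpec(1, 1, 0.0),
                              T_eff=1, fs=60.0)
        with pytest.raises(InstabilityError, match="1.05"):
            compute_H(fit, L=5)

    def test_companion_radius_of_diagonal_ar1(self):
        A = np.zeros((2, 2, 1))
        A[0, 0, 0], A[1, 1, 0] = 0.5, -0.9
        assert companion_spectral_radius(A) == pytest.approx(0.9)


class TestResponseMetrics:
    def _set(self, kernel, fs=60.0, window=(0.0, 0.6)):
        return ImpulseResponseSet(kernels=np.asarray(kernel, float)[None, None, :],
                                  fs=fs, window=window)

    def test_power_of_zero_and_constant_kernels(self):
        assert response_power(self._set(np.zeros(36)))[0, 0] == 0.0
        c = 0.7
        assert response_power(self._set(np.full(36, c)))[0, 0] == pytest.approx(c * c)

    def test_power_of_geometric_kernel_matches_closed_form(self):
        a, n = 0.9, 36
        kern = a ** np.arange(n)
        expected = (1 - a ** (2 * n)) / (n * (1 - a * a))
        assert response_power(self._set(kern))[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_triangular_pulse_width_is_half_base(self):
        # symmetric triangle (base 20 samples) on a mostly-zero kernel,
        # so the median baseline is exactly zero
        kern = np.zeros(64)
        tri = np.concatenate([np.linspace(0, 1, 11), np.linspace(1, 0, 11)[1:]])
        kern[4:25] = tri
        width = response_length(self._set(kern, window=(0.0, 64 / 60.0)))[0, 0]
        assert width == pytest.approx(20 / 2 / 60.0 * 1000.0, rel=1e-9)

    def test_monotone_decay_width_matches_brute_force_scan(self):
        a = 0.8
        kern = a ** np.arange(36)
        got = response_length(self._set(kern))[0, 0]
        # independent scan using the documented definition
        m = np.abs(kern)
        baseline = np.median(m)
        half = baseline + 0.5 * (m.max() - baseline)
        k = 0
        while m[k + 1] >= half:
            k += 1
        frac = (m[k] - half) / (m[k] - m[k + 1])
        expected = (k + frac) / 60.0 * 1000.0  # one-sided: peak at window edge
        assert got == pytest.approx(expected, rel=1e-9)

    def test_flat_kernel_has_undefined_width(self):
        assert np.isnan(response_length(self._set(np.zeros(36)))[0, 0])

    def test_metrics_frame_layout(self, fitted_small_model):
        _, model = fitted_small_model
        H = compute_H(model, L=12)
        df = H.metrics_frame()
        assert list(df.columns) == ["channel", "feature", "power", "length_ms"]
        assert len(df) == model.A_.shape[0] * model.B_.shape[1]


class TestCompareBvsH:
    def _fit(self, a, brief_b, fs=60.0):
        B = np.zeros((1, 1, 8))
        B[0, 0, :len(brief_b)] = brief_b
        return vn.VARXModelFit(A=np.array([[[a]]]), B=B, sigma2_full=np.zeros(1),
                               residuals=np.zeros((1, 1)), lag_spec=vn.LagSpec(1, 8, 0.0),
                               T_eff=1, fs=fs)

    def test_slow_recurrence_strengthens_and_prolongs_response(self):
        fit = self._fit(0.95, [1.0, 0.5])
        b_set = impulse_responses_from_B(fit, L=36)
        h_set = compute_H(fit, L=36)
        assert response_power(h_set)[0, 0] > response_power(b_set)[0, 0]
        assert response_length(h_set)[0, 0] > response_length(b_set)[0, 0]

    def test_no_recurrence_gives_zero_deltas_and_p_one(self):
        fits = [self._fit(0.0, [1.0, 0.5]) for _ in range(5)]
        b_sets = [impulse_responses_from_B(f, L=36) for f in fits]
        h_sets = [compute_H(f, L=36) for f in fits]
        masks = [np.ones((1, 1), bool)] * 5
        out = compare_B_vs_H(b_sets, h_sets, masks)
        np.testing.assert_allclose(out["power_delta"], 0.0, atol=1e-14)
        assert out["power_wilcoxon"]["p"] == 1.0

    def test_empty_selection_yields_nan_with_warning(self):
        fit = self._fit(0.5, [1.0])
        b = impulse_responses_from_B(fit, L=36)
        h = compute_H(fit, L=36)
        with pytest.warns(UserWarning):
            out = compare_B_vs_H([b], [h], [np.zeros((1, 1), bool)])
        assert np.isnan(out["power_delta"][0])


def test_omitting_uncorrelated_input_leaves_kernel_alone():
    """In a feed-forward encoding fit, omitting an uncorrelated feature barely
    moves the other kernel; omitting a temporally correlated one (the coupled
    envelope/edge pair) makes the survivor absorb the shared response."""
    T = 30_000
    x3 = vn.make_stimulus(
        T, 60.0,
        [{"kind": "continuous", "smoothness": 0.1},
         {"kind": "pulse", "rate": 1.0},
         {"kind": "pulse", "rate": 1.0}],
        couple=[(0, 1)],  # feature 1 = derivative peaks of feature 0
        seed=20,
    )
    rng = np.random.default_rng(22)
    spec = vn.oscillator_ground_truth(d_y=2, d_x=3, n_a=2, n_b=6, b_scale=1.0, seed=21)
    B = spec.B_true.copy()
    B[:, 1, :] *= 4.0
    B[:, 2, :] *= 4.0
    # pure moving-average data: y responds to all three features, no recurrence
    y_data = np.zeros((2, T))
    for j in range(3):
        for i in range(2):
            y_data[i] += np.convolve(x3.data[j], B[i, j])[:T]
    y_data += 0.3 * rng.standard_normal((2, T))
    y = NeuralTimeSeries(y_data, fs=60.0)

    def kernel0(features):
        xs = StimulusFeatureSet(data=x3.data[features], fs=60.0)
        return vn.fit_mtrf(y, xs, L=6, lambda_reg=0.0).kernels[:, 0, :]

    b_full = kernel0([0, 1, 2])
    err_uncorr = np.linalg.norm(kernel0([0, 1]) - b_full)  # drops independent train
    err_corr = np.linalg.norm(kernel0([0, 2]) - b_full)    # drops coupled edges
    assert err_corr > 3 * err_uncorr
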