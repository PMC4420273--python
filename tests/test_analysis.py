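"""Kernel fitting, residual/noise, decorrelation and morph-model fits."""

import math

import numpy as np
import pytest

from bulbnet.analysis import (
    MORPH_CONCS,
    FitQuality,
    delta_rate_correlation,
    fit_linear_kernel,
    fit_morph_model,
    morph_prediction,
    morph_sigmoid,
    phase_correlation,
    predict_response,
    predict_two_odor,
    residual_over_noise,
)


def _known_kernel_response(rng, kernel, conc, baseline=3.0):
    y = np.zeros(len(conc))
    for k in range(len(kernel)):
        y[k:] += kernel[k] * conc[: len(conc) - k]
    return y + baseline


class TestKernelFit:
    def test_noiseless_recovery(self, rng):
        """Exact inverse on noiseless synthetic convolutions (primary
        correctness oracle): error < 1e-6 for well-conditioned stimuli."""
        true_k = rng.normal(0, 1, 40) * np.exp(-np.arange(40) / 10.0)
        c1 = (rng.random(240) > 0.5).astype(float)
        c2 = (rng.random(240) > 0.5).astype(float)
        fit = fit_linear_kernel(
            [_known_kernel_response(rng, true_k, c1),
             _known_kernel_response(rng, true_k, c2)], [c1, c2])
        assert np.max(np.abs(fit.kernel - true_k)) < 1e-6
        assert fit.baseline == pytest.approx(3.0, abs=1e-6)

    def test_baseline_only_response_gives_zero_kernel(self, rng):
        c = (rng.random(200) > 0.5).astype(float)
        fit = fit_linear_kernel([np.full(200, 5.0)], [c])
        assert np.max(np.abs(fit.kernel)) < 1e-8

    def test_residual_to_noise_approaches_one_with_noise(self, rng):
        """With i.i.d. noise the in-sample prediction's residual/noise is
        near 1 as trials grow (variance decomposition)."""
        true_k = np.exp(-np.arange(40) / 8.0)
        c = (rng.random(400) > 0.5).astype(float)
        clean = _known_kernel_response(rng, true_k, c)
        trials = clean + rng.normal(0, 1.0, size=(40, len(clean)))
        fit = fit_linear_kernel([trials.mean(axis=0)], [c])
        pred = predict_response(fit, c, rectify=False)
        q = residual_over_noise(pred, trials)
        # prediction error ~ sigma^2/ntrials scaled by dof; well below noise
        assert q.ratio < 1.0

    def test_two_odor_prediction_reduces_to_single(self, rng):
        k = np.exp(-np.arange(40) / 5.0)
        c = (rng.random(150) > 0.5).astype(float)
        fit = fit_linear_kernel([_known_kernel_response(rng, k, c, 0.0)], [c],
                                air_baseline=0.0)
        both = predict_two_odor(fit, fit, c, np.zeros_like(c), baseline=0.0)
        single = predict_response(fit, c)
        assert np.allclose(both, single)

    def test_two_odor_linearity_prerectification(self, rng):
        k = np.exp(-np.arange(40) / 5.0)
        c = (rng.random(150) > 0.5).astype(float)
        fit = fit_linear_kernel([_known_kernel_response(rng, k, c, 0.0)], [c],
                                air_baseline=0.0)
        one = predict_two_odor(fit, fit, c, c, baseline=0.0)
        two = predict_two_odor(fit, fit, 2 * c, 2 * c, baseline=0.0)
        assert np.allclose(two, 2 * one)  # all-positive here, so exact

    def test_grid_mismatch_rejected(self, rng):
        k = np.exp(-np.arange(40) / 5.0)
        c = (rng.random(150) > 0.5).astype(float)
        fit = fit_linear_kernel([_known_kernel_response(rng, k, c, 0.0)], [c])
        with pytest.raises(ValueError):
            predict_two_odor(fit, fit, c, c[:-10])


class TestResidualOverNoise:
    def test_worked_example(self):
        """3-bin, 2-trial example verified by direct arithmetic."""
        trials = np.array([[1.0, 2.0, 3.0], [3.0, 4.0, 5.0]])
        # trial mean (2,3,4); per-bin variance (ddof=1) = 2 each
        q = residual_over_noise(np.array([2.0, 3.0, 5.0]), trials)
        assert q.residual == pytest.approx((0 + 0 + 1) / 3)
        assert q.noise == pytest.approx(2.0)
        assert q.ratio == pytest.approx(1.0 / 6.0)

    def test_perfect_prediction(self):
        trials = np.array([[1.0, 2.0], [3.0, 4.0]])
        q = residual_over_noise(trials.mean(axis=0), trials)
        assert q.ratio == 0.0

    def test_zero_noise_sentinel(self):
        trials = np.array([[1.0, 2.0], [1.0, 2.0]])
        q = residual_over_noise(np.array([1.5, 2.0]), trials)
        assert math.isinf(q.ratio)
        assert not q.acceptable

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            residual_over_noise(np.zeros(3), np.zeros((1, 3)))

    def test_scale_invariance(self, rng):
        trials = rng.random((5, 8))
        pred = rng.random(8)
        r1 = residual_over_noise(pred, trials).ratio
        r2 = residual_over_noise(7.0 * pred, 7.0 * trials).ratio
        assert r1 == pytest.approx(r2)


class TestPhaseCorrelation:
    def test_identical_responses(self):
        r = phase_correlation([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert r == pytest.approx(1.0)

    def test_anticorrelated(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r = phase_correlation(a, -a + 10.0)
        assert r == pytest.approx(-1.0)

    def test_zero_response_excluded(self):
        assert phase_correlation(np.zeros(5), [1, 2, 3, 4, 5]) is None
        assert phase_correlation(np.full(5, 2.0), [1, 2, 3, 4, 5]) is None

    def test_bin_permutation_invariance(self, rng):
        a, b = rng.random(5), rng.random(5)
        perm = rng.permutation(5)
        assert phase_correlation(a, b) == pytest.approx(
            phase_correlation(a[perm], b[perm]))

    def test_bounded(self, rng):
        for _ in range(20):
            r = phase_correlation(rng.random(5), rng.random(5))
            assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12


class TestDeltaRate:
    def test_identical_deltas(self):
        assert delta_rate_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_sign_flipped(self):
        assert delta_rate_correlation([1, 2, 3], [-1, -2, -3]) == \
            pytest.approx(-1.0)

    def test_too_few_entries(self):
        with pytest.raises(ValueError):
            delta_rate_correlation([1.0], [2.0])


class TestMorphModel:
    @pytest.fixture()
    def synthetic(self, rng):
        nb = 9
        F_air = rng.normal(0, 0.3, nb)
        F_A = rng.normal(0.3, 0.3, nb)
        F_B = rng.normal(0.2, 0.3, nb)
        rmax = 20.0
        wA = np.array([0.25, 0.5, 0.7, 0.9])
        wB = np.array([0.85, 0.6, 0.45, 0.2])
        resp = {"air": rmax * morph_sigmoid(F_air),
                "A": rmax * morph_sigmoid(F_A),
                "B": rmax * morph_sigmoid(F_B)}
        for i, key in enumerate(MORPH_CONCS):
            resp[key] = rmax * morph_sigmoid(wA[i] * F_A + wB[i] * F_B + F_air)
        return resp, wA, wB

    def test_parameter_recovery(self, synthetic):
        resp, wA, wB = synthetic
        m = fit_morph_model(resp, seed=3)
        assert m.quality["mse"] < 1e-6
        assert np.allclose(m.w_A, wA, atol=0.02)
        assert np.allclose(m.w_B, wB, atol=0.02)

    def test_weights_monotone(self, synthetic):
        m = fit_morph_model(synthetic[0], seed=4)
        assert np.all(np.diff(m.w_A) >= -1e-9)  # w_A rises with c_A
        assert np.all(np.diff(m.w_B) <= 1e-9)  # w_B falls as c_B falls

    def test_sigmoid_midpoint(self):
        assert morph_sigmoid(0.0) == pytest.approx(0.5)

    def test_rectifier_mode_uses_linear_weights(self, synthetic):
        m = fit_morph_model(synthetic[0], mode="linear_weights_rectifier",
                            seed=5, n_restarts=2)
        assert np.allclose(m.w_A, [c[0] for c in MORPH_CONCS])
        assert np.allclose(m.w_B, [c[1] for c in MORPH_CONCS])
        pred = morph_prediction(m, 0)
        assert np.all(pred >= 0)

    def test_unknown_mode(self, synthetic):
        with pytest.raises(ValueError):
            fit_morph_model(synthetic[0], mode="quadratic")
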