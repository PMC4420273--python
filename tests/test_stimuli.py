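"""ORN kernels, pulse trains, respiration and spike generation."""

import numpy as np
import pytest

from bulbnet.stimuli import (
    AIR_PEAK_RANGE,
    DT_MS,
    ODOR_PEAK_RANGE,
    RESP_PERIOD_MS,
    background_trains,
    logistic_nonlinearity,
    make_orn_kernel,
    msequence_bits,
    msequence_concentration,
    poisson_spikes,
    rate_from_stimulus,
    respiration,
    respiration_cycle,
    single_pulse_concentration,
    steady_cycle_peak,
    valve_filter,
)


class TestRespiration:
    def test_starts_from_zero(self):
        # the two dual-exponential inhalation terms vanish at t = 0
        assert respiration(0.0) == pytest.approx(0.0, abs=1e-9)

    def test_periodicity(self):
        t = np.linspace(0, 500, 101)
        assert np.allclose(respiration(t), respiration(t + RESP_PERIOD_MS))

    def test_rectified_nonnegative(self):
        t = np.linspace(0, 500, 2001)
        assert np.all(respiration(t) >= 0)

    def test_cycle_maximum_matches_fine_grid(self):
        """Location/height of the in-cycle maximum against a dense numeric
        evaluation of the printed three-term expression."""
        tf = np.linspace(0, 500, 200_001)
        wf = respiration(tf)
        cyc = respiration_cycle(normalize=False)
        assert cyc.max() == pytest.approx(wf.max(), rel=1e-3)
        assert abs(np.argmax(cyc) * DT_MS - tf[np.argmax(wf)]) <= 1.0


class TestKernels:
    def test_zero_at_origin_and_peak_value(self, rng):
        k = make_orn_kernel("odor", rng)
        assert k(0.0) == 0.0
        assert k(k.t_p) == pytest.approx(k.k_p)

    def test_post_convolution_peaks_in_printed_ranges(self, rng):
        for kind, (lo, hi) in (("air", AIR_PEAK_RANGE),
                               ("odor", ODOR_PEAK_RANGE)):
            peaks = [steady_cycle_peak(make_orn_kernel(kind, rng))
                     for _ in range(40)]
            assert min(peaks) >= lo - 1e-6
            assert max(peaks) <= hi + 1e-6

    def test_mixed_kernel_has_negative_lobe(self, rng):
        k = make_orn_kernel("odor", rng, polarity="mixed")
        t = np.arange(0, 2500.0)
        assert k(t).min() < 0

    def test_parameter_ranges(self, rng):
        for _ in range(20):
            k = make_orn_kernel("odor", rng)
            assert 150.0 <= k.t_p <= 350.0
            assert 250.0 <= k.sigma_p <= 450.0


class TestPulseTrains:
    def test_msequence_full_length_350_ms(self, rng):
        bits = msequence_bits(rng)
        assert len(bits) == 7  # 7 x 50 ms = 350 ms
        assert bits.sum() == 4  # maximal-length property: 4 ones, 3 zeros

    def test_all_zero_bits_give_pedestal_only(self, rng):
        conc, air = msequence_concentration(0.0, rng)
        assert np.allclose(conc, 0.0)
        assert np.allclose(air, 1.0 / 3.0)

    def test_valve_step_response_time_constant(self):
        step = np.ones(500)
        out = valve_filter(step)
        # reaches 1 - 1/e of the plateau at ~40 ms
        i63 = np.argmax(out >= (1 - np.exp(-1)) * out[-1])
        assert abs(i63 * DT_MS - 40.0) <= 2.0

    def test_negative_concentration_rejected(self, rng):
        with pytest.raises(ValueError):
            msequence_concentration(-1.0, rng)

    def test_single_pulse_layout(self):
        conc, air = single_pulse_concentration(2.0, pulse_ms=200.0,
                                               lead_ms=200.0)
        assert conc[:150].max() == 0.0
        assert conc.max() == pytest.approx(2.0, rel=0.05)


class TestRateGeneration:
    def test_logistic_values(self):
        assert logistic_nonlinearity(7.2) == pytest.approx(9.0)
        assert logistic_nonlinearity(1e3) == pytest.approx(18.0)
        assert logistic_nonlinearity(0.0) == pytest.approx(
            18.0 / (1.0 + np.exp(7.2)))

    def test_mismatched_time_bases_rejected(self, rng):
        ko = make_orn_kernel("odor", rng)
        ka = make_orn_kernel("air", rng)
        with pytest.raises(ValueError):
            rate_from_stimulus(np.zeros(100), np.zeros(200), ko, ka)

    def test_generator_linearity_without_nonlinearity(self, rng):
        """rate(alpha C) - baseline = alpha (rate(C) - baseline)."""
        ko = make_orn_kernel("odor", rng)
        ka = make_orn_kernel("air", rng)
        c = np.zeros(3000)
        c[500:700] = 1.0
        air = np.zeros(3000)
        r1 = rate_from_stimulus(c, air, ko, ka).rate - 0.5
        r3 = rate_from_stimulus(3.0 * c, air, ko, ka).rate - 0.5
        assert np.allclose(r3, 3.0 * r1, atol=1e-9)

    def test_rates_nonnegative_with_mixed_kernel(self, rng):
        ko = make_orn_kernel("odor", rng, polarity="mixed")
        ka = make_orn_kernel("air", rng)
        c = np.zeros(4000)
        c[500:800] = 3.0
        out = rate_from_stimulus(c, np.zeros(4000), ko, ka)
        assert np.all(out.rate >= 0)


class TestPoisson:
    def test_zero_rate_empty(self, rng):
        trains = poisson_spikes(np.zeros(1000), 3, rng)
        assert all(len(t) == 0 for t in trains)

    def test_dead_time_corrected_rate(self, rng):
        """Constant 35 Hz with 1 ms dead time: renewal-process rate
        35/(1 + 0.001*35) within 2%."""
        trains = poisson_spikes(np.full(200_000, 35.0), 3, rng)
        emp = np.mean([len(t) for t in trains]) / 200.0
        assert emp == pytest.approx(35.0 / (1.0 + 0.001 * 35.0), rel=0.02)

    def test_refractory_isi(self, rng):
        trains = poisson_spikes(np.full(20_000, 80.0), 5, rng)
        for t in trains:
            assert np.diff(t).min() >= 1.0

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            poisson_spikes(np.array([-1.0]), 1, rng)


class TestBackground:
    def test_in_vitro_mean_rate(self, rng):
        trains = background_trains("in_vitro", 20, 50_000.0, rng)
        emp = np.mean([len(t) for t in trains]) / 50.0
        assert emp == pytest.approx(3.45, abs=0.1)

    def test_in_vivo_mean_rate(self, rng):
        trains = background_trains("in_vivo", 20, 50_000.0, rng)
        emp = np.mean([len(t) for t in trains]) / 50.0
        assert emp == pytest.approx(35.0, abs=1.0)

    def test_trains_uncorrelated(self, rng):
        a, b = background_trains("in_vivo", 2, 100_000.0, rng)
        bins = np.arange(0, 100_000.0, 10.0)
        ca, _ = np.histogram(a, bins)
        cb, _ = np.histogram(b, bins)
        # both are respiration-modulated; correlate the residuals around the
        # common cycle-average to test independence of the point processes
        n = (len(ca) // 50) * 50
        ca, cb = ca[:n].astype(float), cb[:n].astype(float)
        mean_cycle = ca.reshape(-1, 50).mean(0)
        ca -= np.tile(mean_cycle, n // 50)
        cb -= np.tile(cb.reshape(-1, 50).mean(0), n // 50)
        r = np.corrcoef(ca, cb)[0, 1]
        assert abs(r) < 0.05

    def test_unknown_context(self, rng):
        with pytest.raises(ValueError):
            background_trains("awake", 1, 1000.0, rng)
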