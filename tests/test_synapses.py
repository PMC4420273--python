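"""Synaptic conductance shapes, delays, weights and aggregation rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bulbnet.synapses import (
    AUTO_INHIBITORY_G,
    AggregatedInhibition,
    AutoInhibitorySynapse,
    DualExpSynapse,
    E_EXC,
    E_INH,
    NMDAComponent,
    SYNAPSE_TABLE,
    WeightSampler,
    assign_delays,
    conductance_series,
    distance_decay,
    dual_exp_g,
    dual_exp_peak_time,
    make_synapse,
    mg_block,
    nmda_g,
)


class TestDualExp:
    def test_zero_at_event_time(self):
        syn = DualExpSynapse(1.0, 1.0, 20.0, E_INH)
        assert dual_exp_g(syn, 0.0) == pytest.approx(0.0)

    def test_peak_equals_gmax(self):
        for t1, t2, g in ((1.0, 20.0, 1.0), (1.0, 4.0, 0.2), (25.0, 200.0, 0.052)):
            syn = DualExpSynapse(g, t1, t2, E_EXC)
            tp = dual_exp_peak_time(t1, t2)
            assert dual_exp_g(syn, tp) == pytest.approx(g, rel=1e-12)

    def test_negative_time_is_zero(self):
        syn = DualExpSynapse(1.0, 1.0, 20.0, E_INH)
        assert dual_exp_g(syn, -5.0) == 0.0

    def test_alpha_limit(self):
        """tau1 -> tau2 approaches the alpha function within 1e-6."""
        tau = 1.0
        near = DualExpSynapse(1.0, tau * (1 + 1e-7), tau, E_EXC)
        t = np.linspace(0.0, 10.0, 500)
        alpha = (t / tau) * np.exp(1.0 - t / tau)
        assert np.max(np.abs(dual_exp_g(near, t) - alpha)) < 1e-6

    @given(st.floats(0.1, 50.0), st.floats(0.1, 50.0))
    @settings(max_examples=40, deadline=None)
    def test_nonnegative_conductance(self, t1, t2):
        syn = DualExpSynapse(1.0, t1, t2, E_EXC)
        t = np.linspace(0, 10 * max(t1, t2), 200)
        assert np.all(dual_exp_g(syn, t) >= -1e-12)

    def test_superposition_of_simultaneous_events(self):
        syn = DualExpSynapse(0.5, 1.0, 20.0, E_INH)
        tg = np.linspace(0, 100, 400)
        single = conductance_series(syn, [10.0], tg)
        five = conductance_series(syn, [10.0] * 5, tg)
        assert np.allclose(five, 5 * single)


class TestNMDA:
    def test_mg_block_depolarized_limit(self):
        assert mg_block(60.0) > 0.9

    def test_mg_block_monotone(self):
        v = np.linspace(-90, 60, 300)
        assert np.all(np.diff(mg_block(v)) > 0)

    def test_zero_at_event_regardless_of_voltage(self):
        syn = NMDAComponent(0.052, 25.0, 200.0, E_EXC)
        for v in (-70.0, 0.0, 60.0):
            assert nmda_g(syn, 0.0, v) == pytest.approx(0.0)

    def test_conductance_time_integral_quadrature(self):
        """At fixed V the integral equals the dual-exp integral times the
        block factor (numeric quadrature oracle)."""
        from scipy.integrate import quad
        syn = NMDAComponent(0.052, 25.0, 200.0, E_EXC)
        V = 0.0
        val, _ = quad(lambda t: nmda_g(syn, t, V), 0, 5000, limit=400)
        envelope, _ = quad(lambda t: dual_exp_g(syn, t), 0, 5000, limit=400)
        assert val == pytest.approx(envelope * mg_block(V), rel=1e-6)

    def test_ratio_to_ampa(self):
        assert SYNAPSE_TABLE["mitral_granule_nmda"][0] == pytest.approx(
            0.26 * SYNAPSE_TABLE["mitral_granule_ampa"][0])


class TestWeights:
    def test_relative_sd(self, rng):
        w = WeightSampler(2.0).sample(rng, size=100_000)
        assert w.std() / w.mean() == pytest.approx(0.25, rel=0.02)
        assert w.mean() == pytest.approx(2.0, rel=0.02)

    def test_all_positive(self, rng):
        w = WeightSampler(0.2).sample(rng, size=10_000)
        assert np.all(w > 0)


class TestDistanceDecay:
    def test_origin(self):
        assert distance_decay(0.0, "primary", 1.0) == 1.0

    def test_length_constants(self):
        assert distance_decay(100.0, "primary") == pytest.approx(math.exp(-1))
        assert distance_decay(150.0, "secondary") == pytest.approx(math.exp(-1))

    def test_diameter_ratio_multiplies(self):
        assert distance_decay(150.0, "secondary", 0.5) == pytest.approx(
            0.5 * math.exp(-1))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            distance_decay(-1.0)


class TestDelays:
    def test_fixed_kinds(self):
        assert assign_delays("orn") == 0.0
        assert assign_delays("excitatory") == 1.8
        assert assign_delays("inhibitory") == 0.6

    def test_mitral_to_pg_uniform(self, rng):
        d = assign_delays("mitral_to_pg", rng, size=10_000)
        assert d.mean() == pytest.approx(20.0, abs=0.5)
        assert d.min() >= 0.0 and d.max() <= 40.0

    def test_pg_to_mitral_exponential_mean(self, rng):
        d = assign_delays("pg_to_mitral", rng, size=100_000)
        assert d.mean() == pytest.approx(160.0, rel=0.02)

    def test_aggregated_delay_sd(self, rng):
        d = assign_delays("aggregated", rng, size=100_000)
        assert d.std() == pytest.approx(160.0, abs=5.0)

    def test_unknown_kind(self, rng):
        with pytest.raises(ValueError):
            assign_delays("gap_junction", rng)


class TestConstruction:
    def test_reversal_potentials(self):
        for kind, (_, _, _, erev) in SYNAPSE_TABLE.items():
            if "mitral" in kind and kind.startswith(("granule", "pg")):
                assert erev == -78.0
            elif kind.startswith(("orn", "mitral")):
                assert erev == 0.0

    def test_auto_inhibitory_defaults(self):
        a = AutoInhibitorySynapse()
        assert a.g_max == pytest.approx(0.005)  # 5 pS
        assert a.reversal == -78.0

    def test_aggregated_integral_factor(self, rng):
        agg = AggregatedInhibition(base_g_max=1.0)
        agg.draw_delays(rng)
        # 10 synapses of 10x strength: integral = 100x a single synapse
        assert agg.count * agg.strength_factor == pytest.approx(100.0)
        assert len(agg.delays) == 10

    def test_negative_gmax_rejected(self):
        with pytest.raises(ValueError):
            DualExpSynapse(-1.0, 1.0, 4.0, 0.0)

    def test_make_synapse_table_values(self):
        syn = make_synapse("orn_mitral")
        assert (syn.g_max, syn.tau1, syn.tau2) == (6.0, 1.0, 1.0)
        inh = make_synapse("granule_mitral")
        assert (inh.g_max, inh.tau1, inh.tau2, inh.reversal) == \
            (1.0, 1.0, 20.0, -78.0)
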