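"""Stochastic connectivity construction, aggregation and reporting."""

import numpy as np
import pytest
from scipy import stats

from bulbnet.network import (
    N_GM_SOMA,
    N_GM_SYNAPSES,
    NetworkInstance,
    WINDOW_REACH,
    aggregate_singles,
    aggregates_per_mitral,
    build_network,
    connectivity_report,
    make_slice,
    mitral_comp_positions,
)


@pytest.fixture(scope="module")
def small_default():
    return build_network("default", 2, seed=3)


class TestConstruction:
    def test_invalid_scheme_and_count(self):
        with pytest.raises(ValueError):
            build_network("smallworld", 2, seed=0)
        with pytest.raises(ValueError):
            build_network("default", 7, seed=0)

    def test_cell_counts_default(self, small_default):
        net = small_default
        assert net.n_mitral == 6  # 3 glomeruli x 2 mitral cells
        assert len(net.pg_variant) == 3000  # 1000 PG per glomerulus

    def test_synapse_counts_per_mitral(self, small_default):
        gm = small_default.gm
        for m in range(6):
            n = int(np.sum(gm.mitral == m))
            extra = sum(1 for (b, a) in small_default.super_edges if b == m)
            assert n == N_GM_SYNAPSES + extra * 100
            on_soma = int(np.sum((gm.mitral == m) & (gm.comp == 0)))
            assert on_soma == N_GM_SOMA

    def test_pg_synapse_completion(self, small_default):
        """Every PG cell completes 25 mitral->PG synapses."""
        counts = np.bincount(small_default.m2pg["pg"],
                             minlength=len(small_default.pg_variant))
        assert counts.min() >= 25

    def test_granule_within_window_of_synapse(self, small_default):
        """The granule soma lies within the dendritic-extent window of its
        synapse site (geometric audit)."""
        gm = small_default.gm
        base = len(gm.mitral) - 100 * len(small_default.super_edges)
        gx = small_default.granule_pos[gm.granule[:base], 0]
        gy = small_default.granule_pos[gm.granule[:base], 1]
        assert np.max(np.abs(gx - gm.x[:base])) <= WINDOW_REACH + 1e-9
        assert np.max(np.abs(gy - gm.y[:base])) <= WINDOW_REACH + 1e-9

    def test_determinism_same_seed(self):
        a = build_network("default", 1, seed=11)
        b = build_network("default", 1, seed=11)
        assert np.array_equal(a.gm.granule, b.gm.granule)
        assert np.array_equal(a.gm.w_inh, b.gm.w_inh)
        assert np.array_equal(a.mitral_soma, b.mitral_soma)
        c = build_network("default", 1, seed=12)
        assert not np.array_equal(a.gm.granule, c.gm.granule)

    def test_random_scheme_has_no_super_edges(self):
        net = build_network("random", 2, seed=0)
        assert net.super_edges == []

    def test_default_scheme_super_edges_alternate_sisters(self, small_default):
        targets = [a for (_, a) in small_default.super_edges]
        assert sorted(targets) == [0, 1]

    def test_placement_uniform_along_dendrite(self, small_default):
        """Synapse placement is uniform per unit dendritic length: counts
        over the equal-length lateral branch segments are consistent with a
        uniform multinomial (chi-square test)."""
        gm = small_default.gm
        sel = (gm.mitral == 0) & (gm.dend == 2) & (gm.path > 100.0)
        comps = gm.comp[sel]
        uniq, counts = np.unique(comps, return_counts=True)
        stat = stats.chisquare(counts)
        assert stat.pvalue > 0.01

    def test_super_inhibition_strengthening(self, small_default):
        """Granule-|mitral weights of shared granules onto the target are
        boosted ~4x relative to non-shared synapses at similar distance."""
        net = small_default
        (b, a) = net.super_edges[0]
        gm = net.gm
        # the 100 added synapses sit at the end of the table
        added = slice(len(gm.mitral) - 100 * len(net.super_edges),
                      len(gm.mitral) - 100 * (len(net.super_edges) - 1))
        shared_g = gm.granule[added]
        on_a = np.isin(gm.granule, shared_g) & (gm.mitral == a) & \
            (gm.path <= 100.0)
        plain = (~np.isin(gm.granule, shared_g)) & (gm.mitral == a) & \
            (gm.path <= 100.0) & (gm.dend == gm.dend)
        if on_a.sum() >= 3 and plain.sum() >= 10:
            ratio = np.median(gm.w_inh[on_a] / 1.0) / \
                np.median(gm.w_inh[plain])
            assert ratio > 2.0


class TestAggregation:
    def test_counts_recorded_per_mitral(self, small_default):
        agg = aggregate_singles(small_default)
        counts = aggregates_per_mitral(agg)
        assert len(counts) == 6
        assert np.all(counts > 0)

    def test_identity_ratio_bookkeeping_only(self):
        net = build_network("default", 0, seed=5)
        agg = aggregate_singles(net, ratio=1)
        assert agg.aggregates is not None
        assert np.all(agg.aggregates.n_members == 1)

    def test_inhibitory_integral_conserved(self):
        """Total granule-|mitral conductance integral onto each mitral cell
        is conserved by aggregation within 1%."""
        net = build_network("default", 1, seed=6)
        deg = net.granule_degree()
        agg = aggregate_singles(net)
        for m in range(net.n_mitral):
            before = net.gm.w_inh[net.gm.mitral == m].sum()
            shared_after = agg.gm.w_inh[
                (agg.gm.mitral == m)
                & (deg[agg.gm.granule] >= 2)].sum()
            agg_w = agg.aggregates.syn_w[agg.aggregates.mitral == m].sum()
            assert shared_after + agg_w == pytest.approx(before, rel=0.01)

    def test_invalid_ratio(self, small_default):
        with pytest.raises(ValueError):
            aggregate_singles(small_default, ratio=0)


class TestSlice:
    def test_separation_and_pruning(self):
        sl = make_slice(None, separation=50.0, seed=2)
        d = np.hypot(*(sl.mitral_soma[0] - sl.mitral_soma[2]))
        assert d == pytest.approx(50.0, abs=1e-6)
        parent = build_network("default", 1, seed=2)
        assert sl.n_granule < parent.n_granule

    def test_granules_within_slab(self):
        sl = make_slice(None, separation=50.0, seed=4)
        a, b = sl.mitral_soma[0], sl.mitral_soma[2]
        d = b - a
        nvec = np.array([-d[1], d[0]]) / np.hypot(*d)
        dist = np.abs((sl.granule_pos - a) @ nvec)
        assert dist.max() <= 100.0 + 1e-9

    def test_invalid_separation(self):
        with pytest.raises(ValueError):
            make_slice(None, separation=-5.0)


class TestConnectivityReport:
    def test_arithmetic_chain(self):
        rep = connectivity_report()
        assert rep["disynaptic_paths"] == 40_000  # 400 contacts x 100 spines
        assert rep["max_super_inhibitors"] == 400  # 40000 / 100 required
        assert rep["reachable_mt"] == 13_125  # 175 glomeruli x 75 M/T
        assert rep["upper_bound_one_in"] == 33
        assert rep["fan_in"] == 20  # 13000 / ~640

    def test_measured_statistics_included(self, small_default):
        rep = connectivity_report(small_default)
        assert rep["n_mitral"] == 6
        assert rep["measured_shared_granules"] > 0
        assert len(rep["measured_proximal_contacts_per_mitral"]) == 6


class TestGeometry:
    def test_comp_positions_rotate(self):
        out0 = mitral_comp_positions((0.0, 0.0), 0.0, (100.0, 0.0))
        out1 = mitral_comp_positions((0.0, 0.0), np.pi, (100.0, 0.0))
        # lateral compartment positions flip under a half-turn
        lat0 = out0[1][-10:], out0[2][-10:]
        lat1 = out1[1][-10:], out1[2][-10:]
        assert np.allclose(lat0[0], -lat1[0], atol=1e-9)
        assert np.allclose(lat0[1], -lat1[1], atol=1e-9)
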