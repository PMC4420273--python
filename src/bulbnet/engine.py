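"""Event-driven network simulation on top of the cable integrator.

Couples the mitral / granule / PG cell populations of a NetworkInstance
through conductance synapses.  Presynaptic release is triggered by the
somatic spike detector of the source cell (all synapses are spike-based);
events are queued into a delay ring buffer and added to per-compartment
dual-exponential conductance states.

ORN drive: per-synapse Poisson trains (1 ms dead time) are pre-generated
for the 400 ORN->mitral synapses per mitral cell and for the per-granule
background train; the 50 ORN->PG trains per PG cell are sampled as grouped
Poisson counts per time step (the per-train dead-time correction at these
rates is <~1% and is absorbed by the input-strength calibration).

Only PG cells that actually inhibit a modeled mitral cell are simulated
(the others have no efferent synapse in the network).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .biophysics import CableGroup
from .cells import build_granule, build_mitral, build_pg
from .network import NetworkInstance
from .stimuli import DT_MS, RateSeries, poisson_spikes
from .synapses import (
    AUTO_INHIBITORY_G,
    DELAY_EXC,
    DELAY_INH,
    SYNAPSE_TABLE,
    dual_exp_norm,
    mg_block,
    sample_lognormal_weights,
)

NS = 1e-3  # nS -> uS
BG_G_MAX = 0.2  # nS; granule background synapse (the mitral->granule AMPA weight)


class SynClass:
    """Per-target-population dual-exponential conductance accumulator."""

    def __init__(self, n_flat: int, tau1: float, tau2: float, erev: float,
                 dt: float, nmda: bool = False):
        self.tau1, self.tau2, self.erev, self.nmda = tau1, tau2, erev, nmda
        self.alpha = abs(tau1 - tau2) < 1e-9
        self.y1 = np.zeros(n_flat)
        self.y2 = np.zeros(n_flat)
        self.d1 = math.exp(-dt / tau1)
        self.d2 = math.exp(-dt / tau2)
        self.dt = dt
        if self.alpha:
            self.scale = math.e
        else:
            self.scale = dual_exp_norm(tau1, tau2) / (tau1 - tau2)

    def decay(self):
        if self.alpha:
            self.y2 = (self.y2 + self.y1 * (self.dt / self.tau1)) * self.d1
            self.y1 *= self.d1
        else:
            self.y1 *= self.d1
            self.y2 *= self.d2

    def add_events(self, idx: np.ndarray, w: np.ndarray):
        """w in uS (event weights)."""
        np.add.at(self.y1, idx, w)
        if not self.alpha:
            np.add.at(self.y2, idx, w)

    def conductance(self, v_flat: Optional[np.ndarray] = None) -> np.ndarray:
        if self.alpha:
            g = self.scale * self.y2
        else:
            g = self.scale * (self.y1 - self.y2)
        if self.nmda:
            g = g * mg_block(v_flat)
        return g


@dataclass
class Stimulus:
    """Per-glomerulus ORN rate series plus the granule background context."""

    glom_rates: list  # one RateSeries (or array, 1 ms grid) per glomerulus
    background: str = "in_vivo"  # granule background context
    mitral_rate_override: Optional[dict] = None  # mitral idx -> constant Hz


class NetworkSimulation:
    """One network instance wired for simulation."""

    def __init__(self, net: NetworkInstance, dt: float = 0.05,
                 orn_scale: float = 1.0, rng: Optional[np.random.Generator] = None,
                 record_voltages: Optional[dict] = None,
                 knockout: tuple = ()):
        """``orn_scale`` multiplies all ORN->mitral weights (the documented
        input-strength calibration).  ``knockout`` may contain "pg" and/or
        "granule" to remove those populations' inhibition."""
        self.net = net
        self.dt = dt
        self.rng = rng or np.random.default_rng(net.seed + 1)
        self.knockout = knockout

        # --- populations ------------------------------------------------
        self.mitral_proto = build_mitral()
        nm = net.n_mitral
        self.mitral = CableGroup(self.mitral_proto, ncell=nm)
        self.n_mc = self.mitral_proto.n_comp

        # granules: only those appearing in the (possibly aggregated) tables
        gm = net.gm
        used = set(np.unique(gm.granule).tolist())
        if net.aggregates is not None:
            used |= set(net.aggregates.representative.tolist())
        self.g_ids = np.array(sorted(used), dtype=int)
        self.g_index = {int(g): i for i, g in enumerate(self.g_ids)}
        ng = len(self.g_ids)
        gran_proto = build_granule()
        g_off = net.granule_leak_offset[self.g_ids] \
            if len(net.granule_leak_offset) else None
        self.granule = CableGroup(gran_proto, ncell=max(ng, 1),
                                  leak_reversal_offsets=g_off)
        self.n_gc = gran_proto.n_comp

        # PG cells: only those with an efferent synapse onto a mitral cell
        pg_used = np.unique(net.pg2m["pg"]).astype(int)
        self.pg_ids = pg_used
        self.pg_index = {int(p): i for i, p in enumerate(pg_used)}
        variants = net.pg_variant[pg_used] if len(pg_used) else np.zeros(0, int)
        self.pg_groups = {}
        self.pg_slot = np.zeros(len(pg_used), dtype=int)  # index inside group
        self.pg_variant_of = variants
        for code, name in ((0, "plateauing"), (1, "LTS")):
            sel = np.nonzero(variants == code)[0]
            if len(sel) == 0:
                continue
            off = net.pg_leak_offset[pg_used[sel]] \
                if len(net.pg_leak_offset) else None
            grp = CableGroup(build_pg(name), ncell=len(sel),
                             leak_reversal_offsets=off)
            self.pg_groups[code] = (grp, sel)
            self.pg_slot[sel] = np.arange(len(sel))
        self.n_pc = 3

        # --- synapse classes --------------------------------------------
        dtm = dt
        self.syn_m_exc = SynClass(nm * self.n_mc, 1.0, 1.0, 0.0, dtm)
        self.syn_m_inh = SynClass(nm * self.n_mc, 1.0, 20.0, -78.0, dtm)
        self.syn_g_ampa = SynClass(max(ng, 1) * self.n_gc, 1.0, 4.0, 0.0, dtm)
        self.syn_g_nmda = SynClass(max(ng, 1) * self.n_gc, 25.0, 200.0, 0.0,
                                   dtm, nmda=True)
        npg = len(pg_used)
        self.syn_p_exc = SynClass(max(npg, 1) * self.n_pc, 1.0, 1.0, 0.0, dtm)

        # --- efferent tables (CSR by source cell) ------------------------
        self._build_efferents(orn_scale)

        self.record_voltages = record_voltages or {}
        self._v_traces = {k: [] for k in self.record_voltages}

    # -----------------------------------------------------------------
    def _csr(self, src, tgt_idx, w, delay):
        src = np.asarray(src, dtype=int)
        order = np.argsort(src, kind="stable")
        src, tgt_idx, w, delay = (src[order], np.asarray(tgt_idx)[order],
                                  np.asarray(w)[order],
                                  np.asarray(delay)[order])
        dsteps = np.clip(np.round(delay / self.dt).astype(int), 1,
                         int(1999.0 / self.dt))
        return src, tgt_idx, w, dsteps

    def _build_efferents(self, orn_scale):
        net, rng = self.net, self.rng
        gm = net.gm
        nm = net.n_mitral
        g_of = np.array([self.g_index[int(g)] for g in gm.granule])

        # mitral spike -> granule AMPA+NMDA (dend comp = 1)
        tgt_g = g_of * self.n_gc + 1
        if "granule" not in self.knockout:
            self.m2g = self._csr(gm.mitral, tgt_g, gm.w_ampa * NS,
                                 np.full(len(gm), DELAY_EXC))
            self.m2g_nmda_w = gm.w_nmda[np.argsort(gm.mitral, kind="stable")] * NS
        else:
            z = np.zeros(0)
            self.m2g = (z.astype(int), z.astype(int), z, z.astype(int))
            self.m2g_nmda_w = z
        # background input synapse: one per simulated granule (AMPA+NMDA)
        self.bg_w_ampa = sample_lognormal_weights(
            np.full(len(self.g_ids), BG_G_MAX), rng) * NS
        self.bg_w_nmda = self.bg_w_ampa * 0.26

        # granule spike -> mitral inhibition
        tgt_m = gm.mitral * self.n_mc + gm.comp
        g2m_w = gm.w_inh * NS
        if "granule" in self.knockout:
            g2m_w = g2m_w * 0.0
        self.g2m = self._csr(g_of, tgt_m, g2m_w,
                             np.full(len(gm), DELAY_INH))
        # aggregated-singles inhibition
        if net.aggregates is not None and len(net.aggregates.representative):
            ag = net.aggregates
            n_syn = ag.syn_comp.shape[1]
            src = np.repeat(np.array([self.g_index[int(g)]
                                      for g in ag.representative]), n_syn)
            tgt = (np.repeat(ag.mitral, n_syn) * self.n_mc
                   + ag.syn_comp.ravel())
            self.agg2m = self._csr(src, tgt, ag.syn_w.ravel() * NS,
                                   ag.syn_delay.ravel())
            self.agg_members = {self.g_index[int(g)]: n for g, n in
                                zip(ag.representative, ag.n_members)}
        else:
            z = np.zeros(0)
            self.agg2m = (z.astype(int), z.astype(int), z, z.astype(int))
            self.agg_members = {}

        # mitral spike -> own auto-inhibitory synapses: 5 pS at every
        # reciprocal site (aggregated sites carry their members' share)
        auto_src = [gm.mitral]
        auto_tgt = [tgt_m]
        auto_w = [np.full(len(gm), AUTO_INHIBITORY_G) * NS]
        auto_d = [np.full(len(gm), DELAY_INH)]
        if net.aggregates is not None and len(net.aggregates.representative):
            ag = net.aggregates
            n_syn = ag.syn_comp.shape[1]
            auto_src.append(np.repeat(ag.mitral, n_syn))
            auto_tgt.append(np.repeat(ag.mitral, n_syn) * self.n_mc
                            + ag.syn_comp.ravel())
            auto_w.append(np.repeat(ag.n_members / n_syn, n_syn)
                          * AUTO_INHIBITORY_G * NS)
            auto_d.append(np.full(len(ag.mitral) * n_syn, DELAY_INH))
        self.m2auto = self._csr(np.concatenate(auto_src),
                                np.concatenate(auto_tgt),
                                np.concatenate(auto_w),
                                np.concatenate(auto_d))

        # mitral spike -> PG (excitatory, uniform 0-40 ms delays)
        sel = np.isin(net.m2pg["pg"], self.pg_ids)
        m2pg_m = net.m2pg["mitral"][sel]
        m2pg_p = np.array([self.pg_index[int(p)] for p in net.m2pg["pg"][sel]])
        pg_var = self.pg_variant_of[m2pg_p]
        w = np.where(pg_var == 0, SYNAPSE_TABLE["mitral_pg_plateauing"][0],
                     SYNAPSE_TABLE["mitral_pg_LTS"][0])
        w = sample_lognormal_weights(w, rng) * NS
        dend = rng.integers(1, 3, size=len(m2pg_p))
        if "pg" in self.knockout:
            z = np.zeros(0)
            self.m2pg = (z.astype(int), z.astype(int), z, z.astype(int))
        else:
            self.m2pg = self._csr(m2pg_m, m2pg_p * self.n_pc + dend, w,
                                  net.m2pg["delay"][sel])

        # PG spike -> mitral tuft inhibition (exponential mean 160 ms delays)
        p2m_p = np.array([self.pg_index[int(p)] for p in net.pg2m["pg"]],
                         dtype=int)
        tuft = self.mitral_proto.meta["tuft_comps"]
        tuft_pick = rng.choice(tuft, size=len(p2m_p))
        if "pg" in self.knockout or len(p2m_p) == 0:
            z = np.zeros(0)
            self.pg2m = (z.astype(int), z.astype(int), z, z.astype(int))
        else:
            self.pg2m = self._csr(p2m_p,
                                  net.pg2m["mitral"] * self.n_mc + tuft_pick,
                                  net.pg2m["w"] * NS, net.pg2m["delay"])

        # ORN -> mitral: per-synapse weights on random tuft compartments
        self.orn_m_comp = rng.choice(tuft, size=(nm, 400))
        self.orn_m_w = sample_lognormal_weights(
            np.full((nm, 400), SYNAPSE_TABLE["orn_mitral"][0]), rng) \
            * NS * orn_scale

        # ORN -> PG grouped rates: weight per PG by variant
        self.orn_pg_w = np.where(
            self.pg_variant_of == 0, SYNAPSE_TABLE["orn_pg_plateauing"][0],
            SYNAPSE_TABLE["orn_pg_LTS"][0]) * NS

        self._csr_index()

    def _csr_index(self):
        """Build index pointers for each efferent table."""
        def ptr(src, n):
            return np.searchsorted(src, np.arange(n + 1))
        nm = self.net.n_mitral
        ng = len(self.g_ids)
        npg = len(self.pg_ids)
        self.m2g_ptr = ptr(self.m2g[0], nm)
        self.g2m_ptr = ptr(self.g2m[0], ng)
        self.agg2m_ptr = ptr(self.agg2m[0], ng)
        self.m2auto_ptr = ptr(self.m2auto[0], nm)
        self.m2pg_ptr = ptr(self.m2pg[0], nm)
        self.pg2m_ptr = ptr(self.pg2m[0], npg)

    # -----------------------------------------------------------------
    def _prepare_inputs(self, stim: Stimulus, duration: float,
                        rng: np.random.Generator):
        """Pre-generate ORN->mitral and granule-background event streams."""
        net = self.net
        nsteps = int(round(duration / self.dt))
        # ORN->mitral: per-synapse Poisson trains with 1 ms dead time
        orn_step, orn_idx, orn_w = [], [], []
        for m in range(net.n_mitral):
            rate = self._rate_for(stim, m, duration)
            trains = poisson_spikes(rate, 400, rng)
            for s, tr in enumerate(trains):
                if len(tr) == 0:
                    continue
                idx = m * self.n_mc + self.orn_m_comp[m, s]
                w = self.orn_m_w[m, s]
                ks = np.minimum((tr / self.dt).astype(int), nsteps)
                orn_step.append(ks)
                orn_idx.append(np.full(len(ks), idx))
                orn_w.append(np.full(len(ks), w))
        self._orn_events = _bucket2(nsteps, orn_step, orn_idx, orn_w)
        # granule background: one train per simulated granule
        from .stimuli import background_trains
        trains = background_trains(stim.background, len(self.g_ids), duration,
                                   rng)
        st, ix, wa, wn = [], [], [], []
        for gi, tr in enumerate(trains):
            if len(tr) == 0:
                continue
            ks = np.minimum((tr / self.dt).astype(int), nsteps)
            st.append(ks)
            ix.append(np.full(len(ks), gi * self.n_gc + 1))
            wa.append(np.full(len(ks), self.bg_w_ampa[gi]))
            wn.append(np.full(len(ks), self.bg_w_nmda[gi]))
        self._bg_events = _bucket3(nsteps, st, ix, wa, wn)
        # ORN->PG grouped rates per dendrite compartment (25 synapses each)
        self._pg_lam = None
        if len(self.pg_ids) and "pg" not in self.knockout:
            nb = int(duration / DT_MS) + 1
            lam = np.zeros((nb, len(self.pg_ids)))
            for g in range(len(net.glom_pos)):
                sel = np.nonzero(net.pg_glom[self.pg_ids] == g)[0]
                if len(sel) == 0:
                    continue
                r = self._glom_rate(stim, g, duration)
                lam[:, sel] = r[:nb, None]
            self._pg_lam = lam  # Hz per single ORN synapse

    def _glom_rate(self, stim: Stimulus, g: int, duration: float) -> np.ndarray:
        r = stim.glom_rates[g]
        r = r.rate if isinstance(r, RateSeries) else np.asarray(r, float)
        nb = int(duration / DT_MS) + 1
        if len(r) < nb:
            r = np.concatenate([r, np.full(nb - len(r), r[-1] if len(r) else 0.0)])
        return r

    def _rate_for(self, stim: Stimulus, m: int, duration: float) -> np.ndarray:
        if stim.mitral_rate_override and m in stim.mitral_rate_override:
            nb = int(duration / DT_MS) + 1
            return np.full(nb, stim.mitral_rate_override[m])
        return self._glom_rate(stim, int(self.net.mitral_glom[m]), duration)

    # -----------------------------------------------------------------
    def run(self, stim: Stimulus, duration: float,
            i_inj: Optional[dict] = None,
            input_seed: Optional[int] = None,
            record_every: int = 20,
            preset_events: Optional[list] = None) -> dict:
        """Simulate and return spikes (and optional voltage traces).

        ``i_inj``: {("mitral", cell): (amp nA, t0, t1)} somatic current steps.
        Returns {"mitral_spikes": [...], "granule_spikes": [...],
        "pg_spikes": [...], "t": ..., "v": {...}}.
        """
        dt = self.dt
        rng = np.random.default_rng(input_seed if input_seed is not None
                                    else self.net.seed + 101)
        # every run starts from the same initial condition, so a run is
        # fully determined by (network, input_seed)
        for grp in [self.mitral, self.granule] + \
                [g for g, _ in self.pg_groups.values()]:
            grp.reset()
        for cls in (self.syn_m_exc, self.syn_m_inh, self.syn_g_ampa,
                    self.syn_g_nmda, self.syn_p_exc):
            cls.y1[:] = 0.0
            cls.y2[:] = 0.0
        self._prepare_inputs(stim, duration, rng)
        nsteps = int(round(duration / dt))
        # preset events: (time ms, class name, flat idx array, weight uS array)
        classes = {"mitral_exc": self.syn_m_exc, "mitral_inh": self.syn_m_inh,
                   "granule_ampa": self.syn_g_ampa,
                   "granule_nmda": self.syn_g_nmda, "pg_exc": self.syn_p_exc}
        preset: dict[int, list] = {}
        for (t_ev, cname, idx, w) in (preset_events or []):
            k = min(int(t_ev / dt), nsteps)
            preset.setdefault(k, []).append((classes[cname], np.asarray(idx),
                                             np.asarray(w)))

        ring_len = int(2000.0 / dt)  # events beyond 2 s delay are dropped
        ring: list[list] = [[] for _ in range(ring_len)]

        nm = self.net.n_mitral
        ng = len(self.g_ids)
        m_spk: list[list[float]] = [[] for _ in range(nm)]
        g_spk: list[list[float]] = [[] for _ in range(ng)]
        p_spk: list[list[float]] = [[] for _ in range(len(self.pg_ids))]
        last_m = np.full(nm, -1e9)
        last_g = np.full(ng, -1e9)
        last_p = np.full(len(self.pg_ids), -1e9)
        vm_prev = self.mitral.v[:, 0].copy()
        vg_prev = self.granule.v[:, 0].copy()
        vp_prev = {c: grp.v[:, 0].copy() for c, (grp, _) in self.pg_groups.items()}

        inj_m = np.zeros((nm, self.n_mc))
        i_inj = i_inj or {}

        for grp in [self.mitral, self.granule] + \
                [g for g, _ in self.pg_groups.values()]:
            grp.build_tables(dt)

        traces = {k: [] for k in self.record_voltages}
        t_rec = []

        for step in range(1, nsteps + 1):
            t = step * dt
            # -- deliver due events
            slot = step % ring_len
            for (cls, idx, w) in ring[slot]:
                cls.add_events(idx, w)
            ring[slot] = []
            for (cls, idx, w) in preset.get(step, ()):
                cls.add_events(idx, w)
            # external inputs
            ev = self._orn_events[min(step, nsteps)]
            if ev is not None:
                self.syn_m_exc.add_events(ev[0], ev[1])
            ev = self._bg_events[min(step, nsteps)]
            if ev is not None:
                self.syn_g_ampa.add_events(ev[0], ev[1])
                self.syn_g_nmda.add_events(ev[0], ev[2])
            if self._pg_lam is not None:
                ms_bin = min(int(t / DT_MS), self._pg_lam.shape[0] - 1)
                lam = self._pg_lam[ms_bin] * 25.0 * (dt / 1000.0)
                counts = rng.poisson(lam)
                hit = np.nonzero(counts)[0]
                if len(hit):
                    dend = rng.integers(1, 3, size=len(hit))
                    idx = hit * self.n_pc + dend
                    self.syn_p_exc.add_events(
                        idx, counts[hit] * self.orn_pg_w[hit])

            # -- decay synaptic states
            for cls in (self.syn_m_exc, self.syn_m_inh, self.syn_g_ampa,
                        self.syn_g_nmda, self.syn_p_exc):
                cls.decay()

            # -- step populations
            g_exc = self.syn_m_exc.conductance()
            g_inh = self.syn_m_inh.conductance()
            G = g_exc + g_inh
            GE = g_inh * (-78.0)  # excitatory reversal is 0 mV
            inj_m[:] = 0.0
            for (pop, cell), (amp, t0, t1) in i_inj.items():
                if pop == "mitral" and t0 <= t < t1:
                    inj_m[cell, 0] += amp
            vm = self.mitral.step(dt, i_inj=inj_m, g_syn=G, ge_syn=GE)

            vflat_g = self.granule.v.ravel()
            ga = self.syn_g_ampa.conductance()
            gn = self.syn_g_nmda.conductance(vflat_g)
            G = ga + gn
            vg = self.granule.step(dt, g_syn=G, ge_syn=G * 0.0)

            for code, (grp, sel) in self.pg_groups.items():
                gsel = np.zeros(grp.ncell * self.n_pc)
                flat = self.syn_p_exc.conductance()
                # map: pg sim index -> group slot
                gsel = flat.reshape(len(self.pg_ids), self.n_pc)[sel].ravel()
                vp = grp.step(dt, g_syn=gsel, ge_syn=gsel * 0.0)

            # -- spike detection + event scheduling
            vs = vm[:, 0]
            fired = np.nonzero((vs >= 0) & (vm_prev < 0) & (t - last_m > 1.0))[0]
            vm_prev[:] = vs
            for m in fired:
                m_spk[m].append(t)
                last_m[m] = t
                self._emit(ring, ring_len, step, self.m2g, self.m2g_ptr, m,
                           self.syn_g_ampa)
                a, b = self.m2g_ptr[m], self.m2g_ptr[m + 1]
                if b > a:
                    dst = (step + self.m2g[3][a:b]) % ring_len
                    for k in np.unique(dst):
                        s = dst == k
                        ring[k].append((self.syn_g_nmda, self.m2g[1][a:b][s],
                                        self.m2g_nmda_w[a:b][s]))
                self._emit(ring, ring_len, step, self.m2auto, self.m2auto_ptr,
                           m, self.syn_m_inh)
                self._emit(ring, ring_len, step, self.m2pg, self.m2pg_ptr, m,
                           self.syn_p_exc)

            vs = vg[:, 0] if ng else np.zeros(0)
            firedg = np.nonzero((vs >= 0) & (vg_prev < 0) &
                                (t - last_g > 1.0))[0] if ng else []
            if ng:
                vg_prev[:] = vs
            for g in firedg:
                g_spk[g].append(t)
                last_g[g] = t
                self._emit(ring, ring_len, step, self.g2m, self.g2m_ptr, g,
                           self.syn_m_inh)
                self._emit(ring, ring_len, step, self.agg2m, self.agg2m_ptr,
                           g, self.syn_m_inh)

            for code, (grp, sel) in self.pg_groups.items():
                vs = grp.v[:, 0]
                fired = np.nonzero((vs >= 0) & (vp_prev[code] < 0) &
                                   (t - last_p[sel] > 1.0))[0]
                vp_prev[code][:] = vs
                for j in fired:
                    p = sel[j]
                    p_spk[p].append(t)
                    last_p[p] = t
                    self._emit(ring, ring_len, step, self.pg2m, self.pg2m_ptr,
                               p, self.syn_m_inh)

            if self.record_voltages and step % record_every == 0:
                t_rec.append(t)
                for key, (pop, cell, comp) in self.record_voltages.items():
                    if pop == "mitral":
                        traces[key].append(self.mitral.v[cell, comp])
                    elif pop == "granule":
                        traces[key].append(self.granule.v[cell, comp])

        return {
            "t": np.array(t_rec),
            "v": {k: np.array(v) for k, v in traces.items()},
            "mitral_spikes": [np.array(s) for s in m_spk],
            "granule_spikes": [np.array(s) for s in g_spk],
            "pg_spikes": [np.array(s) for s in p_spk],
        }

    @staticmethod
    def _emit(ring, ring_len, step, table, ptr, src, cls):
        a, b = ptr[src], ptr[src + 1]
        if b <= a:
            return
        dst = (step + table[3][a:b]) % ring_len
        idx, w = table[1][a:b], table[2][a:b]
        for k in np.unique(dst):
            s = dst == k
            ring[k].append((cls, idx[s], w[s]))


def _bucket2(nsteps, steps, idx, w):
    out = [None] * (nsteps + 1)
    if not steps:
        return out
    steps = np.concatenate(steps)
    idx = np.concatenate(idx)
    w = np.concatenate(w)
    order = np.argsort(steps, kind="stable")
    steps, idx, w = steps[order], idx[order], w[order]
    bounds = np.searchsorted(steps, np.arange(nsteps + 2))
    for k in range(nsteps + 1):
        a, b = bounds[k], bounds[k + 1]
        if b > a:
            out[k] = (idx[a:b], w[a:b])
    return out


def _bucket3(nsteps, steps, idx, w1, w2):
    out = [None] * (nsteps + 1)
    if not steps:
        return out
    steps = np.concatenate(steps)
    idx = np.concatenate(idx)
    w1 = np.concatenate(w1)
    w2 = np.concatenate(w2)
    order = np.argsort(steps, kind="stable")
    steps, idx, w1, w2 = steps[order], idx[order], w1[order], w2[order]
    bounds = np.searchsorted(steps, np.arange(nsteps + 2))
    for k in range(nsteps + 1):
        a, b = bounds[k], bounds[k + 1]
        if b > a:
            out[k] = (idx[a:b], w1[a:b], w2[a:b])
    return out


def mean_rate(spikes: list, t0: float, t1: float) -> float:
    """Mean firing rate (Hz) over [t0, t1) averaged across cells."""
    if not spikes:
        return 0.0
    n = sum(int(np.sum((s >= t0) & (s < t1))) for s in spikes)
    return n / len(spikes) / ((t1 - t0) / 1000.0)
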