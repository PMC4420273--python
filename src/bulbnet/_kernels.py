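"""Numba-compiled inner loops for the cable integrator.

These kernels are deliberately dumb: all model structure is prepared as flat
arrays by :mod:`bulbnet.biophysics`. Gate kinetics are evaluated through
uniformly-spaced voltage lookup tables; the per-step decay factor
``exp(-dt/tau(V))`` is pre-tabulated so the hot loop is table-lerp plus a
fused multiply-add per gate.
"""

from __future__ import annotations

import numba
import numpy as np

F64 = numba.float64


@numba.njit(cache=True, fastmath=True)
def channel_step(vflat, G, GE, i_ca,
                 ch_start, ch_end, ch_ngates, ch_gate_tab, ch_exp,
                 ch_erev, ch_kd, ch_feeds,
                 ent_comp, ent_gbar, ent_ca, states, ca,
                 inf_tabs, dec_tabs, vmin, inv_dv):
    """Fused gate update + conductance accumulation for one population.

    Channels are concatenated entry lists (one entry per bound compartment);
    gate steady states and per-dt decay factors come from shared lookup
    tables.  Updates ``states`` in place and accumulates G (uS), GE (uS*mV)
    and calcium-carrying current (nA) at the pool indices.
    """
    nch = ch_start.shape[0]
    last = inf_tabs.shape[1] - 2
    for c in range(nch):
        ng = ch_ngates[c]
        erev = ch_erev[c]
        kd = ch_kd[c]
        feeds = ch_feeds[c]
        for e in range(ch_start[c], ch_end[c]):
            k = ent_comp[e]
            v = vflat[k]
            x = (v - vmin) * inv_dv
            if x < 0.0:
                x = 0.0
            elif x > last:
                x = float(last)
            j = int(x)
            f = x - j
            g = ent_gbar[e]
            for gi in range(ng):
                ti = ch_gate_tab[c, gi]
                inf = inf_tabs[ti, j] + f * (inf_tabs[ti, j + 1] - inf_tabs[ti, j])
                dec = dec_tabs[ti, j] + f * (dec_tabs[ti, j + 1] - dec_tabs[ti, j])
                s = inf + (states[e, gi] - inf) * dec
                states[e, gi] = s
                for _ in range(ch_exp[c, gi]):
                    g *= s
            if kd > 0.0:
                cav = ca[ent_ca[e]]
                g *= cav / (cav + kd)
            G[k] += g
            GE[k] += g * erev
            if feeds:
                i_ca[ent_ca[e]] += g * (erev - v)


@numba.njit(cache=True, fastmath=True)
def implicit_update(parent, off, ax_diag, cm_dt, gleak, el, v, G, GE, inj,
                    theta):
    """Theta-method voltage update for a batch, solved in Hines order.

    Solves (C/dt + theta M) v_new = (C/dt - (1-theta) M) v_old + b with
    M v = (gleak + G) v + axial coupling and b = gleak el + GE + inj.
    theta = 1 is backward Euler; theta = 0.5 is the trapezoid
    (Crank-Nicolson) rule.  v (N, C) is updated in place."""
    ncell, ncomp = v.shape
    diag = np.empty((ncell, ncomp))
    rhs = np.empty((ncell, ncomp))
    om = 1.0 - theta
    for n in range(ncell):
        base = n * ncomp
        for c in range(ncomp):
            gm = gleak[c] + G[base + c]
            diag[n, c] = cm_dt[c] + theta * (gm + ax_diag[c])
            rhs[n, c] = (cm_dt[c] - om * (gm + ax_diag[c])) * v[n, c] \
                + gleak[c] * el[n, c] + GE[base + c] + inj[n, c]
        # explicit part of the axial coupling
        if om > 0.0:
            for c in range(1, ncomp):
                p = parent[c]
                g = om * off[c]
                rhs[n, c] += g * v[n, p]
                rhs[n, p] += g * v[n, c]
    toff = np.empty(ncomp)
    for c in range(ncomp):
        toff[c] = theta * off[c]
    for c in range(ncomp - 1, 0, -1):
        p = parent[c]
        g = toff[c]
        for n in range(ncell):
            f = g / diag[n, c]
            diag[n, p] -= f * g
            rhs[n, p] += f * rhs[n, c]
    for n in range(ncell):
        rhs[n, 0] /= diag[n, 0]
    for c in range(1, ncomp):
        p = parent[c]
        g = toff[c]
        for n in range(ncell):
            rhs[n, c] = (rhs[n, c] + g * rhs[n, p]) / diag[n, c]
    for n in range(ncell):
        for c in range(ncomp):
            v[n, c] = rhs[n, c]
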