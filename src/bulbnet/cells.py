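"""The three olfactory-bulb cell models and their electrophysiological probes.

* mitral cell: reduced compartmental morphology (soma, Na-rich initial
  segment, primary dendrite + tuft, two lateral dendrite trunks that each
  split into three branched cables of 25 um segments, half-span 1.65 mm),
  membrane time constant ~50 ms.
* granule cell: two compartments (soma + dendrite) with Na, K and KA
  channels, calibrated to a spike threshold ~25 mV above rest so that firing
  requires temporal integration of many EPSPs.
* periglomerular (PG) cell: three compartments, two firing phenotypes
  (plateauing and low-threshold-spiking) built from the same morphology by
  varying Ih, T-type Ca, K, KA and KCa densities; resting potential -65 mV.

Channel densities live in the versioned parameter file
``bulbnet/params/cells.yaml`` (the frozen result of scripted calibration
against the targets above).
"""

from __future__ import annotations

import math
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .biophysics import (
    CableGroup,
    CableModel,
    CalciumPool,
    Compartment,
    integrate,
    simulate_group,
)

NO_SPIKE = "no-spike"

_params_cache: Optional[dict] = None


class ConfigurationError(RuntimeError):
    pass


def load_cell_params(path: Optional[str] = None) -> dict:
    """Load the calibrated cell-parameter file (YAML)."""
    global _params_cache
    if path is None:
        if _params_cache is not None:
            return _params_cache
        try:
            ref = resources.files("bulbnet").joinpath("params/cells.yaml")
            text = ref.read_text()
        except FileNotFoundError as e:  # pragma: no cover
            raise ConfigurationError("calibrated cell parameter file missing") from e
        _params_cache = yaml.safe_load(text)
        return _params_cache
    with open(path) as f:
        return yaml.safe_load(f)


def _chan_list(d: dict) -> list[tuple[str, float]]:
    return [(name, float(dens)) for name, dens in d.items() if dens]


# ---------------------------------------------------------------------------
# granule cell
# ---------------------------------------------------------------------------


def build_granule(seed: Optional[int] = None, params: Optional[dict] = None,
                  leak_offset: float = 0.0) -> CableModel:
    """Two-compartment granule cell (soma + peripheral dendrite)."""
    p = (params or load_cell_params())["granule"]
    el = p["leak_reversal"] + leak_offset
    soma = Compartment(
        "soma", p["soma"]["length"], p["soma"]["diameter"], -1,
        membrane_resistivity=p["membrane_resistivity"],
        axial_resistivity=p["axial_resistivity"], leak_reversal=el,
        channels=_chan_list(p["soma"]["channels"]))
    dend = Compartment(
        "dend", p["dend"]["length"], p["dend"]["diameter"], 0,
        membrane_resistivity=p["membrane_resistivity"],
        axial_resistivity=p["axial_resistivity"], leak_reversal=el,
        channels=_chan_list(p["dend"]["channels"]))
    m = CableModel([soma, dend])
    m.meta["kind"] = "granule"
    m.meta["synapse_comp"] = 1  # dendritic target of mitral -> granule input
    return m


# ---------------------------------------------------------------------------
# PG cell
# ---------------------------------------------------------------------------

PG_VARIANTS = ("plateauing", "LTS")


def build_pg(variant: str = "LTS", seed: Optional[int] = None,
             params: Optional[dict] = None,
             leak_offset: float = 0.0) -> CableModel:
    """Three-compartment PG cell; ``variant`` selects the firing phenotype."""
    if variant not in PG_VARIANTS:
        raise ValueError(f"unknown PG variant {variant!r}; use one of {PG_VARIANTS}")
    p = (params or load_cell_params())["pg"]
    v = p[variant]
    el = v.get("leak_reversal", p["leak_reversal"]) + leak_offset
    rm = v.get("membrane_resistivity", p["membrane_resistivity"])
    pool = CalciumPool(baseline=p["ca_baseline"], concentration=p["ca_baseline"],
                       influx_scale=p["ca_influx_scale"],
                       decay_time=p["ca_decay_time"])

    def comp(label, geom, parent, channels):
        c = Compartment(
            label, geom["length"], geom["diameter"], parent,
            membrane_resistivity=rm,
            axial_resistivity=p["axial_resistivity"], leak_reversal=el,
            channels=_chan_list(channels))
        c.has_calcium = True
        c.calcium = pool
        return c

    m = CableModel([
        comp("soma", p["soma"], -1, v["soma_channels"]),
        comp("dend0", p["dend"], 0, v["dend_channels"]),
        comp("dend1", p["dend"], 0, v["dend_channels"]),
    ])
    m.meta["kind"] = "pg"
    m.meta["variant"] = variant
    m.meta["synapse_comps"] = [1, 2]  # ORN and mitral input on the dendrites
    return m


def pg_variant_split(n: int) -> tuple[int, int]:
    """(n_plateauing, n_LTS): exactly 1/3 plateauing, rounding toward LTS."""
    n_plat = n // 3
    return n_plat, n - n_plat


def sample_leak_offsets(kind: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Leak-reversal spread: granule Normal(SD 2.25 mV) truncated at +-6 SD,
    PG Normal(SD 3 mV) truncated at +-8 SD."""
    sd, trunc = {"granule": (2.25, 6.0), "pg": (3.0, 8.0)}[kind]
    out = rng.normal(0.0, sd, size=n)
    bad = np.abs(out) > trunc * sd
    while np.any(bad):
        out[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(out) > trunc * sd
    return out


# ---------------------------------------------------------------------------
# mitral cell
# ---------------------------------------------------------------------------


def build_mitral(seed: Optional[int] = None,
                 params: Optional[dict] = None) -> CableModel:
    """Reduced mitral cell.

    Morphology: soma (index 0), initial segment, primary dendrite (4
    segments) ending in an 8-compartment tuft, and 2 lateral trunks that
    each split into 3 branches of 25 um segments (half-span 1650 um,
    calibrated against the published connectivity statistics).  ``meta``
    carries the planar layout of the lateral tree (local coordinates at
    rotation 0) used by the connectivity generator, so electrical and
    geometric models stay in register.
    """
    p = (params or load_cell_params())["mitral"]
    rm, ra = p["membrane_resistivity"], p["axial_resistivity"]
    el = p["leak_reversal"]

    def comp(label, length, diameter, parent, channels, calcium=False):
        c = Compartment(label, length, diameter, parent,
                        membrane_resistivity=rm, axial_resistivity=ra,
                        leak_reversal=el, channels=_chan_list(channels))
        if calcium:
            c.has_calcium = True
            c.calcium = CalciumPool(
                baseline=p["ca_baseline"], concentration=p["ca_baseline"],
                influx_scale=p["ca_influx_scale"],
                decay_time=p["ca_decay_time"])
        return c

    comps = [comp("soma", p["soma"]["length"], p["soma"]["diameter"], -1,
                  p["soma"]["channels"], calcium=True)]
    comps.append(comp("initial_segment", 30.0, 1.5, 0, p["initial_segment"]["channels"]))

    # primary dendrite: 4 x 75 um, then 8 tuft branches
    prim_idx = []
    parent = 0
    for i in range(4):
        comps.append(comp(f"primary{i}", 75.0, 3.0, parent, p["primary"]["channels"]))
        parent = len(comps) - 1
        prim_idx.append(parent)
    tuft_idx = []
    for i in range(8):
        comps.append(comp(f"tuft{i}", 20.0, 1.0, prim_idx[-1], p["tuft"]["channels"]))
        tuft_idx.append(len(comps) - 1)

    # Lateral dendrites.  The *geometric* tree (used for synapse placement
    # and granule selection) has 4 trunks (4 x 25 um, d 3.4) each fanning
    # into 8 branches of 30 x 25 um (d 1.7), half-span 850 um -- the stated
    # dendritic reach; its total length (~24 mm) is calibrated so the
    # connectivity generator reproduces the measured shared-granule and
    # aggregated-singles statistics.  The *electrical* tree is coarser (4
    # branches per trunk); geometric branches map onto electrical cables by
    # path distance (branch index modulo the electrical branch count), so
    # synaptic path distances and decay profiles are preserved.
    seg = 25.0
    n_trunk = p.get("n_lateral_trunks", 2)
    n_branch_elec = p.get("n_electrical_branches_per_trunk", 3)
    n_branch_geo = p.get("n_geometric_branches_per_trunk", 3)
    n_branch_seg = p.get("n_branch_segments", 62)
    geo_offsets = np.deg2rad(np.linspace(-30.0, 30.0, n_branch_geo))
    lat = []  # (elec_comp_idx, local_x, local_y, path_dist_um, diameter)
    for tr in range(n_trunk):
        phi = 2.0 * math.pi * tr / n_trunk
        parent = 0
        trunk_elec = []
        for i in range(4):
            comps.append(comp(f"lat{tr}t{i}", seg, 3.4, parent,
                              p["lateral"]["channels"]))
            parent = len(comps) - 1
            trunk_elec.append(parent)
        trunk_end = parent
        branch_elec = []
        for b in range(n_branch_elec):
            parent = trunk_end
            this = []
            for i in range(n_branch_seg):
                comps.append(comp(f"lat{tr}b{b}s{i}", seg, 1.7, parent,
                                  p["lateral"]["channels"]))
                parent = len(comps) - 1
                this.append(parent)
            branch_elec.append(this)
        # geometric segments -> electrical compartments
        tx, ty = 4 * seg * math.cos(phi), 4 * seg * math.sin(phi)
        for i, ci in enumerate(trunk_elec):
            d = (i + 0.5) * seg
            lat.append((ci, d * math.cos(phi), d * math.sin(phi), d, 3.4,
                        n_trunk * n_branch_geo + tr))
        for b in range(n_branch_geo):
            ang = phi + geo_offsets[b]
            elec = branch_elec[b % n_branch_elec]
            gid = tr * n_branch_geo + b
            for i in range(n_branch_seg):
                d = (i + 0.5) * seg
                lat.append((elec[i], tx + d * math.cos(ang),
                            ty + d * math.sin(ang), 100.0 + d, 1.7, gid))

    m = CableModel(comps)
    m.meta.update(
        kind="mitral",
        primary_comps=[(i, (k + 0.5) * 75.0) for k, i in enumerate(prim_idx)],
        tuft_comps=tuft_idx,
        tuft_base=prim_idx[-1],
        lateral_comps=np.array(lat, dtype=float),
        lateral_total_length=n_trunk * 100.0 + n_trunk * n_branch_geo * n_branch_seg * seg,
        primary_length=300.0,
        seg_length=seg,
    )
    return m


# ---------------------------------------------------------------------------
# electrophysiological probes
# ---------------------------------------------------------------------------


def run_with_synaptic_events(cell: CableModel, events, duration: float,
                             dt: float = 0.025, record: Sequence[int] = (0,),
                             record_every: int = 8, nmda_of=None):
    """Integrate one cell driven by synaptic events.

    ``events`` is a list of (synapse, event_times) pairs, where synapse is a
    DualExpSynapse (its ``target`` selects the compartment).  NMDA components
    (voltage-dependent Mg block evaluated at the previous step's target
    voltage) are included when the synapse is an NMDAComponent.  Returns
    (times, traces, spike_times).
    """
    from .synapses import NMDAComponent, conductance_series, mg_block

    n = cell.n_comp
    tgrid_dt = dt
    nstep = int(round(duration / dt)) + 2
    g_tab = np.zeros((nstep, n))
    is_nmda = np.zeros(n, dtype=bool)
    g_nmda_tab = np.zeros((nstep, n))
    tg = np.arange(nstep) * tgrid_dt
    for syn, times in events:
        series = conductance_series(syn, times, tg) * 1e-3  # nS -> uS
        if isinstance(syn, NMDAComponent):
            g_nmda_tab[:, syn.target] += series
            is_nmda[syn.target] = True
        else:
            g_tab[:, syn.target] += series
    erev = np.zeros(n)
    for syn, _ in events:
        erev[syn.target] = syn.reversal  # assumes one reversal per compartment

    group = CableGroup(cell, ncell=1)

    def on_step(t, grp):
        i = min(int(round(t / tgrid_dt)), nstep - 1)
        g = g_tab[i].copy()
        if is_nmda.any():
            block = mg_block(grp.v[0])
            g = g + g_nmda_tab[i] * np.where(is_nmda, block, 0.0)
        return g, g * erev

    t, tr, spikes = simulate_group(group, dt, duration, record=record,
                                   record_every=record_every, on_step=on_step)
    return t, tr[:, 0, :], spikes[0]


def measure_threshold(cell: CableModel, ramp_rate: float = 1e-4,
                      dt: float = 0.025, t_max: float = 4000.0,
                      dvdt_crit: float = 10.0):
    """Spike threshold (mV above rest) under a slow somatic current ramp.

    ramp_rate is in nA/ms (default 0.1 pA/ms).  The initiation voltage is
    where dV/dt first exceeds ``dvdt_crit`` mV/ms on the upstroke of the
    first spike.  Returns the sentinel ``NO_SPIKE`` if the cell never fires.
    """
    n = cell.n_comp
    soma = cell.soma_index
    settle = 500.0  # ms without current, to measure the true resting voltage

    def inj(t):
        out = np.zeros(n)
        out[soma] = ramp_rate * max(t - settle, 0.0)
        return out

    t, tr, spikes = integrate(cell, dt=dt, duration=settle + t_max, i_inj=inj,
                              record=[soma], record_every=4)
    v_rest = float(tr[(t > settle - 100) & (t <= settle), 0].mean())
    spikes = spikes[spikes > settle]
    if len(spikes) == 0:
        return NO_SPIKE
    v = tr[:, 0]
    dvdt = np.gradient(v, t)
    i_sp = np.searchsorted(t, spikes[0])
    upstroke = np.nonzero(dvdt[: i_sp + 1] >= dvdt_crit)[0]
    if len(upstroke) == 0:
        return NO_SPIKE
    return float(v[upstroke[0]] - v_rest)


def measure_time_constant(cell: CableModel, i_step: float = -0.1,
                          dt: float = 0.025, settle: float = 400.0,
                          window: float = 400.0, fit_skip: float = 10.0) -> float:
    """Somatic membrane time constant (ms) from an exponential fit to the
    charging response to a small hyperpolarizing step (default -100 pA)."""
    from scipy.optimize import curve_fit

    n = cell.n_comp
    soma = cell.soma_index

    def inj(t):
        out = np.zeros(n)
        if t >= settle:
            out[soma] = i_step
        return out

    t, tr, _ = integrate(cell, dt=dt, duration=settle + window,
                         i_inj=inj, record=[soma], record_every=8)
    # skip the first few ms of fast charge-equalisation between compartments;
    # the slow (membrane) component is the reported time constant
    sel = t >= settle + fit_skip
    ts = t[sel] - settle - fit_skip
    vs = tr[sel, 0]

    def f(x, a, tau, c):
        return c + a * np.exp(-x / tau)

    v0, v1 = vs[0], vs[-1]
    popt, _ = curve_fit(f, ts, vs, p0=(v0 - v1, 30.0, v1), maxfev=20000)
    return float(abs(popt[1]))


def measure_fI(cell: CableModel, currents: Sequence[float],
               duration: float = 500.0, dt: float = 0.05,
               settle: float = 50.0) -> np.ndarray:
    """Mean firing rate (Hz) per somatic injected current (nA).

    All currents are swept in one batch (one cell copy per current level).
    """
    if duration < 400.0:
        raise ValueError("duration must be >= 400 ms")
    currents = np.asarray(currents, dtype=float)
    group = CableGroup(cell, ncell=len(currents))
    inj = np.zeros((len(currents), cell.n_comp))

    def i_inj(t):
        inj[:, cell.soma_index] = currents if t >= settle else 0.0
        return inj

    _, _, spikes = simulate_group(group, dt, settle + duration, i_inj=i_inj,
                                  record=[cell.soma_index], record_every=1000)
    rates = np.array([np.sum(np.asarray(s) >= settle) for s in spikes])
    return rates / (duration / 1000.0)
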