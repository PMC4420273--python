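"""Orchestrated simulated experiments on the microcircuit model.

Each protocol builds (or accepts) network instances, generates the matching
ORN drive, runs trials with independent input seeds, and returns
analysis-ready binned responses.  All protocols accept instance / trial
multipliers and a time step, so the full-scale experiments can be shrunk
for quick runs while keeping the construction faithful.

Seeding: a protocol receives one integer seed; structural randomness uses
the network seed stream, input/trial randomness a separate stream, so the
same anatomy can be re-stimulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .engine import NetworkSimulation, Stimulus, mean_rate
from .network import NetworkInstance, aggregate_singles, build_network
from .stimuli import (
    DT_MS,
    RESP_PERIOD_MS,
    ORNKernel,
    make_orn_kernel,
    msequence_concentration,
    rate_from_stimulus,
    respiration_series,
    single_pulse_concentration,
)

#: frozen result of the input-strength calibration (see docs/methods.md):
#: a global multiplier on ORN->mitral weights and an independent gain on the
#: air-flow drive, chosen (once) so freely-breathing default networks give
#: mean central-mitral rates of ~14 Hz for odor at 1% saturated vapor and
#: ~8 Hz for air.  Air and odor ORN rates are calibrated independently, as
#: in the reference procedure for matching mean firing across schemes.
ORN_SCALE_DEFAULT = 0.23
AIR_GAIN_DEFAULT = 2.4



@dataclass
class GlomKernels:
    """Per-glomerulus ORN kernels for air and two odors."""

    air: list
    odors: dict  # odor id -> list of ORNKernel per glomerulus


def make_glomerular_kernels(n_glom: int, rng: np.random.Generator,
                            odor_ids=("A", "B"),
                            polarity: str = "excitatory") -> GlomKernels:
    air = [make_orn_kernel("air", rng) for _ in range(n_glom)]
    odors = {o: [make_orn_kernel("odor", rng, polarity=polarity)
                 for _ in range(n_glom)] for o in odor_ids}
    return GlomKernels(air=air, odors=odors)


def freely_breathing_stimulus(kern: GlomKernels, odor: Optional[str] = None,
                              conc: float = 1.0, n_cycles: int = 2,
                              conc_b: float = 0.0,
                              odor_b: Optional[str] = None,
                              air_gain: float = AIR_GAIN_DEFAULT) -> Stimulus:
    """Respiration-sampled ORN drive (odor may be None for odorless air).

    ``conc`` scales the odor concentration (1.0 == 1% saturated vapor).
    A second odor (odor morphs) is supported via odor_b / conc_b.
    """
    n_glom = len(kern.air)
    resp = respiration_series(n_cycles)
    rates = []
    for g in range(n_glom):
        odor_series = resp * conc if odor is not None else resp * 0.0
        ko = kern.odors[odor][g] if odor is not None else kern.air[g]
        r = rate_from_stimulus(odor_series, resp * air_gain, ko, kern.air[g])
        if odor_b is not None and conc_b:
            extra = rate_from_stimulus(resp * conc_b, resp * 0.0,
                                       kern.odors[odor_b][g], kern.air[g])
            r.rate = np.maximum(r.rate + extra.rate - 0.5, 0.0)
        rates.append(r)
    return Stimulus(glom_rates=rates)


def pulse_stimulus(kern: GlomKernels, conc_series: dict, air_series,
                   odor_ids=("A",),
                   air_gain: float = AIR_GAIN_DEFAULT) -> Stimulus:
    """Tracheotomized drive: odor concentration series per odor id."""
    rates = []
    n_glom = len(kern.air)
    for g in range(n_glom):
        total = None
        for o in odor_ids:
            r = rate_from_stimulus(conc_series[o], air_series * 0.0,
                                   kern.odors[o][g], kern.air[g])
            total = r.rate if total is None else total + r.rate - 0.5
        base = rate_from_stimulus(air_series * 0.0, air_series * air_gain,
                                  kern.odors[odor_ids[0]][g], kern.air[g])
        rates.append(np.maximum(total + base.rate - 0.5, 0.0))
    return Stimulus(glom_rates=rates)


def bin_spikes(spikes: np.ndarray, t0: float, t1: float,
               bin_ms: float) -> np.ndarray:
    """Firing-rate histogram (Hz) of one spike train."""
    edges = np.arange(t0, t1 + bin_ms / 2, bin_ms)
    counts, _ = np.histogram(spikes, bins=edges)
    return counts / (bin_ms / 1000.0)


# ---------------------------------------------------------------------------
# nerve shock (spike initiation site)
# ---------------------------------------------------------------------------


def run_nerve_shock(strength: str = "weak", seed: int = 0,
                    dt: float = 0.025) -> dict:
    """ORN shock to one mitral cell + its PG cells.

    weak: 33 of 400 ORN->mitral and 4 of 50 ORN->PG synapses activated over
    4 ms; strong: 66 / 8.  Records soma, tuft-base and tuft voltages and the
    spike initiation order.
    """
    frac = {"weak": (33, 4), "strong": (66, 8)}[strength]
    net = build_network("default", 0, seed=seed)
    sim = NetworkSimulation(net, dt=dt, orn_scale=ORN_SCALE_DEFAULT)
    meta = sim.mitral_proto.meta
    soma, base, tuft = 0, meta["tuft_base"], meta["tuft_comps"][0]
    sim.record_voltages = {"soma": ("mitral", 0, soma),
                           "tuft_base": ("mitral", 0, base),
                           "tuft": ("mitral", 0, tuft)}

    rng = np.random.default_rng(seed + 13)
    events = []
    t0 = 20.0
    # mitral tuft volley
    n_m, n_p = frac
    pick = rng.choice(400, size=n_m, replace=False)
    idx = 0 * sim.n_mc + sim.orn_m_comp[0, pick]
    w = sim.orn_m_w[0, pick]
    times = t0 + rng.uniform(0, 4.0, size=n_m)
    for t, i, ww in zip(times, idx, w):
        events.append((t, "mitral_exc", [i], [ww]))
    # PG volley: n_p of 50 ORN synapses per PG
    for j in range(len(sim.pg_ids)):
        tms = t0 + rng.uniform(0, 4.0, size=n_p)
        dend = rng.integers(1, 3, size=n_p)
        for t, d in zip(tms, dend):
            events.append((t, "pg_exc", [j * sim.n_pc + d],
                           [sim.orn_pg_w[j]]))

    zero = [np.zeros(100) for _ in range(len(net.glom_pos))]
    out = sim.run(Stimulus(zero, background="in_vitro"), duration=60.0,
                  input_seed=seed + 29, record_every=2,
                  preset_events=events)
    v = out["v"]
    t = out["t"]

    def onset(key):
        # +10 mV criterion: synaptic drive alone cannot exceed the 0 mV
        # excitatory reversal, so this isolates the regenerative spike
        tr = v[key]
        above = np.nonzero(tr >= 10.0)[0]
        return float(t[above[0]]) if len(above) else math.inf

    out["onsets"] = {k: onset(k) for k in ("soma", "tuft_base", "tuft")}
    return out


# ---------------------------------------------------------------------------
# activity-dependent inhibition
# ---------------------------------------------------------------------------


def run_adi_invitro(seeds: Sequence[int] = range(10),
                    currents_A: Sequence[float] = (0.25, 0.5, 0.75, 1.0, 1.5),
                    i_b: float = 1.2, n_select: int = 5,
                    dt: float = 0.05, separation: float = 50.0) -> dict:
    """Paired f-I curves in slice networks (A alone vs A with B driven).

    Current is injected into A at 250 ms for 400 ms; B (when present)
    receives ``i_b`` nA starting 5 ms earlier.  Over the seeds, the
    ``n_select`` most-inhibiting pairs are kept and the mean rate reduction
    versus A's control rate is reported.
    """
    per_seed = []
    for seed in seeds:
        net = aggregate_singles(build_network("slice", 1, seed=seed,
                                              separation=separation))
        sim = NetworkSimulation(net, dt=dt)
        zero = [np.zeros(100) for _ in range(len(net.glom_pos))]
        f_ctrl, f_inh = [], []
        for ia in currents_A:
            for with_b in (False, True):
                inj = {("mitral", 0): (ia, 250.0, 650.0)}
                if with_b:
                    inj[("mitral", 2)] = (i_b, 245.0, 650.0)
                out = sim.run(Stimulus(zero, background="in_vitro"),
                              duration=660.0, i_inj=inj,
                              input_seed=seed * 37 + int(ia * 100) + with_b)
                r = mean_rate([out["mitral_spikes"][0]], 250.0, 650.0)
                (f_inh if with_b else f_ctrl).append(r)
        per_seed.append({"seed": seed, "currents": np.asarray(currents_A),
                         "f_control": np.array(f_ctrl),
                         "f_inhibited": np.array(f_inh)})
    # select the pairs with the largest peak reduction at any current
    peak_red = [np.max(d["f_control"] - d["f_inhibited"]) for d in per_seed]
    order = np.argsort(peak_red)[::-1][:n_select]
    selected = [per_seed[i] for i in order]
    ctrl = np.array([d["f_control"] for d in selected])
    inh = np.array([d["f_inhibited"] for d in selected])
    return {"per_seed": per_seed, "selected": selected,
            "mean_reduction": (ctrl - inh).mean(axis=0),
            "control_rates": ctrl.mean(axis=0)}


def run_adi_invivo(scheme: str = "default", separation: float = 400.0,
                   rates_a: Sequence[float] = (0.0, 5.0, 10.0, 15.0, 19.0),
                   rate_b: float = 10.0, seeds: Sequence[int] = range(10),
                   direction: str = "B_on_A", dt: float = 0.1,
                   settle: float = 100.0, window: float = 400.0) -> float:
    """Mean inhibition between two mitral cells at a given separation.

    Two-cell networks (B super-inhibits A in the default scheme); constant
    ORN Poisson drive replaces current injection; granule cells receive the
    35 Hz in-vivo background.  Returns the mean pointwise difference between
    the uninhibited f-vs-ORN curve of the target and the curve with
    ``rate_b`` Hz drive to the source, averaged over seeds (positive =
    inhibition).
    """
    tgt, src = (0, 1) if direction == "B_on_A" else (1, 0)
    diffs = []
    for seed in seeds:
        net = aggregate_singles(build_network(
            scheme if scheme != "default" else "default", 1, seed=seed,
            separation=separation, two_cell=True))
        sim = NetworkSimulation(net, dt=dt)
        base = [np.zeros(100) for _ in range(len(net.glom_pos))]
        f0, f1 = [], []
        for ra in rates_a:
            for rb, acc in ((0.0, f0), (rate_b, f1)):
                stim = Stimulus(base, background="in_vivo",
                                mitral_rate_override={tgt: ra, src: rb})
                out = sim.run(stim, duration=settle + window,
                              input_seed=seed * 1013 + int(ra * 10)
                              + int(rb * 3))
                acc.append(mean_rate([out["mitral_spikes"][tgt]], settle,
                                     settle + window))
        diffs.append(np.mean(np.array(f0) - np.array(f1)))
    return float(np.mean(diffs))


# ---------------------------------------------------------------------------
# tracheotomized random pulse trains (linearity)
# ---------------------------------------------------------------------------


def run_linearity_protocol(seed: int = 0, conc: float = 1.0,
                           n_trials: int = 9, n_repeats: int = 6,
                           dt: float = 0.1, bin_ms: float = 50.0,
                           polarity: str = "excitatory",
                           net: Optional[NetworkInstance] = None,
                           kernels: Optional[GlomKernels] = None) -> dict:
    """5 random pulse-train stimuli (2 per odor + 1 overlapping two-odor),
    ``n_trials`` trials each; central sisters' responses binned at 50 ms.

    Returns concentration series, per-stimulus trial-binned responses of
    the two central sisters, and the air pedestal level.
    """
    rng = np.random.default_rng(seed + 500)
    if net is None:
        net = aggregate_singles(build_network("default", 2, seed=seed))
    if kernels is None:
        kernels = make_glomerular_kernels(len(net.glom_pos), rng,
                                          polarity=polarity)
    sim = NetworkSimulation(net, dt=dt, orn_scale=ORN_SCALE_DEFAULT)

    stims = []
    for o in ("A", "A", "B", "B"):
        c, air = msequence_concentration(conc, rng, n_repeats=n_repeats,
                                         lead_ms=200.0)
        stims.append({"odors": (o,), "conc": {o: c}, "air": air})
    cA, air = msequence_concentration(conc, rng, n_repeats=n_repeats,
                                      lead_ms=200.0)
    cB, _ = msequence_concentration(conc, rng, n_repeats=n_repeats,
                                    lead_ms=200.0)
    stims.append({"odors": ("A", "B"), "conc": {"A": cA, "B": cB},
                  "air": air})
    # air-only reference (for baseline subtraction in the analysis)
    dur = len(air) * DT_MS

    results = []
    for si, st in enumerate(stims):
        stim = pulse_stimulus(kernels, st["conc"], st["air"],
                              odor_ids=st["odors"])
        trials = []
        for tr in range(n_trials):
            out = sim.run(stim, duration=dur,
                          input_seed=seed * 10007 + si * 101 + tr)
            binned = [bin_spikes(out["mitral_spikes"][m], 0.0, dur, bin_ms)
                      for m in (0, 1)]
            trials.append(binned)
        results.append({"odors": st["odors"], "conc": st["conc"],
                        "responses": np.array(trials)})  # (trial, sister, bin)
    air_stim = pulse_stimulus(kernels, {"A": np.zeros_like(air)}, air,
                              odor_ids=("A",))
    air_trials = []
    for tr in range(max(n_trials // 3, 2)):
        out = sim.run(air_stim, duration=dur, input_seed=seed * 10007 + 9001 + tr)
        air_trials.append([bin_spikes(out["mitral_spikes"][m], 0.0, dur, bin_ms)
                           for m in (0, 1)])
    return {"stimuli": results, "air": np.array(air_trials),
            "kernels": kernels, "bin_ms": bin_ms, "duration": dur,
            "net": net}


# ---------------------------------------------------------------------------
# freely-breathing responses (phase decorrelation)
# ---------------------------------------------------------------------------


def run_freely_breathing(seed: int = 0, scheme: str = "default",
                         n_lateral: int = 2, odors=("A", "B"),
                         conc: float = 1.0, n_trials: int = 8,
                         n_cycles: int = 2, n_bins: int = 5,
                         dt: float = 0.1,
                         central_odor_compensation: float = 1.0,
                         n_air_trials: Optional[int] = None,
                         net: Optional[NetworkInstance] = None,
                         kernels: Optional[GlomKernels] = None) -> dict:
    """Respiration-sampled responses: ``n_trials`` trials of ``n_cycles``
    cycles for air and each odor; the average second-cycle response of each
    central sister is binned into ``n_bins`` bins.

    ``central_odor_compensation`` rescales the central glomerulus's odor
    ORN rate (non-default schemes halve it to match the default scheme's
    mean firing, since they lack super-inhibition).  Returns per-condition
    arrays of shape (n_trials, 2 sisters, n_bins).
    """
    rng = np.random.default_rng(seed + 900)
    if net is None:
        net = aggregate_singles(build_network(scheme, n_lateral, seed=seed))
    if kernels is None:
        kernels = make_glomerular_kernels(len(net.glom_pos), rng)
    sim = NetworkSimulation(net, dt=dt, orn_scale=ORN_SCALE_DEFAULT)
    T = RESP_PERIOD_MS
    dur = n_cycles * T
    bin_ms = T / n_bins
    out_all = {}
    for cond in (None,) + tuple(odors):
        n_tr = n_trials if (cond is not None or n_air_trials is None) \
            else n_air_trials
        stim = freely_breathing_stimulus(kernels, cond, conc=conc,
                                         n_cycles=n_cycles)
        if cond is not None and central_odor_compensation != 1.0:
            stim.glom_rates[0].rate = stim.glom_rates[0].rate \
                * central_odor_compensation
        trials = []
        for tr in range(n_tr):
            out = sim.run(stim, duration=dur,
                          input_seed=seed * 20011 + (0 if cond is None else
                                                     ord(cond[0])) * 71 + tr)
            # cycles after the first are analyzed as repeats (the first
            # cycle differs because the ~1 s kernels outlast one period)
            for cyc in range(1, n_cycles):
                binned = [bin_spikes(out["mitral_spikes"][m], cyc * T,
                                     (cyc + 1) * T, bin_ms)
                          for m in (0, 1)]
                trials.append(binned)
        key = "air" if cond is None else cond
        out_all[key] = np.array(trials)  # (repeat, sister, bin)
    return {"responses": out_all, "n_bins": n_bins, "bin_ms": bin_ms,
            "kernels": kernels, "net": net}


# ---------------------------------------------------------------------------
# scaled pulses
# ---------------------------------------------------------------------------

SCALED_CONCS = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0, 2.0, 5.0)


def run_scaled_pulses(seed: int = 0, concs: Sequence[float] = SCALED_CONCS,
                      n_trials: int = 9, dt: float = 0.1,
                      bin_ms: float = 50.0, hist_ms: float = 1700.0,
                      net: Optional[NetworkInstance] = None,
                      kernels: Optional[GlomKernels] = None) -> dict:
    """200 ms odor pulses at scaled concentrations (% saturated vapor).

    Returns per-concentration spike trains and air-subtracted 50 ms
    histograms over 1.7 s after odor onset, for both central sisters.
    """
    rng = np.random.default_rng(seed + 1300)
    if net is None:
        net = aggregate_singles(build_network("default", 2, seed=seed))
    if kernels is None:
        kernels = make_glomerular_kernels(len(net.glom_pos), rng)
    sim = NetworkSimulation(net, dt=dt, orn_scale=ORN_SCALE_DEFAULT)
    onset = 200.0
    dur = onset + hist_ms + 100.0
    results = {}
    for conc in concs:
        c, air = single_pulse_concentration(conc, duration_ms=dur)
        stim = pulse_stimulus(kernels, {"A": c}, air, odor_ids=("A",))
        spikes, hists = [], []
        for tr in range(n_trials):
            out = sim.run(stim, duration=dur,
                          input_seed=seed * 30013 + int(conc * 300) + tr)
            sp = [out["mitral_spikes"][m] for m in (0, 1)]
            spikes.append(sp)
            hists.append([bin_spikes(s, onset, onset + hist_ms, bin_ms)
                          for s in sp])
        results[conc] = {"spikes": spikes, "hist": np.array(hists)}
    # air response (0% is identical, but keep an explicit alias)
    air_hist = results[0.0]["hist"].mean(axis=0) if 0.0 in results else 0.0
    for conc in results:
        results[conc]["hist_minus_air"] = results[conc]["hist"] - air_hist
    return {"onset_ms": onset, "bin_ms": bin_ms, "results": results,
            "net": net, "kernels": kernels}
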