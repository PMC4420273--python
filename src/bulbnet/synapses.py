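"""Synaptic conductance models, delays, weights and aggregation rules.

All synapses are dual-exponential conductances

    g(t) = A g_max (exp(-t/tau1) - exp(-t/tau2)) / (tau1 - tau2),  t > 0

with ``A`` normalizing the peak to ``g_max`` (the tau1 == tau2 limit is the
alpha function ``g_max (t/tau) exp(1 - t/tau)``).  Excitatory reversal is
0 mV, inhibitory -78 mV.  ORN input arrives with zero delay, excitatory
synapses with 1.8 ms and inhibitory synapses with 0.6 ms delay; mitral->PG
delays are spread uniformly over 0-40 ms and PG-|mitral delays
exponentially with mean 160 ms.  The mitral->granule synapse carries an
NMDA component (g_max = 0.26 x AMPA, tau 25/200 ms) under a standard
extracellular-Mg sigmoidal block.  Granule-|mitral strengths decay
exponentially with distance along the dendrite (length constant 100 um
primary, 150 um secondary) and proportionally with diameter.  Individual
weights are log-normal with 25% relative SD around their putative value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

E_EXC = 0.0  # mV
E_INH = -78.0  # mV

DELAY_EXC = 1.8  # ms
DELAY_INH = 0.6  # ms
DELAY_ORN = 0.0  # ms
DELAY_M2PG_MAX = 40.0  # ms, uniform upper bound
DELAY_PG2M_MEAN = 160.0  # ms, exponential mean
DELAY_AGG_SD = 160.0  # ms, exponential (SD = mean)

LAMBDA_PRIMARY = 100.0  # um
LAMBDA_SECONDARY = 150.0  # um

WEIGHT_RELATIVE_SD = 0.25
NMDA_TO_AMPA = 0.26
AUTO_INHIBITORY_G = 0.005  # nS (5 pS)


@dataclass
class DualExpSynapse:
    g_max: float  # nS
    tau1: float  # ms
    tau2: float  # ms
    reversal: float  # mV
    delay: float = 0.0  # ms
    target: int = 0  # target compartment id

    def __post_init__(self):
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")


@dataclass
class NMDAComponent(DualExpSynapse):
    mg_conc: float = 1.0  # mM


def dual_exp_peak_time(tau1: float, tau2: float) -> float:
    """Time of the conductance peak."""
    if abs(tau1 - tau2) < 1e-9 * max(tau1, tau2):
        return tau1
    return tau1 * tau2 * math.log(tau1 / tau2) / (tau1 - tau2)


def dual_exp_norm(tau1: float, tau2: float) -> float:
    """Normalization constant A such that the peak equals g_max."""
    if abs(tau1 - tau2) < 1e-9 * max(tau1, tau2):
        return tau1 * math.e  # alpha-function limit of A
    tp = dual_exp_peak_time(tau1, tau2)
    return (tau1 - tau2) / (math.exp(-tp / tau1) - math.exp(-tp / tau2))


def dual_exp_g(syn: DualExpSynapse, t) -> np.ndarray:
    """Conductance (nS) at time t (ms) after the synaptic event; 0 for t<0."""
    t = np.asarray(t, dtype=float)
    tc = np.maximum(t, 0.0)  # negative times contribute zero
    t1, t2 = syn.tau1, syn.tau2
    if abs(t1 - t2) < 1e-9 * max(t1, t2):
        tau = t1
        out = syn.g_max * (tc / tau) * np.exp(1.0 - tc / tau)
    else:
        A = dual_exp_norm(t1, t2)
        out = syn.g_max * A * (np.exp(-tc / t1) - np.exp(-tc / t2)) / (t1 - t2)
    out = np.where(t >= 0, out, 0.0)
    return float(out) if out.ndim == 0 else out


def mg_block(V, mg_conc: float = 1.0) -> np.ndarray:
    """Sigmoidal extracellular-Mg block of the NMDA conductance, in [0, 1].

    Jahr–Stevens form: 1 / (1 + [Mg]/3.57 mM * exp(-0.062 V)).
    """
    V = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + (mg_conc / 3.57) * np.exp(-0.062 * V))
    return float(out) if out.ndim == 0 else out


def nmda_g(syn: NMDAComponent, t, V) -> np.ndarray:
    """NMDA conductance: dual-exponential envelope times the Mg block at V."""
    return dual_exp_g(syn, t) * mg_block(V, syn.mg_conc)


@dataclass
class WeightSampler:
    """Log-normal synaptic weights with fixed relative SD about the mean."""

    putative_mean: float  # nS
    relative_sd: float = WEIGHT_RELATIVE_SD

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        sigma2 = math.log(1.0 + self.relative_sd ** 2)
        sigma = math.sqrt(sigma2)
        mu = math.log(self.putative_mean) - sigma2 / 2.0
        return rng.lognormal(mu, sigma, size=size)


def sample_lognormal_weights(mean, rng: np.random.Generator,
                             relative_sd: float = WEIGHT_RELATIVE_SD):
    """Vectorized log-normal weights: per-element means, common relative SD."""
    mean = np.asarray(mean, dtype=float)
    sigma2 = math.log(1.0 + relative_sd ** 2)
    sigma = math.sqrt(sigma2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(rng.normal(mu, sigma))


def distance_decay(x, dendrite: str = "secondary", diameter_ratio=1.0):
    """Granule-|mitral strength multiplier at path distance x (um).

    exp(-x/lambda) times the local/proximal diameter ratio; lambda is 100 um
    on the primary and 150 um on secondary (lateral) dendrites.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("distance must be non-negative")
    lam = {"primary": LAMBDA_PRIMARY, "secondary": LAMBDA_SECONDARY}[dendrite]
    out = np.exp(-x / lam) * diameter_ratio
    return float(out) if out.ndim == 0 else out


def assign_delays(kind: str, rng: Optional[np.random.Generator] = None,
                  size=None):
    """Synaptic delay(s) in ms for a synapse kind.

    Fixed: excitatory 1.8, inhibitory 0.6, orn 0.  Random (rng required):
    mitral_to_pg uniform(0, 40); pg_to_mitral exponential(mean 160);
    aggregated exponential(SD = 160).
    """
    fixed = {"excitatory": DELAY_EXC, "inhibitory": DELAY_INH, "orn": DELAY_ORN}
    if kind in fixed:
        v = fixed[kind]
        return v if size is None else np.full(size, v)
    if rng is None:
        raise ValueError(f"kind {kind!r} requires an rng")
    if kind == "mitral_to_pg":
        return rng.uniform(0.0, DELAY_M2PG_MAX, size=size)
    if kind == "pg_to_mitral":
        return rng.exponential(DELAY_PG2M_MEAN, size=size)
    if kind == "aggregated":
        return rng.exponential(DELAY_AGG_SD, size=size)
    raise ValueError(f"unknown delay kind {kind!r}")


# ---------------------------------------------------------------------------
# putative synapse parameters (dendro-dendritic microcircuit)
# ---------------------------------------------------------------------------

#: (g_max nS, tau1 ms, tau2 ms, reversal mV) per connection kind.
SYNAPSE_TABLE: dict[str, tuple[float, float, float, float]] = {
    "orn_mitral": (6.0, 1.0, 1.0, E_EXC),
    "orn_pg_plateauing": (0.45, 1.0, 1.0, E_EXC),
    "orn_pg_LTS": (1.25, 1.0, 1.0, E_EXC),
    "mitral_pg_plateauing": (0.45, 1.0, 1.0, E_EXC),
    "mitral_pg_LTS": (1.25, 1.0, 1.0, E_EXC),
    "mitral_granule_ampa": (0.2, 1.0, 4.0, E_EXC),
    "mitral_granule_nmda": (0.2 * NMDA_TO_AMPA, 25.0, 200.0, E_EXC),
    "granule_mitral": (1.0, 1.0, 20.0, E_INH),
    "granule_mitral_baseline": (1.5, 1.0, 20.0, E_INH),  # random/directed nets
    "pg_mitral": (1.0, 1.0, 20.0, E_INH),
}


def make_synapse(kind: str, **overrides) -> DualExpSynapse:
    g, t1, t2, erev = SYNAPSE_TABLE[kind]
    cls = NMDAComponent if kind.endswith("nmda") else DualExpSynapse
    syn = cls(g_max=g, tau1=t1, tau2=t2, reversal=erev)
    if erev == E_INH:
        assert syn.reversal == E_INH
    return replace(syn, **overrides) if overrides else syn


@dataclass
class AutoInhibitorySynapse:
    """Weak self-inhibition at every reciprocal mitral|->granule site.

    Models the inhibitory effect of the spine calcium transient: activated
    by the HOST mitral cell's own spike (not by a granule spike), with an
    effective strength of 5 pS.
    """

    g_max: float = AUTO_INHIBITORY_G
    tau1: float = 1.0
    tau2: float = 20.0
    reversal: float = E_INH


@dataclass
class AggregatedInhibition:
    """Inhibition proxy for 100 aggregated singly-connected granule cells.

    One presynaptic granule spike triggers ``count`` staggered synapses of
    ``strength_factor`` x the base weight, with exponentially distributed
    delays (SD 160 ms), so the total conductance-time integral equals
    ratio x the single-synapse integral.
    """

    base_g_max: float  # nS, mean single-synapse weight of the aggregated group
    count: int = 10
    strength_factor: float = 10.0
    delay_sd: float = DELAY_AGG_SD
    delays: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def draw_delays(self, rng: np.random.Generator) -> np.ndarray:
        self.delays = rng.exponential(self.delay_sd, size=self.count)
        return self.delays


def conductance_series(syn: DualExpSynapse, event_times, tgrid) -> np.ndarray:
    """Total conductance on a time grid from a list of event times
    (linear superposition; used by single-cell protocols and tests)."""
    tgrid = np.asarray(tgrid, dtype=float)
    g = np.zeros_like(tgrid)
    for t0 in np.atleast_1d(event_times):
        g += dual_exp_g(syn, tgrid - (t0 + syn.delay))
    return g
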