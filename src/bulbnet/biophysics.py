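"""Channel gating kinetics, calcium dynamics and the compartmental cable solver.

Units at all public interfaces: mV, ms, um, nA, uS (micro-siemens), nF, mM.
Membrane parameters are specific (F/m^2, ohm*m^2, ohm*m) and converted to
per-compartment absolute values at build time.

The integrator uses exponential-Euler updates for gate variables (via
voltage lookup tables) and a backward-Euler (implicit) solve of the branched
cable equation, eliminated in tree (Hines) order. Populations of cells with
identical topology are integrated as batches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from ._kernels import channel_step, implicit_update

TEMPERATURE_C = 35.0  # simulated temperature; all Q10 factors evaluate here

# ---------------------------------------------------------------------------
# rate-function primitives
# ---------------------------------------------------------------------------


def trap(V, th, a, q, temperature=TEMPERATURE_C):
    """Linoid ("trapezoid-guarded") rate function, in 1/s.

    ``a (V - th) / (1 - exp(-(V - th)/q)) * 2**((T-24)/10)`` with the
    analytic limit ``a*q*2**((T-24)/10)`` within 1 uV of the singularity at
    ``V == th``.  V, th, q are in mV; ``a`` is in s^-1 V^-1, hence the 1e-3
    factor on the mV difference.
    """
    V = np.asarray(V, dtype=float)
    tfac = 2.0 ** ((temperature - 24.0) / 10.0)
    dv = V - th
    safe = np.where(np.abs(dv) > 1e-6, dv, 1.0)
    with np.errstate(over="ignore"):
        out = a * 1e-3 * safe / (1.0 - np.exp(-safe / q)) * tfac
    lim = a * 1e-3 * q * tfac
    out = np.where(np.abs(dv) > 1e-6, out, lim)
    if out.ndim == 0:
        return float(out)
    return out


def _sig(V, mid, slope):
    """1 / (1 + exp((V - mid)/slope)); slope sign sets direction."""
    return 1.0 / (1.0 + np.exp((np.asarray(V, dtype=float) - mid) / slope))


def _lin(x, b):
    """x / (exp(x/b) - 1) with the analytic limit b at x = 0."""
    x = np.asarray(x, dtype=float)
    safe = np.where(np.abs(x) > 1e-9, x, 1.0)
    out = safe / (np.exp(safe / b) - 1.0)
    return np.where(np.abs(x) > 1e-9, out, b)


# ---------------------------------------------------------------------------
# gate kinetics and channel catalogue
# ---------------------------------------------------------------------------


@dataclass
class GateKinetics:
    """Voltage dependence of one gate: steady state and time constant (ms)."""

    steady_state: Callable[[np.ndarray], np.ndarray]
    time_constant: Callable[[np.ndarray], np.ndarray]
    exponent: int = 1


@dataclass
class ChannelSpec:
    """A conductance: ``g = gbar * prod(gate^p) [* Ca/(Ca+kd)]``, I = g(E-V)."""

    name: str
    reversal: float  # mV
    gates: Sequence[GateKinetics] = ()
    ca_half: Optional[float] = None  # mM; Michaelis Ca-dependence half-point
    feeds_ca: bool = False  # does this current drive the calcium pool?

    def with_reversal(self, erev: float) -> "ChannelSpec":
        return ChannelSpec(self.name, erev, self.gates, self.ca_half, self.feeds_ca)


def _alpha_beta_gate(alpha, beta, tau_floor=0.0, inf_override=None, exponent=1):
    """Gate from alpha/beta rates given in 1/s (converted to ms internally)."""

    def inf(V):
        if inf_override is not None:
            return inf_override(V)
        a, b = alpha(V), beta(V)
        return a / (a + b)

    def tau(V):
        a, b = alpha(V), beta(V)
        t = 1000.0 / (np.asarray(a) + b)  # 1/s -> ms
        return np.maximum(t, tau_floor)

    return GateKinetics(inf, tau, exponent)


_Q3 = 3.0 ** ((TEMPERATURE_C - 24.0) / 10.0)


def _make_na_ms(th_shift: float, h_mid: float, erev: float, name: str) -> ChannelSpec:
    """Migliore–Shepherd style Na channel (printed kinetics): m^3 h."""
    m = _alpha_beta_gate(
        lambda V: trap(V, -th_shift, 4.0e5, 7.2),
        lambda V: trap(-np.asarray(V, float), th_shift, 1.24e5, 7.2),
        tau_floor=0.02,
        exponent=3,
    )
    h = _alpha_beta_gate(
        lambda V: trap(V, -(th_shift + 15.0), 3.0e4, 1.5),
        lambda V: trap(-np.asarray(V, float), th_shift + 15.0, 1.0e4, 1.5),
        tau_floor=0.5,
        inf_override=lambda V: _sig(V, -h_mid, 4.0),
    )
    return ChannelSpec(name, erev, [m, h])


def _ka_ms() -> ChannelSpec:
    """Granule A-type K (printed kinetics): m h, E = -90 mV."""
    m = GateKinetics(
        lambda V: _sig(V, 17.5, -14.0),
        lambda V: np.exp(0.75 * (np.asarray(V, float) + 45.0) / 10.0)
        / (_Q3 * 0.04 * (1.0 + np.exp((np.asarray(V, float) + 45.0) / 10.0))),
    )
    h = GateKinetics(
        lambda V: _sig(V, -41.3, 6.0),
        lambda V: np.exp(0.99 * (np.asarray(V, float) + 70.0) / 5.0)
        / (_Q3 * 0.018 * (1.0 + np.exp((np.asarray(V, float) + 70.0) / 5.0))),
    )
    return ChannelSpec("KA_ms", -90.0, [m, h])


def _tca_d() -> ChannelSpec:
    """Low-threshold T-type Ca of the PG cell (printed kinetics): m^2 h."""
    q5 = 5.0 ** ((TEMPERATURE_C - 24.0) / 10.0)
    q3 = 3.0 ** ((TEMPERATURE_C - 24.0) / 10.0)
    m = GateKinetics(
        lambda V: _sig(V, -50.0, -7.4),
        lambda V: (
            3.0
            + 1.0
            / (
                np.exp((np.asarray(V, float) + 25.0) / 10.0)
                + np.exp(-(np.asarray(V, float) + 100.0) / 15.0)
            )
        )
        / q5,
        exponent=2,
    )
    h = GateKinetics(
        lambda V: _sig(V, -78.0, 5.0),
        lambda V: (
            85.0
            + 1.0
            / (
                np.exp((np.asarray(V, float) + 46.0) / 4.0)
                + np.exp(-(np.asarray(V, float) + 405.0) / 50.0)
            )
        )
        / q3,
    )
    return ChannelSpec("TCa_d", 120.0, [m, h], feeds_ca=True)


def _ih_cb() -> ChannelSpec:
    """Hyperpolarization-activated cation current of the PG cell (printed).

    The printed rate constant (0.85) is read as s^-1, giving time constants
    of hundreds of ms in the activation range, as expected for Ih.
    """
    q = 4.5 ** ((TEMPERATURE_C - 30.0) / 10.0)
    l = GateKinetics(
        lambda V: _sig(V, -80.0, 10.0),
        lambda V: 1000.0
        * np.exp((np.asarray(V, float) + 65.0) / 23.529411765)
        / (0.85 * (1.0 + np.exp((np.asarray(V, float) + 65.0) / 11.764705882)))
        / q,
    )
    return ChannelSpec("Ih_cb", -30.0, [l])


# --- Bhalla–Bower–derived rows -------------------------------------------
# EXTERNALLY SOURCED CONSTANTS: the following kinetics are transcribed /
# adapted from the Bhalla & Bower (1993) mitral-cell model (Traub-style
# linoid rates, resting-potential offset -65 mV).  Channel densities are
# re-calibrated against measured cell properties (see bulbnet.cells), so the
# cells are constrained by physiology rather than by transcription fidelity.

_VREST_BB = -65.0


def _na_mit_usb() -> ChannelSpec:
    def am(V):
        v = np.asarray(V, float) - _VREST_BB
        return 0.32 * _lin(13.1 - v, 4.0)

    def bm(V):
        v = np.asarray(V, float) - _VREST_BB
        return 0.28 * _lin(v - 40.1, 5.0)

    def ah(V):
        v = np.asarray(V, float) - _VREST_BB
        return 0.128 * np.exp((17.0 - v) / 18.0)

    def bh(V):
        v = np.asarray(V, float) - _VREST_BB
        return 4.0 / (1.0 + np.exp((40.0 - v) / 5.0))

    m = GateKinetics(lambda V: am(V) / (am(V) + bm(V)),
                     lambda V: 1.0 / (am(V) + bm(V)), exponent=3)
    h = GateKinetics(lambda V: ah(V) / (ah(V) + bh(V)),
                     lambda V: 1.0 / (ah(V) + bh(V)))
    return ChannelSpec("Na_mit_usb", 45.0, [m, h])


def _k_delayed(name: str, vhalf: float, slope: float, tau_min: float,
               tau_amp: float, tau_mid: float, tau_slope: float,
               erev: float) -> ChannelSpec:
    """Delayed rectifier, n^2; activates at spike voltages, sigmoidal tau."""
    n = GateKinetics(
        lambda V: _sig(V, vhalf, -slope),
        lambda V: tau_min
        + tau_amp / (1.0 + np.exp((np.asarray(V, float) - tau_mid) / tau_slope)),
        exponent=2,
    )
    return ChannelSpec(name, erev, [n])


def _ka_bsg_yka(erev: float) -> ChannelSpec:
    m = GateKinetics(lambda V: _sig(V, -42.0, -13.0),
                     lambda V: np.full_like(np.asarray(V, float), 1.4))
    h = GateKinetics(lambda V: _sig(V, -67.0, 9.0),
                     lambda V: np.full_like(np.asarray(V, float), 50.0))
    return ChannelSpec("KA_bsg_yka", erev, [m, h])


def _lca3_mit_usb() -> ChannelSpec:
    s = GateKinetics(lambda V: _sig(V, -25.0, -5.0),
                     lambda V: np.full_like(np.asarray(V, float), 5.0))
    return ChannelSpec("LCa3_mit_usb", 70.0, [s], feeds_ca=True)


def _kca(name: str, ca_half: float, erev: float) -> ChannelSpec:
    return ChannelSpec(name, erev, [], ca_half=ca_half)


#: channel catalogue keyed by the conventional channel-file names.  K-channel
#: reversal is -70 mV in the mitral cell and -80 mV in granule / PG cells.
CHANNELS: dict[str, ChannelSpec] = {
    "Na_mit_usb": _na_mit_usb(),
    "K_mit_usb": _k_delayed("K_mit_usb", -20.0, 9.0, 4.0, 40.0, -30.0, 10.0, -70.0),
    "K2_mit_usb": _k_delayed("K2_mit_usb", -15.0, 8.0, 0.8, 12.0, -25.0, 12.0, -70.0),
    "K2_mit_usb_g": _k_delayed("K2_mit_usb_g", -15.0, 8.0, 0.8, 12.0, -25.0, 12.0, -80.0),
    "KA_bsg_yka": _ka_bsg_yka(-70.0),
    "KA_bsg_yka_pg": _ka_bsg_yka(-80.0),
    "LCa3_mit_usb": _lca3_mit_usb(),
    "Kca_mit_usb": _kca("Kca_mit_usb", 0.015, -70.0),
    "Kca_mit_usb_pg": _kca("Kca_mit_usb_pg", 0.0055, -80.0),
    "Na_mit_initialsegment_MS": _make_na_ms(
        30.0, 50.0, 50.0, "Na_mit_initialsegment_MS"
    ),
    "Na_rat_ms": _make_na_ms(15.0, 35.0, 60.0, "Na_rat_ms"),
    "KA_ms": _ka_ms(),
    "TCa_d": _tca_d(),
    "Ih_cb": _ih_cb(),
}


def get_channel(name: str) -> ChannelSpec:
    try:
        return CHANNELS[name]
    except KeyError:
        raise KeyError(f"unknown channel {name!r}; known: {sorted(CHANNELS)}")


def evaluate_gate(kin: GateKinetics, V) -> tuple[np.ndarray, np.ndarray]:
    """(steady state, time constant in ms) of a gate at voltage V (mV)."""
    return np.asarray(kin.steady_state(V)), np.asarray(kin.time_constant(V))


def kca_activation(Ca, variant: str = "mitral"):
    """Calcium-dependence factor of the KCa conductance, in [0, 1].

    Michaelis form ``Ca / (Ca + kd)``: half-maximal at 0.015 mM for the
    mitral variant and 0.0055 mM for the PG variant.
    """
    Ca = np.asarray(Ca, dtype=float)
    if np.any(Ca < 0):
        raise ValueError("calcium concentration must be non-negative")
    kd = {"mitral": 0.015, "pg": 0.0055}[variant]
    out = Ca / (Ca + kd)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# calcium pool
# ---------------------------------------------------------------------------


@dataclass
class CalciumPool:
    """Single-shell first-order calcium pool.

    d[Ca]/dt = influx_scale * I_Ca - ([Ca] - baseline) / decay_time, so the
    steady state under constant current is
    ``baseline + influx_scale * I_Ca * decay_time``.
    """

    concentration: float = 5e-5  # mM
    baseline: float = 5e-5  # mM
    influx_scale: float = 0.02  # mM per nA per ms
    decay_time: float = 10.0  # ms


def step_calcium(pool: CalciumPool, I_Ca: float, dt: float) -> CalciumPool:
    """Advance the pool by dt (exact update of the linear ODE)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    target = pool.baseline + pool.influx_scale * I_Ca * pool.decay_time
    conc = target + (pool.concentration - target) * math.exp(-dt / pool.decay_time)
    return CalciumPool(max(conc, 0.0), pool.baseline, pool.influx_scale,
                       pool.decay_time)


# ---------------------------------------------------------------------------
# morphology / cable model
# ---------------------------------------------------------------------------


@dataclass
class Compartment:
    """One cylindrical electrical compartment."""

    label: str
    length: float  # um
    diameter: float  # um
    parent: int  # index of parent compartment; -1 for the root (soma)
    specific_capacitance: float = 0.01  # F/m^2  (1 uF/cm^2)
    membrane_resistivity: float = 5.0  # ohm m^2
    axial_resistivity: float = 1.0  # ohm m
    leak_reversal: float = -65.0  # mV
    channels: list[tuple[str, float]] = field(default_factory=list)  # (name, S/m^2)
    has_calcium: bool = False
    calcium: CalciumPool = field(default_factory=CalciumPool)

    @property
    def area(self) -> float:
        """Membrane area in um^2 (open cylinder)."""
        return math.pi * self.length * self.diameter


@dataclass
class CableModel:
    """A tree of compartments; index 0 must be the soma (root)."""

    compartments: list[Compartment]
    soma_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for i, c in enumerate(self.compartments):
            if i == 0:
                if c.parent != -1:
                    raise ValueError("compartment 0 must be the root")
            elif not (0 <= c.parent < i):
                raise ValueError(
                    "compartments must be in topological order (parent < child)"
                )

    @property
    def n_comp(self) -> int:
        return len(self.compartments)


# ---------------------------------------------------------------------------
# batched integrator
# ---------------------------------------------------------------------------

_V_TAB_MIN, _V_TAB_MAX, _V_TAB_N = -130.0, 90.0, 4401


class _BoundChannel:
    """A channel bound to a set of (flattened) compartments of a group."""

    def __init__(self, spec: ChannelSpec, comp_sel: np.ndarray, gbar: np.ndarray,
                 ncell: int, ncomp: int, pool_sel: Optional[np.ndarray],
                 n_pools_per_cell: int = 0):
        self.spec = spec
        self.ncs = len(comp_sel)
        cells = np.arange(ncell, dtype=np.int64)[:, None]
        self.flat_idx = (cells * ncomp + comp_sel[None, :]).ravel()
        self.gbar = np.tile(np.asarray(gbar, float), ncell)
        self.states: list[np.ndarray] = []
        self.tables: list[tuple[np.ndarray, np.ndarray]] = []  # (inf, decay)
        if pool_sel is not None:
            self.ca_idx = (cells * n_pools_per_cell + pool_sel[None, :]).ravel()
        else:
            if spec.feeds_ca or spec.ca_half is not None:
                raise ValueError(f"{spec.name} needs a calcium pool")
            self.ca_idx = np.zeros(0, dtype=np.int64)


class CableGroup:
    """N cells of identical topology, integrated as one batch.

    Leak reversals may vary per cell (population heterogeneity); geometry and
    channel densities are shared.  ``theta`` selects the implicit voltage
    scheme: 0.5 (default) is the trapezoid / Crank-Nicolson rule, 1.0 is
    backward Euler.
    """

    theta = 0.5

    def __init__(self, model: CableModel, ncell: int = 1,
                 leak_reversal_offsets: Optional[np.ndarray] = None):
        self.model = model
        comps = model.compartments
        self.ncell = ncell
        self.ncomp = C = len(comps)
        self.parent = np.array([c.parent for c in comps], dtype=np.int32)

        area_m2 = np.array([c.area * 1e-12 for c in comps])
        self.cm = np.array([c.specific_capacitance for c in comps]) * area_m2 * 1e9
        self.gleak = area_m2 / np.array([c.membrane_resistivity for c in comps]) * 1e6
        el = np.array([c.leak_reversal for c in comps])
        self.el = np.tile(el, (ncell, 1))
        if leak_reversal_offsets is not None:
            self.el += np.asarray(leak_reversal_offsets, float)[:, None]

        # axial coupling to parent: 1/(Ra_half(child)+Ra_half(parent)), uS
        def half_ra(c: Compartment) -> float:  # MOhm
            return c.axial_resistivity * (c.length / 2.0) / (
                math.pi * (c.diameter / 2.0) ** 2
            )

        self.off = np.zeros(C)
        for i in range(1, C):
            self.off[i] = 1.0 / (half_ra(comps[i]) + half_ra(comps[self.parent[i]]))

        self.ax_diag = np.zeros(C)
        for i in range(1, C):
            self.ax_diag[i] += self.off[i]
            self.ax_diag[self.parent[i]] += self.off[i]

        # calcium pools: one per flagged compartment
        pool_comps = np.array([i for i, c in enumerate(comps) if c.has_calcium],
                              dtype=np.int64)
        self.pool_comps = pool_comps
        npp = len(pool_comps)
        self.n_pools = npp * ncell
        if npp:
            p0 = comps[pool_comps[0]].calcium
            self.ca = np.full(self.n_pools, p0.baseline)
            self.ca_base = np.tile(
                np.array([comps[i].calcium.baseline for i in pool_comps]), ncell)
            self.ca_B = np.tile(
                np.array([comps[i].calcium.influx_scale for i in pool_comps]), ncell)
            self.ca_tau = np.tile(
                np.array([comps[i].calcium.decay_time for i in pool_comps]), ncell)
            sel = np.full(C, -1, dtype=np.int64)
            sel[pool_comps] = np.arange(npp)
        else:
            self.ca = np.zeros(0)
        # map comp -> pool index (per cell), for channels
        self._pool_of_comp = {int(c): j for j, c in enumerate(pool_comps)}

        # bind channels, one binding per channel name (densities vary per comp)
        chan_place: dict[str, list[tuple[int, float]]] = {}
        for i, c in enumerate(comps):
            for name, dens in c.channels:
                chan_place.setdefault(name, []).append((i, dens))
        self.channels: list[_BoundChannel] = []
        for name, placements in chan_place.items():
            spec = get_channel(name)
            comp_list = [i for i, _ in placements]
            csel = np.array(comp_list, dtype=np.int64)
            dens_arr = np.array([d for _, d in placements])
            gbar = dens_arr * area_m2[csel] * 1e6  # S -> uS
            if spec.feeds_ca or spec.ca_half is not None:
                psel = np.array([self._pool_of_comp[int(i)] for i in comp_list],
                                dtype=np.int64)
            else:
                psel = None
            bc = _BoundChannel(spec, csel, gbar, ncell, C, psel, len(pool_comps))
            self.channels.append(bc)

        self.v = np.tile(el, (ncell, 1))
        self._tables_dt = None
        self._pack_channels()
        self._init_states()

    # -- packed channel layout for the fused kernel ----------------------
    def _pack_channels(self):
        nch = len(self.channels)
        max_g = max([len(bc.spec.gates) for bc in self.channels] + [1])
        counts = [len(bc.flat_idx) for bc in self.channels]
        self._ch_start = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(
            np.int64) if nch else np.zeros(0, np.int64)
        self._ch_end = np.cumsum(counts).astype(np.int64) if nch else \
            np.zeros(0, np.int64)
        self._ch_ngates = np.array([len(bc.spec.gates) for bc in self.channels],
                                   dtype=np.int64)
        self._ch_exp = np.zeros((max(nch, 1), max_g), dtype=np.int64)
        self._ch_erev = np.array([bc.spec.reversal for bc in self.channels])
        self._ch_kd = np.array([bc.spec.ca_half if bc.spec.ca_half else -1.0
                                for bc in self.channels])
        self._ch_feeds = np.array([bc.spec.feeds_ca for bc in self.channels],
                                  dtype=np.bool_)
        self._ch_gate_tab = np.zeros((max(nch, 1), max_g), dtype=np.int64)
        tab = 0
        for c, bc in enumerate(self.channels):
            for gi, g in enumerate(bc.spec.gates):
                self._ch_exp[c, gi] = g.exponent
                self._ch_gate_tab[c, gi] = tab
                tab += 1
        self._n_tabs = max(tab, 1)
        self._ent_comp = np.concatenate(
            [bc.flat_idx for bc in self.channels]) if nch else \
            np.zeros(0, np.int64)
        self._ent_gbar = np.concatenate(
            [bc.gbar for bc in self.channels]) if nch else np.zeros(0)
        self._ent_ca = np.concatenate(
            [bc.ca_idx if len(bc.ca_idx) else np.zeros(len(bc.flat_idx),
                                                       dtype=np.int64)
             for bc in self.channels]) if nch else np.zeros(0, np.int64)
        self._states = np.zeros((len(self._ent_comp), max_g))
        self._max_g = max_g

    # -- state ----------------------------------------------------------
    def _init_states(self):
        vflat = self.v.ravel()
        for c, bc in enumerate(self.channels):
            a, b = self._ch_start[c], self._ch_end[c]
            for gi, g in enumerate(bc.spec.gates):
                inf, _ = evaluate_gate(g, vflat[bc.flat_idx])
                self._states[a:b, gi] = inf

    def set_voltage(self, v0: float):
        self.v[:] = v0
        self._init_states()

    def reset(self):
        """Return to the initial condition: leak-reversal voltages,
        steady-state gates, baseline calcium."""
        self.v = self.el.copy()
        self._init_states()
        if self.n_pools:
            self.ca = self.ca_base.copy()

    def build_tables(self, dt: float):
        """(Re)build gate lookup tables embedding exp(-dt/tau)."""
        if self._tables_dt == dt:
            return
        vgrid = np.linspace(_V_TAB_MIN, _V_TAB_MAX, _V_TAB_N)
        self._inf_tabs = np.zeros((self._n_tabs, _V_TAB_N))
        self._dec_tabs = np.ones((self._n_tabs, _V_TAB_N))
        for c, bc in enumerate(self.channels):
            for gi, g in enumerate(bc.spec.gates):
                ti = self._ch_gate_tab[c, gi]
                inf, tau = evaluate_gate(g, vgrid)
                self._inf_tabs[ti] = inf
                self._dec_tabs[ti] = np.exp(-dt / np.maximum(tau, 1e-6))
        self._tables_dt = dt
        self._inv_dv = (_V_TAB_N - 1) / (_V_TAB_MAX - _V_TAB_MIN)

    # -- one implicit step ----------------------------------------------
    def step(self, dt: float, i_inj: Optional[np.ndarray] = None,
             g_syn: Optional[np.ndarray] = None,
             ge_syn: Optional[np.ndarray] = None) -> np.ndarray:
        """Advance by dt. i_inj (nA), g_syn (uS), ge_syn (uS*mV) are flat
        (ncell*ncomp) accumulators supplied by the caller; returns the new
        voltage array of shape (ncell, ncomp)."""
        if self._tables_dt != dt:
            self.build_tables(dt)
        vflat = self.v.ravel()
        n = vflat.shape[0]
        G = np.zeros(n)
        GE = np.zeros(n)
        i_ca = np.zeros(max(self.n_pools, 1))

        if len(self.channels):
            channel_step(vflat, G, GE, i_ca,
                         self._ch_start, self._ch_end, self._ch_ngates,
                         self._ch_gate_tab, self._ch_exp, self._ch_erev,
                         self._ch_kd, self._ch_feeds,
                         self._ent_comp, self._ent_gbar, self._ent_ca,
                         self._states,
                         self.ca if self.n_pools else np.zeros(1),
                         self._inf_tabs, self._dec_tabs, _V_TAB_MIN,
                         self._inv_dv)

        if g_syn is not None:
            G += g_syn
            GE += ge_syn

        if not hasattr(self, "_zero_inj") or self._zero_inj.shape != self.v.shape:
            self._zero_inj = np.zeros_like(self.v)
        if i_inj is None:
            inj = self._zero_inj
        else:
            inj = np.ascontiguousarray(i_inj.reshape(self.ncell, self.ncomp))
        implicit_update(self.parent, self.off, self.ax_diag, self.cm / dt,
                        self.gleak, self.el, self.v, G, GE, inj, self.theta)

        if self.n_pools:
            target = self.ca_base + self.ca_B * i_ca[: self.n_pools] * self.ca_tau
            dec = np.exp(-dt / self.ca_tau)
            self.ca = np.maximum(target + (self.ca - target) * dec, 0.0)
        return self.v


class IntegrationError(RuntimeError):
    pass


def simulate_group(group: CableGroup, dt: float, duration: float,
                   i_inj=None, record: Sequence[int] = (0,),
                   record_every: int = 1, spike_threshold: float = 0.0,
                   refractory: float = 1.0, on_step=None):
    """Integrate a cell batch; return (times, traces, spikes_per_cell).

    i_inj may be None, a static (ncell, ncomp) array, or a callable
    ``t -> (ncell, ncomp)`` of injected currents in nA.  ``on_step(t, group)``
    may return (g_syn, ge_syn) flat synaptic accumulators.  Spikes are upward
    crossings of ``spike_threshold`` at the soma, with a refractory dead time
    per cell.  traces has shape (ntimes, ncell, len(record)).
    """
    group.build_tables(dt)
    soma = group.model.soma_index
    nstep = int(round(duration / dt))
    record = list(record)
    nrec = nstep // record_every + 1
    traces = np.empty((nrec, group.ncell, len(record)))
    times = np.empty(nrec)
    traces[0] = group.v[:, record]
    times[0] = 0.0
    spikes: list[list[float]] = [[] for _ in range(group.ncell)]
    last_spike = np.full(group.ncell, -np.inf)
    v_prev = group.v[:, soma].copy()
    static_inj = i_inj if isinstance(i_inj, np.ndarray) else None
    k = 1
    for s in range(1, nstep + 1):
        t = s * dt
        inj = static_inj if static_inj is not None else (
            i_inj(t) if i_inj is not None else None)
        gsyn = gesyn = None
        if on_step is not None:
            out = on_step(t, group)
            if out is not None:
                gsyn, gesyn = out
        v = group.step(dt, i_inj=inj, g_syn=gsyn, ge_syn=gesyn)
        vs = v[:, soma]
        if not np.all(np.isfinite(vs)) or np.any(np.abs(vs) > 500.0):
            bad = int(np.argmax(~np.isfinite(vs) | (np.abs(vs) > 500.0)))
            raise IntegrationError(
                f"voltage diverged at t={t:.3f} ms (cell {bad}, compartment "
                f"{group.model.compartments[soma].label})"
            )
        fired = (vs >= spike_threshold) & (v_prev < spike_threshold) & \
                ((t - last_spike) > refractory)
        for c in np.nonzero(fired)[0]:
            spikes[int(c)].append(t)
            last_spike[c] = t
        v_prev[:] = vs
        if s % record_every == 0 and k < nrec:
            traces[k] = v[:, record]
            times[k] = t
            k += 1
    return times[:k], traces[:k], [np.array(s) for s in spikes]


def integrate(model: CableModel, dt: float = 0.025, duration: float = 100.0,
              i_inj: Optional[Callable[[float], np.ndarray]] = None,
              record: Sequence[int] = (0,), record_every: int = 1,
              spike_threshold: float = 0.0, refractory: float = 1.0):
    """Integrate a single cell and return (times, traces, spike_times).

    i_inj(t) returns per-compartment injected current (nA) at time t (ms).
    Spikes are upward crossings of ``spike_threshold`` at the soma with a
    ``refractory`` ms dead time for event emission.
    """
    group = CableGroup(model, ncell=1)
    fn = None
    if i_inj is not None:
        fn = lambda t: np.asarray(i_inj(t), dtype=float)[None, :]
    times, traces, spikes = simulate_group(
        group, dt, duration, i_inj=fn, record=record,
        record_every=record_every, spike_threshold=spike_threshold,
        refractory=refractory)
    return times, traces[:, 0, :], spikes[0]
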