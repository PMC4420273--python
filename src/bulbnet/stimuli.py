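"""Synthetic ORN drive: kernels, pulse trains, respiration and spike trains.

ORN firing rates are built by convolving odor-concentration and air-flow
time series with per-glomerulus linear kernels (Gaussians in time,
pre-multiplied so they start from zero), adding a constant 0.5 Hz baseline,
and optionally applying a logistic output non-linearity.  Spikes are
inhomogeneous Poisson with a 1 ms refractory period.

Conventions: the time grid is 1 ms; concentration is normalized so that
1.0 == 1% saturated vapor; the respiration waveform (period 0.5 s,
half-rectified) is normalized to unit peak.  Kernel amplitudes are
calibrated so that steady-state respiration-convolved peaks land in the
printed ranges (air 0.8-3 Hz, odor 2.4-9 Hz at 1% saturated vapor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

DT_MS = 1.0  # stimulus time grid
RESP_PERIOD_MS = 500.0  # anesthetized respiration period T = 0.5 s
BASELINE_HZ = 0.5

KERNEL_TP_RANGE = (150.0, 350.0)  # ms, latency to peak
KERNEL_SIGMA_RANGE = (250.0, 450.0)  # ms, width
AIR_PEAK_RANGE = (0.8, 3.0)  # Hz after respiration convolution
ODOR_PEAK_RANGE = (2.4, 9.0)  # Hz at 1% saturated vapor

VALVE_TAU_MS = 40.0  # odor valve opening/closing time constant
MSEQ_BITS = 7  # maximal-length sequence of a 3-stage LFSR
PULSE_MS = 50.0

LOGISTIC_MAX = 18.0  # Hz
LOGISTIC_MID = 7.2  # Hz
LOGISTIC_STEEPNESS = 1.0  # Hz


# ---------------------------------------------------------------------------
# respiration waveform
# ---------------------------------------------------------------------------


def _dualexp(t, tau1, tau2):
    t = np.asarray(t, dtype=float)
    return (np.exp(-t / tau1) - np.exp(-t / tau2)) / (tau1 - tau2)


def respiration(t, period: float = RESP_PERIOD_MS, rectify: bool = True):
    """Respiratory air-flow waveform (arbitrary units), periodic in t (ms).

    Three dual-exponential terms with coefficients (0.6, 0.5, -0.1); the
    third acts on (T - t).  Half-rectified (expiration carries no odor).
    """
    t = np.mod(np.asarray(t, dtype=float), period)
    T = period
    out = (0.6 * _dualexp(t, 0.06 * T, 0.05 * T)
           + 0.5 * _dualexp(t, 0.3 * T, 0.1 * T)
           - 0.1 * _dualexp(T - t, 0.03 * T, 0.025 * T))
    if rectify:
        out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out


def respiration_cycle(period: float = RESP_PERIOD_MS,
                      normalize: bool = True) -> np.ndarray:
    """One period of the (rectified) respiration waveform on the 1 ms grid."""
    t = np.arange(0.0, period, DT_MS)
    w = respiration(t, period)
    if normalize:
        w = w / w.max()
    return w


# ---------------------------------------------------------------------------
# ORN kernels
# ---------------------------------------------------------------------------


@dataclass
class ORNKernel:
    """Gaussian-in-time linear kernel, zero at t=0 and peaking at t_p.

    k(t) = k_p (t/t_p)^(t_p/(2 sigma_p)) exp(-(t - t_p)^2 / (2 sigma_p^2)).
    ``mixed`` kernels subtract a second, time-displaced Gaussian lobe
    (excitatory + inhibitory components).
    """

    k_p: float
    t_p: float  # ms
    sigma_p: float  # ms
    polarity: str = "excitatory"  # or "mixed"
    inhib_weight: float = 0.0
    inhib_shift: float = 0.0  # ms, displacement of the inhibitory Gaussian
    kind: str = "odor"  # or "air"

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = _gauss_lobe(t, self.k_p, self.t_p, self.sigma_p)
        if self.polarity == "mixed" and self.inhib_weight:
            out = out - _gauss_lobe(t, self.inhib_weight * self.k_p,
                                    self.t_p + self.inhib_shift, self.sigma_p)
        return out

    def sample(self, duration: float = 2500.0) -> np.ndarray:
        """Kernel values on the 1 ms grid over ``duration`` ms."""
        return self(np.arange(0.0, duration, DT_MS))


def _gauss_lobe(t, kp, tp, sp):
    t = np.asarray(t, dtype=float)
    tc = np.maximum(t, 0.0)
    with np.errstate(divide="ignore"):
        prefac = np.where(tc > 0, (tc / tp) ** (tp / (2.0 * sp)), 0.0)
    return kp * prefac * np.exp(-((tc - tp) ** 2) / (2.0 * sp ** 2))


def convolve_rate(series: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Discrete convolution on the 1 ms grid: (series * kernel) dt, dt in s.

    With normalized stimulus series and kernel amplitudes calibrated by
    :func:`make_orn_kernel`, the result is a firing rate in Hz.
    """
    full = np.convolve(series, kernel)[: len(series)]
    return full * (DT_MS / 1000.0)


def steady_cycle_peak(kernel: ORNKernel, n_cycles: int = 8) -> float:
    """Peak of the kernel convolved with steady periodic respiration."""
    resp = np.tile(respiration_cycle(), n_cycles)
    out = convolve_rate(resp, kernel.sample())
    last = out[-int(RESP_PERIOD_MS / DT_MS):]
    return float(last.max())


def make_orn_kernel(kind: str, rng: np.random.Generator,
                    polarity: str = "excitatory") -> ORNKernel:
    """Draw a random ORN kernel for ``kind`` in {'air', 'odor'}.

    t_p ~ U(150, 350) ms, sigma_p ~ U(250, 450) ms; the amplitude is scaled
    so the steady-state peak after convolution with the respiration waveform
    is uniform in 0.8-3 Hz (air) or 2.4-9 Hz (odor, at 1% saturated vapor).
    """
    lo, hi = {"air": AIR_PEAK_RANGE, "odor": ODOR_PEAK_RANGE}[kind]
    tp = rng.uniform(*KERNEL_TP_RANGE)
    sp = rng.uniform(*KERNEL_SIGMA_RANGE)
    kern = ORNKernel(1.0, tp, sp, polarity=polarity, kind=kind)
    if polarity == "mixed":
        kern.inhib_weight = rng.uniform(0.3, 0.7)
        kern.inhib_shift = rng.uniform(100.0, 300.0)
    target = rng.uniform(lo, hi)
    peak = steady_cycle_peak(kern)
    kern.k_p = target / peak
    return kern


# ---------------------------------------------------------------------------
# odor concentration / air flow series
# ---------------------------------------------------------------------------


def msequence_bits(rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """7-bit maximal-length sequence from the 3-stage LFSR x^3 + x^2 + 1.

    A seeded rng rotates the starting phase (different pulse trains share
    the same spectrum); without an rng the canonical phase 1110100 is used.
    """
    bits = np.array([1, 1, 1, 0, 1, 0, 0], dtype=float)  # LFSR output cycle
    if rng is not None:
        bits = np.roll(bits, rng.integers(0, 7))
    return bits


def valve_filter(series: np.ndarray, tau: float = VALVE_TAU_MS) -> np.ndarray:
    """First-order valve dynamics: convolution with (1/tau) exp(-t/tau),
    normalized so a sustained opening reaches the commanded level."""
    t = np.arange(0.0, 10.0 * tau, DT_MS)
    kern = np.exp(-t / tau)
    kern /= kern.sum()
    return np.convolve(series, kern)[: len(series)]


def msequence_concentration(peak_conc: float, rng: np.random.Generator,
                            n_repeats: int = 6,
                            lead_ms: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """(odor concentration series, air pedestal series) for the
    tracheotomized random pulse-train protocol.

    Binary m-sequence bits gate 50 ms pulses (full 7-bit sequence 350 ms),
    repeated ``n_repeats`` times, filtered by the 40 ms valve time constant
    and scaled to ``peak_conc`` (1.0 == 1% saturated vapor).  The air
    pedestal is constant at one third of the respiration peak (which is
    normalized to 1), matching the reduced tracheotomized flow rate.
    """
    if peak_conc < 0:
        raise ValueError("peak_conc must be non-negative")
    bits = msequence_bits(rng)
    per_bit = int(PULSE_MS / DT_MS)
    gate = np.repeat(np.tile(bits, n_repeats), per_bit)
    if lead_ms > 0:
        gate = np.concatenate([np.zeros(int(lead_ms / DT_MS)), gate])
    conc = valve_filter(gate) * peak_conc
    air = np.full_like(conc, 1.0 / 3.0)
    return conc, air


def single_pulse_concentration(peak_conc: float, pulse_ms: float = 200.0,
                               lead_ms: float = 200.0,
                               duration_ms: float = 2200.0
                               ) -> tuple[np.ndarray, np.ndarray]:
    """(odor, air) series for the scaled-pulse protocol: one valve-filtered
    pulse of ``pulse_ms`` on the constant air pedestal."""
    n = int(duration_ms / DT_MS)
    gate = np.zeros(n)
    i0 = int(lead_ms / DT_MS)
    gate[i0: i0 + int(pulse_ms / DT_MS)] = 1.0
    conc = valve_filter(gate) * peak_conc
    air = np.full(n, 1.0 / 3.0)
    return conc, air


def respiration_series(n_cycles: int, scale: float = 1.0) -> np.ndarray:
    """``n_cycles`` of the unit-peak rectified respiration waveform."""
    return np.tile(respiration_cycle(), n_cycles) * scale


# ---------------------------------------------------------------------------
# rates and spikes
# ---------------------------------------------------------------------------


@dataclass
class RateSeries:
    """An ORN firing-rate waveform on the 1 ms grid."""

    rate: np.ndarray  # Hz, >= 0
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.rate) * DT_MS


def logistic_nonlinearity(rate):
    """ORN output non-linearity: 18 / (1 + exp(-(r - 7.2))) Hz."""
    rate = np.asarray(rate, dtype=float)
    out = LOGISTIC_MAX / (1.0 + np.exp(-(rate - LOGISTIC_MID) / LOGISTIC_STEEPNESS))
    return float(out) if out.ndim == 0 else out


def rate_from_stimulus(odor_series, air_series, odor_kernel: ORNKernel,
                       air_kernel: ORNKernel,
                       nonlinearity: str = "none") -> RateSeries:
    """ORN firing rate: odor x odor-kernel + air x air-kernel + 0.5 Hz,
    optionally passed through the logistic non-linearity, floored at 0."""
    odor_series = np.asarray(odor_series, dtype=float)
    air_series = np.asarray(air_series, dtype=float)
    if odor_series.shape != air_series.shape:
        raise ValueError("odor and air series must share a time base")
    r = (convolve_rate(odor_series, odor_kernel.sample())
         + convolve_rate(air_series, air_kernel.sample())
         + BASELINE_HZ)
    if nonlinearity == "logistic":
        r = logistic_nonlinearity(r)
    elif nonlinearity != "none":
        raise ValueError(f"unknown nonlinearity {nonlinearity!r}")
    return RateSeries(np.maximum(r, 0.0))


def poisson_spikes(rate, n_trains: int, rng: np.random.Generator,
                   refractory: float = 1.0) -> list[np.ndarray]:
    """Inhomogeneous Poisson spike trains with a dead time (default 1 ms).

    ``rate`` is a RateSeries or an array on the 1 ms grid.  Each train is an
    independent realization (thinning of a homogeneous process at the peak
    rate, then dead-time enforcement).
    """
    r = rate.rate if isinstance(rate, RateSeries) else np.asarray(rate, float)
    if np.any(r < 0):
        raise ValueError("rates must be non-negative")
    dur = len(r) * DT_MS
    rmax = float(r.max())
    trains = []
    if rmax <= 0:
        return [np.zeros(0) for _ in range(n_trains)]
    lam = rmax / 1000.0  # per ms
    for _ in range(n_trains):
        n_exp = int(lam * dur + 6 * math.sqrt(lam * dur) + 20)
        gaps = rng.exponential(1.0 / lam, size=n_exp)
        cand = np.cumsum(gaps)
        while cand.size and cand[-1] < dur:
            more = np.cumsum(rng.exponential(1.0 / lam, size=n_exp)) + cand[-1]
            cand = np.concatenate([cand, more])
        cand = cand[cand < dur]
        keep = rng.random(cand.size) < r[np.minimum(
            (cand / DT_MS).astype(int), len(r) - 1)] / rmax
        cand = cand[keep]
        # dead time: drop spikes closer than `refractory` to the last kept
        out = []
        last = -np.inf
        for t in cand:
            if t - last >= refractory:
                out.append(t)
                last = t
        trains.append(np.array(out))
    return trains


def background_trains(context: str, n_cells: int, duration: float,
                      rng: np.random.Generator,
                      modulation_depth: float = 0.5) -> list[np.ndarray]:
    """Granule-cell background input trains (proxy for unmodeled mitral cells).

    ``in_vitro``: constant 3.45 Hz Poisson.  ``in_vivo``: 35 Hz mean,
    modulated by the respiration waveform (depth 0.5 of the mean by default;
    the cycle average stays 35 Hz).
    """
    n_bins = int(duration / DT_MS)
    if context == "in_vitro":
        r = np.full(n_bins, 3.45)
    elif context == "in_vivo":
        cyc = respiration_cycle()
        mod = cyc / cyc.mean()
        wave = np.tile(mod, n_bins // len(cyc) + 1)[:n_bins]
        r = 35.0 * ((1.0 - modulation_depth) + modulation_depth * wave)
        # compensate the 1 ms dead time so the realized mean stays 35 Hz
        r = r / np.maximum(1.0 - r * 1e-3, 0.5)
    else:
        raise ValueError(f"unknown context {context!r}")
    return poisson_spikes(r, n_cells, rng)
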