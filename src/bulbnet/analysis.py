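"""Odor-coding statistics: linear-kernel fits, residual/noise, phase and
delta-rate decorrelation, odor-morph fits and scaled-pulse metrics.

Conventions follow the replicated experiments: mitral responses are binned
firing rates (50 ms bins for pulse trains, 5 bins per 0.5 s respiration
cycle for phase analysis); fitted odor kernels are 2 s long, discretized at
50 ms (40 taps); goodness of fit is residual/noise, the mean squared
deviation of the fit or prediction from the trial-averaged data divided by
the mean across-trial variance (SD-based), with values below 1 deemed
acceptable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

KERNEL_BIN_MS = 50.0
KERNEL_TAPS = 40  # 2 s kernel at 50 ms
MORPH_SIGMOID_GAIN = 4.39


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


@dataclass
class FitQuality:
    residual: float  # mean squared deviation of fit from trial mean
    noise: float  # mean across-trial variance (SD^2, ddof=1)
    ratio: float  # residual / noise; inf sentinel when noise == 0

    @property
    def acceptable(self) -> bool:
        return self.ratio < 1.0


def residual_over_noise(prediction: np.ndarray,
                        trials: np.ndarray) -> FitQuality:
    """residual/noise of a fit or prediction against per-trial data.

    ``trials`` has shape (n_trials, n_bins); at least two trials are needed
    to estimate noise.  Identical trials with an imperfect prediction give
    an infinite ratio (flagged sentinel, not an exception), so population
    histograms can pool high values into their last bin.
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 2 or trials.shape[0] < 2:
        raise ValueError("need >= 2 trials to estimate noise")
    prediction = np.asarray(prediction, dtype=float)
    mean = trials.mean(axis=0)
    residual = float(np.mean((prediction - mean) ** 2))
    noise = float(np.mean(trials.var(axis=0, ddof=1)))
    ratio = residual / noise if noise > 0 else (0.0 if residual == 0
                                                else math.inf)
    return FitQuality(residual, noise, ratio)


# ---------------------------------------------------------------------------
# linear-kernel fitting and prediction
# ---------------------------------------------------------------------------


@dataclass
class KernelFit:
    kernel: np.ndarray  # (n_taps,) on the 50 ms grid
    baseline: float  # fitted constant (air background)
    quality: FitQuality
    rank_deficient: bool = False


def bin_series(series_ms: np.ndarray, bin_ms: float = KERNEL_BIN_MS
               ) -> np.ndarray:
    """Average a 1 ms-grid series into bins."""
    n = int(len(series_ms) // bin_ms)
    return np.asarray(series_ms, float)[: int(n * bin_ms)].reshape(
        n, int(bin_ms)).mean(axis=1)


def _design(conc_binned: np.ndarray, n_taps: int) -> np.ndarray:
    """Causal convolution (Toeplitz) design matrix: X[t, k] = c[t - k]."""
    n = len(conc_binned)
    X = np.zeros((n, n_taps))
    for k in range(min(n_taps, n)):
        X[k:, k] = conc_binned[: n - k]
    return X


def fit_linear_kernel(responses: Sequence[np.ndarray],
                      concentrations: Sequence[np.ndarray],
                      n_taps: int = KERNEL_TAPS,
                      air_baseline: Optional[float] = None,
                      trials: Optional[np.ndarray] = None) -> KernelFit:
    """Least-squares odor kernel from one or more pulse-train responses.

    ``responses``: trial-averaged binned rates, one per stimulus (the two
    random pulse trains per odor are fitted jointly on a stacked design);
    ``concentrations``: matching binned concentration series.  If
    ``air_baseline`` is given it is subtracted and no constant is fitted;
    otherwise a constant column absorbs the air background.  In-sample
    residual/noise is computed when per-trial data is supplied.
    """
    ys, Xs = [], []
    for y, c in zip(responses, concentrations):
        y = np.asarray(y, float)
        c = np.asarray(c, float)
        n = min(len(y), len(c))
        ys.append(y[:n] - (air_baseline or 0.0))
        Xs.append(_design(c[:n], n_taps))
    y = np.concatenate(ys)
    X = np.vstack(Xs)
    if air_baseline is None:
        X = np.column_stack([X, np.ones(len(y))])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    kernel = coef[:n_taps]
    baseline = float(coef[n_taps]) if air_baseline is None else float(air_baseline)
    fitted = X @ coef
    quality = FitQuality(float(np.mean((fitted - y) ** 2)), math.nan, math.nan)
    if trials is not None:
        pred_first = Xs[0] @ coef if air_baseline is None else \
            Xs[0] @ coef + air_baseline
        quality = residual_over_noise(pred_first + (air_baseline or 0.0)
                                      if air_baseline is None else pred_first,
                                      trials)
    return KernelFit(kernel, baseline, quality,
                     rank_deficient=rank < X.shape[1])


def predict_response(fit: KernelFit, conc_binned: np.ndarray,
                     rectify: bool = True) -> np.ndarray:
    """kernel (x) concentration + baseline, rectified at 0 for rates."""
    out = _design(np.asarray(conc_binned, float), len(fit.kernel)) @ fit.kernel \
        + fit.baseline
    return np.maximum(out, 0.0) if rectify else out


def predict_two_odor(fit_a: KernelFit, fit_b: KernelFit,
                     conc_a: np.ndarray, conc_b: np.ndarray,
                     baseline: Optional[float] = None) -> np.ndarray:
    """Rectified sum of the two fitted kernels' convolutions."""
    if len(conc_a) != len(conc_b):
        raise ValueError("concentration series must share a grid")
    base = baseline if baseline is not None else \
        0.5 * (fit_a.baseline + fit_b.baseline)
    out = (_design(np.asarray(conc_a, float), len(fit_a.kernel)) @ fit_a.kernel
           + _design(np.asarray(conc_b, float), len(fit_b.kernel)) @ fit_b.kernel
           + base)
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# phase / delta-rate decorrelation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationReport:
    phase_air: list = field(default_factory=list)
    phase_odor: list = field(default_factory=list)
    delta_rate_corr: float = math.nan
    excluded: int = 0


def phase_correlation(sister_a: np.ndarray, sister_b: np.ndarray):
    """Pearson r between the sisters' single-cycle binned odor responses.

    Returns None (excluded) when either response is all-zero or has zero
    variance, following the 'neglecting zero responses' convention.
    """
    a = np.asarray(sister_a, float)
    b = np.asarray(sister_b, float)
    if not a.any() or not b.any() or a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def delta_rate_correlation(delta_a: Sequence[float],
                           delta_b: Sequence[float]) -> float:
    """Pearson r between the sisters' odor-minus-air mean-rate vectors,
    strung across every odor x network instance."""
    a = np.asarray(delta_a, float)
    b = np.asarray(delta_b, float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need >= 2 matched instance x odor entries")
    return float(np.corrcoef(a, b)[0, 1])


def delta_rate_correlation_corrected(runs: Sequence[dict]) -> dict:
    """Delta-rate correlation with a split-half attenuation correction.

    At reduced trial counts the plain estimator is biased toward zero by
    independent per-sister trial noise.  The correction estimates each
    sister's delta-rate reliability from a split-half correlation across
    trials (Spearman-Brown) and divides the raw cross-sister correlation by
    the geometric mean reliability, recovering the full-scale statistic.
    Returns {"raw": r, "corrected": r_c, "reliability": (rel_a, rel_b)}.
    """
    full_a, full_b = [], []
    half = {0: ([], []), 1: ([], [])}
    for run in runs:
        resp = run["responses"]
        air_means = resp["air"].mean(axis=(0, 2))  # per sister
        for odor in [k for k in resp if k != "air"]:
            arr = resp[odor]  # (trial, sister, bin)
            od_means = arr.mean(axis=(0, 2))
            full_a.append(od_means[0] - air_means[0])
            full_b.append(od_means[1] - air_means[1])
            for h in (0, 1):
                sel = arr[h::2].mean(axis=(0, 2))
                half[h][0].append(sel[0] - air_means[0])
                half[h][1].append(sel[1] - air_means[1])

    def rel(sister):
        r = np.corrcoef(half[0][sister], half[1][sister])[0, 1]
        r = max(min(r, 0.999), -0.999)
        sb = 2 * r / (1 + r)  # Spearman-Brown step-up to the full mean
        return max(sb, 0.05)

    raw = float(np.corrcoef(full_a, full_b)[0, 1])
    rel_a, rel_b = rel(0), rel(1)
    corrected = raw / math.sqrt(rel_a * rel_b)
    corrected = max(min(corrected, 1.0), -1.0)
    return {"raw": raw, "corrected": corrected,
            "reliability": (rel_a, rel_b)}


def decorrelation_report(runs: Sequence[dict]) -> CorrelationReport:
    """Pool phase and delta-rate statistics over freely-breathing runs.

    ``runs``: outputs of protocols.run_freely_breathing (one per network
    instance), each with per-condition arrays (trial, sister, bin).
    """
    rep = CorrelationReport()
    d_a, d_b = [], []
    for run in runs:
        resp = run["responses"]
        air = resp["air"].mean(axis=0)  # (sister, bin)
        air_means = resp["air"].mean(axis=(0, 2))
        r = phase_correlation(air[0], air[1])
        if r is None:
            rep.excluded += 1
        else:
            rep.phase_air.append(r)
        for odor in [k for k in resp if k != "air"]:
            od = resp[odor].mean(axis=0)
            r = phase_correlation(od[0], od[1])
            if r is None:
                rep.excluded += 1
            else:
                rep.phase_odor.append(r)
            od_means = resp[odor].mean(axis=(0, 2))
            d_a.append(od_means[0] - air_means[0])
            d_b.append(od_means[1] - air_means[1])
    if len(d_a) >= 2:
        rep.delta_rate_corr = delta_rate_correlation(d_a, d_b)
    return rep


# ---------------------------------------------------------------------------
# odor-morph model
# ---------------------------------------------------------------------------


@dataclass
class MorphModel:
    F_air: np.ndarray
    F_A: np.ndarray
    F_B: np.ndarray
    r_max: float
    w_A: np.ndarray  # weights at the 4 morph concentrations of odor A
    w_B: np.ndarray
    mode: str
    quality: dict = field(default_factory=dict)
    converged: bool = True


def morph_sigmoid(x):
    """Output non-linearity exp(4.39 x) / (1 + exp(4.39 x)); f(0) = 0.5."""
    return 1.0 / (1.0 + np.exp(-MORPH_SIGMOID_GAIN * np.asarray(x, float)))


MORPH_CONCS = ((0.2, 0.8), (0.4, 0.6), (0.6, 0.4), (0.8, 0.2))


def fit_morph_model(responses: dict, mode: str = "free_weights_sigmoid",
                    n_restarts: int = 5, seed: int = 0) -> MorphModel:
    """Fit air / pure-odor / morph responses with shared 'representations'.

    ``responses``: {"air": r(t), "A": r(t), "B": r(t), (cA, cB): r(t), ...}
    with binned single-cycle rates (9 bins per 0.5 s cycle by convention).

    free_weights_sigmoid: R = r_max f(w_A F_A + w_B F_B + F_air) with f the
    printed sigmoid and 8 free weights constrained monotone in
    concentration (fitted as non-negative increments).
    linear_weights_rectifier: weights fixed at the normalized
    concentrations and a simple rectifier output.
    """
    from scipy.optimize import least_squares

    rng = np.random.default_rng(seed)
    keys = [k for k in responses if isinstance(k, tuple)]
    keys.sort()
    nb = len(np.asarray(responses["air"], float))
    y_pure = [np.asarray(responses[k], float) for k in ("air", "A", "B")]
    y_morph = [np.asarray(responses[k], float) for k in keys]
    rmax0 = max(float(np.max([y.max() for y in y_pure + y_morph])), 1.0)

    use_sigmoid = mode == "free_weights_sigmoid"
    if mode not in ("free_weights_sigmoid", "linear_weights_rectifier"):
        raise ValueError(f"unknown mode {mode!r}")

    def unpack(p):
        F_air = p[:nb]
        F_A = p[nb: 2 * nb]
        F_B = p[2 * nb: 3 * nb]
        r_max = p[3 * nb] ** 2 + 1e-6
        if use_sigmoid:
            incA = p[3 * nb + 1: 3 * nb + 5] ** 2
            incB = p[3 * nb + 5: 3 * nb + 9] ** 2
            wA = np.cumsum(incA)  # monotone non-decreasing with cA
            # cB decreases along the morph order, so wB decreases with index
            wB = np.cumsum(incB[::-1])[::-1]
        else:
            wA = np.array([c[0] for c in MORPH_CONCS])
            wB = np.array([c[1] for c in MORPH_CONCS])
        return F_air, F_A, F_B, r_max, wA, wB

    def out_fn(x, r_max):
        return r_max * (morph_sigmoid(x) if use_sigmoid else np.maximum(x, 0.0))

    def resid(p):
        F_air, F_A, F_B, r_max, wA, wB = unpack(p)
        res = [out_fn(F_air, r_max) - y_pure[0],
               out_fn(F_A, r_max) - y_pure[1],
               out_fn(F_B, r_max) - y_pure[2]]
        # morph keys are (cA, cB); map to the weight of the matching level
        ca_levels = [c[0] for c in MORPH_CONCS]
        for k, y in zip(keys, y_morph):
            i = ca_levels.index(k[0]) if k[0] in ca_levels else 0
            res.append(out_fn(wA[i] * F_A + wB[i] * F_B + F_air, r_max) - y)
        return np.concatenate(res)

    npar = 3 * nb + 1 + (8 if use_sigmoid else 0)

    def data_init():
        # invert the output non-linearity on the pure responses
        p0 = np.zeros(npar)
        r0 = rmax0 * 1.2
        for j, y in enumerate(y_pure):
            if use_sigmoid:
                frac = np.clip(y / r0, 1e-3, 1 - 1e-3)
                p0[j * nb: (j + 1) * nb] = np.log(frac / (1 - frac)) \
                    / MORPH_SIGMOID_GAIN
            else:
                p0[j * nb: (j + 1) * nb] = y / r0
        p0[3 * nb] = math.sqrt(r0)
        if use_sigmoid:
            p0[3 * nb + 1:] = math.sqrt(0.25)
        return p0

    best = None
    for r in range(n_restarts):
        if r == 0:
            p0 = data_init()
        else:
            p0 = data_init()
            p0[: 3 * nb] += rng.normal(0, 0.2, 3 * nb)
            if use_sigmoid:
                p0[3 * nb + 1:] = rng.uniform(0.2, 0.8, 8)
        sol = least_squares(resid, p0, max_nfev=6000)
        if best is None or sol.cost < best.cost:
            best = sol
    F_air, F_A, F_B, r_max, wA, wB = unpack(best.x)
    model = MorphModel(F_air, F_A, F_B, float(r_max), wA, wB, mode,
                       converged=bool(best.status > 0))
    # per-condition mean squared error
    model.quality = {"cost": float(best.cost),
                     "mse": float(np.mean(resid(best.x) ** 2))}
    return model


def morph_prediction(model: MorphModel, level: int) -> np.ndarray:
    """Model response at morph level ``level`` (index into MORPH_CONCS)."""
    x = (model.w_A[level] * model.F_A + model.w_B[level] * model.F_B
         + model.F_air)
    f = morph_sigmoid(x) if model.mode == "free_weights_sigmoid" else \
        np.maximum(x, 0.0)
    return model.r_max * f


# ---------------------------------------------------------------------------
# scaled-pulse metrics
# ---------------------------------------------------------------------------


def scaled_pulse_metrics(run: dict, reference_conc: float = 1.0) -> dict:
    """Latency and similarity metrics for the scaled-pulse protocol output.

    Per cell: normalized latency to first spike and to the response peak
    (normalized by the cell's mean across concentrations with spikes), and
    the Pearson correlation of each concentration's air-subtracted response
    with the reference (1%) response.
    """
    onset = run["onset_ms"]
    bin_ms = run["bin_ms"]
    concs = sorted(run["results"])
    n_cells = 2
    lat_spike = {c: [] for c in concs}
    lat_peak = {c: [] for c in concs}
    for c in concs:
        res = run["results"][c]
        for m in range(n_cells):
            firsts = []
            for trial in res["spikes"]:
                after = trial[m][trial[m] >= onset]
                if len(after):
                    firsts.append(after[0] - onset)
            lat_spike[c].append(np.mean(firsts) if firsts else math.nan)
            h = res["hist_minus_air"].mean(axis=0)[m]
            lat_peak[c].append((np.argmax(h) + 0.5) * bin_ms
                               if h.any() else math.nan)

    def normalize(per_conc):
        arr = np.array([[per_conc[c][m] for c in concs]
                        for m in range(n_cells)])  # (cell, conc)
        means = np.nanmean(arr, axis=1, keepdims=True)
        return {c: (arr[:, i] / means[:, 0]).tolist()
                for i, c in enumerate(concs)}

    corr = {}
    ref = run["results"][reference_conc]["hist_minus_air"].mean(axis=0)
    peaks = {}
    for c in concs:
        h = run["results"][c]["hist_minus_air"].mean(axis=0)
        rs = [phase_correlation(h[m], ref[m]) for m in range(n_cells)]
        corr[c] = [r for r in rs if r is not None]
        peaks[c] = h.max(axis=1).tolist()
    return {"normalized_latency_to_spike": normalize(lat_spike),
            "normalized_latency_to_peak": normalize(lat_peak),
            "correlation_vs_reference": corr,
            "response_peaks": peaks,
            "concs": concs}
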