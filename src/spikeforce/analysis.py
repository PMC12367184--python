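"""Quantitative comparisons of trained spiking and rate networks.

Test error and RMSE, decoder correlation and swapping, trial alignment,
cross-trial bias-variance decomposition, error-vs-size power-law fits,
return maps for chaotic outputs, and cross-network basis/principal-
component correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import argrelextrema

from .force import BasisDecomposition, ForceResult
from .netmodels import NetworkInit, NeuronParams, RecordSpec, SimTrace, run_network
from .supervisors import SupervisorSignal

__all__ = [
    "TrialStats",
    "ScalingFit",
    "l2_error",
    "rmse",
    "decoder_correlation",
    "swap_and_test",
    "align_repetitions",
    "bias_variance",
    "fit_power_law",
    "lorenz_return_map",
    "basis_correlation",
    "pc_correlation",
]


def _target_array(x, dt_s: float | None) -> tuple[np.ndarray, float]:
    if isinstance(x, SupervisorSignal):
        return x.values, x.dt
    if dt_s is None:
        raise ValueError("dt_s required when the target is a bare array")
    return np.atleast_2d(np.asarray(x, dtype=np.float64)), dt_s


def l2_error(x_hat: np.ndarray, x, dt_s: float | None = None) -> float:
    """Dimension-averaged integrated squared error.

    ``E = (1/M) sum_i integral (x_hat_i - x_i)^2 dt`` with the integral as
    a Riemann sum and dt in seconds.  Note the integral is not normalized
    by the duration, so the value scales with the test-window length.
    """
    xv, dt = _target_array(x, dt_s)
    x_hat = np.atleast_2d(np.asarray(x_hat, dtype=np.float64))
    if x_hat.shape != xv.shape:
        raise ValueError(f"shape mismatch: {x_hat.shape} vs {xv.shape}")
    return float(np.sum((x_hat - xv) ** 2) * dt / xv.shape[0])


def rmse(x_hat: np.ndarray, x, dt_s: float | None = None) -> float:
    """Root of the time-and-dimension-averaged squared error.

    Related to :func:`l2_error` by ``rmse = sqrt(l2 / T)`` on M = 1.
    """
    xv, _ = _target_array(x, dt_s if dt_s is not None else 1.0)
    x_hat = np.atleast_2d(np.asarray(x_hat, dtype=np.float64))
    if x_hat.shape != xv.shape:
        raise ValueError(f"shape mismatch: {x_hat.shape} vs {xv.shape}")
    return float(np.sqrt(np.mean((x_hat - xv) ** 2)))


def decoder_correlation(phi_R: np.ndarray, phi_S: np.ndarray) -> float:
    """Pearson correlation between two decoders over all N x M entries.

    Grand means over all entries are used (not per-column means), so the
    value is invariant to a common affine rescaling of either decoder.
    """
    a = np.asarray(phi_R, dtype=np.float64).ravel()
    b = np.asarray(phi_S, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("decoders must have equal shapes")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("decoder correlation undefined for a zero-variance decoder")
    return float(a @ b / (na * nb))


def swap_and_test(
    pair: tuple[ForceResult, ForceResult],
    init: NetworkInit,
    params: NeuronParams,
    supervisor: SupervisorSignal,
    duration_s: float,
    dt_ms: float = 0.05,
) -> dict[str, float]:
    """Exchange decoders between a trained matched pair and measure errors.

    Runs the four combinations {spiking, rate} x {phi_S, phi_R} without
    learning, each continuing from the end-of-training state of its own
    network kind, and returns the four L2 test errors keyed as
    ``"spiking+phiS"``, ``"spiking+phiR"``, ``"rate+phiR"``,
    ``"rate+phiS"``.  The supervisor clock continues from training, so a
    periodic task must have trained for a whole number of periods.
    """
    import copy

    res_s, res_r = pair
    n = int(round(duration_s * 1e3 / dt_ms))
    target = supervisor.values[:, :n]
    out = {}
    for kind, res in (("spiking", res_s), ("rate", res_r)):
        for tag, phi in (("phiS", res_s.phi), ("phiR", res_r.phi)):
            state = copy.deepcopy(res.final_state)
            trace = run_network(
                kind, init, params, phi, duration_s, dt_ms, state=state
            )
            out[f"{kind}+{tag}"] = l2_error(trace.readout, target, supervisor.dt)
    return out


def align_repetitions(
    readout: np.ndarray,
    period_s: float,
    dt_s: float,
    expected_peak_s: float,
    smooth_window_s: float | None = None,
) -> np.ndarray:
    """Segment a 1-D readout into periods and align each to its peak.

    Each period window is circularly rolled so that its maximum lands at
    ``expected_peak_s`` (for a 5 Hz sinusoid, 0.05 s into the 0.2 s
    window), undoing the slow phase drift a trained oscillator accumulates
    across repetitions.  With ``smooth_window_s`` the peak is located on a
    copy smoothed by a circular square window (used for spiking readouts,
    width 0.025 s) while the unsmoothed samples are rolled.  Rolling is a
    pure circular shift: the multiset of values in each window is
    unchanged.  Returns an ``(n_rep, K_period)`` matrix.
    """
    readout = np.asarray(readout, dtype=np.float64).ravel()
    k_per = int(round(period_s / dt_s))
    if k_per < 1 or readout.size % k_per != 0:
        raise ValueError("duration is not an integer multiple of the period")
    segments = readout.reshape(-1, k_per)
    peak_idx = int(round(expected_peak_s / dt_s)) % k_per
    if smooth_window_s:
        w = max(1, int(round(smooth_window_s / dt_s)))
        probe = uniform_filter1d(segments, size=w, axis=1, mode="wrap")
    else:
        probe = segments
    shifts = peak_idx - np.argmax(probe, axis=1)
    aligned = np.empty_like(segments)
    for i, s in enumerate(shifts):
        aligned[i] = np.roll(segments[i], s)
    return aligned


@dataclass
class TrialStats:
    """Cross-trial decomposition of a repeated output."""

    aligned_trials: np.ndarray  # (n_rep, K)
    trial_mean: np.ndarray  # (K,)
    bias_sq: float
    variance: float
    var_proportion: float
    n_rep: int


def bias_variance(
    trials: np.ndarray, x_target: np.ndarray, dt_s: float
) -> TrialStats:
    """Cross-trial bias-variance decomposition of aligned repetitions.

    ``Bias^2 = (1/T) int (mean_i xhat_i - x)^2 dt`` and ``Var = (1/n_rep)
    sum_j (1/T) int (xhat_j - mean_i xhat_i)^2 dt`` (the cross-trial
    average of per-trial deviations, which makes ``mean_j (1/T) int
    (xhat_j - x)^2 dt = Bias^2 + Var`` an exact identity).  The reported
    proportion is ``Var / (Bias^2 + Var)``.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=np.float64))
    n_rep, k = trials.shape
    if n_rep < 2:
        raise ValueError("bias-variance decomposition needs n_rep >= 2")
    x_target = np.asarray(x_target, dtype=np.float64).ravel()
    if x_target.size != k:
        raise ValueError("target length must match the trial window")
    mean = trials.mean(axis=0)
    bias_sq = float(np.mean((mean - x_target) ** 2))
    variance = float(np.mean((trials - mean) ** 2))
    total = bias_sq + variance
    prop = variance / total if total > 0 else 0.0
    return TrialStats(trials, mean, bias_sq, variance, prop, n_rep)


@dataclass
class ScalingFit:
    """Least-squares power law ``RMSE ~ N^zeta`` fitted on log10-log10 axes."""

    sizes: np.ndarray
    rmse_values: list[np.ndarray]  # per size, per repetition
    zeta: float
    intercept: float


def fit_power_law(sizes, rmse_table) -> ScalingFit:
    """Fit ``log10 RMSE = zeta * log10 N + intercept`` over all repetitions.

    ``rmse_table`` maps each size to its per-repetition RMSE values (dict,
    or a sequence aligned with ``sizes``).  Non-positive RMSE values are
    excluded with a warning.  At least 3 distinct sizes are required.
    """
    sizes = np.asarray(sorted(sizes), dtype=np.float64)
    if np.unique(sizes).size < 3:
        raise ValueError("need at least 3 distinct sizes")
    if isinstance(rmse_table, dict):
        values = [np.atleast_1d(np.asarray(rmse_table[s], dtype=np.float64))
                  for s in sizes]
    else:
        values = [np.atleast_1d(np.asarray(v, dtype=np.float64)) for v in rmse_table]
    log_n, log_e = [], []
    for s, vals in zip(sizes, values):
        bad = vals <= 0
        if bad.any():
            warnings.warn(f"excluding {bad.sum()} non-positive RMSE at N={s:g}",
                          stacklevel=2)
        good = vals[~bad]
        log_n.extend([np.log10(s)] * good.size)
        log_e.extend(np.log10(good))
    zeta, intercept = np.polyfit(log_n, log_e, 1)
    return ScalingFit(sizes, values, float(zeta), float(intercept))


def lorenz_return_map(
    z_series: np.ndarray, smooth_len: int = 21, extremum_order: int = 10000
) -> np.ndarray:
    """Successive-maximum return map of a (decoded) Lorenz z component.

    The series is smoothed by a moving-average window of ``smooth_len``
    steps, local maxima are located with a +-``extremum_order``-step
    neighbourhood test, and pairs ``(z_n, z_{n+1})`` of successive maxima
    are returned as an ``(n-1, 2)`` array.  For the chaotic attractor the
    map traces the classic unimodal tent shape.
    """
    z = np.asarray(z_series, dtype=np.float64).ravel()
    if z.size <= smooth_len:
        raise ValueError("series shorter than the smoothing window")
    smoothed = np.convolve(z, np.ones(smooth_len) / smooth_len, mode="same")
    (idx,) = argrelextrema(smoothed, np.greater, order=extremum_order)
    if idx.size < 2:
        raise ValueError("fewer than 2 local maxima found")
    peaks = smoothed[idx]
    return np.column_stack([peaks[:-1], peaks[1:]])


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sum(a * b, axis=1) / (na * nb)
    return out


def basis_correlation(
    trace_S: SimTrace | np.ndarray, trace_R: SimTrace | np.ndarray
) -> np.ndarray:
    """Per-neuron Pearson correlation between two sets of sampled traces.

    Matched spiking/rate runs under a shared stabilizing drive show
    positively correlated postsynaptic currents; undriven chaotic pairs do
    not.  Zero-variance traces yield NaN (flagged via a warning).
    """
    a = trace_S.sampled_r if isinstance(trace_S, SimTrace) else np.atleast_2d(trace_S)
    b = trace_R.sampled_r if isinstance(trace_R, SimTrace) else np.atleast_2d(trace_R)
    if a is None or b is None:
        raise ValueError("traces must carry sampled_r (set RecordSpec.sample_idx)")
    if a.shape != b.shape:
        raise ValueError("traces must come from matched runs on identical grids")
    out = _pearson_rows(np.asarray(a, float), np.asarray(b, float))
    if np.isnan(out).any():
        warnings.warn("zero-variance trace(s) produced NaN correlations",
                      stacklevel=2)
    return out


def pc_correlation(
    decomp_S: BasisDecomposition, decomp_R: BasisDecomposition
) -> np.ndarray:
    """|Pearson correlation| between matching transformed basis traces.

    Component n of one network's spectral decomposition is compared with
    component n of the other's; absolute values are reported because
    eigenvector signs are arbitrary.  On trained matched pairs the leading
    (high-eigenvalue) components are the most correlated.
    """
    ks, kr = decomp_S.k_traces, decomp_R.k_traces
    if ks.shape != kr.shape:
        raise ValueError("component count mismatch between decompositions")
    return np.abs(_pearson_rows(ks.copy(), kr.copy()))
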