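"""Config-driven experiment protocols for the spiking/rate comparison.

Each runner reproduces one published protocol at native or scaled-down
size: (Q, G) grid sweeps with decoder correlation, error-vs-size scaling
fits, cross-trial bias-variance decompositions of a periodic task, and
decoder time-series diagnostics during learning.  Results come back as
tidy pandas DataFrames with full (seed, parameter) provenance per row.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import supervisors as sv
from .analysis import (
    ScalingFit,
    align_repetitions,
    bias_variance,
    decoder_correlation,
    fit_power_law,
    l2_error,
    rmse,
)
from .force import (
    RELATIVE_SUCCESS_THRESHOLD,
    ForceResult,
    TrainSchedule,
    converged,
    force_train,
    force_train_pair,
)
from .netmodels import NetworkInit, NeuronParams, make_network, run_network

__all__ = [
    "ExperimentConfig",
    "make_supervisor",
    "train_pair_cell",
    "run_grid_sweep",
    "run_scaling",
    "run_bias_variance",
    "run_decoder_dynamics",
    "PRESETS",
]


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment.

    Durations in seconds, ``dt`` and ``dt_rls`` in milliseconds.  Grids
    (``q_values``, ``g_values``, ``alphas``, ``sizes``) may be single
    points; every cell is trained independently with a seed derived from
    ``seed`` and the cell index, so sweeps are restartable and order-
    independent.
    """

    task: str = "sine"
    task_params: dict = field(default_factory=dict)
    kinds: tuple[str, ...] = ("spiking", "rate")
    N: int = 2000
    p: float = 0.4
    row_balanced: bool = True
    q_values: tuple[float, ...] = (25.0,)
    g_values: tuple[float, ...] = (0.15,)
    alphas: tuple[float, ...] = (5e-6,)
    t_pre: float = 0.6
    t_learn: float = 2.0
    t_test: float = 2.0
    dt: float = 0.05
    dt_rls: float = 5.0
    n_rep: int = 100
    sizes: tuple[int, ...] = (200, 400, 800, 1600)
    n_seeds: int = 2
    seed: int = 0
    #: convergence cut as a fraction of integrated target power
    success_threshold: float = RELATIVE_SUCCESS_THRESHOLD
    out_dir: str | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ExperimentConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        for key in ("kinds", "q_values", "g_values", "alphas", "sizes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def schedule(self) -> TrainSchedule:
        return TrainSchedule(self.t_pre, self.t_learn, self.t_test)


def make_supervisor(
    task: str, dt_s: float, duration_s: float, seed: int = 0, **kw
):
    """Build the supervisor (and optional input signal) for a named task.

    Returns ``(supervisor, external)`` where ``external`` is None except
    for the pitchfork task, whose kick signal drives the network as input.
    Tasks: sine (5 Hz unit amplitude), product, fourier (9 modes),
    ode2joy, ode2joy_hdts (16 clock components), pitchfork, lorenz.
    """
    if task == "sine":
        return (
            sv.gen_sine(kw.get("freq_hz", 5.0), kw.get("amplitude", 1.0), dt_s,
                        duration_s),
            None,
        )
    if task == "product":
        return sv.gen_product_oscillator(dt_s, duration_s), None
    if task == "fourier":
        return sv.gen_fourier(kw.get("n_components", 9), dt_s, duration_s), None
    if task in ("ode2joy", "ode2joy_hdts"):
        reps = int(np.ceil(duration_s / sv.BAR_SECONDS))
        song = sv.gen_ode_to_joy(dt_s, reps)
        if task == "ode2joy_hdts":
            hdts = sv.gen_hdts(kw.get("m", 16), sv.BAR_SECONDS, dt_s).tile(reps)
            song = sv.append_components(song, hdts)
        return song, None
    if task == "pitchfork":
        spec = sv.PitchforkSpec(seed=seed, **{
            k: v for k, v in kw.items()
            if k in ("r", "gamma", "gap_range", "width_range", "height_sd")
        })
        return sv.gen_pitchfork(spec, dt_s, duration_s)
    if task == "lorenz":
        spec = sv.LorenzSpec(dt=dt_s, **{
            k: v for k, v in kw.items()
            if k in ("rho", "sigma", "beta", "initial_state", "method")
        })
        return sv.gen_lorenz(spec, duration_s), None
    raise ValueError(f"unknown task {task!r}")


def _cell_seed(base: int, *idx: int) -> int:
    return int(np.random.SeedSequence([base, *idx]).generate_state(1)[0] % 2**31)


def _build_network(cfg: ExperimentConfig, N: int, M: int, Q: float, G: float,
                   seed: int, n_in: int) -> NetworkInit:
    return make_network(N, M, cfg.p, G, Q, seed, cfg.row_balanced, n_in=n_in)


def train_pair_cell(
    cfg: ExperimentConfig,
    Q: float,
    G: float,
    alpha: float,
    seed: int,
    params: NeuronParams = NeuronParams(),
    record_decoder: bool = False,
    snap_every: int = 0,
) -> tuple[dict, ForceResult, ForceResult, NetworkInit]:
    """Train one matched pair at a single grid cell and score it.

    The returned record carries the cell coordinates, both test errors,
    the cross-network decoder correlation, and per-kind convergence flags.
    """
    dt_s = cfg.dt * 1e-3
    supervisor, external = make_supervisor(
        cfg.task, dt_s, cfg.t_learn + cfg.t_test, seed=seed, **cfg.task_params
    )
    n_in = 0 if external is None else external.M
    init = _build_network(cfg, cfg.N, supervisor.M, Q, G, seed, n_in)
    schedule = cfg.schedule()
    res_s, res_r = force_train_pair(
        init, params, supervisor, schedule, alpha, cfg.dt_rls, cfg.dt,
        seed=seed, external=external, record_decoder=record_decoder,
        snap_every=snap_every,
    )
    n_test = res_s.trace_post.readout.shape[1]
    target = supervisor.values[:, int(round(cfg.t_learn / dt_s)):][:, :n_test]
    err_s = l2_error(res_s.trace_post.readout, target, dt_s)
    err_r = l2_error(res_r.trace_post.readout, target, dt_s)
    rec = {
        "Q": Q, "G": G, "alpha": alpha, "seed": seed, "N": cfg.N,
        "error_S": err_s, "error_R": err_r,
        "decoder_corr": decoder_correlation(res_r.phi, res_s.phi),
        "converged_S": converged(err_s, target, dt_s, cfg.success_threshold),
        "converged_R": converged(err_r, target, dt_s, cfg.success_threshold),
    }
    return rec, res_s, res_r, init


def run_grid_sweep(cfg: ExperimentConfig,
                   params: NeuronParams = NeuronParams()) -> pd.DataFrame:
    """Train matched pairs over the (Q, G, alpha) grid.

    Per-cell failures (numerical divergence) are recorded as NaN rows and
    the sweep continues.  A 1 x 1 grid reduces to a single training run
    plus its analyses.
    """
    rows = []
    for ia, alpha in enumerate(cfg.alphas):
        for iq, Q in enumerate(cfg.q_values):
            for ig, G in enumerate(cfg.g_values):
                seed = _cell_seed(cfg.seed, ia, iq, ig)
                try:
                    rec, *_ = train_pair_cell(cfg, Q, G, alpha, seed, params)
                except FloatingPointError as err:
                    rec = {"Q": Q, "G": G, "alpha": alpha, "seed": seed,
                           "N": cfg.N, "error_S": np.nan, "error_R": np.nan,
                           "decoder_corr": np.nan, "converged_S": False,
                           "converged_R": False, "failure": str(err)}
                rows.append(rec)
    df = pd.DataFrame(rows)
    if cfg.out_dir:
        Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(cfg.out_dir) / "sweep.csv", index=False)
    return df


def run_scaling(
    cfg: ExperimentConfig, params: NeuronParams = NeuronParams()
) -> tuple[dict[tuple[str, float], ScalingFit], pd.DataFrame]:
    """Error-vs-size scaling at fixed (Q, G) for each kind and learning rate.

    Trains ``n_seeds`` networks per size on the task, computes the test
    RMSE per run (non-converged runs included, as in the published
    protocol), and fits the log10-log10 line per (kind, alpha).
    """
    if len(cfg.sizes) < 3:
        raise ValueError("scaling needs at least 3 network sizes")
    Q, G = cfg.q_values[0], cfg.g_values[0]
    dt_s = cfg.dt * 1e-3
    rows = []
    fits: dict[tuple[str, float], ScalingFit] = {}
    for kind in cfg.kinds:
        for alpha in cfg.alphas:
            table: dict[int, list[float]] = {}
            for i_n, N in enumerate(cfg.sizes):
                table[N] = []
                for i_s in range(cfg.n_seeds):
                    seed = _cell_seed(cfg.seed, i_n, i_s)
                    supervisor, external = make_supervisor(
                        cfg.task, dt_s, cfg.t_learn + cfg.t_test, seed=seed,
                        **cfg.task_params,
                    )
                    sub = replace(cfg, N=N)
                    init = _build_network(
                        sub, N, supervisor.M, Q, G, seed,
                        0 if external is None else external.M,
                    )
                    res = force_train(
                        kind, init, params, supervisor, cfg.schedule(), alpha,
                        cfg.dt_rls, cfg.dt, seed=seed, external=external,
                    )
                    n_test = res.trace_post.readout.shape[1]
                    target = supervisor.values[
                        :, int(round(cfg.t_learn / dt_s)):][:, :n_test]
                    value = rmse(res.trace_post.readout, target, dt_s)
                    table[N].append(value)
                    rows.append({"kind": kind, "alpha": alpha, "N": N,
                                 "seed": seed, "rmse": value})
            fit = fit_power_law(list(table), table)
            fits[(kind, alpha)] = fit
    df = pd.DataFrame(rows)
    if cfg.out_dir:
        Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(cfg.out_dir) / "scaling.csv", index=False)
    return fits, df


def run_bias_variance(
    cfg: ExperimentConfig,
    params: NeuronParams = NeuronParams(),
    expected_peak_s: float = 0.05,
    smooth_window_s: float = 0.025,
) -> pd.DataFrame:
    """Cross-trial bias-variance decomposition on a periodic task.

    Trains a matched pair per cell, then simulates ``n_rep`` further
    periods with the decoder frozen, peak-aligns each period window
    (smoothing the spiking readout before locating peaks), and decomposes
    the cross-trial error into squared bias and variance per kind.
    """
    if cfg.n_rep < 2:
        raise ValueError("bias-variance needs n_rep >= 2")
    if cfg.task != "sine":
        raise ValueError("bias-variance protocol is defined for periodic tasks")
    freq = cfg.task_params.get("freq_hz", 5.0)
    period = 1.0 / freq
    dt_s = cfg.dt * 1e-3
    test_s = cfg.n_rep * period
    rows = []
    for ia, alpha in enumerate(cfg.alphas):
        for iq, Q in enumerate(cfg.q_values):
            for ig, G in enumerate(cfg.g_values):
                seed = _cell_seed(cfg.seed, ia, iq, ig)
                sub = replace(cfg, t_test=test_s)
                try:
                    rec, res_s, res_r, init = train_pair_cell(
                        sub, Q, G, alpha, seed, params
                    )
                except FloatingPointError as err:
                    rows.append({"Q": Q, "G": G, "alpha": alpha, "seed": seed,
                                 "failure": str(err)})
                    continue
                k_per = int(round(period / dt_s))
                target = sv.gen_sine(freq, 1.0, dt_s, period).values[0]
                for kind, res in (("spiking", res_s), ("rate", res_r)):
                    smooth = smooth_window_s if kind == "spiking" else None
                    trials = align_repetitions(
                        res.trace_post.readout[0], period, dt_s,
                        expected_peak_s, smooth,
                    )
                    st = bias_variance(trials, target[:k_per], dt_s)
                    rows.append({
                        "Q": Q, "G": G, "alpha": alpha, "seed": seed,
                        "kind": kind, "n_rep": st.n_rep,
                        "bias_sq": st.bias_sq, "variance": st.variance,
                        "var_proportion": st.var_proportion,
                        "error": rec[f"error_{'S' if kind == 'spiking' else 'R'}"],
                        "converged": rec[
                            f"converged_{'S' if kind == 'spiking' else 'R'}"],
                    })
    df = pd.DataFrame(rows)
    if cfg.out_dir:
        Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(cfg.out_dir) / "bias_variance.csv", index=False)
    return df


def run_decoder_dynamics(
    cfg: ExperimentConfig,
    params: NeuronParams = NeuronParams(),
    snap_every: int = 1,
) -> dict:
    """Decoder time series during learning for both network kinds.

    Records, at every RLS update: the decoder norm ||phi||2, the update
    magnitude ||dphi||, the instantaneous error norm, and (from decoder
    snapshots) the cross-network decoder correlation over training.
    """
    Q, G, alpha = cfg.q_values[0], cfg.g_values[0], cfg.alphas[0]
    seed = _cell_seed(cfg.seed, 0)
    rec, res_s, res_r, _ = train_pair_cell(
        cfg, Q, G, alpha, seed, params, record_decoder=True,
        snap_every=snap_every,
    )
    out: dict = {"record": rec}
    for kind, res in (("spiking", res_s), ("rate", res_r)):
        out[kind] = {
            "phi_norm": res.decoder_diag["phi_norm"],
            "dphi_norm": res.decoder_diag["dphi_norm"],
            "error": res.decoder_diag["error"],
            "log_error": np.log(np.maximum(res.decoder_diag["error"], 1e-300)),
        }
    snaps_s = res_s.decoder_diag["phi_snapshots"]
    snaps_r = res_r.decoder_diag["phi_snapshots"]
    rho = np.full(snaps_s.shape[0], np.nan)
    for k in range(snaps_s.shape[0]):
        a = snaps_s[k].ravel() - snaps_s[k].mean()
        b = snaps_r[k].ravel() - snaps_r[k].mean()
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na > 0 and nb > 0:
            rho[k] = a @ b / (na * nb)
    out["cross_corr"] = rho
    out["update_times_ms"] = np.arange(len(out["spiking"]["phi_norm"])) * cfg.dt_rls
    return out


#: Scaled-down and native presets for the main protocols.  The reduced
#: presets exercise every pipeline end-to-end in minutes; the native ones
#: reproduce the published problem sizes (cluster scale).
PRESETS: dict[str, ExperimentConfig] = {
    "sine_sweep_native": ExperimentConfig(
        task="sine", N=2000, q_values=tuple(np.linspace(2, 30, 40)),
        g_values=tuple(np.linspace(0.0, 0.2, 40)), alphas=(5e-6,),
        t_pre=0.6, t_learn=2.0, t_test=2.0, dt_rls=5.0,
    ),
    "sine_sweep_small": ExperimentConfig(
        task="sine", N=500, q_values=(15.0, 20.0, 25.0),
        g_values=(0.1, 0.15), alphas=(5e-6,),
        t_pre=0.3, t_learn=2.0, t_test=0.4, dt_rls=1.0,
    ),
    "scaling_native": ExperimentConfig(
        task="sine", q_values=(20.0,), g_values=(0.125,),
        alphas=(5e0, 5e-2, 5e-4, 5e-6),
        sizes=tuple(100 * 2**k for k in range(9)), n_seeds=21,
        t_pre=0.6, t_learn=5.0, t_test=0.4, dt_rls=1.0,
    ),
    "scaling_small": ExperimentConfig(
        task="sine", q_values=(20.0,), g_values=(0.125,), alphas=(5e-6,),
        sizes=(200, 400, 800), n_seeds=2,
        t_pre=0.3, t_learn=2.0, t_test=0.4, dt_rls=1.0,
    ),
    "biasvar_native": ExperimentConfig(
        task="sine", N=2000, q_values=(25.0,), g_values=(0.15,),
        alphas=(5e-6,), t_pre=0.6, t_learn=2.0, n_rep=100, dt_rls=0.25,
    ),
    "biasvar_small": ExperimentConfig(
        task="sine", N=500, q_values=(25.0,), g_values=(0.15,),
        alphas=(5e-6,), t_pre=0.3, t_learn=2.0, n_rep=10, dt_rls=0.25,
    ),
    "decoder_dynamics_native": ExperimentConfig(
        task="sine", N=2000, q_values=(25.0,), g_values=(0.15,),
        alphas=(5e-6,), t_pre=0.6, t_learn=10.0, t_test=1.0, dt_rls=0.25,
    ),
    "decoder_dynamics_small": ExperimentConfig(
        task="sine", N=500, q_values=(25.0,), g_values=(0.15,),
        alphas=(5e-6,), t_pre=0.3, t_learn=2.0, t_test=0.4, dt_rls=1.0,
    ),
}
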