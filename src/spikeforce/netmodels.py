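"""Parameter-matched spiking (LIF) and instantaneous-rate network simulators.

Both network types share one random structure: a sparse Gaussian reservoir
``omega0`` scaled by ``G``, a uniform feedback encoder ``eta`` scaled by
``Q``, and a learned linear decoder ``phi``, giving the effective recurrent
weights ``G*omega0 + Q*eta*phi^T`` (never materialized densely).  The
spiking network integrates leaky integrate-and-fire voltages with threshold
reset and a refractory period; the rate network replaces the spike
mechanism with the steady-state transfer function (f-I curve) of the same
neuron.  Spikes and rates alike drive double-exponential synaptic filters
whose outputs ``r`` form the neural basis read out by ``phi``.

Internally everything runs in millivolts and milliseconds; durations at
the API boundary are seconds to match the supervisor generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import scipy.sparse as sp

from . import _kernels
from .supervisors import SupervisorSignal

__all__ = [
    "NeuronParams",
    "NetworkInit",
    "LifState",
    "RateState",
    "SimTrace",
    "RecordSpec",
    "sample_reservoir",
    "sample_encoder",
    "make_network",
    "input_current",
    "rate_transfer",
    "lif_step",
    "rate_step",
    "initial_state",
    "run_network",
    "save_trace",
]

DT_MS_DEFAULT = 0.05


@dataclass(frozen=True)
class NeuronParams:
    """LIF neuron constants (ms / mV); defaults reproduce the reference set.

    ``i_bias`` is held at the rheobase: with unit resistance absorbed into
    the current, a neuron with no synaptic input sits exactly at threshold
    asymptote and never fires.
    """

    tau_r: float = 2.0
    tau_d: float = 20.0
    tau_m: float = 10.0
    tau_ref: float = 2.0
    v_reset: float = -65.0
    v_th: float = -40.0
    i_bias: float = -40.0

    def __post_init__(self) -> None:
        if min(self.tau_r, self.tau_d, self.tau_m, self.tau_ref) <= 0:
            raise ValueError("time constants must be positive")
        if self.v_reset >= self.v_th:
            raise ValueError("v_reset must be below v_th")


def sample_reservoir(
    N: int, p: float, seed: int, row_balanced: bool = True
) -> sp.csr_matrix:
    """Sparse Gaussian reservoir: entries N(0, 1/(N p^2)) kept with probability p.

    With ``row_balanced`` the mean of each row's retained entries is
    subtracted from those entries, so every row sums to zero exactly while
    the sparsity pattern is untouched (balancing over the zero entries
    would densify the matrix).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    rng = np.random.default_rng(seed)
    sd = 1.0 / (np.sqrt(N) * p)
    indptr = np.zeros(N + 1, dtype=np.int64)
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for i in range(N):
        mask = rng.random(N) < p
        c = np.nonzero(mask)[0]
        x = rng.normal(0.0, sd, size=c.size)
        if row_balanced and c.size > 0:
            x -= x.mean()
        cols.append(c)
        vals.append(x)
        indptr[i + 1] = indptr[i] + c.size
    mat = sp.csr_matrix(
        (np.concatenate(vals), np.concatenate(cols).astype(np.int32), indptr),
        shape=(N, N),
    )
    return mat


def sample_encoder(N: int, M: int, seed: int) -> np.ndarray:
    """Feedback encoder with i.i.d. Uniform(-1, 1) entries."""
    if N < 1 or M < 1:
        raise ValueError("N and M must be >= 1")
    return np.random.default_rng(seed).uniform(-1.0, 1.0, size=(N, M))


@dataclass
class NetworkInit:
    """Shared random structure used identically by both network types."""

    N: int
    M: int
    p: float
    G: float
    Q: float
    omega0: sp.csr_matrix
    eta: np.ndarray
    row_balanced: bool
    seed: int
    eta_in: np.ndarray | None = None  # (N, n_in) input encoder, optional
    _w32: np.ndarray | None = field(default=None, repr=False, compare=False)

    def scaled_dense32(self) -> np.ndarray:
        """Dense float32 ``G * omega0`` for the simulation kernel's BLAS matvec.

        Cached: G and omega0 are fixed for the lifetime of an init.
        """
        if self._w32 is None:
            self._w32 = np.ascontiguousarray(
                (self.G * self.omega0).toarray(), dtype=np.float32
            )
        return self._w32


def make_network(
    N: int,
    M: int,
    p: float,
    G: float,
    Q: float,
    seed: int,
    row_balanced: bool = True,
    n_in: int = 0,
) -> NetworkInit:
    """Draw the full shared initialization from one seed.

    The reservoir, feedback encoder, and (optional) input encoder come
    from independent child streams of ``seed``, so a matched spiking/rate
    pair built from the same ``NetworkInit`` is identical down to every
    random draw.
    """
    ss = np.random.SeedSequence(seed)
    s_res, s_enc, s_in = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    omega0 = sample_reservoir(N, p, s_res, row_balanced)
    eta = sample_encoder(N, M, s_enc)
    eta_in = sample_encoder(N, n_in, s_in) if n_in > 0 else None
    return NetworkInit(N, M, p, G, Q, omega0, eta, row_balanced, seed, eta_in)


@dataclass
class LifState:
    v: np.ndarray
    refractory_remaining: np.ndarray
    h: np.ndarray
    r: np.ndarray
    t: float = 0.0  # ms


@dataclass
class RateState:
    h: np.ndarray
    r: np.ndarray
    t: float = 0.0  # ms


#: upper edge of the initial voltage draw (mV); above threshold so that a
#: fraction of neurons fires immediately and ignites the network
V_INIT_HIGH = 30.0
#: upper edge of the rate network's initial postsynaptic-current draw
#: (spikes/s); a fifth of the absolute refractory ceiling 1/tau_ref
R_INIT_HIGH = 100.0


def initial_state(
    kind: str, N: int, params: NeuronParams, seed: int = 0
) -> LifState | RateState:
    """Fresh, desynchronized network state.

    With the bias current at rheobase an idle network is a fixed point:
    voltages below threshold never cross it, and a rate network with zero
    postsynaptic currents feeds itself zero rate forever.  Activity is
    therefore ignited at t=0: LIF voltages are drawn Uniform(v_reset,
    +30 mV) so that a fraction of neurons starts above threshold (the
    customary initialization for FORCE-trained spiking reservoirs), and
    the rate network's postsynaptic currents start Uniform(0, 100)
    spikes/s.  Both draws are seeded.
    """
    rng = np.random.default_rng(seed)
    zeros = np.zeros(N)
    if kind == "spiking":
        v = rng.uniform(params.v_reset, V_INIT_HIGH, size=N)
        return LifState(v, np.zeros(N), zeros.copy(), zeros.copy())
    if kind == "rate":
        return RateState(zeros.copy(), rng.uniform(0.0, R_INIT_HIGH, size=N))
    raise ValueError("kind must be 'spiking' or 'rate'")


def input_current(
    r_vector: np.ndarray,
    init: NetworkInit,
    phi: np.ndarray,
    params: NeuronParams = NeuronParams(),
    external: np.ndarray | None = None,
) -> np.ndarray:
    """Synaptic input ``I = G omega0 r + Q eta (phi^T r) + I_bias (+ external)``.

    Evaluated in low-rank form; the learned dense ``N x N`` part is never
    built.  Reference implementation (the simulation kernel repeats this
    computation in compiled code).
    """
    r_vector = np.asarray(r_vector, dtype=np.float64)
    if r_vector.shape[0] != init.N or phi.shape != (init.N, init.M):
        raise ValueError("shape mismatch between r, phi, and network")
    I = init.G * (init.omega0 @ r_vector) + init.Q * (init.eta @ (phi.T @ r_vector))
    I += params.i_bias
    if external is not None:
        I = I + external
    return I


def rate_transfer(I: np.ndarray, params: NeuronParams = NeuronParams()) -> np.ndarray:
    """Steady-state LIF firing rate (spikes/ms) for constant current I.

    ``R(I) = 1 / (tau_ref - tau_m * log((I - v_th)/(I - v_reset)))`` above
    threshold and 0 at or below it; monotone increasing and bounded by
    ``1/tau_ref``.  A guard of 1e-12 mV above threshold absorbs the
    logarithmic singularity.
    """
    I = np.asarray(I, dtype=np.float64)
    out = np.zeros_like(I)
    mask = I > params.v_th + _kernels.RATE_EPS
    Im = I[mask]
    out[mask] = 1.0 / (
        params.tau_ref
        - params.tau_m * np.log((Im - params.v_th) / (Im - params.v_reset))
    )
    return out


def lif_step(
    state: LifState, I: np.ndarray, params: NeuronParams, dt: float
) -> tuple[LifState, np.ndarray]:
    """One forward-Euler LIF step (dt in ms); returns (state, spike flags).

    Refractory neurons hold ``v_reset``; others integrate
    ``v += dt (I - v)/tau_m`` and reset on crossing threshold.  At a spike
    the synaptic rise variable jumps by ``1000/(tau_r tau_d)`` — the exact
    integral of the delta drive, step-size independent, with the factor
    1000 making the filtered spike train ``r`` a rate in spikes/s even
    though the time constants are in ms.  Mutates ``state`` in place.
    """
    refr = state.refractory_remaining > 0.0
    state.refractory_remaining[refr] -= dt
    state.v[refr] = params.v_reset
    act = ~refr
    state.v[act] += dt * (I[act] - state.v[act]) / params.tau_m
    spiked = act & (state.v >= params.v_th)
    state.v[spiked] = params.v_reset
    state.refractory_remaining[spiked] = params.tau_ref
    state.h *= 1.0 - dt / params.tau_r
    state.h[spiked] += _kernels.RATE_SCALE / (params.tau_r * params.tau_d)
    state.r = state.r * (1.0 - dt / params.tau_d) + dt * state.h
    state.t += dt
    if not np.all(np.isfinite(state.v)):
        raise FloatingPointError("LIF state became non-finite")
    return state, spiked


def rate_step(
    state: RateState, I: np.ndarray, params: NeuronParams, dt: float
) -> RateState:
    """One forward-Euler step of the rate neuron's synaptic filters (dt in ms).

    The transfer-function output drives the same double-exponential filter
    as the spike train does, so under a constant current the postsynaptic
    current settles at the firing rate in spikes/s
    (``r = 1000 * rate_transfer(I)``).
    """
    R = _kernels.RATE_SCALE * rate_transfer(I, params)
    state.h += dt * (-state.h / params.tau_r + R / (params.tau_r * params.tau_d))
    state.r += dt * (-state.r / params.tau_d + state.h)
    state.t += dt
    if not np.all(np.isfinite(state.h)):
        raise FloatingPointError("rate state became non-finite")
    return state


@dataclass
class RecordSpec:
    """What to record during a run beyond the readout (always recorded)."""

    sample_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    sample_stride: int = 1
    sample_current: bool = False
    spikes: bool = False
    spike_cap: int | None = None

    def __post_init__(self) -> None:
        self.sample_idx = np.asarray(self.sample_idx, dtype=np.int64)
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")


@dataclass
class SimTrace:
    """Result of one simulation run."""

    readout: np.ndarray  # (M, K)
    dt: float  # ms
    kind: str
    spike_times: list[np.ndarray] | None = None  # per-neuron, ms
    spike_neuron: np.ndarray | None = None  # flat raster
    spike_step: np.ndarray | None = None
    sampled_r: np.ndarray | None = None
    sampled_current: np.ndarray | None = None
    sample_idx: np.ndarray | None = None
    sample_stride: int = 1
    n_spikes: int = 0

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.readout.shape[1]) * self.dt * 1e-3


def _spike_lists(
    spike_neuron: np.ndarray, spike_step: np.ndarray, N: int, dt: float
) -> list[np.ndarray]:
    order = np.argsort(spike_neuron, kind="stable")
    sn, st = spike_neuron[order], spike_step[order]
    out: list[np.ndarray] = []
    bounds = np.searchsorted(sn, np.arange(N + 1))
    for i in range(N):
        out.append(st[bounds[i] : bounds[i + 1]] * dt)
    return out


def _simulate_block(
    kind: str,
    init: NetworkInit,
    params: NeuronParams,
    phi: np.ndarray,
    state: LifState | RateState,
    n_steps: int,
    dt: float,
    external: np.ndarray | None = None,
    P: np.ndarray | None = None,
    target: np.ndarray | None = None,
    rls_every: int = 1,
    record: RecordSpec | None = None,
    record_decoder: bool = False,
    snap_every: int = 0,
) -> tuple[SimTrace, dict]:
    """Advance one phase; shared by :func:`run_network` and FORCE training.

    Mutates ``phi``, ``P`` and ``state`` in place.  Returns the trace and a
    dict of decoder diagnostics (empty unless training with recording).
    """
    record = record or RecordSpec()
    kcode = _kernels.KIND_SPIKING if kind == "spiking" else _kernels.KIND_RATE
    N, M = init.N, init.M
    w32 = init.scaled_dense32()
    qeta = np.ascontiguousarray(init.Q * init.eta)
    phi = np.ascontiguousarray(phi)

    if external is not None:
        if init.eta_in is None:
            raise ValueError("network has no input encoder for external input")
        ext = np.ascontiguousarray(external, dtype=np.float64)
        if ext.shape[1] < n_steps:
            raise ValueError("external input shorter than the run")
        ext = ext[:, :n_steps]
        ext_enc = np.ascontiguousarray(init.Q * init.eta_in)
    else:
        ext = np.zeros((0, n_steps))
        ext_enc = np.zeros((N, 0))

    do_rls = P is not None
    if do_rls:
        if target is None:
            raise ValueError("training requires a target")
        target = np.ascontiguousarray(target, dtype=np.float64)
        if target.shape != (M, n_steps):
            raise ValueError("target must have shape (M, n_steps)")
        n_updates = (n_steps + rls_every - 1) // rls_every
    else:
        P = np.zeros((0, 0))
        target = np.zeros((M, 0))
        n_updates = 0

    readout = np.empty((M, n_steps))
    S = record.sample_idx.size
    n_samp = (n_steps + record.sample_stride - 1) // record.sample_stride
    sample_r = np.empty((S, n_samp)) if S else np.zeros((0, 0))
    sample_i = (
        np.empty((S, n_samp)) if (S and record.sample_current) else np.zeros((0, 0))
    )
    if record.spikes and kind == "spiking":
        cap = record.spike_cap or int(N * n_steps * dt * 0.5) + 16
        spike_neuron = np.empty(cap, dtype=np.int32)
        spike_step = np.empty(cap, dtype=np.int64)
    else:
        spike_neuron = np.empty(0, dtype=np.int32)
        spike_step = np.empty(0, dtype=np.int64)

    n_diag = n_updates if (do_rls and record_decoder) else 0
    phi_norm = np.empty(n_diag)
    dphi_norm = np.empty(n_diag)
    err = np.empty(n_diag)
    if do_rls and snap_every > 0:
        n_snap = (n_updates + snap_every - 1) // snap_every
        phi_snap = np.empty((n_snap, N, M))
    else:
        phi_snap = np.zeros((0, N, M))
        snap_every = 0

    if kind == "spiking":
        v, refrac = state.v, state.refractory_remaining
    else:
        # the kernel touches v/refrac only on the spiking path; pass dummies
        v = np.zeros(N)
        refrac = np.zeros(N)

    n_spk, n_upd, status, bad_step = _kernels.simulate_block(
        kcode,
        n_steps,
        dt,
        w32,
        qeta,
        phi,
        ext_enc,
        ext,
        params.tau_r,
        params.tau_d,
        params.tau_m,
        params.tau_ref,
        params.v_reset,
        params.v_th,
        params.i_bias,
        v,
        refrac,
        state.h,
        state.r,
        do_rls,
        P,
        target,
        rls_every,
        readout,
        record.sample_idx,
        record.sample_stride,
        sample_r,
        sample_i,
        record.spikes and kind == "spiking",
        spike_neuron,
        spike_step,
        phi_norm,
        dphi_norm,
        err,
        phi_snap,
        snap_every,
    )
    state.t += n_steps * dt
    if status == _kernels.STATUS_NONFINITE:
        raise FloatingPointError(
            f"{kind} network readout became non-finite at t={bad_step * dt:.2f} ms"
        )
    if status == _kernels.STATUS_RLS_BREAKDOWN:
        raise FloatingPointError(
            f"RLS denominator non-positive at t={bad_step * dt:.2f} ms"
        )

    n_stored = min(n_spk, spike_neuron.size)
    trace = SimTrace(
        readout=readout,
        dt=dt,
        kind=kind,
        spike_neuron=spike_neuron[:n_stored] if record.spikes else None,
        spike_step=spike_step[:n_stored] if record.spikes else None,
        spike_times=(
            _spike_lists(spike_neuron[:n_stored], spike_step[:n_stored], N, dt)
            if record.spikes and kind == "spiking"
            else None
        ),
        sampled_r=sample_r if S else None,
        sampled_current=sample_i if (S and record.sample_current) else None,
        sample_idx=record.sample_idx if S else None,
        sample_stride=record.sample_stride,
        n_spikes=n_spk,
    )
    diag = {}
    if n_diag:
        diag = {"phi_norm": phi_norm, "dphi_norm": dphi_norm, "error": err}
    if snap_every:
        diag["phi_snapshots"] = phi_snap
    return trace, diag


def run_network(
    kind: str,
    init: NetworkInit,
    params: NeuronParams,
    phi: np.ndarray | None,
    duration_s: float,
    dt_ms: float = DT_MS_DEFAULT,
    state: LifState | RateState | None = None,
    external: SupervisorSignal | np.ndarray | None = None,
    record: RecordSpec | None = None,
    seed: int = 0,
) -> SimTrace:
    """Closed-loop simulation without learning.

    The readout ``phi^T r`` is fed back through ``Q eta`` every step.  With
    ``phi=None`` (or zeros) the network runs in its spontaneous regime.
    ``state`` continues a previous run when given; otherwise a fresh seeded
    state is drawn.  External input signals (in seconds) are projected
    through the network's input encoder scaled by Q.
    """
    if kind not in ("spiking", "rate"):
        raise ValueError("kind must be 'spiking' or 'rate'")
    n_steps = int(round(duration_s * 1e3 / dt_ms))
    phi = np.zeros((init.N, init.M)) if phi is None else np.array(phi, dtype=np.float64)
    if state is None:
        state = initial_state(kind, init.N, params, seed)
    if isinstance(external, SupervisorSignal):
        if not np.isclose(external.dt * 1e3, dt_ms, rtol=1e-9):
            raise ValueError("external signal dt must match the integration step")
        external = external.values
    trace, _ = _simulate_block(
        kind, init, params, phi, state, n_steps, dt_ms, external=external, record=record
    )
    return trace


def save_trace(trace: SimTrace, path: str | Path, meta: dict | None = None) -> None:
    """Export a trace as an array archive plus a JSON parameter sidecar."""
    path = Path(path)
    arrays = {"readout": trace.readout}
    for name in ("spike_neuron", "spike_step", "sampled_r", "sampled_current",
                 "sample_idx"):
        val = getattr(trace, name)
        if val is not None:
            arrays[name] = val
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"dt_ms": trace.dt, "kind": trace.kind, "n_spikes": trace.n_spikes,
               "sample_stride": trace.sample_stride}
    sidecar.update(meta or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
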