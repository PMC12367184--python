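"""Synthetic target signals ("supervisors") for recurrent-network training.

Every task trained in this package is a low-dimensional dynamical system
sampled on a uniform time grid: sinusoidal oscillators, a bank of Fourier
modes, a note-pulse rendition of the first bar of "Ode to Joy" (optionally
with a high-dimensional temporal signal acting as a clock), a randomly
kicked pitchfork normal form, and the Lorenz system.  All generators are
deterministic given their seed and return a :class:`SupervisorSignal`
holding an ``(M, K)`` array of target values at time step ``dt`` (seconds).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SupervisorSignal",
    "PitchforkSpec",
    "LorenzSpec",
    "gen_sine",
    "gen_product_oscillator",
    "gen_fourier",
    "gen_ode_to_joy",
    "gen_hdts",
    "gen_pitchfork",
    "gen_lorenz",
    "append_components",
    "save_text",
    "load_text",
]


@dataclass
class SupervisorSignal:
    """A multi-dimensional target time series on a fixed grid.

    Attributes
    ----------
    values
        Array of shape ``(M, K)``: M output dimensions by K time steps.
        Sample ``k`` is the signal at time ``t = k * dt``.
    dt
        Time step in seconds.
    names
        Per-dimension labels, length M.
    """

    values: np.ndarray
    dt: float
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("signal must have at least one dimension and one sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("supervisor contains non-finite values")
        if not self.names:
            self.names = [f"x{i}" for i in range(self.values.shape[0])]
        if len(self.names) != self.values.shape[0]:
            raise ValueError("names length must match number of dimensions")

    @property
    def M(self) -> int:
        return self.values.shape[0]

    @property
    def K(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Total covered time in seconds (K * dt)."""
        return self.values.shape[1] * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) * self.dt

    def tile(self, n: int) -> "SupervisorSignal":
        """Repeat the signal ``n`` times along the time axis."""
        if n < 1:
            raise ValueError("n must be >= 1")
        return replace(self, values=np.tile(self.values, (1, n)))

    def resample(self, dt: float) -> "SupervisorSignal":
        """Linearly interpolate onto a new step ``dt`` (seconds)."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        t_new = np.arange(int(round(self.duration / dt))) * dt
        vals = np.vstack([np.interp(t_new, self.times, row) for row in self.values])
        return SupervisorSignal(vals, dt, list(self.names))


def _time_grid(dt: float, duration: float) -> np.ndarray:
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be positive")
    k = int(round(duration / dt))
    if k < 1:
        raise ValueError("duration shorter than one time step")
    return np.arange(k) * dt


def gen_sine(
    freq_hz: float, amplitude: float, dt: float, duration: float
) -> SupervisorSignal:
    """A one-dimensional sinusoid ``amplitude * sin(2 pi f t)``.

    The default oscillator task of the comparison experiments is a 5 Hz
    sinusoid with unit amplitude.
    """
    if freq_hz <= 0:
        raise ValueError("freq_hz must be positive")
    t = _time_grid(dt, duration)
    return SupervisorSignal(
        amplitude * np.sin(2 * np.pi * freq_hz * t)[None, :], dt, ["sine"]
    )


def gen_product_oscillator(dt: float, duration: float) -> SupervisorSignal:
    """Product of a 1 Hz and a 2 Hz sine wave (the "complex oscillator")."""
    t = _time_grid(dt, duration)
    vals = np.sin(2 * np.pi * t) * np.sin(4 * np.pi * t)
    return SupervisorSignal(vals[None, :], dt, ["product"])


def gen_fourier(n_components: int, dt: float, duration: float) -> SupervisorSignal:
    """Bank of sinusoidal modes; component n (1-based) is ``sin(n pi t)``.

    With ``n_components = 9`` the mode frequencies run evenly from 0.5 Hz
    to 4.5 Hz.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    t = _time_grid(dt, duration)
    n = np.arange(1, n_components + 1)
    vals = np.sin(np.pi * n[:, None] * t[None, :])
    return SupervisorSignal(vals, dt, [f"f{0.5 * i:g}Hz" for i in n])


#: Component order of the note-pulse song supervisor.
NOTE_NAMES = ("G", "F", "E", "D", "C")
#: (note, kind) per beat of the opening bar; "q" = quarter, "h" = half.
FIRST_BAR = (("E", "q"), ("E", "q"), ("F", "q"), ("G", "q"))
BAR_SECONDS = 4.0


def gen_ode_to_joy(dt: float, n_repetitions: int) -> SupervisorSignal:
    """Five-component note-pulse supervisor for the opening bar of a song.

    Components are the notes G, F, E, D, C.  Each beat of the 4 s bar
    places a pulse in the component of the note played on that beat: a
    quarter note is the positive half of a 2 Hz sine (0.25 s), a half note
    the positive half of a 1 Hz sine (0.5 s).  Pulses never overlap, so at
    any instant at most one component is nonzero.  The bar is repeated
    ``n_repetitions`` times, giving ``4 * n_repetitions`` seconds total.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    t = _time_grid(dt, BAR_SECONDS)
    bar = np.zeros((len(NOTE_NAMES), t.size))
    beat_len = BAR_SECONDS / len(FIRST_BAR)
    for beat, (note, kind) in enumerate(FIRST_BAR):
        freq = 2.0 if kind == "q" else 1.0
        start = beat * beat_len
        width = 0.5 / freq  # positive half-period
        mask = (t >= start) & (t < start + width)
        row = NOTE_NAMES.index(note)
        bar[row, mask] = np.sin(2 * np.pi * freq * (t[mask] - start))
    sig = SupervisorSignal(bar, dt, list(NOTE_NAMES))
    return sig.tile(n_repetitions)


def gen_hdts(m: int, duration: float, dt: float) -> SupervisorSignal:
    """High-dimensional temporal signal: m sequential unit pulses.

    The interval ``[0, T]`` is divided into m equal subintervals
    ``I_n = [T(n-1)/m, T n/m]``; component n equals ``|sin(m pi t / T)|``
    inside ``I_n`` and zero elsewhere.  Components therefore have disjoint
    supports partitioning the interval, acting as a clock when appended to
    a long supervisor.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    t = _time_grid(dt, duration)
    T = duration
    vals = np.zeros((m, t.size))
    idx = np.minimum((t * m / T).astype(np.int64), m - 1)
    pulse = np.abs(np.sin(m * np.pi * t / T))
    for n in range(m):
        vals[n, idx == n] = pulse[idx == n]
    return SupervisorSignal(vals, dt, [f"hdts{n + 1}" for n in range(m)])


@dataclass(frozen=True)
class PitchforkSpec:
    """Parameters of the kicked pitchfork normal form ``gamma x' = r x - x^3 + p(t)``."""

    r: float = 1.0
    gamma: float = 0.01
    gap_range: tuple[float, float] = (0.1, 0.5)
    width_range: tuple[float, float] = (0.005, 0.01)
    height_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r <= 0 or self.gamma <= 0:
            raise ValueError("r and gamma must be positive")
        for lo, hi in (self.gap_range, self.width_range):
            if not (0 < lo <= hi):
                raise ValueError("gap_range and width_range must be positive intervals")


def _pulse_train(
    spec: PitchforkSpec, t: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    p = np.zeros(t.size)
    dt = t[1] - t[0] if t.size > 1 else 1.0
    pos = rng.uniform(*spec.gap_range)
    while pos < t[-1]:
        width = rng.uniform(*spec.width_range)
        height = rng.normal(0.0, spec.height_sd)
        i0 = int(np.ceil(pos / dt))
        i1 = min(int(np.ceil((pos + width) / dt)), t.size)
        p[i0:i1] = height
        pos += width + rng.uniform(*spec.gap_range)
    return p


def gen_pitchfork(
    spec: PitchforkSpec, dt: float, duration: float, x0: float | None = None
) -> tuple[SupervisorSignal, SupervisorSignal]:
    """Kicked pitchfork system; returns (state supervisor, kick input).

    The state ``x`` relaxes to one of the stable fixed points at
    ``+-sqrt(r)`` and is knocked between them by a random square-pulse
    input ``p(t)`` (gaps ~ U(gap_range), widths ~ U(width_range), heights
    ~ N(0, height_sd^2)).  Forward-Euler integration at ``dt``.  The kick
    signal is returned separately so the network layer can decide how to
    inject it.
    """
    t = _time_grid(dt, duration)
    rng = np.random.default_rng(spec.seed)
    p = _pulse_train(spec, t, rng)
    x = np.empty(t.size)
    x[0] = np.sqrt(spec.r) if x0 is None else x0
    bound = 100.0 * np.sqrt(spec.r)
    for k in range(1, t.size):
        xk = x[k - 1]
        x[k] = xk + dt * (spec.r * xk - xk**3 + p[k - 1]) / spec.gamma
        if abs(x[k]) > bound:
            raise FloatingPointError(
                f"pitchfork integration blew up at t={t[k]:.4f} s"
            )
    return (
        SupervisorSignal(x[None, :], dt, ["pitchfork"]),
        SupervisorSignal(p[None, :], dt, ["kick"]),
    )


@dataclass(frozen=True)
class LorenzSpec:
    """Lorenz system parameters; defaults are the classic chaotic set."""

    rho: float = 28.0
    sigma: float = 10.0
    beta: float = 8.0 / 3.0
    initial_state: tuple[float, float, float] = (1.0, 1.0, 1.0)
    dt: float = 5e-5
    method: str = "euler"  # or "rk4"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.method not in ("euler", "rk4"):
            raise ValueError("method must be 'euler' or 'rk4'")


def gen_lorenz(spec: LorenzSpec, duration: float) -> SupervisorSignal:
    """Integrate the Lorenz system for ``duration`` seconds.

    Forward Euler at ``spec.dt`` by default (one integration clock shared
    with the network simulations); classic fourth-order Runge-Kutta behind
    ``method='rk4'``.
    """
    t = _time_grid(spec.dt, duration)
    out = np.empty((3, t.size))
    state = np.array(spec.initial_state, dtype=np.float64)
    s, r, b = spec.sigma, spec.rho, spec.beta

    def deriv(u: np.ndarray) -> np.ndarray:
        x, y, z = u
        return np.array([s * (y - x), x * (r - z) - y, x * y - b * z])

    dt = spec.dt
    for k in range(t.size):
        out[:, k] = state
        if spec.method == "euler":
            state = state + dt * deriv(state)
        else:
            k1 = deriv(state)
            k2 = deriv(state + 0.5 * dt * k1)
            k3 = deriv(state + 0.5 * dt * k2)
            k4 = deriv(state + dt * k3)
            state = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(state)) or np.max(np.abs(state)) > 1e4:
            raise FloatingPointError(f"Lorenz integration diverged at t={t[k]:.4f} s")
    return SupervisorSignal(out, spec.dt, ["x", "y", "z"])


def append_components(
    base: SupervisorSignal, extra: SupervisorSignal
) -> SupervisorSignal:
    """Concatenate the components of two signals on the same grid, base first."""
    if not np.isclose(base.dt, extra.dt, rtol=1e-9):
        raise ValueError("cannot append signals with different dt")
    if base.K != extra.K:
        raise ValueError("cannot append signals with different durations")
    return SupervisorSignal(
        np.vstack([base.values, extra.values]),
        base.dt,
        list(base.names) + list(extra.names),
    )


def save_text(signal: SupervisorSignal, path: str | Path) -> None:
    """Write a signal as columns (time, components) with a labelled header."""
    header = "time_s\t" + "\t".join(signal.names)
    np.savetxt(
        path,
        np.column_stack([signal.times, signal.values.T]),
        header=header,
        delimiter="\t",
    )


def load_text(path: str | Path) -> SupervisorSignal:
    """Read a signal written by :func:`save_text`."""
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip().split("\t")
    data = np.loadtxt(path)
    data = np.atleast_2d(data)
    dt = float(data[1, 0] - data[0, 0]) if data.shape[0] > 1 else 1.0
    return SupervisorSignal(data[:, 1:].T, dt, header[1:])
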