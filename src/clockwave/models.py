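"""Clock + reporter models and their Euler–Maruyama simulation.

Two coupled systems are implemented:

* a three-variable Goodwin transcriptional–translational feedback loop
  (mRNA u, cytosolic protein v, nuclear protein w) driving a reporter x at
  rate ``alpha + beta*g(w)``, with gene-expression noise on the u equation
  and the clock equations rescaled by the clock's own free-running period
  tau so one oscillation spans ~1 time unit ("one day"); and

* a noisy phase oscillator ``theta' = omega + epsilon*sqrt(D)*xi(t)`` driving
  the reporter at rate ``alpha + beta*f(theta)``, the generic reduction of
  any self-sustained clock.

The noiseless phase model has a closed-form periodic steady state
(:func:`limit_cycle_x`) used both by the period-statistics conventions and by
the analytic CV decomposition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _kernels
from .regfun import FourierRegFunction, PolynomialRegulation, check_rate_positivity

__all__ = [
    "PhaseModelParams",
    "GoodwinParams",
    "Trajectory",
    "simulate_phase_output",
    "simulate_goodwin_output",
    "limit_cycle_x",
    "limit_cycle_harmonics",
    "measure_deterministic_period",
    "NonOscillationError",
    "RateViolationError",
]

DEFAULT_DT = 1.0e-3
DEFAULT_DISCARD = 100.0


class NonOscillationError(RuntimeError):
    """The deterministic clock failed to produce sustained oscillations."""


class RateViolationError(ValueError):
    """The synthesis rate alpha + beta*f(theta) goes negative."""


@dataclass(frozen=True)
class PhaseModelParams:
    """Parameters of the phase-oscillator + reporter model."""

    omega: float = 2.0 * math.pi
    epsilon: float = 0.1
    D: float = 3.0
    alpha: float = 3.0
    beta: float = 1.0
    k: float = 10.0

    def __post_init__(self) -> None:
        if self.omega <= 0 or self.k <= 0:
            raise ValueError("omega and k must be positive")
        if self.epsilon < 0 or self.D < 0:
            raise ValueError("epsilon and D must be nonnegative")

    @property
    def tau(self) -> float:
        """Clock period 2*pi/omega."""
        return 2.0 * math.pi / self.omega


@dataclass(frozen=True)
class GoodwinParams:
    """Parameters of the Goodwin clock + reporter model.

    ``tau`` is the free-running period of the *unscaled* deterministic clock;
    the clock equations are multiplied by tau so the rescaled system has
    period ~1.  The Hill coefficient defaults to 10, above the oscillation
    threshold of the three-variable loop with near-equal degradation rates;
    with k_u = k_v = k_w = 0.1 this gives a free-running period of ~39.7-39.9
    time units, which should be *measured* (see
    :func:`measure_deterministic_period`) rather than assumed.
    """

    tau: float = 39.7
    m: float = 10.0
    ku: float = 0.1
    kv: float = 0.1
    kw: float = 0.1
    alpha: float = 1.0
    beta: float = 1.0
    k: float = 1.0
    epsilon: float = 1.0e-4
    D: float = 1.0

    def __post_init__(self) -> None:
        if min(self.tau, self.ku, self.kv, self.kw, self.k) <= 0:
            raise ValueError("rates and tau must be positive")
        if self.m < 1:
            raise ValueError("Hill coefficient must be >= 1")
        if self.epsilon < 0 or self.D < 0:
            raise ValueError("epsilon and D must be nonnegative")


@dataclass
class Trajectory:
    """Uniformly sampled state time series from one model run."""

    t0: float
    dt: float
    components: dict[str, np.ndarray]
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.components.values()}
        if len(lengths) != 1:
            raise ValueError("all component arrays must have equal length")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n(self) -> int:
        return len(next(iter(self.components.values())))

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.components[name]

    def to_csv(self, path, decimate: int = 10) -> None:
        """Write ``t,<components>`` CSV (every ``decimate``-th step) plus a JSON
        sidecar with parameters and seed.  Period statistics should always be
        computed from the in-memory (undecimated) arrays."""
        path = Path(path)
        names = list(self.components)
        sl = slice(None, None, max(1, int(decimate)))
        data = np.column_stack([self.t[sl]] + [self.components[c][sl] for c in names])
        header = ",".join(["t"] + names)
        np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.10g")
        sidecar = {"seed": self.seed, "dt": self.dt, "t0": self.t0,
                   "decimate": int(decimate), **self.meta}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def simulate_phase_output(
    params: PhaseModelParams,
    f: FourierRegFunction,
    duration: float,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    initial: tuple[float, float] = (0.0, 0.0),
    check_positivity: bool = True,
) -> Trajectory:
    """Euler–Maruyama simulation of the phase + reporter system.

    The phase is integrated unwrapped and stored modulo 2*pi; the reporter is
    x' = alpha + beta*f(theta) - k*x.  Initial condition defaults to (0, 0).
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if check_positivity:
        ok, min_rate = check_rate_positivity(params.alpha, params.beta, f)
        if not ok:
            raise RateViolationError(
                f"synthesis rate goes negative (min {min_rate:.4g}); "
                "normalize the coefficients or raise alpha"
            )
    vec = f.as_vector()
    A = np.ascontiguousarray(vec[0::2])
    B = np.ascontiguousarray(vec[1::2])
    n_steps = int(round(duration / dt))
    theta, x = _kernels.phase_em(
        n_steps, dt, params.omega, params.epsilon, params.D, A, B,
        params.alpha, params.beta, params.k, initial[0], initial[1], seed,
    )
    return Trajectory(
        t0=0.0, dt=dt,
        components={"theta": np.mod(theta, 2.0 * np.pi), "theta_unwrapped": theta, "x": x},
        seed=seed,
        meta={"model": "phase", "params": asdict(params)},
    )


def simulate_goodwin_output(
    params: GoodwinParams,
    g: PolynomialRegulation,
    regulator: str = "w",
    duration: float = 500.0,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    initial: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0),
) -> Trajectory:
    """Euler–Maruyama simulation of the Goodwin clock + reporter system.

    Gene-expression noise acts on the u (mRNA) equation only; ``regulator``
    chooses which clock variable the output reads (u, v or w, default w).
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    reg_idx = {"u": 0, "v": 1, "w": 2}.get(regulator)
    if reg_idx is None:
        raise ValueError("regulator must be one of 'u', 'v', 'w'")
    coef, powr = g.coefficient_arrays()
    n_steps = int(round(duration / dt))
    u, v, w, x = _kernels.goodwin_em(
        n_steps, dt, params.tau, params.m, params.ku, params.kv, params.kw,
        params.alpha, params.beta, params.k, params.epsilon, params.D,
        coef, powr, reg_idx, *initial, seed,
    )
    return Trajectory(
        t0=0.0, dt=dt, components={"u": u, "v": v, "w": w, "x": x}, seed=seed,
        meta={"model": "goodwin", "regulator": regulator, "params": asdict(params)},
    )


def limit_cycle_harmonics(
    params: PhaseModelParams, f: FourierRegFunction
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitudes and phases of the harmonics of the noiseless limit cycle.

    The reporter is a first-order low-pass filter of the drive, so harmonic i
    of f appears in x with amplitude ``sqrt(r_i^2 / (k^2 + (i omega)^2))`` and
    a phase lag ``arctan(i omega / k)``:
    x*(t) = alpha/k + beta * sum_i R_i sin(i omega t + phi_i).
    """
    vec = f.as_vector()
    H = f.harmonics
    k, om = params.k, params.omega
    i = np.arange(1, H + 1)
    a, b = vec[0::2], vec[1::2]
    R = np.sqrt((a**2 + b**2) / (k**2 + (i * om) ** 2))
    phi = np.arctan2(a, b) - np.arctan(i * om / k)
    return R, phi


def limit_cycle_x(params: PhaseModelParams, f: FourierRegFunction, t) -> np.ndarray:
    """Exact periodic steady state x*(t) of the noiseless (epsilon=0) model."""
    R, phi = limit_cycle_harmonics(params, f)
    t = np.asarray(t, dtype=float)
    out = np.full_like(t, params.alpha / params.k)
    for i in range(1, f.harmonics + 1):
        if R[i - 1] != 0.0:
            out = out + params.beta * R[i - 1] * np.sin(i * params.omega * t + phi[i - 1])
    return out if out.ndim else float(out)


def _period_from_crossings(t: np.ndarray, y: np.ndarray) -> float:
    mid = 0.5 * (y.max() + y.min())
    z = y - mid
    up = np.nonzero((z[:-1] < 0) & (z[1:] >= 0))[0]
    if len(up) < 3:
        raise NonOscillationError("fewer than three midpoint crossings found")
    frac = z[up] / (z[up] - z[up + 1])
    times = t[up] + frac * (t[1] - t[0])
    periods = np.diff(times)
    # sustained oscillation check: crossing spacing must not drift systematically
    if periods.min() <= 0:
        raise NonOscillationError("non-monotone crossing sequence")
    return float(periods.mean())


def measure_deterministic_period(
    model: str,
    params,
    g_or_f=None,
    duration: float | None = None,
    dt: float = DEFAULT_DT,
    discard: float | None = None,
) -> float:
    """Free-running period of the noiseless clock, from midpoint crossings.

    For the phase model this trivially returns tau = 2*pi/omega measured from
    crossings of the phase.  For the Goodwin model the *unscaled* clock
    (tau factor set to 1) is integrated and the period of w is measured after
    a transient, with linear interpolation between steps.  Raises
    :class:`NonOscillationError` when no sustained oscillation is found.
    """
    if model == "phase":
        return 2.0 * math.pi / params.omega
    if model != "goodwin":
        raise ValueError("model must be 'phase' or 'goodwin'")
    # unscaled clock: integrate with tau=1 and epsilon=0
    duration = 800.0 if duration is None else duration
    discard = 400.0 if discard is None else discard
    coef = np.array([1.0])
    powr = np.array([1], dtype=np.int64)
    n_steps = int(round(duration / dt))
    u, v, w, x = _kernels.goodwin_em(
        n_steps, dt, 1.0, params.m, params.ku, params.kv, params.kw,
        params.alpha, params.beta, params.k, 0.0, 0.0,
        coef, powr, 2, 0.0, 0.0, 0.0, 0.0, 0,
    )
    i0 = int(discard / dt)
    t = dt * np.arange(len(w))
    w_tail = w[i0:]
    if w_tail.max() - w_tail.min() < 1e-6:
        raise NonOscillationError("clock amplitude collapsed; is m above the Hopf threshold?")
    return _period_from_crossings(t[i0:], w_tail)
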