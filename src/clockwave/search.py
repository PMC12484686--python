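"""Samplers and optimizers over regulatory-function coefficient space.

Three ways of exploring the space of Fourier regulatory functions, each
scoring candidate coefficient vectors by the CV of the output period:

* :func:`sample_random_functions` — independent uniform draws on [-1,1]^(2H);
* :func:`gibbs_sample` — Gibbs sampling with conditional weights
  ``p(x_i | rest) ∝ exp(-CV)`` evaluated on a uniform grid per coordinate;
* :func:`evolve_minimum` — a simple mutation + truncation-selection
  evolutionary minimizer.

CV values come from a :class:`CVEvaluator`: either the closed-form
decomposition (:class:`AnalyticCVEvaluator`) or stochastic simulation on a
*frozen* noise realization (:class:`SimulationCVEvaluator`).  Freezing the
noise path makes the simulation evaluator a deterministic function of the
coefficients for a given seed, so comparisons between candidate functions
(and against the pure sine reference) use common random numbers, which
suppresses most Monte-Carlo noise in the comparison.

Both evaluators are invariant under rescaling of the coefficient vector, so
the Gibbs chain samples raw coordinates in [-1,1] without renormalizing
between updates; normalization is applied only in reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _kernels
from .models import PhaseModelParams
from .periodstats import TRACK_WINDOW_FRACTION
from .regfun import FourierRegFunction

__all__ = [
    "AnalyticCVEvaluator",
    "SimulationCVEvaluator",
    "GibbsConfig",
    "EvolveConfig",
    "SampleRecord",
    "sample_random_functions",
    "gibbs_sample",
    "evolve_minimum",
    "mean_harmonic_power",
    "records_to_array",
]


@dataclass(frozen=True)
class SampleRecord:
    """One sampled regulatory function and its evaluated CV (percent)."""

    coefficients: np.ndarray
    normalized_coefficients: np.ndarray
    cv: float
    index: int


def _normalize_vec(c: np.ndarray) -> np.ndarray:
    nrm = float(np.sqrt(np.sum(c * c)))
    return c / nrm if nrm > 0 else c.copy()


def _make_records(coeffs: np.ndarray, cvs: np.ndarray) -> list[SampleRecord]:
    return [
        SampleRecord(
            coefficients=coeffs[i].copy(),
            normalized_coefficients=_normalize_vec(coeffs[i]),
            cv=float(cvs[i]),
            index=i,
        )
        for i in range(len(cvs))
    ]


def records_to_array(records: Sequence[SampleRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(coefficient matrix, cv vector) views of a record list."""
    c = np.array([r.coefficients for r in records])
    cv = np.array([r.cv for r in records])
    return c, cv


class AnalyticCVEvaluator:
    """Closed-form CV (percent) as a function of the coefficient vector."""

    mode = "analytic"

    def __init__(self, params: PhaseModelParams, grid_m: int = 96):
        self.params = params
        self.grid_m = int(grid_m)

    def __call__(self, coefficients) -> float:
        c = np.ascontiguousarray(coefficients, dtype=float)
        return float(
            _kernels.analytic_cv_kernel(
                c, self.params.k, self.params.omega, self.params.D,
                self.params.epsilon, self.grid_m,
            )
        )

    def sine_cv(self, harmonics: int = 3) -> float:
        return self(FourierRegFunction.sine(harmonics).as_vector())


class SimulationCVEvaluator:
    """Peak-to-peak CV (percent) from simulation on a frozen noise path.

    One realization of the noisy phase is drawn at construction (from
    ``seed``) and the reporter's linear-filter responses to each Fourier
    component of the drive are integrated once along it.  Because the
    reporter equation is linear in the drive, the response to any coefficient
    vector is the matching linear combination of those basis responses — so
    each evaluation costs one combination plus peak tracking, is exactly
    reproducible, and shares its noise realization with every other
    evaluation (common random numbers).

    Peak detection runs on a ``decimate``-fold thinned series; the tracking
    window and quadratic refinement make the CV insensitive to this thinning
    (the markers move by far less than the period jitter being measured).
    """

    mode = "simulation"

    def __init__(
        self,
        params: PhaseModelParams,
        harmonics: int,
        seed: int,
        n_intervals: int = 400,
        discard: float = 100.0,
        dt: float = 1.0e-3,
        decimate: int = 5,
        window: float | None = None,
        refine_half: float = 0.0,
    ):
        self.params = params
        self.harmonics = int(harmonics)
        self.seed = int(seed)
        self.n_intervals = int(n_intervals)
        self.discard = float(discard)
        self.dt = float(dt)
        self.decimate = int(decimate)
        tau = params.tau
        self.window = TRACK_WINDOW_FRACTION * tau if window is None else float(window)
        # 0.0 selects three-point quadratic peak refinement, which at the
        # default five-fold thinning reproduces the full-resolution marker
        # times to well under the period jitter being measured; a positive
        # value switches to a least-squares parabola over that half-width
        self.refine_half = float(refine_half)
        duration = discard + (n_intervals + 2) * tau
        n_steps = int(round(duration / dt))
        th = _kernels.theta_path(n_steps, dt, params.omega, params.epsilon,
                                 params.D, seed)
        self.basis = _kernels.basis_responses(th, self.harmonics, params.k, dt,
                                              self.decimate)
        self.dt_dec = dt * self.decimate
        self.i0 = int(round(discard / self.dt_dec))
        self._ybuf = np.empty(self.basis.shape[0])

    def __call__(self, coefficients) -> float:
        c = np.ascontiguousarray(coefficients, dtype=float)
        if c.size != 2 * self.harmonics:
            raise ValueError(
                f"expected {2 * self.harmonics} coefficients, got {c.size}"
            )
        return float(
            _kernels.combo_cv(
                self.basis, c, self.params.alpha, self.params.beta,
                self.dt_dec, self.i0, self.params.tau, self.window,
                self.refine_half, self._ybuf,
            )
        )

    def sine_cv(self) -> float:
        return self(FourierRegFunction.sine(self.harmonics).as_vector())


def sample_random_functions(
    harmonics: int,
    n: int,
    seed: int,
    evaluator: Callable[[np.ndarray], float],
) -> list[SampleRecord]:
    """n independent functions with coefficients uniform on [-1, 1].

    All-zero draws (probability zero, but guarded) are redrawn.  Each record
    carries the evaluated CV.
    """
    if harmonics < 1 or n < 1:
        raise ValueError("harmonics and n must be positive")
    rng = np.random.default_rng(seed)
    d = 2 * harmonics
    coeffs = np.empty((n, d))
    cvs = np.empty(n)
    for i in range(n):
        c = rng.uniform(-1.0, 1.0, d)
        while np.all(c == 0.0):
            c = rng.uniform(-1.0, 1.0, d)
        coeffs[i] = c
        cvs[i] = evaluator(c)
    return _make_records(coeffs, cvs)


@dataclass(frozen=True)
class GibbsConfig:
    """Gibbs chain settings.

    ``grid_n`` is the conditional-grid resolution: each coordinate update
    evaluates the weight at x_i = -1 + 2j/grid_n for j = 0..grid_n and samples
    from the normalized discrete distribution.  One sample is recorded per
    full sweep; the first ``burn_in`` sweeps are discarded.  ``cv_units``
    selects the scale of CV inside exp(-CV): "percent" (default; e.g. 2.7)
    or "fraction" (0.027, a nearly flat weight).
    """

    n_max: int
    burn_in: int = 1000
    grid_n: int = 100
    seed: int = 0
    cv_units: str = "percent"

    def __post_init__(self) -> None:
        if not (self.n_max > self.burn_in >= 0):
            raise ValueError("need n_max > burn_in >= 0")
        if self.grid_n < 2:
            raise ValueError("grid_n must be >= 2")
        if self.cv_units not in ("percent", "fraction"):
            raise ValueError("cv_units must be 'percent' or 'fraction'")


def gibbs_sample(
    evaluator: Callable[[np.ndarray], float],
    config: GibbsConfig,
    harmonics: int = 3,
) -> list[SampleRecord]:
    """Gibbs sampling of coefficient vectors with weights exp(-CV).

    Dispatches to compiled chains for the built-in evaluators; any other
    callable runs through a (slower) generic loop with identical semantics.
    """
    percent = config.cv_units == "percent"
    if isinstance(evaluator, AnalyticCVEvaluator):
        p = evaluator.params
        coeffs, cvs = _kernels.gibbs_chain_analytic(
            harmonics, p.k, p.omega, p.D, p.epsilon,
            config.n_max, config.burn_in, config.grid_n, config.seed,
            percent, evaluator.grid_m,
        )
    elif isinstance(evaluator, SimulationCVEvaluator):
        if harmonics != evaluator.harmonics:
            raise ValueError("harmonics must match the evaluator's basis")
        p = evaluator.params
        coeffs, cvs = _kernels.gibbs_chain_simulation(
            evaluator.basis, p.alpha, p.beta, evaluator.dt_dec, evaluator.i0,
            p.tau, evaluator.window, evaluator.refine_half,
            config.n_max, config.burn_in, config.grid_n, config.seed, percent,
        )
    else:
        coeffs, cvs = _gibbs_generic(evaluator, config, harmonics)
    if not np.all(np.isfinite(cvs)):
        raise RuntimeError("Gibbs chain produced non-finite CV values")
    return _make_records(coeffs, cvs)


def _gibbs_generic(evaluator, config: GibbsConfig, harmonics: int):
    rng = np.random.default_rng(config.seed)
    d = 2 * harmonics
    scale = 1.0 if config.cv_units == "percent" else 0.01
    x = rng.uniform(-1.0, 1.0, d)
    grid = -1.0 + 2.0 * np.arange(config.grid_n + 1) / config.grid_n
    n_ret = config.n_max - config.burn_in
    out_c = np.empty((n_ret, d))
    out_cv = np.empty(n_ret)
    cur = evaluator(x)
    for s in range(config.n_max):
        for i in range(d):
            cvg = np.empty(config.grid_n + 1)
            for j, g in enumerate(grid):
                x[i] = g
                cvg[j] = evaluator(x)
            w = np.exp(-(cvg - cvg.min()) * scale)
            tot = w.sum()
            if not np.isfinite(tot) or tot <= 0:
                raise RuntimeError(
                    f"degenerate conditional at sweep {s}, coordinate {i}: "
                    f"state {x!r}, weights {w!r}"
                )
            pick = int(np.searchsorted(np.cumsum(w), rng.random() * tot))
            pick = min(pick, config.grid_n)
            x[i] = grid[pick]
            cur = cvg[pick]
        if s >= config.burn_in:
            out_c[s - config.burn_in] = x
            out_cv[s - config.burn_in] = cur
    return out_c, out_cv


@dataclass(frozen=True)
class EvolveConfig:
    """Evolutionary-minimization settings (population search on [-1,1]^2H)."""

    population: int = 64
    generations: int = 300
    sigma: float = 0.05
    survival_fraction: float = 0.25
    seed: int = 0


def evolve_minimum(
    evaluator: Callable[[np.ndarray], float],
    harmonics: int,
    config: EvolveConfig = EvolveConfig(),
) -> tuple[SampleRecord, np.ndarray]:
    """Minimize CV by Gaussian mutation + truncation selection.

    Returns the best record found and the per-generation best-CV trace.
    The best individual is retained unmutated across generations (elitism).
    """
    rng = np.random.default_rng(config.seed)
    d = 2 * harmonics
    n_pop = config.population
    n_sur = max(1, int(round(config.survival_fraction * n_pop)))
    pop = rng.uniform(-1.0, 1.0, (n_pop, d))
    fit = np.array([evaluator(c) for c in pop])
    trace = np.empty(config.generations)
    for gen in range(config.generations):
        order = np.argsort(fit)
        pop, fit = pop[order], fit[order]
        trace[gen] = fit[0]
        parents = pop[:n_sur]
        children = parents[rng.integers(0, n_sur, n_pop - 1)] + rng.normal(
            0.0, config.sigma, (n_pop - 1, d)
        )
        np.clip(children, -1.0, 1.0, out=children)
        pop = np.vstack([pop[:1], children])  # elitism
        fit = np.concatenate([fit[:1], [evaluator(c) for c in children]])
    best = int(np.argmin(fit))
    record = SampleRecord(
        coefficients=pop[best].copy(),
        normalized_coefficients=_normalize_vec(pop[best]),
        cv=float(fit[best]),
        index=0,
    )
    return record, trace


def mean_harmonic_power(
    records: Sequence[SampleRecord],
    selector: Callable[[float], bool] | None = None,
) -> np.ndarray:
    """Average per-harmonic power <r_i^2> over (selected) records.

    Each record's coefficients are normalized to unit total power before the
    powers are averaged, so the result sums to 1.  ``selector`` filters
    records by their CV value.
    """
    chosen = [r for r in records if selector is None or selector(r.cv)]
    if not chosen:
        raise ValueError("selector matched no records")
    mats = np.array([r.normalized_coefficients for r in chosen])
    powers = mats[:, 0::2] ** 2 + mats[:, 1::2] ** 2
    return powers.mean(axis=0)
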