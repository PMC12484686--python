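"""Closed-form CV of the threshold-defined output period.

For the phase-oscillator + reporter model the period fluctuation of the
output, measured at a fixed checkpoint (an upward crossing of the midpoint
of the noiseless oscillation range), has the weak-noise expansion

    CV = (epsilon / tau) * sqrt(R_TT + R_hh + 2 R_Th) + O(epsilon^2)

where ``R_TT`` is the variance of the system-level phase, ``R_hh`` the
autocorrelation of the amplitude deviation, and ``R_Th`` their
cross-correlation (the only possibly negative component).  For this model all
three have explicit expressions in the Fourier coefficients of the regulatory
function, the reporter degradation rate k and the clock frequency omega; the
basal rate alpha and coupling strength beta drop out entirely, which is the
analytical counterpart of the numerical observation that they do not affect
the output CV.

All component formulas are transcribed literally, including the per-harmonic
phase offsets

    Phi_i(t_cp) = i*omega*t_cp + arctan((k A_i - i omega B_i)/(i omega A_i + k B_i))
                  + (pi/2) (1 - sgn(i omega A_i + k B_i))

with ``sgn(0) = +1`` (the correction term then vanishes, continuous with the
limit from above).  The sums truncate exactly at the function's harmonic
count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from .models import PhaseModelParams, limit_cycle_harmonics
from .regfun import FourierRegFunction

__all__ = [
    "CVBreakdown",
    "phase_offsets",
    "checkpoint_time",
    "cv_components",
    "analytic_cv",
    "clock_cv",
    "DegenerateFunctionError",
    "IllConditionedCheckpointError",
]


class DegenerateFunctionError(ValueError):
    """The output has no oscillation (no nonzero harmonic / no crossing)."""


class IllConditionedCheckpointError(RuntimeError):
    """The checkpoint sits at zero slope; the decomposition denominator vanishes."""


@dataclass(frozen=True)
class CVBreakdown:
    """The three variance components, checkpoint time and composed CV."""

    R_theta_theta: float
    R_hh: float
    R_theta_h: float
    t_cp: float
    cv: float

    @property
    def cv_percent(self) -> float:
        return 100.0 * self.cv

    @property
    def radicand(self) -> float:
        return self.R_theta_theta + self.R_hh + 2.0 * self.R_theta_h


def phase_offsets(
    f: FourierRegFunction, k: float, omega: float, t_cp: float
) -> np.ndarray:
    """Per-harmonic phase offsets Phi_i(t_cp), literal transcription.

    Harmonics with zero power are assigned Phi_i = 0; they multiply a zero
    amplitude in every sum so the value is immaterial.
    """
    if k <= 0 or omega <= 0:
        raise ValueError("k and omega must be positive")
    vec = f.as_vector()
    out = np.zeros(f.harmonics)
    for i in range(1, f.harmonics + 1):
        a, b = vec[2 * i - 2], vec[2 * i - 1]
        if a == 0.0 and b == 0.0:
            continue
        den = i * omega * a + k * b
        num = k * a - i * omega * b
        sgn = 1.0 if den >= 0.0 else -1.0  # sgn(0) -> +1
        if den != 0.0:
            base = math.atan(num / den)
        else:
            base = math.pi / 2 if num >= 0.0 else -math.pi / 2
        out[i - 1] = i * omega * t_cp + base + (math.pi / 2) * (1.0 - sgn)
    return out


def checkpoint_time(
    params: PhaseModelParams, f: FourierRegFunction, grid_n: int = 8192
) -> float:
    """Checkpoint time in [0, tau): the upward midpoint crossing of x*(t).

    When the noiseless limit cycle crosses its midpoint upward more than once
    per period, the crossing with the steepest slope is used — the
    best-conditioned checkpoint (largest decomposition denominator).
    """
    R, phi = limit_cycle_harmonics(params, f)
    if np.all(R == 0.0):
        raise DegenerateFunctionError("all harmonics vanish; output is constant")
    om = params.omega
    tau = params.tau
    H = f.harmonics

    def y(t):
        s = 0.0
        for i in range(1, H + 1):
            s += R[i - 1] * math.sin(i * om * t + phi[i - 1])
        return s

    def dy(t):
        s = 0.0
        for i in range(1, H + 1):
            s += R[i - 1] * i * om * math.cos(i * om * t + phi[i - 1])
        return s

    grid = np.linspace(0.0, tau, grid_n, endpoint=False)
    vals = np.zeros(grid_n)
    for i in range(1, H + 1):
        vals += R[i - 1] * np.sin(i * om * grid + phi[i - 1])
    mid = 0.5 * (vals.max() + vals.min())
    z = vals - mid
    z_next = np.roll(z, -1)
    up = np.nonzero((z < 0) & (z_next >= 0))[0]
    if len(up) == 0:
        raise DegenerateFunctionError("no upward midpoint crossing found")
    best_t, best_slope = None, -np.inf
    step = tau / grid_n
    for j in up:
        t_c = brentq(lambda t: y(t) - mid, grid[j], grid[j] + step, xtol=1e-14)
        sl = dy(t_c)
        if sl > best_slope:
            best_slope, best_t = sl, t_c
    return float(best_t % tau)


def cv_components(
    params: PhaseModelParams, f: FourierRegFunction, t_cp: float
) -> CVBreakdown:
    """The three CV components at a given checkpoint time.

    R_TT = D tau^2 / (2 pi omega) exactly; R_hh and R_Th follow the explicit
    double/single sums over harmonics with the common denominator
    ``sum_i i omega sqrt(r_i^2/(k^2+(i omega)^2)) cos Phi_i(t_cp)``.
    """
    vec = f.as_vector()
    r_tt, r_hh, r_th, _, cv = _kernels.cv_components_kernel(
        vec, params.k, params.omega, params.D, params.epsilon, t_cp
    )
    if math.isnan(r_hh):
        raise IllConditionedCheckpointError(
            "decomposition denominator vanishes at this checkpoint (zero slope)"
        )
    if math.isnan(cv):
        raise IllConditionedCheckpointError(
            f"negative radicand {r_tt + r_hh + 2 * r_th:.3g}; "
            "checkpoint inconsistent with the weak-noise expansion"
        )
    return CVBreakdown(R_theta_theta=r_tt, R_hh=r_hh, R_theta_h=r_th, t_cp=t_cp, cv=cv)


def analytic_cv(params: PhaseModelParams, f: FourierRegFunction) -> float:
    """Closed-form CV (as a fraction) of the threshold-defined output period.

    Composition checkpoint_time -> cv_components -> cv.  Independent of alpha
    and beta by construction, and invariant under rescaling the coefficients.
    """
    t_cp = checkpoint_time(params, f)
    return cv_components(params, f, t_cp).cv


def clock_cv(epsilon: float, D: float, omega: float) -> float:
    """CV (fraction) of the clock itself: epsilon * sqrt(D / (2 pi omega))."""
    if omega <= 0:
        raise ValueError("omega must be positive")
    if D < 0:
        raise ValueError("D must be nonnegative")
    return epsilon * math.sqrt(D / (2.0 * math.pi * omega))
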