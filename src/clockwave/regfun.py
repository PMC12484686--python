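"""Regulatory functions mapping clock state to output synthesis rate.

Two families are supported: truncated Fourier series ``f(theta)`` driving the
phase-oscillator output model, and polynomials ``g(w)`` driving the output of
the Goodwin clock.  The Fourier coefficients live in the space the waveform
samplers explore, so this module also provides normalization, per-harmonic
power and the biological rate-positivity check ``alpha + beta*f(theta) >= 0``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FourierRegFunction",
    "PolynomialRegulation",
    "HarmonicPower",
    "check_rate_positivity",
]


class InvalidFunctionError(ValueError):
    """Raised for degenerate regulatory functions (e.g. all-zero coefficients)."""


@dataclass(frozen=True)
class HarmonicPower:
    """Per-harmonic power ``r_i^2 = A_i^2 + B_i^2`` of a Fourier regulatory function."""

    powers: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.powers):
            raise ValueError("harmonic powers must be nonnegative")

    @property
    def total(self) -> float:
        return float(sum(self.powers))


@dataclass(frozen=True)
class FourierRegFunction:
    """Finite Fourier series ``f(theta) = sum_i A_i cos(i theta) + B_i sin(i theta)``.

    Parameters
    ----------
    coeffs
        Ordered ``(A_i, B_i)`` pairs for harmonics ``i = 1..H``.
    normalized
        Set when the coefficients are known to satisfy ``sum_i r_i^2 = 1``.
        Functions are stored as given; the period-variability measures in this
        package are invariant under an overall rescaling of the coefficients,
        so normalization matters only for reporting and sampling bounds.
    """

    coeffs: tuple[tuple[float, float], ...]
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        if len(self.coeffs) < 1:
            raise InvalidFunctionError("need at least one harmonic")
        object.__setattr__(
            self, "coeffs", tuple((float(a), float(b)) for a, b in self.coeffs)
        )
        if self.normalized:
            if abs(self.power().total - 1.0) > 1e-12:
                raise InvalidFunctionError("normalized flag set but total power != 1")

    # -- constructors -------------------------------------------------
    @classmethod
    def from_vector(cls, vec: Sequence[float], normalized: bool = False) -> "FourierRegFunction":
        """Build from the flat coordinate vector ``(A_1, B_1, ..., A_H, B_H)``."""
        v = np.asarray(vec, dtype=float)
        if v.ndim != 1 or v.size % 2 != 0 or v.size == 0:
            raise InvalidFunctionError("coordinate vector must have even positive length")
        pairs = tuple((float(v[2 * i]), float(v[2 * i + 1])) for i in range(v.size // 2))
        return cls(pairs, normalized=normalized)

    @classmethod
    def sine(cls, harmonics: int = 1) -> "FourierRegFunction":
        """The pure sine wave ``f(theta) = sin(theta)`` padded to ``harmonics`` terms."""
        pairs = [(0.0, 1.0)] + [(0.0, 0.0)] * (harmonics - 1)
        return cls(tuple(pairs), normalized=True)

    # -- basic views --------------------------------------------------
    @property
    def harmonics(self) -> int:
        return len(self.coeffs)

    def as_vector(self) -> np.ndarray:
        """Flat coordinate vector ``(A_1, B_1, ..., A_H, B_H)``."""
        return np.array([c for pair in self.coeffs for c in pair], dtype=float)

    # -- evaluation ---------------------------------------------------
    def __call__(self, theta):
        theta = np.asarray(theta, dtype=float)
        out = np.zeros_like(theta)
        for i, (a, b) in enumerate(self.coeffs, start=1):
            if a != 0.0:
                out = out + a * np.cos(i * theta)
            if b != 0.0:
                out = out + b * np.sin(i * theta)
        return out if out.ndim else float(out)

    # -- power and normalization --------------------------------------
    def power(self) -> HarmonicPower:
        return HarmonicPower(tuple(a * a + b * b for a, b in self.coeffs))

    def normalize(self) -> "FourierRegFunction":
        """Rescale so the total harmonic power is 1.

        Idempotent; raises :class:`InvalidFunctionError` for an all-zero
        coefficient vector.
        """
        total = self.power().total
        if total <= 0.0:
            raise InvalidFunctionError("cannot normalize an all-zero coefficient vector")
        if abs(total - 1.0) <= 1e-12:
            return FourierRegFunction(self.coeffs, normalized=True)
        s = 1.0 / math.sqrt(total)
        pairs = tuple((a * s, b * s) for a, b in self.coeffs)
        f = FourierRegFunction(pairs)
        # re-tag after the rescale; rounding keeps the sum within 1e-12 of 1
        object.__setattr__(f, "normalized", True)
        return f

    def amplitude_bound(self) -> float:
        """Cauchy-Schwarz bound ``max |f| <= sqrt(H * sum r_i^2)``."""
        return math.sqrt(self.harmonics * self.power().total)

    # -- serialization ------------------------------------------------
    def to_record(self) -> dict:
        rec = {"H": self.harmonics}
        for i, (a, b) in enumerate(self.coeffs, start=1):
            rec[f"A{i}"] = a
            rec[f"B{i}"] = b
        return rec

    @classmethod
    def from_record(cls, rec: dict) -> "FourierRegFunction":
        h = int(rec["H"])
        pairs = tuple((float(rec[f"A{i}"]), float(rec[f"B{i}"])) for i in range(1, h + 1))
        return cls(pairs)

    def to_csv_row(self) -> str:
        vals = [str(self.harmonics)] + [repr(float(c)) for c in self.as_vector()]
        return ",".join(vals)

    @classmethod
    def from_csv_row(cls, row: str) -> "FourierRegFunction":
        parts = row.strip().split(",")
        h = int(parts[0])
        vec = [float(p) for p in parts[1 : 1 + 2 * h]]
        return cls.from_vector(vec)


@dataclass(frozen=True)
class PolynomialRegulation:
    """Polynomial regulation ``g(w) = sum_p c_p w^p`` of the output by clock protein w.

    At least one term must have power >= 1; a constant g makes the output
    arrhythmic.
    """

    terms: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "terms", tuple((float(c), int(p)) for c, p in self.terms)
        )
        if any(p < 0 for _, p in self.terms):
            raise InvalidFunctionError("polynomial powers must be nonnegative")
        if not any(p >= 1 and c != 0.0 for c, p in self.terms):
            raise InvalidFunctionError("regulation must depend on the clock (a term with power >= 1)")

    def __call__(self, w):
        w = np.asarray(w, dtype=float)
        out = np.zeros_like(w)
        for c, p in self.terms:
            out = out + c * w**p
        return out if out.ndim else float(out)

    def coefficient_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(coefficients, powers) arrays for compiled simulation kernels."""
        c = np.array([t[0] for t in self.terms], dtype=float)
        p = np.array([t[1] for t in self.terms], dtype=np.int64)
        return c, p

    def to_json(self) -> str:
        return json.dumps([[c, p] for c, p in self.terms])

    @classmethod
    def from_json(cls, text: str) -> "PolynomialRegulation":
        return cls(tuple((float(c), int(p)) for c, p in json.loads(text)))


def check_rate_positivity(
    alpha: float,
    beta: float,
    f: FourierRegFunction,
    grid_n: int = 4096,
) -> tuple[bool, float]:
    """Check the synthesis-rate constraint ``alpha + beta * f(theta) >= 0``.

    The minimum is taken over a uniform theta grid.  A sufficient analytic
    bound (``alpha - |beta| * sqrt(H * sum r_i^2) >= 0``) short-circuits the
    grid scan when it already guarantees positivity.

    Returns ``(ok, min_rate)`` where ``min_rate`` is the grid minimum of the
    rate.
    """
    if grid_n < 64:
        raise ValueError("grid_n must be at least 64")
    theta = np.linspace(0.0, 2.0 * np.pi, grid_n, endpoint=False)
    rate = alpha + beta * f(theta)
    min_rate = float(np.min(rate))
    if alpha - abs(beta) * f.amplitude_bound() >= 0.0:
        return True, min_rate
    return min_rate >= 0.0, min_rate
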