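"""Periodic smooth random functions.

Band-limited, L-periodic Gaussian trigonometric sums

    zeta(t) = alpha * ( a_0 + sum_{j=1}^{r} a_j cos(2*pi*j*t/L) + b_j sin(2*pi*j*t/L) ),
    r = floor(L / lambda_w),

used as pathwise-differentiable fluctuation models in random ODEs.  Being
trigonometric polynomials, they are entire: derivatives and antiderivatives of
every order exist in closed form, which this module exposes exactly.

Two normalisations are provided for the i.i.d. zero-mean normal coefficients:

``standard``
    every coefficient has variance 1/(2r+1); the pointwise variance of zeta is
    alpha^2 (r+1)/(2r+1).
``big``
    a_0 has variance 2/((2r+1) lambda_w) and a_j, b_j (j>=1) have variance
    4/((2r+1) lambda_w).  With this scaling the indefinite integral
    int_0^t zeta has variance 2Lt/((2r+1) lambda_w) -> t, so it converges to a
    standard Brownian path as the wavelength shrinks.

The module also provides the classical level-crossing (Rice) bound on the
probability that zeta leaves a tube of half-width ``u_thr`` over a horizon T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrigonometricSum",
    "SmoothRandomFunction",
    "TubeBoundInputs",
    "sample_srf",
    "derivative_function",
    "integral_path",
    "tube_exceedance_bound",
    "pointwise_std",
    "derivative_rms",
]


@dataclass(frozen=True)
class TrigonometricSum:
    """An L-periodic trigonometric polynomial with exact calculus.

    ``alpha * (a[0] + sum_j a[j] cos(w_j t) + b[j-1] sin(w_j t))`` with
    ``w_j = 2*pi*j/L``.  ``a`` has length r+1 and ``b`` length r.
    """

    period: float
    a: np.ndarray
    b: np.ndarray
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError(f"period must be positive, got {self.period}")
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        b = np.atleast_1d(np.asarray(self.b, dtype=float)) if np.size(self.b) else np.zeros(0)
        if a.size != b.size + 1:
            raise ValueError("need len(a) == len(b) + 1")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def r(self) -> int:
        """Truncation index: highest harmonic present."""
        return self.b.size

    @property
    def frequencies(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(1, self.r + 1) / self.period

    def evaluate(self, t, order: int = 0):
        """Exact value of the ``order``-th derivative at time(s) ``t``.

        Term-wise differentiation shifts each harmonic's phase by
        order*pi/2 and scales it by w_j**order; the constant term survives
        only at order 0.
        """
        if order < 0:
            raise ValueError("derivative order must be >= 0")
        t = np.asarray(t, dtype=float)
        w = self.frequencies
        phase = np.multiply.outer(t, w) + order * (np.pi / 2.0)
        gain = w**order
        val = (np.cos(phase) * (gain * self.a[1:])).sum(axis=-1)
        val = val + (np.sin(phase) * (gain * self.b)).sum(axis=-1)
        if order == 0:
            val = val + self.a[0]
        out = self.alpha * val
        return float(out) if out.ndim == 0 else out

    __call__ = evaluate

    def derivative(self, order: int = 1) -> "TrigonometricSum":
        """Closed-form derivative as a new trigonometric sum.

        One application maps (a_j, b_j) -> (w_j b_j, -w_j a_j) and zeroes the
        constant term.
        """
        if order < 1:
            raise ValueError("derivative order must be >= 1")
        a, b = self.a.copy(), self.b.copy()
        w = self.frequencies
        for _ in range(order):
            a_new = np.concatenate(([0.0], w * b))
            b_new = -w * a[1:]
            a, b = a_new, b_new
        return TrigonometricSum(self.period, a, b, self.alpha)

    def integral(self, t):
        """Exact antiderivative int_0^t of the sum, vectorised over ``t``."""
        t = np.asarray(t, dtype=float)
        w = self.frequencies
        val = self.a[0] * t
        if self.r:
            wt = np.multiply.outer(t, w)
            val = val + (np.sin(wt) * (self.a[1:] / w)).sum(axis=-1)
            val = val + ((1.0 - np.cos(wt)) * (self.b / w)).sum(axis=-1)
        out = self.alpha * val
        return float(out) if out.ndim == 0 else out


def _coefficient_stds(r: int, lambda_w: float, mode: str) -> tuple[float, float]:
    """(std of a_0, std of a_j/b_j for j>=1) under the chosen normalisation."""
    if mode == "standard":
        s = math.sqrt(1.0 / (2 * r + 1))
        return s, s
    if mode == "big":
        base = 2.0 / ((2 * r + 1) * lambda_w)
        return math.sqrt(base), math.sqrt(2.0 * base)
    raise ValueError(f"unknown normalisation mode {mode!r}")


@dataclass(frozen=True)
class SmoothRandomFunction(TrigonometricSum):
    """A seeded sample of an L-periodic smooth random function."""

    wavelength: float = 1.0
    mode: str = "standard"
    seed: int = 0
    # a, b are filled in by sample_srf; dataclass needs defaults after parent's
    a: np.ndarray = field(default_factory=lambda: np.zeros(1))
    b: np.ndarray = field(default_factory=lambda: np.zeros(0))


def sample_srf(
    L: float,
    lambda_w: float,
    mode: str = "standard",
    alpha: float = 1.0,
    seed: int = 0,
) -> SmoothRandomFunction:
    """Draw one smooth random function.

    ``r = floor(L/lambda_w)`` harmonics; the 2r+1 coefficients are drawn
    i.i.d. zero-mean normal in the fixed order (a_0, a_1, b_1, ..., a_r, b_r)
    from ``numpy.random.default_rng(seed)``, so identical seeds reproduce
    identical coefficients.  ``alpha`` scales the whole sum.
    """
    if L <= 0:
        raise ValueError(f"period L must be positive, got {L}")
    if lambda_w <= 0:
        raise ValueError(f"wavelength must be positive, got {lambda_w}")
    if alpha < 0:
        raise ValueError(f"amplitude scale must be >= 0, got {alpha}")
    r = int(math.floor(L / lambda_w))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(2 * r + 1)
    s0, s1 = _coefficient_stds(r, lambda_w, mode)
    a = np.empty(r + 1)
    b = np.empty(r)
    a[0] = s0 * z[0]
    if r:
        a[1:] = s1 * z[1::2]
        b[:] = s1 * z[2::2]
    return SmoothRandomFunction(
        period=L, a=a, b=b, alpha=alpha, wavelength=lambda_w, mode=mode, seed=seed
    )


def derivative_function(f: TrigonometricSum, order: int = 1) -> TrigonometricSum:
    """Functional form of the ``order``-th derivative of ``f``."""
    return f.derivative(order)


def integral_path(f: TrigonometricSum, t_grid) -> np.ndarray:
    """int_0^t f on an increasing time grid, via the closed-form antiderivative."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or (t_grid.size > 1 and np.any(np.diff(t_grid) <= 0)):
        raise ValueError("t_grid must be a strictly increasing 1-d grid")
    return np.asarray(f.integral(t_grid), dtype=float).reshape(t_grid.shape)


def pointwise_std(L: float, lambda_w: float, mode: str = "standard", alpha: float = 1.0) -> float:
    """Analytic RMS of zeta(t) under the coefficient law (sigma)."""
    r = int(math.floor(L / lambda_w))
    s0, s1 = _coefficient_stds(r, lambda_w, mode)
    return alpha * math.sqrt(s0**2 + r * s1**2)


def derivative_rms(L: float, lambda_w: float, mode: str = "standard", alpha: float = 1.0) -> float:
    """Analytic RMS of d zeta/dt under the coefficient law (lambda_2)."""
    r = int(math.floor(L / lambda_w))
    _, s1 = _coefficient_stds(r, lambda_w, mode)
    w2 = sum((2.0 * math.pi * j / L) ** 2 for j in range(1, r + 1))
    return alpha * math.sqrt(s1**2 * w2)


@dataclass(frozen=True)
class TubeBoundInputs:
    """Inputs to the tube-exceedance bound.

    sigma   -- RMS of zeta,          sigma^2 = E[zeta(t)^2]
    lambda2 -- RMS of d zeta/dt,     lambda2^2 = E[zeta'(t)^2]
    u_thr   -- tube half-width (same units as zeta)
    horizon -- time horizon T
    """

    sigma: float
    lambda2: float
    u_thr: float
    horizon: float

    def __post_init__(self) -> None:
        for name in ("sigma", "lambda2", "u_thr", "horizon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def tube_exceedance_bound(inputs: TubeBoundInputs) -> float:
    """Upper bound on P( sup_{[0,T]} zeta(t) >= u_thr ).

    Mills-ratio bound on the time-zero Gaussian tail plus the Rice expected
    up-crossing count, sharing the common Gaussian factor:

        exp(-u^2 / (2 sigma^2)) * ( sigma / (sqrt(2 pi) u) + T lambda2 / (2 pi sigma) )

    The value is clipped to [0, 1] since it reports a probability.
    """
    s, l2, u, T = inputs.sigma, inputs.lambda2, inputs.u_thr, inputs.horizon
    raw = math.exp(-(u**2) / (2.0 * s**2)) * (
        s / (math.sqrt(2.0 * math.pi) * u) + T * l2 / (2.0 * math.pi * s)
    )
    return float(min(1.0, max(0.0, raw)))
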