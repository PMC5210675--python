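"""Holling Type II functional response with prey depletion.

In a closed feeding arena prey are not replaced, so the number eaten over a
trial of length ``T`` is governed by the random predator equation

    Ne = N0 * (1 - exp(-a * (T - h * Ne)))

where ``a`` is the attack rate (per arena per day) and ``h`` the handling
time (days per prey item).  The implicit equation has the closed-form
solution on the principal branch of the Lambert W function

    Ne = N0 - W(a * h * N0 * exp(-a * (T - h * N0))) / (a * h)

for ``a, h > 0``; the limits ``a = 0`` (no attacks) and ``h = 0`` (pure
exponential depletion, Ne = N0 * (1 - exp(-a*T))) are handled analytically.

Everything here works on a single common time unit (days throughout this
package); attack-rate and handling-time estimates are meaningless without
their unit, so trial durations must be expressed on the same scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "FRParams",
    "TrialContext",
    "ConvergenceError",
    "lambert_w0",
    "holling_rate",
    "rogers_expected",
    "rogers_fixed_point",
]

_NEG_INV_E = -math.exp(-1.0)


class ConvergenceError(RuntimeError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class FRParams:
    """Functional-response parameters on a common time unit (days).

    Attributes
    ----------
    a : float
        Attack rate, arena^-1 day^-1 per predator; >= 0.
    h : float
        Handling time, days per prey item; >= 0.
    """

    a: float
    h: float

    def __post_init__(self):
        for name, value in (("a", self.a), ("h", self.h)):
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class TrialContext:
    """Fixed conditions of one feeding trial.

    Attributes
    ----------
    n0 : int
        Initial prey count; >= 1.
    T : float
        Trial duration in days; > 0.  A 72 h trial is T = 3.
    """

    n0: int
    T: float

    def __post_init__(self):
        if int(self.n0) != self.n0 or self.n0 < 1:
            raise ValueError(f"n0 must be a positive integer, got {self.n0!r}")
        if not math.isfinite(self.T) or self.T <= 0:
            raise ValueError(f"T must be a positive finite duration, got {self.T!r}")


def lambert_w0(x: float) -> float:
    """Principal branch of the Lambert W function, w * exp(w) = x.

    Halley iteration with a series-based start near the branch point
    x = -1/e; guaranteed absolute residual |w*e^w - x| <= 1e-10 on the
    domain x >= -1/e (internal tolerance 1e-12).

    Raises
    ------
    ValueError
        For non-finite input or x < -1/e (off the principal branch).
    """
    x = float(x)
    if not math.isfinite(x):
        raise ValueError(f"lambert_w0 requires finite input, got {x!r}")
    if x < _NEG_INV_E:
        # allow for representation error of -1/e itself
        if x > _NEG_INV_E - 1e-15:
            x = _NEG_INV_E
        else:
            raise ValueError(f"lambert_w0 domain is x >= -1/e, got {x!r}")
    if x == 0.0:
        return 0.0
    if x == _NEG_INV_E:
        return -1.0

    # initial guess
    if x < -0.25:
        # series about the branch point: w = -1 + p - p^2/3 + 11 p^3/72
        p = math.sqrt(2.0 * (math.e * x + 1.0))
        w = -1.0 + p - p * p / 3.0 + 11.0 * p ** 3 / 72.0
    elif x < 1.0:
        # low-order series about 0
        w = x * (1.0 - x + 1.5 * x * x)
    else:
        lx = math.log(x)
        w = lx - math.log(lx) if lx > 1.0 else lx

    for _ in range(100):
        ew = math.exp(w)
        f = w * ew - x
        if abs(f) <= max(1e-12, 1e-14 * abs(x)):
            break
        wp1 = w + 1.0
        # Halley step
        denom = ew * wp1 - (w + 2.0) * f / (2.0 * wp1)
        w -= f / denom
    residual = abs(w * math.exp(w) - x)
    # absolute 1e-10 is guaranteed on moderate x; for very large x double
    # precision only supports a relative residual (~1e-13 here)
    if residual > max(1e-10, 1e-13 * abs(x)):
        raise ConvergenceError(
            f"lambert_w0 did not reach tolerance at x={x!r}", residual=residual
        )
    return w


def _w0_from_log(logx: float) -> float:
    """W(exp(logx)) for large logx, where exp(logx) would overflow.

    For w > 0, w * e^w = x is equivalent to w + log(w) = log(x); the
    fixed-point iteration w <- logx - log(w) converges rapidly from
    w = logx when logx is large.
    """
    w = logx
    for _ in range(100):
        w_next = logx - math.log(w)
        if abs(w_next - w) <= 1e-12 * w_next:
            return w_next
        w = w_next
    raise ConvergenceError("log-scale Lambert W iteration did not converge")


def holling_rate(n: float, params: FRParams) -> float:
    """Instantaneous Type II consumption rate a*n / (1 + a*h*n).

    Prey consumed per predator per day at constant prey density ``n``;
    saturates at 1/h for h > 0.
    """
    if not math.isfinite(n) or n < 0:
        raise ValueError(f"prey count must be finite and >= 0, got {n!r}")
    return params.a * n / (1.0 + params.a * params.h * n)


def rogers_expected(ctx: TrialContext, params: FRParams) -> float:
    """Expected prey consumed over a depletion trial (random predator equation).

    Closed-form solution via the Lambert W function; the a = 0 and h = 0
    limits are evaluated analytically rather than as limits of the W
    expression.  The result lies in [0, n0).
    """
    a, h = params.a, params.h
    n0, T = ctx.n0, ctx.T
    if a == 0.0:
        return 0.0
    if h == 0.0:
        return n0 * (1.0 - math.exp(-a * T))
    log_arg = math.log(a * h * n0) - a * (T - h * n0)
    if log_arg > 500.0:
        # exp(log_arg) overflows; solve w + log(w) = log_arg directly
        w = _w0_from_log(log_arg)
    else:
        w = lambert_w0(math.exp(log_arg))
    ne = n0 - w / (a * h)
    # guard against representation error at the boundaries
    return min(max(ne, 0.0), float(n0))


def rogers_fixed_point(
    ctx: TrialContext,
    params: FRParams,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> float:
    """Brute-force fixed-point solution of the random predator equation.

    Iterates ``Ne <- N0 * (1 - exp(-a*(T - h*Ne)))`` from Ne = 0 until the
    successive change is below ``tol``.  Serves as an independent check on
    :func:`rogers_expected`.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    a, h = params.a, params.h
    n0, T = ctx.n0, ctx.T
    ne = 0.0
    for _ in range(max_iter):
        ne_next = n0 * (1.0 - math.exp(-a * (T - h * ne)))
        if abs(ne_next - ne) < tol:
            return ne_next
        ne = ne_next
    raise ConvergenceError(
        f"fixed-point iteration did not converge in {max_iter} steps",
        residual=abs(ne_next - ne),
    )
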