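"""Quasi-steady-state reduction of the active protein and the emergent
deterministic rate equation.

At frozen inactive-protein concentration x the active protein is a birth-death
process with constant birth rate x (an M/M/s_max/s_max loss queue); its
equilibrium is the truncated Poisson distribution

    rho_s(x) = N(x) x^s / s!,   s = 0..s_max.

Averaging the instantaneous burst frequency f_s over rho(x) mollifies it into
the smooth effective rate fbar(x), and the slow dynamics of x reduce to

    xdot = <B> fbar(x) - x.

This module computes rho, fbar and its exact derivative, the rate-equation
right-hand side, and the (transversal) fixed points with their stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

from .model import ModelSpec

__all__ = [
    "QSSDistribution",
    "FixedPoint",
    "qss_distribution",
    "effective_rate",
    "effective_rate_derivative",
    "rate_rhs",
    "find_fixed_points",
]


@dataclass(frozen=True)
class QSSDistribution:
    """Truncated Poisson rho_s(x) with normalising constant N(x)."""

    x: float
    rho: np.ndarray
    norm_const: float


def _truncated_poisson(s_max: int, x: float) -> np.ndarray:
    if x < 0:
        raise ValueError("x must be non-negative")
    if x == 0.0:
        rho = np.zeros(s_max + 1)
        rho[0] = 1.0
        return rho
    s = np.arange(s_max + 1)
    logw = s * np.log(x) - gammaln(s + 1.0)  # log-space: stable for large x
    return np.exp(logw - logsumexp(logw))


def qss_distribution(model: ModelSpec, x: float) -> QSSDistribution:
    rho = _truncated_poisson(model.s_max, x)
    return QSSDistribution(x=float(x), rho=rho, norm_const=float(rho[0]))


def effective_rate(model: ModelSpec, x: float) -> float:
    """fbar(x) = sum_s f_s rho_s(x): the QSS-mollified burst frequency."""
    return float(model.feedback.rates @ _truncated_poisson(model.s_max, x))


def effective_rate_derivative(model: ModelSpec, x: float) -> float:
    """Exact derivative of fbar:

    fbar'(x) = sum_{s < s_max} (f_{s+1} - f_s) rho_s(x)
               + (fbar(x) - f_{s_max}) rho_{s_max}(x).
    """
    f = model.feedback.rates
    rho = _truncated_poisson(model.s_max, x)
    fbar = float(f @ rho)
    return float((f[1:] - f[:-1]) @ rho[:-1] + (fbar - f[-1]) * rho[-1])


def rate_rhs(model: ModelSpec, x: float) -> float:
    """Right-hand side <B> fbar(x) - x of the emergent rate equation; equals
    H_theta(x, 0)."""
    return model.burst.mean * effective_rate(model, x) - x


@dataclass(frozen=True)
class FixedPoint:
    """Root of the rate equation with linear stability and a role label
    (x_0 for the monostable case, x_minus/x_zero/x_plus for the bistable
    triple, fp<i> otherwise)."""

    x_star: float
    stability: str  # "stable" | "unstable"
    role: str

    @property
    def stable(self) -> bool:
        return self.stability == "stable"


def find_fixed_points(
    model: ModelSpec,
    x_upper: float | None = None,
    n_scan: int = 2000,
    degenerate_tol: float = 1e-8,
) -> list[FixedPoint]:
    """All transversal roots of the rate equation on [0, x_upper].

    Roots are located by a sign-change scan on a uniform grid followed by
    Brent refinement; each is classified stable/unstable by the sign of
    <B> fbar'(x_*) - 1.  Tangent (double) roots are reported as errors.
    """
    if x_upper is None:
        x_upper = 2.0 * model.burst.mean * model.feedback.max_rate
    if x_upper <= 0:
        raise ValueError("x_upper must be positive")

    grid = np.linspace(0.0, x_upper, n_scan + 1)
    vals = np.array([rate_rhs(model, x) for x in grid])

    roots: list[float] = []
    for i in range(n_scan):
        a, b = grid[i], grid[i + 1]
        fa, fb = vals[i], vals[i + 1]
        if fa == 0.0:
            if not roots or abs(roots[-1] - a) > 1e-9:
                roots.append(float(a))
            continue
        if fa * fb < 0.0:
            roots.append(float(brentq(lambda x: rate_rhs(model, x), a, b,
                                      xtol=1e-14, rtol=8.9e-16)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))

    if not roots or len(roots) % 2 == 0:
        raise ValueError(
            f"expected an odd number of transversal fixed points on "
            f"[0, {x_upper}], found {len(roots)}; enlarge the bracket or "
            "check the feedback response"
        )

    fps: list[FixedPoint] = []
    for x_star in roots:
        d = model.burst.mean * effective_rate_derivative(model, x_star) - 1.0
        if abs(d) < degenerate_tol:
            raise ValueError(
                f"fixed point at x = {x_star} is degenerate (tangent root); "
                "stability cannot be classified"
            )
        fps.append(FixedPoint(x_star=x_star,
                              stability="stable" if d < 0 else "unstable",
                              role=""))

    stable_count = sum(fp.stable for fp in fps)
    if len(fps) == 1:
        roles = ["x_0"]
    elif len(fps) == 3 and stable_count == 2:
        roles = ["x_minus", "x_zero", "x_plus"]
    else:
        roles = [f"fp{i}" for i in range(len(fps))]
    return [
        FixedPoint(fp.x_star, fp.stability, role)
        for fp, role in zip(fps, roles)
    ]
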