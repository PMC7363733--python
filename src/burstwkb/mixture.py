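"""Gaussian/Poisson singleton and mixture approximations of the stationary
distribution.

Laplace expansion of the WKB solution around the potential minima turns the
stationary joint distribution into a sum of mode-local products: at each
stable fixed point x_*, the inactive protein is Gaussian with mean x_*
(variance epsilon / Phi''(x_*); in molecule numbers X = x/epsilon, mean
x_*/epsilon and variance 1/(epsilon Phi''(x_*))) and the active protein is
truncated Poisson rho(x_*).  The mode weights are

    omega_* = C k(x_*) / sqrt(Phi''(x_*)) * exp(-Phi(x_*)/epsilon),

with C fixed by sum omega = 1.  A single stable fixed point degenerates to a
lone mode of weight 1; the construction extends verbatim to any number of
stable fixed points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ModelSpec
from .potential import PotentialBranch
from .qss import qss_distribution

__all__ = ["MixtureMode", "MixtureApprox", "build_mixture", "marginal_s", "marginal_X", "joint_approx"]


@dataclass(frozen=True)
class MixtureMode:
    x_star: float
    phi: float
    curvature: float  # Phi''(x_*) > 0
    prefactor_value: float
    weight: float


@dataclass(frozen=True)
class MixtureApprox:
    modes: list[MixtureMode]
    epsilon: float
    C: float


def build_mixture(
    model: ModelSpec,
    branch: PotentialBranch,
    fixed_points=None,
) -> MixtureApprox:
    """One mode per stable fixed point, weighted by potential depth,
    curvature and prefactor; requires ``branch`` with phi and prefactor
    filled.  Curvatures Phi''(x_*) come from the saddle linearisation (the
    slope of the nontrivial eigenvector), not from grid differencing."""
    if branch.phi is None or branch.prefactor is None:
        raise ValueError("branch must have phi and prefactor filled")
    fps = branch.fixed_points if fixed_points is None else fixed_points
    eps = model.epsilon

    entries = []
    for fp, sd in zip(fps, branch.saddles):
        if not fp.stable:
            continue
        curv = sd.slope
        if curv <= 0:
            raise ValueError(
                f"non-positive curvature {curv} at stable fixed point {fp.x_star}"
            )
        entries.append((fp.x_star, branch.phi_at(fp.x_star), curv,
                        branch.prefactor_at(fp.x_star)))
    if not entries:
        raise ValueError("no stable fixed points: cannot build a mixture")

    phi_min = min(e[1] for e in entries)
    raw = np.array(
        [k / math.sqrt(c) * math.exp(-(p - phi_min) / eps) for _, p, c, k in entries]
    )
    weights = raw / raw.sum()
    # C on the natural scale: omega = C k/sqrt(Phi'') exp(-Phi/eps)
    c_const = math.exp(phi_min / eps) / raw.sum()
    modes = [
        MixtureMode(x_star=xs, phi=p, curvature=c, prefactor_value=k, weight=wt)
        for (xs, p, c, k), wt in zip(entries, weights)
    ]
    return MixtureApprox(modes=modes, epsilon=eps, C=c_const)


def marginal_s(mix: MixtureApprox, model: ModelSpec) -> np.ndarray:
    """Marginal of the active protein: mixture of truncated Poissons located
    at the stable fixed points."""
    out = np.zeros(model.s_max + 1)
    for mode in mix.modes:
        out += mode.weight * qss_distribution(model, mode.x_star).rho
    return out


def marginal_X(
    mix: MixtureApprox, model: ModelSpec, X_grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal of the inactive protein on integer copy numbers: mixture of
    Gaussians with means x_*/epsilon and variances 1/(epsilon Phi''(x_*)),
    evaluated on ``X_grid`` (default 0..4*ceil(max x_*/epsilon), the lattice
    used by the truncated master equation) and renormalised over the grid."""
    eps = mix.epsilon
    if X_grid is None:
        x_top = max(mode.x_star for mode in mix.modes)
        X_grid = np.arange(4 * math.ceil(x_top / eps) + 1)
    X_grid = np.asarray(X_grid)
    dens = np.zeros(X_grid.size)
    for mode in mix.modes:
        mean = mode.x_star / eps
        var = 1.0 / (eps * mode.curvature)
        dens += (
            mode.weight
            / math.sqrt(2.0 * math.pi * var)
            * np.exp(-((X_grid - mean) ** 2) / (2.0 * var))
        )
    return X_grid, dens / dens.sum()


def joint_approx(mix: MixtureApprox, model: ModelSpec, x: float, s: int) -> float:
    """Joint density value p(x, s): sum over modes of
    weight * rho_s(x_*) * Normal(x; x_*, epsilon/Phi''(x_*))."""
    if not (0 <= s <= model.s_max):
        raise ValueError("s outside 0..s_max")
    eps = mix.epsilon
    total = 0.0
    for mode in mix.modes:
        var = eps / mode.curvature
        gauss = math.exp(-((x - mode.x_star) ** 2) / (2.0 * var)) / math.sqrt(
            2.0 * math.pi * var
        )
        total += mode.weight * qss_distribution(model, mode.x_star).rho[s] * gauss
    return total
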