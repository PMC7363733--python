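"""WKB potential of the slow (inactive-protein) dynamics.

The stationary distribution has the WKB form p(x, s) ~ k(x) w_s(x)
exp(-Phi(x)/epsilon).  The potential derivative theta = Phi'(x) is the
nontrivial branch of the zero-level set H(x, theta) = 0 of the principal
eigenvalue Hamiltonian; it connects the saddles (x_*, 0) of the Hamiltonian
system, where x_* are the fixed points of the rate equation.  Phi is a
Lyapunov function of the rate equation: theta has the opposite sign to
<B> fbar(x) - x, so Phi falls along deterministic trajectories and has minima
(maxima) at stable (unstable) fixed points.

Tracing the branch
------------------
The whole x-axis is part of the zero set (H(x, 0) = 0 for every x), so we
work with the deflated function G(x, theta) = H(x, theta)/theta, whose zero
set is exactly the nontrivial branch; G has a simple root in theta even at
the saddles, where the two branches of H cross.  Starting from each saddle
with the direction theta ~ -2 (H_xtheta / H_thetatheta) (x - x_*) supplied by
the linearisation, the branch is continued node by node over a grid with a
secant predictor and a Newton corrector on G.  This keeps |H| at machine
precision on every node and does not stall at the saddles, unlike direct
integration of dtheta/dx = -H_x/H_theta (a 0/0 limit there).

The prefactor k(x) follows from the solvability (orthogonality) condition of
the first-order WKB correction: with alpha_s = (dA/dtheta) w applied on the
branch and beta_s collecting the remaining first-order terms,

    k(x) = exp( - int  sum_s l_s beta_s / sum_s l_s alpha_s  dx ),

where l is the left nullvector of A on the branch.  The integrand is 0/0 at
the fixed points (the denominator equals H_theta, which vanishes there) and
is repaired by one-sided polynomial extrapolation from neighbouring nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .hamiltonian import value_and_grad
from .model import ModelSpec, mgf
from .operators import assemble_A, dA_dtheta
from .qss import FixedPoint, effective_rate_derivative, qss_distribution

__all__ = [
    "SaddleData",
    "PotentialBranch",
    "saddle_linearization",
    "trace_branch",
    "potential",
    "prefactor",
    "conditional_distribution",
]


@dataclass(frozen=True)
class SaddleData:
    """Local data of the Hamiltonian system at a saddle (x_*, 0).

    The linearisation has eigenvalues +-H_xtheta; the nontrivial eigenvector
    is (1, slope) with slope = -2 H_xtheta / H_thetatheta, which equals
    Phi''(x_*).
    """

    x_star: float
    H_xtheta: float
    H_thetatheta: float
    v_tilde: np.ndarray
    slope: float


def saddle_linearization(model: ModelSpec, fp: FixedPoint) -> SaddleData:
    """Second derivatives of H at a fixed point (x_*, 0).

    H_xtheta = <B> fbar'(x_*) - 1 and

    H_thetatheta = x_* (1 + <B^2>/<B>) + 2 * 1^T (dA/dtheta) vtilde,

    where vtilde solves the singular system A(x_*, 0) vtilde =
    -(dA/dtheta) rho(x_*) (solvable because 1^T (dA/dtheta) rho =
    H_theta(x_*, 0) = 0); the result is gauge-invariant under
    vtilde -> vtilde + c rho, and we fix sum_s vtilde_s = 0.
    """
    x = fp.x_star
    rho = qss_distribution(model, x).rho
    a0 = assemble_A(model, x, 0.0)
    dath = dA_dtheta(model, x, 0.0)
    b = -(dath @ rho)

    vt, *_ = np.linalg.lstsq(a0, b, rcond=None)
    vt = vt - vt.sum() * rho  # gauge: sum_s vtilde_s = 0
    resid = np.linalg.norm(a0 @ vt - b, np.inf)
    if resid > 1e-8 * max(1.0, np.linalg.norm(b, np.inf)):
        raise ValueError(f"singular solve for vtilde failed (residual {resid:.2e})")

    h_xt = model.burst.mean * effective_rate_derivative(model, x) - 1.0
    b2_over_b = mgf(model.burst, 0.0, 2) / model.burst.mean
    h_tt = x * (1.0 + b2_over_b) + 2.0 * float((dath @ vt).sum())
    return SaddleData(
        x_star=x,
        H_xtheta=h_xt,
        H_thetatheta=h_tt,
        v_tilde=vt,
        slope=-2.0 * h_xt / h_tt,
    )


@dataclass
class PotentialBranch:
    """Nontrivial heteroclinic branch on a concentration grid.

    Filled progressively: ``trace_branch`` supplies theta together with the
    WKB conditional distributions w (right nullvectors of A on the branch,
    rows sum to 1) and left nullvectors l; ``potential`` fills phi;
    ``prefactor`` fills k.
    """

    grid: np.ndarray
    theta: np.ndarray
    model: ModelSpec
    fixed_points: list[FixedPoint]
    saddles: list[SaddleData]
    fp_indices: np.ndarray
    w: np.ndarray  # (n_grid, s_max + 1)
    l: np.ndarray  # (n_grid, s_max + 1)
    phi: np.ndarray | None = None
    prefactor: np.ndarray | None = None
    integrand: np.ndarray | None = field(default=None, repr=False)

    def node_of(self, x_star: float) -> int:
        i = int(np.argmin(np.abs(self.grid - x_star)))
        return i

    def phi_at(self, x_star: float) -> float:
        if self.phi is None:
            raise ValueError("phi not filled; call potential() first")
        return float(self.phi[self.node_of(x_star)])

    def prefactor_at(self, x_star: float) -> float:
        if self.prefactor is None:
            raise ValueError("prefactor not filled; call prefactor() first")
        return float(self.prefactor[self.node_of(x_star)])


def _build_grid(
    fps: list[float], margin: float, n_grid: int, lo_floor_frac: float = 0.02
) -> tuple[np.ndarray, np.ndarray]:
    """Grid spanning the fixed points plus margins, containing every fixed
    point as a node.  The potential derivative diverges logarithmically as
    x -> 0 when f_0 > 0, so the left edge keeps a positive floor."""
    lo = max(lo_floor_frac * fps[0], fps[0] - margin)
    hi = fps[-1] + margin
    breaks = [lo] + list(fps) + [hi]
    span = hi - lo
    pieces = []
    for a, b in zip(breaks[:-1], breaks[1:]):
        n = max(3, int(round(n_grid * (b - a) / span)))
        pieces.append(np.linspace(a, b, n))
    grid = np.concatenate([p if i == 0 else p[1:] for i, p in enumerate(pieces)])
    fp_idx = np.array([int(np.argmin(np.abs(grid - x))) for x in fps])
    for i, x in zip(fp_idx, fps):
        grid[i] = x  # exact fixed-point nodes
    return grid, fp_idx


def _newton_on_branch(model: ModelSpec, x: float, theta0: float, max_iter: int = 60):
    """Newton iteration on G(theta) = H(x, theta)/theta from the guess
    ``theta0``; returns (theta, principal triple at theta).

    Convergence is judged on |H| relative to the magnitude of the matrix
    entries (the eigenvalue is only computed to that noise floor)."""
    scale = max(1.0, x + model.s_max + 2.0 * model.feedback.max_rate)
    htol = 1e-11 * scale
    th = float(theta0)
    best = None
    for _ in range(max_iter):
        h, _, h_t, trip = value_and_grad(model, x, th)
        if best is None or abs(h) < best[0]:
            best = (abs(h), th, trip)
        if abs(h) <= htol:
            return th, trip
        denom = th * h_t - h
        if denom == 0.0:
            break
        th -= th * h / denom
    raise RuntimeError(
        f"branch continuation failed to converge at x = {x} "
        f"(best |H| = {best[0]:.2e})"
    )


def trace_branch(
    model: ModelSpec,
    fixed_points: list[FixedPoint],
    margin: float | None = None,
    n_grid: int = 2001,
) -> PotentialBranch:
    """Trace theta = Phi'(x) through all fixed points and outer margins.

    Default margin: half the fixed-point span, or 1.0 for a single fixed
    point.  The branch object also carries the nullvectors w (= v on the
    branch, the WKB conditional distribution of s) and l (= u) at each node.
    """
    if not fixed_points:
        raise ValueError("at least one fixed point is required")
    fps = sorted(fixed_points, key=lambda fp: fp.x_star)
    xs = [fp.x_star for fp in fps]
    if margin is None:
        margin = 0.5 * (xs[-1] - xs[0]) if len(xs) > 1 else 1.0

    saddles = [saddle_linearization(model, fp) for fp in fps]
    grid, fp_idx = _build_grid(xs, margin, n_grid)
    n = grid.size
    s_dim = model.s_max + 1
    theta = np.zeros(n)
    w = np.zeros((n, s_dim))
    l = np.ones((n, s_dim))

    # exact values at the saddles: theta = 0, v = rho(x_*), u = 1
    for i, fp in zip(fp_idx, fps):
        w[i] = qss_distribution(model, grid[i]).rho

    def march(start: int, stop: int, step: int, sd: SaddleData) -> None:
        """Continue the branch from the saddle node ``start`` towards
        ``stop`` (inclusive), seeding with the linearised direction."""
        prev_x, prev_th = grid[start], 0.0
        slope = sd.slope
        for j in range(start + step, stop + step, step):
            guess = prev_th + slope * (grid[j] - prev_x)
            th, trip = _newton_on_branch(model, grid[j], guess)
            theta[j], w[j], l[j] = th, trip.v, trip.u
            if grid[j] != prev_x:
                slope = (th - prev_th) / (grid[j] - prev_x)  # secant predictor
            prev_x, prev_th = grid[j], th

    march(int(fp_idx[0]), 0, -1, saddles[0])
    for k, (i, sd) in enumerate(zip(fp_idx, saddles)):
        stop = int(fp_idx[k + 1]) - 1 if k + 1 < len(fp_idx) else n - 1
        march(int(i), stop, +1, sd)

    return PotentialBranch(
        grid=grid,
        theta=theta,
        model=model,
        fixed_points=fps,
        saddles=saddles,
        fp_indices=fp_idx,
        w=w,
        l=l,
    )


def potential(branch: PotentialBranch) -> PotentialBranch:
    """Fill Phi by composite trapezoidal quadrature of theta over the grid,
    anchored so that the lowest stable-fixed-point value is zero."""
    phi = cumulative_trapezoid(branch.theta, branch.grid, initial=0.0)
    stable_nodes = [
        i for i, fp in zip(branch.fp_indices, branch.fixed_points) if fp.stable
    ]
    phi -= min(phi[i] for i in stable_nodes)
    branch.phi = phi
    return branch


def _repair_integrand(
    grid: np.ndarray, g: np.ndarray, fp_indices: np.ndarray, window: float
) -> np.ndarray:
    """Replace the 0/0 integrand near each fixed point by one-sided
    polynomial extrapolation from neighbouring grid nodes."""
    out = g.copy()
    for i in fp_indices:
        x0 = grid[i]
        masked = np.abs(grid - x0) <= window
        for side in (-1, +1):
            half = masked & ((grid - x0) * side >= 0)
            donors = (~masked) & ((grid - x0) * side > 0)
            idx = np.nonzero(donors)[0]
            idx = idx[np.argsort(np.abs(grid[idx] - x0))][:8]
            if idx.size < 3:
                continue
            coef = np.polyfit(grid[idx] - x0, g[idx], deg=2)
            out[half] = np.polyval(coef, grid[half] - x0)
    return out


def prefactor(model: ModelSpec, branch: PotentialBranch) -> PotentialBranch:
    """Fill the prefactor k(x) from the first-order solvability condition.

    k is determined up to a multiplicative constant (it cancels in the
    mixture weights through their normalisation); the gauge k = 1 at the
    leftmost stable fixed point is used.  The quadrature runs continuously
    across the whole grid so that prefactor values at different stable fixed
    points share a common gauge.
    """
    x = branch.grid
    th = branch.theta
    w = branch.w
    l = branch.l
    f = model.feedback.rates

    m1 = np.array([mgf(model.burst, t, 1) for t in th])
    m2 = np.array([mgf(model.burst, t, 2) for t in th])
    emt = np.exp(-th)
    phipp = np.gradient(th, x)
    wp = np.gradient(w, x, axis=0)

    def rshift(rows: np.ndarray) -> np.ndarray:
        out = np.zeros_like(rows)
        out[:, 1:] = rows[:, :-1]
        out[:, -1] += rows[:, -1]
        return out

    rw, rwp = rshift(w), rshift(wp)
    alpha = m1[:, None] * f[None, :] * w - (emt * x)[:, None] * rw
    beta = (
        m1[:, None] * f[None, :] * wp
        + 0.5 * (phipp * m2)[:, None] * f[None, :] * w
        - emt[:, None] * ((1.0 - 0.5 * phipp * x)[:, None] * rw + x[:, None] * rwp)
    )
    num = np.einsum("ns,ns->n", l, beta)
    den = np.einsum("ns,ns->n", l, alpha)  # equals H_theta on the branch

    spacing = np.median(np.diff(x))
    window = max(3.0 * spacing, 0.015)
    g = np.where(np.abs(den) > 0, num / np.where(den == 0, 1.0, den), 0.0)
    g = _repair_integrand(x, g, branch.fp_indices, window)
    if not np.all(np.isfinite(g)):
        raise ValueError("prefactor integrand is not finite after repair")

    logk = -cumulative_trapezoid(g, x, initial=0.0)
    anchor = next(
        i for i, fp in zip(branch.fp_indices, branch.fixed_points) if fp.stable
    )
    logk -= logk[anchor]
    branch.prefactor = np.exp(logk)
    branch.integrand = g
    return branch


def conditional_distribution(branch: PotentialBranch, x: float) -> np.ndarray:
    """WKB conditional distribution w_s(x) of the active protein at fixed x,
    interpolated linearly from the branch grid; at critical points of the
    potential it coincides with the QSS truncated Poisson rho(x_*)."""
    grid = branch.grid
    if not (grid[0] <= x <= grid[-1]):
        raise ValueError(f"x = {x} outside the branch grid [{grid[0]}, {grid[-1]}]")
    out = np.array(
        [np.interp(x, grid, branch.w[:, s]) for s in range(branch.w.shape[1])]
    )
    out = np.clip(out, 0.0, None)
    return out / out.sum()
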