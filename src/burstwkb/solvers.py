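"""Reference solvers: truncated-CME steady state and Gillespie simulation.

These serve as ground truth for the WKB mixture approximations.  The master
equation is truncated to the lattice {0..X_max} x {0..s_max}; the stationary
distribution is the normalised nullvector of the sparse generator.  The
default truncation bound is X_max = 4 * ceil(x_+/epsilon), where x_+ is the
uppermost stable fixed point of the rate equation -- generous enough that
stochastic-simulation sample paths (almost) never reach it.

Rates follow the reaction table: production bursts fire at rate f_s/epsilon
and add B ~ (b_j) copies of X; activation fires at rate X and converts one X
into one S (or removes the X when s = s_max); decay fires at rate s/epsilon.
Bursts that would overshoot the lattice boundary are lumped into X_max, which
preserves the generator property; the adequacy of the truncation is checked
through the boundary mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .model import ModelSpec
from .qss import FixedPoint

__all__ = [
    "LatticeDistribution",
    "SSATrace",
    "default_Xmax",
    "build_cme_generator",
    "cme_steady_state",
    "ssa_simulate",
]

#: refuse to build generators beyond this order (memory guard)
MAX_LATTICE_ORDER = 4_000_000


@dataclass(frozen=True)
class LatticeDistribution:
    """Joint steady-state probabilities P(X, s) on the truncated lattice."""

    probs: np.ndarray  # shape (X_max + 1, s_max + 1)
    X_max: int
    epsilon: float

    def marginal_X(self) -> np.ndarray:
        return self.probs.sum(axis=1)

    def marginal_s(self) -> np.ndarray:
        return self.probs.sum(axis=0)

    @property
    def boundary_mass(self) -> float:
        return float(self.probs[-1].sum())


@dataclass(frozen=True)
class SSATrace:
    """Jump times and post-jump states of a Gillespie realisation."""

    times: np.ndarray
    X: np.ndarray
    s: np.ndarray
    seed: int
    total_events: int


def default_Xmax(model: ModelSpec, fixed_points: list[FixedPoint]) -> int:
    """X_max = 4 * ceil(x_up / epsilon) with x_up the uppermost stable fixed
    point (the monostable case uses its single fixed point)."""
    stable = [fp.x_star for fp in fixed_points if fp.stable]
    if not stable:
        raise ValueError("no stable fixed points to anchor the truncation")
    return 4 * math.ceil(max(stable) / model.epsilon)


def build_cme_generator(model: ModelSpec, X_max: int) -> scipy.sparse.csc_matrix:
    """Sparse generator over the lattice, columns = source states, column
    sums zero.  State index = X * (s_max + 1) + s."""
    if X_max < 1:
        raise ValueError("X_max must be >= 1")
    s_dim = model.s_max + 1
    order = (X_max + 1) * s_dim
    if order > MAX_LATTICE_ORDER:
        raise MemoryError(
            f"lattice order {order} exceeds the configured cap {MAX_LATTICE_ORDER}"
        )
    pmf = model.burst.require_pmf()
    eps_inv = 1.0 / model.epsilon
    f = model.feedback.rates

    X = np.repeat(np.arange(X_max + 1), s_dim)
    s = np.tile(np.arange(s_dim), X_max + 1)
    src = X * s_dim + s

    rows, cols, vals = [], [], []

    def add(mask, targets, rates):
        rows.append(targets[mask])
        cols.append(src[mask])
        vals.append(rates[mask])

    # decay (X, s) -> (X, s-1) at rate s/eps
    add(s >= 1, src - 1, eps_inv * s.astype(float))
    # activation (X, s) -> (X-1, min(s+1, s_max)) at rate X
    s_up = np.minimum(s + 1, model.s_max)
    add(X >= 1, (X - 1) * s_dim + s_up, X.astype(float))
    # production bursts (X, s) -> (min(X+j, X_max), s) at rate f_s b_j / eps
    for j, bj in enumerate(pmf):
        if j == 0 or bj == 0.0:
            continue
        tgt = np.minimum(X + j, X_max) * s_dim + s
        add(np.ones_like(src, dtype=bool), tgt, eps_inv * bj * f[s])

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)

    outflow = np.zeros(order)
    np.add.at(outflow, cols, vals)
    rows = np.concatenate([rows, np.arange(order)])
    cols = np.concatenate([cols, np.arange(order)])
    vals = np.concatenate([vals, -outflow])
    gen = scipy.sparse.coo_matrix((vals, (rows, cols)), shape=(order, order))
    return gen.tocsc()


def cme_steady_state(model: ModelSpec, X_max: int) -> LatticeDistribution:
    """Normalised nullvector of the truncated generator.

    Primary method: replace the last balance equation by the normalisation
    row and solve the resulting nonsingular sparse system; fallback: shifted
    sparse eigensolve near zero.  Entries more negative than -1e-12 raise;
    smaller negative noise is clamped.
    """
    gen = build_cme_generator(model, X_max)
    order = gen.shape[0]

    lil = gen.tolil(copy=True)
    lil[-1, :] = 1.0
    rhs = np.zeros(order)
    rhs[-1] = 1.0
    try:
        p = scipy.sparse.linalg.spsolve(lil.tocsc(), rhs)
        if not np.all(np.isfinite(p)):
            raise RuntimeError("non-finite solution")
    except Exception:
        vals, vecs = scipy.sparse.linalg.eigs(
            gen, k=1, sigma=1e-12, which="LM", v0=np.ones(order)
        )
        p = vecs[:, 0].real
        p = p * np.sign(p.sum())

    p = p / p.sum()
    if p.min() < -1e-12:
        raise ValueError(f"nullvector has negative entries down to {p.min():.2e}")
    p = np.clip(p, 0.0, None)
    p = p / p.sum()

    resid = np.abs(gen @ p).max()
    if resid > 1e-9:
        raise ValueError(f"steady-state residual too large: {resid:.2e}")
    return LatticeDistribution(
        probs=p.reshape(X_max + 1, model.s_max + 1),
        X_max=X_max,
        epsilon=model.epsilon,
    )


def ssa_simulate(
    model: ModelSpec,
    t_end: float,
    seed: int,
    burn_in: float = 0.0,
    x0: int | None = None,
    s0: int = 0,
    max_events: int | None = None,
    record_trace: bool = True,
) -> tuple[SSATrace, np.ndarray]:
    """Exact Gillespie simulation of the reaction table.

    Returns the trace (if recorded) and the time-weighted occupancy histogram
    over (X, s) accumulated after ``burn_in``.  X is unbounded in simulation;
    the histogram array extends to the largest X visited.  All randomness
    flows through ``numpy.random.default_rng(seed)``.
    """
    if not (t_end > burn_in >= 0.0):
        raise ValueError("need t_end > burn_in >= 0")
    pmf = model.burst.require_pmf()
    burst_cdf = np.cumsum(pmf)
    burst_cdf[-1] = 1.0
    rng = np.random.default_rng(seed)

    eps_inv = 1.0 / model.epsilon
    f = (eps_inv * model.feedback.rates).tolist()
    s_max = model.s_max
    X = int(x0) if x0 is not None else int(round(model.burst.mean * model.feedback.rates[0]))
    s = int(s0)

    occupancy: dict[tuple[int, int], float] = {}
    times: list[float] = []
    xs_tr: list[int] = []
    ss_tr: list[int] = []

    t = 0.0
    events = 0
    exp_sample = rng.exponential
    uniform = rng.random
    while t < t_end:
        a_prod = f[s]
        a_act = float(X)
        a_dec = eps_inv * s
        total = a_prod + a_act + a_dec
        dt = exp_sample() / total
        t_next = t + dt
        if t_next > burn_in:
            lo = t if t > burn_in else burn_in
            hi = t_next if t_next < t_end else t_end
            key = (X, s)
            occupancy[key] = occupancy.get(key, 0.0) + (hi - lo)
        t = t_next
        if t >= t_end:
            break
        u = uniform() * total
        if u < a_prod:
            j = int(np.searchsorted(burst_cdf, uniform()))
            X += j
        elif u < a_prod + a_act:
            X -= 1
            if s < s_max:
                s += 1
        else:
            s -= 1
        events += 1
        if record_trace:
            times.append(t)
            xs_tr.append(X)
            ss_tr.append(s)
        if max_events is not None and events >= max_events:
            break

    x_top = max(k[0] for k in occupancy) if occupancy else 0
    hist = np.zeros((x_top + 1, s_max + 1))
    for (xx, ss), wt in occupancy.items():
        hist[xx, ss] = wt
    hist /= hist.sum()

    trace = SSATrace(
        times=np.asarray(times),
        X=np.asarray(xs_tr, dtype=np.int64),
        s=np.asarray(ss_tr, dtype=np.int64),
        seed=seed,
        total_events=events,
    )
    return trace, hist
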