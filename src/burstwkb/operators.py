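"""Boundary-modified shift operators and the tridiagonal matrix A(x, theta).

For sequences v_s indexed by 0 <= s <= s_max, the left shift L drops the top
cell (L v)_{s_max} = 0, while the right shift R lumps the top two cells,
(R v)_{s_max} = v_{s_max - 1} + v_{s_max}; away from the boundary they are the
usual van Kampen step operator and its inverse.  R conserves the sum of the
sequence (activation never loses probability), L does not (there is no state
above s_max to decay from).

The leading order of the WKB expansion of the stationary master equation is
governed by the operator

    A v = e^{-theta} x R v + L (s v) - (f_s (1 - M(theta)) + x + s) v,

represented here as a dense (s_max+1) x (s_max+1) tridiagonal matrix, together
with its partial derivatives in x and theta.
"""

from __future__ import annotations

import math

import numpy as np

from .model import ModelSpec, mgf

__all__ = ["left_shift", "right_shift", "assemble_A", "dA_dx", "dA_dtheta"]


def left_shift(v: np.ndarray) -> np.ndarray:
    """(L v)_s = v_{s+1} for s < s_max, 0 at s = s_max."""
    v = np.asarray(v, dtype=float)
    out = np.zeros_like(v)
    out[:-1] = v[1:]
    return out


def right_shift(v: np.ndarray) -> np.ndarray:
    """(R v)_0 = 0, (R v)_s = v_{s-1} in the interior, and the boundary cell
    receives the lumped mass v_{s_max-1} + v_{s_max}."""
    v = np.asarray(v, dtype=float)
    out = np.zeros_like(v)
    out[1:] = v[:-1]
    out[-1] += v[-1]
    return out


def _right_shift_matrix(n: int) -> np.ndarray:
    r = np.zeros((n, n))
    idx = np.arange(n - 1)
    r[idx + 1, idx] = 1.0
    r[-1, -1] += 1.0
    return r


def assemble_A(model: ModelSpec, x: float, theta: float) -> np.ndarray:
    """Dense matrix of A(x, theta) acting on column vectors v.

    Main diagonal: -f_s (1 - M(theta)) - x - s, except the last entry, which
    is -f_{s_max} (1 - M(theta)) - x (1 - e^{-theta}) - s_max (the boundary
    lump of R feeds x e^{-theta} back into the top cell).  Superdiagonal:
    1, 2, ..., s_max.  Subdiagonal: constant e^{-theta} x.
    """
    if x < 0:
        raise ValueError("x must be non-negative")
    n = model.s_max + 1
    s = np.arange(n, dtype=float)
    f = model.feedback.rates
    m = mgf(model.burst, theta, 0)
    emt = math.exp(-theta)

    a = np.zeros((n, n))
    diag = -(f * (1.0 - m) + x + s)
    diag[-1] = -(f[-1] * (1.0 - m) + x * (1.0 - emt) + model.s_max)
    np.fill_diagonal(a, diag)
    idx = np.arange(n - 1)
    a[idx, idx + 1] = idx + 1.0  # L(s v): (s+1) v_{s+1}
    a[idx + 1, idx] = emt * x
    return a


def dA_dx(model: ModelSpec, theta: float) -> np.ndarray:
    """Matrix of dA/dx = e^{-theta} R - I (independent of x)."""
    n = model.s_max + 1
    return math.exp(-theta) * _right_shift_matrix(n) - np.eye(n)


def dA_dtheta(model: ModelSpec, x: float, theta: float) -> np.ndarray:
    """Matrix of dA/dtheta v = M'(theta) f_s v - e^{-theta} x R v."""
    n = model.s_max + 1
    m1 = mgf(model.burst, theta, 1)
    return np.diag(m1 * model.feedback.rates) - math.exp(-theta) * x * _right_shift_matrix(n)
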