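"""Principal eigenvalue Hamiltonian of the WKB problem.

A(x, theta) has non-negative off-diagonal entries, so by Perron-Frobenius its
eigenvalue of largest real part -- the principal eigenvalue -- is real, with
positive left and right eigenvectors.  The Hamiltonian of the large-deviation
problem is H(x, theta) = lambda_1(A(x, theta)); the stationary WKB solution
lives on its zero-level set.  With the normalisation u^T v = 1, sum_s v_s = 1,
the gradient of H is given by the eigenvector sandwich formulas

    H_x = u^T (dA/dx) v,   H_theta = u^T (dA/dtheta) v,

and the Hamiltonian flow is (xdot, thetadot) = (H_theta, -H_x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .model import ModelSpec
from .operators import assemble_A, dA_dtheta, dA_dx

__all__ = [
    "PrincipalTriple",
    "principal_triple",
    "hamiltonian",
    "grad_hamiltonian",
    "hamiltonian_flow",
]


@dataclass(frozen=True)
class PrincipalTriple:
    """Principal eigenvalue H with left (u) and right (v) eigenvectors,
    normalised so that u @ v = 1 and v.sum() = 1."""

    H: float
    u: np.ndarray
    v: np.ndarray


def _fix_positive(vec: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Rotate a (numerically complex) eigenvector to the real positive axis.

    The Perron eigenvector is positive up to a scalar; tiny negative
    components (< 1e-12 of the peak, numerical noise near the boundary of
    positivity) are clamped to a positive floor.
    """
    peak = np.argmax(np.abs(vec))
    phase = vec[peak] / abs(vec[peak])
    vec = (vec / phase).real.copy()
    floor = 1e-300
    small = vec < 0
    if np.any(vec[small] < -tol * vec.max()):
        raise ValueError(
            "principal eigenvector has significantly negative components; "
            "the matrix is not a valid A(x, theta)"
        )
    vec[small] = floor
    return vec


def principal_triple(a: np.ndarray, residual_tol: float = 1e-8) -> PrincipalTriple:
    """Eigenvalue of largest real part of ``a`` with sign-fixed, normalised
    positive eigenvectors (dense solve; the matrix order is s_max + 1)."""
    w, vl, vr = scipy.linalg.eig(a, left=True, right=True)
    i = int(np.argmax(w.real))
    lam = w[i]
    scale = max(1.0, float(np.abs(a).max()))
    if abs(lam.imag) > 1e-9 * scale:
        raise ValueError("principal eigenvalue has a non-negligible imaginary part")
    h = float(lam.real)

    v = _fix_positive(vr[:, i])
    u = _fix_positive(vl[:, i])
    v = v / v.sum()
    u = u / (u @ v)

    if np.linalg.norm(a @ v - h * v, np.inf) > residual_tol * scale:
        raise ValueError("right eigen-residual above tolerance")
    if np.linalg.norm(u @ a - h * u, np.inf) > residual_tol * scale * np.abs(u).max():
        raise ValueError("left eigen-residual above tolerance")
    return PrincipalTriple(H=h, u=u, v=v)


def hamiltonian(model: ModelSpec, x: float, theta: float) -> float:
    """H(x, theta): principal eigenvalue of A(x, theta)."""
    return principal_triple(assemble_A(model, x, theta)).H


def grad_hamiltonian(model: ModelSpec, x: float, theta: float) -> tuple[float, float]:
    """(H_x, H_theta) via the eigenvector sandwich formulas."""
    trip = principal_triple(assemble_A(model, x, theta))
    h_x = float(trip.u @ dA_dx(model, theta) @ trip.v)
    h_t = float(trip.u @ dA_dtheta(model, x, theta) @ trip.v)
    return h_x, h_t


def value_and_grad(model: ModelSpec, x: float, theta: float) -> tuple[float, float, float, PrincipalTriple]:
    """(H, H_x, H_theta, triple) from a single eigen-decomposition."""
    trip = principal_triple(assemble_A(model, x, theta))
    h_x = float(trip.u @ dA_dx(model, theta) @ trip.v)
    h_t = float(trip.u @ dA_dtheta(model, x, theta) @ trip.v)
    return trip.H, h_x, h_t, trip


def hamiltonian_flow(model: ModelSpec, x: float, theta: float) -> tuple[float, float]:
    """Right-hand side (xdot, thetadot) = (H_theta, -H_x) of the Hamiltonian
    system; on the invariant x-axis (theta = 0) it reduces to the emergent
    rate equation xdot = <B> fbar(x) - x."""
    h_x, h_t = grad_hamiltonian(model, x, theta)
    return h_t, -h_x
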