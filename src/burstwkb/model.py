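"""Model definition for bursty gene expression with a one-step production delay.

The model has two protein species: inactive protein X, produced in bursts of
size B ~ (b_j) at frequency ``f_s / epsilon``, and active protein S, obtained
from X by one-step activation at rate X and degraded at rate ``s / epsilon``.
The active copy number s is capped at ``s_max``; the burst frequency f_s
implements (positive or negative) feedback. ``epsilon`` separates the O(1)
slow activation timescale from the O(epsilon) fast production/decay
timescale; the slow-activation regime is ``epsilon << 1``.

This module holds the parameterisation: burst-size distributions (a
mean/Fano-factor family plus explicit pmfs), feedback response sequences, and
the assembled :class:`ModelSpec`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "BurstDistribution",
    "FeedbackResponse",
    "ModelSpec",
    "make_burst_distribution",
    "explicit_burst_distribution",
    "mgf",
    "make_step_response",
    "explicit_response",
    "choose_smax",
]

#: default tail mass below which unbounded burst pmfs are truncated
DEFAULT_TAIL_CUTOFF = 1e-12

_VALID_FAMILIES = {"fixed", "binomial", "poisson", "negative_binomial", "explicit"}


@dataclass(frozen=True)
class BurstDistribution:
    """Burst-size distribution with mean ``mean`` and Fano factor ``fano``.

    The mean/Fano family has moment generating function

        M(theta) = (F + (1 - F) e^theta)^(<B>/(1 - F)),

    which specialises to a point mass (F = 0), a binomial (0 < F < 1, valid
    only for integer trial count <B>/(1-F)), a Poisson (F -> 1) and a negative
    binomial (F > 1; F = 1 + <B> gives the geometric distribution).

    ``pmf`` may be ``None`` for family members that are defined at the MGF
    level but do not correspond to a lattice distribution (non-integer
    binomial trial counts); such objects support all spectral/WKB operations
    but cannot be simulated or put into a master equation.
    """

    mean: float
    fano: float
    family_tag: str
    pmf: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError(f"burst mean must be positive, got {self.mean}")
        if self.fano < 0:
            raise ValueError(f"burst Fano factor must be >= 0, got {self.fano}")
        if self.family_tag not in _VALID_FAMILIES:
            raise ValueError(f"unknown burst family {self.family_tag!r}")
        if self.pmf is not None:
            pmf = np.asarray(self.pmf, dtype=float)
            if pmf.ndim != 1 or pmf.size == 0:
                raise ValueError("pmf must be a non-empty 1-D sequence")
            if np.any(pmf < 0):
                raise ValueError("pmf entries must be non-negative")
            if abs(pmf.sum() - 1.0) > 1e-9:
                raise ValueError("pmf must sum to 1")
            j = np.arange(pmf.size)
            if abs(pmf @ j - self.mean) > 1e-7 * max(1.0, self.mean):
                raise ValueError("pmf mean does not match the stored mean")
            object.__setattr__(self, "pmf", pmf)

    @property
    def has_pmf(self) -> bool:
        return self.pmf is not None

    def require_pmf(self) -> np.ndarray:
        if self.pmf is None:
            raise ValueError(
                "this burst distribution is defined only at the MGF level "
                "(no lattice pmf); CME/SSA operations are unavailable"
            )
        return self.pmf

    @property
    def second_moment(self) -> float:
        """<B^2> = M''(0) = mean * (mean + fano)."""
        return mgf(self, 0.0, 2)


@dataclass(frozen=True)
class FeedbackResponse:
    """Burst-frequency response f_s >= 0 for s = 0..s_max.

    ``s_thresh``/``a0``/``a1`` are retained when the response was built as a
    step function (f_s = a0 below the threshold, a1 at and above it).
    """

    rates: np.ndarray
    s_thresh: int | None = None
    a0: float | None = None
    a1: float | None = None

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        if rates.ndim != 1 or rates.size == 0:
            raise ValueError("rates must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(rates)) or np.any(rates < 0):
            raise ValueError("feedback rates must be finite and non-negative")
        object.__setattr__(self, "rates", rates)

    @property
    def s_max(self) -> int:
        return self.rates.size - 1

    @property
    def max_rate(self) -> float:
        return float(self.rates.max())


@dataclass(frozen=True)
class ModelSpec:
    """Full parameterisation: burst distribution, feedback, s_max, epsilon."""

    burst: BurstDistribution
    feedback: FeedbackResponse
    s_max: int
    epsilon: float

    def __post_init__(self) -> None:
        if self.s_max < 0:
            raise ValueError("s_max must be a non-negative integer")
        if self.feedback.rates.size != self.s_max + 1:
            raise ValueError(
                f"feedback response has {self.feedback.rates.size} entries; "
                f"expected s_max + 1 = {self.s_max + 1}"
            )
        if not (self.epsilon > 0):
            raise ValueError("epsilon must be positive")

    def with_epsilon(self, epsilon: float) -> "ModelSpec":
        return ModelSpec(self.burst, self.feedback, self.s_max, epsilon)


def make_burst_distribution(
    mean: float,
    fano: float,
    tail_cutoff: float = DEFAULT_TAIL_CUTOFF,
    mgf_only: bool = False,
) -> BurstDistribution:
    """Construct a burst distribution from its mean and Fano factor.

    fano = 0 -> point mass at ``mean`` (must be a positive integer);
    0 < fano < 1 -> binomial with ``mean / (1 - fano)`` trials (must be a
    positive integer) and success probability ``1 - fano``;
    fano = 1 -> Poisson; fano > 1 -> negative binomial.

    Unbounded pmfs are truncated at the smallest size whose upper tail mass
    falls below ``tail_cutoff`` and renormalised; MGF evaluations always use
    the closed-form family expression, so truncation only affects simulation
    and master-equation paths.

    With ``mgf_only=True`` the integer-count requirements are waived and the
    returned object carries no pmf (useful for Fano-factor sweeps of the
    potential, which depend on the burst distribution only through its MGF).
    """
    if mean <= 0:
        raise ValueError("burst mean must be positive")
    if fano < 0:
        raise ValueError("Fano factor must be >= 0")

    if mgf_only:
        tag = _family_tag(fano)
        return BurstDistribution(mean=mean, fano=fano, family_tag=tag, pmf=None)

    if fano == 0:
        b = _as_integer(mean, "a fixed burst size requires an integer mean")
        pmf = np.zeros(b + 1)
        pmf[b] = 1.0
        return BurstDistribution(mean=float(b), fano=0.0, family_tag="fixed", pmf=pmf)

    if fano < 1:
        trials = _as_integer(
            mean / (1.0 - fano),
            "a binomial burst distribution requires mean/(1-fano) to be a "
            "positive integer (the trial count)",
        )
        p = 1.0 - fano
        pmf = stats.binom.pmf(np.arange(trials + 1), trials, p)
        pmf = pmf / pmf.sum()
        return BurstDistribution(mean=mean, fano=fano, family_tag="binomial", pmf=pmf)

    if fano == 1:
        dist = stats.poisson(mean)
        tag = "poisson"
    else:
        r = mean / (fano - 1.0)
        p = 1.0 / fano
        dist = stats.nbinom(r, p)
        tag = "negative_binomial"

    top = int(dist.isf(tail_cutoff))
    while dist.sf(top) >= tail_cutoff:  # isf can be off by one on a lattice
        top += 1
    pmf = dist.pmf(np.arange(top + 1))
    pmf = pmf / pmf.sum()
    return BurstDistribution(mean=mean, fano=fano, family_tag=tag, pmf=pmf)


def _family_tag(fano: float) -> str:
    if fano == 0:
        return "fixed"
    if fano < 1:
        return "binomial"
    if fano == 1:
        return "poisson"
    return "negative_binomial"


def _as_integer(value: float, message: str) -> int:
    rounded = round(value)
    if rounded <= 0 or abs(value - rounded) > 1e-9 * max(1.0, abs(value)):
        raise ValueError(f"{message}; got {value}")
    return int(rounded)


def explicit_burst_distribution(pmf) -> BurstDistribution:
    """Burst distribution from an explicit probability sequence b_j."""
    pmf = np.asarray(pmf, dtype=float)
    if np.any(pmf < 0) or not np.all(np.isfinite(pmf)):
        raise ValueError("pmf entries must be finite and non-negative")
    total = pmf.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError("pmf must sum to 1")
    pmf = pmf / total
    j = np.arange(pmf.size)
    mean = float(pmf @ j)
    if mean <= 0:
        raise ValueError("burst mean must be positive")
    var = float(pmf @ (j - mean) ** 2)
    return BurstDistribution(
        mean=mean, fano=var / mean, family_tag="explicit", pmf=pmf
    )


def mgf(dist: BurstDistribution, theta: float, order: int = 0) -> float:
    """Moment generating function M(theta) = sum_j b_j e^(j theta), or its
    first/second derivative (``order`` 1 or 2).

    Family-tagged distributions use the closed-form expression of the
    mean/Fano family (exact even where the stored pmf is truncated); explicit
    distributions fall back to direct summation over the pmf.
    """
    if order not in (0, 1, 2):
        raise ValueError(f"order must be 0, 1, or 2, got {order}")

    if dist.family_tag == "explicit":
        pmf = dist.require_pmf()
        j = np.arange(pmf.size, dtype=float)
        return float(pmf @ (j**order * np.exp(j * theta)))

    mean, fano = dist.mean, dist.fano
    et = math.exp(theta)
    if fano == 1.0:  # Poisson: M = exp(mean (e^theta - 1))
        m = math.exp(mean * (et - 1.0))
        if order == 0:
            return m
        if order == 1:
            return mean * et * m
        return (mean * et + (mean * et) ** 2) * m

    # generic family: M = g^c with g = F + (1-F) e^theta, c = mean/(1-F)
    g = fano + (1.0 - fano) * et
    c = mean / (1.0 - fano)
    if order == 0:
        return g**c
    if order == 1:
        return mean * et * g ** (c - 1.0)
    return mean * et * g ** (c - 1.0) + mean * (mean - (1.0 - fano)) * et**2 * g ** (
        c - 2.0
    )


def make_step_response(
    s_max: int, s_thresh: int, a0: float, a1: float
) -> FeedbackResponse:
    """Step feedback: f_s = a0 for s < s_thresh and a1 for s >= s_thresh."""
    if a0 < 0 or a1 < 0:
        raise ValueError("step rates must be non-negative")
    if not (0 <= s_thresh <= s_max + 1):
        raise ValueError(f"s_thresh must lie in [0, s_max + 1], got {s_thresh}")
    rates = np.where(np.arange(s_max + 1) < s_thresh, float(a0), float(a1))
    return FeedbackResponse(rates=rates, s_thresh=int(s_thresh), a0=float(a0), a1=float(a1))


def explicit_response(rates) -> FeedbackResponse:
    """Feedback response from an explicit table of rates f_0..f_{s_max}."""
    return FeedbackResponse(rates=np.asarray(rates, dtype=float))


def choose_smax(burst: BurstDistribution, max_rate: float) -> int:
    """Upper bound on the active protein: the smallest integer s at which the
    decay rate s exceeds the maximal mean production rate <B> * max_s f_s by a
    factor of two.  Such a level is reached rarely, so truncating there
    perturbs the dynamics negligibly."""
    if max_rate <= 0:
        raise ValueError("max_rate must be positive")
    return int(math.ceil(2.0 * burst.mean * max_rate))
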