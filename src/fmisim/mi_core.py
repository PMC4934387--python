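"""Rubin's combining rules and the fraction of missing information.

For an estimand Q estimated on each of m completed datasets, the per-imputation
point estimates Q_i and within-imputation variances U_i are pooled into

    Q-bar = mean(Q_i)
    U-bar = mean(U_i)                       (within-imputation variance)
    B     = var(Q_i), divisor m - 1         (between-imputation variance)
    T     = U-bar + (1 + 1/m) B             (total variance)
    r     = (1 + 1/m) B / U-bar             (relative variance increase)
    v     = (m - 1) (1 + 1/r)^2             (degrees of freedom)
    gamma = (r + 2/(v + 3)) / (r + 1)       (fraction of missing information)

As m grows, gamma tends to B / (B + U-bar): the share of the total variance
that multiple imputation recovers and single-value analysis would miss.  The
relative efficiency of m imputations against infinitely many is
RE = (1 + gamma/m)^(-1/2).

Two conventions for U_i are in circulation when Q is a mean: the sampling
variance of the estimate (s^2/n, Rubin's standard) and the element-level
sample variance (s^2).  The choice changes gamma by a factor of order n; both
are first-class here (:class:`VarianceConvention`) so the discrepancy can be
measured rather than hidden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import DegenerateVarianceError, InvalidInputError

__all__ = [
    "VarianceConvention",
    "EstimateSet",
    "PooledInference",
    "pool",
    "gamma_limit",
    "relative_efficiency",
    "gamma_upper_bound",
]


class VarianceConvention(str, Enum):
    """How the within-imputation variance U_i of a mean is measured.

    ``ESTIMATE``: U_i = s^2 / n, the sampling variance of the point estimate
    (Rubin's definition).  ``ELEMENT``: U_i = s^2, the element-level sample
    variance, under which gamma for a mean is bounded by roughly 1/n.
    """

    ESTIMATE = "estimate_variance"
    ELEMENT = "element_variance"


@dataclass(frozen=True)
class EstimateSet:
    """Per-imputation estimates Q_i and within-imputation variances U_i."""

    q_values: np.ndarray
    u_values: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q_values, dtype=float)
        u = np.asarray(self.u_values, dtype=float)
        if q.ndim != 1 or u.ndim != 1 or q.shape != u.shape:
            raise InvalidInputError(
                "q_values and u_values must be 1-d sequences of equal length"
            )
        object.__setattr__(self, "q_values", q)
        object.__setattr__(self, "u_values", u)

    @property
    def m(self) -> int:
        """Number of imputations."""
        return int(self.q_values.shape[0])


@dataclass(frozen=True)
class PooledInference:
    """Pooled MI inference for one estimand.

    ``v`` is ``math.inf`` when the between-imputation variance is exactly
    zero (the r -> 0 limit, where gamma = 0).
    """

    q_bar: float
    u_bar: float
    b: float
    t: float
    r: float
    v: float
    gamma: float
    m: int


def pool(estimates: EstimateSet | Sequence) -> PooledInference:
    """Apply the combining rules to one set of per-imputation estimates.

    Parameters
    ----------
    estimates
        An :class:`EstimateSet` (or a ``(q_values, u_values)`` pair).

    Raises
    ------
    InvalidInputError
        If m < 2 or any U_i is negative or non-finite.
    DegenerateVarianceError
        If U-bar = 0 while B > 0 (r is undefined); this cannot arise from
        valid variance inputs.
    """
    if not isinstance(estimates, EstimateSet):
        estimates = EstimateSet(*estimates)
    q, u = estimates.q_values, estimates.u_values
    m = estimates.m
    if m < 2:
        raise InvalidInputError(f"pooling requires m >= 2 imputations, got m={m}")
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(u))):
        raise InvalidInputError("Q_i and U_i must all be finite")
    if np.any(u < 0):
        raise InvalidInputError("within-imputation variances U_i must be >= 0")

    q_bar = float(np.mean(q))
    u_bar = float(np.mean(u))
    b = float(np.var(q, ddof=1))
    t = u_bar + (1.0 + 1.0 / m) * b

    if b == 0.0:
        # Identical point estimates across imputations: no information was
        # missing as far as this pool can tell.  r -> 0 makes v diverge and
        # gamma -> 0.
        return PooledInference(q_bar, u_bar, b, t, 0.0, math.inf, 0.0, m)
    if u_bar == 0.0:
        raise DegenerateVarianceError(
            "U-bar = 0 with B > 0: relative variance increase r is undefined"
        )
    r = (1.0 + 1.0 / m) * b / u_bar
    v = (m - 1) * (1.0 + 1.0 / r) ** 2
    gamma = (r + 2.0 / (v + 3.0)) / (r + 1.0)
    return PooledInference(q_bar, u_bar, b, t, r, v, gamma, m)


def gamma_limit(b: float, u: float) -> float:
    """Large-m limit of the fraction of missing information, B / (B + U)."""
    if b < 0 or u < 0:
        raise InvalidInputError("variance components must be >= 0")
    if b + u == 0:
        raise DegenerateVarianceError("B + U = 0: the variance ratio is undefined")
    return b / (b + u)


def relative_efficiency(gamma: float, m: int) -> float:
    """Efficiency of m imputations relative to m = infinity, (1 + gamma/m)^(-1/2)."""
    if m < 1:
        raise InvalidInputError(f"relative efficiency requires m >= 1, got m={m}")
    if not 0.0 <= gamma <= 1.0:
        raise InvalidInputError(f"gamma must lie in [0, 1], got {gamma}")
    return (1.0 + gamma / m) ** -0.5


def gamma_upper_bound(n: int) -> float:
    """Bound on gamma for a sample mean under the element-variance convention.

    If every one of the n values were redrawn by imputation, the variance of
    the mean across completions would be B ~ U/n with U the element variance;
    since U <= T this caps gamma at 1/n.  Partial missingness (delta < 1)
    only lowers B, so 1/n bounds the whole delta grid.
    """
    if n < 1:
        raise InvalidInputError(f"sample size must be >= 1, got n={n}")
    return 1.0 / n
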