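"""Synthetic physician-survey generator.

Emulates the 2012 NAMCS Physician Workflow mail survey (PWS12, n = 2567
responding physicians) closely enough to drive the imputation experiments:

* ``SIZE100`` — practice size in physicians, integers 1..100, calibrated so
  that its published moments (mean 11.41, variance 483.02) and the moments of
  its two deterministic recodes are all reproduced;
* ``SIZE5`` — 5-category recode (solo / two / 3-5 / 6-10 / 11+);
* ``SIZE20`` — SIZE100 top-coded at 20;
* ``REGION`` — 4 census regions (uniform; the survey's split is unpublished);
* ``PRIMEMP`` — 14 primary-employment codes with a synthetic long-tailed
  probability vector (the survey's split is unpublished);
* ``DERIVED_SIZE5/20/100`` — coarse regroupings of each size coding into
  4/9/17 numeric categories with randomized boundary assignment, built to be
  strongly rank-correlated with the size variable they regroup.

Missingness is emulated by nested MCAR deletion: the largest level is drawn
uniformly at random and each smaller level is a uniform subset of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .errors import (
    CalibrationError,
    EmptyPatternError,
    GroupingError,
    InvalidInputError,
)

__all__ = [
    "MomentTargets",
    "PWS12_MOMENTS",
    "N_PHYSICIANS",
    "DELTAS",
    "SIZE_SUPPORT",
    "REGION_LEVELS",
    "PRIMEMP_CODES",
    "SizeDistribution",
    "MissingnessPattern",
    "calibrate_size_distribution",
    "recode_size5",
    "topcode_size20",
    "derive_grouping",
    "generate_population",
    "make_nested_missingness",
]

#: practice-size support (number of physicians in the practice)
SIZE_SUPPORT = np.arange(1, 101)

#: sample size of the survey being emulated
N_PHYSICIANS = 2567

#: missing-data fractions studied, smallest to largest
DELTAS = (0.04, 0.10, 0.20, 0.29)

REGION_LEVELS = (1, 2, 3, 4)  # Northeast, Midwest, South, West

#: the 14 primary-employment codes carried by the survey
PRIMEMP_CODES = (11, 13, 20, 21, 22, 23, 30, 31, 35, 40, 64, 97, 110, 200)

# Synthetic employment mix: a few dominant settings plus a long tail, so every
# category is non-empty with high probability at n = 2567.  Not estimated from
# the survey (its split is unpublished).
_PRIMEMP_PROBS = (
    0.30, 0.14, 0.10, 0.08, 0.07, 0.06, 0.05, 0.04,
    0.04, 0.03, 0.03, 0.03, 0.02, 0.01,
)


@dataclass(frozen=True)
class MomentTargets:
    """Published moments of the practice-size variable and its recodes."""

    size100_mean: float = 11.41
    size100_var: float = 483.02
    size5_mean: float = 3.06
    size5_var: float = 1.97
    size20_mean: float = 6.47
    size20_var: float = 38.26


#: the survey's printed Table-of-characteristics moments
PWS12_MOMENTS = MomentTargets()


def recode_size5(size100):
    """5-category practice-size recode: 1, 2, 3-5, 6-10, 11+."""
    x = np.asarray(size100)
    if np.any(x < 1) or np.any(x > 100):
        raise InvalidInputError("SIZE100 values must lie in 1..100")
    out = np.select([x <= 2, x <= 5, x <= 10], [x, 3, 4], default=5)
    return out if x.ndim else int(out)


def topcode_size20(size100):
    """Top-code practice size at 20 physicians (values above 20 become 20)."""
    x = np.asarray(size100)
    if np.any(x < 1) or np.any(x > 100):
        raise InvalidInputError("SIZE100 values must lie in 1..100")
    out = np.minimum(x, 20)
    return out if x.ndim else int(out)


@dataclass(frozen=True)
class SizeDistribution:
    """A calibrated probability vector over practice sizes 1..100."""

    probs: np.ndarray
    support: np.ndarray = field(default_factory=lambda: SIZE_SUPPORT.copy())

    def _moments_of(self, values: np.ndarray) -> tuple[float, float]:
        mean = float(self.probs @ values)
        var = float(self.probs @ (values - mean) ** 2)
        return mean, var

    def moments(self) -> dict[str, float]:
        """Implied mean/variance of SIZE100 and of its two recodes."""
        m100, v100 = self._moments_of(self.support.astype(float))
        m5, v5 = self._moments_of(recode_size5(self.support).astype(float))
        m20, v20 = self._moments_of(topcode_size20(self.support).astype(float))
        return {
            "size100_mean": m100, "size100_var": v100,
            "size5_mean": m5, "size5_var": v5,
            "size20_mean": m20, "size20_var": v20,
        }

    def central_moment4(self) -> float:
        """Implied fourth central moment of SIZE100 (for variance-of-s^2 SEs)."""
        mean = float(self.probs @ self.support)
        return float(self.probs @ (self.support - mean) ** 4)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.support, size=n, p=self.probs)


def _maxent_fit(targets: MomentTargets) -> np.ndarray:
    """Solve the maximum-entropy dual for the calibrated probability vector."""
    k = SIZE_SUPPORT.astype(float)
    s5 = recode_size5(SIZE_SUPPORT).astype(float)
    s20 = topcode_size20(SIZE_SUPPORT).astype(float)
    feats = np.column_stack([k, k**2, s5, s5**2, s20, s20**2])
    scale = feats.max(axis=0)
    f = feats / scale

    raw = np.array([
        targets.size100_mean,
        targets.size100_var + targets.size100_mean**2,
        targets.size5_mean,
        targets.size5_var + targets.size5_mean**2,
        targets.size20_mean,
        targets.size20_var + targets.size20_mean**2,
    ])
    mu = raw / scale

    def dual(lam):
        z = f @ lam
        return logsumexp(z) - lam @ mu

    def grad(lam):
        return f.T @ softmax(f @ lam) - mu

    with np.errstate(over="ignore", invalid="ignore"):
        res = minimize(dual, np.zeros(6), jac=grad, method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 2000})
    return softmax(f @ res.x)


@lru_cache(maxsize=8)
def calibrate_size_distribution(
    targets: MomentTargets = PWS12_MOMENTS, rel_tol: float = 0.01
) -> SizeDistribution:
    """Moment-calibrate the practice-size distribution on support 1..100.

    Fits a maximum-entropy exponential family whose sufficient statistics are
    the first two moments of SIZE100, SIZE5 and SIZE20; at the optimum all six
    published moments are matched exactly (up to optimizer precision).  The
    solve is a smooth convex dual and is deterministic.

    Raises
    ------
    CalibrationError
        If any implied moment misses its target by more than ``rel_tol``
        relative error (infeasible targets); the achieved moments ride along
        on the exception.
    """
    probs = _maxent_fit(targets)
    if not np.all(np.isfinite(probs)):
        raise CalibrationError(
            "calibration diverged (infeasible moment targets)", achieved={"probs": "nan"}
        )
    dist = SizeDistribution(probs)
    achieved = dist.moments()
    for name, target in (
        ("size100_mean", targets.size100_mean),
        ("size100_var", targets.size100_var),
        ("size5_mean", targets.size5_mean),
        ("size5_var", targets.size5_var),
        ("size20_mean", targets.size20_mean),
        ("size20_var", targets.size20_var),
    ):
        if not abs(achieved[name] - target) <= rel_tol * abs(target):  # NaN-safe
            raise CalibrationError(
                f"calibration failed: {name} achieved {achieved[name]:.4f}, "
                f"target {target:.4f}",
                achieved=achieved,
            )
    return dist


def derive_grouping(
    values: Sequence, k_groups: int, rng: np.random.Generator
) -> np.ndarray:
    """Regroup a numeric column into ``k_groups`` contiguous categories.

    Bins are equal-frequency slices of the empirical cumulative distribution.
    Each distinct value is labelled by the slice containing the midpoint of
    its cumulative-probability interval; a value whose interval straddles a
    slice boundary is split row-by-row between its lowest and highest
    overlapped slice by the parity of a random integer.  Labels are 1-based
    and monotone in the source value, so the grouping is strongly
    rank-correlated with its source.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise InvalidInputError("values must be a non-empty 1-d sequence")
    distinct, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
    if k_groups < 1 or k_groups > distinct.size:
        raise GroupingError(
            f"cannot form {k_groups} groups from {distinct.size} distinct values"
        )
    cum = np.concatenate([[0.0], np.cumsum(counts) / x.size])
    # slice index of a cumulative position, clipped into 0..k-1
    def _slice(pos):
        return np.clip((pos * k_groups).astype(int), 0, k_groups - 1)

    lo = _slice(cum[:-1] + 1e-12)            # slice just after the interval opens
    hi = _slice(cum[1:] - 1e-12)             # slice just before it closes
    mid = _slice((cum[:-1] + cum[1:]) / 2.0)

    labels = mid[inverse]
    straddlers = np.flatnonzero(hi > lo)
    for j in straddlers:
        rows = np.flatnonzero(inverse == j)
        pick_upper = rng.integers(0, 2, size=rows.size).astype(bool)
        labels[rows] = np.where(pick_upper, hi[j], lo[j])
    return labels + 1


def make_nested_missingness(
    n: int,
    deltas: Sequence[float] = DELTAS,
    rng: np.random.Generator | int | None = None,
    weights: Sequence[float] | None = None,
) -> "MissingnessPattern":
    """Draw nested missingness patterns for each level of delta.

    The largest level is a random draw of round(max(delta) * n) rows; every
    smaller level is a random subset of the next larger one (realized as
    prefixes of one random ordering).  By default the draw is uniform
    (MCAR).  ``weights`` (per-row, positive) makes selection probability
    proportional to the weight — an MAR-style mode when the weights are a
    function of an observed covariate such as region.
    """
    deltas = tuple(float(d) for d in deltas)
    if not deltas or any(not 0.0 < d < 1.0 for d in deltas):
        raise InvalidInputError("each delta must lie in (0, 1)")
    if any(b <= a for a, b in zip(deltas, deltas[1:])):
        raise InvalidInputError("deltas must be strictly increasing")
    sizes = [int(np.round(d * n)) for d in deltas]
    if sizes[0] == 0:
        raise EmptyPatternError(f"delta={deltas[0]} rounds to zero missing rows at n={n}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if weights is None:
        perm = rng.permutation(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w <= 0):
            raise InvalidInputError("weights must be n positive values")
        # Efraimidis-Spirakis keys: sorting by rng.random()**(1/w) descending
        # yields successive weighted draws without replacement
        keys = rng.random(n) ** (1.0 / w)
        perm = np.argsort(-keys, kind="stable")
    missing_sets = {d: np.sort(perm[:s]) for d, s in zip(deltas, sizes)}
    return MissingnessPattern(n=n, deltas=deltas, missing_sets=missing_sets)


@dataclass
class MissingnessPattern:
    """Nested sets of missing row indices, one per missing-data fraction."""

    n: int
    deltas: tuple[float, ...]
    missing_sets: Mapping[float, np.ndarray]

    def size(self, delta: float) -> int:
        return int(self.missing_sets[delta].shape[0])

    def to_frame(self) -> pd.DataFrame:
        """Row-index table with one boolean flag column per delta level."""
        out = pd.DataFrame({"row": np.arange(self.n)})
        for d in self.deltas:
            flags = np.zeros(self.n, dtype=bool)
            flags[self.missing_sets[d]] = True
            out[f"missing_{d:g}"] = flags
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MissingnessPattern":
        deltas = tuple(
            float(c.split("_", 1)[1]) for c in frame.columns if c.startswith("missing_")
        )
        sets = {
            d: frame.loc[frame[f"missing_{d:g}"], "row"].to_numpy(np.int64)
            for d in deltas
        }
        return cls(n=len(frame), deltas=deltas, missing_sets=sets)


def generate_population(
    n: int = N_PHYSICIANS,
    seed: int = 0,
    dist: SizeDistribution | None = None,
    region_probs: Sequence[float] | None = None,
    primemp_probs: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Generate a synthetic physician table of ``n`` rows.

    SIZE100 is drawn i.i.d. from the calibrated distribution; SIZE5/SIZE20
    are its deterministic recodes; REGION and PRIMEMP are independent
    multinomials; the three DERIVED groupings are built from the complete
    size columns (they act as fully observed analytic covariates downstream).
    Deterministic given ``seed``.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if dist is None:
        dist = calibrate_size_distribution()
    region_p = np.full(4, 0.25) if region_probs is None else np.asarray(region_probs, float)
    prim_p = np.asarray(_PRIMEMP_PROBS if primemp_probs is None else primemp_probs, float)
    if region_p.size != len(REGION_LEVELS) or not np.isclose(region_p.sum(), 1.0):
        raise InvalidInputError("region_probs must be 4 probabilities summing to 1")
    if prim_p.size != len(PRIMEMP_CODES) or not np.isclose(prim_p.sum(), 1.0):
        raise InvalidInputError("primemp_probs must be 14 probabilities summing to 1")

    streams = np.random.SeedSequence(seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in streams]

    size100 = dist.sample(n, rngs[0])
    table = pd.DataFrame(
        {
            "SIZE100": size100,
            "SIZE5": recode_size5(size100),
            "SIZE20": topcode_size20(size100),
            "REGION": rngs[1].choice(REGION_LEVELS, size=n, p=region_p),
            "PRIMEMP": rngs[2].choice(PRIMEMP_CODES, size=n, p=prim_p),
        }
    )
    table["DERIVED_SIZE5"] = derive_grouping(table["SIZE5"], min(4, table["SIZE5"].nunique()), rngs[3])
    table["DERIVED_SIZE20"] = derive_grouping(table["SIZE20"], min(9, table["SIZE20"].nunique()), rngs[4])
    table["DERIVED_SIZE100"] = derive_grouping(table["SIZE100"], min(17, table["SIZE100"].nunique()), rngs[5])
    return table
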