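"""The factorial fraction-of-missing-information experiment.

Crosses missing-data fraction (delta: 4/10/20/29%), imputation variable
(SIZE5/SIZE20/SIZE100) and analytic treatment (CONTROL = overall mean;
REGION / PRIMEMP / DERIVED = category means) over 30 replicates of m = 99
multiple imputation drawn from pools of 1000 independent hot-deck
completions — 1440 trials at the defaults.  Every trial pools per-category
estimates with the combining rules under both within-variance conventions
and records gamma alongside its variance components.

Seeding is hierarchical: a single master seed derives named sub-streams for
the population, the missingness pattern, each pool and each factorial cell,
so any single gamma value can be re-derived in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import mi_core
from .errors import ConfigError, InvalidInputError
from .hotdeck import ImputationPool, build_pool, draw_mi_sample
from .mi_core import EstimateSet, VarianceConvention
from .synthetic_data import (
    DELTAS,
    N_PHYSICIANS,
    MissingnessPattern,
    calibrate_size_distribution,
    generate_population,
    make_nested_missingness,
)

__all__ = [
    "IMP_VARS",
    "TREATMENT_TAGS",
    "AnalyticTreatment",
    "RunConfig",
    "compute_estimates",
    "run_cell",
    "run_factorial",
    "CELL_KEY",
]

IMP_VARS = ("SIZE5", "SIZE20", "SIZE100")
TREATMENT_TAGS = ("CONTROL", "REGION", "PRIMEMP", "DERIVED")

#: columns that identify one factorial cell
CELL_KEY = ["delta", "imp_v", "anal_v", "replicate"]

# stream tags for hierarchical seeding
_TAG_POPULATION, _TAG_PATTERN, _TAG_POOL, _TAG_CELL = 1, 2, 3, 4


@dataclass(frozen=True)
class AnalyticTreatment:
    """An analytic treatment: the grouping (if any) that defines the estimands.

    CONTROL has no grouping column and a single estimand (the overall mean);
    the other treatments estimate one mean per category of their grouping
    column.  DERIVED resolves to the regrouping built for the imputation
    variable in play (DERIVED_SIZE5/20/100).
    """

    tag: str
    groups: np.ndarray | None = None  # per-row category labels, None for CONTROL

    @classmethod
    def from_table(cls, tag: str, table: pd.DataFrame, imp_var: str) -> "AnalyticTreatment":
        if tag == "CONTROL":
            return cls(tag, None)
        column = f"DERIVED_{imp_var}" if tag == "DERIVED" else tag
        if column not in table.columns:
            raise ConfigError(f"treatment {tag!r} needs column {column!r}")
        return cls(tag, table[column].to_numpy())


def _group_codes(treatment: AnalyticTreatment, n: int):
    """Integer codes, labels and counts for a treatment's categories."""
    if treatment.groups is None:
        return np.zeros(n, dtype=np.int64), np.array(["ALL"], dtype=object), np.array([n])
    labels, codes = np.unique(treatment.groups, return_inverse=True)
    counts = np.bincount(codes, minlength=labels.size)
    return codes, labels.astype(object), counts


def _batch_group_stats(columns: np.ndarray, codes: np.ndarray, n_groups: int):
    """Per-group mean and sample variance (ddof=1) for a batch of completions.

    ``columns`` is (m, n); returns (m, G) arrays of means and variances.
    """
    onehot = np.zeros((codes.size, n_groups))
    onehot[np.arange(codes.size), codes] = 1.0
    counts = onehot.sum(axis=0)
    sums = columns @ onehot
    sumsq = (columns**2) @ onehot
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
        var = (sumsq - counts * means**2) / (counts - 1.0)
    # guard tiny negative values from cancellation
    return means, np.clip(var, 0.0, None), counts.astype(np.int64)


def compute_estimates(
    completion: np.ndarray,
    treatment: AnalyticTreatment,
    convention: VarianceConvention = VarianceConvention.ELEMENT,
) -> dict:
    """Point estimate and within-imputation variance per category.

    For CONTROL the single estimand is the overall mean of the completed
    column (key ``"ALL"``); otherwise one mean per category.  Under the
    estimate-variance convention U = s^2 / n_g (sampling variance of the
    mean); under the element-variance convention U = s^2 (sample variance of
    the column itself).  Categories with fewer than two rows carry no
    variance estimate and are dropped with a warning.
    """
    col = np.asarray(completion, dtype=float)
    if np.any(~np.isfinite(col)):
        raise InvalidInputError("completion must have no missing cells")
    convention = VarianceConvention(convention)
    codes, labels, _ = _group_codes(treatment, col.size)
    means, var, counts = _batch_group_stats(col[None, :], codes, labels.size)
    out = {}
    for g, label in enumerate(labels):
        if counts[g] < 2:
            warnings.warn(
                f"category {label!r} has {counts[g]} row(s); dropped", stacklevel=2
            )
            continue
        u = var[0, g] if convention is VarianceConvention.ELEMENT else var[0, g] / counts[g]
        out[label] = (float(means[0, g]), float(u))
    return out


def _pool_rows(q: np.ndarray, u: np.ndarray) -> mi_core.PooledInference:
    return mi_core.pool(EstimateSet(q, u))


def run_cell(
    pool: ImputationPool,
    treatment: AnalyticTreatment,
    m: int,
    rng: np.random.Generator,
    conventions: Sequence[VarianceConvention] = tuple(VarianceConvention),
    aggregation: str = "unweighted",
) -> list[dict]:
    """One MI trial: draw m completions, pool per category, emit gamma rows.

    Returns tidy row dicts: one per (convention, category) plus a
    treatment-level ``"ALL"`` row per convention whose gamma is the
    unweighted (or category-size-weighted) mean of the per-category gammas;
    for CONTROL the single estimand is itself the treatment level.
    """
    if aggregation not in ("unweighted", "weighted"):
        raise ConfigError(f"unknown aggregation {aggregation!r}")
    sample = draw_mi_sample(pool, m, rng)
    columns = np.tile(pool.base.astype(float), (m, 1))
    columns[:, pool.missing_idx] = pool.imputed[sample.indices]

    codes, labels, counts = _group_codes(treatment, pool.n)
    keep = counts >= 2
    if not np.all(keep):
        warnings.warn(
            f"{int((~keep).sum())} category(ies) of {treatment.tag} with <2 rows dropped",
            stacklevel=2,
        )
    means, var, counts = _batch_group_stats(columns, codes, labels.size)

    rows: list[dict] = []
    for convention in conventions:
        convention = VarianceConvention(convention)
        per_cat: list[mi_core.PooledInference] = []
        cat_rows: list[dict] = []
        kept_counts = []
        for g, label in enumerate(labels):
            if not keep[g]:
                continue
            u = var[:, g] if convention is VarianceConvention.ELEMENT else var[:, g] / counts[g]
            inf = _pool_rows(means[:, g], u)
            per_cat.append(inf)
            kept_counts.append(counts[g])
            if treatment.groups is not None:
                cat_rows.append(_row(inf, convention, category=str(label)))
        weights = None
        if aggregation == "weighted":
            weights = np.asarray(kept_counts, float)
            weights = weights / weights.sum()
        agg = _aggregate(per_cat, weights)
        rows.append(_row(agg, convention, category="ALL"))
        rows.extend(cat_rows)
    return rows


def _aggregate(infs: list[mi_core.PooledInference], weights=None) -> mi_core.PooledInference:
    def mean(attr):
        vals = np.array([getattr(i, attr) for i in infs], dtype=float)
        return float(np.average(vals, weights=weights))

    if len(infs) == 1:
        return infs[0]
    return mi_core.PooledInference(
        q_bar=mean("q_bar"), u_bar=mean("u_bar"), b=mean("b"), t=mean("t"),
        r=mean("r"), v=mean("v"), gamma=mean("gamma"), m=infs[0].m,
    )


def _row(inf: mi_core.PooledInference, convention: VarianceConvention, category: str) -> dict:
    return {
        "category": category,
        "convention": convention.value,
        "gamma": inf.gamma,
        "b": inf.b,
        "u_bar": inf.u_bar,
        "t": inf.t,
        "r": inf.r,
        "v": inf.v,
        "m": inf.m,
    }


@dataclass(frozen=True)
class RunConfig:
    """Full description of one factorial run (serializable, round-trippable)."""

    seed: int = 0
    n: int = N_PHYSICIANS
    deltas: tuple[float, ...] = DELTAS
    pool_size: int = 1000
    m: int = 99
    replicates: int = 30
    imp_vars: tuple[str, ...] = IMP_VARS
    treatments: tuple[str, ...] = TREATMENT_TAGS
    conventions: tuple[str, ...] = tuple(c.value for c in VarianceConvention)
    aggregation: str = "unweighted"

    def __post_init__(self) -> None:
        if self.m > self.pool_size:
            raise ConfigError(f"m={self.m} exceeds pool_size={self.pool_size}")
        if self.replicates < 1 or self.n < 1:
            raise ConfigError("replicates and n must be >= 1")
        for c in self.conventions:
            VarianceConvention(c)
        for v in self.imp_vars:
            if v not in IMP_VARS:
                raise ConfigError(f"unknown imputation variable {v!r}")
        for t in self.treatments:
            if t not in TREATMENT_TAGS:
                raise ConfigError(f"unknown treatment {t!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        for key in ("deltas", "imp_vars", "treatments", "conventions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _child_seed(master: int, *tags: int) -> int:
    """A reproducible 31-bit child seed for a named sub-stream."""
    return int(np.random.SeedSequence([master, *tags]).generate_state(1)[0] >> 1)


def _cell_rng(master: int, i_d: int, i_v: int, i_t: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([master, _TAG_CELL, i_d, i_v, i_t, rep])
    )


def build_pools(
    table: pd.DataFrame, pattern: MissingnessPattern, config: RunConfig
) -> dict[tuple[str, float], ImputationPool]:
    """One hot-deck pool per (imputation variable, delta)."""
    pools = {}
    for i_v, var in enumerate(config.imp_vars):
        for i_d, delta in enumerate(config.deltas):
            seed = _child_seed(config.seed, _TAG_POOL, i_v, i_d)
            pools[(var, delta)] = build_pool(
                table, var, pattern.missing_sets[delta], config.pool_size, seed
            )
    return pools


def run_factorial(
    config: RunConfig,
    table: pd.DataFrame | None = None,
    pattern: MissingnessPattern | None = None,
    existing: pd.DataFrame | None = None,
    progress: Iterable | None = None,
) -> pd.DataFrame:
    """Run the full delta x Imp_V x Anal_V x replicate crossing.

    Deterministic given ``config.seed``.  If ``existing`` holds rows from an
    interrupted run, completed cells are reused verbatim and only the missing
    cells are recomputed (per-cell seeding makes the result identical to an
    uninterrupted run).
    """
    if table is None:
        dist = calibrate_size_distribution()
        table = generate_population(
            config.n, seed=_child_seed(config.seed, _TAG_POPULATION), dist=dist
        )
    if pattern is None:
        pattern = make_nested_missingness(
            config.n, config.deltas, np.random.default_rng(
                np.random.SeedSequence([config.seed, _TAG_PATTERN])
            ),
        )
    pools = build_pools(table, pattern, config)
    conventions = tuple(VarianceConvention(c) for c in config.conventions)

    done: set[tuple] = set()
    kept: list[pd.DataFrame] = []
    if existing is not None and len(existing):
        done = set(map(tuple, existing[CELL_KEY].drop_duplicates().to_numpy()))
        kept.append(existing)

    records: list[dict] = []
    for i_d, delta in enumerate(config.deltas):
        for i_v, var in enumerate(config.imp_vars):
            pool = pools[(var, delta)]
            for i_t, tag in enumerate(config.treatments):
                treatment = AnalyticTreatment.from_table(tag, table, var)
                for rep in range(config.replicates):
                    if (delta, var, tag, rep) in done:
                        continue
                    rng = _cell_rng(config.seed, i_d, i_v, i_t, rep)
                    seed_id = f"{config.seed}:{i_d}:{i_v}:{i_t}:{rep}"
                    for row in run_cell(
                        pool, treatment, config.m, rng, conventions, config.aggregation
                    ):
                        row.update(
                            delta=delta, imp_v=var, anal_v=tag,
                            replicate=rep, seed=seed_id,
                        )
                        records.append(row)
                if progress is not None:
                    progress.append((delta, var, tag))

    new = pd.DataFrame.from_records(records) if records else pd.DataFrame()
    out = pd.concat([*kept, new], ignore_index=True) if kept else new
    order = CELL_KEY + ["convention", "category"]
    front = order + ["gamma", "b", "u_bar", "t", "r", "v", "m", "seed"]
    out = out[front].sort_values(order, kind="mergesort").reset_index(drop=True)
    return out
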