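"""Random hot-deck imputation with a pool-and-resample design.

A large bank (default 1000) of independent single imputations of one column is
built once per (variable, missingness level); each multiple-imputation
replicate then draws m distinct completions from the bank without replacement.
The hot deck is unconditional: every observed row is a donor, and each missing
cell is filled by a value drawn uniformly with replacement from the donors.
An optional within-cell mode restricts donors to rows sharing a covariate
category with the recipient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, NoDonorError, PoolExhaustedError, SchemaError

__all__ = ["ImputationPool", "MISample", "impute_once", "build_pool", "draw_mi_sample"]


@dataclass
class ImputationPool:
    """A bank of independently completed copies of one column.

    Only the imputed cells are stored: completion ``i`` equals ``base`` with
    ``imputed[i]`` written into the rows ``missing_idx``.
    """

    variable: str
    delta: float
    base: np.ndarray            # observed column, length n; entries at missing_idx are stale
    missing_idx: np.ndarray     # sorted row indices that were imputed
    imputed: np.ndarray         # (pool_size, n_missing) imputed values
    donor_indices: np.ndarray   # (pool_size, n_missing) donor row per imputed cell
    seed: int

    @property
    def n(self) -> int:
        return int(self.base.shape[0])

    @property
    def pool_size(self) -> int:
        return int(self.imputed.shape[0])

    @property
    def n_missing(self) -> int:
        return int(self.missing_idx.shape[0])

    def completion(self, i: int) -> np.ndarray:
        """The i-th completed column (full length n)."""
        out = self.base.astype(float, copy=True)
        out[self.missing_idx] = self.imputed[i]
        return out

    def completions_frame(self) -> pd.DataFrame:
        """All completions as a units x completion-index table (for persistence)."""
        mat = np.tile(self.base.astype(float), (self.pool_size, 1))
        mat[:, self.missing_idx] = self.imputed
        return pd.DataFrame(mat.T, columns=[f"imp{i}" for i in range(self.pool_size)])


@dataclass
class MISample:
    """m distinct completion indices drawn from a pool."""

    pool: ImputationPool
    indices: np.ndarray
    m: int = field(init=False)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.m = int(self.indices.shape[0])


def impute_once(
    values: np.ndarray,
    missing: np.ndarray,
    rng: np.random.Generator,
    cells: np.ndarray | None = None,
    return_donors: bool = False,
):
    """Complete one column by random hot deck.

    Each cell flagged in ``missing`` is filled with the value of a donor row
    drawn uniformly at random with replacement from the observed rows.
    With ``cells`` (per-row adjustment-cell labels) donors are restricted to
    the recipient's cell.  Observed cells pass through unchanged.
    """
    values = np.asarray(values, dtype=float)
    missing = np.asarray(missing, dtype=bool)
    if values.shape != missing.shape or values.ndim != 1:
        raise InvalidInputError("values and missing flags must be 1-d and aligned")
    out = values.copy()
    chosen = np.empty(int(missing.sum()), dtype=np.int64)
    if cells is None:
        donor_rows = np.flatnonzero(~missing)
        if donor_rows.size == 0:
            raise NoDonorError("hot deck has no donor rows")
        chosen[:] = donor_rows[rng.integers(0, donor_rows.size, size=chosen.size)]
    else:
        cells = np.asarray(cells)
        if cells.shape != values.shape:
            raise InvalidInputError("cells must align with values")
        miss_rows = np.flatnonzero(missing)
        pos = {r: i for i, r in enumerate(miss_rows)}
        for label in np.unique(cells[miss_rows]):
            in_cell = cells == label
            donor_rows = np.flatnonzero(in_cell & ~missing)
            if donor_rows.size == 0:
                raise NoDonorError(f"hot deck has no donor rows in cell {label!r}")
            recipients = np.flatnonzero(in_cell & missing)
            picks = donor_rows[rng.integers(0, donor_rows.size, size=recipients.size)]
            for r, d in zip(recipients, picks):
                chosen[pos[r]] = d
    out[missing] = values[chosen]
    if return_donors:
        return out, chosen
    return out


def build_pool(
    table: pd.DataFrame,
    variable: str,
    missing_rows: np.ndarray,
    pool_size: int = 1000,
    seed: int = 0,
    cell_column: str | None = None,
) -> ImputationPool:
    """Build ``pool_size`` independent hot-deck completions of one column.

    Each completion uses its own child stream of ``seed``, so the pool is
    bit-reproducible given (table, missing_rows, pool_size, seed) and any
    single completion can be regenerated in isolation.  ``cell_column``
    switches on within-cell imputation (donors share the recipient's
    category of that column).
    """
    if variable not in table.columns:
        raise SchemaError(f"column {variable!r} not in table")
    if pool_size < 1:
        raise InvalidInputError("pool_size must be >= 1")
    n = len(table)
    missing_idx = np.unique(np.asarray(missing_rows, dtype=np.int64))
    if missing_idx.size and (missing_idx[0] < 0 or missing_idx[-1] >= n):
        raise InvalidInputError("missing row indices out of range")
    values = table[variable].to_numpy(dtype=float)
    missing = np.zeros(n, dtype=bool)
    missing[missing_idx] = True
    cells = None
    if cell_column is not None:
        if cell_column not in table.columns:
            raise SchemaError(f"cell column {cell_column!r} not in table")
        cells = table[cell_column].to_numpy()

    children = np.random.SeedSequence(seed).spawn(pool_size)
    imputed = np.empty((pool_size, missing_idx.size), dtype=float)
    donors = np.empty((pool_size, missing_idx.size), dtype=np.int64)
    for i, child in enumerate(children):
        completed, chosen = impute_once(
            values, missing, np.random.default_rng(child), cells=cells,
            return_donors=True,
        )
        imputed[i] = completed[missing_idx]
        donors[i] = chosen
    delta = missing_idx.size / n if n else 0.0
    return ImputationPool(variable, delta, values, missing_idx, imputed, donors, seed)


def draw_mi_sample(pool: ImputationPool, m: int, rng: np.random.Generator) -> MISample:
    """Draw m distinct completions from the pool, uniformly without replacement."""
    if m > pool.pool_size:
        raise PoolExhaustedError(
            f"requested m={m} imputations from a pool of {pool.pool_size}"
        )
    if m < 1:
        raise InvalidInputError("m must be >= 1")
    indices = rng.choice(pool.pool_size, size=m, replace=False)
    return MISample(pool, indices)
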