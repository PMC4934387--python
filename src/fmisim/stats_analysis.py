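"""Downstream summaries of the factorial gamma results.

Three-way fixed-effects ANOVA with all interactions, per-combination linear
regressions of gamma on the missing-data fraction, range summaries of gamma
means by factor, F critical values, and the report-table layouts (gamma-mean
cross tables and gamma-delta curve data).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import InvalidInputError, UnbalancedDesignError, ValidationError
from .mi_core import VarianceConvention

__all__ = [
    "DEFAULT_CONVENTION",
    "treatment_rows",
    "anova_three_way",
    "regress_gamma_on_delta",
    "RangeSummary",
    "range_summary",
    "f_critical",
    "gamma_means_table",
    "factor_range_table",
    "curve_table",
]

#: the element-variance convention reproduces the strikingly small gamma
#: magnitudes the study design is built around, so reports default to it
DEFAULT_CONVENTION = VarianceConvention.ELEMENT.value

_RESULT_COLUMNS = ("delta", "imp_v", "anal_v", "replicate", "category",
                   "convention", "gamma")


def _validate(results: pd.DataFrame) -> None:
    missing = [c for c in _RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValidationError(f"result table lacks required column(s): {missing}")


def treatment_rows(
    results: pd.DataFrame, convention: str = DEFAULT_CONVENTION
) -> pd.DataFrame:
    """Treatment-level rows (category == "ALL") for one variance convention."""
    _validate(results)
    convention = VarianceConvention(convention).value
    out = results[(results["category"] == "ALL") & (results["convention"] == convention)]
    return out.reset_index(drop=True)


def anova_three_way(
    results: pd.DataFrame,
    convention: str = DEFAULT_CONVENTION,
    response: str = "gamma",
) -> pd.DataFrame:
    """Fixed-effects ANOVA of gamma on delta, Anal_V, Imp_V and interactions.

    Requires a balanced full factorial (equal replicates in every cell), under
    which sequential and marginal sums of squares coincide; unbalanced input
    raises rather than silently committing to a sum-of-squares type.  Returns
    a table with Model / main effects / interactions / Error rows carrying
    df, sum of squares, mean square, F and p.
    """
    data = treatment_rows(results, convention)
    if data.empty:
        raise ValidationError("no treatment-level rows for the requested convention")
    counts = data.groupby(["delta", "anal_v", "imp_v"], observed=True).size()
    n_cells = data["delta"].nunique() * data["anal_v"].nunique() * data["imp_v"].nunique()
    if counts.size != n_cells or counts.nunique() != 1:
        raise UnbalancedDesignError(
            "ANOVA requires a balanced full factorial (equal replicates per cell)"
        )

    if np.allclose(data[response].var(ddof=0), 0.0):
        warnings.warn("constant response: ANOVA is degenerate, F undefined")

    model = smf.ols(
        f"{response} ~ C(delta) * C(anal_v) * C(imp_v)", data=data
    ).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on near-zero SS
        table = anova_lm(model, typ=1)

    rename = {
        "C(delta)": "delta",
        "C(anal_v)": "anal_v",
        "C(imp_v)": "imp_v",
        "C(delta):C(anal_v)": "delta:anal_v",
        "C(delta):C(imp_v)": "delta:imp_v",
        "C(anal_v):C(imp_v)": "anal_v:imp_v",
        "C(delta):C(anal_v):C(imp_v)": "delta:anal_v:imp_v",
        "Residual": "Error",
    }
    table = table.rename(index=rename)
    effects = table.drop(index="Error")
    error = table.loc["Error"]
    model_df = float(effects["df"].sum())
    model_ss = float(effects["sum_sq"].sum())
    error_ms = error["sum_sq"] / error["df"]
    model_row = pd.DataFrame(
        {
            "df": [model_df],
            "sum_sq": [model_ss],
            "F": [(model_ss / model_df) / error_ms if error_ms > 0 else np.nan],
        },
        index=["Model"],
    )
    model_row["PR(>F)"] = scipy.stats.f.sf(model_row["F"], model_df, error["df"])
    out = pd.concat([model_row, table])
    out["mean_sq"] = out["sum_sq"] / out["df"]
    out = out.rename(columns={"sum_sq": "sum_sq", "PR(>F)": "p"})
    out.index.name = "source"
    return out[["df", "sum_sq", "mean_sq", "F", "p"]]


def regress_gamma_on_delta(
    results: pd.DataFrame,
    convention: str = DEFAULT_CONVENTION,
    delta_scale: str = "fraction",
) -> pd.DataFrame:
    """OLS of gamma on delta within every Anal_V x Imp_V combination.

    ``delta_scale`` is ``"fraction"`` (delta as 0.04..0.29) or ``"percent"``
    (4..29; slopes shrink by 100x, matching how such slopes are usually
    printed).  t tests H0: b = 0, two-sided, with the sign of b preserved.
    A perfect linear fit has zero residual variance; its t is reported as
    signed infinity with p = 0.
    """
    if delta_scale not in ("fraction", "percent"):
        raise InvalidInputError(f"unknown delta_scale {delta_scale!r}")
    data = treatment_rows(results, convention).copy()
    scale = 100.0 if delta_scale == "percent" else 1.0
    data["x"] = data["delta"].astype(float) * scale

    rows = []
    for (anal, imp), grp in data.groupby(["anal_v", "imp_v"], observed=True, sort=False):
        if grp["x"].nunique() < 2:
            raise InvalidInputError(
                f"combination ({anal}, {imp}) has a single delta level; "
                "the slope is not identified"
            )
        fit = sm.OLS(grp["gamma"].to_numpy(), sm.add_constant(grp["x"].to_numpy())).fit()
        a, b = fit.params
        se = fit.bse[1]
        exact_fit = fit.ssr <= 1e-12 * max(fit.centered_tss, 1e-300)
        if exact_fit:
            se = 0.0
        if se == 0.0 or not np.isfinite(se):
            t = math.copysign(math.inf, b) if b != 0 else 0.0
            p = 0.0 if b != 0 else 1.0
        else:
            t, p = fit.tvalues[1], fit.pvalues[1]
        rows.append(
            {"anal_v": anal, "imp_v": imp, "intercept": a, "slope": b,
             "se": se, "t": t, "p": p, "n": int(len(grp)),
             "delta_scale": delta_scale}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RangeSummary:
    """Min, max and spread of a set of gamma means.

    ``diff_pct`` is 100 x (max - min) / min truncated toward zero to an
    integer — the convention under which the published worked examples
    (105, 13439, 135) reproduce exactly.
    """

    min: float
    max: float
    diff_pct: int


def range_summary(gamma_means) -> RangeSummary:
    """Range of per-level gamma means, spread as integer percent over the min."""
    values = np.asarray(list(gamma_means), dtype=float)
    if values.size < 2:
        raise InvalidInputError("range summary needs at least two level means")
    lo, hi = float(values.min()), float(values.max())
    if lo <= 0:
        raise InvalidInputError("minimum gamma mean must be > 0 for a ratio spread")
    return RangeSummary(lo, hi, math.trunc(100.0 * (hi - lo) / lo))


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Upper-alpha quantile of the F(df1, df2) distribution."""
    if not 0.0 < alpha < 1.0:
        raise InvalidInputError("alpha must lie in (0, 1)")
    if df1 < 1 or df2 < 1:
        raise InvalidInputError("degrees of freedom must be >= 1")
    return float(scipy.stats.f.isf(alpha, df1, df2))


# ---------------------------------------------------------------- report layouts

def gamma_means_table(
    results: pd.DataFrame,
    delta: float = 0.10,
    convention: str = DEFAULT_CONVENTION,
) -> pd.DataFrame:
    """Mean gamma per Anal_V x Imp_V at one delta level (cross-table layout)."""
    data = treatment_rows(results, convention)
    data = data[np.isclose(data["delta"].astype(float), delta)]
    if data.empty:
        raise ValidationError(f"no rows at delta={delta}")
    out = data.pivot_table(index="anal_v", columns="imp_v", values="gamma", aggfunc="mean")
    return out.reindex(index=[t for t in ("CONTROL", "REGION", "PRIMEMP", "DERIVED")
                              if t in out.index])


def factor_range_table(
    results: pd.DataFrame, convention: str = DEFAULT_CONVENTION
) -> pd.DataFrame:
    """Range of gamma means over the levels of each factor (spread layout)."""
    data = treatment_rows(results, convention)
    rows = []
    for factor in ("delta", "anal_v", "imp_v"):
        level_means = data.groupby(factor, observed=True)["gamma"].mean()
        summary = range_summary(level_means)
        rows.append({"factor": factor, "min": summary.min, "max": summary.max,
                     "diff_pct": summary.diff_pct})
    return pd.DataFrame(rows)


def curve_table(
    results: pd.DataFrame,
    convention: str = DEFAULT_CONVENTION,
    per_category: str | None = None,
) -> pd.DataFrame:
    """Mean gamma against delta for every Anal_V x Imp_V (curve data).

    With ``per_category`` set to a treatment tag, returns the per-category
    curves of that treatment instead (one line per category x Imp_V).
    """
    _validate(results)
    convention = VarianceConvention(convention).value
    if per_category is None:
        data = treatment_rows(results, convention)
        keys = ["anal_v", "imp_v", "delta"]
    else:
        data = results[
            (results["anal_v"] == per_category)
            & (results["category"] != "ALL")
            & (results["convention"] == convention)
        ]
        if data.empty:
            raise ValidationError(f"no per-category rows for treatment {per_category!r}")
        keys = ["anal_v", "category", "imp_v", "delta"]
    out = data.groupby(keys, observed=True)["gamma"].mean().reset_index()
    return out.rename(columns={"gamma": "gamma_mean"})
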