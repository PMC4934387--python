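"""ANOVA decomposition, gamma-delta regression, range summaries, F quantiles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from fmisim.errors import InvalidInputError, UnbalancedDesignError, ValidationError
from fmisim.stats_analysis import (
    anova_three_way,
    curve_table,
    f_critical,
    factor_range_table,
    gamma_means_table,
    range_summary,
    regress_gamma_on_delta,
    treatment_rows,
)


def make_results(deltas, anals, imps, replicates, gamma_fn, convention="element_variance"):
    """A tidy treatment-level result table with gamma set by ``gamma_fn``."""
    rows = []
    for (d, a, v), rep in itertools.product(
        itertools.product(deltas, anals, imps), range(replicates)
    ):
        rows.append({
            "delta": d, "anal_v": a, "imp_v": v, "replicate": rep,
            "category": "ALL", "convention": convention,
            "gamma": gamma_fn(d, a, v, rep),
        })
    return pd.DataFrame(rows)


def balanced_anova_oracle(data):
    """Hand-rolled balanced three-way decomposition by mean differences."""
    y = data["gamma"].to_numpy()
    grand = y.mean()
    ss = {"total": ((y - grand) ** 2).sum()}

    def level_means(cols):
        return data.groupby(list(cols), observed=True)["gamma"].mean()

    reps = len(data) / (data["delta"].nunique() * data["anal_v"].nunique()
                        * data["imp_v"].nunique())
    n_per = {cols: len(data) / level_means(cols).size
             for cols in [("delta",), ("anal_v",), ("imp_v",),
                          ("delta", "anal_v"), ("delta", "imp_v"),
                          ("anal_v", "imp_v"), ("delta", "anal_v", "imp_v")]}
    main = {c: n_per[(c,)] * ((level_means((c,)) - grand) ** 2).sum()
            for c in ("delta", "anal_v", "imp_v")}
    two = {}
    for a, b in itertools.combinations(("delta", "anal_v", "imp_v"), 2):
        cell = level_means((a, b))
        full = n_per[(a, b)] * ((cell - grand) ** 2).sum()
        two[f"{a}:{b}"] = full - main[a] - main[b]
    cell3 = level_means(("delta", "anal_v", "imp_v"))
    full3 = n_per[("delta", "anal_v", "imp_v")] * ((cell3 - grand) ** 2).sum()
    three = full3 - sum(main.values()) - sum(two.values())
    effects = {**main, **two, "delta:anal_v:imp_v": three}
    effects["Error"] = ss["total"] - sum(effects.values())
    return effects, ss["total"]


class TestAnova:
    def test_sums_of_squares_match_mean_decomposition_oracle(self, rng):
        noise = iter(rng.normal(0, 1.0, size=2 * 2 * 2 * 4))
        data = make_results(
            (0.1, 0.2), ("CONTROL", "REGION"), ("SIZE5", "SIZE20"), 4,
            lambda d, a, v, rep: 10 * d + (a == "REGION") * 2 + (v == "SIZE20") * 0.5
            + (a == "REGION") * (v == "SIZE20") * 1.5 + next(noise),
        )
        table = anova_three_way(data)
        oracle, ss_total = balanced_anova_oracle(data)
        for source, ss in oracle.items():
            assert table.loc[source, "sum_sq"] == pytest.approx(ss, rel=1e-9), source
        # conservation of SS and df
        effects = table.drop(index="Model")
        assert effects["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-9)
        assert table.loc["Model", "df"] + table.loc["Error", "df"] == len(data) - 1
        # mean square and F consistency
        err_ms = table.loc["Error", "mean_sq"]
        for source in ("delta", "anal_v", "imp_v"):
            assert table.loc[source, "F"] == pytest.approx(
                table.loc[source, "mean_sq"] / err_ms, rel=1e-9)
            p = scipy.stats.f.sf(table.loc[source, "F"], table.loc[source, "df"],
                                 table.loc["Error", "df"])
            assert table.loc[source, "p"] == pytest.approx(p, abs=1e-12)

    def test_full_design_degrees_of_freedom(self, rng):
        data = make_results(
            (0.04, 0.10, 0.20, 0.29),
            ("CONTROL", "REGION", "PRIMEMP", "DERIVED"),
            ("SIZE5", "SIZE20", "SIZE100"), 2,
            lambda d, a, v, rep: d + rng.normal(0, 0.01),
        )
        table = anova_three_way(data)
        assert table.loc["Model", "df"] == 47
        assert list(table["df"].astype(int)) == [47, 3, 3, 2, 9, 6, 6, 18, len(data) - 48]

    def test_unbalanced_design_rejected(self, rng):
        data = make_results((0.1, 0.2), ("CONTROL", "REGION"), ("SIZE5",), 3,
                            lambda d, a, v, rep: rng.normal())
        data = data.drop(index=0)
        with pytest.raises(UnbalancedDesignError):
            anova_three_way(data)

    def test_constant_response_flagged_degenerate(self):
        data = make_results((0.1, 0.2), ("CONTROL", "REGION"), ("SIZE5", "SIZE20"), 2,
                            lambda d, a, v, rep: 0.5)
        with pytest.warns(UserWarning, match="degenerate"):
            anova_three_way(data)


class TestRegression:
    def test_slope_matches_closed_form(self):
        data = make_results((0.1, 0.2, 0.3, 0.4), ("CONTROL",), ("SIZE5",), 1,
                            lambda d, a, v, rep: {0.1: 1, 0.2: 2, 0.3: 2, 0.4: 3}[d])
        fit = regress_gamma_on_delta(data)
        assert len(fit) == 1
        assert fit.loc[0, "slope"] == pytest.approx(6.0, rel=1e-10)
        assert fit.loc[0, "intercept"] == pytest.approx(2 - 6.0 * 0.25, rel=1e-10)
        assert fit.loc[0, "t"] == pytest.approx(fit.loc[0, "slope"] / fit.loc[0, "se"])

    def test_closed_form_normal_equations_on_random_data(self, rng):
        gammas = {}
        data = make_results((0.04, 0.10, 0.20, 0.29), ("CONTROL",), ("SIZE5",), 5,
                            lambda d, a, v, rep: gammas.setdefault((d, rep), rng.normal(d, 0.3)))
        fit = regress_gamma_on_delta(data)
        x = data["delta"].to_numpy(float)
        y = data["gamma"].to_numpy(float)
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        assert fit.loc[0, "slope"] == pytest.approx(slope, rel=1e-10)
        resid = y - (y.mean() + slope * (x - x.mean()))
        se = math.sqrt(resid @ resid / (len(x) - 2) / sxx)
        assert fit.loc[0, "se"] == pytest.approx(se, rel=1e-10)

    def test_perfect_line_flags_infinite_t(self):
        data = make_results((0.1, 0.2, 0.3), ("CONTROL",), ("SIZE5",), 1,
                            lambda d, a, v, rep: 2 * d + 1)
        fit = regress_gamma_on_delta(data)
        assert math.isinf(fit.loc[0, "t"]) and fit.loc[0, "t"] > 0
        assert fit.loc[0, "p"] == 0.0

    def test_percent_scale_rescales_slope(self):
        data = make_results((0.1, 0.3), ("CONTROL",), ("SIZE5",), 2,
                            lambda d, a, v, rep: d + 0.01 * rep)
        frac = regress_gamma_on_delta(data, delta_scale="fraction")
        pct = regress_gamma_on_delta(data, delta_scale="percent")
        assert pct.loc[0, "slope"] == pytest.approx(frac.loc[0, "slope"] / 100)
        assert pct.loc[0, "t"] == pytest.approx(frac.loc[0, "t"])

    def test_single_delta_level_rejected(self):
        data = make_results((0.1,), ("CONTROL",), ("SIZE5",), 3,
                            lambda d, a, v, rep: rep * 0.1)
        with pytest.raises(InvalidInputError):
            regress_gamma_on_delta(data)


class TestRangeSummary:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [(0.0017, 0.0035, 105), (0.000043, 0.005822, 13439), (0.0017, 0.0040, 135)],
    )
    def test_published_worked_examples(self, lo, hi, expected):
        summary = range_summary([lo, hi])
        assert summary.diff_pct == expected
        assert (summary.min, summary.max) == (lo, hi)

    def test_equal_levels_and_errors(self):
        assert range_summary([0.2, 0.2]).diff_pct == 0
        with pytest.raises(InvalidInputError):
            range_summary([0.0, 0.1])
        with pytest.raises(InvalidInputError):
            range_summary([0.1])


class TestFCritical:
    def test_published_quantiles(self):
        assert round(f_critical(0.05, 2, 1392), 2) == 3.00
        # the published 1.60 for df1 = 18 is the df2 -> infinity table row
        # (1.6039); the exact quantile at df2 = 1392 is 1.6113
        assert f_critical(0.05, 18, 1392) == pytest.approx(1.60, rel=0.02)
        assert round(f_critical(0.05, 18, 10**9), 2) == 1.60

    def test_inverts_the_cdf(self):
        for alpha, d1, d2 in [(0.05, 2, 1392), (0.01, 5, 30), (0.1, 18, 7)]:
            assert scipy.stats.f.cdf(f_critical(alpha, d1, d2), d1, d2) == pytest.approx(
                1 - alpha, abs=1e-10)

    def test_normal_limit(self):
        assert f_critical(0.05, 1, 10**8) == pytest.approx(1.959964**2, abs=1e-3)

    def test_domain_errors(self):
        with pytest.raises(InvalidInputError):
            f_critical(0.0, 2, 10)
        with pytest.raises(InvalidInputError):
            f_critical(0.05, 0, 10)


class TestReportLayouts:
    @pytest.fixture()
    def results(self, rng):
        frames = []
        for conv in ("element_variance", "estimate_variance"):
            frame = make_results(
                (0.04, 0.10), ("CONTROL", "REGION"), ("SIZE5", "SIZE20"), 3,
                lambda d, a, v, rep: d * (1 + (a == "REGION")) + rng.uniform(0, 1e-3),
                convention=conv,
            )
            frames.append(frame)
        out = pd.concat(frames, ignore_index=True)
        cats = out[out.anal_v == "REGION"].copy()
        cats["category"] = "1"
        cats["gamma"] *= 1.1
        return pd.concat([out, cats], ignore_index=True)

    def test_treatment_rows_filters(self, results):
        rows = treatment_rows(results)
        assert set(rows["convention"]) == {"element_variance"}
        assert set(rows["category"]) == {"ALL"}

    def test_gamma_means_table_layout(self, results):
        table = gamma_means_table(results, delta=0.10)
        assert list(table.index) == ["CONTROL", "REGION"]
        assert list(table.columns) == ["SIZE20", "SIZE5"]
        manual = treatment_rows(results).query("delta == 0.10 and anal_v == 'CONTROL'")
        assert table.loc["CONTROL", "SIZE5"] == pytest.approx(
            manual.query("imp_v == 'SIZE5'")["gamma"].mean())
        with pytest.raises(ValidationError):
            gamma_means_table(results, delta=0.5)

    def test_factor_range_table(self, results):
        table = factor_range_table(results)
        assert list(table["factor"]) == ["delta", "anal_v", "imp_v"]
        assert (table["max"] >= table["min"]).all()
        assert (table["diff_pct"] >= 0).all()

    def test_curve_tables(self, results):
        curves = curve_table(results)
        assert set(curves.columns) == {"anal_v", "imp_v", "delta", "gamma_mean"}
        assert len(curves) == 2 * 2 * 2
        per_cat = curve_table(results, per_category="REGION")
        assert set(per_cat["category"]) == {"1"}
        with pytest.raises(ValidationError):
            curve_table(results, per_category="PRIMEMP")

    def test_schema_validation(self):
        with pytest.raises(ValidationError):
            treatment_rows(pd.DataFrame({"gamma": [1.0]}))
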