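# fmisim

Simulation pipeline for studying the **fraction of missing information
(γ)** in hot-deck multiple imputation of survey data, built around the 2012
NAMCS Physician Workflow mail survey setting (n = 2567 office-based
physicians, practice-size variables imputed at missing-data fractions
δ = 4–29%).

## The problem

Multiple imputation (MI) replaces each missing value with m independent
plausible draws, analyses the m completed datasets, and pools the results.
How many imputations are enough?  The classical answer comes from the
relative efficiency

    RE = (1 + γ/m)^(-1/2),

where γ is the *fraction of missing information*: with m completed datasets
and per-imputation estimates Q_i with within-imputation variances U_i,

    Ū = mean(U_i),   B = var(Q_i),   T = Ū + (1 + 1/m)·B,
    r = (1 + 1/m)·B/Ū,   v = (m-1)(1 + 1/r)²,
    γ = (r + 2/(v+3)) / (r + 1)   →   B/(B+Ū)  as m → ∞.

If γ ≤ 0.5, RE suggests a handful of imputations suffice.  But how large is
γ in practice, and does it track the missing-data fraction δ?  This package
measures γ empirically across a factorial design — δ level × imputed
variable (SIZE5/SIZE20/SIZE100 practice-size codings) × analytic treatment
(overall mean, or category means by REGION / PRIMEMP / a derived regrouping)
— with 30 replicates of m = 99 MI drawn from pools of 1000 independent
hot-deck completions (1440 MI trials), then summarises the results with a
three-way ANOVA and per-combination regressions γ = a + bδ.

Because the underlying survey microdata are not public, the pipeline ships a
synthetic generator moment-calibrated to the survey's published practice-size
distribution (mean 11.41, variance 483.02 on 1–100, plus the moments of both
recodes), so every stage is reproducible from a single seed.

A pivotal modelling fork is made explicit throughout: whether the
within-imputation variance U_i of a mean is the sampling variance of the
estimate (s²/n, the textbook convention) or the element-level sample
variance (s²).  The second convention bounds γ for a mean by roughly 1/n
and reproduces the "strikingly small" γ regime (10⁻⁶–10⁻²) that motivates
the study; both are computed side by side in every run.

## Worked example

```python
import numpy as np
from fmisim import EstimateSet, pool, relative_efficiency

inf = pool(EstimateSet(np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0, 1.0])))
print(f"gamma = {inf.gamma:.5f}  (r = {inf.r:.4f}, v = {inf.v:.3f}, "
      f"B = {inf.b:.1f}, U-bar = {inf.u_bar:.1f}, T = {inf.t:.4f})")
for m in (1, 3, 5, 99):
    print(f"RE(m={m:2d}) = {relative_efficiency(inf.gamma, m):.4f}")
```

prints

```
gamma = 0.66536  (r = 1.3333, v = 6.125, B = 1.0, U-bar = 1.0, T = 2.3333)
RE(m= 1) = 0.7749
RE(m= 3) = 0.9047
RE(m= 5) = 0.9394
RE(m=99) = 0.9967
```

Three imputations of an estimand with two-thirds of its information missing
already recover 90% efficiency — the classical argument for small m, which
only holds if γ is ever that large.

## The analysis

The study itself is a sequence of four drivers (each writes its tables under
`results/`):

```
python analysis/01_simulate.py          # calibrate + generate the survey
python analysis/02_run_factorial.py     # 1440 MI trials, tidy gamma table
python analysis/03_anova_ranges.py      # factor effects on gamma
python analysis/04_regression_curves.py # gamma-delta regressions and curves
```

Stage 2 prints the mean γ per treatment at δ = 10% (element-variance
convention); on the default seed:

```
imp_v    SIZE100   SIZE20    SIZE5
anal_v
CONTROL 0.000041 0.000039 0.000040
REGION  0.000163 0.000159 0.000154
PRIMEMP 0.002104 0.001069 0.000954
DERIVED 0.004214 0.001872 0.000623
```

γ is orders of magnitude smaller than δ = 0.10, and spans three orders of
magnitude across analytic treatments at a fixed δ — the analysis choice,
not the amount of missing data, dominates the fraction of missing
information.  Stage 3's ANOVA (error df 1392) makes the same point by F
values; stage 4 shows γ rising near-linearly in δ for the overall mean and
region means but not for groupings correlated with the imputed variable.

The same stages are exposed as a CLI (`fmisim simulate | run | anova |
regress | report`) for custom configurations; see `fmisim --help`.

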