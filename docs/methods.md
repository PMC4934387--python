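# Methods

## Estimand and combining rules

Every trial estimates means of one practice-size column (overall, or within
the categories of an analytic covariate) from m completed datasets and pools
them with the standard MI combining rules (`fmisim.mi_core`).  The fraction
of missing information is computed from the relative variance increase r and
its degrees of freedom v, γ = (r + 2/(v+3))/(r+1), and tends to B/(B+Ū) as
m → ∞.  Two conventions for the within-imputation variance of a mean are
carried through the whole pipeline:

* **estimate variance** (U = s²/n): the textbook definition; γ then scales
  like δ/(1+δ) for an overall mean under hot-deck imputation.
* **element variance** (U = s²): treats the column's sample variance as the
  within component; γ for a mean is then bounded by about 1/n (at n = 2567,
  γ ≤ 0.00039), since even redrawing *all* n values gives B ≈ U/n.  This
  convention reproduces the strikingly small published γ magnitudes
  (10⁻⁶–10⁻²), and its bound is exposed as `gamma_upper_bound(n) = 1/n`.

Which convention the original analysts intended is not decidable from the
published account; the package therefore computes both in every run and
defaults reports to the element convention, whose magnitudes match the
published tables.  The ratio between the two conventions' γ is itself a
tested property (order n for the overall mean).

Degenerate cases: B = 0 (all imputations agree) returns r = 0, v = ∞ and
γ = 0, the r → 0 limit of the γ formula; Ū = 0 with B > 0 raises, since no
valid variance inputs produce it.  γ is kept in full double precision;
rounding happens only in report tables.

## Hot deck and the pool-and-resample design

Imputation is an unconditional random hot deck: all observed rows are
donors, and each missing cell is filled with a donor value drawn uniformly
with replacement.  (A within-cell mode — donors restricted to the
recipient's category of an adjustment-cell column — exists for sensitivity
checks but is not part of the default design.)  For each (imputed variable, δ) a pool of P = 1000 independent
completions is built once; each MI replicate draws m = 99 distinct
completions from the pool uniformly without replacement.  Replicates use
fresh sub-streams and may overlap in pool membership, which mirrors
resampling from a fixed imputation bank and slightly couples replicates
within a cell; the 30 replicates are used only for means and spreads of γ,
not for independence-sensitive inference.

m = 99 (not 100) is retained as the study's convention; with r of order
10⁻⁵–10⁻² the finite-m correction 2/(v+3) is already negligible, so m = 99
is effectively the m → ∞ regime.

## Synthetic survey

The real survey's microdata are unavailable, so the generator reproduces the
features the experiment is sensitive to:

* **SIZE100** is drawn i.i.d. from a maximum-entropy distribution on 1..100
  whose sufficient statistics are the first two moments of SIZE100 and of
  its two recodes.  The max-ent dual is a smooth convex problem (solved by
  BFGS, deterministic); at the optimum all six published moments — mean
  11.41 / variance 483.02, recode mean 3.06 / 1.97, top-coded mean 6.47 /
  38.26 — are matched to optimizer precision, comfortably inside the 1%
  calibration tolerance.  A parametric long-tail family (e.g. a lognormal
  mixture) was considered and rejected: it cannot hit all six targets
  simultaneously, and the max-ent family is the least-committal distribution
  consistent with exactly what is published.
* **SIZE5** (1/2/3–5/6–10/11+) and **SIZE20** (top-code at 20) are the
  deterministic recodes.
* **REGION** is uniform over 4 regions and **PRIMEMP** a 14-category
  multinomial with a synthetic dominant-head/long-tail probability vector
  (0.30 down to 0.01); neither split is published, and both are labelled
  synthetic.  The smallest employment category still expects ~26 physicians
  at n = 2567, so per-category pooling never degenerates at the defaults.
* **DERIVED_SIZE5/20/100** regroup each size coding into 4/9/17 contiguous
  categories by equal-frequency slices of the cumulative distribution, with
  rows whose value straddles a slice boundary assigned to the lower or upper
  neighbouring group by the parity of a random integer.  The published
  description fixes only the group counts and the randomized-boundary idea;
  the equal-frequency rule is this package's stand-in, chosen to guarantee
  the property the design needs — a grouping strongly rank-correlated
  (Spearman > 0.9) with the variable being imputed.
* **Missingness** is nested MCAR: one random permutation yields prefixes of
  round(δ·n) rows for δ = 4/10/20/29% (103/257/513/744 rows at n = 2567),
  so smaller patterns are uniform subsets of larger ones.  The real survey's
  item nonresponse was partially repaired from the prior panel year and is
  not MCAR; a weighted mode (selection probability proportional to per-row
  weights, e.g. a function of region, giving MAR-style patterns) is
  available for sensitivity, but all shipped results use MCAR.  Consequently
  the pipeline speaks to the *structure* of the γ–δ relationship, not to the
  survey's exact γ values.

## What passing tests do and do not show

The suite verifies the combining rules against exact rational arithmetic,
the hot deck against exhaustive enumeration at toy scale, the calibration
against the published moments, and the factorial against its bookkeeping
(1440 trials, ANOVA df 47/1392) and structural findings: γ of order 1e-5
for the overall mean at δ = 10%, monotone γ–δ growth for CONTROL/REGION,
and dominance of the analytic treatment in the ANOVA.  It does not — and
cannot, without the microdata — reproduce the published per-cell γ values,
F statistics or regression slopes; the synthetic values land in the same
regimes (e.g. mean γ at δ = 10%: CONTROL ≈ 4×10⁻⁵ vs the published
3.3–3.8×10⁻⁵) but their digits are not comparable.

## Numerical and design notes

* Group statistics in the factorial are computed by one matrix product per
  trial over the m × n completion matrix; per-group variances clip tiny
  negative cancellation residues to zero.
* Categories with fewer than two rows after subsetting are dropped with a
  warning (variance undefined); this never triggers at the default n.
* Treatment-level γ is the unweighted mean of per-category γ (the simplest
  rule consistent with reporting both one γ per trial and per-category γ);
  a category-size-weighted mean is available via `aggregation="weighted"`.
* The ANOVA requires a balanced design and refuses unbalanced input rather
  than silently picking a sum-of-squares type; with balance, sequential and
  marginal decompositions coincide.
* Regression of γ on δ uses δ as a fraction internally; report tables use
  the percent scale, which matches how such slopes are conventionally
  printed.  The t statistic tests b = 0 two-sided with its sign preserved;
  an exactly collinear fit reports signed infinite t rather than dividing
  by a zero standard error.
* `range_summary` truncates (not rounds) the percent spread toward zero,
  the convention under which the published worked examples (105, 13439,
  135) reproduce exactly.
* `f_critical` is the exact upper-α F quantile.  At (α = 0.05, df 18, 1392)
  it equals 1.6113; the published criterion 1.60 corresponds to the
  df₂ → ∞ table row (1.6039) and is treated as a table-lookup approximation.
* Seeding is hierarchical (`SeedSequence` with named stream tags for
  population, pattern, each pool and each cell), so runs are deterministic,
  resumable per cell, and any single trial can be regenerated alone.

## Problem sizes

The shipped analyses and the test suite run the full default design —
n = 2567, twelve pools of 1000 completions, 1440 trials of m = 99 — which
completes in well under a minute on one core thanks to the vectorised
group-statistics path.  The acceptance script samples 100 survey-sized
populations to estimate the generator's grand moments.
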