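# Methods

This note documents the statistical procedures implemented in `homovar`,
the numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Notation and data model

`k` treatment groups; group `i` holds `n_i` observations `Y_ij`,
`N = Σ n_i`. `Ȳ_i`, `s_i²`, `Ỹ_i` are the group sample mean, variance
(denominator `n_i − 1` everywhere) and median; `s_p² = Σ(n_i−1)s_i²/(N−k)`
is the pooled variance. All homogeneity tests address
`H₀: σ₁² = ⋯ = σ_k²` two-sidedly, except Cochran's C, whose alternative is
one-sided ("one group's variance is larger than the rest"). Two-sample
functions interpret `alternative='greater'` as "x is more dispersed than y".

Input tables are long-format CSV/TSV with one label column and one numeric
column; rows with a missing value or label are dropped and counted (logged),
never imputed. Groups keep first-appearance order; ordering affects labels
only, never statistics.

## Exact null of the Ansari–Bradley statistic

The pooled sorted sample of size `N` is scored `min(j, N+1−j)` at position
`j`: the extremes score 1, the center scores `⌈N/2⌉`. `W` is the score sum
of the smaller group, so small `W` marks the more dispersed group. Under
`H₀` (equal medians assumed) every size-`m` subset of positions is equally
likely, so the null pmf of `W` is the subset-sum count of the score vector
divided by `C(N, m)`. The count is computed by a dynamic-programming
convolution — exact and polynomial-time — for `m + n ≤ 200`; the test suite
verifies it against brute-force subset enumeration at small sizes. Beyond
the cap, a normal approximation uses the exact moments

    E W = m·S₁/N,   Var W = m·n·(N·S₂ − S₁²) / (N²(N−1)),

with `S₁, S₂` the sum and sum of squares of the scores; this moment formula
holds for any score vector, so it also covers midrank-averaged scores under
ties. Exact critical values: the upper value is the smallest `w` with
`P(W ≥ w) ≤ α`, the lower the largest `w` with `P(W ≤ w) ≤ α`; at very
small sizes no support point may attain the bound and `None` is returned
(e.g. `m = n = 5`, `α = 0.005`: the smallest attainable tail is
`2/252 ≈ 0.0079`).

Ties receive averaged scores over the tied block and disable the exact
null (the permutation argument assumes continuity); the approximation then
drops the 0.5 continuity correction. Median alignment, when requested,
shifts each group by the median of its Walsh means (all `n(n+1)/2` pairwise
averages — the one-sample Hodges–Lehmann estimate); a warning notes that
this alignment is not strictly distribution-free.

## Hartley's Fmax distribution

With `X_i = s_i²/σ² ~ χ²_df/df` iid across `k` balanced groups,

    P(Fmax ≤ c) = ∫₀^∞ k·g(x)·[G(cx) − G(x)]^{k−1} dx,   c > 1,

where `g`/`G` are the density/CDF of `χ²_df/df`. The integral is evaluated
by adaptive quadrature on the interval carrying all but `1e−14` of the
χ² mass, with interior break points at central quantiles; the estimated
quadrature error is checked against `1e−6`. Quantiles are obtained by
bracketing (doubling from 10) and Brent root-finding at tolerance `1e−10`.
Two independent checks: at `k = 2`, `P(Fmax ≤ c) = 1 − 2P(F_{df,df} > c)`;
at `df = 2` a closed form exists,
`1 + Σ_{j=1}^{k−1} (−1)^j C(k−1, j)·k/((k−j)+jc)`. The classical critical
values 39.0 (`k=2, df=2, α=.05`), 199 (`α=.01`) and 87.5 (`k=3, df=2,
α=.05`) are reproduced to three significant figures. As `df → ∞` the
quantile tends to 1 (all sample variances converge to σ²). Unbalanced
designs are accepted with the conservative convention `df = min(n_i) − 1`,
and a p-value `1 − P(Fmax ≤ fmax)` is reported alongside the table
decision.

## Cochran's C upper limit

`C_j = s_j²/Σ s_i²` for a balanced design. The upper limit implemented is

    C_UL(α, n, k) = 1 / (1 + (k−1)/F*),   F* = F_{α/k; n−1, (k−1)(n−1)},

the standard bound for testing the largest of `k` variances: dividing the
level by `k` accounts for the one-at-a-time outlier test over `k`
candidate groups. (A circulating rendering of this bound without the
reciprocal would exceed 1 and could never be crossed by `C_j ≤ 1`; the
form above is the usable one, and at `k=2, n=3, α=.05` it gives
`39/40 = 0.975`, consistent with the `F(2,2)` quantile 39.0.) The test
reports all per-group `C_j`; by default the largest is tested. No p-value
is reported — the decision is a critical-value comparison.

## The remaining tests

- **Levene family.** `Z_ij = |Y_ij − c_i|` and `W` is the one-way ANOVA F
  on the `Z` values against `F(k−1, N−k)` — the test suite verifies the
  identity `W ≡ F_anova(Z)` to 1e−10 on random instances. Centers: group
  mean (classical), median (Brown–Forsythe, an exact alias), trimmed mean
  (`⌊0.25·n_i⌋` dropped from each tail by default; deviations still use all
  observations), or pooled midranks followed by mean centering (the
  non-parametric variant; the source description is terse, and this is the
  implemented reading). Two-point groups make `|Y − mean|` constant within
  group; the within-group SS is then zero up to round-off and a relative
  guard (`ssw ≤ 1e−12·(ssb+ssw)`) raises a degenerate-input error rather
  than emitting an astronomically large W.
- **Bartlett.** `χ² = [(N−k)ln s_p² − Σ(n_i−1)ln s_i²] / C` with
  `C = 1 + (Σ 1/(n_i−1) − 1/(N−k)) / (3(k−1))`, on `k−1` df. The numerator
  is the `(n_i−1)`-weighted sum of `ln(s_p²/s_i²)`, zero iff all variances
  are equal.
- **Fligner–Killeen.** Midranks `m` of the pooled `|Y_ij − Ỹ_i|` receive
  scores `a_{N,m} = Φ⁻¹((1 + m/(N+1))/2)`; the statistic
  `x₀² = Σ n_i(Ā_i − ā)²/V²` with `V² = Σ(a_m − ā)²/(N−1)` is referred to
  `χ²(k−1)`. Matches `scipy.stats.fligner` (and R's `fligner.test`) exactly.
- **Jackknife.** Leave-one-out variances are computed by the O(n)
  downdating identity `ss_loo = S₂ − x_i² − (n−1)·mean_loo²`; values within
  `1e−13` of zero (relative to `S₂`) are treated as exact zeros and raise a
  degenerate-input error naming the offending observation. `auto` mode uses
  the `t(n₁+n₂−2)` reference below a combined size of 60 and the normal
  reference above. Under pure rescaling `y = c·x` the pseudo-value shift is
  exactly `2 ln c`, so `γ̂² = c²` to machine precision — asserted as a test.
- **Moses.** Defaults: subset size 3, 200 repartitions, median-p
  aggregation, mandatory seed. The interquartile range of the per-partition
  p-values is reported as a stability diagnostic. The subset mean (not the
  group mean) centers each subset's sum of squares — the only reading that
  yields a scale statistic when group medians differ.
- **Welch ANOVA.** Weights `w_i = n_i/s_i²`; the denominator df is
  `(k²−1)/(3λ)` with `λ = Σ(1/(n_i−1))(1 − w_i/w)²`. At `k = 2` this is
  *algebraically identical* to the Satterthwaite two-sample df, and the
  statistic equals the squared Welch t — both identities are asserted. Note
  the statistic does **not** reduce to the plain ANOVA F for `k > 2` even
  with equal `n` and equal `s_i²`: the denominator correction
  `1 + 2(k−2)λ/(k²−1)` only vanishes at `k = 2`.

Degenerate inputs (zero variances, all-tied ranks) raise
`DegenerateDataError` rather than returning `NaN` p-values.

## Synthetic populations and scenarios

Three families, chosen to probe normality, heavy tails and skewness:

- `normal(mean, variance)` — the second parameter is a **variance**. The
  classic two-sample illustration "N(0,1) vs N(0,5)" is read as variance 5;
  the qualitative pooled-vs-Welch contrast is unchanged under the sd = √5
  reading, but the numbers are not, so the convention is fixed here.
- `t(df)`, location 0, variance `df/(df−2)` for `df > 2`. Pairs with dfs
  (3, 12), (3, 6), (3, 4) give true-variance ratios 5:2, 2:1, 3:2; triples
  (3, 12, 12) etc. give 5:2:2, 2:1:1, 3:2:2. Null cells use df = 3 for
  every group.
- `skew_normal(ξ, ω, α)` with variance `ω²(1 − 2α²/((1+α²)π))`. Scenario
  builders invert this formula in ω so that the **true variances** hit the
  requested ratios exactly (a config switch `ratio_on='omega2'` instead
  reads the ratios as ω² ratios). Groups share ξ and α and differ in ω
  only. Caveat: because the skew-normal mean is `ξ + ωδ√(2/π)` with
  `δ = α/√(1+α²)`, varying ω alone also shifts group means — the
  vary-ω-only design is kept as the default study condition, and an
  optional `mean_corrected` mode re-centers ξ per group for users who want
  a pure scale alternative. Shapes 10 and 50 are the two skewness levels
  studied.

Seeding: one scenario seed deterministically derives a `SeedSequence` per
(replicate, group) via spawn keys, so any single replicate is reproducible
in isolation and group streams are independent (paired-stream correlation
< 0.01 at n = 10⁵, tested).

What the generators do *not* emulate: dependence between observations,
measurement error, missingness, mixtures/contamination, or unequal group
sizes within a scenario. Passing tests therefore speak to the tests'
behaviour under clean iid sampling from these three shapes, not to messy
real-world trial data.

## The simulation engine

`estimate_rejection` draws `reps` replicates of a scenario (default 2000,
α = 0.05) and records, per test, the fraction rejected — `p < α` for
p-value tests, the table decision for Hartley and Cochran — together with
the Monte-Carlo standard error `√(p̂(1−p̂)/reps)`. Replicates where a test
raises a degenerate-input error count as non-rejections and are tallied in
a separate column. The default two-sample battery is the 11-test set (F,
four Levene variants, Bartlett, Ansari–Bradley with and without median
alignment, both jackknife modes, Fligner–Killeen); the Moses test is
excluded from grids because its internal random repartitioning makes it a
different kind of procedure (it remains available by name, seeded from the
replicate's own bytes for determinism). The multi-sample battery adds
Hartley and Cochran and drops the two-sample-only tests.

Grid defaults mirror the full study design (n from 11 to 100, 2000 reps per
cell) but every axis is configurable; the shipped test suite runs reduced
grids — e.g. n ∈ {15, 60} × two ratios at 400–500 reps, and the headline
cells (n = 50 and n = 100, 2000 reps) — sized so the whole suite stays
fast while keeping Monte-Carlo error small relative to the assertions
(3 MC-se tolerances throughout). The F-test cells are additionally checked
against the closed-form power of the scaled central F distribution
(`ratio·F ~ F(n−1, n−1)` under the alternative).

`location_type1_experiment` is fully vectorised (equal group sizes make
the pooled and Welch statistics identical, only the reference df differ),
so the stable high-replication mode (10⁵ reps) costs milliseconds; at the
classic 100 replicates the results are noisy by design (MC se ≈ 0.03).

## The recommender

A fully enumerated rule table maps (group-count band, distribution shape,
sample-size band, variance-ratio band) — 24 cells — to a ranked list of
tests with one-line rationales and cautions. Band thresholds are coarse
implementation choices: per-group n < 30 is "small", an anticipated
max/min variance ratio ≤ 2 is "small". The table encodes the simulation
findings: F/Bartlett (with the jackknife close behind) for normal
two-sample problems; the jackknife for heavy-tailed or skewed two-sample
problems, preferring the exact-t reference at small n and carrying an
explicit caution that its type-I error runs near 0.08 at small n with
heavy tails; Cochran (an outlier-variance test, flagged as such) then
Bartlett for normal multi-sample problems, with Hartley demoted at small
n; mean-centered Levene for heavy-tailed multi-sample problems (the rank
variant noted for small ratios); trimmed-mean Levene for skewed
multi-sample problems, with Fligner–Killeen noted for small ratios and
median Levene as the size-conservative companion. Parametric tests
(F, Bartlett, Hartley, Cochran) are never recommended off-normal, and a
test asserts that every recommended test holds its size within twice the
nominal level on the family it is recommended for, using a reduced null
grid. Unmapped queries fall back to median-centered Levene as a
conservative default.

`battery` runs every applicable test on a dataset, reports failures as
"not applicable (reason)" instead of aborting, appends the
equal-variance/Welch location contrast, and prints raw p-values with an
explicit no-multiplicity-correction note.

## Known limitations

- The exact Ansari–Bradley null assumes no ties; tied data fall back to a
  moment-based normal approximation without a finite-sample guarantee.
- Hartley/Cochran require balanced designs for their exact references;
  the unbalanced Hartley fallback is conservative, and Cochran refuses
  unbalanced input outright.
- The Fligner–Killeen null is asymptotic (χ²); no exact small-sample null
  is provided.
- The Moses median-p aggregation is a pragmatic stabiliser; the aggregated
  p-value is not exactly uniform under the null.
- The recommender's bands are deliberately coarse and its rules reflect
  the three simulated families only; it does not detect distribution shape
  from data — users declare it.
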