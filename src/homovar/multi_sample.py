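"""k-group homogeneity-of-variance tests.

The Levene family (mean / median / trimmed-mean / rank centering),
Bartlett's chi-square test, Hartley's Fmax, Cochran's C outlier-variance
test, the Fligner-Killeen normal-scores test, plus Welch's ANOVA and the
plain one-way ANOVA used downstream for location inference.

All functions take a :class:`~homovar.samples.GroupedSample` and return a
:class:`~homovar.samples.TestResult`.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .exceptions import DegenerateDataError, ValidationError
from .nulls import cochran_upper_limit, fmax_cdf, fmax_quantile
from .samples import GroupedSample, TestResult, summarize

__all__ = [
    "levene_test",
    "brown_forsythe",
    "bartlett_test",
    "hartley_test",
    "cochran_c_test",
    "fligner_killeen_test",
    "welch_anova",
    "one_way_anova",
]

_CENTERS = ("mean", "median", "trimmed", "rank")


def _trimmed_mean(values: np.ndarray, trim_fraction: float) -> float:
    n = values.size
    t = int(math.floor(trim_fraction * n))
    if n - 2 * t < 1:
        raise ValidationError(
            f"trimming {trim_fraction:g} from each tail leaves no value in a "
            f"group of size {n}"
        )
    s = np.sort(values, kind="mergesort")  # stable: ties by value then input order
    return float(s[t: n - t].mean())


def levene_test(
    sample: GroupedSample, center: str = "mean", trim_fraction: float = 0.25
) -> TestResult:
    """Levene-family test of variance homogeneity.

    Transforms each observation to an absolute deviation
    ``Z_ij = |Y_ij - c_i|`` from a group center ``c_i`` and runs the
    one-way ANOVA F statistic on the Z values:

    ``W = [(N - k) / (k - 1)] * sum n_i (Zbar_i - Zbar)^2
        / sum sum (Z_ij - Zbar_i)^2``  ~  ``F(k - 1, N - k)``.

    Centers: ``'mean'`` (classical Levene), ``'median'`` (Brown-Forsythe),
    ``'trimmed'`` (mean after discarding ``floor(trim_fraction * n_i)``
    values from each tail; deviations are still taken for *all*
    observations), ``'rank'`` (all values replaced by pooled midranks
    first, then mean-centered — a non-parametric variant).
    """
    if center not in _CENTERS:
        raise ValidationError(f"center must be one of {_CENTERS}")
    groups = list(sample.groups)
    label = {
        "mean": "Levene test (mean center)",
        "median": "Brown-Forsythe test (median center)",
        "trimmed": f"Levene test (trimmed mean, {trim_fraction:g} per tail)",
        "rank": "Rank-based Levene test",
    }[center]
    if center == "rank":
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled, method="average")
        cuts = np.cumsum([g.size for g in groups])[:-1]
        groups = list(np.split(ranks, cuts))
        center = "mean"
    if center == "mean":
        centers = [g.mean() for g in groups]
    elif center == "median":
        centers = [np.median(g) for g in groups]
    else:
        centers = [_trimmed_mean(g, trim_fraction) for g in groups]
    z = [np.abs(g - c) for g, c in zip(groups, centers)]
    N, k = sample.total_n, sample.k
    zbar_i = np.array([zi.mean() for zi in z])
    n_i = np.array(sample.sizes, dtype=float)
    zbar = float((n_i * zbar_i).sum() / N)
    ssb = float((n_i * (zbar_i - zbar) ** 2).sum())
    ssw = float(sum(((zi - m) ** 2).sum() for zi, m in zip(z, zbar_i)))
    # relative guard: 2-point groups leave a ~1-ulp residual instead of an
    # exact zero in |Y - mean| deviations
    if ssw <= 1e-12 * max(ssb + ssw, np.finfo(float).tiny):
        raise DegenerateDataError(
            "within-group sum of squares of |deviations| is zero; "
            "the Levene statistic is undefined"
        )
    w = (N - k) / (k - 1) * ssb / ssw
    p = float(stats.f.sf(w, k - 1, N - k))
    return TestResult(
        method=label,
        statistic=float(w),
        reference=f"F({k - 1}, {N - k})",
        df=(float(k - 1), float(N - k)),
        p_value=p,
        alternative="two-sided",
    )


def brown_forsythe(sample: GroupedSample) -> TestResult:
    """Alias for :func:`levene_test` with median centering."""
    return levene_test(sample, center="median")


def bartlett_test(sample: GroupedSample) -> TestResult:
    """Bartlett's chi-square test of variance homogeneity.

    ``chi2 = [ (N - k) ln s_p^2 - sum (n_i - 1) ln s_i^2 ]
           / [ 1 + (1 / (3(k - 1))) (sum 1/(n_i - 1) - 1/(N - k)) ]``
    on ``k - 1`` df.  The numerator is the (n_i - 1)-weighted sum of
    ``ln(s_p^2 / s_i^2)``, hence zero iff all group variances are equal.
    """
    summ = summarize(sample)
    if any(v == 0.0 for v in summ.variances):
        raise DegenerateDataError("a group has zero sample variance")
    N, k = sample.total_n, sample.k
    n_i = np.array(sample.sizes, dtype=float)
    num = (N - k) * math.log(summ.pooled_variance) - float(
        ((n_i - 1) * np.log(summ.variances)).sum()
    )
    corr = 1.0 + (1.0 / (3.0 * (k - 1))) * (
        float((1.0 / (n_i - 1)).sum()) - 1.0 / (N - k)
    )
    stat = max(num / corr, 0.0)
    return TestResult(
        method="Bartlett test",
        statistic=float(stat),
        reference=f"chi-square({k - 1})",
        df=(float(k - 1),),
        p_value=float(stats.chi2.sf(stat, k - 1)),
        alternative="two-sided",
    )


def hartley_test(sample: GroupedSample, alpha: float = 0.05) -> TestResult:
    """Hartley's Fmax test: largest over smallest group variance.

    Designed for balanced normal data on ``df = n - 1``; an unbalanced
    design is accepted with the conservative rule of using the smallest
    group's degrees of freedom.  Reports both the table-style decision at
    ``alpha`` and a p-value from the Fmax distribution.
    """
    summ = summarize(sample)
    vmin, vmax = min(summ.variances), max(summ.variances)
    if vmin == 0.0:
        raise DegenerateDataError("smallest group variance is zero; Fmax undefined")
    stat = vmax / vmin
    df = min(sample.sizes) - 1
    crit = fmax_quantile(alpha, sample.k, df)
    p = 1.0 - fmax_cdf(stat, sample.k, df) if stat > 1.0 else 1.0
    extras = {"critical_value": crit, "df": df}
    if not sample.is_balanced:
        extras["note"] = "unbalanced design: conservative df = min(n_i) - 1"
    return TestResult(
        method="Hartley Fmax test",
        statistic=float(stat),
        reference=f"Fmax(k={sample.k}, df={df})",
        p_value=float(p),
        alternative="two-sided",
        reject_at=(alpha, bool(stat > crit)),
        extras=extras,
    )


def cochran_c_test(
    sample: GroupedSample, alpha: float = 0.05, which: str | int = "max"
) -> TestResult:
    """Cochran's C test for one exceptionally large group variance.

    ``C_j = s_j^2 / sum_i s_i^2`` for a balanced design; the default tests
    the largest variance against the upper limit
    :func:`~homovar.nulls.cochran_upper_limit` (level split over the ``k``
    candidate groups).  Unlike the other tests here the alternative is
    one-sided — "group j has a larger variance than the rest" — not a
    global homogeneity alternative.
    """
    if not sample.is_balanced:
        raise ValidationError(
            "Cochran's C requires equal group sizes; use the Levene family "
            "or Bartlett's test for unbalanced designs"
        )
    summ = summarize(sample)
    total = sum(summ.variances)
    if total <= 0.0:
        raise DegenerateDataError("all group variances are zero")
    c_values = np.array(summ.variances) / total
    if which == "max":
        j = int(np.argmax(c_values))
    elif isinstance(which, int):
        if not (0 <= which < sample.k):
            raise ValidationError(f"group index {which} out of range")
        j = which
    else:
        raise ValidationError("which must be 'max' or a group index")
    n = sample.sizes[0]
    limit = cochran_upper_limit(alpha, n, sample.k)
    stat = float(c_values[j])
    return TestResult(
        method="Cochran C test",
        statistic=stat,
        reference="critical-value comparison (Cochran upper limit)",
        p_value=None,
        alternative="greater",
        reject_at=(alpha, bool(stat > limit)),
        extras={
            "tested_group": sample.labels[j],
            "c_values": dict(zip(sample.labels, map(float, c_values))),
            "upper_limit": limit,
        },
    )


def fligner_killeen_test(sample: GroupedSample) -> TestResult:
    """Fligner-Killeen normal-scores test of variance homogeneity.

    Absolute deviations from the group medians are pooled and midranked;
    rank ``m`` receives the score ``a_{N,m} = Phi^{-1}((1 + m/(N+1)) / 2)``.
    With group score means ``Abar_i``, overall mean ``abar`` and score
    variance ``V^2 = sum (a_m - abar)^2 / (N - 1)``, the statistic
    ``x0^2 = sum n_i (Abar_i - abar)^2 / V^2`` is referred to
    chi-square(k - 1).
    """
    groups = sample.groups
    absdev = [np.abs(g - np.median(g)) for g in groups]
    pooled = np.concatenate(absdev)
    N, k = sample.total_n, sample.k
    ranks = stats.rankdata(pooled, method="average")
    a = stats.norm.ppf((1.0 + ranks / (N + 1)) / 2.0)
    abar = float(a.mean())
    v2 = float(((a - abar) ** 2).sum() / (N - 1))
    if v2 <= 0.0:
        raise DegenerateDataError(
            "all scored deviations are tied; score variance is zero"
        )
    cuts = np.cumsum(sample.sizes)[:-1]
    stat = 0.0
    for n_i, a_i in zip(sample.sizes, np.split(a, cuts)):
        stat += n_i * (a_i.mean() - abar) ** 2
    stat /= v2
    return TestResult(
        method="Fligner-Killeen test",
        statistic=float(stat),
        reference=f"chi-square({k - 1})",
        df=(float(k - 1),),
        p_value=float(stats.chi2.sf(stat, k - 1)),
        alternative="two-sided",
    )


def welch_anova(sample: GroupedSample) -> TestResult:
    """Welch's heteroscedasticity-robust one-way ANOVA for means.

    Weights ``w_i = n_i / s_i^2``, weighted grand mean ``Ybar'``; the
    statistic

    ``F = [ sum w_i (Ybar_i - Ybar')^2 / (k - 1) ]
        / [ 1 + (2(k - 2)/(k^2 - 1)) sum (1/(n_i - 1)) (1 - w_i/w)^2 ]``

    is referred to ``F(k - 1, df)`` with
    ``df = (k^2 - 1) / (3 sum (1/(n_i - 1)) (1 - w_i/w)^2)``.
    At ``k = 2`` this reduces to the squared Welch t statistic on
    Satterthwaite df.
    """
    summ = summarize(sample)
    if any(v == 0.0 for v in summ.variances):
        raise DegenerateDataError("a group has zero sample variance")
    k = sample.k
    n_i = np.array(sample.sizes, dtype=float)
    means = np.array(summ.means)
    w_i = n_i / np.array(summ.variances)
    w = w_i.sum()
    grand = float((w_i * means).sum() / w)
    lam = float(((1.0 / (n_i - 1)) * (1.0 - w_i / w) ** 2).sum())
    num = float((w_i * (means - grand) ** 2).sum()) / (k - 1)
    den = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * lam
    stat = num / den
    df2 = (k**2 - 1) / (3.0 * lam) if lam > 0 else math.inf
    p = float(stats.f.sf(stat, k - 1, df2))
    return TestResult(
        method="Welch ANOVA",
        statistic=float(stat),
        reference=f"F({k - 1}, {df2:.4g})",
        df=(float(k - 1), float(df2)),
        p_value=p,
        alternative="two-sided",
        extras={"weighted_grand_mean": grand},
    )


def one_way_anova(sample: GroupedSample) -> TestResult:
    """Classical one-way ANOVA F test for equal group means."""
    summ = summarize(sample)
    N, k = sample.total_n, sample.k
    n_i = np.array(sample.sizes, dtype=float)
    means = np.array(summ.means)
    ssb = float((n_i * (means - summ.grand_mean) ** 2).sum())
    ssw = float(sum((n - 1) * v for n, v in zip(sample.sizes, summ.variances)))
    if ssw <= 0.0:
        raise DegenerateDataError("zero within-group variation; F undefined")
    stat = (ssb / (k - 1)) / (ssw / (N - k))
    return TestResult(
        method="One-way ANOVA",
        statistic=float(stat),
        reference=f"F({k - 1}, {N - k})",
        df=(float(k - 1), float(N - k)),
        p_value=float(stats.f.sf(stat, k - 1, N - k)),
        alternative="two-sided",
    )
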