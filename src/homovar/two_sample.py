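"""Two-group scale comparisons, plus the Welch location helpers.

Scale tests: the variance-ratio F test, the Ansari-Bradley rank test (with
optional Walsh-median alignment), the Moses rank-like test on subset sums
of squares, and the Miller jackknife test on log sample variances.

Conventions: ``alternative`` always refers to the dispersion of ``x``
relative to ``y`` — ``'greater'`` means the alternative "x is more spread
out than y".
"""
from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats

from .exceptions import DegenerateDataError, ValidationError
from .nulls import ENUMERATION_CAP, ansari_exact_null, ansari_scores, score_moments
from .samples import TestResult

logger = logging.getLogger("homovar")

__all__ = [
    "f_test",
    "welch_df",
    "welch_t_test",
    "walsh_means",
    "ansari_bradley_test",
    "moses_test",
    "jackknife_test",
]

_ALTERNATIVES = ("two-sided", "less", "greater")


def _check_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise ValidationError(f"alternative must be one of {_ALTERNATIVES}")


def _as_group(values, name: str, min_size: int = 2) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < min_size:
        raise ValidationError(f"group {name} needs at least {min_size} observations")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"group {name} contains non-finite values")
    return arr


def f_test(
    x, y, alternative: str = "two-sided", ratio0: float = 1.0
) -> TestResult:
    """Variance-ratio F test for two normal samples.

    The statistic is ``F = (s_x^2 / s_y^2) / ratio0`` referred to
    ``F(n_x - 1, n_y - 1)``.  The two-sided p-value doubles the smaller
    tail (capped at 1).
    """
    _check_alternative(alternative)
    x = _as_group(x, "x")
    y = _as_group(y, "y")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 or vy == 0.0:
        raise DegenerateDataError("zero sample variance: F statistic undefined")
    if ratio0 <= 0:
        raise ValidationError("ratio0 must be positive")
    d1, d2 = x.size - 1, y.size - 1
    stat = (vx / vy) / ratio0
    dist = stats.f(d1, d2)
    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(dist.cdf(stat), dist.sf(stat)))
    elif alternative == "greater":
        p = float(dist.sf(stat))
    else:
        p = float(dist.cdf(stat))
    return TestResult(
        method="F test (variance ratio)",
        statistic=float(stat),
        reference=f"F({d1}, {d2})",
        df=(float(d1), float(d2)),
        p_value=float(p),
        alternative=alternative,
        extras={"variance_ratio": float(vx / vy)},
    )


def welch_df(s1sq: float, s2sq: float, n1: int, n2: int) -> float:
    """Welch-Satterthwaite degrees of freedom for two sample variances.

    ``df = (s1^2/n1 + s2^2/n2)^2 / [ (s1^2/n1)^2/(n1-1) + (s2^2/n2)^2/(n2-1) ]``,
    which always lies between ``min(n1, n2) - 1`` and ``n1 + n2 - 2``.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("welch_df requires n1, n2 >= 2")
    if s1sq < 0 or s2sq < 0:
        raise ValidationError("variances cannot be negative")
    if s1sq == 0 and s2sq == 0:
        raise DegenerateDataError("both variances are zero; df undefined")
    a, b = s1sq / n1, s2sq / n2
    return float((a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1)))


def welch_t_test(
    x,
    y,
    assume_equal_variance: bool = False,
    alternative: str = "two-sided",
) -> TestResult:
    """Two-sample t test for means, pooled or Welch (Satterthwaite df).

    With ``assume_equal_variance`` the classical pooled test on
    ``n1 + n2 - 2`` df is used; otherwise the Welch statistic with
    :func:`welch_df`.  At equal group sizes the two statistics coincide
    and only the reference df differ.
    """
    _check_alternative(alternative)
    x = _as_group(x, "x")
    y = _as_group(y, "y")
    n1, n2 = x.size, y.size
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if assume_equal_variance:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        if sp2 == 0.0:
            raise DegenerateDataError("pooled variance is zero; t undefined")
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
        method = "Two-sample t test (pooled variance)"
    else:
        if v1 == 0.0 and v2 == 0.0:
            raise DegenerateDataError("both variances are zero; t undefined")
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = welch_df(v1, v2, n1, n2)
        method = "Welch t test (Satterthwaite df)"
    stat = diff / se
    dist = stats.t(df)
    if alternative == "two-sided":
        p = 2.0 * float(dist.sf(abs(stat)))
    elif alternative == "greater":
        p = float(dist.sf(stat))
    else:
        p = float(dist.cdf(stat))
    return TestResult(
        method=method,
        statistic=float(stat),
        reference=f"t({df:g})",
        df=(df,),
        p_value=min(1.0, p),
        alternative=alternative,
        extras={"mean_difference": float(diff)},
    )


def walsh_means(x) -> np.ndarray:
    """All ``n(n+1)/2`` pairwise averages ``(Y_a + Y_b)/2`` with ``a <= b``.

    Their median is a robust location estimate (the Hodges-Lehmann
    one-sample estimator) used to align group medians before the
    Ansari-Bradley test.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 1:
        raise ValidationError("walsh_means requires at least one observation")
    sums = np.add.outer(x, x) / 2.0
    iu = np.triu_indices(x.size)
    return sums[iu]


def _walsh_median(x: np.ndarray) -> float:
    return float(np.median(walsh_means(x)))


_ALIGN_WARNED = False


def ansari_bradley_test(
    x,
    y,
    alternative: str = "two-sided",
    mode: str = "auto",
    align_medians: bool = False,
) -> TestResult:
    """Ansari-Bradley rank test of equal scales.

    The pooled sample is scored symmetrically from both ends (extremes
    score 1); ``W`` is the score sum of the *smaller* group.  A small ``W``
    means that group occupies the extreme positions, i.e. is the more
    dispersed one.  Ties receive averaged scores over the tied block; the
    exact null (no ties, ``m + n`` within the enumeration cap) or the
    normal approximation on the exact moments supplies the p-value.

    The test assumes equal medians.  With ``align_medians`` each group is
    first shifted to put its median of Walsh means at zero; note this
    alignment is not a strictly distribution-free practice.
    """
    _check_alternative(alternative)
    if mode not in ("exact", "approximate", "auto"):
        raise ValidationError("mode must be 'exact', 'approximate' or 'auto'")
    x = _as_group(x, "x")
    y = _as_group(y, "y")
    if align_medians:
        global _ALIGN_WARNED
        if not _ALIGN_WARNED:  # warn once, not per call in a simulation loop
            logger.warning(
                "Ansari-Bradley median alignment in use; shifting by estimated "
                "medians is not a distribution-free practice"
            )
            _ALIGN_WARNED = True
        x = x - _walsh_median(x)
        y = y - _walsh_median(y)
    pooled = np.concatenate([x, y])
    N = pooled.size
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("all observations identical; ranks undefined")
    order = np.argsort(pooled, kind="mergesort")
    base = ansari_scores(N).astype(float)
    sorted_vals = pooled[order]
    uniq, inv, counts = np.unique(sorted_vals, return_inverse=True, return_counts=True)
    has_ties = uniq.size < N
    if has_ties:
        block_sums = np.bincount(inv, weights=base)
        scores_sorted = (block_sums / counts)[inv]
    else:
        scores_sorted = base
    scores = np.empty(N)
    scores[order] = scores_sorted

    # score the smaller group ("without loss of generality n1 < n2")
    if x.size <= y.size:
        scored, other, scored_is_x = x.size, y.size, True
        w = float(scores[: x.size].sum())
    else:
        scored, other, scored_is_x = y.size, x.size, False
        w = float(scores[x.size:].sum())

    use_exact = mode == "exact" or (
        mode == "auto" and not has_ties and N <= ENUMERATION_CAP
    )
    if mode == "exact" and (has_ties or N > ENUMERATION_CAP):
        raise ValidationError(
            "exact Ansari-Bradley null unavailable: "
            + ("ties present" if has_ties else "sample too large")
        )

    # One-sided probabilities in terms of the scored group: small W means
    # the scored group is the more dispersed one.
    if use_exact:
        null = ansari_exact_null(scored, other)
        p_scored_disp = null.cdf(w)  # P(W <= w)
        p_scored_conc = null.sf(w)   # P(W >= w)
        reference = "exact W"
    else:
        mean, var = score_moments(scores, scored)
        if var <= 0:
            raise DegenerateDataError("degenerate score variance")
        sd = math.sqrt(var)
        cc = 0.0 if has_ties else 0.5
        p_scored_disp = float(stats.norm.cdf((w - mean + cc) / sd))
        p_scored_conc = float(stats.norm.sf((w - mean - cc) / sd))
        reference = "normal approximation to W"

    # map to the x-vs-y alternative
    p_x_disp = p_scored_disp if scored_is_x else p_scored_conc
    p_x_conc = p_scored_conc if scored_is_x else p_scored_disp
    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_x_disp, p_x_conc))
    elif alternative == "greater":
        p = min(1.0, p_x_disp)
    else:
        p = min(1.0, p_x_conc)
    extras = {
        "scored_group": "x" if scored_is_x else "y",
        "ties": bool(has_ties),
        "aligned_medians": bool(align_medians),
    }
    return TestResult(
        method="Ansari-Bradley test"
        + (" (median-aligned)" if align_medians else ""),
        statistic=w,
        reference=reference,
        p_value=float(p),
        alternative=alternative,
        extras=extras,
    )


def moses_test(
    x,
    y,
    subset_size: int = 3,
    repartitions: int = 200,
    seed: int | np.random.Generator | None = None,
    alternative: str = "two-sided",
) -> TestResult:
    """Moses rank-like test of dispersion for unknown, unequal medians.

    Each group is randomly partitioned into ``floor(n_i / subset_size)``
    subsets of equal size (leftovers discarded); each subset contributes
    ``D = sum (x - subset mean)^2``; a Wilcoxon rank-sum test compares the
    two collections of D values.  Because the partition is random, the
    procedure is repeated ``repartitions`` times and the median p-value is
    reported, with the interquartile spread of the per-partition p-values
    as a stability diagnostic.
    """
    _check_alternative(alternative)
    if subset_size < 2:
        raise ValidationError("subset_size must be at least 2")
    if repartitions < 1:
        raise ValidationError("repartitions must be at least 1")
    x = _as_group(x, "x")
    y = _as_group(y, "y")
    counts = [x.size // subset_size, y.size // subset_size]
    for name, grp, c in zip("xy", (x, y), counts):
        if c < 2:
            raise ValidationError(
                f"group {name} yields {c} subset(s) of size {subset_size}; "
                f"need at least 2 (n >= {2 * subset_size})"
            )
    if seed is None:
        raise ValidationError("moses_test requires an explicit seed for reproducibility")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def subset_ss(values: np.ndarray, n_subsets: int) -> np.ndarray:
        perm = rng.permutation(values)[: n_subsets * subset_size]
        mat = perm.reshape(n_subsets, subset_size)
        return ((mat - mat.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)

    pvals = np.empty(repartitions)
    stats_w = np.empty(repartitions)
    for r in range(repartitions):
        dx = subset_ss(x, counts[0])
        dy = subset_ss(y, counts[1])
        res = stats.mannwhitneyu(dx, dy, alternative=alternative)
        pvals[r] = res.pvalue
        stats_w[r] = res.statistic
    p = float(np.median(pvals))
    q25, q75 = np.percentile(pvals, [25, 75])
    return TestResult(
        method="Moses rank-like test",
        statistic=float(np.median(stats_w)),
        reference="Wilcoxon rank-sum on subset sums of squares",
        p_value=p,
        alternative=alternative,
        extras={
            "subset_size": subset_size,
            "repartitions": repartitions,
            "subsets": tuple(counts),
            "discarded": (x.size % subset_size, y.size % subset_size),
            "p_iqr": (float(q25), float(q75)),
        },
    )


def _jackknife_side(values: np.ndarray, name: str) -> tuple[float, float]:
    """Mean and variance-of-mean of the log-variance pseudo-values."""
    n = values.size
    s1 = values.sum()
    s2 = (values**2).sum()
    mean_loo = (s1 - values) / (n - 1)
    ss_loo = s2 - values**2 - (n - 1) * mean_loo**2
    # guard against tiny negative round-off before the log
    ss_loo = np.where(np.abs(ss_loo) < 1e-13 * max(s2, 1.0), 0.0, ss_loo)
    loo_var = ss_loo / (n - 2)
    bad = np.nonzero(loo_var <= 0)[0]
    if bad.size:
        raise DegenerateDataError(
            f"leave-one-out variance of group {name} is zero when dropping "
            f"observation index {int(bad[0])}"
        )
    d0 = values.var(ddof=1)
    if d0 <= 0:
        raise DegenerateDataError(f"group {name} has zero sample variance")
    s0 = math.log(d0)
    si = np.log(loo_var)
    pseudo = n * s0 - (n - 1) * si
    pbar = float(pseudo.mean())
    vbar = float(((pseudo - pbar) ** 2).sum() / (n * (n - 1)))
    return pbar, vbar


def jackknife_test(
    x, y, mode: str = "auto", alternative: str = "two-sided"
) -> TestResult:
    """Miller's jackknife test on log sample variances.

    Pseudo-values ``A_i = n ln D_(0) - (n - 1) ln D_(i)`` are built from the
    leave-one-out variances ``D_(i)``; the statistic
    ``Q = (B_bar - A_bar) / sqrt(V_A + V_B)`` is referred to a
    ``t(n1 + n2 - 2)`` distribution (``mode='exact_t'``) or to the standard
    normal (``mode='normal'``); ``'auto'`` uses the t reference below a
    combined size of 60.  Also returns ``gamma2 = exp(B_bar - A_bar)``, the
    estimated ratio var(y) / var(x).
    """
    _check_alternative(alternative)
    if mode not in ("exact_t", "normal", "auto"):
        raise ValidationError("mode must be 'exact_t', 'normal' or 'auto'")
    x = _as_group(x, "x", min_size=3)
    y = _as_group(y, "y", min_size=3)
    abar, va = _jackknife_side(x, "x")
    bbar, vb = _jackknife_side(y, "y")
    denom = va + vb
    if denom <= 0:
        raise DegenerateDataError("zero pseudo-value variance; Q undefined")
    q = (bbar - abar) / math.sqrt(denom)
    gamma2 = math.exp(bbar - abar)
    n_total = x.size + y.size
    if mode == "auto":
        mode = "exact_t" if n_total < 60 else "normal"
    if mode == "exact_t":
        dist = stats.t(n_total - 2)
        reference = f"t({n_total - 2})"
        df: tuple[float, ...] = (float(n_total - 2),)
    else:
        dist = stats.norm()
        reference = "standard normal"
        df = ()
    # Q > 0 means y looks more dispersed than x; 'greater' (x more
    # dispersed) therefore sits in the lower tail of Q.
    if alternative == "two-sided":
        p = 2.0 * float(dist.sf(abs(q)))
    elif alternative == "greater":
        p = float(dist.cdf(q))
    else:
        p = float(dist.sf(q))
    return TestResult(
        method=f"Jackknife test ({'exact t' if reference.startswith('t') else 'normal'})",
        statistic=float(q),
        reference=reference,
        df=df,
        p_value=min(1.0, p),
        alternative=alternative,
        extras={"gamma2": float(gamma2)},
    )
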