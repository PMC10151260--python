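"""Null-distribution machinery shared by the variance tests.

Three families live here:

* the exact permutation null of the Ansari-Bradley rank statistic ``W``
  (symmetric scores 1, 2, ..., from both ends of the pooled order),
* the distribution of Hartley's ``Fmax`` — the ratio of the largest to the
  smallest of ``k`` independent sample variances on a common ``df`` — via
  numerical quadrature, and
* the upper limit of Cochran's ``C`` statistic (one large variance among
  ``k`` groups).
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy.stats import chi2, f as f_dist

from .exceptions import NumericalError, ValidationError

__all__ = [
    "ExactNull",
    "ansari_scores",
    "ansari_exact_null",
    "ansari_critical",
    "ansari_large_sample",
    "score_moments",
    "fmax_cdf",
    "fmax_quantile",
    "cochran_upper_limit",
    "ansari_critical_table",
    "fmax_table",
    "ENUMERATION_CAP",
]

#: Largest pooled size m + n for which the exact Ansari-Bradley null is
#: computed (by a dynamic-programming convolution over the scores, which is
#: exact and polynomial-time).  Beyond this, callers fall back to the
#: normal approximation built on the exact first two moments.
ENUMERATION_CAP = 200


def ansari_scores(N: int) -> np.ndarray:
    """Ansari-Bradley scores for a pooled sample of size ``N``.

    Position ``j`` (1-based, in sorted order) receives score
    ``min(j, N + 1 - j)``: the smallest and largest observations score 1,
    the second smallest and second largest score 2, and so on.  The score
    list is palindromic with maximum ``ceil(N / 2)``.
    """
    N = int(N)
    if N < 2:
        raise ValidationError("ansari_scores requires N >= 2")
    j = np.arange(1, N + 1)
    return np.minimum(j, N + 1 - j)


@dataclass(frozen=True)
class ExactNull:
    """Finite support and probability mass of a discrete rank statistic."""

    support: np.ndarray
    pmf: np.ndarray
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if np.any(self.pmf <= 0):
            raise ValidationError("pmf entries must be positive")
        if abs(self.pmf.sum() - 1.0) > 1e-12:
            raise ValidationError("pmf must sum to 1")

    def cdf(self, w: float) -> float:
        """P(W <= w)."""
        return float(self.pmf[self.support <= w + 1e-9].sum())

    def sf(self, w: float) -> float:
        """P(W >= w)."""
        return float(self.pmf[self.support >= w - 1e-9].sum())


@lru_cache(maxsize=64)
def ansari_exact_null(m: int, n: int) -> ExactNull:
    """Exact null law of the Ansari-Bradley sum ``W`` for group sizes m <= n.

    Under the null every size-``m`` subset of the ``N = m + n`` pooled
    positions is equally likely to be group 1, so the pmf is the subset-sum
    count of the score list divided by C(N, m).  Computed by a
    dynamic-programming convolution (exact; no ties assumed).
    """
    m, n = int(m), int(n)
    if not (2 <= m <= n):
        raise ValidationError("require 2 <= m <= n")
    N = m + n
    if N > ENUMERATION_CAP:
        raise ValidationError(
            f"m + n = {N} exceeds the exact-null cap ({ENUMERATION_CAP}); "
            "use the large-sample approximation (ansari_large_sample)"
        )
    scores = ansari_scores(N)
    wmax = int(np.sort(scores)[-m:].sum())
    # counts[j, w] = number of j-subsets of the score list with sum w
    counts = np.zeros((m + 1, wmax + 1))
    counts[0, 0] = 1.0
    for s in scores:
        s = int(s)
        for j in range(m, 0, -1):
            counts[j, s:] += counts[j - 1, : wmax + 1 - s]
    row = counts[m]
    support = np.nonzero(row)[0]
    pmf = row[support] / row.sum()
    mean = float((support * pmf).sum())
    var = float(((support - mean) ** 2 * pmf).sum())
    return ExactNull(support=support, pmf=pmf, mean=mean, variance=var)


def ansari_critical(
    m: int, n: int, alpha: float, tail: str
) -> int | None:
    """Exact critical value of ``W`` at one-sided level ``alpha``.

    ``tail='upper'`` returns the smallest ``w`` with ``P(W >= w) <= alpha``;
    ``tail='lower'`` the largest ``w`` with ``P(W <= w) <= alpha``.  Returns
    ``None`` when no support point attains the bound (small samples).
    """
    if not (0 < alpha <= 0.5):
        raise ValidationError("alpha must lie in (0, 0.5]")
    if tail not in ("lower", "upper"):
        raise ValidationError("tail must be 'lower' or 'upper'")
    null = ansari_exact_null(m, n)
    if tail == "upper":
        tailprob = np.cumsum(null.pmf[::-1])[::-1]  # P(W >= w)
        ok = np.nonzero(tailprob <= alpha + 1e-12)[0]
        return int(null.support[ok[0]]) if ok.size else None
    tailprob = np.cumsum(null.pmf)  # P(W <= w)
    ok = np.nonzero(tailprob <= alpha + 1e-12)[0]
    return int(null.support[ok[-1]]) if ok.size else None


def score_moments(scores: np.ndarray, m: int) -> tuple[float, float]:
    """Mean and variance of a sum of ``m`` scores drawn without replacement.

    Valid for any score vector (including tie-averaged scores): with
    ``S1 = sum(scores)`` and ``S2 = sum(scores**2)``,
    ``mean = m S1 / N`` and
    ``var = m (N - m) (N S2 - S1^2) / (N^2 (N - 1))``.
    """
    scores = np.asarray(scores, dtype=float)
    N = scores.size
    m = int(m)
    if not (1 <= m <= N):
        raise ValidationError("require 1 <= m <= N")
    s1 = scores.sum()
    s2 = (scores**2).sum()
    mean = m * s1 / N
    var = m * (N - m) * (N * s2 - s1**2) / (N**2 * (N - 1))
    return float(mean), float(var)


def ansari_large_sample(m: int, n: int) -> tuple[float, float]:
    """Exact first two moments of the null ``W`` (no enumeration needed)."""
    m, n = int(m), int(n)
    if m < 2 or n < 2:
        raise ValidationError("require m, n >= 2")
    return score_moments(ansari_scores(m + n), m)


# ---------------------------------------------------------------------------
# Hartley's Fmax
# ---------------------------------------------------------------------------

def fmax_cdf(c: float, k: int, df: int) -> float:
    """P(Fmax <= c) for ``k`` independent variances on ``df`` df each.

    With ``X_i = s_i^2 / sigma^2 ~ chi2(df) / df`` iid, the CDF of
    ``max X / min X`` is ``integral of k g(x) [G(c x) - G(x)]^(k-1) dx``
    over x > 0, with g/G the density/CDF of chi2(df)/df.  Evaluated by
    adaptive quadrature to absolute accuracy well below 1e-6.
    """
    k, df = int(k), int(df)
    if k < 2:
        raise ValidationError("fmax_cdf requires k >= 2")
    if df < 1:
        raise ValidationError("fmax_cdf requires df >= 1")
    if c <= 1.0:
        return 0.0
    dist = chi2(df)

    def integrand(x: float) -> float:
        return k * df * dist.pdf(df * x) * (dist.cdf(df * c * x) - dist.cdf(df * x)) ** (k - 1)

    lo = dist.ppf(1e-14) / df
    hi = dist.isf(1e-14) / df
    interior = [dist.ppf(q) / df for q in (0.05, 0.25, 0.5, 0.75, 0.95)]
    val, err = integrate.quad(
        integrand, lo, hi, points=interior, limit=500, epsabs=1e-10, epsrel=1e-10
    )
    if err > 1e-6:
        raise NumericalError(f"fmax_cdf quadrature error {err:g} too large")
    return float(min(max(val, 0.0), 1.0))


def fmax_quantile(alpha: float, k: int, df: int) -> float:
    """Upper-``alpha`` critical value ``c`` with ``P(Fmax > c) = alpha``.

    Solved as the root of ``fmax_cdf(c) = 1 - alpha`` by bracketing
    (doubling the upper end from 10) and Brent's method, relative
    tolerance 1e-8.
    """
    if not (0 < alpha <= 0.5):
        raise ValidationError("alpha must lie in (0, 0.5]")
    target = 1.0 - alpha
    lo, hi = 1.0 + 1e-12, 10.0
    for _ in range(80):
        if fmax_cdf(hi, k, df) >= target:
            break
        lo = hi
        hi *= 2.0
    else:  # pragma: no cover - cannot happen for valid alpha
        raise NumericalError(
            f"failed to bracket the Fmax quantile (alpha={alpha}, k={k}, df={df})"
        )
    try:
        root = optimize.brentq(
            lambda c: fmax_cdf(c, k, df) - target, lo, hi, xtol=1e-10, rtol=1e-10
        )
    except ValueError as exc:  # pragma: no cover
        raise NumericalError(
            f"Fmax quantile root-finding failed: alpha={alpha}, k={k}, df={df}: {exc}"
        ) from exc
    return float(root)


def cochran_upper_limit(alpha: float, n: int, k: int) -> float:
    """Upper bound for Cochran's ``C`` at one-sided level ``alpha``.

    ``C_UL = 1 / (1 + (k - 1) / F*)`` where ``F*`` is the upper
    ``alpha / k`` quantile of ``F(n - 1, (k - 1)(n - 1))``; dividing the
    level by ``k`` accounts for testing each of the ``k`` group variances
    one at a time.  The limit always lies in ``(1/k, 1)``.
    """
    n, k = int(n), int(k)
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    if n < 2 or k < 2:
        raise ValidationError("require n >= 2 and k >= 2")
    fstar = f_dist.isf(alpha / k, n - 1, (k - 1) * (n - 1))
    return float(1.0 / (1.0 + (k - 1) / fstar))


# ---------------------------------------------------------------------------
# Table regeneration (for comparison against published critical-value tables)
# ---------------------------------------------------------------------------

def ansari_critical_table(
    m_values: tuple[int, ...] = (2, 5),
    n_max: int = 20,
    levels: tuple[float, ...] = (0.005, 0.01, 0.025, 0.05),
) -> pd.DataFrame:
    """Exact lower/upper critical values of ``W`` over a grid of (m, n)."""
    rows = []
    for m in m_values:
        for n in range(m, n_max + 1):
            row: dict[str, object] = {"m": m, "n": n}
            for a in levels:
                lower = ansari_critical(m, n, a, "lower")
                upper = ansari_critical(m, n, a, "upper")
                row[f"lower_{1 - a:g}"] = lower
                row[f"upper_{a:g}"] = upper
            rows.append(row)
    return pd.DataFrame(rows)


def fmax_table(
    k_values: tuple[int, ...] = (2, 3, 4, 5),
    df_values: tuple[int, ...] = (2, 3, 4, 5),
    alphas: tuple[float, ...] = (0.05, 0.01),
) -> pd.DataFrame:
    """Critical values of Hartley's ``Fmax`` over a (k, df, alpha) grid."""
    rows = [
        {
            "k": k,
            "df": df,
            "alpha": a,
            "critical_value": fmax_quantile(a, k, df),
        }
        for k in k_values
        for df in df_values
        for a in alphas
    ]
    return pd.DataFrame(rows)
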