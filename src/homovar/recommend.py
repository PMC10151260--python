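"""Scenario-based test recommendations and the full test battery.

The rule table distils the Monte-Carlo power and type-I-error study into an
auditable mapping from a coarse description of the data — number of groups,
distribution shape, sample-size band, anticipated variance-ratio band — to
a ranked list of homogeneity tests, each with a one-line rationale and,
where relevant, a caution.  Band thresholds are deliberately coarse:
``n < 30`` counts as "small", an anticipated max/min variance ratio of at
most 2 counts as "small".
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import DegenerateDataError, ValidationError
from .multi_sample import (
    bartlett_test,
    cochran_c_test,
    fligner_killeen_test,
    hartley_test,
    levene_test,
    one_way_anova,
    welch_anova,
)
from .samples import GroupedSample, TestResult
from .two_sample import ansari_bradley_test, f_test, jackknife_test, welch_t_test

__all__ = [
    "RecommendationQuery",
    "Recommendation",
    "recommend",
    "battery",
    "BatteryReport",
    "SMALL_N_THRESHOLD",
    "SMALL_RATIO_THRESHOLD",
]

SMALL_N_THRESHOLD = 30
SMALL_RATIO_THRESHOLD = 2.0

_K_BANDS = ("2", "3+")
_DISTS = ("normal", "heavy_tailed", "skewed")
_SIZES = ("small", "large")
_RATIOS = ("small", "large")


@dataclass(frozen=True)
class RecommendationQuery:
    """Coarse description of a planned variance comparison."""

    k_groups: str  # '2' or '3+'
    distribution: str  # 'normal', 'heavy_tailed', 'skewed'
    sample_size: str  # 'small' (< ~30 per group) or 'large'
    variance_ratio: str  # 'small' (<= ~2) or 'large'

    def __post_init__(self) -> None:
        checks = [
            (self.k_groups, _K_BANDS, "k_groups"),
            (self.distribution, _DISTS, "distribution"),
            (self.sample_size, _SIZES, "sample_size"),
            (self.variance_ratio, _RATIOS, "variance_ratio"),
        ]
        for value, allowed, name in checks:
            if value not in allowed:
                raise ValidationError(f"{name} must be one of {allowed}, got {value!r}")

    @classmethod
    def from_values(
        cls, k: int, distribution: str, n: int, ratio: float
    ) -> "RecommendationQuery":
        """Build a query from raw numbers (group count, per-group n, ratio)."""
        return cls(
            k_groups="2" if k == 2 else "3+",
            distribution=distribution,
            sample_size="small" if n < SMALL_N_THRESHOLD else "large",
            variance_ratio="small" if ratio <= SMALL_RATIO_THRESHOLD else "large",
        )


@dataclass(frozen=True)
class Recommendation:
    """One ranked test suggestion."""

    test: str
    rationale: str
    caution: str | None = None


_JACK_SMALL_N_CAUTION = (
    "jackknife type-I error runs high (around 0.08) at small n with heavy "
    "tails; prefer the exact-t reference"
)
_LEVENE_SMALL_N_CAUTION = (
    "Levene-family error rates are inflated at small sample sizes"
)

# Fully enumerated rule table: (k_band, distribution, size_band, ratio_band)
# -> ranked recommendations.  Rationales summarise the package's own
# simulation grids (power under the alternative, size under the null).
_RULES: dict[tuple[str, str, str, str], tuple[Recommendation, ...]] = {
    # ---- two groups, normal -------------------------------------------
    ("2", "normal", "large", "large"): (
        Recommendation("f", "most powerful for normal data at large n"),
        Recommendation("bartlett", "near-F power with a simple chi-square reference"),
        Recommendation("jackknife_normal", "non-parametric yet competitive on normal data"),
    ),
    ("2", "normal", "large", "small"): (
        Recommendation("f", "F, Bartlett and jackknife dominate as the ratio shrinks"),
        Recommendation("bartlett", "close second to the F test for small ratios"),
        Recommendation("jackknife_normal", "retains power for small variance ratios"),
    ),
    ("2", "normal", "small", "large"): (
        Recommendation("f", "large ratios are detected even at small n"),
        Recommendation("bartlett", "comparable power to the F test"),
        Recommendation("jackknife_exact", "exact-t reference behaves better at small n",
                       caution=_JACK_SMALL_N_CAUTION),
    ),
    ("2", "normal", "small", "small"): (
        Recommendation("f", "still the reference test for normal data"),
        Recommendation("levene_mean", "comparably powerful at small n and small ratios",
                       caution=_LEVENE_SMALL_N_CAUTION),
        Recommendation("bartlett", "parametric alternative with similar power"),
        Recommendation("jackknife_exact", "competitive, but size is inflated at small n",
                       caution=_JACK_SMALL_N_CAUTION),
    ),
    # ---- two groups, heavy-tailed -------------------------------------
    ("2", "heavy_tailed", "large", "large"): (
        Recommendation("jackknife_normal", "best power across heavy-tailed grids"),
        Recommendation("levene_mean", "valid under approximate normality of deviations"),
        Recommendation("levene_trimmed", "trims the heavy tails before centering"),
    ),
    ("2", "heavy_tailed", "large", "small"): (
        Recommendation("jackknife_normal", "best power for small ratios under heavy tails"),
        Recommendation("levene_mean", "robust runner-up"),
        Recommendation("ansari", "rank-based option when medians are equal"),
    ),
    ("2", "heavy_tailed", "small", "large"): (
        Recommendation("jackknife_exact", "exact-t jackknife beats the normal version at small n",
                       caution=_JACK_SMALL_N_CAUTION),
        Recommendation("levene_trimmed", "robust to extreme observations"),
        Recommendation("levene_mean", "simple robust fallback"),
    ),
    ("2", "heavy_tailed", "small", "small"): (
        Recommendation("levene_mean", "keeps its size where the jackknife inflates"),
        Recommendation("jackknife_exact", "most powerful but with inflated type-I error here",
                       caution=_JACK_SMALL_N_CAUTION),
        Recommendation("ansari", "conservative rank-based choice"),
    ),
    # ---- two groups, skewed -------------------------------------------
    ("2", "skewed", "large", "large"): (
        Recommendation("levene_trimmed", "highest rejection rates at large ratio and n"),
        Recommendation("jackknife_normal", "strong second on skewed data"),
        Recommendation("levene_median", "robust but dominated by the trimmed version"),
    ),
    ("2", "skewed", "large", "small"): (
        Recommendation("jackknife_normal", "most powerful when the ratio is small"),
        Recommendation("ansari_adjusted", "performs well at small ratios once medians are aligned",
                       caution="median alignment is not strictly distribution-free"),
        Recommendation("levene_trimmed", "robust alternative"),
    ),
    ("2", "skewed", "small", "large"): (
        Recommendation("jackknife_exact", "most powerful at small n on skewed data",
                       caution=_JACK_SMALL_N_CAUTION),
        Recommendation("levene_trimmed", "robust, keeps reasonable power"),
    ),
    ("2", "skewed", "small", "small"): (
        Recommendation("jackknife_exact", "best of a weak field: small skewed samples are hard",
                       caution=_JACK_SMALL_N_CAUTION),
        Recommendation("ansari_adjusted", "usable at small ratios after median alignment",
                       caution="median alignment is not strictly distribution-free"),
        Recommendation("levene_median", "conservative default with controlled size"),
    ),
    # ---- three or more groups, normal ---------------------------------
    ("3+", "normal", "large", "large"): (
        Recommendation("cochran", "most powerful when one variance is inflated",
                       caution="tests one outlying variance, not global homogeneity"),
        Recommendation("bartlett", "best global test for normal groups"),
        Recommendation("hartley", "simple max/min ratio, competitive at large n"),
    ),
    ("3+", "normal", "large", "small"): (
        Recommendation("cochran", "retains an edge for small ratios",
                       caution="tests one outlying variance, not global homogeneity"),
        Recommendation("bartlett", "preferred global test"),
        Recommendation("levene_mean", "robust global alternative"),
    ),
    ("3+", "normal", "small", "large"): (
        Recommendation("cochran", "highest rejection rate at small n",
                       caution="tests one outlying variance, not global homogeneity"),
        Recommendation("levene_mean", "joins Cochran as the best small-n choice",
                       caution=_LEVENE_SMALL_N_CAUTION),
        Recommendation("bartlett", "still usable; Hartley loses its advantage here"),
    ),
    ("3+", "normal", "small", "small"): (
        Recommendation("cochran", "best power in the hardest normal cell",
                       caution="tests one outlying variance, not global homogeneity"),
        Recommendation("levene_mean", "comparable power at small n and ratio",
                       caution=_LEVENE_SMALL_N_CAUTION),
        Recommendation("bartlett", "parametric fallback"),
    ),
    # ---- three or more groups, heavy-tailed ---------------------------
    ("3+", "heavy_tailed", "large", "large"): (
        Recommendation("levene_mean", "best test across the heavy-tailed multi-sample grids"),
        Recommendation("levene_trimmed", "use when tail contamination is a concern"),
    ),
    ("3+", "heavy_tailed", "large", "small"): (
        Recommendation("levene_mean", "best power for small differences"),
        Recommendation("levene_rank", "rank variant detects small ratios well under heavy tails"),
        Recommendation("levene_trimmed", "robust alternative"),
    ),
    ("3+", "heavy_tailed", "small", "large"): (
        Recommendation("levene_mean", "retains the most power at small n",
                       caution=_LEVENE_SMALL_N_CAUTION),
        Recommendation("levene_trimmed", "robust to extreme tails"),
    ),
    ("3+", "heavy_tailed", "small", "small"): (
        Recommendation("levene_mean", "best available, though power is low here",
                       caution=_LEVENE_SMALL_N_CAUTION),
        Recommendation("levene_rank", "good at small ratios"),
        Recommendation("levene_median", "smallest type-I error under heavy tails"),
    ),
    # ---- three or more groups, skewed ---------------------------------
    ("3+", "skewed", "large", "large"): (
        Recommendation("levene_trimmed", "most effective throughout the skewed multi-sample grids"),
        Recommendation("levene_median", "robust with well-controlled size"),
    ),
    ("3+", "skewed", "large", "small"): (
        Recommendation("levene_trimmed", "still first choice"),
        Recommendation("fligner", "performs well for small variance ratios on skewed data"),
        Recommendation("levene_median", "smallest error rates on skewed data"),
    ),
    ("3+", "skewed", "small", "large"): (
        Recommendation("levene_trimmed", "most effective at small n too",
                       caution=_LEVENE_SMALL_N_CAUTION),
        Recommendation("levene_median", "conservative companion"),
    ),
    ("3+", "skewed", "small", "small"): (
        Recommendation("levene_trimmed", "best of the usable tests"),
        Recommendation("fligner", "sensitive to small ratios"),
        Recommendation("levene_median", "keeps the smallest error rates"),
    ),
}

_FALLBACK = (
    Recommendation(
        "levene_median",
        "conservative default: median-centered Levene keeps its size across "
        "all simulated families",
    ),
)


def recommend(query: RecommendationQuery) -> tuple[Recommendation, ...]:
    """Ranked test recommendations for a scenario description."""
    key = (query.k_groups, query.distribution, query.sample_size, query.variance_ratio)
    return _RULES.get(key, _FALLBACK)


def all_rule_cells() -> tuple[tuple[str, str, str, str], ...]:
    """Every (k, distribution, size, ratio) cell the rule table must cover."""
    return tuple(
        (k, d, s, r) for k in _K_BANDS for d in _DISTS for s in _SIZES for r in _RATIOS
    )


# ---------------------------------------------------------------------------
# Battery: run everything applicable, then the matching location test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BatteryReport:
    """All applicable homogeneity tests on one dataset, plus location tests."""

    results: tuple[TestResult, ...]
    not_applicable: tuple[tuple[str, str], ...]  # (test, reason)
    alpha: float
    any_reject: bool
    location: tuple[TestResult, ...] = ()

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "any_reject": self.any_reject,
            "results": [r.to_dict() for r in self.results],
            "not_applicable": [
                {"method": m, "reason": why} for m, why in self.not_applicable
            ],
            "location": [r.to_dict() for r in self.location],
            "note": "p-values are reported raw, without multiplicity correction",
        }

    def render(self) -> str:
        lines = [f"Homogeneity-of-variance battery (alpha = {self.alpha:g})", ""]
        lines.append(f"{'method':<45} {'statistic':>12} {'p-value':>10} conclusion")
        for r in self.results:
            p = "n/a" if r.p_value is None else f"{r.p_value:.4f}"
            if r.reject_at is not None:
                rej = r.reject_at[1]
            else:
                rej = r.p_value is not None and r.p_value < self.alpha
            concl = "variances differ" if rej else "cannot reject equal variances"
            lines.append(f"{r.method:<45} {r.statistic:>12.4f} {p:>10} {concl}")
        for method, reason in self.not_applicable:
            lines.append(f"{method:<45} {'-':>12} {'-':>10} not applicable ({reason})")
        if self.location:
            lines.append("")
            lines.append("Location tests (equal-variance vs heteroscedasticity-robust):")
            for r in self.location:
                lines.append(f"  {r.method}: statistic={r.statistic:.4f}, p={r.p_value:.4f}")
            if self.any_reject:
                lines.append(
                    "  A homogeneity test rejected: prefer the Welch-based result."
                )
        lines.append("")
        lines.append("Note: raw p-values; no multiplicity correction applied.")
        return "\n".join(lines)


def battery(sample: GroupedSample, alpha: float = 0.05) -> BatteryReport:
    """Run every applicable homogeneity test, then the location contrast.

    A test that fails on this dataset (degenerate input, unbalanced design
    for Cochran/Hartley's exact reference, ...) is reported as "not
    applicable" rather than aborting the battery.  When any homogeneity
    test rejects at ``alpha``, the report pairs the equal-variance location
    test (pooled t / one-way ANOVA) with its Welch counterpart so the
    sensitivity of the downstream inference is visible.
    """
    runners: list[tuple[str, object]] = [
        ("Levene (mean)", lambda: levene_test(sample, center="mean")),
        ("Brown-Forsythe (median)", lambda: levene_test(sample, center="median")),
        ("Levene (trimmed mean)", lambda: levene_test(sample, center="trimmed")),
        ("Levene (rank)", lambda: levene_test(sample, center="rank")),
        ("Bartlett", lambda: bartlett_test(sample)),
        ("Fligner-Killeen", lambda: fligner_killeen_test(sample)),
        ("Hartley Fmax", lambda: hartley_test(sample, alpha=alpha)),
        ("Cochran C", lambda: cochran_c_test(sample, alpha=alpha)),
    ]
    if sample.k == 2:
        x, y = sample.groups
        runners = [
            ("F test", lambda: f_test(x, y)),
            ("Ansari-Bradley", lambda: ansari_bradley_test(x, y)),
            ("Ansari-Bradley (median-aligned)",
             lambda: ansari_bradley_test(x, y, align_medians=True)),
            ("Jackknife", lambda: jackknife_test(x, y)),
        ] + runners
    results: list[TestResult] = []
    skipped: list[tuple[str, str]] = []
    for name, run in runners:
        try:
            results.append(run())
        except (DegenerateDataError, ValidationError) as exc:
            skipped.append((name, str(exc)))
    any_reject = any(
        (r.reject_at[1] if r.reject_at is not None else (r.p_value is not None and r.p_value < alpha))
        for r in results
    )
    location: list[TestResult] = []
    try:
        if sample.k == 2:
            x, y = sample.groups
            location.append(welch_t_test(x, y, assume_equal_variance=True))
            location.append(welch_t_test(x, y, assume_equal_variance=False))
        else:
            location.append(one_way_anova(sample))
            location.append(welch_anova(sample))
    except (DegenerateDataError, ValidationError):
        pass
    return BatteryReport(
        results=tuple(results),
        not_applicable=tuple(skipped),
        alpha=alpha,
        any_reject=any_reject,
        location=tuple(location),
    )
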