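"""Grouped observations, long-format table I/O and result containers.

The data model mirrors the usual clinical-trial layout: ``k`` treatment
groups, group ``i`` holding ``n_i`` numeric responses ``Y_ij``, with
``N = sum(n_i)`` subjects in total.  Every variance in the package uses the
unbiased ``n - 1`` denominator.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

logger = logging.getLogger("homovar")

__all__ = [
    "GroupedSample",
    "GroupSummary",
    "TestResult",
    "read_grouped_table",
    "summarize",
    "results_frame",
    "write_results",
]


@dataclass(frozen=True)
class GroupedSample:
    """``k`` labelled groups of numeric observations.

    Parameters
    ----------
    labels : tuple of str
        Group labels in first-appearance order.
    groups : tuple of ndarray
        One 1-d float array per label; every group needs at least two
        values so a sample variance exists.
    """

    labels: tuple[str, ...]
    groups: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.groups):
            raise ValidationError("labels and groups must have equal length")
        if len(self.groups) < 2:
            raise ValidationError("need at least 2 groups (k >= 2)")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("group labels must be unique")
        clean = []
        for label, values in zip(self.labels, self.groups):
            arr = np.asarray(values, dtype=float).ravel()
            if arr.size < 2:
                raise ValidationError(
                    f"group {label!r} has {arr.size} value(s); at least 2 are "
                    "required for a sample variance"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"group {label!r} contains non-finite values")
            clean.append(arr)
        object.__setattr__(self, "groups", tuple(clean))
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))

    # -- basic structure -------------------------------------------------
    @property
    def k(self) -> int:
        """Number of groups."""
        return len(self.groups)

    @property
    def sizes(self) -> tuple[int, ...]:
        """Per-group sizes ``n_i``."""
        return tuple(int(g.size) for g in self.groups)

    @property
    def total_n(self) -> int:
        """Total number of observations ``N``."""
        return int(sum(self.sizes))

    @property
    def is_balanced(self) -> bool:
        return len(set(self.sizes)) == 1

    def group(self, label: str) -> np.ndarray:
        try:
            return self.groups[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no group labelled {label!r}") from None

    def __iter__(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(zip(self.labels, self.groups))

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        groups: Sequence[Iterable[float]],
        labels: Sequence[str] | None = None,
    ) -> "GroupedSample":
        if labels is None:
            labels = [f"g{i + 1}" for i in range(len(groups))]
        return cls(tuple(labels), tuple(np.asarray(g, dtype=float) for g in groups))

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, value_col: str, group_col: str
    ) -> "GroupedSample":
        """Build from a long-format table; see :func:`read_grouped_table`."""
        for col in (value_col, group_col):
            if col not in frame.columns:
                raise ConfigurationError(f"column {col!r} not found in table")
        values = pd.to_numeric(frame[value_col], errors="coerce")
        labels_col = frame[group_col]
        keep = values.notna() & labels_col.notna()
        dropped = int((~keep).sum())
        if dropped:
            logger.warning(
                "dropped %d row(s) with missing value or group label", dropped
            )
        values = values[keep].to_numpy(dtype=float)
        labels_col = labels_col[keep].astype(str).to_numpy()
        order = pd.unique(labels_col)  # first-appearance order
        groups = tuple(values[labels_col == lab] for lab in order)
        for lab, g in zip(order, groups):
            if g.size < 2:
                raise ValidationError(
                    f"group {lab!r} has only {g.size} usable value(s); "
                    "at least 2 are required"
                )
        return cls(tuple(order), groups)

    # -- export ----------------------------------------------------------
    def to_frame(
        self, value_col: str = "value", group_col: str = "group"
    ) -> pd.DataFrame:
        recs = [
            {group_col: lab, value_col: float(v)}
            for lab, g in self
            for v in g
        ]
        return pd.DataFrame.from_records(recs, columns=[group_col, value_col])

    def to_csv(
        self,
        path: str | Path,
        value_col: str = "value",
        group_col: str = "group",
        sep: str = ",",
    ) -> None:
        # %.17g round-trips IEEE doubles exactly
        self.to_frame(value_col, group_col).to_csv(
            path, index=False, sep=sep, float_format="%.17g"
        )


@dataclass(frozen=True)
class GroupSummary:
    """Per-group and pooled moments of a :class:`GroupedSample`."""

    labels: tuple[str, ...]
    means: tuple[float, ...]
    variances: tuple[float, ...]
    medians: tuple[float, ...]
    grand_mean: float
    pooled_variance: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.variances):
            raise ValidationError("sample variances cannot be negative")


def summarize(sample: GroupedSample) -> GroupSummary:
    """Group means/variances/medians plus the grand mean and pooled variance.

    The pooled variance is ``s_p^2 = sum((n_i - 1) s_i^2) / (N - k)``, the
    (n_i - 1)-weighted average of the group variances, so it always lies
    between the smallest and largest group variance.
    """
    means = tuple(float(g.mean()) for g in sample.groups)
    variances = tuple(float(g.var(ddof=1)) for g in sample.groups)
    medians = tuple(float(np.median(g)) for g in sample.groups)
    N, k = sample.total_n, sample.k
    grand_mean = float(np.concatenate(sample.groups).mean())
    pooled = float(
        sum((n - 1) * v for n, v in zip(sample.sizes, variances)) / (N - k)
    )
    return GroupSummary(sample.labels, means, variances, medians, grand_mean, pooled)


def read_grouped_table(
    path: str | Path,
    value_col: str = "value",
    group_col: str = "group",
    sep: str | None = None,
) -> GroupedSample:
    """Read a long-format CSV/TSV table into a :class:`GroupedSample`.

    One row per observation, with a group-label column and a numeric
    response column.  Rows with a missing value or label are dropped (and
    counted via logging); values are never imputed.  ``sep=None`` infers
    the delimiter from the file extension (``.tsv``/``.txt`` -> tab).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return GroupedSample.from_frame(frame, value_col=value_col, group_col=group_col)


_ALTERNATIVES = ("two-sided", "less", "greater")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one homogeneity (or location) test.

    ``reference`` is a human-readable description of the null distribution
    ("F(2, 20)", "chi-square(2)", "exact W", "critical-value comparison").
    ``p_value`` may be ``None`` for critical-value-only tests (Hartley,
    Cochran), in which case ``reject_at`` carries the decision.
    """

    method: str
    statistic: float
    reference: str
    df: tuple[float, ...] = ()
    p_value: float | None = None
    alternative: str = "two-sided"
    reject_at: tuple[float, bool] | None = None
    extras: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alternative not in _ALTERNATIVES:
            raise ValidationError(f"alternative must be one of {_ALTERNATIVES}")
        if self.p_value is not None and not (
            0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)
        ):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")
        if any(d <= 0 for d in self.df):
            raise ValidationError("degrees of freedom must be positive")

    @property
    def rejected(self) -> bool | None:
        return None if self.reject_at is None else self.reject_at[1]

    def to_dict(self) -> dict:
        out: dict[str, object] = {
            "method": self.method,
            "statistic": self.statistic,
            "reference": self.reference,
            "df": list(self.df),
            "p_value": self.p_value,
            "alternative": self.alternative,
        }
        if self.reject_at is not None:
            out["alpha"] = self.reject_at[0]
            out["reject"] = self.reject_at[1]
        if self.extras:
            out["extras"] = {k: _jsonable(v) for k, v in self.extras.items()}
        return out

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        p = "n/a" if self.p_value is None else f"{self.p_value:.4g}"
        return (
            f"{self.method}: statistic={self.statistic:.6g}, "
            f"reference={self.reference}, p={p} ({self.alternative})"
        )


def _jsonable(v: object) -> object:
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v


def results_frame(results: Iterable[TestResult]) -> pd.DataFrame:
    """Tabulate test results (one row per test)."""
    rows = []
    for r in results:
        rows.append(
            {
                "method": r.method,
                "statistic": r.statistic,
                "reference": r.reference,
                "df": "/".join(f"{d:g}" for d in r.df),
                "p_value": r.p_value,
                "alternative": r.alternative,
            }
        )
    return pd.DataFrame(rows)


def write_results(
    results: Iterable[TestResult], path: str | Path, fmt: str | None = None
) -> None:
    """Write test results as CSV or JSON records (format from extension)."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    results = list(results)
    if fmt == "json":
        path.write_text(json.dumps([r.to_dict() for r in results], indent=2))
    elif fmt == "csv":
        results_frame(results).to_csv(path, index=False)
    else:
        raise ConfigurationError(f"unknown output format {fmt!r}")
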