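"""Seeded generators for the simulation-study population families.

Three families are supported, chosen to probe the variance tests under
normality, heavy tails and skewness:

* ``normal(mean, variance)`` — note the second parameter is a *variance*;
* ``t(df)`` — Student t, heavy-tailed, finite variance ``df / (df - 2)``
  only for ``df > 2``;
* ``skew_normal(xi, omega, shape)`` — the three-parameter skew-normal with
  location xi, scale omega and shape alpha, whose variance is
  ``omega^2 (1 - 2 alpha^2 / ((1 + alpha^2) pi))``.

Scenario builders set group scales so that *true variances* hit the
requested ratios exactly (for the skew-normal this inverts the variance
formula in ``omega``), and a counter-based seed-splitting scheme makes any
single replicate and group reproducible in isolation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import skewnorm

from .exceptions import ConfigurationError, ValidationError
from .samples import GroupedSample

__all__ = [
    "PopulationSpec",
    "Scenario",
    "true_variance",
    "omega_for_variance",
    "draw",
    "make_scenario_groups",
    "normal_scenario",
    "t_scenario",
    "skew_normal_scenario",
    "scenario_from_dict",
]

_FAMILIES = ("normal", "t", "skew_normal")


@dataclass(frozen=True)
class PopulationSpec:
    """One group's population: a family plus its parameters.

    Only the fields relevant to ``family`` are read: ``mean``/``variance``
    for the normal, ``df`` for the t (location fixed at 0), and
    ``xi``/``omega``/``shape`` for the skew-normal.
    """

    family: str
    mean: float = 0.0
    variance: float = 1.0
    df: float = 3.0
    xi: float = 0.0
    omega: float = 1.0
    shape: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(f"family must be one of {_FAMILIES}")
        if self.family == "normal" and self.variance <= 0:
            raise ValidationError("normal variance must be positive")
        if self.family == "t" and self.df <= 2:
            raise ValidationError(
                "t family requires df > 2 for a finite variance"
            )
        if self.family == "skew_normal" and self.omega <= 0:
            raise ValidationError("skew-normal scale omega must be positive")

    @classmethod
    def normal(cls, mean: float = 0.0, variance: float = 1.0) -> "PopulationSpec":
        return cls("normal", mean=mean, variance=variance)

    @classmethod
    def t(cls, df: float) -> "PopulationSpec":
        return cls("t", df=df)

    @classmethod
    def skew_normal(
        cls, xi: float = 0.0, omega: float = 1.0, shape: float = 0.0
    ) -> "PopulationSpec":
        return cls("skew_normal", xi=xi, omega=omega, shape=shape)


def true_variance(spec: PopulationSpec) -> float:
    """Closed-form population variance of a :class:`PopulationSpec`."""
    if spec.family == "normal":
        return float(spec.variance)
    if spec.family == "t":
        return float(spec.df / (spec.df - 2.0))
    a2 = spec.shape**2
    return float(spec.omega**2 * (1.0 - 2.0 * a2 / ((1.0 + a2) * math.pi)))


def omega_for_variance(target_variance: float, shape: float) -> float:
    """Skew-normal scale whose variance equals ``target_variance``.

    Inverts ``var = omega^2 (1 - 2 delta^2 / pi)`` with
    ``delta = shape / sqrt(1 + shape^2)``; exact up to round-off, so scenario
    variance ratios are hit exactly.
    """
    if target_variance <= 0:
        raise ValidationError("target variance must be positive")
    delta2 = shape**2 / (1.0 + shape**2)
    return float(math.sqrt(target_variance / (1.0 - 2.0 * delta2 / math.pi)))


def draw(
    spec: PopulationSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """``n`` reproducible draws from the population described by ``spec``."""
    if n < 1:
        raise ValidationError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.family == "normal":
        return rng.normal(spec.mean, math.sqrt(spec.variance), size=n)
    if spec.family == "t":
        return rng.standard_t(spec.df, size=n)
    return skewnorm.rvs(
        spec.shape, loc=spec.xi, scale=spec.omega, size=n, random_state=rng
    )


@dataclass(frozen=True)
class Scenario:
    """One simulation cell: populations, group size, replication and seed."""

    specs: tuple[PopulationSpec, ...]
    n: int
    reps: int = 2000
    alpha: float = 0.05
    seed: int = 0
    scenario_id: str = ""
    truth: str = "alternative"  # 'null' or 'alternative'

    def __post_init__(self) -> None:
        if len(self.specs) < 2:
            raise ValidationError("a scenario needs at least 2 groups")
        if self.n < 2:
            raise ValidationError("group size n must be at least 2")
        if self.reps < 1:
            raise ValidationError("reps must be at least 1")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.truth not in ("null", "alternative"):
            raise ValidationError("truth must be 'null' or 'alternative'")
        variances = [true_variance(s) for s in self.specs]
        if self.truth == "null" and not np.allclose(variances, variances[0]):
            raise ValidationError(
                "truth='null' requires equal true variances across groups"
            )

    @property
    def k(self) -> int:
        return len(self.specs)

    @property
    def family(self) -> str:
        fams = {s.family for s in self.specs}
        return fams.pop() if len(fams) == 1 else "mixed"

    @property
    def true_variances(self) -> tuple[float, ...]:
        return tuple(true_variance(s) for s in self.specs)


def make_scenario_groups(
    scenario: Scenario, rep: int = 0, seed: int | None = None
) -> GroupedSample:
    """Materialise one replicate of a scenario as a :class:`GroupedSample`.

    Group ``g`` of replicate ``rep`` draws from an independent stream keyed
    by ``(seed, rep, g)`` via ``numpy.random.SeedSequence`` spawn keys, so
    individual replicates are reproducible without re-running the study.
    """
    base = scenario.seed if seed is None else seed
    groups = []
    for g, spec in enumerate(scenario.specs):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=base, spawn_key=(rep, g))
        )
        groups.append(draw(spec, scenario.n, rng))
    return GroupedSample.from_arrays(groups)


# ---------------------------------------------------------------------------
# Scenario builders for the study's three families
# ---------------------------------------------------------------------------

def normal_scenario(
    variances: tuple[float, ...],
    n: int,
    mean: float = 0.0,
    **kwargs,
) -> Scenario:
    """Normal groups sharing one mean, variances given directly.

    ``variances=(1, 1.5)`` is the canonical two-sample 1:1.5 cell;
    ``(1, 1, 4)`` a three-sample 1:1:4 cell.
    """
    specs = tuple(PopulationSpec.normal(mean, v) for v in variances)
    sid = kwargs.pop("scenario_id", "normal-" + ":".join(f"{v:g}" for v in variances))
    return Scenario(specs=specs, n=n, scenario_id=sid, **kwargs)


def t_scenario(dfs: tuple[float, ...], n: int, **kwargs) -> Scenario:
    """Student-t groups (location 0) with given degrees of freedom.

    Variances follow as ``df / (df - 2)``: dfs ``(3, 12)`` give the 5:2
    variance ratio, ``(3, 6)`` 2:1, ``(3, 4)`` 3:2; triples such as
    ``(3, 4, 4)`` give 3:2:2.
    """
    specs = tuple(PopulationSpec.t(df) for df in dfs)
    sid = kwargs.pop("scenario_id", "t-" + ":".join(f"{d:g}" for d in dfs))
    return Scenario(specs=specs, n=n, scenario_id=sid, **kwargs)


def skew_normal_scenario(
    variances: tuple[float, ...],
    shape: float,
    n: int,
    xi: float = 0.0,
    ratio_on: str = "variance",
    mean_corrected: bool = False,
    **kwargs,
) -> Scenario:
    """Skew-normal groups sharing xi and shape, differing in omega only.

    ``ratio_on='variance'`` (default) inverts the variance formula so the
    *true variances* equal ``variances`` exactly; ``'omega2'`` instead
    takes the entries as omega^2.  Because the skew-normal mean is
    ``xi + omega * delta * sqrt(2/pi)``, varying omega alone also shifts
    the group means; ``mean_corrected=True`` re-centers each xi so all
    group means coincide (off by default, matching the plain
    vary-omega-only design).
    """
    if ratio_on not in ("variance", "omega2"):
        raise ValidationError("ratio_on must be 'variance' or 'omega2'")
    if ratio_on == "variance":
        omegas = [omega_for_variance(v, shape) for v in variances]
    else:
        omegas = [math.sqrt(v) for v in variances]
    specs = []
    delta = shape / math.sqrt(1.0 + shape**2)
    for om in omegas:
        xi_g = xi - om * delta * math.sqrt(2.0 / math.pi) if mean_corrected else xi
        specs.append(PopulationSpec.skew_normal(xi=xi_g, omega=om, shape=shape))
    sid = kwargs.pop(
        "scenario_id",
        f"skew{shape:g}-" + ":".join(f"{v:g}" for v in variances),
    )
    return Scenario(specs=tuple(specs), n=n, scenario_id=sid, **kwargs)


def scenario_from_dict(cfg: dict) -> Scenario:
    """Build a scenario from a configuration mapping (YAML-friendly).

    Keys: ``family`` plus the family's shorthand — ``variances`` (normal,
    skew_normal), ``dfs`` (t), ``shape`` (skew_normal) — and the common
    ``n``, ``reps``, ``alpha``, ``seed``, ``truth``, ``scenario_id``.
    """
    cfg = dict(cfg)
    family = cfg.pop("family", None)
    if family not in _FAMILIES:
        raise ConfigurationError(f"scenario family must be one of {_FAMILIES}")
    common = {
        key: cfg.pop(key)
        for key in ("n", "reps", "alpha", "seed", "truth", "scenario_id")
        if key in cfg
    }
    if "n" not in common:
        raise ConfigurationError("scenario config requires 'n'")
    try:
        if family == "normal":
            return normal_scenario(
                tuple(cfg.pop("variances")), mean=cfg.pop("mean", 0.0), **common
            )
        if family == "t":
            return t_scenario(tuple(cfg.pop("dfs")), **common)
        return skew_normal_scenario(
            tuple(cfg.pop("variances")),
            shape=cfg.pop("shape"),
            xi=cfg.pop("xi", 0.0),
            ratio_on=cfg.pop("ratio_on", "variance"),
            mean_corrected=cfg.pop("mean_corrected", False),
            **common,
        )
    except KeyError as exc:
        raise ConfigurationError(f"scenario config missing key: {exc}") from exc
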