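"""Domain types for dietary comparative risk assessment.

Comparative risk assessment (CRA) attributes part of a population's disease
burden to a risk factor by contrasting the observed exposure distribution
with a counterfactual in which everyone is at the theoretical minimum risk
exposure level (TMREL).  The types here carry the four ingredients of that
calculation: the exposure distribution ``P(x)`` for one population stratum,
the relative-risk curve ``RR(x)`` for one diet-disease pair (direct, or
composed through a mediator such as systolic blood pressure), the TMREL with
its conventional +/-20% uncertainty band, and the cause-specific burden
envelope the attributable fraction is applied to.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats


class Direction(str, enum.Enum):
    """Which side of the optimum carries risk.

    ``harmful_low``: a diet *low* in the item is harmful (fruits, fibre...);
    risk accrues below the TMREL.  ``harmful_high``: a diet *high* in the
    item is harmful (sodium, red meat...); risk accrues above the TMREL.
    """

    harmful_low = "harmful_low"
    harmful_high = "harmful_high"


#: Recognised mediators for two-stage (indirect) relative risks.
MEDIATORS = ("sbp", "bmi")

#: Burden metrics an envelope may carry.
METRICS = ("deaths", "dalys", "ylls", "ylds")

DISTRIBUTION_FAMILIES = ("lognormal", "gamma", "truncated_normal")


class ValidationError(ValueError):
    """Raised when an input table or config violates its contract."""


@dataclass(frozen=True)
class RiskFactor:
    """One dietary risk factor (e.g. "diet low in fruits").

    ``mediator`` is set for risks whose effect on outcomes is modelled
    through an intermediate factor: sodium via systolic blood pressure
    ("sbp"), sugar-sweetened beverages via body-mass index ("bmi").
    """

    name: str
    direction: Direction
    exposure_unit: str = "g/day"
    mediator: str | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction(self.direction))
        if self.mediator is not None and self.mediator not in MEDIATORS:
            raise ValidationError(
                f"unknown mediator {self.mediator!r} for risk {self.name!r}; "
                f"expected one of {MEDIATORS}"
            )

    @property
    def mediated(self) -> bool:
        return self.mediator is not None


def load_risk_registry(config: Mapping | str) -> list[RiskFactor]:
    """Build a risk registry from a config mapping or a YAML file path.

    The config holds a ``risks`` list of entries with keys ``name``,
    ``direction``, ``unit`` and optional ``mediator``/``category``.
    Duplicate names, unknown directions and unknown mediators are rejected.
    """
    if isinstance(config, (str,)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    entries = config.get("risks", []) if config else []
    risks: list[RiskFactor] = []
    seen: set[str] = set()
    for entry in entries:
        name = entry["name"]
        if name in seen:
            raise ValidationError(f"duplicate risk name {name!r} in registry config")
        seen.add(name)
        direction = entry.get("direction")
        try:
            direction = Direction(direction)
        except ValueError:
            raise ValidationError(
                f"unknown direction {direction!r} for risk {name!r}"
            ) from None
        risks.append(
            RiskFactor(
                name=name,
                direction=direction,
                exposure_unit=entry.get("unit", "g/day"),
                mediator=entry.get("mediator"),
                category=entry.get("category"),
            )
        )
    return risks


def registry_to_config(risks: Sequence[RiskFactor]) -> dict:
    """Inverse of :func:`load_risk_registry` (lossless round trip)."""
    out = []
    for r in risks:
        entry: dict = {"name": r.name, "direction": r.direction.value, "unit": r.exposure_unit}
        if r.mediator is not None:
            entry["mediator"] = r.mediator
        if r.category is not None:
            entry["category"] = r.category
        out.append(entry)
    return {"risks": out}


def default_risk_registry() -> list[RiskFactor]:
    """The 14 dietary risks of the GBD 2013 CRA, from the packaged config."""
    text = resources.files("dietcra.config").joinpath("risks_gbd2013.yaml").read_text()
    return load_risk_registry(yaml.safe_load(text))


@dataclass(frozen=True)
class AgeGroup:
    """Half-open age interval ``[lower, upper)`` in years."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValidationError(f"age group upper {self.upper} must exceed lower {self.lower}")

    @property
    def label(self) -> str:
        return f"{self.lower:g}-{self.upper:g}"

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


def validate_age_partition(groups: Sequence[AgeGroup]) -> None:
    """Check that age groups tile the modelled range with no gap/overlap."""
    ordered = sorted(groups, key=lambda g: g.lower)
    for a, b in zip(ordered, ordered[1:]):
        if not np.isclose(a.upper, b.lower):
            raise ValidationError(
                f"age groups do not partition the age range: [{a.lower},{a.upper}) "
                f"then [{b.lower},{b.upper})"
            )


@dataclass(frozen=True)
class Stratum:
    """One (location, age, sex, year) cell -- the a, s, t subscripts."""

    location: str
    age_group: AgeGroup
    sex: str
    year: int


class ExposureDistribution:
    """Parametric intake distribution ``P(x)`` for one stratum.

    Parameterised by its mean and sd on the natural exposure scale; the
    family (lognormal by default -- intakes are right-skewed) maps those
    moments onto its own parameters.  The distribution is truncated and
    renormalised to the integration support ``[l, u]``, by default the
    0.001 and 0.999 quantiles of the fitted distribution.

    ``sd == 0`` marks a degenerate point mass at ``mean`` (used for the
    no-excess-risk limiting case); the density methods are unavailable then.
    """

    def __init__(
        self,
        mean: float,
        sd: float,
        family: str = "lognormal",
        support: tuple[float, float] | None = None,
        stratum: Stratum | None = None,
        support_quantiles: tuple[float, float] = (0.001, 0.999),
    ) -> None:
        if family not in DISTRIBUTION_FAMILIES:
            raise ValidationError(f"unknown distribution family {family!r}")
        if not mean > 0:
            raise ValidationError(f"exposure mean must be positive, got {mean}")
        if sd < 0:
            raise ValidationError(f"exposure sd must be non-negative, got {sd}")
        self.mean = float(mean)
        self.sd = float(sd)
        self.family = family
        self.stratum = stratum
        if self.degenerate:
            self.support = (self.mean, self.mean) if support is None else tuple(support)
            self._base = None
            return
        self._base = _moment_matched(family, self.mean, self.sd)
        if support is None:
            q0, q1 = support_quantiles
            lo = float(self._base.ppf(q0))
            hi = float(self._base.ppf(q1))
            support = (max(lo, 0.0), hi)
        l, u = float(support[0]), float(support[1])
        if l < 0 or not u > l:
            raise ValidationError(f"invalid support [{l}, {u}]")
        self.support = (l, u)
        self._Fl = float(self._base.cdf(l))
        self._Fu = float(self._base.cdf(u))
        self._mass = self._Fu - self._Fl
        if not self._mass > 0:
            raise ValidationError("support interval carries no probability mass")

    @property
    def degenerate(self) -> bool:
        return self.sd == 0.0

    def _require_continuous(self) -> None:
        if self.degenerate:
            raise ValidationError("degenerate (point-mass) distribution has no density")

    def pdf(self, x):
        """Truncation-renormalised density on [l, u] (0 outside)."""
        self._require_continuous()
        x = np.asarray(x, dtype=float)
        l, u = self.support
        inside = (x >= l) & (x <= u)
        return np.where(inside, self._base.pdf(x) / self._mass, 0.0)

    def cdf(self, x):
        self._require_continuous()
        x = np.asarray(x, dtype=float)
        raw = (self._base.cdf(x) - self._Fl) / self._mass
        return np.clip(raw, 0.0, 1.0)

    def ppf(self, q):
        """Quantile function of the truncated distribution."""
        self._require_continuous()
        q = np.asarray(q, dtype=float)
        return self._base.ppf(self._Fl + q * self._mass)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "mean": self.mean,
            "sd": self.sd,
            "support_lower": self.support[0],
            "support_upper": self.support[1],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExposureDistribution":
        return cls(
            mean=d["mean"],
            sd=d["sd"],
            family=d.get("family", "lognormal"),
            support=(d["support_lower"], d["support_upper"]),
        )


def _moment_matched(family: str, mean: float, sd: float):
    """Frozen scipy distribution with the requested mean/sd."""
    if family == "lognormal":
        sigma2 = np.log1p((sd / mean) ** 2)
        sigma = np.sqrt(sigma2)
        scale = mean * np.exp(-sigma2 / 2.0)
        return stats.lognorm(s=sigma, scale=scale)
    if family == "gamma":
        shape = (mean / sd) ** 2
        scale = sd * sd / mean
        return stats.gamma(a=shape, scale=scale)
    # truncated_normal: plain normal here; truncation to [l, u] (l clipped at
    # 0 by the support default) is applied by ExposureDistribution itself.
    return stats.norm(loc=mean, scale=sd)


@dataclass(frozen=True)
class RelativeRiskCurve:
    """Log-linear relative-risk curve for one diet-disease pair.

    ``RR(x) = exp(log_rr_per_unit * excess(x))`` where the excess is the
    signed distance from the reference level toward the harmful side
    (above it for harmful_high risks, below it for harmful_low ones).
    With ``cap_at_tmrel`` the excess is clamped at zero on the no-risk
    side, so the curve plateaus at RR = 1 beyond the TMREL.
    """

    risk: RiskFactor
    outcome: str
    log_rr_per_unit: float
    se: float = 0.0
    age_group: AgeGroup | None = None
    sex: str | None = None
    reference_level: float | None = None
    cap_at_tmrel: bool = True

    def excess(self, x, reference):
        """Signed exposure excess toward the harmful side, capped at 0."""
        x = np.asarray(x, dtype=float)
        if self.risk.direction is Direction.harmful_high:
            exc = x - reference
        else:
            exc = reference - x
        if self.cap_at_tmrel:
            exc = np.maximum(exc, 0.0)
        return exc

    def rr(self, x, reference=None):
        """Relative risk at exposure ``x`` given the reference (TMREL)."""
        ref = self.reference_level if reference is None else reference
        if ref is None:
            raise ValidationError("no reference level: pass the TMREL explicitly")
        return np.exp(self.log_rr_per_unit * self.excess(x, ref))


@dataclass(frozen=True)
class MediationChain:
    """Two-stage indirect effect: exposure -> mediator -> outcome.

    Stage one is the linear shift of the mediator per unit of exposure
    excess (e.g. mmHg systolic blood pressure per g/day of sodium); stage
    two is the relative-risk curve on the mediator scale.  The composed
    curve is log-linear in exposure with slope
    ``exposure_to_mediator_slope * mediator log-RR per unit``.
    """

    risk: RiskFactor
    mediator: str
    exposure_to_mediator_slope: float
    mediator_rr: RelativeRiskCurve
    slope_se: float = 0.0

    def __post_init__(self) -> None:
        if self.mediator not in MEDIATORS:
            raise ValidationError(f"unknown mediator {self.mediator!r}")

    @property
    def outcome(self) -> str:
        return self.mediator_rr.outcome

    def effective_log_rr_per_unit(self) -> float:
        return self.exposure_to_mediator_slope * self.mediator_rr.log_rr_per_unit

    def excess(self, x, reference):
        x = np.asarray(x, dtype=float)
        if self.risk.direction is Direction.harmful_high:
            exc = x - reference
        else:
            exc = reference - x
        if self.mediator_rr.cap_at_tmrel:
            exc = np.maximum(exc, 0.0)
        return exc

    def rr(self, x, reference):
        """Composed relative risk at exposure ``x``; equals 1 at the reference."""
        return np.exp(self.effective_log_rr_per_unit() * self.excess(x, reference))


@dataclass(frozen=True)
class Tmrel:
    """Theoretical minimum risk exposure level with uniform +/-20% band."""

    risk: RiskFactor
    optimal_mean: float

    def __post_init__(self) -> None:
        if not self.optimal_mean > 0:
            raise ValidationError("TMREL optimal mean must be positive")

    @property
    def lower(self) -> float:
        return 0.8 * self.optimal_mean

    @property
    def upper(self) -> float:
        return 1.2 * self.optimal_mean

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=n)


@dataclass(frozen=True)
class CauseBurden:
    """Burden envelope for one outcome/metric/stratum: count + population."""

    outcome: str
    metric: str
    stratum: Stratum
    count: float
    population: float

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValidationError(f"unknown burden metric {self.metric!r}")
        if self.count < 0:
            raise ValidationError(f"burden count must be non-negative, got {self.count}")
        if not self.population > 0:
            raise ValidationError(f"population must be positive, got {self.population}")


@dataclass
class DrawSet:
    """Ordered Monte Carlo realisations of one scalar quantity."""

    values: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("DrawSet values must be one-dimensional")

    @property
    def n_draws(self) -> int:
        return self.values.shape[0]

    def __len__(self) -> int:
        return self.n_draws


__all__ = [
    "AgeGroup",
    "CauseBurden",
    "Direction",
    "DrawSet",
    "ExposureDistribution",
    "MEDIATORS",
    "METRICS",
    "MediationChain",
    "RelativeRiskCurve",
    "RiskFactor",
    "Stratum",
    "Tmrel",
    "ValidationError",
    "default_risk_registry",
    "load_risk_registry",
    "registry_to_config",
    "validate_age_partition",
]
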