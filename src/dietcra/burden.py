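"""Attributable-burden accounting: counts, rates, shares, trends.

Applies population attributable fractions to cause-specific burden
envelopes and produces the reporting quantities: attributable counts
(summed over outcomes), crude and age-standardized rates per 100,000,
proportions of all-cause and NCD burden, and percentage change between
periods.  All arithmetic is unrounded internally; rounding to the
reporting precision (counts and rates to integers, percentages to one
decimal) happens only at format time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .risk_model import CauseBurden, Stratum, ValidationError
from .paf import PafEstimate


@dataclass(frozen=True)
class StandardPopulation:
    """Age weights for direct standardization; must sum to 1."""

    weights: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        w = dict(self.weights)
        if any(v < 0 for v in w.values()):
            raise ValidationError("standard population weights must be non-negative")
        if abs(sum(w.values()) - 1.0) > 1e-12:
            raise ValidationError("standard population weights must sum to 1")

    @classmethod
    def equal(cls, age_labels: Sequence[str]) -> "StandardPopulation":
        n = len(age_labels)
        return cls(tuple((a, 1.0 / n) for a in age_labels))

    def as_dict(self) -> dict[str, float]:
        return dict(self.weights)


@dataclass
class AttributableBurden:
    """Diet-attributable burden for one stratum and metric."""

    stratum: Stratum | None
    metric: str
    count: float
    population: float
    rate_per_100k: float = field(init=False)
    proportion_of_all_cause: float | None = None
    proportion_of_ncd: float | None = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValidationError("attributable count cannot be negative")
        self.rate_per_100k = rate_per_100k(self.count, self.population)


def attributable_burden(
    envelopes: Sequence[CauseBurden],
    pafs: Sequence[PafEstimate],
    metric: str | None = None,
) -> AttributableBurden:
    """Total attributable burden for one stratum: sum_o Burden_o * PAF_o.

    Envelope outcomes without a matching PAF contribute zero (with a
    warning) — absence of evidence for a diet-outcome link attributes
    nothing, it does not fail the accounting.
    """
    if not envelopes:
        raise ValidationError("no burden envelopes supplied")
    metrics = {e.metric for e in envelopes}
    if metric is None:
        if len(metrics) > 1:
            raise ValidationError(f"mixed metrics in envelopes: {sorted(metrics)}")
        metric = next(iter(metrics))
    paf_by_outcome = {p.outcome: p.point_value for p in pafs}
    total = 0.0
    for env in envelopes:
        paf = paf_by_outcome.get(env.outcome)
        if paf is None:
            warnings.warn(
                f"no PAF for outcome {env.outcome!r}; treating as 0", stacklevel=2
            )
            paf = 0.0
        total += env.count * paf
    population = envelopes[0].population
    return AttributableBurden(
        stratum=envelopes[0].stratum, metric=metric, count=total, population=population
    )


def rate_per_100k(count: float, population: float) -> float:
    """Crude rate per 100,000 population (or person-years)."""
    if not population > 0:
        raise ValidationError("population must be positive for a rate")
    return count / population * 100_000.0


def age_standardize(
    stratum_rates: Mapping[str, float], std: StandardPopulation
) -> float:
    """Directly age-standardized rate: sum_a weight_a * rate_a."""
    weights = std.as_dict()
    missing = [a for a in weights if a not in stratum_rates]
    if missing:
        raise ValidationError(f"missing age-specific rates for groups: {missing}")
    return float(sum(w * stratum_rates[a] for a, w in weights.items()))


def pct_change(v_start: float, v_end: float) -> float:
    """Percentage change between two periods, 100*(end-start)/start."""
    if v_start == 0:
        raise ValidationError("percentage change undefined for zero baseline")
    return 100.0 * (v_end - v_start) / v_start


def proportion(part: float, whole: float) -> float:
    """Share of a whole, in percent."""
    if not whole > 0:
        raise ValidationError("proportion denominator must be positive")
    if part < 0:
        raise ValidationError("proportion numerator must be non-negative")
    return 100.0 * part / whole


# --- report-precision formatting (Table-style rounding) --------------------

def fmt_count(x: float) -> str:
    return f"{x:,.0f}"


def fmt_rate(x: float) -> str:
    return f"{x:,.0f}"


def fmt_pct(x: float) -> str:
    return f"{x:.1f}%"


__all__ = [
    "AttributableBurden",
    "StandardPopulation",
    "age_standardize",
    "attributable_burden",
    "fmt_count",
    "fmt_pct",
    "fmt_rate",
    "pct_change",
    "proportion",
    "rate_per_100k",
]
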