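"""Monte Carlo uncertainty propagation.

Every uncertain parameter (a stratum exposure mean, a log relative risk,
a TMREL) gets its own reproducible draw stream: the root seed plus a
CRC-32 hash of the parameter name seeds a dedicated NumPy ``SeedSequence``
child, so draws are bit-identical across runs and invariant to the order
in which parameters are requested.  Calculations are repeated across the
draws (1000 by default) and summarised as the draw mean with a 95%
uncertainty interval from the empirical 2.5th and 97.5th percentiles.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .risk_model import DrawSet, ValidationError

DEFAULT_N_DRAWS = 1000


@dataclass(frozen=True)
class ParameterSpec:
    """Sampling law for one uncertain parameter.

    laws:
      - ``normal``: args (mean, sd) — exposure means, log relative risks,
        mediator slopes.
      - ``tmrel``: args (optimal_mean,) — uniform on [0.8 m, 1.2 m].
      - ``uniform``: args (lower, upper).
    """

    name: str
    law: str
    args: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.law not in ("normal", "tmrel", "uniform"):
            raise ValidationError(f"unknown sampling law {self.law!r}")


def parameter_rng(root_seed: int, name: str) -> np.random.Generator:
    """Deterministic per-parameter child stream of the root seed."""
    child = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=(child,))
    return np.random.default_rng(ss)


def draw_parameter(spec: ParameterSpec, n_draws: int, seed: int) -> DrawSet:
    if n_draws <= 0:
        raise ValidationError("n_draws must be positive")
    rng = parameter_rng(seed, spec.name)
    if spec.law == "normal":
        mean, sd = spec.args
        values = mean + sd * rng.standard_normal(n_draws) if sd > 0 else np.full(n_draws, mean)
    elif spec.law == "tmrel":
        (m,) = spec.args
        values = rng.uniform(0.8 * m, 1.2 * m, size=n_draws)
    else:
        lo, hi = spec.args
        values = rng.uniform(lo, hi, size=n_draws)
    return DrawSet(values=values, seed=seed)


def draw_parameters(
    specs: Iterable[ParameterSpec], n_draws: int = DEFAULT_N_DRAWS, seed: int = 0
) -> dict[str, DrawSet]:
    """Draw all parameters; distinct parameters are independent streams."""
    out: dict[str, DrawSet] = {}
    for spec in specs:
        if spec.name in out:
            raise ValidationError(f"duplicate parameter name {spec.name!r}")
        out[spec.name] = draw_parameter(spec, n_draws, seed)
    return out


@dataclass(frozen=True)
class UiSummary:
    mean: float
    lower: float
    upper: float


def summarize_ui(draws: DrawSet | np.ndarray) -> UiSummary:
    """Draw mean with 95% UI (2.5th/97.5th percentiles, linear interpolation).

    The mean may fall outside the central interval only for pathological
    skew; lower <= upper always holds, lower <= mean is not required.
    """
    values = draws.values if isinstance(draws, DrawSet) else np.asarray(draws, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot summarise an empty draw set")
    if values.size < 2:
        raise ValidationError("uncertainty summary requires at least 2 draws")
    lower, upper = np.percentile(values, [2.5, 97.5])
    return UiSummary(mean=float(values.mean()), lower=float(lower), upper=float(upper))


__all__ = [
    "DEFAULT_N_DRAWS",
    "ParameterSpec",
    "UiSummary",
    "draw_parameter",
    "draw_parameters",
    "parameter_rng",
    "summarize_ui",
]
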