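"""Population attributable fractions by numerical integration.

The attributable fraction for one diet-disease pair and stratum is

    PAF = ( E[RR] - RR(TMREL) ) / E[RR],     E[RR] = int_l^u RR(x) P(x) dx

with the relative-risk curve normalised so that RR(TMREL) = 1, which
reduces the expression to ``1 - 1/E[RR]``.  The expectation is computed by
Gauss-Legendre quadrature on the exposure support, with the node count
doubled until the result is stable to an absolute tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats

from .risk_model import (
    Direction,
    DrawSet,
    ExposureDistribution,
    MediationChain,
    RelativeRiskCurve,
    RiskFactor,
    Stratum,
    ValidationError,
)


@dataclass
class PafEstimate:
    """PAF for one risk-outcome-stratum, optionally with draws and a 95% UI."""

    risk: str
    outcome: str
    stratum: Stratum | None
    point_value: float
    draws: DrawSet | None = None
    ui: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.point_value > 1.0:
            raise ValidationError(f"PAF cannot exceed 1, got {self.point_value}")


def evaluate_rr(curve: RelativeRiskCurve, x, tmrel_value: float):
    """Relative risk at exposure ``x`` with the TMREL as reference level.

    RR(tmrel_value) = 1 by construction; for capped curves the no-risk side
    plateaus at 1.  Exposures are non-negative quantities; negative ``x``
    is outside the support of every curve.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0) or not np.all(np.isfinite(x_arr)):
        raise ValidationError("exposure outside curve support (negative or non-finite)")
    return curve.rr(x_arr, tmrel_value)


def compose_mediated_rr(chain: MediationChain, x, tmrel_value: float):
    """Relative risk of a mediated risk at exposure ``x``.

    The exposure excess beyond the TMREL is translated into a mediator
    shift (slope) and pushed through the mediator-scale log-linear curve;
    the composition equals 1 at the TMREL and is identically 1 when the
    exposure-mediator slope is zero.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0) or not np.all(np.isfinite(x_arr)):
        raise ValidationError("exposure outside curve support (negative or non-finite)")
    return chain.rr(x_arr, tmrel_value)


@lru_cache(maxsize=16)
def _leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(n)


def expected_rr(
    dist: ExposureDistribution,
    curve: RelativeRiskCurve | MediationChain,
    tmrel_value: float,
    n_nodes: int = 256,
) -> float:
    """E[RR] under the (truncated, renormalised) exposure distribution.

    Self-normalising quadrature: the density weights are divided by their
    own quadrature mass so small truncation-mass errors cancel.
    """
    if dist.degenerate:
        return float(curve.rr(dist.mean, tmrel_value))
    l, u = dist.support
    t, w = _leggauss(n_nodes)
    # the capped RR curve has a kink at the TMREL: integrate piecewise on
    # either side so Gauss-Legendre retains spectral accuracy
    mid = min(max(tmrel_value, l), u)
    xs, ws = [], []
    for a, b in ((l, mid), (mid, u)):
        xs.append(0.5 * (b + a) + 0.5 * (b - a) * t)
        ws.append(0.5 * (b - a) * w)
    x = np.concatenate(xs)
    wx = np.concatenate(ws)
    p = dist.pdf(x)
    rr = curve.rr(x, tmrel_value)
    mass = float(np.sum(wx * p))
    if not np.isfinite(mass) or mass <= 0:
        raise ValidationError("non-finite or vanishing quadrature mass")
    return float(np.sum(wx * rr * p) / mass)


def compute_paf(
    dist: ExposureDistribution,
    curve: RelativeRiskCurve | MediationChain,
    tmrel_value: float,
    *,
    n_nodes: int = 256,
    tol: float = 1e-8,
    max_nodes: int = 4096,
) -> float:
    """PAF = 1 - RR(TMREL)/E[RR] with node-doubling convergence check.

    For capped curves RR >= 1 everywhere, hence 0 <= PAF < 1; uncapped
    curves may yield negative (protective) fractions, never above 1.
    """
    if n_nodes < 64:
        raise ValidationError("quadrature requires at least 64 nodes")
    if dist.degenerate:
        e_rr = expected_rr(dist, curve, tmrel_value)
    else:
        e_rr = expected_rr(dist, curve, tmrel_value, n_nodes)
        n = n_nodes
        while True:
            n *= 2
            e_next = expected_rr(dist, curve, tmrel_value, n)
            if abs(e_next - e_rr) <= tol:
                e_rr = e_next
                break
            e_rr = e_next
            if n >= max_nodes:
                raise ValidationError(
                    f"quadrature did not stabilise to {tol} within {max_nodes} nodes"
                )
    if not np.isfinite(e_rr):
        raise ValidationError("non-finite E[RR]")
    if e_rr <= 0:  # impossible for RR = exp(.) > 0; guard anyway
        raise ValidationError(f"E[RR] must be positive, got {e_rr}")
    rr_ref = float(curve.rr(tmrel_value, tmrel_value))
    return (e_rr - rr_ref) / e_rr


def combine_pafs(pafs: Sequence[float | PafEstimate]) -> float:
    """Combine PAFs of several risks for one outcome-stratum.

    Under independence the survival fractions multiply:
    ``combined = 1 - prod(1 - PAF_i)``.  The sum of individual PAFs can
    exceed the combined value because risk factors overlap.
    """
    values = [p.point_value if isinstance(p, PafEstimate) else float(p) for p in pafs]
    if any(v > 1 for v in values):
        raise ValidationError("individual PAF exceeds 1")
    if any(v == 1 for v in values):
        return 1.0
    one_minus = np.prod([1.0 - v for v in values]) if values else 1.0
    return float(1.0 - one_minus)


# ---------------------------------------------------------------------------
# Vectorised draw-level evaluation (used by the Monte Carlo pipeline)
# ---------------------------------------------------------------------------

def _family_base(family: str, mean: np.ndarray, sd: np.ndarray):
    if family == "lognormal":
        sigma2 = np.log1p((sd / mean) ** 2)
        sigma = np.sqrt(sigma2)
        scale = mean * np.exp(-sigma2 / 2.0)
        return stats.lognorm(s=sigma, scale=scale)
    if family == "gamma":
        return stats.gamma(a=(mean / sd) ** 2, scale=sd * sd / mean)
    if family == "truncated_normal":
        return stats.norm(loc=mean, scale=sd)
    raise ValidationError(f"unknown distribution family {family!r}")


def paf_draws(
    mean: np.ndarray,
    sd: np.ndarray,
    log_rr_per_unit: np.ndarray,
    tmrel: np.ndarray,
    direction: Direction | str,
    *,
    family: str = "lognormal",
    cap_at_tmrel: bool = True,
    n_nodes: int = 64,
    support_quantiles: tuple[float, float] = (0.001, 0.999),
) -> np.ndarray:
    """PAF for each element of broadcast parameter arrays.

    All four parameter arrays are broadcast together (typically one entry
    per Monte Carlo draw, or per stratum for point estimates).  For
    mediated risks pass the *effective* exposure-scale slope,
    ``exposure_to_mediator_slope * mediator log-RR per unit``.  Entries
    with ``sd == 0`` are treated as point masses.
    """
    direction = Direction(direction)
    mean, sd, log_rr_per_unit, tmrel = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (mean, sd, log_rr_per_unit, tmrel))
    )
    shape = mean.shape
    mean = mean.ravel()
    sd = sd.ravel()
    lrr = log_rr_per_unit.ravel()
    tm = tmrel.ravel()
    out = np.empty(mean.shape)

    def _excess(x, ref):
        exc = x - ref if direction is Direction.harmful_high else ref - x
        return np.maximum(exc, 0.0) if cap_at_tmrel else exc

    degen = sd == 0.0
    if np.any(degen):
        e_rr = np.exp(lrr[degen] * _excess(mean[degen], tm[degen]))
        out[degen] = 1.0 - 1.0 / e_rr
    cont = ~degen
    if np.any(cont):
        m, s = mean[cont], sd[cont]
        base = _family_base(family, m, s)
        q0, q1 = support_quantiles
        l = np.maximum(base.ppf(q0), 0.0)
        u = base.ppf(q1)
        t, w = _leggauss(n_nodes)
        # split each integral at the (clipped) TMREL where the capped RR
        # curve kinks; both pieces are then smooth for Gauss-Legendre
        mid = np.clip(tm[cont], l, u)
        x = np.concatenate(
            [
                0.5 * (mid + l)[:, None] + 0.5 * (mid - l)[:, None] * t[None, :],
                0.5 * (u + mid)[:, None] + 0.5 * (u - mid)[:, None] * t[None, :],
            ],
            axis=1,
        )
        wx = np.concatenate(
            [
                0.5 * (mid - l)[:, None] * w[None, :],
                0.5 * (u - mid)[:, None] * w[None, :],
            ],
            axis=1,
        )
        base_mat = _family_base(family, m[:, None], s[:, None])
        p = base_mat.pdf(x)
        rr = np.exp(lrr[cont][:, None] * _excess(x, tm[cont][:, None]))
        mass = np.sum(wx * p, axis=1)
        e_rr = np.sum(wx * rr * p, axis=1) / mass
        out[cont] = 1.0 - 1.0 / e_rr
    return out.reshape(shape)


__all__ = [
    "PafEstimate",
    "combine_pafs",
    "compose_mediated_rr",
    "compute_paf",
    "evaluate_rr",
    "expected_rr",
    "paf_draws",
]
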