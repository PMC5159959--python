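"""Exposure estimation: pooling sparse survey data down a location cascade.

The estimator has two components.  The first is an inverse-variance
weighted mixed-effects style meta-regression of reported stratum means on
sex, age and year (plus covariates).  The second is a cascade down the
four-level location hierarchy (global, super-region, region, country):
each node's estimate acts as a prior for its children, which update it
with whatever local data exist.  Countries without data inherit their
ancestors' estimates — the borrow-strength behaviour that lets a national
analysis proceed when the data representativeness index is low.

Utility operations cover the residual-method energy adjustment to a
2000 kcal/day reference, the dietary-to-urinary sodium multiplier, and
the data representativeness index itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .risk_model import AgeGroup, ValidationError

LEVELS = ("global", "super_region", "region", "country")


@dataclass(frozen=True)
class HierarchyNode:
    name: str
    level: str
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(f"unknown hierarchy level {self.level!r}")
        if (self.parent is None) != (self.level == "global"):
            raise ValidationError(
                f"node {self.name!r}: only the global root may lack a parent"
            )


class Hierarchy:
    """Four-level location tree with exactly one global root."""

    def __init__(self, nodes: Iterable[HierarchyNode]) -> None:
        self.nodes: dict[str, HierarchyNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise ValidationError(f"duplicate hierarchy node {node.name!r}")
            self.nodes[node.name] = node
        roots = [n for n in self.nodes.values() if n.level == "global"]
        if len(roots) != 1:
            raise ValidationError(f"hierarchy must have exactly one global root, found {len(roots)}")
        self.root = roots[0]
        self._children: dict[str, list[str]] = {name: [] for name in self.nodes}
        for node in self.nodes.values():
            if node.parent is not None:
                if node.parent not in self.nodes:
                    raise ValidationError(f"node {node.name!r} has unknown parent {node.parent!r}")
                self._children[node.parent].append(node.name)
        for country in self.countries():
            levels = {self.nodes[a].level for a in self.ancestors(country)}
            if not {"region", "super_region", "global"} <= levels:
                raise ValidationError(f"country {country!r} lacks a full ancestor chain")

    def children(self, name: str) -> list[str]:
        return sorted(self._children[name])

    def ancestors(self, name: str) -> list[str]:
        out = []
        node = self.nodes[name]
        while node.parent is not None:
            out.append(node.parent)
            node = self.nodes[node.parent]
        return out

    def countries(self) -> list[str]:
        return sorted(n.name for n in self.nodes.values() if n.level == "country")

    def at_level(self, level: str) -> list[str]:
        return sorted(n.name for n in self.nodes.values() if n.level == level)

    def subtree(self, name: str) -> set[str]:
        out = {name}
        stack = list(self._children[name])
        while stack:
            n = stack.pop()
            out.add(n)
            stack.extend(self._children[n])
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"name": n.name, "level": n.level, "parent": n.parent or ""}
            for n in sorted(self.nodes.values(), key=lambda n: (LEVELS.index(n.level), n.name))
        ]
        return pd.DataFrame(rows, columns=["name", "level", "parent"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Hierarchy":
        nodes = [
            HierarchyNode(r["name"], r["level"], r["parent"] or None)
            for r in df.to_dict("records")
        ]
        return cls(nodes)


@dataclass(frozen=True)
class SurveyDatum:
    """One tabulated survey observation of a stratum intake mean."""

    location: str
    year: int
    sex: str
    age_group: AgeGroup
    reported_mean: float
    standard_error: float
    sample_size: int
    mean_energy: float | None = None
    covariates: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.standard_error > 0:
            raise ValidationError("survey standard error must be positive")
        if self.sample_size < 1:
            raise ValidationError("survey sample size must be at least 1")


@dataclass(frozen=True)
class ExposureEstimate:
    """Posterior mean/sd of a stratum exposure mean at one location."""

    node: str
    level: str
    posterior_mean: float
    posterior_sd: float
    source_level: str
    year: int | None = None
    sex: str | None = None
    age_group: AgeGroup | None = None

    def __post_init__(self) -> None:
        if not self.posterior_sd > 0:
            raise ValidationError("posterior sd must be positive")


@dataclass
class GlobalFit:
    """Inverse-variance weighted regression fit."""

    column_names: list[str]
    coefficients: np.ndarray
    covariance: np.ndarray
    residual_variance: float

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[self.column_names.index(name)])

    def standard_error(self, name: str) -> float:
        i = self.column_names.index(name)
        return float(np.sqrt(self.covariance[i, i]))

    def confidence_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        from scipy import stats as _st

        z = _st.norm.ppf(0.5 + level / 2.0)
        b, se = self.coefficient(name), self.standard_error(name)
        return (b - z * se, b + z * se)


def _design_matrix(
    data: Sequence[SurveyDatum], covariate_names: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(data))}
    sexes = sorted({d.sex for d in data})
    if len(sexes) > 1:
        # reference = first sex alphabetically; indicator per remaining sex
        for s in sexes[1:]:
            cols[f"sex[{s}]"] = np.array([1.0 if d.sex == s else 0.0 for d in data])
    age_mid = np.array([d.age_group.midpoint for d in data])
    if len(np.unique(age_mid)) > 1:
        cols["age_midpoint"] = age_mid
    years = np.array([float(d.year) for d in data])
    if len(np.unique(years)) > 1:
        cols["year"] = years
    for name in covariate_names:
        vals = []
        for d in data:
            cov = dict(d.covariates)
            if name not in cov:
                raise ValidationError(f"survey datum missing covariate {name!r}")
            vals.append(cov[name])
        cols[name] = np.asarray(vals, dtype=float)
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys())


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [names[i] for i in range(len(names)) if diag[i] <= tol]


def fit_global(
    data: Sequence[SurveyDatum], covariate_names: Sequence[str] = ()
) -> GlobalFit:
    """Inverse-variance weighted regression of survey means on fixed effects.

    Fixed effects are sex, age-group midpoint, year and any named
    covariates (columns without variation are dropped rather than fit as
    degenerate).  Weights are 1/SE^2.
    """
    if len(data) < 2:
        raise ValidationError("fit_global requires at least 2 survey data points")
    X, names = _design_matrix(data, covariate_names)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValidationError(f"design matrix rank-deficient; collinear columns: {bad}")
    y = np.array([d.reported_mean for d in data])
    weights = np.array([1.0 / d.standard_error**2 for d in data])
    res = sm.WLS(y, X, weights=weights).fit()
    dof = max(len(data) - X.shape[1], 1)
    resid_var = float(np.sum(weights * res.resid**2) / np.sum(weights) * len(data) / dof) \
        if len(data) > X.shape[1] else 0.0
    # exact zero when the fit is saturated or residuals vanish
    if np.allclose(res.resid, 0.0):
        resid_var = 0.0
    return GlobalFit(
        column_names=names,
        coefficients=np.asarray(res.params, dtype=float),
        covariance=np.asarray(res.cov_params(), dtype=float),
        residual_variance=resid_var,
    )


def _ivw(means: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    prec = 1.0 / ses**2
    total = prec.sum()
    return float((prec * means).sum() / total), float(np.sqrt(1.0 / total))


def cascade_fit(
    parent: ExposureEstimate,
    local_data: Sequence[SurveyDatum],
    prior_strength: float = 1.0,
    node: str | None = None,
    level: str | None = None,
) -> ExposureEstimate:
    """One cascade step: update the parent prior with local data.

    The parent estimate enters as a Gaussian prior with variance
    ``parent_sd^2 / prior_strength``; local data enter via their
    inverse-variance weighted mean.  With no local data the child simply
    inherits the parent estimate (and its source level).
    """
    if not prior_strength > 0:
        raise ValidationError("prior_strength must be positive")
    if not np.isfinite(parent.posterior_mean) or not np.isfinite(parent.posterior_sd):
        raise ValidationError("parent posterior must be finite")
    child_node = node if node is not None else parent.node
    child_level = level if level is not None else parent.level
    if not local_data:
        return replace(parent, node=child_node, level=child_level)
    means = np.array([d.reported_mean for d in local_data])
    ses = np.array([d.standard_error for d in local_data])
    local_mean, local_sd = _ivw(means, ses)
    prior_prec = prior_strength / parent.posterior_sd**2
    local_prec = 1.0 / local_sd**2
    post_prec = prior_prec + local_prec
    post_mean = (prior_prec * parent.posterior_mean + local_prec * local_mean) / post_prec
    return ExposureEstimate(
        node=child_node,
        level=child_level,
        posterior_mean=post_mean,
        posterior_sd=float(np.sqrt(1.0 / post_prec)),
        source_level=child_level,
        year=parent.year,
        sex=parent.sex,
        age_group=parent.age_group,
    )


def _between_heterogeneity(groups: Sequence[tuple[float, float]]) -> float:
    """Method-of-moments between-group sd from (ivw mean, ivw sd) pairs.

    The spread of child-level pooled means in excess of their sampling
    variance estimates how much true exposure varies between siblings;
    it widens the parent prior so that plentiful data at one level cannot
    masquerade as certainty about another location's mean.
    """
    if len(groups) < 2:
        return 0.0
    means = np.array([g[0] for g in groups])
    vars_ = np.array([g[1] ** 2 for g in groups])
    tau2 = np.var(means, ddof=1) - vars_.mean()
    return float(np.sqrt(max(tau2, 0.0)))


def estimate_exposure_surface(
    surveys: pd.DataFrame,
    hierarchy: Hierarchy,
    prior_strength: float = 1.0,
) -> pd.DataFrame:
    """Cascade country-level exposure estimates for every stratum.

    ``surveys`` holds one risk's data with columns location, year, sex,
    age_lower, age_upper, mean, se, n.  Returns one row per
    (country, year, sex, age group) with the posterior mean, the sd of
    that mean, and the level the estimate was informed from.
    """
    required = {"location", "year", "sex", "age_lower", "age_upper", "mean", "se"}
    missing = required - set(surveys.columns)
    if missing:
        raise ValidationError(f"survey table missing columns {sorted(missing)}")
    if surveys.empty:
        raise ValidationError("no survey data to estimate from")
    out_rows = []
    for (year, sex, lo, hi), grp in surveys.groupby(
        ["year", "sex", "age_lower", "age_upper"], sort=True
    ):
        means = grp["mean"].to_numpy(dtype=float)
        ses = grp["se"].to_numpy(dtype=float)
        g_mean, g_sd = _ivw(means, ses)
        g_est = ExposureEstimate(
            node=hierarchy.root.name,
            level="global",
            posterior_mean=g_mean,
            posterior_sd=g_sd,
            source_level="global",
            year=int(year),
            sex=sex,
            age_group=AgeGroup(lo, hi),
        )
        by_location = {loc: sub for loc, sub in grp.groupby("location")}

        def subtree_rows(name: str) -> pd.DataFrame:
            members = hierarchy.subtree(name)
            keep = [loc for loc in by_location if loc in members]
            if not keep:
                return grp.iloc[0:0]
            return pd.concat([by_location[k] for k in keep])

        def level_heterogeneity(level: str) -> float:
            summaries = []
            for node in hierarchy.at_level(level):
                sub = subtree_rows(node)
                if len(sub):
                    summaries.append(
                        _ivw(sub["mean"].to_numpy(float), sub["se"].to_numpy(float))
                    )
            return _between_heterogeneity(summaries)

        tau = {lvl: level_heterogeneity(lvl) for lvl in ("super_region", "region", "country")}

        def cascade_to(node_name: str, parent_est: ExposureEstimate) -> ExposureEstimate:
            level = hierarchy.nodes[node_name].level
            sub = subtree_rows(node_name)
            data = [
                SurveyDatum(
                    location=r["location"],
                    year=int(r["year"]),
                    sex=r["sex"],
                    age_group=AgeGroup(r["age_lower"], r["age_upper"]),
                    reported_mean=float(r["mean"]),
                    standard_error=float(r["se"]),
                    sample_size=int(r.get("n", 1) or 1),
                )
                for r in sub.to_dict("records")
            ]
            prior_sd = float(np.sqrt(parent_est.posterior_sd**2 + tau[level] ** 2))
            prior = replace(parent_est, posterior_sd=prior_sd)
            return cascade_fit(prior, data, prior_strength, node=node_name, level=level)

        for sr in hierarchy.children(hierarchy.root.name):
            sr_est = cascade_to(sr, g_est)
            for region in hierarchy.children(sr):
                r_est = cascade_to(region, sr_est)
                for country in hierarchy.children(region):
                    c_est = cascade_to(country, r_est)
                    out_rows.append(
                        {
                            "location": country,
                            "year": int(year),
                            "sex": sex,
                            "age_lower": float(lo),
                            "age_upper": float(hi),
                            "mean": c_est.posterior_mean,
                            "sd_of_mean": c_est.posterior_sd,
                            "source_level": c_est.source_level,
                        }
                    )
    return pd.DataFrame(out_rows).sort_values(
        ["location", "year", "sex", "age_lower"], ignore_index=True
    )


def energy_adjust(
    intakes: Sequence[tuple[float, float]], target_energy: float = 2000.0
) -> np.ndarray:
    """Residual-method energy adjustment to a common kcal/day reference.

    Each intake is regressed on total energy; the adjusted value is the
    residual plus the predicted intake at ``target_energy``.  With fewer
    than two distinct energy values the adjustment is the identity.
    """
    arr = np.asarray(intakes, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("intakes must be (intake, energy) pairs")
    intake, energy = arr[:, 0], arr[:, 1]
    if np.any(energy <= 0):
        raise ValidationError("energy intake must be positive")
    if len(np.unique(energy)) < 2:
        return intake.copy()
    slope, icept = np.polyfit(energy, intake, 1)
    return intake + slope * (target_energy - energy)


def estimate_sodium_multiplier(paired: Sequence[tuple[float, float]]) -> float:
    """Dietary-to-urinary sodium conversion multiplier.

    Regression-through-origin slope of urinary on dietary sodium from
    surveys reporting both: ``sum(x*y) / sum(x^2)``.  Applied as
    ``urinary_equivalent = multiplier * dietary``.
    """
    arr = np.asarray(paired, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 1:
        raise ValidationError("need at least one (dietary, urinary) pair")
    if np.any(arr <= 0):
        raise ValidationError("sodium values must be positive")
    x, y = arr[:, 0], arr[:, 1]
    return float(np.sum(x * y) / np.sum(x * x))


def convert_dietary_sodium(dietary, multiplier: float):
    return np.asarray(dietary, dtype=float) * multiplier


def data_representativeness(nodes_with_data: set, all_countries: set) -> float:
    """Fraction of countries with at least one exposure datum (the DRI)."""
    if not all_countries:
        raise ValidationError("all_countries must be non-empty")
    return len(set(nodes_with_data) & set(all_countries)) / len(all_countries)


__all__ = [
    "ExposureEstimate",
    "GlobalFit",
    "Hierarchy",
    "HierarchyNode",
    "LEVELS",
    "SurveyDatum",
    "cascade_fit",
    "convert_dietary_sodium",
    "data_representativeness",
    "energy_adjust",
    "estimate_exposure_surface",
    "estimate_sodium_multiplier",
    "fit_global",
]
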