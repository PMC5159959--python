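"""End-to-end orchestration: surveys -> exposures -> PAFs -> burden.

Stages are plain functions over data frames so the command-line interface
can run them separately (writing/reading intermediate tables) or chained;
because every Monte Carlo stream is derived deterministically from the
root seed and a parameter name, re-running a stage from saved
intermediates reproduces the direct end-to-end output byte for byte.

Draw sharing: a parameter that is common to both reporting periods (a
relative risk, a TMREL, a mediator slope) uses one draw stream across
years, so period contrasts are properly correlated; exposure means are
per-stratum parameters and get their own streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as dio
from .burden import StandardPopulation
from .exposure import estimate_exposure_surface
from .paf import combine_pafs, paf_draws
from .risk_model import ValidationError
from .synthetic import WorldBundle
from .uncertainty import ParameterSpec, draw_parameter, summarize_ui

CELL_KEYS = ["location", "year", "sex", "age_lower", "age_upper"]


def estimate_all_exposures(
    bundle: WorldBundle, prior_strength: float | None = None
) -> pd.DataFrame:
    """Cascaded country exposure estimates for every risk in the bundle."""
    hierarchy = bundle.hierarchy_tree()
    ps = (
        prior_strength
        if prior_strength is not None
        else float(bundle.config.get("prior_strength", 1.0))
    )
    frames = []
    for risk in sorted(bundle.config["risks"]):
        sub = bundle.surveys[bundle.surveys["risk"] == risk]
        if sub.empty:
            raise ValidationError(f"no survey data anywhere for risk {risk!r}")
        est = estimate_exposure_surface(sub, hierarchy, prior_strength=ps)
        est.insert(0, "risk", risk)
        frames.append(est)
    return pd.concat(frames, ignore_index=True)[dio.EXPOSURE_ESTIMATE_COLUMNS]


def _risk_cells(exposures: pd.DataFrame, risk: str) -> pd.DataFrame:
    cells = exposures[exposures["risk"] == risk].sort_values(
        CELL_KEYS, ignore_index=True
    )
    if cells.empty:
        raise ValidationError(f"no exposure estimates for risk {risk!r}")
    return cells


def _exposure_mean_draws(
    risk: str, cells: pd.DataFrame, n_draws: int, seed: int
) -> np.ndarray:
    """(n_cells, n_draws) draws of each stratum's exposure mean."""
    out = np.empty((len(cells), n_draws))
    for i, r in enumerate(cells.to_dict("records")):
        name = (
            f"exposure|{risk}|{r['location']}|{r['sex']}"
            f"|{r['age_lower']:g}|{int(r['year'])}"
        )
        spec = ParameterSpec(name, "normal", (float(r["mean"]), float(r["sd_of_mean"])))
        draws = draw_parameter(spec, n_draws, seed).values
        # an exposure mean is a positive quantity; keep draws off zero
        out[i] = np.maximum(draws, 1e-6 * float(r["mean"]))
    return out


def _effective_logrr_draws(rr_row: Mapping, n_draws: int, seed: int) -> np.ndarray:
    """Draws of the exposure-scale log-RR slope for one risk-outcome pair."""
    risk, outcome = rr_row["risk"], rr_row["outcome"]
    mediator = rr_row.get("mediator")
    if isinstance(mediator, str) and mediator:
        slope = draw_parameter(
            ParameterSpec(f"slope|{risk}", "normal",
                          (float(rr_row["slope"]), float(rr_row["slope_se"]))),
            n_draws, seed,
        ).values
        mlrr = draw_parameter(
            ParameterSpec(
                f"mediator_logrr|{risk}|{outcome}", "normal",
                (float(rr_row["mediator_log_rr_per_unit"]), float(rr_row["mediator_se"])),
            ),
            n_draws, seed,
        ).values
        return slope * mlrr
    se = float(rr_row["se"]) if np.isfinite(rr_row["se"]) else 0.0
    return draw_parameter(
        ParameterSpec(f"logrr|{risk}|{outcome}", "normal",
                      (float(rr_row["log_rr_per_unit"]), se)),
        n_draws, seed,
    ).values


def _paf_matrix(
    mean_mat: np.ndarray,
    cv: float,
    lrr_draws: np.ndarray,
    tmrel_draws: np.ndarray,
    direction: str,
    family: str,
    support_quantiles: tuple[float, float],
    n_nodes: int = 64,
    chunk: int = 20000,
) -> np.ndarray:
    """PAF per (cell, draw), evaluated in flat chunks to bound memory."""
    n_cells, n_draws = mean_mat.shape
    lrr = np.broadcast_to(lrr_draws, (n_cells, n_draws)).ravel()
    tm = np.broadcast_to(tmrel_draws, (n_cells, n_draws)).ravel()
    mean = mean_mat.ravel()
    sd = cv * mean
    out = np.empty(mean.shape)
    for start in range(0, mean.size, chunk):
        sl = slice(start, start + chunk)
        out[sl] = paf_draws(
            mean[sl], sd[sl], lrr[sl], tm[sl], direction,
            family=family, n_nodes=n_nodes, support_quantiles=support_quantiles,
        )
    return out.reshape(n_cells, n_draws)


@dataclass
class PafCube:
    """Point PAFs and draw matrices per (risk, outcome), on a shared cell grid."""

    cells: pd.DataFrame  # canonical (location, year, sex, age) grid
    point: dict[tuple[str, str], np.ndarray]
    draws: dict[tuple[str, str], np.ndarray]


def compute_paf_cube(
    bundle: WorldBundle,
    exposures: pd.DataFrame,
    n_draws: int = 1000,
    seed: int = 0,
    n_nodes_point: int = 256,
    n_nodes_mc: int = 64,
) -> PafCube:
    cfg = bundle.config
    support_q = tuple(cfg.get("support_quantiles", (0.001, 0.999)))
    risks = sorted(cfg["risks"])
    cells = _risk_cells(exposures, risks[0])[CELL_KEYS]
    point: dict[tuple[str, str], np.ndarray] = {}
    draws: dict[tuple[str, str], np.ndarray] = {}
    for risk in risks:
        rcfg = cfg["risks"][risk]
        rcells = _risk_cells(exposures, risk)
        if not rcells[CELL_KEYS].equals(cells):
            raise ValidationError(f"exposure grid for {risk!r} does not match the cell grid")
        tmrel_row = bundle.tmrels[bundle.tmrels["risk"] == risk]
        if tmrel_row.empty:
            raise ValidationError(f"no TMREL for risk {risk!r}")
        optimal = float(tmrel_row["optimal"].iloc[0])
        mean_draws = _exposure_mean_draws(risk, rcells, n_draws, seed)
        half_width = float(cfg.get("tmrel_uncertainty", 0.2))
        tmrel_draws = draw_parameter(
            ParameterSpec(
                f"tmrel|{risk}", "uniform",
                ((1.0 - half_width) * optimal, (1.0 + half_width) * optimal),
            ),
            n_draws, seed,
        ).values
        rr_rows = bundle.relative_risks[bundle.relative_risks["risk"] == risk]
        for rr_row in rr_rows.to_dict("records"):
            outcome = rr_row["outcome"]
            point[(risk, outcome)] = paf_draws(
                rcells["mean"].to_numpy(float),
                rcfg["cv"] * rcells["mean"].to_numpy(float),
                float(rr_row["log_rr_per_unit"]),
                optimal,
                rcfg["direction"],
                family=rcfg["family"],
                n_nodes=n_nodes_point,
                support_quantiles=support_q,
            )
            lrr_draws = _effective_logrr_draws(rr_row, n_draws, seed)
            draws[(risk, outcome)] = _paf_matrix(
                mean_draws, rcfg["cv"], lrr_draws, tmrel_draws,
                rcfg["direction"], rcfg["family"], support_q, n_nodes=n_nodes_mc,
            )
    return PafCube(cells=cells, point=point, draws=draws)


def paf_table(cube: PafCube) -> pd.DataFrame:
    """Flat PAF report: point value plus 95% UI per risk-outcome-stratum."""
    frames = []
    for (risk, outcome), pts in sorted(cube.point.items()):
        d = cube.draws[(risk, outcome)]
        lo, hi = np.percentile(d, [2.5, 97.5], axis=1)
        f = cube.cells.copy()
        f.insert(0, "risk", risk)
        f.insert(1, "outcome", outcome)
        f["age_group"] = [
            f"{a:g}-{b:g}" for a, b in zip(f["age_lower"], f["age_upper"])
        ]
        f["paf_mean"] = d.mean(axis=1)
        f["paf_point"] = pts
        f["paf_lower"] = lo
        f["paf_upper"] = hi
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    cols = dio.PAF_OUTPUT_COLUMNS + ["paf_point"]
    return out[cols]


@dataclass
class PipelineResult:
    exposures: pd.DataFrame
    pafs: pd.DataFrame
    burden_summary: pd.DataFrame
    risk_attribution: pd.DataFrame
    trend: pd.DataFrame | None = None
    flags: list[str] = field(default_factory=list)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        dio.write_table(self.exposures, directory / "exposure_estimates.tsv")
        dio.write_table(self.pafs, directory / "paf_estimates.tsv")
        dio.write_table(self.burden_summary, directory / "burden_summary.tsv")
        dio.write_table(self.risk_attribution, directory / "risk_attribution.tsv")
        if self.trend is not None:
            dio.write_table(self.trend, directory / "trend_report.tsv")
        with open(directory / "flags.txt", "w") as fh:
            for line in self.flags:
                fh.write(line + "\n")


def _aligned_envelope(
    envelopes: pd.DataFrame, cells: pd.DataFrame, outcome: str, metric: str
) -> tuple[np.ndarray, np.ndarray]:
    """Envelope counts and populations aligned to the canonical cell grid."""
    sub = envelopes[(envelopes["outcome"] == outcome) & (envelopes["metric"] == metric)]
    merged = cells.merge(sub, on=CELL_KEYS, how="left", validate="one_to_one")
    if merged["count"].isna().any():
        missing = merged[merged["count"].isna()][CELL_KEYS].iloc[0].to_dict()
        raise ValidationError(
            f"envelope missing for outcome {outcome!r}, metric {metric!r}, cell {missing}"
        )
    return merged["count"].to_numpy(float), merged["population"].to_numpy(float)


def compute_burden_summary(
    bundle: WorldBundle,
    cube: PafCube,
    std: StandardPopulation | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """National burden summaries and per-risk attribution from a PAF cube.

    Combined (all-diet) attributable burden multiplies survival fractions
    across risks per outcome before applying the envelopes; per-risk
    attribution applies each risk's own PAF alone.  Envelope counts are
    treated as fixed (no envelope UIs in the bundle).
    """
    cfg = bundle.config
    cells = cube.cells
    outcomes = sorted({o for (_, o) in cube.point})
    metrics = sorted(bundle.envelopes["metric"].unique())
    years = sorted(cells["year"].unique())
    age_labels = [f"{a:g}-{b:g}" for a, b in cfg["age_groups"]]
    if std is None:
        std = StandardPopulation.equal(age_labels)
    weights = std.as_dict()
    n_draws = next(iter(cube.draws.values())).shape[1]

    # combined PAF across risks, per outcome
    combined_draws: dict[str, np.ndarray] = {}
    combined_point: dict[str, np.ndarray] = {}
    for outcome in outcomes:
        surv_d = np.ones((len(cells), n_draws))
        surv_p = np.ones(len(cells))
        for (risk, o), d in cube.draws.items():
            if o == outcome:
                surv_d *= 1.0 - d
                surv_p *= 1.0 - cube.point[(risk, o)]
        combined_draws[outcome] = 1.0 - surv_d
        combined_point[outcome] = 1.0 - surv_p

    age_lower_of = dict(zip(age_labels, [a for a, _ in cfg["age_groups"]]))
    summary_rows = []
    attribution_rows = []
    for metric in metrics:
        counts = {}
        pop_vec = None
        for outcome in outcomes:
            c, p = _aligned_envelope(bundle.envelopes, cells, outcome, metric)
            counts[outcome] = c
            pop_vec = p
        env_total_vec = np.sum([counts[o] for o in outcomes], axis=0)
        attr_draws = np.zeros((len(cells), n_draws))
        attr_point = np.zeros(len(cells))
        for outcome in outcomes:
            attr_draws += counts[outcome][:, None] * combined_draws[outcome]
            attr_point += counts[outcome] * combined_point[outcome]
        for year in years:
            mask = (cells["year"] == year).to_numpy()
            pop = float(pop_vec[mask].sum())
            count_draws = attr_draws[mask].sum(axis=0)
            count_point = float(attr_point[mask].sum())
            env_total = float(env_total_vec[mask].sum())
            ncd_total = env_total * cfg["ncd_factor"]
            all_total = env_total * cfg["allcause_factor"]
            rate_draws = count_draws / pop * 1e5
            # age-standardized attributable and envelope rates
            asr_draws = np.zeros(n_draws)
            asr_point = 0.0
            asr_env = 0.0
            for (a_lo, a_hi) in cfg["age_groups"]:
                label = f"{a_lo:g}-{a_hi:g}"
                amask = mask & (cells["age_lower"] == a_lo).to_numpy()
                pop_a = float(pop_vec[amask].sum())
                w = weights[label]
                asr_draws += w * attr_draws[amask].sum(axis=0) / pop_a * 1e5
                asr_point += w * float(attr_point[amask].sum()) / pop_a * 1e5
                asr_env += w * float(env_total_vec[amask].sum()) / pop_a * 1e5
            row = {
                "metric": metric,
                "year": int(year),
                "population": pop,
                "count_point": count_point,
                "envelope_total": env_total,
            }
            for name, draws_vec in (
                ("count", count_draws),
                ("rate", rate_draws),
                ("as_rate", asr_draws),
                ("prop_all", count_draws / all_total * 100.0),
                ("prop_ncd", count_draws / ncd_total * 100.0),
                ("as_prop_all", asr_draws / (asr_env * cfg["allcause_factor"]) * 100.0),
                ("as_prop_ncd", asr_draws / (asr_env * cfg["ncd_factor"]) * 100.0),
            ):
                ui = summarize_ui(draws_vec)
                row[f"{name}_mean"] = ui.mean
                row[f"{name}_lower"] = ui.lower
                row[f"{name}_upper"] = ui.upper
            row["rate_point"] = count_point / pop * 1e5
            row["as_rate_point"] = asr_point
            summary_rows.append(row)
        # per-risk attribution (no cross-risk combination)
        for risk in sorted(cfg["risks"]):
            r_draws = np.zeros((len(cells), n_draws))
            r_point = np.zeros(len(cells))
            for (rk, o), d in cube.draws.items():
                if rk == risk:
                    r_draws += counts[o][:, None] * d
                    r_point += counts[o] * cube.point[(rk, o)]
            for year in years:
                mask = (cells["year"] == year).to_numpy()
                ui = summarize_ui(r_draws[mask].sum(axis=0))
                attribution_rows.append(
                    {
                        "risk": risk,
                        "metric": metric,
                        "year": int(year),
                        "count_point": float(r_point[mask].sum()),
                        "count_mean": ui.mean,
                        "count_lower": ui.lower,
                        "count_upper": ui.upper,
                    }
                )
    summary = pd.DataFrame(summary_rows).sort_values(
        ["metric", "year"], ignore_index=True
    )
    attribution = pd.DataFrame(attribution_rows).sort_values(
        ["risk", "metric", "year"], ignore_index=True
    )
    return summary, attribution


def run_all(
    bundle: WorldBundle,
    n_draws: int = 1000,
    seed: int = 0,
    prior_strength: float | None = None,
    std: StandardPopulation | None = None,
) -> PipelineResult:
    """Chain every stage on one bundle."""
    from .report import build_trend_table

    exposures = estimate_all_exposures(bundle, prior_strength)
    cube = compute_paf_cube(bundle, exposures, n_draws=n_draws, seed=seed)
    pafs = paf_table(cube)
    summary, attribution = compute_burden_summary(bundle, cube, std=std)
    trend, flags = None, []
    years = sorted(summary["year"].unique())
    if len(years) == 2:
        trend, flags = build_trend_table(summary, (years[0], years[1]))
    return PipelineResult(
        exposures=exposures,
        pafs=pafs,
        burden_summary=summary,
        risk_attribution=attribution,
        trend=trend,
        flags=flags,
    )


__all__ = [
    "CELL_KEYS",
    "PafCube",
    "PipelineResult",
    "compute_burden_summary",
    "compute_paf_cube",
    "estimate_all_exposures",
    "paf_table",
    "run_all",
]
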