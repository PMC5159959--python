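"""Human-readable trend reports (two-period burden tables).

Produces the familiar burden-table layout: one block of rows per metric
for unstandardized all-cause quantities (number, rate per 100,000,
proportion of all-cause burden), one for age-standardized rates, and two
proportion-only blocks against the NCD envelope.  Counts and rates are
printed as integers, percentages to one decimal; the change column is
computed from unrounded values.  Cells where a reader recomputing the
change from the *printed* (rounded) numbers would get a visibly different
answer are flagged rather than silently absorbed.
"""

from __future__ import annotations

import pandas as pd

from .burden import fmt_count, fmt_pct, fmt_rate, pct_change
from .risk_model import ValidationError


def _ui(fmt, row, stem):
    return (
        f"{fmt(row[f'{stem}_mean'])} "
        f"({fmt(row[f'{stem}_lower'])}–{fmt(row[f'{stem}_upper'])})"
    )


def _flag_if_inconsistent(
    flags: list[str], label: str, v1: float, v2: float, change: float, decimals: int
) -> None:
    """Flag change cells that cannot be recomputed from their rounded neighbours."""
    r1, r2 = round(v1, decimals), round(v2, decimals)
    if r1 == 0:
        return
    from_rounded = 100.0 * (r2 - r1) / r1
    if abs(round(change, 1) - round(from_rounded, 1)) > 0.1:
        flags.append(
            f"{label}: change {change:.1f}% not reproducible from rounded cells "
            f"({r1:g} -> {r2:g} gives {from_rounded:.1f}%)"
        )


def build_trend_table(
    burden_summary: pd.DataFrame, years: tuple[int, int]
) -> tuple[pd.DataFrame, list[str]]:
    """Two-period trend table from a burden summary.

    ``burden_summary`` is the per-(metric, year) national summary produced
    by the pipeline; both years must be present for every metric.
    """
    y1, y2 = years
    flags: list[str] = []
    rows = []
    metric_order = [m for m in ("deaths", "dalys", "ylls", "ylds")
                    if m in set(burden_summary["metric"])]
    blocks = [
        ("unstandardized", "all_causes"),
        ("age_standardized", "all_causes"),
        ("unstandardized", "ncd"),
        ("age_standardized", "ncd"),
    ]
    for standardization, denominator in blocks:
        for metric in metric_order:
            r1 = burden_summary[
                (burden_summary["metric"] == metric) & (burden_summary["year"] == y1)
            ]
            r2 = burden_summary[
                (burden_summary["metric"] == metric) & (burden_summary["year"] == y2)
            ]
            if r1.empty or r2.empty:
                raise ValidationError(
                    f"missing period for metric {metric!r}: need both {y1} and {y2}"
                )
            r1, r2 = r1.iloc[0], r2.iloc[0]
            row: dict[str, object] = {
                "metric": metric,
                "standardization": standardization,
                "denominator": denominator,
            }
            label = f"{standardization}/{denominator}/{metric}"
            if standardization == "unstandardized" and denominator == "all_causes":
                change = pct_change(r1["count_mean"], r2["count_mean"])
                row[f"number_{y1}"] = _ui(fmt_count, r1, "count")
                row[f"number_{y2}"] = _ui(fmt_count, r2, "count")
                row["number_change"] = fmt_pct(change)
                _flag_if_inconsistent(
                    flags, label + "/number",
                    r1["count_mean"], r2["count_mean"], change, 0,
                )
            else:
                row[f"number_{y1}"] = "-"
                row[f"number_{y2}"] = "-"
                row["number_change"] = "-"
            if denominator == "all_causes":
                stem = "rate" if standardization == "unstandardized" else "as_rate"
                change = pct_change(r1[f"{stem}_mean"], r2[f"{stem}_mean"])
                row[f"rate_{y1}"] = _ui(fmt_rate, r1, stem)
                row[f"rate_{y2}"] = _ui(fmt_rate, r2, stem)
                row["rate_change"] = fmt_pct(change)
                _flag_if_inconsistent(
                    flags, label + "/rate",
                    r1[f"{stem}_mean"], r2[f"{stem}_mean"], change, 0,
                )
            else:
                row[f"rate_{y1}"] = "-"
                row[f"rate_{y2}"] = "-"
                row["rate_change"] = "-"
            prop_stem = {
                ("unstandardized", "all_causes"): "prop_all",
                ("age_standardized", "all_causes"): "as_prop_all",
                ("unstandardized", "ncd"): "prop_ncd",
                ("age_standardized", "ncd"): "as_prop_ncd",
            }[(standardization, denominator)]
            change = pct_change(r1[f"{prop_stem}_mean"], r2[f"{prop_stem}_mean"])
            row[f"proportion_{y1}"] = _ui(fmt_pct, r1, prop_stem)
            row[f"proportion_{y2}"] = _ui(fmt_pct, r2, prop_stem)
            row["proportion_change"] = fmt_pct(change)
            _flag_if_inconsistent(
                flags, label + "/proportion",
                r1[f"{prop_stem}_mean"], r2[f"{prop_stem}_mean"], change, 1,
            )
            rows.append(row)
    return pd.DataFrame(rows), flags


__all__ = ["build_trend_table"]
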