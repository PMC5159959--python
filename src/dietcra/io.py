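"""Delimited-text table I/O with schema validation.

Every table in the pipeline is tab-separated text with a header row; the
expected columns per table are declared here so a malformed input fails
with an explicit column diff rather than a downstream KeyError.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
import yaml

from .risk_model import ValidationError

HIERARCHY_COLUMNS = ["name", "level", "parent"]
SURVEY_COLUMNS = [
    "risk", "location", "level", "year", "sex",
    "age_lower", "age_upper", "mean", "se", "n", "energy",
]
RR_COLUMNS = [
    "risk", "outcome", "log_rr_per_unit", "se",
    "mediator", "slope", "slope_se", "mediator_log_rr_per_unit", "mediator_se",
]
TMREL_COLUMNS = ["risk", "optimal"]
ENVELOPE_COLUMNS = [
    "outcome", "metric", "location", "year", "sex",
    "age_lower", "age_upper", "count", "population",
]
TRUTH_PAF_COLUMNS = [
    "risk", "outcome", "location", "year", "sex", "age_lower", "age_upper", "paf_true",
]
TRUTH_EXPOSURE_COLUMNS = [
    "risk", "location", "year", "sex", "age_lower", "age_upper", "true_mean", "true_sd",
]
EXPOSURE_ESTIMATE_COLUMNS = [
    "risk", "location", "year", "sex", "age_lower", "age_upper",
    "mean", "sd_of_mean", "source_level",
]
PAF_OUTPUT_COLUMNS = [
    "risk", "outcome", "location", "year", "sex", "age_group",
    "age_lower", "age_upper", "paf_mean", "paf_lower", "paf_upper",
]

BUNDLE_FILES = {
    "hierarchy.tsv": HIERARCHY_COLUMNS,
    "surveys.tsv": SURVEY_COLUMNS,
    "relative_risks.tsv": RR_COLUMNS,
    "tmrels.tsv": TMREL_COLUMNS,
    "envelopes.tsv": ENVELOPE_COLUMNS,
    "ground_truth_paf.tsv": TRUTH_PAF_COLUMNS,
    "ground_truth_exposure.tsv": TRUTH_EXPOSURE_COLUMNS,
}


#: dtype normalisation applied after parsing: age bounds are half-open
#: interval edges in years and must stay float even when integral-valued.
COLUMN_DTYPES = {
    "age_lower": "float64",
    "age_upper": "float64",
    "year": "int64",
}


class SchemaError(ValidationError):
    """Input table columns do not match the documented schema."""

    def __init__(self, path: str, missing: list[str], extra: list[str]) -> None:
        self.path = str(path)
        self.missing = missing
        self.extra = extra
        super().__init__(
            f"{path}: schema mismatch; missing columns {missing}, unexpected columns {extra}"
        )


def read_table(path: str | Path, columns: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    # round_trip float parsing so staged re-runs from saved intermediates
    # are bit-identical to chained in-memory runs
    df = pd.read_csv(path, sep="\t", keep_default_na=True,
                     float_precision="round_trip")
    for col, dtype in COLUMN_DTYPES.items():
        if col in df.columns:
            df[col] = df[col].astype(dtype)
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        extra = [c for c in df.columns if c not in columns]
        if missing or extra:
            raise SchemaError(path, missing, extra)
        df = df[columns]
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips float64 exactly, so staged runs that re-read
    # intermediate tables reproduce chained runs byte for byte
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_yaml(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with open(path) as fh:
        return yaml.safe_load(fh)


__all__ = [
    "BUNDLE_FILES",
    "ENVELOPE_COLUMNS",
    "EXPOSURE_ESTIMATE_COLUMNS",
    "HIERARCHY_COLUMNS",
    "PAF_OUTPUT_COLUMNS",
    "RR_COLUMNS",
    "SURVEY_COLUMNS",
    "SchemaError",
    "TMREL_COLUMNS",
    "TRUTH_EXPOSURE_COLUMNS",
    "TRUTH_PAF_COLUMNS",
    "read_table",
    "read_yaml",
    "sha256_of",
    "write_table",
    "write_yaml",
]
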