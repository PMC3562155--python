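"""Table and parameter I/O for the pipeline.

All tables are plain TSV with explicit headers; parameter sets and fit
results are JSON with explicit field names.  Validation reports the
offending line numbers (1-based, counting the header as line 1).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .relay import CONDITION_LABELS, STRAIN_LABELS, Condition, DomainError, PtsParameters


class ValidationError(ValueError):
    """A table failed validation; the message lists the offending rows."""


MEASUREMENT_COLUMNS = ("strain", "condition", "ptsN_fraction", "rel_error")


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a PtsN measurement table (TSV or CSV)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = {"strain", "condition", "ptsN_fraction"} - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: missing required columns {sorted(missing)}")
    if "rel_error" not in df.columns:
        df["rel_error"] = np.nan
    problems = []
    for i, row in df.iterrows():
        line = i + 2
        if row["strain"] not in STRAIN_LABELS:
            problems.append(f"line {line}: unknown strain {row['strain']!r} "
                            f"(allowed: {list(STRAIN_LABELS)})")
        if row["condition"] not in CONDITION_LABELS:
            problems.append(f"line {line}: unknown condition {row['condition']!r} "
                            f"(allowed: {list(CONDITION_LABELS)})")
        frac = row["ptsN_fraction"]
        if not np.isfinite(frac) or not (0.0 <= frac <= 1.0):
            problems.append(f"line {line}: ptsN_fraction {frac!r} outside [0, 1]")
        rel = row["rel_error"]
        if np.isfinite(rel) and rel < 0:
            problems.append(f"line {line}: negative rel_error {rel!r}")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    return df[list(MEASUREMENT_COLUMNS)]


def write_measurements(data: pd.DataFrame, path) -> None:
    cols = [c for c in MEASUREMENT_COLUMNS if c in data.columns]
    data[cols].to_csv(path, sep="\t", index=False)


def read_design(path) -> dict[str, Condition]:
    """Read a condition-design table: condition, pp, r_fru, fruB_induced.

    A ``strain`` column (design tables are sometimes written per
    strain x condition row) is accepted; the per-condition quantities
    must then be consistent across strains and are read once.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"condition", "pp", "r_fru", "fruB_induced"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if "strain" in df.columns:
        dedup = df.drop(columns=["strain"]).drop_duplicates()
        if dedup["condition"].duplicated().any():
            raise ValidationError(
                f"{path}: inconsistent per-condition values across strains")
        df = dedup.reset_index(drop=True)
    out = {}
    for i, row in df.iterrows():
        try:
            out[row["condition"]] = Condition(
                label=row["condition"], pp=float(row["pp"]),
                r_fru=float(row["r_fru"]), fruB_induced=bool(row["fruB_induced"]))
        except DomainError as exc:
            raise ValidationError(f"{path}: line {i + 2}: {exc}") from exc
    return out


def write_design(conditions: Mapping[str, Condition], path) -> None:
    rows = [{"condition": c.label, "pp": c.pp, "r_fru": c.r_fru,
             "fruB_induced": c.fruB_induced} for c in conditions.values()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_flux_table(path) -> pd.DataFrame:
    """Read a node flux-summary table: condition, reaction, nominal, min, max."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"condition", "reaction", "nominal"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    problems = []
    if {"min", "max"} <= set(df.columns):
        for i, row in df.iterrows():
            if not (row["min"] <= row["nominal"] + 1e-12
                    and row["nominal"] <= row["max"] + 1e-12):
                problems.append(
                    f"line {i + 2}: min <= nominal <= max violated "
                    f"({row['min']}, {row['nominal']}, {row['max']})")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    return df


def write_flux_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_parameters_json(params: PtsParameters, path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2))


def read_parameters_json(path) -> PtsParameters:
    d = json.loads(Path(path).read_text())
    try:
        return PtsParameters.from_dict(d)
    except (TypeError, DomainError) as exc:
        raise ValidationError(f"{path}: invalid parameter set: {exc}") from exc
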