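"""Cohort CSV reading/writing with data-dictionary validation, and the
packaged aggregate count tables from the published validation cohort.

CSV dialect: UTF-8, comma-separated, '.' decimal, header row required. An
optional leading comment line ``# provenance: <tag>`` carries the cohort's
provenance tag through a round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .contingency import ContingencyTable, TwoByTwoTable
from .scoring import InvalidInputError

# data dictionary: column -> (kind, allowed values or None)
SCHEMA: dict[str, tuple[str, tuple | None]] = {
    "patient_id": ("str", None),
    "sex": ("cat", ("M", "F")),
    "marital": ("cat", ("married", "single", "divorced_widowed")),
    "age": ("float", None),
    "bmi": ("float", None),
    "functional": ("functional", None),
    "vintage_years": ("float", None),
    "albumin_gL": ("float", None),
    "ferritin_ugL": ("float", None),
    "dm": ("flag", (0, 1)),
    "htn": ("flag", (0, 1)),
    "ihd": ("flag", (0, 1)),
    "cvd": ("flag", (0, 1)),
    "epo": ("flag", (0, 1)),
    "hemoglobin_gL": ("float_opt", None),
    "ktv": ("float_opt", None),
    "adm_vascular": ("flag", (0, 1)),
    "adm_nonvascular": ("flag", (0, 1)),
    "died": ("flag", (0, 1)),
    "quarter": ("int_opt", None),
}

FUNCTIONAL_NAMES = ("normal", "occasional_difficulty", "dependent_difficulty", "bed_chair_bound")

REQUIRED_COLUMNS = [c for c, (kind, _) in SCHEMA.items() if not kind.endswith("_opt")]


class SchemaError(ValueError):
    """Header does not match the data dictionary."""


@dataclass
class Cohort:
    """Patient-level cohort table plus provenance ({real, synthetic, fixture})."""

    data: pd.DataFrame
    provenance: str = "real"
    rejected: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.data)

    def __len__(self) -> int:
        return len(self.data)


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split into (valid, rejected-with-reason) per the data dictionary."""
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        bad = mask & (reasons == "")
        reasons[bad] = reason

    for col in ("sex", "marital"):
        allowed = SCHEMA[col][1]
        flag(~df[col].isin(allowed), f"{col} not in {allowed}")
    func = df["functional"]
    numeric = pd.to_numeric(func, errors="coerce")
    ok_code = numeric.isin([0, 1, 2, 3])
    ok_name = func.astype(str).isin(FUNCTIONAL_NAMES)
    flag(~(ok_code | ok_name), "functional not a 0-3 code or level name")
    for col in ("dm", "htn", "ihd", "cvd", "epo", "adm_vascular", "adm_nonvascular", "died"):
        flag(~pd.to_numeric(df[col], errors="coerce").isin([0, 1]), f"{col} not 0/1")
    for col in ("age", "bmi", "albumin_gL"):
        vals = pd.to_numeric(df[col], errors="coerce")
        flag(vals.isna() | (vals <= 0), f"{col} not a positive number")
    for col in ("vintage_years", "ferritin_ugL"):
        vals = pd.to_numeric(df[col], errors="coerce")
        flag(vals.isna() | (vals < 0), f"{col} not a non-negative number")

    bad = reasons != ""
    rejected = df.loc[bad].copy()
    rejected["reason"] = reasons[bad]
    rejected["row"] = rejected.index + 1  # 1-based data-row numbers
    return df.loc[~bad].copy(), rejected


def read_cohort(path: str | Path, strict: bool = False) -> Cohort:
    """Read and validate a cohort CSV.

    Row-level dictionary violations are collected into ``cohort.rejected``
    (with 1-based row numbers and reasons) unless ``strict``, in which case
    the first violation raises. Unknown or missing required columns raise
    :class:`SchemaError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    provenance = "real"
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("# provenance:"):
        provenance = first.split(":", 1)[1].strip()
    try:
        df = pd.read_csv(path, comment="#", dtype={"patient_id": str})
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path} is empty") from None
    if df.columns.size == 0 or len(df) == 0 and df.columns.size < len(REQUIRED_COLUMNS):
        raise SchemaError(f"{path} has no usable header")
    unknown = set(df.columns) - set(SCHEMA)
    if unknown:
        raise SchemaError(f"unknown columns: {sorted(unknown)}")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing required columns: {sorted(missing)}")
    valid, rejected = _validate_rows(df)
    if strict and len(rejected):
        first_bad = rejected.iloc[0]
        raise InvalidInputError(f"row {first_bad['row']}: {first_bad['reason']}")
    for col in ("dm", "htn", "ihd", "cvd", "epo", "adm_vascular", "adm_nonvascular", "died"):
        valid[col] = valid[col].astype(int)
    return Cohort(data=valid.reset_index(drop=True), provenance=provenance, rejected=rejected)


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort CSV (provenance preserved in a leading comment line)."""
    if cohort.n == 0:
        raise InvalidInputError("refusing to write an empty cohort")
    path = Path(path)
    cols = [c for c in SCHEMA if c in cohort.data.columns]
    try:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# provenance: {cohort.provenance}\n")
            cohort.data.to_csv(fh, index=False, columns=cols)
    except OSError as exc:
        raise OSError(f"cannot write cohort to {path}: {exc}") from exc
    return path


@dataclass(frozen=True)
class FixtureTables:
    """The published aggregate cross-tabulations, as typed tables."""

    gender: TwoByTwoTable
    marital: ContingencyTable
    diabetes: TwoByTwoTable
    hypertension: TwoByTwoTable
    ihd: TwoByTwoTable
    epo: TwoByTwoTable
    mortality: TwoByTwoTable
    group_sizes: dict
    raw: dict


def load_fixtures() -> FixtureTables:
    """Load the packaged published counts (factor x risk group, deaths by group)."""
    raw = json.loads(
        resources.files("pewrisk").joinpath("data/table_counts.json").read_text()
    )
    t = raw["tables"]

    def two_by_two(name: str) -> TwoByTwoTable:
        (a, b), (c, d) = t[name]["counts"]
        return TwoByTwoTable(a, b, c, d)

    marital = ContingencyTable(
        counts=tuple(tuple(row) for row in t["marital"]["counts"]),
        row_labels=tuple(t["marital"]["rows"]),
        col_labels=tuple(raw["columns"]),
    )
    return FixtureTables(
        gender=two_by_two("gender"),
        marital=marital,
        diabetes=two_by_two("diabetes"),
        hypertension=two_by_two("hypertension"),
        ihd=two_by_two("ihd"),
        epo=two_by_two("epo"),
        mortality=two_by_two("mortality"),
        group_sizes=raw["group_sizes"],
        raw=raw,
    )


def export_fixtures_json(path: str | Path) -> Path:
    """Write the packaged counts to a JSON sidecar."""
    raw = json.loads(
        resources.files("pewrisk").joinpath("data/table_counts.json").read_text()
    )
    path = Path(path)
    path.write_text(json.dumps(raw, indent=2))
    return path
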