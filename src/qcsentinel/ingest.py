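"""Reading, validating and writing measurement reports and run logs.

Inputs are post-integration reports (delimited text) as exported from
chromatogram-integration software — one row per (run, precursor) with areas,
retention time, mass error and the M0/M+1/M+2 isotope-peak areas — plus a
run-metadata table declaring each run's type and batch. No science happens
here; everything downstream consumes the two validated containers.

Missing values are encoded as empty fields and mean "not measured", never
zero. Run order is acquisition time, ties broken by run id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "AnalyteClass",
    "RunType",
    "MeasurementTable",
    "RunLog",
    "DEFAULT_COLUMN_MAP",
    "parse_measurement_report",
    "parse_run_log",
    "write_table",
]


class AnalyteClass(str, Enum):
    SUITABILITY_PEPTIDE = "SUITABILITY_PEPTIDE"
    PROTEIN_IQC = "PROTEIN_IQC"
    PEPTIDE_IQC = "PEPTIDE_IQC"
    ENDOGENOUS = "ENDOGENOUS"


class RunType(str, Enum):
    SYSTEM_SUITABILITY = "SYSTEM_SUITABILITY"
    SAMPLE = "SAMPLE"
    EXTERNAL_QC_INTERBATCH = "EXTERNAL_QC_INTERBATCH"
    EXTERNAL_QC_INTEREXPERIMENT = "EXTERNAL_QC_INTEREXPERIMENT"


MEASUREMENT_COLUMNS = [
    "run_id",
    "acquired_at",
    "analyte_id",
    "analyte_class",
    "precursor_area",
    "transition_area",
    "rt_min",
    "mass_error_ppm",
    "iso_m0",
    "iso_m1",
    "iso_m2",
]

RUNLOG_COLUMNS = [
    "run_id",
    "acquired_at",
    "run_type",
    "batch_id",
    "prep_arm",
    "annotation",
    "truth_event",
]

_ISO_COLS = ["iso_m0", "iso_m1", "iso_m2"]
_AREA_COLS = ["precursor_area", "transition_area", "iso_m0", "iso_m1", "iso_m2"]

# Default mapping from semantic fields to "Transition Results"-style export
# column names. "analyte_id" may instead be assembled from peptide + charge.
DEFAULT_COLUMN_MAP = {
    "run_id": "Replicate",
    "acquired_at": "Acquired Time",
    "peptide": "Peptide",
    "charge": "Precursor Charge",
    "analyte_class": "Analyte Class",
    "precursor_area": "Total Area",
    "transition_area": "Total Area Fragment",
    "rt_min": "Retention Time",
    "mass_error_ppm": "Average Mass Error PPM",
    "iso_m0": "Isotope Area M0",
    "iso_m1": "Isotope Area M+1",
    "iso_m2": "Isotope Area M+2",
}


def _sorted_measurements(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(
        ["acquired_at", "run_id", "analyte_id"], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class MeasurementTable:
    """Long-format per-run, per-analyte observations; the universal exchange unit."""

    data: pd.DataFrame

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, runlog: "RunLog | None" = None) -> "MeasurementTable":
        missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df[MEASUREMENT_COLUMNS].copy()
        df["acquired_at"] = pd.to_datetime(df["acquired_at"])
        df["analyte_class"] = df["analyte_class"].map(lambda v: AnalyteClass(v).value)
        for col in _AREA_COLS:
            df[col] = pd.to_numeric(df[col])
            bad = df.index[df[col] < 0]
            if len(bad):
                raise ValidationError(f"negative {col} at row index {bad[0]}")
        dup = df.duplicated(subset=["run_id", "analyte_id"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["run_id", "analyte_id"]].tolist()
            raise ValidationError(f"duplicate (run_id, analyte_id) pair: {tuple(pair)}")
        iso_na = df[_ISO_COLS].isna()
        partial = iso_na.any(axis=1) & ~iso_na.all(axis=1)
        if partial.any():
            raise ValidationError(
                f"isotope areas must be all present or all absent (row index {int(partial.idxmax())})"
            )
        if runlog is not None:
            unknown = set(df["run_id"]) - set(runlog.data["run_id"])
            if unknown:
                raise ValidationError(f"run_id(s) absent from run log: {sorted(unknown)[:5]}")
        return cls(_sorted_measurements(df))

    def to_frame(self) -> pd.DataFrame:
        return self.data.copy()

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class RunLog:
    """Per-run metadata: type, timestamp, batch, optional arm/annotation/truth label."""

    data: pd.DataFrame

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RunLog":
        required = ["run_id", "acquired_at", "run_type", "batch_id"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df.copy()
        for opt in ("prep_arm", "annotation", "truth_event"):
            if opt not in df.columns:
                df[opt] = pd.NA
            df[opt] = df[opt].astype("string")
        df = df[RUNLOG_COLUMNS]
        df["acquired_at"] = pd.to_datetime(df["acquired_at"])
        allowed = [t.value for t in RunType]

        def norm_type(v) -> str:
            s = str(v).strip().upper()
            if s not in allowed:
                raise ValidationError(
                    f"unknown run_type {v!r}; allowed values: {', '.join(allowed)}"
                )
            return s

        df["run_type"] = df["run_type"].map(norm_type)
        if df["run_id"].duplicated().any():
            raise ValidationError("duplicate run_id in run log")
        df = df.sort_values(["acquired_at", "run_id"], kind="mergesort").reset_index(drop=True)
        return cls(df)

    def to_frame(self) -> pd.DataFrame:
        return self.data.copy()

    def run_ids(self, run_types: set[RunType] | None = None) -> list[str]:
        df = self.data
        if run_types is not None:
            wanted = {t.value for t in run_types}
            df = df[df["run_type"].isin(wanted)]
        return df["run_id"].tolist()

    def __len__(self) -> int:
        return len(self.data)


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        if isinstance(payload, dict) and "records" in payload:
            return pd.DataFrame(payload["records"], columns=payload.get("columns"))
        return pd.DataFrame(payload)
    return pd.read_csv(path, sep=None, engine="python")


def parse_measurement_report(path, column_map: dict[str, str] | None = None) -> MeasurementTable:
    """Read a delimited measurement report into a validated MeasurementTable.

    ``column_map`` maps semantic field names to source column names; it
    defaults to the package's canonical names when present in the file, else
    to DEFAULT_COLUMN_MAP ("Transition Results"-style). ``analyte_id`` may be
    given directly or assembled from ``peptide`` + ``charge`` columns.
    ``analyte_class`` falls back to ENDOGENOUS when unmapped.
    """
    raw = _read_delimited(path)
    if column_map is None:
        if all(c in raw.columns for c in MEASUREMENT_COLUMNS):
            column_map = {c: c for c in MEASUREMENT_COLUMNS}
        else:
            column_map = dict(DEFAULT_COLUMN_MAP)
    df = pd.DataFrame(index=raw.index)
    for field in MEASUREMENT_COLUMNS:
        if field == "analyte_id" and "analyte_id" not in column_map:
            for part in ("peptide", "charge"):
                src = column_map.get(part)
                if src is None or src not in raw.columns:
                    raise SchemaError(f"missing required column: {part} ({src!r})")
            df["analyte_id"] = (
                raw[column_map["peptide"]].astype(str)
                + "/"
                + raw[column_map["charge"]].astype(int).astype(str)
            )
            continue
        src = column_map.get(field)
        if src is None or src not in raw.columns:
            if field == "analyte_class":
                df["analyte_class"] = AnalyteClass.ENDOGENOUS.value
                continue
            raise SchemaError(f"missing required column: {field}" + (f" ({src!r})" if src else ""))
        df[field] = raw[src]
    return MeasurementTable.from_dataframe(df)


def parse_run_log(path) -> RunLog:
    """Read a delimited run log; run_type matched case-insensitively."""
    return RunLog.from_dataframe(_read_delimited(path))


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    if hasattr(table, "to_frame"):
        return table.to_frame()
    raise TypeError(f"cannot serialize object of type {type(table).__name__}")


def write_table(table, path, format: str = "TSV") -> None:
    """Write any result table as TSV (tab, '.' decimal, ISO-8601) or JSON records.

    Floats are written with 12 significant digits so a write/parse round trip
    reproduces values to better than 1e-9 relative.
    """
    df = _as_frame(table).copy()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = format.upper()
    for col in df.columns:
        if pd.api.types.is_datetime64_any_dtype(df[col]):
            df[col] = df[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    if fmt == "TSV":
        df.to_csv(path, sep="\t", index=False, float_format="%.12g", lineterminator="\n")
    elif fmt == "JSON":
        records = json.loads(df.to_json(orient="records", double_precision=15))
        path.write_text(json.dumps({"columns": list(df.columns), "records": records}, indent=1))
    else:
        raise ValueError("format must be 'TSV' or 'JSON'")
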