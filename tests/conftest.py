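import numpy as np
import pandas as pd
import pytest

from qcsentinel.ingest import AnalyteClass, MeasurementTable, RunLog, RunType


def make_runlog(rows):
    """rows: list of (run_id, run_type, batch_id) or dicts."""
    recs = []
    for i, r in enumerate(rows):
        if isinstance(r, dict):
            rec = dict(r)
        else:
            rec = {"run_id": r[0], "run_type": r[1], "batch_id": r[2]}
        rec.setdefault("acquired_at", pd.Timestamp("2024-03-01") + i * pd.Timedelta(hours=1))
        recs.append(rec)
    return RunLog.from_dataframe(pd.DataFrame(recs))


def make_table(rows, runlog=None):
    """rows: dicts with at least run_id, analyte_id; the rest defaulted."""
    recs = []
    for i, r in enumerate(rows):
        rec = {
            "acquired_at": pd.Timestamp("2024-03-01") + i * pd.Timedelta(minutes=10),
            "analyte_class": AnalyteClass.SUITABILITY_PEPTIDE.value,
            "precursor_area": 1000.0,
            "transition_area": 700.0,
            "rt_min": 10.0,
            "mass_error_ppm": 0.5,
            "iso_m0": 600.0,
            "iso_m1": 300.0,
            "iso_m2": 100.0,
        }
        rec.update(r)
        recs.append(rec)
    df = pd.DataFrame(recs)
    if runlog is not None:
        df = df.drop(columns=["acquired_at"]).merge(
            runlog.data[["run_id", "acquired_at"]], on="run_id", how="left"
        )
    return MeasurementTable.from_dataframe(df, runlog)


@pytest.fixture
def three_run_suitability():
    runlog = make_runlog(
        [("SS001", "SYSTEM_SUITABILITY", "B01"), ("SS002", "SYSTEM_SUITABILITY", "B01"),
         ("SS003", "SYSTEM_SUITABILITY", "B01")]
    )
    table = make_table(
        [
            {"run_id": rid, "analyte_id": "GISNEGQNASIK/2", "transition_area": area}
            for rid, area in [("SS001", 700.0), ("SS002", 710.0), ("SS003", 690.0)]
        ],
        runlog,
    )
    return table, runlog
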