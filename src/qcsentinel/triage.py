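"""Per-run failure triage from internal QCs and system-suitability context.

The logic exploits the asymmetry of the two internal QCs: the protein IQC
(ENO, spiked before digestion) sees the whole preparation, while the peptide
IQC (PRTC, spiked just before injection) sees only the LC-MS system. Combined
with retention-time shifts, isotope-envelope scores and the state of recent
system-suitability runs, each sample run is classified by the first matching
rule:

R1 ISOTOPE_ENVELOPE_LOSS — envelope degraded while intensities are normal
   (evaluated first: intensity metrics alone miss this failure);
R2 SAMPLE_PREP_FAILURE   — protein IQC lost, peptide IQC normal;
R3 INJECTION_LC_EVENT    — both IQCs low AND late retention, isolated run;
R4 MS_SENSITIVITY_LOSS   — peptide IQC low/declining, suitability degraded;
R5 SYSTEM_CHECK_NEEDED   — same intensity evidence, suitability not (yet)
   degraded: queue suitability runs to confirm.

Medians across the analytes of each class make the summaries robust to a
single badly behaving peptide. All thresholds are configuration with
documented defaults; none is derived from data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .analytes import expected_envelope
from .errors import ConfigurationError, InsufficientDataError
from .ingest import AnalyteClass, MeasurementTable, RunLog, RunType
from .spc import Baseline, Flag, Metric, establish_baseline, extract_metric, levey_jennings

__all__ = [
    "SsStatus",
    "TriageCallKind",
    "TriageConfig",
    "IqcBaselines",
    "RunIqcSummary",
    "TriageCall",
    "TriageReport",
    "build_iqc_baselines",
    "summarize_internal_qc",
    "classify_run",
    "triage_experiment",
]

_SAMPLE_LIKE = {
    RunType.SAMPLE.value,
    RunType.EXTERNAL_QC_INTERBATCH.value,
    RunType.EXTERNAL_QC_INTEREXPERIMENT.value,
}


class SsStatus(str, Enum):
    OK = "OK"
    DEGRADED = "DEGRADED"
    UNKNOWN = "UNKNOWN"


class TriageCallKind(str, Enum):
    PASS = "PASS"
    SAMPLE_PREP_FAILURE = "SAMPLE_PREP_FAILURE"
    INJECTION_LC_EVENT = "INJECTION_LC_EVENT"
    MS_SENSITIVITY_LOSS = "MS_SENSITIVITY_LOSS"
    ISOTOPE_ENVELOPE_LOSS = "ISOTOPE_ENVELOPE_LOSS"
    SYSTEM_CHECK_NEEDED = "SYSTEM_CHECK_NEEDED"


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds of the triage rules (engineering defaults, all configurable).

    low_ratio: an IQC class is "lost" below this fraction of its baseline mean.
    rt_tol: retention shift (minutes) implicating the LC path.
    idotp_min: isotope dot product below which the envelope counts as degraded.
    decline_runs / decline_ratio: a run of this many strictly decreasing
        peptide-IQC ratios ending below decline_ratio also counts as intensity
        evidence (catches decay before it crosses low_ratio).
    prtc_z_tol: |peptide-IQC z| bound under which the spike is "consistent".
    ss_window: how many recent suitability runs define the system status.
    """

    low_ratio: float = 0.5
    rt_tol: float = 2.0
    idotp_min: float = 0.90
    decline_runs: int = 3
    decline_ratio: float = 0.7
    prtc_z_tol: float = 2.0
    ss_window: int = 3


@dataclass
class IqcBaselines:
    """Per-analyte transition-area and retention-time baselines from guide runs."""

    area: dict[str, Baseline]
    rt: dict[str, Baseline]
    analyte_class: dict[str, str]
    guide_run_ids: list[str]


@dataclass
class RunIqcSummary:
    run_id: str
    acquired_at: pd.Timestamp
    batch_id: str
    eno_z: float | None
    prtc_z: float | None
    eno_ratio: float | None
    prtc_ratio: float | None
    rt_shift_min: float | None
    min_idotp: float | None
    ss_status: SsStatus


@dataclass
class TriageCall:
    run_id: str
    call: TriageCallKind
    rule_id: str | None
    evidence: dict = field(default_factory=dict)


@dataclass
class TriageReport:
    calls: pd.DataFrame  # run_id, acquired_at, batch_id, call, rule_id, evidence
    summaries: pd.DataFrame
    batch_counts: pd.DataFrame
    ss_timeline: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.calls.copy()


def build_iqc_baselines(
    table: MeasurementTable,
    runlog: RunLog,
    guide_run_ids: list[str] | None = None,
    first_k: int = 10,
    min_guide: int = 5,
) -> IqcBaselines:
    """Baselines for every internal-QC analyte from early sample-type runs.

    The guide set defaults to the first ``first_k`` sample/external-QC runs in
    acquisition order; pass an explicit in-control list when the head of the
    series is suspect.
    """
    rl = runlog.data
    sample_runs = rl[rl["run_type"].isin(_SAMPLE_LIKE)]
    if guide_run_ids is None:
        guide_run_ids = sample_runs["run_id"].head(first_k).tolist()
    guide_set = set(guide_run_ids)
    df = table.data
    iqc = df[
        df["analyte_class"].isin((AnalyteClass.PROTEIN_IQC.value, AnalyteClass.PEPTIDE_IQC.value))
    ]
    area: dict[str, Baseline] = {}
    rt: dict[str, Baseline] = {}
    classes: dict[str, str] = {}
    for aid, grp in iqc.groupby("analyte_id", sort=True):
        g = grp[grp["run_id"].isin(guide_set)]
        if len(g) < min_guide:
            continue
        v = g["transition_area"].to_numpy(dtype=float)
        r = g["rt_min"].to_numpy(dtype=float)
        ids = g["run_id"].tolist()
        area[aid] = Baseline(float(v.mean()), float(v.std(ddof=1)), len(v), ids)
        rt[aid] = Baseline(float(r.mean()), float(r.std(ddof=1)), len(r), ids)
        classes[aid] = grp["analyte_class"].iloc[0]
    if not any(c == AnalyteClass.PROTEIN_IQC.value for c in classes.values()) or not any(
        c == AnalyteClass.PEPTIDE_IQC.value for c in classes.values()
    ):
        raise ConfigurationError(
            "baselines require at least one PROTEIN_IQC and one PEPTIDE_IQC analyte with enough guide runs"
        )
    return IqcBaselines(area, rt, classes, guide_run_ids)


def _suitability_fail_timeline(
    table: MeasurementTable, runlog: RunLog, first_k: int = 10, min_guide: int = 5
) -> pd.DataFrame:
    """Per-suitability-run FAIL status: Levey-Jennings on transition area,
    a run fails when at least half the suitability analytes fail."""
    rl = runlog.data
    ss = rl[rl["run_type"] == RunType.SYSTEM_SUITABILITY.value]
    if ss.empty:
        return pd.DataFrame(columns=["run_id", "acquired_at", "n_fail", "n_analytes", "failed"])
    df = table.data
    suit_ids = sorted(
        df[df["analyte_class"] == AnalyteClass.SUITABILITY_PEPTIDE.value]["analyte_id"].unique()
    )
    fail_counts: dict[str, int] = {rid: 0 for rid in ss["run_id"]}
    n_used = 0
    for aid in suit_ids:
        try:
            series = extract_metric(
                table, runlog, Metric.TRANSITION_AREA, aid, {RunType.SYSTEM_SUITABILITY}
            )
            base = establish_baseline(series, first_k=first_k, min_guide=min_guide)
        except InsufficientDataError:
            continue
        n_used += 1
        chart = levey_jennings(series, base)
        failed = chart.data.loc[chart.data["flag"] == Flag.FAIL.value, "run_id"]
        for rid in failed:
            fail_counts[rid] += 1
    out = ss[["run_id", "acquired_at"]].copy().reset_index(drop=True)
    out["n_fail"] = out["run_id"].map(fail_counts)
    out["n_analytes"] = n_used
    out["failed"] = (n_used > 0) & (out["n_fail"] >= n_used / 2.0)
    return out


def _median_or_none(values: np.ndarray) -> float | None:
    values = values[~np.isnan(values)]
    return float(np.median(values)) if len(values) else None


def summarize_internal_qc(
    table: MeasurementTable,
    runlog: RunLog,
    baselines: IqcBaselines,
    ss_window: int = 3,
) -> list[RunIqcSummary]:
    """One summary per sample/external-QC run, in acquisition order.

    Per run: median z and median ratio-to-baseline of the transition areas of
    each IQC class, median RT deviation and minimum idotp across both classes,
    plus the suitability status derived from the last ``ss_window``
    suitability runs at or before the run.
    """
    rl = runlog.data
    runs = rl[rl["run_type"].isin(_SAMPLE_LIKE)].reset_index(drop=True)
    df = table.data
    iqc = df[df["analyte_id"].isin(baselines.area.keys())].copy()
    iqc = iqc[iqc["run_id"].isin(set(runs["run_id"]))]

    mean_map = {a: b.mean for a, b in baselines.area.items()}
    sd_map = {a: b.sd for a, b in baselines.area.items()}
    rt_map = {a: b.mean for a, b in baselines.rt.items()}
    iqc["base_mean"] = iqc["analyte_id"].map(mean_map)
    iqc["base_sd"] = iqc["analyte_id"].map(sd_map)
    with np.errstate(divide="ignore", invalid="ignore"):
        iqc["z"] = (iqc["transition_area"] - iqc["base_mean"]) / iqc["base_sd"]
        iqc["ratio"] = iqc["transition_area"] / iqc["base_mean"]
    iqc["rt_dev"] = iqc["rt_min"] - iqc["analyte_id"].map(rt_map)

    has_iso = iqc["iso_m0"].notna()
    idotp_vals = np.full(len(iqc), np.nan)
    if has_iso.any():
        sub = iqc[has_iso]
        envs = np.stack([expected_envelope(aid) for aid in sub["analyte_id"]])
        iso = sub[["iso_m0", "iso_m1", "iso_m2"]].to_numpy(dtype=float)
        norms = np.linalg.norm(iso, axis=1) * np.linalg.norm(envs, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.clip(np.einsum("ij,ij->i", iso, envs) / norms, 0.0, 1.0)
        idotp_vals[has_iso.to_numpy()] = scores
    iqc["idotp"] = idotp_vals

    ss = _suitability_fail_timeline(table, runlog)
    ss_times = ss["acquired_at"].to_numpy() if len(ss) else np.array([], dtype="datetime64[ns]")
    ss_failed = ss["failed"].to_numpy() if len(ss) else np.array([], dtype=bool)

    is_prot = iqc["analyte_class"] == AnalyteClass.PROTEIN_IQC.value
    summaries: list[RunIqcSummary] = []
    grouped = dict(tuple(iqc.groupby("run_id")))
    for _, run in runs.iterrows():
        g = grouped.get(run["run_id"])
        if g is None:
            continue
        prot = g[g["analyte_class"] == AnalyteClass.PROTEIN_IQC.value]
        pep = g[g["analyte_class"] == AnalyteClass.PEPTIDE_IQC.value]
        n_before = int(np.searchsorted(ss_times, np.datetime64(run["acquired_at"]), side="right"))
        if n_before == 0:
            status = SsStatus.UNKNOWN
        else:
            window = ss_failed[max(0, n_before - ss_window) : n_before]
            status = SsStatus.DEGRADED if window.any() else SsStatus.OK
        idotp_known = g["idotp"].dropna()
        summaries.append(
            RunIqcSummary(
                run_id=run["run_id"],
                acquired_at=run["acquired_at"],
                batch_id=run["batch_id"],
                eno_z=_median_or_none(prot["z"].to_numpy(dtype=float)),
                prtc_z=_median_or_none(pep["z"].to_numpy(dtype=float)),
                eno_ratio=_median_or_none(prot["ratio"].to_numpy(dtype=float)),
                prtc_ratio=_median_or_none(pep["ratio"].to_numpy(dtype=float)),
                rt_shift_min=_median_or_none(g["rt_dev"].to_numpy(dtype=float)),
                min_idotp=float(idotp_known.min()) if len(idotp_known) else None,
                ss_status=status,
            )
        )
    return summaries


def _pass_like(s: RunIqcSummary | None, cfg: TriageConfig) -> bool:
    if s is None:
        return True  # boundary runs treated as pass-like
    ok = True
    if s.eno_ratio is not None:
        ok &= s.eno_ratio >= cfg.low_ratio
    if s.prtc_ratio is not None:
        ok &= s.prtc_ratio >= cfg.low_ratio
    return ok


def classify_run(
    summary: RunIqcSummary,
    prev: list[RunIqcSummary] | tuple[RunIqcSummary, ...] = (),
    next_summary: RunIqcSummary | None = None,
    config: TriageConfig = TriageConfig(),
) -> TriageCall:
    """First matching rule wins; fields that are undefined skip their rules.

    ``prev`` is the list of earlier summaries in acquisition order (the last
    entry is the immediate predecessor); it feeds both the R3 neighbor check
    and the R4/R5 decline detector.
    """
    cfg = config
    eno, prtc = summary.eno_ratio, summary.prtc_ratio
    # R1: envelope degraded while intensities normal
    if (
        summary.min_idotp is not None
        and summary.min_idotp < cfg.idotp_min
        and eno is not None
        and prtc is not None
        and eno >= cfg.low_ratio
        and prtc >= cfg.low_ratio
    ):
        return TriageCall(
            summary.run_id,
            TriageCallKind.ISOTOPE_ENVELOPE_LOSS,
            "R1",
            {"min_idotp": summary.min_idotp, "eno_ratio": eno, "prtc_ratio": prtc},
        )
    # R2: protein IQC lost, peptide IQC consistent
    if (
        eno is not None
        and eno < cfg.low_ratio
        and summary.prtc_z is not None
        and abs(summary.prtc_z) <= cfg.prtc_z_tol
    ):
        return TriageCall(
            summary.run_id,
            TriageCallKind.SAMPLE_PREP_FAILURE,
            "R2",
            {"eno_ratio": eno, "prtc_z": summary.prtc_z},
        )
    # R3: isolated low-intensity + late-RT run
    if (
        eno is not None
        and prtc is not None
        and eno < cfg.low_ratio
        and prtc < cfg.low_ratio
        and summary.rt_shift_min is not None
        and abs(summary.rt_shift_min) > cfg.rt_tol
        and _pass_like(prev[-1] if prev else None, cfg)
        and _pass_like(next_summary, cfg)
    ):
        return TriageCall(
            summary.run_id,
            TriageCallKind.INJECTION_LC_EVENT,
            "R3",
            {"eno_ratio": eno, "prtc_ratio": prtc, "rt_shift_min": summary.rt_shift_min},
        )
    # R4/R5: peptide-IQC intensity evidence, split on suitability status
    declining = False
    if prtc is not None and len(prev) >= cfg.decline_runs - 1:
        seq = [s.prtc_ratio for s in prev[-(cfg.decline_runs - 1) :]] + [prtc]
        if all(v is not None for v in seq):
            declining = all(a > b for a, b in zip(seq, seq[1:])) and seq[-1] < cfg.decline_ratio
    intensity_evidence = (prtc is not None and prtc < cfg.low_ratio) or declining
    if intensity_evidence:
        evidence = {
            "prtc_ratio": prtc,
            "declining": declining,
            "ss_status": summary.ss_status.value,
        }
        if summary.ss_status is SsStatus.DEGRADED:
            return TriageCall(summary.run_id, TriageCallKind.MS_SENSITIVITY_LOSS, "R4", evidence)
        return TriageCall(summary.run_id, TriageCallKind.SYSTEM_CHECK_NEEDED, "R5", evidence)
    return TriageCall(summary.run_id, TriageCallKind.PASS, None, {})


def triage_experiment(
    table: MeasurementTable,
    runlog: RunLog,
    baselines: IqcBaselines | None = None,
    config: TriageConfig = TriageConfig(),
) -> TriageReport:
    """Classify every sample/external-QC run of an experiment.

    Deterministic given inputs. Baselines default to the first 10 sample-type
    runs; the suitability timeline used for the status calls is included in
    the report.
    """
    rl = runlog.data
    if not rl["run_type"].isin(_SAMPLE_LIKE).any():
        warnings.warn("no sample or external-QC runs to triage; empty report", stacklevel=2)
        empty = pd.DataFrame(columns=["run_id", "acquired_at", "batch_id", "call", "rule_id", "evidence"])
        return TriageReport(empty, pd.DataFrame(), pd.DataFrame(), pd.DataFrame())
    if baselines is None:
        baselines = build_iqc_baselines(table, runlog)
    summaries = summarize_internal_qc(table, runlog, baselines, ss_window=config.ss_window)
    calls: list[TriageCall] = []
    for i, s in enumerate(summaries):
        nxt = summaries[i + 1] if i + 1 < len(summaries) else None
        calls.append(classify_run(s, summaries[:i], nxt, config))
    calls_df = pd.DataFrame(
        {
            "run_id": [c.run_id for c in calls],
            "acquired_at": [s.acquired_at for s in summaries],
            "batch_id": [s.batch_id for s in summaries],
            "call": [c.call.value for c in calls],
            "rule_id": [c.rule_id for c in calls],
            "evidence": [json.dumps(c.evidence, sort_keys=True) for c in calls],
        }
    )
    summaries_df = pd.DataFrame(
        {
            "run_id": [s.run_id for s in summaries],
            "eno_z": [s.eno_z for s in summaries],
            "prtc_z": [s.prtc_z for s in summaries],
            "eno_ratio": [s.eno_ratio for s in summaries],
            "prtc_ratio": [s.prtc_ratio for s in summaries],
            "rt_shift_min": [s.rt_shift_min for s in summaries],
            "min_idotp": [s.min_idotp for s in summaries],
            "ss_status": [s.ss_status.value for s in summaries],
        }
    )
    batch_counts = (
        calls_df.groupby(["batch_id", "call"]).size().rename("n").reset_index()
    )
    ss_timeline = _suitability_fail_timeline(table, runlog)
    return TriageReport(calls_df, summaries_df, batch_counts, ss_timeline)
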