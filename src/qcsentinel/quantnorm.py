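"""The level-1/2/3 abundance ladder and external-QC CV assessment.

Level 1 is the raw linear-scale area matrix (analytes × runs). Level 2 is
log2-transformed and median-normalized: each run's median is shifted to the
grand median of run medians, removing per-run loading/injection scale. Level 3
additionally removes batch effects by per-analyte location adjustment: within
each analyte, subtract the batch mean and restore the analyte grand mean (a
transparent, variance-preserving alternative to empirical-Bayes adjustment,
sufficient for location-type batch effects; an optional switch also equalizes
batch SDs).

External-QC coefficients of variation quantify what each rung buys: CVs are
computed on the linear scale (back-transforming log2 matrices), summarized by
the median CV across analytes (η), per batch (intra-batch), across batches
(inter-batch), or across experiments. A LOESS curve of CV against log2 median
abundance shows the abundance dependence of precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import InsufficientDataError, ValidationError
from .ingest import MeasurementTable, RunLog, RunType

__all__ = [
    "Level",
    "AnalyteKind",
    "CvScope",
    "QuantMatrix",
    "CVTable",
    "LevelComparison",
    "build_matrix",
    "log2_median_normalize",
    "batch_adjust",
    "rollup_proteins",
    "compute_cv",
    "cv_abundance_curve",
    "assess_levels",
]


class Level(str, Enum):
    L1_RAW = "L1_RAW"
    L2_NORMALIZED = "L2_NORMALIZED"
    L3_BATCH_ADJUSTED = "L3_BATCH_ADJUSTED"


class AnalyteKind(str, Enum):
    PEPTIDE = "PEPTIDE"
    PROTEIN = "PROTEIN"


class CvScope(str, Enum):
    INTRA_BATCH = "INTRA_BATCH"
    INTER_BATCH = "INTER_BATCH"
    INTER_EXPERIMENT = "INTER_EXPERIMENT"


@dataclass
class QuantMatrix:
    """Analytes × runs abundance matrix tagged with processing level and batch map.

    Level 1 holds linear areas (missing = not measured, never 0); levels 2-3
    hold log2 values. ``provenance`` records each transformation applied.
    """

    values: pd.DataFrame  # index: analyte_id, columns: run_id
    level: Level
    batch_of: pd.Series  # run_id -> batch_id
    analyte_kind: AnalyteKind = AnalyteKind.PEPTIDE
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.batch_of.index)
        if missing:
            raise ValidationError(f"batch map missing runs: {sorted(missing)[:5]}")

    @property
    def is_log2(self) -> bool:
        return self.level is not Level.L1_RAW

    def linear_values(self) -> pd.DataFrame:
        return np.exp2(self.values) if self.is_log2 else self.values

    def to_frame(self) -> pd.DataFrame:
        df = self.values.copy()
        df.insert(0, "analyte_id", df.index)
        return df.reset_index(drop=True)


@dataclass
class CVTable:
    """Per-analyte CV% and log2 median abundance for one scope; η = median CV."""

    data: pd.DataFrame  # analyte_id, scope, batch_id, cv_percent, log2_median_abundance, n_obs
    scope: CvScope
    median_cv_eta: float
    min_obs: int

    def to_frame(self) -> pd.DataFrame:
        return self.data.copy()


@dataclass
class LevelComparison:
    etas: pd.DataFrame  # level, scope, analyte_kind, median_cv_eta
    deltas: pd.DataFrame  # transition, scope, analyte_kind, delta_eta
    flagged: pd.DataFrame  # transitions that increased η

    def to_frame(self) -> pd.DataFrame:
        return self.etas.copy()


def build_matrix(
    table: MeasurementTable,
    runlog: RunLog,
    run_filter: set[RunType] = frozenset({RunType.EXTERNAL_QC_INTERBATCH}),
    quantity: str = "TRANSITION_AREA",
) -> QuantMatrix:
    """Pivot the long table into a level-1 matrix over the selected run types.

    Zero areas are recorded as missing: a zero from integration software means
    "nothing integrated", which the ladder must not conflate with a measured
    abundance.
    """
    col = {"TRANSITION_AREA": "transition_area", "PRECURSOR_AREA": "precursor_area"}[
        str(quantity).upper()
    ]
    wanted = {RunType(t).value for t in run_filter}
    rl = runlog.data[runlog.data["run_type"].isin(wanted)]
    run_order = rl["run_id"].tolist()
    if len(run_order) < 2:
        raise InsufficientDataError("need >= 2 runs in the selected run types")
    df = table.data[table.data["run_id"].isin(set(run_order))]
    if df.empty:
        raise InsufficientDataError("no measurements in the selected runs")
    values = df.pivot(index="analyte_id", columns="run_id", values=col)
    values = values.reindex(columns=run_order).replace(0.0, np.nan)
    values = values.sort_index()
    batch_of = rl.set_index("run_id")["batch_id"]
    return QuantMatrix(values, Level.L1_RAW, batch_of, AnalyteKind.PEPTIDE, ["build_matrix"])


def log2_median_normalize(m: QuantMatrix, min_obs: int = 10) -> QuantMatrix:
    """Level 1 → level 2: log2 transform, then equalize per-run medians.

    Each run's median (over its observed values) is shifted to the grand
    median of run medians, keeping values in the original intensity register.
    Runs with fewer than ``min_obs`` observed values are refused.
    """
    if m.level is not Level.L1_RAW:
        raise ValidationError("log2_median_normalize expects a level-1 matrix")
    counts = m.values.notna().sum(axis=0)
    bad = counts[counts < min_obs]
    if len(bad):
        raise InsufficientDataError(
            f"runs below min_obs={min_obs} observed values: {', '.join(bad.index)}"
        )
    log2v = np.log2(m.values)
    run_medians = log2v.median(axis=0)
    grand = float(run_medians.median())
    out = log2v.subtract(run_medians - grand, axis=1)
    return QuantMatrix(
        out, Level.L2_NORMALIZED, m.batch_of, m.analyte_kind,
        [*m.provenance, f"log2_median_normalize(grand_median={grand:.6g})"],
    )


def batch_adjust(m: QuantMatrix, min_per_batch: int = 2, scale_adjust: bool = False) -> QuantMatrix:
    """Level 2 → level 3: per-analyte batch location adjustment.

    For each analyte, subtract the batch mean and restore the analyte grand
    mean (over all observed cells), so batch means coincide while within-batch
    deviations — and hence within-batch variances — are untouched. Analytes
    with fewer than ``min_per_batch`` observations in some batch are passed
    through unadjusted and listed in provenance. With ``scale_adjust`` the
    within-batch SDs are additionally equalized to the pooled SD.
    """
    if m.level is not Level.L2_NORMALIZED:
        raise ValidationError("batch_adjust expects a level-2 matrix")
    batches = m.batch_of.reindex(m.values.columns)
    if batches.nunique() < 2:
        warnings.warn("single batch: batch adjustment is a no-op", stacklevel=2)
        return QuantMatrix(
            m.values.copy(), Level.L3_BATCH_ADJUSTED, m.batch_of, m.analyte_kind,
            [*m.provenance, "batch_adjust(noop_single_batch)"],
        )
    values = m.values
    # per (analyte, batch) observation counts
    counts = values.notna().T.groupby(batches).sum().T
    adjustable = (counts >= min_per_batch).all(axis=1)
    skipped = values.index[~adjustable].tolist()

    batch_means = values.T.groupby(batches).mean().T  # analyte × batch
    grand = values.mean(axis=1)
    centered = values.subtract(batch_means.loc[:, batches.values].set_axis(values.columns, axis=1))
    if scale_adjust:
        batch_sd = values.T.groupby(batches).std(ddof=1).T
        pooled = values.sub(batch_means.loc[:, batches.values].set_axis(values.columns, axis=1)).std(
            axis=1, ddof=1
        )
        factor = pooled.to_numpy()[:, None] / batch_sd.loc[:, batches.values].set_axis(
            values.columns, axis=1
        )
        centered = centered * factor
    out = centered.add(grand, axis=0)
    out.loc[skipped] = values.loc[skipped]
    prov = [*m.provenance, f"batch_adjust(location{', scale' if scale_adjust else ''})"]
    if skipped:
        prov.append(f"batch_adjust_skipped={','.join(map(str, skipped[:20]))}")
    return QuantMatrix(out, Level.L3_BATCH_ADJUSTED, m.batch_of, m.analyte_kind, prov)


def rollup_proteins(
    m: QuantMatrix, mapping: dict[str, str], min_peptides: int = 1
) -> QuantMatrix:
    """Peptide → protein roll-up.

    Levels 2-3: protein value per run is the mean of the protein's observed
    peptide log2 values. Level 1: the sum of the linear peptide areas.
    Proteins with fewer than ``min_peptides`` mapped peptides are dropped.
    The method is recorded in provenance; protein results are comparable only
    within one roll-up scheme.
    """
    if not mapping:
        raise ValidationError("empty peptide-to-protein mapping")
    mapped = m.values.index.intersection(mapping.keys())
    if len(mapped) == 0:
        raise ValidationError("mapping covers no analytes in the matrix")
    prot_of = pd.Series({p: mapping[p] for p in mapped})
    sub = m.values.loc[mapped]
    n_peps = prot_of.groupby(prot_of).size()
    keep = n_peps[n_peps >= min_peptides].index
    sub = sub[prot_of.isin(keep)]
    prot_of = prot_of[prot_of.isin(keep)]
    if m.is_log2:
        out = sub.groupby(prot_of).mean()
        method = "mean_log2"
    else:
        out = sub.groupby(prot_of).sum(min_count=1)
        method = "sum_linear"
    return QuantMatrix(
        out.sort_index(), m.level, m.batch_of, AnalyteKind.PROTEIN,
        [*m.provenance, f"rollup_proteins({method}, min_peptides={min_peptides})"],
    )


def _cv_percent(linear: pd.DataFrame, min_obs: int, cv_method: str) -> pd.DataFrame:
    n = linear.notna().sum(axis=1)
    if cv_method == "linear":
        sd = linear.std(axis=1, ddof=1)
        mean = linear.mean(axis=1)
        cv = 100.0 * sd / mean
    elif cv_method == "geometric":
        logv = np.log(linear)
        s2 = logv.std(axis=1, ddof=1) ** 2
        cv = 100.0 * np.sqrt(np.expm1(s2))
    else:
        raise ValueError("cv_method must be 'linear' or 'geometric'")
    out = pd.DataFrame(
        {
            "cv_percent": cv,
            "log2_median_abundance": np.log2(linear).median(axis=1),
            "n_obs": n,
        }
    )
    return out[out["n_obs"] >= min_obs]


def compute_cv(
    m: QuantMatrix,
    runs: list[str] | None = None,
    scope: CvScope = CvScope.INTER_BATCH,
    min_obs: int = 3,
    cv_method: str = "linear",
) -> CVTable:
    """Per-analyte CV% over a run subset, computed on the linear scale.

    Log2 matrices are back-transformed before CV = 100·sd/mean (sample SD);
    ``cv_method="geometric"`` uses the log-normal closed form instead. For
    INTRA_BATCH scope, CVs are computed separately within each batch.
    η (median_cv_eta) is the median CV over analytes with at least ``min_obs``
    observations.
    """
    scope = CvScope(scope)
    runs = list(m.values.columns) if runs is None else [r for r in runs if r in m.values.columns]
    if len(runs) < 2:
        raise InsufficientDataError("CV needs >= 2 runs in the subset")
    linear = m.linear_values()[runs]
    if scope is CvScope.INTRA_BATCH:
        pieces = []
        bser = m.batch_of.reindex(runs)
        for batch in pd.unique(bser):
            cols = list(bser.index[bser == batch])
            if len(cols) < 2:
                continue
            piece = _cv_percent(linear[cols], min_obs, cv_method)
            piece.insert(0, "batch_id", batch)
            pieces.append(piece)
        if not pieces:
            raise InsufficientDataError("no batch has >= 2 runs in the subset")
        data = pd.concat(pieces)
    else:
        data = _cv_percent(linear, min_obs, cv_method)
        data.insert(0, "batch_id", pd.NA)
    data = data.rename_axis("analyte_id").reset_index()
    data.insert(1, "scope", scope.value)
    eta = float(data["cv_percent"].median()) if len(data) else float("nan")
    return CVTable(data, scope, eta, min_obs)


def cv_abundance_curve(
    cvt: CVTable, span: float = 0.5, n_grid: int = 100
) -> pd.DataFrame:
    """LOESS curve of CV% against log2 median abundance.

    Locally weighted linear regression (tricube weights, ``span`` = fraction
    of points per fit, one robustness iteration) evaluated on an ``n_grid``-
    point grid spanning the observed abundance range. Deterministic.
    """
    df = cvt.data.dropna(subset=["cv_percent", "log2_median_abundance"])
    if len(df) < 10:
        raise InsufficientDataError(
            "need >= 10 analytes for a smoothed curve; plot the raw scatter instead"
        )
    x = df["log2_median_abundance"].to_numpy(dtype=float)
    y = df["cv_percent"].to_numpy(dtype=float)
    fitted = lowess(y, x, frac=span, it=1, return_sorted=True)
    grid = np.linspace(x.min(), x.max(), n_grid)
    smoothed = np.interp(grid, fitted[:, 0], fitted[:, 1])
    return pd.DataFrame({"log2_median_abundance": grid, "cv_percent_smoothed": smoothed})


def assess_levels(
    l1: QuantMatrix,
    l2: QuantMatrix,
    l3: QuantMatrix,
    qc_runs: dict[CvScope, list[str]],
    mapping: dict[str, str] | None = None,
    min_obs: int = 3,
    cv_method: str = "linear",
) -> LevelComparison:
    """η per (level, scope, analyte kind) and the deltas along the ladder.

    Transitions that *increase* an η are flagged — the external QCs exist
    precisely to catch a normalization step that hurts.
    """
    mats = {Level.L1_RAW: l1, Level.L2_NORMALIZED: l2, Level.L3_BATCH_ADJUSTED: l3}
    for lvl, m in mats.items():
        if m.level is not lvl:
            raise ValidationError(f"matrix tagged {m.level.value} passed in the {lvl.value} slot")
        if not m.values.index.equals(l1.values.index) or list(m.values.columns) != list(l1.values.columns):
            raise ValidationError("level matrices must share analytes and runs")
    rows = []
    for lvl, m in mats.items():
        kinds = [(AnalyteKind.PEPTIDE, m)]
        if mapping:
            kinds.append((AnalyteKind.PROTEIN, rollup_proteins(m, mapping)))
        for kind, mat in kinds:
            for scope, runs in qc_runs.items():
                cvt = compute_cv(mat, runs, scope, min_obs=min_obs, cv_method=cv_method)
                rows.append(
                    {
                        "level": lvl.value,
                        "scope": CvScope(scope).value,
                        "analyte_kind": kind.value,
                        "median_cv_eta": cvt.median_cv_eta,
                    }
                )
    etas = pd.DataFrame(rows)
    deltas = []
    order = [Level.L1_RAW.value, Level.L2_NORMALIZED.value, Level.L3_BATCH_ADJUSTED.value]
    for (scope, kind), grp in etas.groupby(["scope", "analyte_kind"]):
        g = grp.set_index("level")["median_cv_eta"]
        for a, b in zip(order, order[1:]):
            deltas.append(
                {
                    "transition": f"{a}->{b}",
                    "scope": scope,
                    "analyte_kind": kind,
                    "delta_eta": float(g[b] - g[a]),
                }
            )
    deltas = pd.DataFrame(deltas)
    flagged = deltas[deltas["delta_eta"] > 0].reset_index(drop=True)
    return LevelComparison(etas, deltas, flagged)
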