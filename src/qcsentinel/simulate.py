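"""Synthetic LC-MS QC experiment generator with ground-truth failure labels.

The generator emulates the statistical structure of targeted QC reports:
log-normally noisy peak areas (log2-additive noise), retention-time jitter,
ppm-scale mass error, and three isotope peaks per precursor drawn from the
theoretical envelope. Six injectable event kinds reproduce the canonical
failure modes this toolkit is built to detect:

* STEP_CHANGE          — abrupt, sustained intensity drop (buffer/LC fault);
* ISOTOPE_LOSS         — sporadic attenuation of M+1/M+2 peaks (ion optics);
* ARM_DIGESTION_FAILURE— one preparation arm loses digested-protein signal
                         while pre-injection peptide spikes stay normal
                         (expired denaturant);
* BAD_INJECTION        — a single run with low areas and late retention
                         (clogged injection line);
* SENSITIVITY_DECAY    — rapid per-injection multiplicative signal decay
                         (debris in the ion path);
* BATCH_EFFECT_ONLY    — per-(batch, analyte) abundance offsets with no
                         acute failure.

Every run the event touches carries its label in the run log's
``truth_event`` column, so detectors can be scored against ground truth.
Identical seeds give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analytes as panel
from .errors import ConfigurationError
from .ingest import AnalyteClass, MeasurementTable, RunLog, RunType

__all__ = [
    "SimAnalyte",
    "StepChange",
    "IsotopeLoss",
    "ArmDigestionFailure",
    "BadInjection",
    "SensitivityDecay",
    "BatchEffectOnly",
    "SimulationConfig",
    "default_suitability_panel",
    "default_iqc_panel",
    "endogenous_panel",
    "simulate_experiment",
    "vignette_presets",
    "VIGNETTES",
]

_ORIGIN = pd.Timestamp("2024-03-01 06:00:00")
_RUN_SPACING = pd.Timedelta(minutes=90)


@dataclass(frozen=True)
class SimAnalyte:
    analyte_id: str
    sequence: str
    base_log2_mean: float
    rt_mean_min: float
    transition_fraction: float = 0.7
    protein_id: str | None = None


def default_suitability_panel() -> list[SimAnalyte]:
    """17 monitored suitability precursors: 2 BSA + 15 PRTC peptides."""
    out = []
    for i, seq in enumerate(panel.SUITABILITY_SEQUENCES):
        out.append(
            SimAnalyte(
                analyte_id=panel.make_analyte_id(seq, 2),
                sequence=seq,
                base_log2_mean=19.5 + (i % 5) * 0.45,
                rt_mean_min=5.0 + (i * 23.0 / 17.0) % 24.0,
            )
        )
    return out


def default_iqc_panel() -> tuple[list[SimAnalyte], list[SimAnalyte]]:
    """(protein-IQC ENO peptides, peptide-IQC PRTC peptides) for sample runs."""
    eno = [
        SimAnalyte(
            analyte_id=panel.make_analyte_id(seq, 2),
            sequence=seq,
            base_log2_mean=18.8 + (i % 4) * 0.5,
            rt_mean_min=6.0 + (i * 19.0 / 5.0) % 21.0,
            protein_id="ENO1_YEAST",
        )
        for i, seq in enumerate(panel.ENO_SEQUENCES)
    ]
    # PRTC is spiked at the same level in samples as in suitability runs, so
    # the peptide-IQC entries reuse the suitability-panel parameters.
    prtc = [a for a in default_suitability_panel() if a.sequence in panel.PRTC_SEQUENCES]
    return eno, prtc


_RESIDUES = "ACDEFGHILMNPQSTVWY"  # no K/R internally; tryptic peptides end K/R


def endogenous_panel(n_proteins: int = 10, peptides_per_protein: int = 3) -> list[SimAnalyte]:
    """Synthetic endogenous tryptic peptides grouped into proteins.

    Sequences and abundances are drawn from a fixed internal stream
    (independent of the experiment seed) so the panel is a stable property of
    the configuration. Log2 base abundances are normally distributed
    (unimodal, ~18 ± 2), matching the shape of real peptide intensity
    distributions — a dense center is what makes per-run median normalization
    a stable location estimate.
    """
    rng = np.random.default_rng(20240301)
    out = []
    for p in range(n_proteins):
        pid = f"PROT{p + 1:03d}"
        for j in range(peptides_per_protein):
            length = int(rng.integers(8, 15))
            seq = "".join(rng.choice(list(_RESIDUES), size=length)) + ("K" if (p + j) % 2 else "R")
            out.append(
                SimAnalyte(
                    analyte_id=panel.make_analyte_id(seq, 2),
                    sequence=seq,
                    base_log2_mean=float(18.0 + 2.0 * rng.standard_normal()),
                    rt_mean_min=float(rng.uniform(4.0, 30.0)),
                    protein_id=pid,
                )
            )
    return out


@dataclass(frozen=True)
class StepChange:
    """Multiply all areas by ``magnitude`` from global run ``start`` to ``end``."""

    start: int
    magnitude: float = 0.5
    end: int | None = None


@dataclass(frozen=True)
class IsotopeLoss:
    """Attenuate M+1/M+2 areas in randomly chosen sample runs of a window."""

    start_sample: int
    end_sample: int | None = None
    probability: float = 0.3
    attenuation: float = 0.05


@dataclass(frozen=True)
class ArmDigestionFailure:
    """Multiply digested-protein (protein-IQC + endogenous) areas in one prep arm."""

    arm: str
    magnitude: float = 0.01


@dataclass(frozen=True)
class BadInjection:
    """One sample run with all areas scaled and retention times shifted."""

    sample_index: int
    factor: float = 0.3
    rt_shift_min: float = 4.0


@dataclass(frozen=True)
class SensitivityDecay:
    """Areas decay by ``decay`` per injection (all run types) from a sample run on."""

    start_sample: int
    decay: float = 0.5
    end_sample: int | None = None


@dataclass(frozen=True)
class BatchEffectOnly:
    """Draw per-(batch, analyte) log2 offsets; no acute failure, no labels."""

    sd_log2: float | None = None  # falls back to config.batch_offset_sd_log2


Event = StepChange | IsotopeLoss | ArmDigestionFailure | BadInjection | SensitivityDecay | BatchEffectOnly


@dataclass
class SimulationConfig:
    """Layout, noise levels and events of a synthetic experiment.

    Defaults mirror the monitored study conditions: a 17-peptide suitability
    panel, 5 ENO + 15 PRTC internal QCs, 10% area CV, 2 ppm mass-error SD,
    0.05 min RT jitter, suitability injections every 8 sample runs and a
    10-run suitability lead-in that charts use as their guide set.
    """

    n_batches: int = 1
    samples_per_batch: int = 24
    qc_per_batch: int = 0  # inter-batch external QC runs per batch
    qc_interexp_per_batch: int = 0
    ss_every: int = 8  # suitability cadence, in sample runs
    ss_lead_in: int = 10
    n_ss_only: int = 0  # >0: pure suitability series, no samples
    arms: tuple[str, ...] | None = None  # sample prep arms, assigned round-robin then shuffled
    noise_cv: float = 0.10
    ratio_noise_cv: float | None = None  # default noise_cv / 5
    iso_noise_cv: float | None = None  # default noise_cv / 2
    rt_jitter_sd: float = 0.05  # minutes
    ppm_sd: float = 2.0
    run_scale_sd_log2: float = 0.0  # per-run loading/injection variability
    batch_offset_sd_log2: float = 0.5
    suitability: list[SimAnalyte] = field(default_factory=default_suitability_panel)
    protein_iqc: list[SimAnalyte] = field(default_factory=lambda: default_iqc_panel()[0])
    peptide_iqc: list[SimAnalyte] = field(default_factory=lambda: default_iqc_panel()[1])
    endogenous: list[SimAnalyte] = field(default_factory=list)
    events: tuple[Event, ...] = ()
    seed: int = 0

    def protein_mapping(self) -> dict[str, str]:
        """peptide analyte_id -> protein id, for protein roll-up."""
        out = {}
        for a in [*self.protein_iqc, *self.endogenous]:
            if a.protein_id:
                out[a.analyte_id] = a.protein_id
        return out


def _lognoise_sd(cv: float) -> float:
    """log2-scale SD equivalent to a linear-scale CV (log-normal relation)."""
    return float(np.sqrt(np.log1p(cv**2)) / np.log(2))


def _build_schedule(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows: list[dict] = []
    counters = {rt: 0 for rt in RunType}

    def add(run_type: RunType, batch: str, arm=None, sample_ordinal=None):
        counters[run_type] += 1
        prefix = {
            RunType.SYSTEM_SUITABILITY: "SS",
            RunType.SAMPLE: "S",
            RunType.EXTERNAL_QC_INTERBATCH: "QB",
            RunType.EXTERNAL_QC_INTEREXPERIMENT: "QX",
        }[run_type]
        rows.append(
            {
                "run_id": f"{prefix}{counters[run_type]:03d}",
                "run_type": run_type.value,
                "batch_id": batch,
                "prep_arm": arm,
                "sample_ordinal": sample_ordinal,
            }
        )

    if cfg.n_ss_only > 0:
        for _ in range(cfg.n_ss_only):
            add(RunType.SYSTEM_SUITABILITY, "B01")
    else:
        for _ in range(cfg.ss_lead_in):
            add(RunType.SYSTEM_SUITABILITY, "B01")
        sample_ordinal = 0
        for b in range(cfg.n_batches):
            batch = f"B{b + 1:02d}"
            arm_seq: list[str | None]
            if cfg.arms:
                arm_seq = [cfg.arms[i % len(cfg.arms)] for i in range(cfg.samples_per_batch)]
                rng.shuffle(arm_seq)
            else:
                arm_seq = [None] * cfg.samples_per_batch
            qc_slots = set()
            if cfg.qc_per_batch > 0:
                qc_slots = {
                    int(round(i * cfg.samples_per_batch / max(1, cfg.qc_per_batch)))
                    for i in range(cfg.qc_per_batch)
                }
            for j in range(cfg.samples_per_batch):
                if j in qc_slots:
                    add(RunType.EXTERNAL_QC_INTERBATCH, batch)
                if j > 0 and j % cfg.ss_every == 0:
                    add(RunType.SYSTEM_SUITABILITY, batch)
                add(RunType.SAMPLE, batch, arm_seq[j], sample_ordinal)
                sample_ordinal += 1
            for _ in range(cfg.qc_interexp_per_batch):
                add(RunType.EXTERNAL_QC_INTEREXPERIMENT, batch)
    df = pd.DataFrame(rows)
    df["acquired_at"] = [_ORIGIN + i * _RUN_SPACING for i in range(len(df))]
    return df


def _apply_events(
    cfg: SimulationConfig, sched: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str | None], float | None]:
    """Per-run multipliers and labels implied by the configured events.

    Returns (area_factor, arm_area_factor, iso_factor, rt_shift, labels,
    batch_sd): ``area_factor`` applies to every analyte of the run,
    ``arm_area_factor`` only to digested material (protein IQC + endogenous).
    """
    n = len(sched)
    area = np.ones(n)
    arm_area = np.ones(n)
    iso = np.ones(n)
    rt = np.zeros(n)
    labels: list[str | None] = [None] * n
    batch_sd: float | None = None

    sample_pos = sched.index[sched["run_type"] == RunType.SAMPLE.value].to_numpy()

    def claim(idx: np.ndarray | list[int], name: str) -> None:
        for i in idx:
            if labels[i] is not None and labels[i] != name:
                raise ConfigurationError(
                    f"contradictory events {labels[i]} and {name} on run index {i}"
                )
            labels[i] = name

    for ev in cfg.events:
        if isinstance(ev, StepChange):
            if not 0 < ev.magnitude:
                raise ConfigurationError("step magnitude must be > 0")
            end = ev.end if ev.end is not None else n
            idx = np.arange(ev.start, min(end, n))
            area[idx] *= ev.magnitude
            claim(idx, "STEP_CHANGE")
        elif isinstance(ev, IsotopeLoss):
            end = ev.end_sample if ev.end_sample is not None else len(sample_pos)
            window = sample_pos[ev.start_sample : end]
            hit = window[rng.random(len(window)) < ev.probability]
            iso[hit] *= ev.attenuation
            claim(hit, "ISOTOPE_LOSS")
        elif isinstance(ev, ArmDigestionFailure):
            if ev.arm not in set(sched["prep_arm"].dropna()):
                raise ConfigurationError(f"unknown prep arm {ev.arm!r}")
            idx = sched.index[sched["prep_arm"] == ev.arm].to_numpy()
            arm_area[idx] *= ev.magnitude
            claim(idx, "ARM_DIGESTION_FAILURE")
        elif isinstance(ev, BadInjection):
            if ev.sample_index >= len(sample_pos):
                raise ConfigurationError("bad-injection sample index out of range")
            i = sample_pos[ev.sample_index]
            area[i] *= ev.factor
            rt[i] += ev.rt_shift_min
            claim([i], "BAD_INJECTION")
        elif isinstance(ev, SensitivityDecay):
            if not 0 < ev.decay <= 1:
                raise ConfigurationError("decay rate must be in (0, 1]")
            start = sample_pos[ev.start_sample]
            stop = sample_pos[ev.end_sample] if ev.end_sample is not None else n
            idx = np.arange(start, min(stop, n))
            area[idx] *= ev.decay ** np.arange(1, len(idx) + 1)
            claim(idx, "SENSITIVITY_DECAY")
        elif isinstance(ev, BatchEffectOnly):
            batch_sd = ev.sd_log2 if ev.sd_log2 is not None else cfg.batch_offset_sd_log2
        else:  # pragma: no cover
            raise ConfigurationError(f"unknown event type {type(ev).__name__}")
    return area, arm_area, iso, rt, labels, batch_sd


def simulate_experiment(cfg: SimulationConfig) -> tuple[MeasurementTable, RunLog]:
    """Generate a (MeasurementTable, RunLog) pair; deterministic given cfg.seed.

    Linear area model per run r, analyte a:
    ``2^(base_log2_mean_a + batch_offset + run_scale_r + eps)`` with eps the
    log2-SD equivalent of ``noise_cv``, then multiplied by any event factors.
    Isotope areas are the precursor area split by the analyte's theoretical
    envelope with independent log-normal noise on each peak.
    """
    rng = np.random.default_rng(cfg.seed)
    sched = _build_schedule(cfg, rng)
    area_f, arm_f, iso_f, rt_shift, labels, batch_sd = _apply_events(cfg, sched, rng)

    batches = sorted(sched["batch_id"].unique())
    sigma = _lognoise_sd(cfg.noise_cv)
    sigma_ratio = _lognoise_sd(cfg.ratio_noise_cv if cfg.ratio_noise_cv is not None else cfg.noise_cv / 5)
    sigma_iso = _lognoise_sd(cfg.iso_noise_cv if cfg.iso_noise_cv is not None else cfg.noise_cv / 2)
    run_scale = (
        rng.normal(0.0, cfg.run_scale_sd_log2, size=len(sched))
        if cfg.run_scale_sd_log2 > 0
        else np.zeros(len(sched))
    )

    sample_like = {
        RunType.SAMPLE.value,
        RunType.EXTERNAL_QC_INTERBATCH.value,
        RunType.EXTERNAL_QC_INTEREXPERIMENT.value,
    }
    blocks: list[tuple[np.ndarray, list[SimAnalyte], list[str]]] = []
    ss_rows = sched.index[sched["run_type"] == RunType.SYSTEM_SUITABILITY.value].to_numpy()
    if len(ss_rows):
        blocks.append((ss_rows, cfg.suitability, [AnalyteClass.SUITABILITY_PEPTIDE.value] * len(cfg.suitability)))
    sm_rows = sched.index[sched["run_type"].isin(sample_like)].to_numpy()
    if len(sm_rows):
        sample_panel = [*cfg.protein_iqc, *cfg.peptide_iqc, *cfg.endogenous]
        classes = (
            [AnalyteClass.PROTEIN_IQC.value] * len(cfg.protein_iqc)
            + [AnalyteClass.PEPTIDE_IQC.value] * len(cfg.peptide_iqc)
            + [AnalyteClass.ENDOGENOUS.value] * len(cfg.endogenous)
        )
        blocks.append((sm_rows, sample_panel, classes))

    # per-(batch, analyte_id) offsets, shared across contexts
    all_ids = sorted({a.analyte_id for _, pl, _ in blocks for a in pl})
    id_pos = {aid: i for i, aid in enumerate(all_ids)}
    if batch_sd is not None and len(batches) > 0:
        offsets = rng.normal(0.0, batch_sd, size=(len(batches), len(all_ids)))
    else:
        offsets = np.zeros((len(batches), len(all_ids)))
    batch_pos = {b: i for i, b in enumerate(batches)}

    frames = []
    for run_idx, plist, classes in blocks:
        n_r, n_a = len(run_idx), len(plist)
        base = np.array([a.base_log2_mean for a in plist])
        rt_mean = np.array([a.rt_mean_min for a in plist])
        tfrac = np.array([a.transition_fraction for a in plist])
        envs = np.stack([panel.expected_envelope(a.analyte_id) for a in plist])
        off = offsets[
            np.array([batch_pos[b] for b in sched.loc[run_idx, "batch_id"]])[:, None],
            np.array([id_pos[a.analyte_id] for a in plist])[None, :],
        ]
        eps = rng.normal(0.0, sigma, size=(n_r, n_a)) if sigma > 0 else np.zeros((n_r, n_a))
        log2_area = base[None, :] + off + run_scale[run_idx][:, None] + eps
        precursor = np.exp2(log2_area)
        # event multipliers
        precursor *= area_f[run_idx][:, None]
        is_digested = np.array(
            [c in (AnalyteClass.PROTEIN_IQC.value, AnalyteClass.ENDOGENOUS.value) for c in classes]
        )
        precursor *= np.where(is_digested[None, :], arm_f[run_idx][:, None], 1.0)
        eps_ratio = (
            rng.normal(0.0, sigma_ratio, size=(n_r, n_a)) if sigma_ratio > 0 else np.zeros((n_r, n_a))
        )
        transition = precursor * tfrac[None, :] * np.exp2(eps_ratio)
        eps_iso = (
            rng.normal(0.0, sigma_iso, size=(n_r, n_a, 3)) if sigma_iso > 0 else np.zeros((n_r, n_a, 3))
        )
        iso = precursor[:, :, None] * envs[None, :, :] * np.exp2(eps_iso)
        iso[:, :, 1:] *= iso_f[run_idx][:, None, None]
        rt = (
            rt_mean[None, :]
            + (rng.normal(0.0, cfg.rt_jitter_sd, size=(n_r, n_a)) if cfg.rt_jitter_sd > 0 else 0.0)
            + rt_shift[run_idx][:, None]
        )
        ppm = rng.normal(0.0, cfg.ppm_sd, size=(n_r, n_a)) if cfg.ppm_sd > 0 else np.zeros((n_r, n_a))
        frames.append(
            pd.DataFrame(
                {
                    "run_id": np.repeat(sched.loc[run_idx, "run_id"].to_numpy(), n_a),
                    "acquired_at": np.repeat(sched.loc[run_idx, "acquired_at"].to_numpy(), n_a),
                    "analyte_id": np.tile([a.analyte_id for a in plist], n_r),
                    "analyte_class": np.tile(classes, n_r),
                    "precursor_area": precursor.ravel(),
                    "transition_area": transition.ravel(),
                    "rt_min": rt.ravel(),
                    "mass_error_ppm": ppm.ravel(),
                    "iso_m0": iso[:, :, 0].ravel(),
                    "iso_m1": iso[:, :, 1].ravel(),
                    "iso_m2": iso[:, :, 2].ravel(),
                }
            )
        )
    measurements = pd.concat(frames, ignore_index=True)

    runlog_df = sched[["run_id", "acquired_at", "run_type", "batch_id", "prep_arm"]].copy()
    runlog_df["annotation"] = pd.NA
    runlog_df["truth_event"] = pd.array(labels, dtype="string")
    runlog = RunLog.from_dataframe(runlog_df)
    table = MeasurementTable.from_dataframe(measurements, runlog)
    return table, runlog


VIGNETTES = (
    "vignette1",
    "vignette2",
    "vignette3",
    "vignette4",
    "vignette5",
    "vignette6",
)


def vignette_presets(name: str, seed: int = 0) -> SimulationConfig:
    """Documented configurations reproducing the six failure-vignette layouts.

    1. suitability-only series with a 50% step drop and recovery;
    2. sporadic M+1/M+2 isotope loss in sample runs;
    3. four prep arms × 8 randomized replicates, ISD arm digestion failure;
    4. one bad injection (30% intensity, +4 min RT) in a plasma-style series;
    5. rapid per-injection sensitivity decay confirmed by suitability runs;
    6. eight batches with external QC runs and batch effects only.

    Event magnitudes are synthetic: chosen comfortably detectable rather than
    fit to any instrument record.
    """
    if name == "vignette1":
        return SimulationConfig(n_ss_only=40, events=(StepChange(start=20, magnitude=0.5, end=28),), seed=seed)
    if name == "vignette2":
        return SimulationConfig(
            samples_per_batch=30,
            events=(IsotopeLoss(start_sample=10, probability=0.3, attenuation=0.05),),
            seed=seed,
        )
    if name == "vignette3":
        return SimulationConfig(
            samples_per_batch=32,
            arms=("1BD", "2BD", "STR", "ISD"),
            events=(ArmDigestionFailure(arm="ISD", magnitude=0.01),),
            seed=seed,
        )
    if name == "vignette4":
        return SimulationConfig(
            samples_per_batch=20,
            events=(BadInjection(sample_index=12, factor=0.3, rt_shift_min=4.0),),
            seed=seed,
        )
    if name == "vignette5":
        return SimulationConfig(
            samples_per_batch=32,
            ss_every=4,
            events=(SensitivityDecay(start_sample=16, decay=0.5),),
            seed=seed,
        )
    if name == "vignette6":
        return SimulationConfig(
            n_batches=8,
            samples_per_batch=10,
            qc_per_batch=3,
            qc_interexp_per_batch=1,
            ss_every=6,
            run_scale_sd_log2=0.15,
            endogenous=endogenous_panel(120, 3),
            events=(BatchEffectOnly(),),
            seed=seed,
        )
    raise ConfigurationError(f"unknown preset {name!r}; available: {', '.join(VIGNETTES)}")
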