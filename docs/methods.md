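# Methods

This note documents the models, parameters and design choices behind
qcsentinel: what the statistics assume, what the synthetic-data generator
does and does not emulate, and where genuinely open choices were decided.

## Scope and division of labor

The package consumes *post-integration* reports — one row per (run,
precursor) with peak areas, retention time, mass error and the M0/M+1/M+2
isotope-peak areas — as exported by chromatogram-integration software. Raw
spectra, peak picking and library searching are upstream and out of scope.
Three isotope peaks are modeled because the envelope failure of interest is
the loss of M+1/M+2 relative to M0; the schema would extend to more peaks.

Missing values are encoded as empty fields and always mean "not measured",
never zero; a zero area from integration software is likewise treated as
missing in the quantitative matrix. Run order is acquisition time with ties
broken by run id, so every chart and report is deterministic.

## Isotope envelopes and the idotp

A peptide's elemental composition is the sum of residue compositions plus one
water; carbamidomethylation adds C2H3NO per cysteine. The aggregated-nucleon
envelope is the convolution of per-element multinomial distributions using a
natural-abundance table frozen in the source (representative IUPAC values:
¹³C 1.07%, ²H 0.0115%, ¹⁵N 0.364%, ¹⁸O 0.205%, ³⁴S 4.25%, ...). Convolution
is truncated to `n_peaks`; because convolution's low-order terms depend only
on low-order inputs, the retained peaks are exact, and they are renormalized
to sum to 1 (the renormalization is recorded). Heavy-label atoms (13C6+15N2
on C-terminal K, 13C6+15N4 on C-terminal R, as in commercial heavy peptide
mixes) are isotopically pure: they shift mass but not envelope shape, so they
are removed from the natural pool before convolution.

The isotope dot product is plain cosine similarity between the expected
envelope and the observed peak areas: 1 iff proportional, invariant to
positive scaling, symmetric. Integration software sometimes weights peaks by
square root first; a `transform="sqrt"` switch provides that variant, default
off. An all-zero observed vector raises an error rather than returning a low
score — "no signal" and "wrong envelope" are different findings. Numerical
agreement with any particular vendor implementation is not claimed.

## Control charts

Baselines are the arithmetic mean and sample SD (n−1) of a guide set,
defaulting to the first 10 runs of matching type; an explicit run list
overrides, which is the natural choice when the in-control preamble of a
series is longer (the step-power harness below uses its scenario's full
20-run initial block). A numerically constant guide set (SD below 10⁻¹²
relative) is treated as SD = 0, in which case Levey-Jennings degenerates to
"any deviation beyond serialization precision (10⁻⁹ relative) fails".

Defaults follow common SPC practice and are all configurable: Westgard-style
rules 1_3s (FAIL) and 2_2s (WARN); CUSUM k = 0.5, h = 5 (tabulated in-control
ARL ≈ 465, ARL ≈ 10.4 under a sustained 1σ shift); moving-range limit
3.267·mean(MR) (the n = 2 individuals-chart constant), with mean(MR) taken
over the guide region when a baseline is supplied; trailing window 5 with a
20% CV FAIL threshold — an operational convention, not science. The trailing
CV at run *i* is computed over the window ending at *i* (current run
included) with the sample SD; for the reference series
[10,10,10,10,10,20] the last window [10,10,10,10,20] has mean 12, SD
√20 ≈ 4.4721, trailing CV ≈ 37.27%.

Trailing CV is only offered for metrics on a positive scale (areas, RT); for
a signed, zero-centered metric like mass error the ratio is meaningless and
the monitor omits it.

## Triage

Per sample-type run, transition areas of each internal-QC class are reduced
to medians across that class's analytes (robust to one badly behaving
peptide): median z and median ratio-to-baseline-mean for the protein IQC
(ENO) and the peptide IQC (PRTC), the median RT deviation, and the minimum
idotp across both classes (the minimum because envelope loss is clearest on
M+1-rich analytes; small M0-dominated peptides barely move). The
system-suitability status of a run is derived from the last 3 suitability
runs at or before it: DEGRADED if any of them failed Levey-Jennings on
transition area for at least half the suitability analytes, OK if none did,
UNKNOWN if there were none.

Rules are evaluated in order, first match wins; undefined fields skip their
rules:

* **R1 isotope-envelope loss** — min idotp < 0.90 while both IQC ratios are
  ≥ 0.5. Ordered first because intensity metrics alone miss this failure.
* **R2 sample-prep failure** — ENO ratio < 0.5 while |PRTC z| ≤ 2.
* **R3 injection/LC event** — both ratios < 0.5, |RT shift| > 2 min, and the
  adjacent runs are pass-like (an isolated event; missing neighbors count as
  pass-like).
* **R4 MS sensitivity loss** — PRTC ratio < 0.5, *or* three consecutive
  strictly decreasing PRTC ratios ending below 0.7, with suitability status
  DEGRADED.
* **R5 system check needed** — the same intensity evidence with status OK or
  UNKNOWN: the instrument-side evidence is not yet confirmed, so the
  recommendation is to queue suitability runs. R4 and R5 are two phases of
  the same finding; harnesses that score triage against simulated decay
  accept either.

All thresholds (0.5, 2 min, 0.90, 3 runs / 0.7) are engineering defaults in
`TriageConfig`; nothing quantitative in their sources pins them down.

## Normalization ladder and CV assessment

Level 1 is the raw linear-area matrix (analytes × runs). Level 2 is log₂
with per-run medians equalized to the grand median of run medians — keeping
values in the original intensity register rather than centering at zero.
Level 3 removes batch effects by per-analyte location adjustment: subtract
the batch mean, restore the analyte grand mean. This is deliberately the
transparent estimator rather than an empirical-Bayes one: it is exactly
variance-preserving within batches, its estimates are analyzable in closed
form, and it suffices for location-type batch effects. An optional
`scale_adjust` additionally equalizes within-batch SDs. Analytes with fewer
than 2 observations in some batch pass through unadjusted and are listed in
the matrix provenance. Batch offsets are identifiable only up to a
per-analyte location, so offset-recovery checks compare against the centered
injected offsets.

CVs are computed on the linear scale (log₂ matrices are back-transformed),
CV% = 100·sd/mean with the sample SD, matching clinical-lab convention; a
`cv_method="geometric"` switch gives the log-normal closed form
100·√(e^{σ̂²}−1). η is the median CV across analytes with ≥ 3 observations.
Protein roll-up is the mean of observed peptide log₂ values (levels 2–3) or
the sum of linear areas (level 1); the method is recorded in provenance and
protein results are comparable only within one scheme. No imputation is
performed anywhere.

The CV-vs-abundance curve is LOWESS (tricube-weighted local linear
regression, span = fraction of points, one robustness iteration, via
statsmodels) evaluated at the data points and linearly interpolated onto a
100-point grid; constants and linear trends are reproduced exactly, and the
curve is deterministic.

Median normalization presumes enough analytes that a run median is a stable
location estimate. With few analytes spread thinly across the abundance
range, the run median tracks a single mid-abundance analyte's random batch
offset and normalization can *add* inter-batch variance; the simulator's
external-QC preset therefore carries a realistically sized panel (360
endogenous peptides with unimodal log₂ abundances), and the same caution
applies to real targeted panels.

## The synthetic-data generator

Per run r and analyte a the linear area is
2^(μ_a + batch_offset_{b(r),a} + run_scale_r + ε), with ε normal on the log₂
scale at the SD equivalent of the configured CV (default 10%); transition
area is a fixed fraction (0.7) of precursor area with small extra noise
(CV/5); isotope areas split the precursor area by the theoretical envelope
with independent log-normal noise per peak (CV/2); RT jitter SD 0.05 min;
mass error SD 2 ppm. Run-scale variability (per-run loading differences) is
off by default and 0.15 log₂ (≈11% CV) in the batch-effect preset. Batch
offsets are drawn per (batch, analyte) at SD 0.5 log₂ when the batch-effect
event is present. The default panels are the real standards: 17 suitability
precursors (2 BSA + 15 PRTC), 5 ENO peptides, 15 PRTC peptides; the peptide
IQC reuses the suitability parameters because it is the same spike at the
same level. Suitability cadence is expressed in runs (default 1 per 8
samples) with a 10-run lead-in.

Event kinds and preset magnitudes (magnitudes are synthetic — chosen to be
comfortably detectable, not fit to any instrument record): step change ×0.5
sustained; isotope loss ×0.05 on M+1/M+2 in randomly chosen runs (p = 0.3);
arm digestion failure ×0.01 on digested material (protein IQC + endogenous)
in one arm, peptide IQC untouched; bad injection ×0.3 with +4 min RT on one
run; sensitivity decay ×0.5 per injection (all run types) from an onset run;
batch effects as above. Every modified run carries its event label in the
run log. Identical seeds give byte-identical outputs.

What the generator does **not** emulate: chromatographic peak shape (poor
chromatography appears only as area/RT effects), m/z-resolved spectra,
autocorrelated instrument drift, missingness mechanisms, or interference
between co-eluting analytes. Detectors passing on this generator therefore
demonstrate correctness of the statistics under the stated noise model, not
robustness to every real-data pathology.

## Measured operating characteristics

The validation harnesses (and `scripts/acceptance.py`) measure, per seed
batch: Levey-Jennings false-FAIL fraction on 10,000 in-control points
(theory 0.27%); CUSUM average run length under a sustained 1σ shift over
2,000 series (tabulated ≈ 10.4); first-run detection power for a 50% step on
a 10% CV baseline over 1,000 seeds (the scenario's 20-run in-control block
as guide; with a 10-run guide, baseline-estimation noise alone caps power
near 98.8%); triage precision/recall per failure class over 200 seeded
vignette simulations; and the inter-batch η of levels 1/2/3 with the
fraction of seeds ordered L3 ≤ L2 ≤ L1 over 200 simulations. Problem sizes
were chosen so the full suite and the reproduction script each run in
minutes on one CPU.

## Known limitations

* Chart limits assume independent observations; autocorrelated drift
  inflates false-positive rates and is not corrected for.
* The triage rules are threshold logic, not probabilistic inference; calls
  carry evidence but no calibrated confidence.
* Batch adjustment is location(-scale) only; it will not remove batch ×
  abundance interactions.
* The idotp is computed on integrated peak areas; other software may compute
  it at apex intensity, so absolute values are comparable only within one
  pipeline.
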