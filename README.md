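# qcsentinel

Quality control for quantitative bottom-up proteomics, in three tiers:

1. **System suitability.** Repeated targeted injections of a fixed standard
   (a tryptic BSA digest plus the 15 heavy PRTC retention-time peptides) are
   monitored longitudinally with statistical-process-control charts —
   Levey-Jennings, CUSUM, moving range, trailing mean and trailing CV — over
   peak areas, area ratios, retention time, mass error, and the isotope dot
   product.
2. **Internal-QC triage.** Every experimental sample carries two exogenous
   spikes: yeast enolase 1 (ENO), added *before* digestion, and the PRTC
   peptides, added *just before injection*. Because the protein spike sees
   the whole preparation while the peptide spike sees only the LC-MS system,
   their joint behavior localizes a failure: preparation problem, bad
   injection / LC event, MS sensitivity loss, or isotope-envelope loss.
3. **Quantitative assessment.** External pooled QC samples run in every batch
   grade the processing ladder — level 1 (raw linear areas), level 2 (log₂ +
   median normalization), level 3 (batch adjustment) — by the median
   coefficient of variation η across analytes, within and between batches,
   and by the LOESS trend of CV against log₂ median abundance.

A built-in simulator generates labeled experiments reproducing six canonical
failure modes (intensity step change, isotope-envelope loss, per-arm
digestion failure, single bad injection, progressive sensitivity decay, and
batch effects), so every detector in the package is testable end to end
without instrument data.

## Core statistics

For a metric series $x_1, x_2, \dots$ against a guide-set baseline
$(\mu, \sigma)$ (mean and sample SD of the initial in-control runs):

* Levey-Jennings: $z_i = (x_i - \mu)/\sigma$; FAIL when $|z_i| > 3$ (rule
  `1_3s`), WARN when two consecutive points sit on the same side beyond 2σ
  (rule `2_2s`).
* CUSUM (slack $k{=}0.5$, decision interval $h{=}5$):
  $S^+_i = \max(0, S^+_{i-1} + z_i - k)$,
  $S^-_i = \max(0, S^-_{i-1} - z_i - k)$; FAIL when either exceeds $h$.
* Moving range: $\mathrm{MR}_i = |x_i - x_{i-1}|$; FAIL above
  $3.267 \times \overline{\mathrm{MR}}$.
* Trailing CV: $100\,s/\bar{x}$ over the most recent 5 runs.
* Isotope dot product: cosine similarity between observed M0/M+1/M+2 peak
  areas and the theoretical envelope convolved from the peptide's elemental
  composition (natural C/H/N/O/S abundances; heavy-label atoms excluded from
  the natural pool).
* η: the median CV% across analytes of an external-QC run set, per batch
  (intra-batch) or across batches (inter-batch).

## Worked example

Simulate the digestion-failure vignette (four prep arms × 8 randomized
replicates of pooled CSF; the in-solution-digestion arm "ISD" loses its ENO
signal), then triage it:

```sh
$ qcsentinel simulate --preset vignette3 --seed 7 --out sim
simulate: seed=7 preset=vignette3 runs=45 rows=861 -> sim
$ qcsentinel triage --report sim/report.tsv --runlog sim/runlog.tsv --out triage
triage: 32 runs, 8 non-PASS -> triage
$ echo $?
2
```

Exit status 2 signals non-PASS calls (0 = clean, 1 = execution error), so the
tool can gate an acquisition queue. The call table names the rule and the
evidence; here run S010 lost its protein IQC (0.8% of baseline) while the
peptide IQC stayed consistent (z = 0.06) — the signature of a preparation
failure, not an instrument problem:

```
run_id  batch_id  call                  rule_id  evidence
S010    B01       SAMPLE_PREP_FAILURE   R2       {"eno_ratio": 0.0117, "prtc_z": 0.062}
```

All 8 ISD replicates are flagged and all 24 other runs PASS. The same
pipeline exposes the library API (`qcsentinel.simulate`, `qcsentinel.spc`,
`qcsentinel.triage`, `qcsentinel.quantnorm`) for use without the CLI.

## Layout

```
src/qcsentinel/
  ingest.py      report/run-log parsing, validation, TSV/JSON writing
  isotope.py     elemental compositions, isotope envelopes, idotp
  spc.py         metric extraction, baselines, the five chart types
  triage.py      internal-QC summaries and rules R1-R5
  quantnorm.py   level 1/2/3 ladder, CV tables, η, LOESS curve
  simulate.py    synthetic experiments with the six failure vignettes
  validation.py  seeded harnesses measuring operating characteristics
  cli.py         qcsentinel simulate|monitor|triage|quantify|report
docs/methods.md  model, parameter and design documentation
```
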