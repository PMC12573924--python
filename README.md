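# cifaudit

Audit pipeline for single-crystal refinement-quality metrics in CIF 1.1
files. It extracts the common quality items (R, wR, goodness of fit,
shift/su, residual electron densities, θmax, wavelength, parameter counts),
curates them against open-interval validity ranges, classifies entries along
six category axes, derives Bragg resolution and residual-density (DTEST)
reference levels, assigns checkCIF-style A/B/C alerts, and produces cohort
distribution statistics with per-entry percentile contextualization.

Because real deposition archives are licensed, the package ships a seeded
synthetic corpus generator whose marginals are calibrated to published
survey anchors (median R 0.046, median GooF 1.045, bimodal θmax tied to
Mo/Cu wavelengths, Zmax-coupled residual densities) with quota-exact
injection of missing/malformed/out-of-range values and a full ground-truth
table, so every pipeline stage is testable end to end.

## Command line

```sh
# generate a 1000-entry synthetic corpus
cifaudit synth --n 1000 --seed 1 --out corpus/

# audit CIFs (files or directories); ground_truth.csv doubles as a sidecar
# for axes not derivable from a CIF (polymeric, refinement type)
cifaudit audit corpus/ --sidecar corpus/ground_truth.csv --out audit-out/

# summary tables + histogram bin counts from an audit
cifaudit survey audit-out/ --out survey-out/

# percentile context against a prior audit as reference cohort
cifaudit audit corpus/ --reference prior-audit/entries.csv --out audit-out/
```

`audit` writes `entries.csv` (one row per entry: curated metrics, six-axis
categories with provenance, alert levels, resolution), `tallies.csv`/`.json`
(per-tag completeness accounting), `alerts.json` and `metadata.json`.
Validity ranges (`--rules`) and alert thresholds (`--thresholds`, JSON) are
overridable; `--profile strict-goof` selects the alternate GooF calibration.
The shift/su alert threshold has no published value and is flagged as a
non-survey default in every report.

## Alert boundaries (defaults)

| metric            | A                  | B                  | C                  |
|-------------------|--------------------|--------------------|--------------------|
| R                 | —                  | —                  | > 0.1              |
| wR                | —                  | —                  | > 0.25             |
| GooF              | outside (0.4, 6.0) | outside (0.6, 4.0) | outside (0.8, 2.0) |
| residual density  | > 2 × 0.1·Zmax     | > 10% of Zmax      | > 7.5% of Zmax     |
| resolution        | —                  | —                  | sinθ/λ < 0.6 Å⁻¹   |
| shift/su          | —                  | —                  | > 0.2 (flagged)    |

All boundaries are strict; values exactly at a threshold do not trigger.

## Layout

- `cifaudit.cif_io` — minimal CIF 1.1 reader/writer (tag-value, loops,
  semicolon text fields); raw values preserved byte-for-byte
- `cifaudit.curation` — value parsing (numeric/bounded/missing/malformed,
  su suffixes), validity rules, corpus accounting
- `cifaudit.classification` — chemistry/disorder/radiation/pressure axes
  from CIF content; polymeric/refinement type via sidecar
- `cifaudit.derived_metrics` — Bragg resolution, sinθ/λ, DTEST, |Δρmin|
- `cifaudit.alert_engine` — A/B/C alert levels and threshold profiles
- `cifaudit.cohort_stats` — summaries, central intervals, percentile ranks,
  per-category tables, histogram bin counts
- `cifaudit.synthetic_corpus` — seeded corpus generator + ground truth
- `cifaudit.cli` — `audit` / `survey` / `synth` subcommands
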