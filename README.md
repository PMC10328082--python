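# histoquant

Quantification of dual-color (old vs. new) histone inheritance in stem-cell
divisions from calibrated fluorescence z-stacks, plus a seeded
synthetic-microscopy generator that makes every stage testable without raw
image data.

## What it does

- **imaging_io** — TIFF/OME-TIFF stack I/O with mandatory physical
  calibration, JSON ROI sidecars (polygon / ellipse / label-mask),
  pixel-center containment semantics.
- **synthetic** — seeded scenes with planted ground truth: early-mitotic
  nuclei with a controllable channel-overlap mix, late-mitotic
  sister-chromatid masses with a controllable old-signal partition
  fraction, postmitotic cell pairs with planted Delta/histone levels and
  EdU flags, and 2D tissue fields with planted clusters and intensity
  profiles. Noise model: Poisson(gain·signal)/gain + Gaussian read noise +
  baseline, clipped to 16-bit.
- **colocalization** — Pearson/Spearman coefficients over ROI voxels
  pooled across z (per-slice mode available), and a fixed-size (default
  150 µm) square region grid.
- **quantify** — sum-of-slices integrated density with equal-area
  background subtraction; per-cell measurements (corrected totals,
  centroid, equivalent diameter, EdU flag).
- **segregation** — brighter/dimmer chromatid ratios, control-derived
  asymmetry thresholds (mean + 1σ, mean + 2σ), three-way category
  classification and percentages.
- **pairs** — pair eligibility rules (≤ 5 µm, ≤ 1.5× size ratio, EdU
  negative, quantifiable totals), Delta-ratio division-mode classification
  (> 2 asymmetric), old/new log2 inheritance ratios, geometric fold
  changes, 2D quadrant assignment, specimen-averaged summaries.
- **tissue** — single-linkage cluster statistics of marker-positive cells,
  single-cell fraction, marker censuses, percent-positive summaries, and
  band-averaged line profiles with 1,000-position block averaging.
- **stats** — Shapiro–Wilk–gated one-sample test (t or Wilcoxon
  signed-rank), unpaired two-sample t-test (Student/Welch), Pearson
  chi-square (independence and goodness-of-fit), asterisk mapping.

## CLI

One entry point with subcommands:

```bash
histoquant simulate --scenario pair --seed 1 --out out/            # stack + truth + ROIs
histoquant coloc out/pair.tif --roi out/pair.rois.json --channels old,new
histoquant measure out/pair.tif --roi out/pair.rois.json --edu-channel EdU
histoquant segregation ratios.csv --t-med 1.15 --t-high 1.22
histoquant pairs cells.csv
histoquant clusters cells.csv --radius 10
histoquant census cells.csv --marker prospero
histoquant profile field.tif --path "0,128;1023,128" --width 500 --block 1000
histoquant stats values.csv --test one-sample --columns log2_ratio
histoquant run --seed 1 --n-pairs 20 --out out/                    # end-to-end synthetic
```

A YAML config (`histoquant --config run.yaml <cmd>`) can override any
default; flags win over the file. Exit codes: 0 success, 2 input error,
3 contract violation.

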