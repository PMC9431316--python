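# mdquant

Membrane-microdomain quantification for yeast fluorescence micrographs,
plus lipid-amount-table post-processing — with a ground-truthed
synthetic-data generator used to validate every stage.

## What it does

Given multi-channel 2D (optionally time-lapse) TIFF fields and integer
label masks (0 = background, one positive label per cell), the pipeline:

- converts label masks into per-cell ROIs, fits area-preserving moment
  ellipses, and applies rule-based QC (border-touching cells, area
  gates, degenerate fits) — `mdquant.geometry`;
- computes per-cell metrics: mean/integrated intensity in the membrane
  band, cell interior and whole cell; membrane/interior intensity ratio;
  circular membrane intensity profiles; patch detection with topographic
  prominence; patch count and density per µm of perimeter; dye-uptake
  ratio — `mdquant.quant`;
- registers two channels by integer translation and computes per-cell
  Pearson colocalization plus normalized dual-channel membrane line
  profiles — `mdquant.coloc`;
- summarizes time-lapse patch density (median + IQR per frame) and
  estimates the half-decay time by interpolated crossing or exponential
  fit — `mdquant.kinetics`;
- post-processes samples × lipids amount tables: inorganic-phosphate
  (Pi) normalization, log2 fold changes against per-strain controls,
  lipid-class pooling, PCA with per-lipid component contributions, and
  protein–lipid Pearson correlation with a two-tailed p ≤ 0.05 gate and
  µ_r (mean significant r) — `mdquant.lipidomics`;
- aggregates hierarchically (cell → replicate mean → condition mean ± SD;
  the statistical unit is the replicate, never the cell) and runs
  one-way/two-way ANOVA and paired t tests — `mdquant.statsagg`;
- generates synthetic micrographs with known ground truth (elliptical
  membrane rings with Gaussian angular patches of exact peak/valley
  contrast, two-channel shared-patch fields, exponentially decaying
  time-lapse series, uptake fields) and synthetic lipid tables with
  class-structured condition effects — `mdquant.simulate`.

## CLI

All stages are exposed through a single `mdquant` entry point:

```sh
# synthetic data (config YAML optional; any FieldParams field)
mdquant simulate field     --seed 7 --out-dir out/field
mdquant simulate timelapse --seed 7 --half-life-min 80 --out-dir out/tl
mdquant simulate coloc     --seed 7 --shared-fraction 0.5 --shift 2 -1 --out-dir out/co
mdquant simulate uptake    --seed 7 --uptake-fraction 0.6 --out-dir out/up
mdquant simulate lipids    --seed 7 --out-dir out/lip

# quantification
mdquant quantify out/field/field.tif out/field/mask.tif \
    --band-um 0.5 --background 20 --out metrics.csv
mdquant coloc out/co/field.tif out/co/mask.tif --out coloc.csv
mdquant kinetics metrics.csv --method crossing --out curve.csv
mdquant lipids out/lip/amounts.csv out/lip/pi.csv out/lip/classes.csv \
    --protein out/lip/protein.csv --out-dir lipid_results
mdquant report metrics.csv --metrics patch_count,pm_interior_ratio \
    --out-prefix report
```

Fields are written as 16-bit multi-page TIFF with JSON metadata (pixel
size, channel names, frame times) in the image description; masks as
single-page integer TIFF. All CSV outputs are byte-deterministic for a
fixed seed and config.

## Conventions

- Coordinates are 0-based `(row, col)`; angles measured from the +col
  axis, counter-clockwise in array coordinates; ellipse orientation in
  `[0, π)`.
- The membrane band is an annulus centered on the fitted ellipse
  boundary (half inside, half outside); band + interior partition the
  whole-cell region exactly.
- Quartiles use linear interpolation (numpy default, type 7).
- Patch prominence is mean peak over mean valley intensity of the
  smoothed circular profile; undefined (excluded, counted) for cells
  with no detected patches.
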