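# cellquant

Automatic cell-area quantification for transmitted-light (brightfield)
micrographs.

Unstained cells imaged by transmitted light are nearly invisible in
perfect focus; defocusing slightly makes whole cells uniformly darker
than the background, and the fraction of the field they cover
(confluence) becomes a usable proxy for proliferation.  The catch is the
background: cells grown in microfluidic chambers sit on uneven surfaces
whose shadows defeat any single global threshold.  `cellquant` solves
this locally — it cuts each image into tiles (36 by default, as a 6 × 6
grid), computes a **Ridler–Calvard (ISODATA)** threshold per tile,

&nbsp;&nbsp;&nbsp;&nbsp;T ← (μ<sub>≤T</sub> + μ<sub>>T</sub>) / 2&nbsp;&nbsp;&nbsp;iterated to a fixed point,

applies it to a Gaussian-smoothed copy of the tile (σ = 6 px), and
stitches the per-tile cell/background decisions into a full-image mask.
From the mask it reports percent area covered, physical area (given a
pixels-per-unit calibration), mean cell size via connected components,
and an estimated cell count (foreground ÷ mean cell area, robust to
confluent clusters).  Batches of images grouped by condition and
timepoint become growth curves (mean ± SEM) with a Kruskal–Wallis
omnibus and Dunn's post-hoc pairwise comparisons (Bonferroni, α = 0.05).

A seeded synthetic-micrograph generator — defocused dark ellipses of
fusiform and rounded shape over gradients, shading blobs and pixel
noise, with exact ground-truth masks — makes the whole pipeline
verifiable end to end without real microscopy data.

Intended for cell-culture labs quantifying growth from plain
transmitted-light images, and as a reference implementation of tiled
automatic thresholding with a fully synthetic test bed.

## Worked example

```python
import dataclasses
import cellquant as cq

# synthesize a ~20%-confluent 600x600 scene with known ground truth
base = cq.SceneSpec(seed=11)
n = cq.cell_count_for_coverage(base, 20.0)
scene = cq.generate_scene(dataclasses.replace(base, cell_count=n))

mask = cq.segment_image(scene.image)            # 6x6 tiles, sigma 6, dark cells
res = cq.measure_mask(mask, cq.CalibrationInfo(pixels_per_unit=820, unit_name="mm"))

print("true coverage :", round(scene.true_coverage_percent, 2), "% (", scene.true_cell_count, "cells )")
print("measured      :", round(res.area_percent, 2), "%")
print("physical area :", round(res.physical_area, 4), "mm^2")
print("mean cell area:", round(res.mean_cell_area_px, 1), "px^2")
print("est. count    :", round(res.estimated_cell_count, 1))
```

prints

```
true coverage : 19.52 % ( 123 cells )
measured      : 19.31 %
physical area : 0.1034 mm^2
mean cell area: 902.9 px^2
est. count    : 77.0
```

The measured confluence lands within a fraction of a percentage point of
the exact rasterized truth.  The estimated count is below the 123 placed
ellipses because at 20 % confluence neighbouring cells merge into single
connected components — the count estimate is designed for sparser
fields (where it recovers the truth within ~15 %), while the area
readout stays accurate at any confluence.

## Command line

```bash
cellquant simulate --out demo --seed 1          # synthetic growth experiment
cellquant segment demo/images/10_d10_r1.png --out results --ppm 820
cellquant batch demo/manifest.csv --out results --plot
cellquant stats results/results.csv --day 10 --out results
```

`segment` writes `<stem>_mask.png` (cells black, background white) and a
CSV row; `batch` processes a manifest
(`image_path,condition,timepoint_days,replicate_id`) into results,
summary and comparisons CSVs, skipping unreadable images with a logged
diagnostic; `--tiles 1x1` gives the classic global-threshold baseline.
Every flag has a `key=value` config-file equivalent via `--config`,
with command-line flags taking precedence.

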