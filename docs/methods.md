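# Methods

## Problem and model

Unstained cells imaged by transmitted light show very little contrast:
in perfect focus only the membrane is visible as a dark line.  The
acquisition regime this package targets therefore defocuses slightly, so
that the whole cell appears blurred but *constantly darker than the
background*.  Confluence — the percentage of the field of view covered
by cells — is then a well-defined intensity-segmentation problem and
serves as the proxy for proliferation in growth experiments.

The complication is the background itself.  Cells cultured in PDMS
microfluidic chambers sit on an uneven surface whose irregularities cast
shadows, so the background carries smooth lateral gradients and shaded
patches that defeat any single global threshold.  The pipeline's answer
is locality:

1. **Tiling.** The image is partitioned into a grid of tiles (6 × 6 =
   36 by default).  Tile sizes along each axis differ by at most one
   pixel, with the remainder assigned to the first tiles, so the tiles
   are an exact partition of the image.
2. **Ridler–Calvard (ISODATA) threshold per tile.**  Starting from the
   tile's global mean, iterate T ← (mean of intensities ≤ T + mean of
   intensities > T)/2 until the update is smaller than `tol` (0.5
   intensity units) or `max_iter` (100) is reached.  If either class is
   empty the current value is already a fixed point.  The threshold is
   computed on the raw tile by default (`threshold_on="raw_tile"`;
   computing it on the smoothed tile is available as an option because
   the order of operations is a genuine design choice).
3. **Gaussian smoothing.**  Each tile is smoothed with an isotropic
   Gaussian, σ = 6 px by default, reflect padding, kernel truncated at
   4σ, and the threshold is applied to this smoothed version: pixels
   strictly below the threshold are cells (dark-cells polarity; a
   bright-cells option inverts the comparison).  Pixels exactly at the
   threshold are background, so a uniform tile yields no foreground.
4. **Stitching.**  Per-tile binary decisions are written back at the
   exact tile boundaries; the result is deterministic for fixed input
   and parameters, and a 1 × 1 grid reproduces classic global
   thresholding exactly (used as the comparison baseline).

### Empty-tile guard

ISODATA always returns *some* threshold, including on tiles that
contain no cells at all, where it happily splits background noise in
half.  Two guards prevent this.  A tile whose intensity range is below
`tol` is trivially uniform and yields no foreground.  That alone is not
sufficient under realistic pixel noise (a blank tile with noise SD 3
spans ~25 intensity units), so a second guard inspects the converged
partition: if the two class means differ by less than `min_contrast`
(default 20 intensity units) the "cells" the threshold found are noise
or smooth shading, and the tile is declared cell-free.  The default sits
well below the ~50-unit cell/background contrast of the targeted
acquisition regime and well above the ~6–12-unit separation ISODATA
induces on pure noise plus within-tile shading.  Tiles whose true cell
content is a tiny sliver (≲2 % of the tile) can be zeroed by this guard;
at the coverages the pipeline is specified for this costs a fraction of
a percentage point.

## Quantification

From the stitched mask: foreground pixels are counted exactly and
divided by total pixels (percent area); with a pixels-per-unit
calibration the covered area is also reported in physical units
(foreground / ppu²).  Connected components are labelled with
8-connectivity (4-connectivity splits blurred diagonal contacts);
components below `min_area_px` (default 9 px, settable to 0) are
discarded as noise.  The mean component area, with the equivalent
circular diameter 2·√(mean/π) as a size proxy, yields the estimated
cell count as foreground ÷ mean component area — deliberately *not* the
number of components, because confluent clusters merge into single
components while the ratio stays approximately right.

## Statistics

Per-image coverages are grouped by condition × timepoint; each cell of
that grid is reported as mean ± SEM (sample SD / √n; 0 for identical
replicates, missing for n = 1).  Differences between conditions are
tested with a Kruskal–Wallis omnibus (tie-corrected, χ² approximation on
k−1 df; defined as H = 0 when every observation ties) followed by
Dunn's rank-based pairwise comparisons,

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j)),

two-sided normal p-values, Bonferroni-adjusted by default (Šidák and
unadjusted available), α = 0.05.  Dunn's test is the conventional
post-hoc after a Kruskal–Wallis omnibus because it is defined on the
pooled ranks; classical one-way ANOVA is exposed as an optional
alternative omnibus for users who prefer the parametric route.  Batch
processing is skip-and-log: a corrupt image is reported per file and
dropped rather than aborting a thousand-image run.

## Synthetic micrographs

The generator produces the study conditions for every verification in
this repository.  A scene is: a background at level 200 with a linear
left-to-right ramp of total amplitude 60 and three smooth dark shading
blobs (depth ~20, σ ~90 px) emulating chamber-surface shadows; elliptical
cells at a constant −50 intensity offset, blurred with σ = 2 px to
imitate slight defocus; pixel noise SD 3; everything clamped to
[0, 255].  Cells are a 50/50 mixture of fusiform (axis ratio sampled in
[3, 6]) and rounded (ratio in [1, 1.3]) footprints with mean area
600 px² (equivalent diameter ≈ 28 px — a plausible adherent-cell
footprint at a 20× acquisition scale, and large relative to the σ = 6
processing blur, so boundary blur remains a small fraction of cell
size).  Placement is rejection-sampled against a per-cell overlap cap
(default 5 %; a separation pad keeps cells countable in sparse scenes);
if packing cannot satisfy the request the generator raises an error
naming the limiting parameter.  The ground-truth mask records the exact
pre-blur ellipse geometry, so true coverage is an exact rasterized
count.

The growth-series generator emulates a serum-dose experiment: each
condition is a label plus a logistic growth rate, coverage follows
c(t) = c_max / (1 + ((c_max − c₀)/c₀)·e^(−rt)) with c₀ = 2 % and
c_max = 60 %, and one scene is generated per condition × day ×
replicate.  At high confluence random non-overlapping packing is
infeasible, so series scenes allow free overlap and invert the Boolean
coverage model, n = −ln(1 − c)·total/mean area, to choose the cell
count.  The logistic curve is a fixture choice that exists to exercise
the statistics stage, not a biological growth model.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: optics (no PSF, no vignetting beyond the
linear ramp), membrane rings of in-focus cells, intensity texture inside
cells, debris, cells detaching or clustering, and chamber boundaries
beyond simple dark frame lines (real chamber walls are handled by the
rectangular ROI crop, which is also the only ROI shape supported).

## Numerical choices and degenerate inputs

- RGB→gray uses Rec. 601 weights; 16-bit inputs are rescaled by the full
  dtype range (not per-image min/max) so thresholds stay comparable
  across a batch.
- Mask files are written black-foreground (cells 0, background 255) and
  round-trip exactly.
- ISODATA stopping: tol 0.5 intensity units, max 100 iterations;
  convergence is monotone in practice and both limits are generous.
- Non-square tile counts must be given explicitly as rows × cols; 36 is
  mapped to 6 × 6.
- Empty region list → an explicit no-cells signal, never a NaN; empty
  mask → estimated count 0.
- All randomness flows through `numpy.random.default_rng` seeded from a
  single integer; identical seeds give bit-identical scenes, masks and
  CSVs.

## Verification problem sizes

The repository's verification suite generates its own data: 500 random
bimodal tiles for the threshold oracle (exhaustive integer-threshold
scan), 50 scenes at 5–40 % coverage for coverage recovery, 20 scenes for
the tiled-vs-global comparison, 20 sparse scenes (10–50 separated cells)
for count recovery, 2000 simulated null datasets for type-I-error
calibration, and a full 6-condition × 6-day × 3-replicate series (108
scenes, 600 × 600 px) for the end-to-end ordering check.  These sizes
give stable statistics while keeping a complete verification run in the
order of a minute.

## Known limitations

- The class-separation guard trades a small loss of very sparse tiles
  for robustness on blank ones; scenes below ~1 % true coverage are
  reported as ~0 %.
- Count estimation assumes the mean component area approximates the mean
  single-cell area; it degrades once most cells touch (confluence ≳50 %),
  where only the area readout remains meaningful.
- The χ² approximation of the Kruskal–Wallis p-value is used at any
  group size; for very small n an exact permutation test would be more
  faithful (the test suite checks agreement at moderate n).
- No per-cell instance segmentation, morphology classification, or
  multi-page/z-stack input.
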