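# Methods

This note records the models, conventions, and numerical choices behind
`landfrag`, and what the synthetic test bed does and does not establish
about real map data.

## Carriers and conventions

All computation happens on rectangular integer-code grids with square
cells and a declared nodata code. Row 0 is the top (north) row; the
center of cell (r, c) is at offset ((c + 0.5)·cell, −(r + 0.5)·cell)
from the origin. Geotransforms are carried as opaque metadata for
output files but never used in computation: every distance and area
derives from the cell size in meters and grid indices. Rasters with
unequal x/y resolution are rejected rather than resampled, because all
metric formulas assume a single cell area.

Nodata is excluded consistently: it never joins patches, never fills
gaps between them, is excluded from moving-window denominators, and
does not count toward landscape area.

## Reclassification and landscape area

Source legends are collapsed to natural (1) / anthropic (2) / water (3)
through explicit, total mapping tables; an unmapped code is an error,
never a silent default. Water is background for fragmentation — it is
neither natural foreground (forest does not connect across rivers) nor
excluded from the landscape. Landscape area A therefore equals the
count of all non-nodata cells times cell area, which keeps the PD, LPI
and MESH denominators stable across dates: zone clipping, not class
content, defines the analysis extent. Clipping is applied before patch
labeling and FAD, so patches never extend across a zone boundary.

The shipped reclassification tables for real sources are editable CSV
files and should be treated as assumptions: typical level-1 legends do
not prescribe a unique grouping into these three classes.

## Patch metrics

Patches are 8-connected components (horizontal, vertical, and diagonal
adjacency), labeled deterministically in row-major discovery order.
ENN is the minimum center-to-center Euclidean distance from a patch to
any cell of a different patch, computed with a Euclidean distance
transform per patch; two cells separated by one empty cell in a row are
2 cell-widths apart. This grid-native convention was chosen over
polygon-edge distance because it is unambiguous and admits an exact
brute-force oracle. ENN_MN averages only patches with a defined
neighbor; a two-patch landscape contributes two (equal) values.

MESH is reported in hectares by dividing the m² ratio Σa²/A by 10⁴.
Degenerate cases are explicit: an all-background landscape has NP = 0,
PD = LPI = MESH = 0, and PA_MN/ENN_MN undefined (NaN, written as empty
fields, never 0); a fully-nodata landscape is an error.

## Forest-area density and fragmentation classes

FAD at a natural pixel is 100 × (natural cells) / (non-nodata cells)
over the window centered there, with the window clipped at the grid
border. The clipped-window denominator is self-consistent, treats map
edges and internal nodata identically, and is verified cell-by-cell
against a naive loop; it is exact because the window sums are integer
counts accumulated in float64.

The six-class scheme (rare/patchy/transitional/dominant/interior below
10/40/60/90/100%, intact at exactly 100%) uses lower-inclusive
intervals — a pixel at exactly 10% is patchy. Five- and two-class
schemes are available in configuration; the pipeline default is the
six-class scheme. Multiscale analysis computes the continuous FAD at
windows 7, 13, 27, 81, 243, averages per pixel, and classifies the
average once (average-then-classify), rather than voting over
per-scale classes.

On grids smaller than a window the computation degenerates gracefully:
the window covers the grid and FAD equals the global foreground share
among non-nodata cells at every pixel. The test suite exploits this
closed form rather than avoiding it. A practical consequence on small
grids: the multiscale *average* rarely reaches 100, so the "intact"
class thins out in the averaged map even where single scales saturate.

Change accounting cross-tabulates the per-pixel classes of two dates
over cells valid at both, with non-natural cells as state 0. Moves
from a higher to a lower class rank are fragmentation increases (mass
below the diagonal), the reverse decreases. Natural-cover loss is the
one-directional count of natural→non-natural cells in hectares.

## Paired source comparison

Differences d = x − y per common year; zero differences are dropped
(the test is undefined if all are zero — reported as such, not as
p = 1). The two-sided p-value is computed by full enumeration of the
2ⁿ sign assignments (subset-sum distribution of W⁺ over ranks 1..n)
when n ≤ 25 and the |d| are untied; otherwise a normal approximation
without continuity correction, with tie-corrected variance. The effect
size always uses the plain normal-approximation Z:
r = |W⁺ − n(n+1)/4| / √(n(n+1)(2n+1)/24) / √n ∈ [0, 1]. This exact-p +
approximate-r mix mirrors the common R workflow (`wilcox.test` with
exact defaults plus `rstatix::wilcox_effsize`) and reproduces both
reference values at n = 8 simultaneously: p = 0.0078125 (2/2⁸) and
r = 0.8911 at W⁺ ∈ {0, 36}. No multiple-testing correction is applied;
p-values are reported raw per metric × zone, rounded to 4 decimals
(r to 3) only in report files.

Note on naming: r is often described as a correlation coefficient on
[−1, 1], but the signed-rank effect size used here is |Z|/√n and lies
in [0, 1]; the sign of the difference is carried by W⁺ itself.

## Synthetic paired-source landscapes

The generator emulates the statistical structure the analysis assumes,
not any real geography. Defaults: 200×200 cells of 30 m (a 6 km
Landsat-resolution window), eight map years (1990–2022 with the real
series' spacing), and:

* a width-3 north–south road corridor (4-connected center line,
  dilated), which splits the initial forest into two patches — so ENN
  is defined from year one — and survives the coarse source's majority
  filter;
* frontier clearing with probability 0.4·exp(−d/2) per step (d = cell
  distance to cleared land), plus Poisson(3) small clearings of 1–5
  cells per step that become new frontier nuclei. These rates clear
  ≈ 2% → 29% of the grid across the series — enough fragmentation to
  drive every downstream stage without exhausting the forest;
* source A (coarse): majority filter of radius 2 (5×5), removing small
  clearings and specks — fewer, larger, more isolated patches;
* source B (fine): per-cell flips with probability 0.01 from a
  *persistent* flip field (the same derived sub-seed every year),
  modelling a systematic classifier bias. Persistence makes the fine
  source's patch count grow monotonically with cleared area, matching
  the monotone fragmentation trends of real series; independent
  per-year noise would make NP fluctuate between close map years.

Process noise and observation noise come from separate streams derived
from the master seed, so changing the observation parameters never
perturbs the underlying landscape. All outputs are bit-identical under
a repeated seed.

What passing tests show: the analysis stages correctly recover planted
contrasts (fine source: more and smaller patches, shorter neighbor
distances; both sources: monotone NP/PA_MN trends; all-same-sign paired
differences reproducing p = 0.0078 / r = 0.891 at n = 8). What they do
not show: realism of deforestation geometry, calibration to real
clearing rates, classifier error structure of any real product, or the
hectare-scale results of any particular territory.

## Problem sizes and tolerances

Oracle suites run on seeded random fixtures: 100 rasters of 20×20 for
the six metrics (flood-fill, all-pairs ENN, direct formulas; 1e-9
relative), 50 rasters of 30×30 for FAD windows 3 and 7 (per-pixel loop;
1e-9). Directional-recovery checks use five seeds of the default
200×200 scenario. These sizes keep the full suite under a minute while
exercising every degenerate branch (nodata, empty class, single patch,
window ⊇ grid). Exact Wilcoxon enumeration is O(n²·2ⁿ)-free via the
subset-sum distribution (O(n·W) with W = n(n+1)/2) and is the default
up to n = 25.

## Known limitations

* No reprojection, resampling, or vector clipping; inputs must already
  be aligned grids with square cells.
* ENN uses cell centers, so reported isolation distances exceed true
  edge-to-edge distances by up to one cell diagonal.
* GeoTIFF support targets single-band integer rasters written by this
  package or similar tools (pixel-scale + nodata tags); exotic GeoTIFF
  layouts are out of scope.
* The transition matrix is computed on the multiscale-average class
  map; per-scale transitions can be built from the per-scale maps but
  are not emitted by the pipeline.
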