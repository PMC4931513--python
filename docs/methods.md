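# Methods

This note documents the models, algorithms and numerical choices behind
`npscreen`: what each stage computes, what the synthetic generator does and
does not emulate, and where the design was genuinely open.

## 1. The well-level statistic

The screen readout is the LAMP1-associated NP ratio of a well: the mean
over QC-passing cells of the total NP intensity inside that cell's
LAMP1-positive spots, divided by the mean over the same cells of the total
NP intensity inside the whole cell mask. This is a **ratio of means**, not
a mean of per-cell ratios: cells contribute in proportion to their NP
content, and the statistic equals (total NP in spots) / (total NP in
cells) over the pooled pixel sets. Consequences used by the tests:

* it is invariant under any uniform rescaling of the NP channel, so the
  unknown intensity calibration of the original microscope is immaterial;
* it lies in [0, 1] because every spot pixel lies inside its cell's mask;
* a well with no passing cells (or zero NP signal) has an undefined ratio,
  flagged NaN rather than raised, and is removed later by the viability
  rule.

Cells are pooled across all fields of a well before averaging. Whether the
original analysis averaged per field first is not documented anywhere we
could find; pooling is the variant that uses every cell with equal weight
and is what `aggregate_wells` implements.

## 2. Background correction

LAMP1 and NP channels (only) are corrected by rolling-ball background
subtraction with a default radius of 10 px. The background is computed as
the grayscale opening of the image with a flat disk structuring element of
that radius — the classical "surface a wide ball rolls to under the
intensity landscape". The estimate never exceeds the image, so corrected
intensities stay non-negative; a constant image maps to zero; smooth
gradients are removed; structures narrower than the 21-px footprint
(cells, puncta at the simulated scale) are preserved. The operation is
idempotent on flat-background inputs. Tests verify the implementation
against a brute-force sliding-window erosion/dilation enumeration to
floating-point accuracy.

The scale relation matters: a radius-10 ball removes *any* plateau wider
than its footprint, so the simulated cells are drawn smaller than the
footprint (radius 6.5–9 px). At real 40x magnification cells are hundreds
of pixels across, and a 10-px ball would instead act inside the cell
texture; the simulated geometry preserves the property the pipeline relies
on — cellular signal survives the correction while the illumination
surface does not.

## 3. Segmentation

* **Nuclei** — Gaussian smoothing (sigma 1 px), Otsu threshold floored at
  (raw mean + 2 raw sd) so structure-free noise fields produce no objects,
  hole filling, minimum-area filter (6 px^2), then a distance-transform
  watershed (peak separation 4 px) to split touching nuclei.
* **Cells** — one region per nucleus, grown by a watershed on
  distance-from-nucleus restricted to a cytoplasm mask. The mask threshold
  is "adaptive": a permissive triangle threshold proposes foreground, the
  cytoplasm plateau level is estimated as the median smoothed intensity
  over that foreground, and the final cut is half the plateau. Plain Otsu
  fails here (it jumps to the bright puncta); plain triangle bleeds into
  the blur tail. Guaranteed properties: cell count equals nucleus count,
  cells are disjoint, each contains its seed nucleus.
* **Spots** — white top-hat at the spot scale (disk radius 3) measures
  contrast over local background; pixels above 40 intensity units are
  grouped, filtered to 2–200 px^2, and each spot is assigned to the cell
  containing its centroid, clipped to that cell's mask (spots outside all
  cells are discarded). Adjacent puncta can merge into one detected blob;
  the measurement that matters downstream is spot *pixel* coverage, which
  the tests check directly.

## 4. Per-cell QC

Three gates, applied with precedence border > apoptotic > mitotic:

* **border** — any cell-mask pixel on the outermost row/column (strictest
  deterministic reading of "close to the border");
* **apoptotic** — segmented nucleus area below 25 px^2;
* **mitotic** — nucleus mean intensity above 140.

The gates are configuration parameters; their defaults are calibrated on
the generator's rendering, where the measured classes separate cleanly
(healthy nuclei >= ~33 px^2 and <= ~126 mean intensity, apoptotic <= ~22
px^2, mitotic >= ~150). On planted fields the default gates remove border
and apoptotic/mitotic cells with 100% recall.

## 5. Screen statistics

`ScreenModel.fit()` performs, in order:

1. **Normalization** — each well ratio is divided by the mean NEG ratio of
   its scope (default per plate per replicate; per-plate and per-screen
   selectable). NEG wells then have mean 1.0 by construction. The control
   sd sigma is computed over the normalized NEG wells pooled across
   scopes; the scope is recorded in the output metadata. Computing sigma
   on replicate-averaged NEG values instead is supported by normalizing
   externally; pooled per-well sigma is the default because the phenotype
   bands are compared against per-well-level variability.
2. **Viability** — a treatment is discarded if any well analyzed fewer
   than 50 cells or its replicates total fewer than 150 ("fewer than" is
   strict, so 50/well and 150 total pass). Thresholds configurable.
3. **Phenotype call** — on the cross-replicate mean of normalized ratios:
   strong/mild decrease at mu - 3 sigma / mu - 2 sigma, mirrored increase
   classes at +2/+3 sigma; boundaries closed toward the more extreme
   class; sigma = 0 is a degenerate-control error. Calls are scale
   invariant: rescaling all raw ratios by any c > 0 changes nothing.
4. **Significance** — one-tailed two-sample Student's t-test (pooled
   variance; Welch selectable) of treatment versus NEG normalized wells,
   default direction "decrease". Zero variance in both groups with equal
   means returns p = 0.5 by convention.
5. **Validation** — a gene is validated when at least k of its siRNAs
   (default 2 of 3) show a mild or strong phenotype in the screened
   direction. Validation is monotone: adding a confirming siRNA never
   revokes it.
6. **Control readouts** — per-treatment mean ± sem of mean LAMP1 intensity
   per cell (and LysoTracker spot count/intensity when the columns are
   present), each tested one-tailed (increase) against NEG; this guards
   against "hits" that merely reorganize the lysosome compartment.

A statistical caveat documented on purpose: with 3 replicates a
treatment-mean estimator has sd ~ sigma/sqrt(3) = 0.58 sigma, while the
mild band is only one sigma wide, so borderline mild effects are
intrinsically uncertain calls. Strong calls (3+ sigma) and null calls are
robust; the planted-hit tests quantify this (sensitivity 1.0, null
false-positive rate 0.0 for 0.5x effects at neg_cv = 0.05).

## 6. Rank Weighted Colocalization

Within one cell mask of n pixels, both channels are ranked descending
(rank 1 = brightest, ties averaged). With D_i the absolute rank difference
and W_i = (n - D_i)/n,

    RWC = sum_{i in C} I_np(i) W_i / sum_{i in A} I_np(i),

A = pixels strictly above the NP threshold, C = pixels above both
thresholds. Properties (all tested, including against a brute-force rank
enumeration): 0 <= RWC <= 1; RWC = 1 iff C = A with all ranks agreeing on
A; RWC = 0 when C is empty; invariant under any strictly increasing
transform of the *marker* channel and under linear rescaling of the NP
channel (the NP intensities themselves weight the sums, so the NP side is
not fully rank-free). Per-cell thresholds default to Otsu within the mask
(fixed-percentile selectable); a constant channel thresholds to itself, so
nothing is "above" it. The original analysis's thresholding scheme is not
published; the method used is recorded in the configuration.

## 7. The synthetic generator

`simulate_field` renders nuclei as filled ellipses (apoptotic: shrunken
x0.35 and 2.5x brighter; mitotic: condensed x0.8, 2x brighter, no
cytoplasm ring), cytoplasm as a concentric ellipse, LAMP1 as a cytoplasm
haze (10 units) plus bright puncta (~150 units), and the NP channel as an
exact split: a planted fraction f_cell = clamp(f0 x effect, 0, 1) of the
cell's total NP intensity (20000 units) spread uniformly over its spot
pixels, the remainder over the non-spot cell pixels. Pre-noise, in-spot +
diffuse NP equals the per-cell total exactly and the field-level spot/cell
NP ratio equals the planted fraction exactly — the property every
downstream accuracy test is anchored to. Degradations applied on top:
a low-order polynomial background surface (amplitude 30) on the LAMP1/NP
channels, Poisson shot noise, Gaussian read noise (sd 3), quantization to
16-bit on write. Cell placement is rejection-sampled with near-contact
separation; impossible packings raise a degenerate-geometry error. Border
cells are planted by pushing centers within a fraction of a cell radius of
an edge.

Default study conditions: 256x256 px fields, 15 cells per field, 2 fields
per well (30 cells/well) for the image-level experiments; 400x400 px
fields with 60 cells for end-to-end runs that must clear the 50-cell
viability gate with one field per well. Screen-level variability enters as
a shared per-replicate multiplicative offset (cv 0.03; cancelled by
per-replicate normalization, as in a real screen) plus an independent
per-well jitter (cv 0.05). The imageless `simulate_well_table` draws well
ratios directly as baseline x effect x (1 + N(0, neg_cv)) truncated at
zero, with analyzed-cell counts from a configurable distribution — this is
what allows 348-treatment x 3-replicate x 20-seed experiments in seconds.

What the generator does **not** emulate: optical PSF and chromatic
effects, 3-D structure, cell-to-cell NP-content variability correlated
with morphology, spatial plate effects (row/column gradients across
wells), densely touching cell monolayers, and real staining variability.
Passing tests therefore demonstrate that the pipeline's estimators are
correct and well-calibrated on images whose ground truth is known — not
that segmentation would reach the same fidelity on arbitrary real screens.

## 8. Problem sizes and numerical conventions

Test and acceptance experiments use 256–400 px fields, 8–20 fields per
experiment, 348-treatment imageless screens over 20 seeds; these sizes
were chosen so the whole suite runs in a few minutes on one CPU while
keeping every statistical margin wide (e.g. planted-fraction recovery is
tested at |error| <= 0.05 where the measured noise-free error is ~0.01).
Label maps use 0 for background with pixel coordinates (row, col), origin
top-left. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning, making every artifact byte-stable
across reruns; CSVs are written with a fixed float format for the same
reason. The nominal pixel size (0.16 um/px) is metadata only.
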