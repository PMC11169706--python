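# Methods

## Scope and model of the data

The package analyzes positive-mode MALDI MSI cohorts of sagittal brain
sections from a two-group design (sham vs injured). A section is a raster of
pixels (imzML convention: 1-based coordinates, x = column), each carrying a
centroided spectrum. The statistical unit throughout is the **section**: ROI
abundances are averaged over a region's pixels, giving one observation per
section per feature. Two serial sections per animal are treated as
independent observations, mirroring the study design this pipeline targets;
this is acknowledged pseudo-replication, and `SectionMetadata.animal_id` is
carried through so users can aggregate to animals instead.

## Mass arithmetic

Monoisotopic atomic masses (CODATA/AME, ≥ 9 decimals) are hard-coded for
C, H, N, O, P, S, Na, K together with the electron mass. The proton mass is
*defined* as mass(H) − mass(e⁻) so that "add a proton" and "add H, remove an
electron" are numerically identical; this differs from the free-proton
CODATA value by ~1.4 × 10⁻⁸ u (hydrogen electronic binding energy), far
below the tolerances in play. Metal adducts are cationization: [M+Na]⁺ and
[M+K]⁺ are M + metal − e⁻, not proton displacement — this is the convention
under which the bundled panel's printed experimental m/z agree with theory
to < 0.7 mDa. The matrix dimer lock mass is modeled as the radical cation of
C20H18N4 (two 1,5-diaminonaphthalene molecules minus H2, minus one
electron), which reproduces the printed 314.152598.

Lipid shorthand (e.g. `PC(36:1)`) is resolved to elemental formulas through
a bundled table rather than a general shorthand parser; the table covers the
discriminant panel (LPC, LPC-O, PC, SM, HexCer species). The two HexCer
species are encoded with trihydroxy-ceramide formulas (C48H91NO9 /
C48H93NO9); these annotations are tentative (no MS/MS confirmation) and are
flagged as such in the table. Annotation matches within a Da tolerance
(default ±0.005) are sorted by |Δm| with ties broken by lipid name.

## Preprocessing

* **RMS normalization** divides each pixel's intensities by
  `sqrt(mean(I²))`; all-zero pixels are left untouched. Normalization is
  scale-invariant per pixel and makes the RMS of every normalized spectrum 1.
* **Mean spectrum** accumulates all pixels of all sections onto a log-spaced
  m/z grid (default 1 ppm bins), dividing by the total pixel count.
* **Sliding-window peak picking** selects apexes greedily by decreasing
  intensity, suppressing candidates within one ±ppm window of an accepted
  apex (default ±5 ppm). The intensity floor defaults to 3× the median
  absolute intensity of the binned mean spectrum — effectively the lowest
  possible threshold on sparse centroided data, intentionally permissive
  because downstream ROC filtering prunes the list.
* **Window refinement** re-centers each apex on the intensity-weighted mean
  m/z within its window and tightens the half-width (default to ±3 ppm).
  Windows are half-open `[lo, hi)` in Da after ppm→Da conversion at the
  apex, so adjacent windows never double-count a centroid. Feature
  abundance is the **sum** of centroid intensities inside the window (the
  area-style convention; `max` is available as an option).
* **Ion-image filters**: hot-spot removal clips above a quantile (default
  0.99); "weak" denoising is one 3×3 median pass and "strong" two 5×5
  passes, both with reflected borders. These definitions stand in for the
  proprietary filters of commercial MSI software; they reproduce the
  intended visual effect and are exactly specified.
* **De-isotoping** removes features lying 1.00336 Da (±tol) above a more
  abundant feature (¹³C satellites) and, optionally, +21.98194 / +37.95588
  Da duplicates of retained features (Na/K replacing H).

## Segmentation and ROIs

Bisecting k-means under the Manhattan metric: the segment with the largest
within-segment L1 cost is split into two by alternating nearest-center
assignment and component-wise **median** updates — the median minimizes L1
cost, so iterations never increase the objective. Two deterministic
initializations are tried per split: (a) the maximally L1-distant pair
within a canonically ordered, seeded subsample (≤ 256 points), and (b) the
parent median plus the farthest point from it; the cheaper result wins.
Initialization (b) guarantees the split never increases total cost.
Segments whose points are identical cannot be split, so a noise-free input
yields exactly one segment per distinct molecular profile. The partition is
invariant to pixel order (points are canonically ordered before any seeded
choice); only the arbitrary label numbering may differ.

ROIs are unions of segments: selected by explicit label sets, by ranking
segments on the mean abundance of a marker feature (keep all segments
≥ 50 % of the top segment's mean, or a fixed top-n), by the outer-cortex
layering rule (order segments outermost-first by mean distance to the
tissue boundary; accumulate inward until the pixel count lands in a target
range, default 2,500–3,500, preferring whichever of under/overshoot is
closer), or by a hand-drawn simple polygon (pixel centers strictly inside,
matching per-pixel ray casting). Segments touching the grid border are
classified as embedding background and excluded from marker-based ROIs.

The default leaf count is 9 (a configuration parameter; the underlying
workflow reports 8–9 segments for the cortical sub-region and does not fix
a whole-section count). The bundled phantom analyses over-segment to 12
leaves and merge by marker rank: over-segmentation followed by merging is
the standard way to let bisecting k-means resolve small structures, and the
marker rule absorbs the extra splits. Those analyses also segment on the
raw per-pixel abundances (`denoise: "none"`): the phantom's noise is
spatially independent, so a median prefilter only erodes the boundaries of
small structures (hippocampus recall drops from 1.00 to ~0.93 with a 3×3
pass at the phantom's 120×80 scale). On real acquisitions with correlated
speckle and ~10× more pixels per structure, the weak/strong presets are the
appropriate choice.

## Discriminant modeling

Per ROI and feature, the Mann–Whitney AUC (ties counted ½) is oriented
sham-positive. The ROC filter keeps AUC > 0.7 or < 0.3 (loose; hippocampus
and outer cortex) or > 0.8 / < 0.2 (strict; gray matter, white matter,
corpus callosum — regions with large input lists).

Models are PLS-DA fits (NIPALS, via scikit-learn's `PLSRegression`) of the
class indicator (1 = sham, 0 = injured) on Pareto-scaled abundances.
Pareto scaling centers each column and divides by √SD (sample SD, ddof = 1);
zero-variance columns become zeros. Feature ranking uses the pooled-variance
two-sample t statistic (the default univariate ranking of the web tool this
emulates); zero-variance/nonzero-difference degenerates rank first as ±∞.

Monte-Carlo cross-validation draws stratified 2/3 train : 1/3 test splits
(default R = 100 repeats; the emulated workflow says only "repeated several
times", and a percentile CI needs ≥ 50). Scaling parameters, t ranking and
top-k selection are computed on the training fold only — a dedicated test
verifies that a feature informative only among held-out sections is never
selected. The headline AUC pools test scores across repeats (stable with
test folds of ~6 sections); per-repeat AUCs give the 2.5/97.5-percentile
CI. Feature importance is the mean |t| over **all** repeats, counting
repeats where the feature was not selected as zero: conditioning on
selected repeats would inflate noise features that enter the top-k a few
times. Direction (higher in sham vs injured) is reported from group means.
Fold change is the injured mean ÷ sham mean of ROI-averaged normalized
abundances. `model_optimize` grid-searches (k, latent variables) by pooled
AUC with ties toward the smaller model.

## The phantom

The generator emulates the statistical structure the pipeline assumes, not
anatomy. A 120×80 pixel grid at 50 µm pitch holds a tissue ellipse on an
embedding background, subdivided by priority (OC > CC > HC > WM > GM) into
five disjoint schematic regions: a dorsal outer-cortex shell, a dorsal
corpus-callosum band, a hippocampal ellipse, a central white-matter core,
and gray matter elsewhere.

Every pixel's spectrum is built from a panel:

* the 17 discriminant lipid ions at theoretical adduct m/z, with
  class-based region baselines (LPC species gray-matter/cortex-leaning, SM
  and HexCer white-matter/callosal, PC broadly uniform, PC potassium
  adducts white-matter-leaning) and per-region injured/sham fold changes
  taken from the bundled reference table (an undetected entry is treated as
  fold change 1);
* 50 decoy lipids with fold change 1 everywhere — five are strong
  region markers (level 3.0 in their region vs 0.3 elsewhere) and the rest
  carry a five-phase level cycle so every pair of regions differs on most
  decoys, giving segmentation its molecular contrast and the ROC filter its
  negatives;
* three matrix ions (DAN monomer/dimer species) on every pixel and three
  embedding-only ions off tissue.

Noise model: peak m/z is jittered multiplicatively, Normal with SD 1 ppm
(default); intensities carry log-normal pixel noise (SD 0.15) and a
log-normal per-section, per-species biological factor (SD 0.05). All
log-normal factors are mean-one (σ²/2 correction), so configured fold
changes are exact in expectation for arithmetic means. The section-level
factor is this package's addition to the minimal noise description: without
it a 20-section cohort has essentially zero within-group variance and every
ROC/AUC property check is degenerate; 0.05 is a modest biological replicate
CV. Optional ¹³C satellites (+1.00336 Da at 0.45× the parent level)
exercise the de-isotoper. Centroided (not profile) spectra only.

Cohorts default to 8 sham + 12 injured sections (two per animal) with
per-section seeds spawned from one master seed; with an output directory the
generator writes imzML/ibd pairs, the samples table, truth masks and the
expectation table. imzML output is byte-deterministic: the file UUID is
derived from the pixel data, and the run id is normalized to the file stem.

### What the phantom does and does not emulate

It reproduces: centroided sub-ppm peaks at theoretical adduct masses,
region-structured composition, multiplicative intensity noise, group fold
changes, matrix/embedding background, optional isotope satellites. It does
**not** reproduce: profile peak shapes, baseline, spatially correlated
noise, section-to-section geometry variation, ionization suppression, or
in-source fragmentation. Passing recovery tests therefore demonstrates that
the pipeline's statistics and bookkeeping are correct under the assumed
noise model — not that the pipeline is robust to every artifact of real
acquisitions.

## Problem sizes and numerical choices

The bundled analyses and tests run 20-section cohorts of 9,600 pixels with
~75-peak panels, 100 MCCV repeats and a 3×3 (k, LV) grid — sizes chosen so
a full cohort analysis completes in minutes on one core while keeping every
group-size ratio of the emulated design (8:12 sections, 2/3 : 1/3 splits).
Recovery checks average over five master seeds. Determinism is exercised at
reduced grids (48×32), where it is equally binding.

Tie-breaks are fixed throughout: stable sorts for t ranking, smaller-model
preference in grid search, lexicographic tie-breaks in annotation sorting
and segment selection. Degenerate inputs have defined behavior (all-zero
pixels flagged and skipped by normalization, zero-variance columns zeroed
by Pareto scaling, unsplittable segments stop bisection early, empty ROI
selections raise stage-named errors).

## Known limitations

* The cross-validated AUCs of the original study are not reproducible
  without its deposited acquisitions; the phantom substitutes
  parameter-recovery and null-control properties.
* Lipid annotation is exact-mass only: isomers are indistinguishable,
  double-bond positions are not assigned, and the HexCer identifications
  are tentative by construction.
* The marker-based ROI rule presumes a feature with known regional
  specificity; on real data this is an analyst's choice, as is manual
  outlining of regions the segmentation misses.
* Sections are treated as independent; animal-level aggregation is left to
  the user via the samples metadata.
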