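# Methods

This note documents the models, algorithms, defaults and design choices in
`spatialtme`, and what the synthetic-data tests do and do not demonstrate
about real tissue data.

## Data model

The pipeline starts downstream of imaging: a cell table with one row per
segmented cell (position in µm, tissue compartment `tumor`/`stroma`, and a
pre-called boolean positivity per panel marker).  Positivity thresholds are
deliberately out of scope — they are set inside the upstream image-analysis
software and are not reconstructible from a cell table — so the file
dialect accepts but ignores optional intensity columns.  A lesion
(`SampleMap`) carries 3–5 regions of interest (ROIs), each one imaged 20×
field with its own bounding rectangle and per-ROI coordinate origin
(lower-left, y up).  ROIs are analyzed independently and pooled per lesion.

Patients with several metastatic lesions are merged into one per-patient
metastasis sample by default (ROI and cell identifiers are prefixed by the
source lesion), because the downstream pairing is per patient; a flag keeps
lesions separate for sensitivity analysis.

## Tumor boundary and region partition

The tumor/stroma interface is estimated per ROI from tumor-compartment
cell positions:

1. rasterize occupancy on a grid (`grid_resolution`, default **5 µm**);
2. morphologically close with a Euclidean disk (`closing_radius`, default
   **30 µm**, about two cell diameters — bridges gaps between neighbouring
   tumor cells without welding separate nests); the closing is computed
   with two exact Euclidean distance transforms (dilate = EDT ≤ r on the
   complement, erode = EDT > r of the dilated complement);
3. fill holes and vectorize the 0.5-level iso-contours into polygons,
   collapsing the half-pixel stair-steps (`simplify` at 0.45·resolution).

Both parameters are configuration-exposed because no canonical values
exist for segmentation done in commercial software; the defaults were
chosen for ~10–15 µm cells imaged at 20×.

Cells are labeled by the **signed Euclidean distance to the boundary**
(negative strictly inside, exact for polygons):

* TC ⇔ d < 0, TF ⇔ 0 ≤ d < `band_width`, PT ⇔ d ≥ `band_width`
  (default 150 µm).

Tie-breaks: a cell exactly on the edge (d = 0) is TF; a cell at exactly
the band width is PT.  The band is measured from the tumor *edge*, not the
lesion centroid — a fixed offset from the centroid would be meaningless
for cm-scale tumors — and the band is strictly extratumoral (cells inside
the mask are TC regardless of edge proximity).

Region **areas** are computed vectorially: TC is the mask clipped to the
ROI rectangle, TF is the clipped `band_width` buffer minus TC, PT the
remainder.  The three areas therefore sum to the ROI area to floating-point
precision (no rasterization error), and scale equivariance (coordinates and
band × k ⇒ labels unchanged, areas × k²) holds exactly.

ROIs with no tumor-compartment cells cannot be banded.  The default policy
is an error — real cohorts contain lesions whose peritumoral region cannot
be delineated, and silently defaulting would hide that — with an explicit
`all_pt` alternative that labels everything peritumoral.

## Densities

Density = phenotype-positive cells per mm² of regional tissue area.  Counts
are pooled across a lesion's ROIs and divided by the summed regional area
(**Σcounts/Σareas**), which is the unbiased estimator under unequal field
areas; an unweighted per-ROI-mean option exists for sensitivity analysis.
Besides TC/TF/PT, an `ALL` row pools TC+TF for non-regional (intratumoral)
comparisons.  A region with zero tissue area yields a *missing* density —
never 0 or ∞ — and missingness propagates into the statistics by pairwise
deletion.  Single-marker phenotypes assert nothing about other markers;
the three macrophage subtypes (CD68⁺CD163⁺ / CD68⁺CD163⁻ / CD68⁻CD163⁺)
plus double-negatives partition the cell set exactly.

## Immunotype classification

With threshold *t* (cells/mm²) on CD8 density: inflamed ⇔ d_TC ≥ t;
excluded ⇔ d_TC < t and d_TF ≥ t; desert ⇔ both < t.  There is no
published numeric cutoff for this three-way phenotype, so the default *t*
is the cohort median of tumor-center CD8 densities (data-adaptive, unit
free); any fixed threshold can be configured, and the threshold used is
recorded in every call.  Raising *t* can only move a lesion along
inflamed → excluded → desert, never backwards (tested property).  Lesions
whose call would depend on a missing density are reported as
`unclassifiable` rather than guessed.

## Statistics

Paired designs (same patient: region-vs-region within a lesion,
primary-vs-metastasis within a patient) use the **Wilcoxon signed-rank
test**; independent clinical subgroups use the **Wilcoxon rank-sum
(Mann–Whitney U) test**.  Both are implemented in-package:

* zero differences dropped before ranking; mid-ranks for ties;
* **exact** two-sided p by dynamic programming over the null distribution
  of rank sums — all 2ⁿ sign assignments (signed-rank, n ≤ 25, untied
  |differences|) or all C(m+n, m) group assignments (rank-sum, m+n ≤ 20,
  no ties across groups); two-sided p = 2·min(P(T ≤ t), P(T ≥ t)) capped
  at 1;
* otherwise the tie-corrected **normal approximation** with a 0.5
  continuity correction.  Exact enumeration is disabled under ties
  (conservative; the approximation handles mid-ranks correctly).

The battery reports raw p-values (α = 0.05) without multiplicity
adjustment, matching common practice for exploratory marker panels; an
optional Benjamini–Hochberg column (per family) flags sensitivity.  Every
row records which test and which path (exact/approximate) produced it.
scipy's implementations serve as independent cross-checks in the test
suite, never as the computation path.

## Synthetic cohorts

`SynthConfig()` *is* the study-conditions preset: 17 patients, one primary
and 1–4 metastatic lesions each (lesion count ~ the 10/3/4 split of the
emulated cohort; diameter lognormal with median 3 cm clipped to 0.5–9 cm),
3–5 ROIs of 1000×1000 µm per lesion.  Each ROI contains a tumor mask (disc
of radius U(280, 360) µm with ±30 µm center jitter, or a smoothed random
blob) filled with tumor-compartment cells at 5000 cells/mm² — dense enough
that boundary estimation recovers the mask to within a few µm.  Each
immune phenotype is an independent inhomogeneous Poisson process, piecewise
constant on the *true* TC/TF/PT zones; macrophages are one process whose
cells draw a joint CD68/CD163 state from per-region probabilities.  Marker
processes are otherwise independent because the analysis only consumes
marginal densities plus that one joint — richer dependence would be
unidentifiable here.

The preset intensities encode the qualitative effect pattern the pipeline
is designed to detect: a 3× invasive-front band for the lymphoid and
checkpoint markers (CD8, Foxp3, CD68, CD163, CD20, CD11c, VEGFR-2, PD-L1),
TC > TF for CD66b and Ki67, flat IFN-γ, a peritumoral CD163 excess in
metastases with the metastatic PT CD68⁻CD163⁺ intensity 3× the primary PT
value, and a CD68⁻CD163⁺-dominated metastatic macrophage pool.  No real
patient's numeric densities are asserted — the emulated study's per-patient
data are unpublished — so synthetic magnitudes are realistic orders of
magnitude (0.5–12 cells/mm² for immune phenotypes), not reproductions.
Clinical subgroup effects (e.g. Foxp3 ×2 for diameter ≥ 3 cm) multiply the
affected patients' intensities; recovery comparisons therefore use each
lesion's *effective* intensity from the ground-truth sidecar.

Ground truth (boundary polygons as WKT, zone areas, effective intensities,
regime labels) is written to a separate `ground_truth.json`, never into the
cell tables, so the pipeline cannot accidentally consume it.  Identical
seed + configuration reproduces cohorts bit-identically.

**What passing synthetic tests does not show:** real tissue has irregular,
sometimes fragmented tumor masks, spatially correlated cell placement
(clustering beyond Poisson), segmentation and thresholding errors, and
markers co-expressed beyond the CD68/CD163 joint model.  The geometry
oracle tests certify the banding computation, not the adequacy of a
150 µm band for any particular tissue.

## Problem sizes and numerical notes

* Acceptance-scale simulation checks use 50 replicate 17-patient cohorts
  (contrast detection rates, density recovery averaged over replicates),
  4 cohorts for immunotype recovery, 200 random instances for the geometry
  oracle and 200 for the exact-test enumeration oracle — sizes chosen so
  the whole suite runs comfortably on one CPU.
* Exact-test p-values are compared to enumeration at 1e-12; geometry labels
  must match the brute-force scan exactly.
* Degenerate inputs: empty pair sets and empty groups give *missing* test
  results (not p = NaN crashes); all-zero differences give p = 1 at
  n_effective = 0; zero-width bands give an empty TF region; a
  zero-area region with a nonzero count raises an integrity error.

## Known limitations

* The boundary estimator assumes the tumor mask is resolvable from
  tumor-compartment centroids; very sparse or single-file tumor cells
  produce fragmented masks (mitigated, not solved, by the closing radius).
* The immunotype rule is a declared operationalization of a qualitative
  concept; published analyses may have classified visually.
* Exact rank-sum enumeration is limited to m+n ≤ 20; beyond that the
  continuity-corrected normal approximation is used (|Δp| ≲ 0.01 at the
  switch point in untied data, verified in tests).
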