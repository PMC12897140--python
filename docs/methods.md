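# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `arrayquant`.  It is written for a reader who wants to
know exactly what the package computes and why, including every place
where the design was genuinely open.

## Image model and coordinate convention

A scan is a 2-D array of non-negative float intensities; pixel (x, y)
means column x, row y, 0-based, y increasing downward (TIFF raster
order).  Spots are assumed bright on dark after optional polarity
inversion (p → max − p).  Inversion is a user flag, not auto-detected:
sparse arrays defeat intensity-histogram heuristics, and a wrong guess
silently corrupts every downstream number.  RGB scans are collapsed by
an unweighted channel mean — array scans are effectively monochrome and
perceptual (luminance) weighting would surprise users comparing
channels.  Scans smaller than 64×64 px are rejected as degenerate.

## Stage 1 — spot detection

**Contrast enhancement.** Intensities are linearly mapped so the
`contrast_lower` (default 1) and `contrast_upper` (default 99)
percentiles become 0 and 1, clipping outside.  A zero-range image is
passed through with a warning.

**Multi-scale LoG.** The scale-normalized response
−σ²·∇²(G_σ ∗ I) is computed at `num_sigma` = 9 scales log-spaced in
[`min_sigma`, `max_sigma`] = [4, 12] px (log spacing is standard
scale-space practice; the defaults suit the 10–30 px spot pitches of
membrane arrays).  Local maxima over the 3-D (scale, y, x) neighborhood
above the detection floor become blobs with radius σ√2; centroids are
refined by a 2-D quadratic (Taylor) fit around the peak, falling back to
the integer pixel at borders or degenerate Hessians.  Maxima within 2 px
of the image border are discarded (filter boundary artifacts).

**Detection floor.** The floor is
`max(threshold, 5 · σ̂_noise · √(3/8π) / min_sigma)`, where `threshold`
(default 0.02) is the configured absolute cutoff and the second term is
the standard deviation that white pixel noise of estimated level
σ̂_noise induces in the finest-scale normalized LoG response (the finest
scale passes noise strongest, so it bounds all scales).  σ̂_noise comes
from a robust high-frequency estimator: the median absolute response of
the 3×3 biharmonic kernel divided by 6·0.6745 — smooth spots several
pixels wide barely excite this kernel, so the estimate tracks noise even
when spots cover most of the membrane.  On clean images the estimate is
≈ 0 and the configured threshold rules; on noisy scans (SNR ≈ 10) the
adaptive term suppresses hundreds of spurious maxima that a fixed
threshold admits.  The multiplier 5 gives a ≈ 3·10⁻⁷ per-pixel false
positive rate under Gaussian noise.

**De-duplication.** Within `radius_filter` (default 15 px) only the blob
with the largest radius survives, ties broken by stronger response, then
smaller (y, x).  "Largest" is taken as largest *radius* with response as
tie-break; reading it as strongest response is the other defensible
choice and differs only when a big faint feature overlaps a small bright
one.  Implementation is greedy suppression in priority order, equivalent
to repeatedly keeping the top remaining blob and deleting its
neighborhood.

**Outlier removal.** DBSCAN on (x, y) with `cluster_eps` defaulting to
2× the median nearest-neighbour distance and `cluster_min_pts` = 4;
noise-labelled blobs (dust, scratches, membrane edges) are dropped.

## Stage 2 — grid reconstruction

**Rotation.** For candidate angles −30°…+30° in 0.1° steps, centroids
are rotated about their mean and scored by total within-row Y scatter
plus within-column X scatter, rows/columns formed by splitting the
sorted coordinate at gaps larger than 0.75× the median nearest-neighbour
distance.  The 0.75 factor matters: a square lattice rotated onto 45°
projects onto a diagonal sublattice with spacing pitch/√2 ≈ 0.707×pitch,
which a smaller gap threshold mistakes for genuine rows (a spurious
variance minimum); at 0.75 those projections merge into high-scatter
groups while true rows (spacing ≈ pitch) still split.  Confidence is the
relative variance reduction versus 0°, clipped to [0, 1] — dimensionless,
0 when rotation does not help, ≈ 1 for a strongly rotated clean grid —
and the correction is applied only when confidence exceeds 0.3.  Fewer
than 9 blobs (no plausible 3×3 grid) skips estimation.  The rotation is
applied to *centroids only*; intensities are later measured in original
image coordinates by mapping well positions back through the inverse
rotation, so pixels are never resampled.

**Rows, columns, lines, wells.** 1-D DBSCAN on Y (rows) and X (columns),
eps defaulting to half the median nearest-neighbour distance,
min_samples 3; groups are ordered by mean coordinate.  Groups smaller
than half the median group size are discarded: margin artifacts
otherwise form a phantom sparse row that shifts every well label by one.
Rows are fitted by OLS of y on x, columns of x on y (vertical columns
stay non-singular); single-member groups get slope 0 with a warning.
Missing lines — a whole row/column of analytes too faint to detect —
are interpolated: gaps of ≈ m pitches between adjacent intercepts get
m − 1 evenly spaced lines with interpolated slope (edge lines outside
the detected span cannot be recovered).  Well positions are exact
row×column line intersections, so wells without a detected spot are
still measurable.  Labels follow plate convention (row letters A…Z,
AA…; 1-based column numbers).  The template (wells, lines, median blob
radius, control tags) serializes to a versioned plain-text file and
reloads bit-identically.

## Stage 3 — template alignment

**Transform.** Similarity transform with rotation θ ∈ ±15°, translation
±50 px, uniform scale 1 ± 10%, parameterized about the template's well
centroid (the natural fixed point available to the template; rotating
about any other point only re-parameterizes the translation).

**Objective.** The reported score is the fraction of *detected blobs*
with no transformed well within the match radius (the template's median
spot radius).  Normalizing by detected blobs rather than template wells
means template wells with no detection cost nothing — absent analytes
are not penalized.  Score 0 is perfect overlap; ≥ 0.9 after the search
flags the template as wrong for the image.

**Global search.** `scipy` differential evolution (populations of 40,
up to 200 generations, seeded, no polish) minimizes a *graded* version
of the objective: each blob contributes credit 1 − d/r clipped to
[0, 1], with r = max(match radius, half the grid pitch).  Two reasons:
the counting objective is piecewise constant below the match radius
(gradient-free plateaus), and a periodic grid has deep local minima one
pitch apart — grading over half a pitch smooths the landscape and
enlarges the true basin (a one-pitch shift still loses its edge
row/column) without moving the optimum.  Up to 3 independent seeded
starts are taken, stopping early once a run reaches near-perfect
overlap; the counting objective of the best transform is reported.

**Local refinement.** Run only when the global objective is below 0.5.
L-BFGS-B within the same bounds on a soft-min objective: each blob's
residual is the soft minimum (temperature = match radius / 3, over its
4 nearest wells) of its distances to transformed wells — smooth where
the counting objective is flat, giving sub-pixel convergence.  If the
refined transform would worsen the counting objective it is reverted;
refinement therefore never degrades the alignment.

**Correspondences and warp.** Mutual-nearest-neighbour pairs within the
match radius (each well and blob used at most once).  With ≥ 10
non-collinear pairs a thin-plate spline (kernel U(r) = r² log r, affine
part plus one weight pair per source point, side conditions P'w = 0) is
solved exactly; regularization λ defaults to 0 (pure interpolation — the
correspondences are already mutual-NN-filtered, and membrane distortion
is smooth at the 1–2 px scale).  Fewer pairs, or collinear geometry,
skips the warp with a recorded reason and keeps the rigid result.

**Template edits.** Orientation inversion (180° relabelling; control
tags follow their physical wells; an involution), control remapping,
and well addition/removal.  Added wells get positions from an affine
lattice fit (position ~ base + row·row_vector + col·col_vector over all
wells), preserving pitch.

## Stage 4 — intensity measurement and normalization

Per-well raw value: mean pixel intensity over a flat disk of the
template median radius at the aligned well position (matching intensity
"averaged over the whole spot area"); a Gaussian-weighted mean
(σ = radius/2, truncated at 2σ) is available to mirror a Gaussian spot
profile.  Disks are clipped at image borders (mean over valid pixels);
a well outside the image gives NaN with a warning.  Measurements are
template-driven: detections that match no well are never measured, and
every well is always measured — the output table always has
n_rows × n_cols rows.

Normalization is a two-point linear anchor:
normalized = (raw − μ_neg)/(μ_pos − μ_neg) with μ_pos the mean of the
positive-control (reference) wells and μ_neg the negative-control mean.
By construction the negative control maps to 0, the positive to 1, and
any gain/offset change of the whole scan cancels exactly.  μ_pos ≤ μ_neg
is a failed array.  Values below the negative control floor at 0;
log_norm = log₂(max(normalized, ε)) with ε = 10⁻⁴ on the normalized
scale (finite logs; below plausible assay noise).  No local background
subtraction is performed — the negative control serves as the global
background reference.  Duplicate spots are averaged *after*
normalization (averaging before would weight spots by raw brightness;
after, each spot contributes on the common normalized scale — with
linear normalization the two differ only through the floor).  The
packaged 105-analyte map yields exactly one value per analyte (105
rows), controls excluded.

## Differential statistics

For replicate groups A (test) and B (reference), per analyte:

* log2FC = log₂(mean(v_A)/mean(v_B)); non-positive means floor at 10⁻¹²
  with a warning.  Antisymmetric under group swap and invariant to
  common positive scaling.
* Z = 1 − 3(σ_a + σ_b)/|μ_a − μ_b| with *sample* (n−1) standard
  deviations (the convention for the statistic's original screening
  use; with n = 4 the n vs n−1 choice shifts Z by ≈ 0.07 near the gate).
  Equal means give a −∞ sentinel (inconclusive).
* Welch t with Welch–Satterthwaite degrees of freedom, two-sided p,
  annotated *: p < 0.01, **: p < 0.001, ***: p < 0.0001.  Zero variance
  in both groups: p = 1 at equal means, p → 0 (flagged) otherwise.
* Quality bands: ideal Z ≥ 0.9; excellent 0.5 < Z < 0.9; marginal
  0 < Z ≤ 0.5; inconclusive Z ≤ 0.  The 0.5 boundary is the standard
  "excellent assay" cut; 0.9 for "ideal" is this package's convention
  for a near-noise-free separation.
* Joint significance gate: |log2FC| > 1 and Z > 0.5.  No
  multiple-testing correction is applied on the protein side: the gate
  already combines effect size and assay quality, and the Welch p is
  reported in bands rather than thresholded alone.

## Concordance

Protein analytes join transcripts case-insensitively through a shipped
analyte→HGNC-symbol table.  Directional calls per platform: up/down when
significant (protein: joint gate; RNA: p_adj < 0.01 and |log2FC| > 1)
with the corresponding sign, else neutral.  The 2×2 table counts
N_overlap (same direction on both), N_cyt and N_rna (directional on one
platform only), N_neither = N − rest, N defaulting to the number of
matched pairs.  Pairs directional on both platforms but in opposite
directions are not overlap; by default each such pair credits both N_cyt
and N_rna ("each platform called it, neither overlaps"), with a
"neither" mode available — the tallying of this rare case is ambiguous
in the field and the choice is exposed.  One-sided Fisher's exact
(alternative "greater") gives P(X ≥ N_overlap) under fixed margins;
p < 0.05 is flagged.  Pearson correlation of paired log2FCs is reported
for all pairs and for the RNA-significant subset.  Pooling across
comparisons is concatenation of pair lists.

## Synthetic arrays (what the generator does and does not emulate)

Rendered image: rectilinear lattice of Gaussian spots
a·exp(−d²/2σ²) (σ default 4.5 px, pitch 24–30 px), similarity transform
about the image center, sinusoidal membrane warp (amplitude ≤ 2 px,
period 200 px), linear background ramp on a 500-count offset, optional
per-spot placement jitter, seeded Gaussian pixel noise, clipped to 8/16
bit.  The canvas is sized from the *untransformed* lattice plus a fixed
margin so that templates and transformed renders share one coordinate
frame.  Spots closer than 4σ, or transforms that push spots off-canvas,
are spec errors.

Replicate experiments: reference amplitudes per analyte default to a
seeded log-uniform draw over 1500–60000 counts at 16 bit (the ~100×
within-membrane dynamic range typical of cytokine panels, scaled to
1500–12000 under a 50000-count reference spot); treated amplitudes are
reference × 2^log2FC.  Each analyte spot (each duplicate independently)
is multiplied by mean-one lognormal noise of coefficient of variation
`cv` (default 10%) — chemiluminescent and NIR spot intensities vary
multiplicatively, and spot-level noise is the physical granularity, so a
replicate's analyte value (the duplicate average) has effective cv ≈
cv/√2.  Positive controls are fixed and bright in every image; the
negative control renders at background.  Each membrane also gets a small
random rotation/translation/scale, as separate physical membranes would.

Not modelled: optical blooming, saturation streaks, membrane texture,
spatially correlated background, antibody cross-reactivity, or
concentration–intensity nonlinearity.  Passing tests therefore
demonstrate geometric and statistical correctness of the pipeline, not
scanner physics or assay chemistry.

## Self-evaluation protocols

`arrayquant.evaluation` fixes three protocols (used by the acceptance
script and tests):

* **Geometric recovery** — 50 seeded fixtures of an 8×10, pitch-30 grid:
  rotation ±25°, translation ±40 px, scale ±8%; 20 clean, 15 with
  0.5–2 px warp, 15 with warp + 1 px jitter + SNR-10 pixel noise.
  Rotation error is scored on the warp-free group (a warp genuinely
  tilts the grid, moving the variance-optimal angle by up to ~0.25°, so
  a 0.1° tolerance is only defined without warp) and on the noisy group;
  localization is scored on clean+warp (within 1 px) and noisy (within
  2 px) wells.
* **Effect recovery** — 2 conditions × 4 replicates of the packaged
  105-analyte layout; injected log2FCs (+2 ×20, −2 ×20, +1 ×5, −1 ×5,
  0 ×55) assigned to a seeded permutation of the panel (scattering
  regulated analytes across the membrane); cv 10%; full pipeline from
  pixels to the differential table.  Reports max |log2FC error|, joint-
  gate power at |log2FC| = 2, and the null false-flag rate.  Note the
  population Z-factor of a 4-fold change at 10% cv is exactly 1 −
  3(0.4μ + 0.1μ)/3μ = 0.5 — precisely at the gate — so even with
  duplicate averaging (effective cv ≈ 7%) power saturates near ~93%,
  its intrinsic ceiling under these conditions.
* **Welch null calibration** — 10,000 equal-mean lognormal analyte pairs
  at n = 4; fraction with p < 0.01.

Problem sizes keep the whole battery within a few minutes on one CPU.

## Numerical choices and degenerate inputs

Ties in the rotation search resolve toward the smallest |angle|; ties in
de-duplication by response then (y, x).  Near-parallel grid lines
(|1 − a_r·a_c| < 10⁻⁹) raise a gridding error rather than produce a wild
intersection.  TPS systems are solved by dense LU; collinear sources are
rejected by a rank test.  Blank images detect zero blobs; fewer than 4
blobs refuse alignment; an all-noise blob set returns empty with a
warning.  CSV round-trips preserve 12 significant digits; templates and
result tables reload bit-identically at fixed seeds.

## Known limitations

Rectilinear grids only (no hexagonal/radial layouts).  One scan is
aligned at a time (no joint multi-image registration).  Semi-quantitative
output only — no absolute concentration calibration.  Edge rows/columns
that are entirely undetectable cannot be distinguished from a smaller
array.  The rotation search window is ±30° and the alignment window
±15°/±50 px/±10%; scans outside those bounds need manual pre-rotation.
RNA-seq processing is out of scope: the concordance module consumes a
precomputed differential-expression table.
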