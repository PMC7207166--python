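# Methods

This note documents the models, statistics and design choices behind
`icdquant`, in the order a screen flows through the package.

## Image model and synthetic fields

Fields are single-plane, 16-bit unsigned, row-major images with 0-based
pixel coordinates and intensities in arbitrary units, matching an sCMOS
camera on an automated widefield microscope.  The generator
(`icdquant.synthetic.make_field`) renders nuclei as filled ellipses
(minor/major axis ratio 0.85, random orientation) with a Gaussian edge
blur of sd 1 px, places them by rejection sampling with a 4-px guard gap
(bounded retries; an overcrowded request fails explicitly rather than
degrading), and adds Gaussian read noise only.  What it deliberately does
**not** emulate: Poisson shot noise, illumination gradients, a realistic
PSF, 3-D structure, or out-of-focus fields.  Passing recovery tests on
these images therefore validates the *measurement logic* — segmentation
topology, ROI accounting, anchoring arithmetic — not robustness to the
full noise structure of real acquisitions.

The planted "signal" channel is painted over the whole cell footprint
(nucleus plus cytoplasmic ring) at `level · (1 − inhibition)`, so both
nuclear readouts (EU/AHA incorporation) and cytoplasmic readouts
(quinacrine, peIF2α) recover the planted level.  Punctate channels place
disks inside the cytoplasmic annulus.  The truth table stores, per cell,
the mean of the noiseless rendered image over the truth mask — i.e. the
value an ideal measurement would return, including the small edge-blur
loss — alongside the planted level itself.

Default study conditions: 512×512 px fields, ~70 cells per field, nucleus
radius 12 ± 1.5 px, signal 1 000–1 500 a.u. over a 50–100 a.u. background,
read noise 5–25 a.u. (recovery tests use 5% of the signal level).  These
are typical for a 20× widefield screen of adherent osteosarcoma-like cells
at sub-confluence.

## Segmentation

Nuclei: Gaussian smoothing (sd 2 px) then Otsu threshold — the standard
parameter-light pipeline; hole filling; watershed on the negated distance
transform.  Watershed seeds are distance-transform maxima with a minimum
separation of 0.7× the median equivalent radius of the foreground
components; the factor is below 1 because merged (touching) blobs inflate
the radius estimate, and a full-radius separation suppresses the second
seed of a fused pair.  Objects touching the image border are discarded
(partial cells bias intensity), as are objects outside a configurable
`[min_area, max_area]` gate — this area gate, plus optional PI gating at
classification, is the debris/dead-cell exclusion step.

Cytoplasm: a fixed-width annulus (default 8 px) around each nucleus,
assigning each background pixel within reach to its nearest nucleus.
Exact ties between two equidistant nuclei resolve deterministically by
the distance transform's scan order.  The nuclear and cytoplasmic masks
of a cell are disjoint by construction and no pixel is claimed twice.
A full-cell (e.g. membrane-to-membrane) segmentation is out of scope; the
annulus is the convention the cytoplasmic readouts assume.

Per-cell measurement uses arithmetic means over mask pixels and the
*population* standard deviation for the cytoplasmic CV (σ/μ).  A cell
whose annulus has zero area keeps its record with cytoplasmic fields NaN
and a `cyto_missing` flag.

## Anchored inhibition

Transcription (EU) and translation (AHA) incorporation are expressed as
percentages ranged between two anchors measured on the same plate: the
untreated control (0% inhibition) and a blank control never exposed to
the label (100%):

    inhibition % = 100 · (x̄_ctr − x̄) / (x̄_ctr − x̄_blank)

The statistic is invariant under shared affine transforms of all three
inputs, which is why multiplicative segmentation biases (edge-blur loss
affects all wells equally) cancel.  Values outside [0, 100] are reported
as-is by default; anchors closer than a tolerance raise an error rather
than returning an unstable ratio.

## CALR dot area

Bright CALR-GFP puncta are isolated with a white top-hat (disk structuring
element, default radius 4 px); pixels above a high threshold inside the
cytoplasmic masks are counted.  The default threshold is mean + 3 sd of
the *control* top-hat response pooled over timepoints — a declared
convention, applied globally rather than per field.  The treated area is
divided by the control area at each timepoint; timepoints with zero
control area are flagged and excluded; the summary is the trapezoid AUC
on the acquired grid, with no interpolation.

## HMGB1 release

Single-cell nuclear-intensity tracks are normalized to their first
timepoint; the release speed per interval is the consecutive difference,
the per-cell speed the mean of the differences, and the assay statistic
the mean over cells.  Because the interval differences telescope, the
per-cell speed equals (last − first)/(n − 1) exactly, which the tests use
as a closed-form oracle.  Release is *negative* (intensity loss); the sign
is kept.  Tracks starting at a non-positive intensity are dropped and
counted.

## Positive-cell fractions

The threshold between a negative and a positive control distribution is
the intensity minimizing the total misclassification of the two control
samples, found by exhaustive search over midpoints of the sorted pooled
values (ties resolve to the midpoint of the two control medians).  This
rule is deterministic and directly checkable against a grid-search
oracle.  Controls that no threshold separates better than chance fail the
assay explicitly.  `direction="below"` supports loss-of-staining calls
(quinacrine-negative cells).

## Surface overlap coefficient

Channels are binarized (Otsu by default, explicit thresholds accepted)
and the SOC is the Jaccard-style |A∩B|/|A∪B|: symmetric, bounded in
[0, 1], and undefined (explicit error) when both masks are empty.  The
alternative normalization |A∩B|/min(|A|,|B|) is a one-line switch inside
the same function should a different colocalization convention be needed.
Per-well SOC values are ranged between the control (0% inhibition) and
the dataset minimum (100%).

## Dose response and IC60

Cells are gated dead (PI ≥ threshold, taking precedence), pyknotic
(condensed nucleus *and* Hoechst-bright, among PI-negative cells) or
healthy; the three labels partition every table.  Default derived gates:
Hoechst-high = control median + 2 MAD, condensed = 0.6× control median
area; the PI gate is instrument-dependent and must be supplied.

The healthy *fraction* (not count — per-well totals vary) is fitted
against dose with the 4-parameter log-logistic model
`y(x) = c + (d−c)/(1+(x/e)^b)`, parameterized internally in log e for
positivity, with a multi-start over b ∈ {0.5, 1, 2, 4}, bounds c ≥ 0 and
d ≤ 1.05 × max fraction, keeping the lowest residual sum of squares.
Untreated (dose 0) wells are offset to one tenth of the smallest positive
dose on the log axis — declared and configurable.  A fit is flagged
non-converged (and no IC60 emitted) when the response has near-zero
variance, every start fails, or the fitted dynamic range d − c collapses
below 1e-6.  The IC60 — the dose at which 40% of cells remain healthy —
is the closed-form inverse `e·((d−c)/(0.4−c) − 1)^{1/b}`, defined only
when 0.4 lies strictly between the asymptotes.

## RUSH kinetics

After pointwise normalization to the control at each timepoint, inhibition
is `100 · (1 − slope_cont/slope_avidin)` with ordinary least-squares
slopes over the full 24-h window (a sub-window is configurable; none is
imposed).  The convention that the avidin-control slope defines 0%
inhibition and the complementary slope ratio the percentage is the one
reading under which a strong transcription blocker scores high inhibition;
it is implemented as such.  Reversibility is
`100 · area(discontinuous − continuous) / area(avidin − biotin)` with
trapezoid areas on the shared grid.  On the generator's linear family this
equals 100·f·r for planted inhibition f and reversibility r, hence equals
the planted reversibility exactly when f = 1.  Outlier exclusion is manual
(an explicit exclusion list); no automatic rule is invented.  Both
percentages are invariant under a common positive rescaling of all four
series.

## Compound-level integration

z-scores use the sample standard deviation, exclude NaNs from the moments
and propagate them.  Pearson correlations run on pairwise-complete records
minus an *explicit* id exclusion list that is echoed into the output — no
automated outlier rejection.  Hit gating: positive = clinical ∧ IC50 < 1 µM
(−log₁₀ of the molar IC50 > 6) ∧ predicted score strictly above the
reference compound's; negative = clinical ∧ IC50 > 1 µM ∧ score < 1; the
strict inequality means the reference itself is never a positive hit.
Class enrichment uses the two-sample Kolmogorov–Smirnov test of the class
scores against the **entire** population, class members included (a
disjoint-background variant sits behind a flag); two-sided by default with
a one-sided "greater" option; raw p-values are reported per class with no
multiple-testing correction by default (Benjamini–Hochberg is available
but off).

## Pipeline and provenance

Every run is driven by a `RunConfig` whose YAML serialization is hashed
(SHA-256, truncated) into every output CSV; the output directory is
excluded from the hash since it carries no scientific content.  Excluded
wells, fields, cells and tracks are always logged with a reason.
Out-of-focus field removal is not automated: fields are dropped only via
an explicit skip-list, keeping exclusions auditable.  Identical config and
seed reproduce every CSV byte for byte.

## Problem sizes and numerical tolerances

Recovery tests use 5 fields × 30 cells (segmentation), 7 wells × 3 sites
× 70 cells ≈ 210 cells/well (anchored inhibition), 8 doses × 3 replicates
× 200 seeds (noisy IC60), 25 timepoints × 100 seeds (noisy RUSH) and
5 000-compound tables × 500 seeds (KS calibration) — sizes chosen so each
statistic's sampling error sits well inside its assertion tolerance while
a full run stays interactive.  Noiseless closed-form identities are
asserted to 1e-6 (RUSH) or 1e-9 (IC60 round-trip); noisy recoveries to
3–5 percentage points or 15% relative error, consistent with the planted
noise levels.

## Known limitations

- The annulus cytoplasm model under-covers large flat cells and
  over-covers dense monolayers; it is a convention, not a cell boundary.
- The watershed splitter is tuned for roughly convex, similar-sized
  nuclei; chains of three or more deeply fused nuclei may under-split.
- The 4PL fit is unweighted; strongly heteroscedastic counts (very few
  cells at high doses) would warrant a binomial weighting the package
  does not implement.
- KS enrichment of a class against a population that includes it slightly
  dilutes the signal for large classes; for the small annotated classes
  this screen targets the effect is negligible (the null calibration test
  covers exactly this regime).
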