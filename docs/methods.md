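# Methods

## Overview

`tauscreen` reconstructs, as tested code, the analysis chain of a
high-content RNAi kinome screen for modulators of tau phosphorylation:
cells carrying a tau reporter are imaged in three channels (nuclear stain,
green "total tau", red "phospho-tau"), each cell is quantified by the mean
red and green intensity in a 4-pixel perinuclear ring, wells are averaged,
normalized to same-plate non-silencing (NS) controls, and each siRNA's
triplicate is tested against the controls with a small-sample t-test.
Hits are classified into two tiers: *phospho-specific* (significant
phospho and phospho/total-ratio change, no significant total change) and
*dual-effect* (significant change in both channels).

Because no raw screen images are publicly available, a synthetic plate
generator with known ground truth stands in for the wet-lab screen; the
27 published candidate rows (per-siRNA Average / St Dev / p for all three
readouts) are the external validation surface.

## Significance test reconstruction

The original analysis used a "paired, two-tailed t-test relative to
non-silencing controls present in triplicate on each plate". After each
replicate is expressed as a fraction of its own plate's NS mean, the
control member of every pair is identically 1, so the paired test is
algebraically a one-sample two-tailed t-test of the n normalized
replicates against 1.0 with n−1 df:

    t = (x̄ − 1) / (s / √n),   p = 2·P(T_{n−1} ≥ |t|)

For triplicates (df = 2) the tail has the closed form

    p = 1 − |t| / √(t² + 2)

which the implementation's general path matches to < 1e−12
(`p_two_tailed_df2`). This reconstruction recomputes all 81 published
(row, readout) p-values from their printed Average/St Dev to within
0.003, and to within what 3-decimal rounding of those printed inputs can
move in every case (`recompute_table_pvalues` reports both deviations).
Degenerate inputs: sd = 0 with x̄ ≠ 1 returns the smallest positive
float; x̄ = 1 returns exactly 1; n < 2 is an error at the single-test
level and a missing value at the screen level.

The per-well ratio is `phospho_norm / total_norm` formed per replicate
and then averaged — not the ratio of the channel averages. The published
rows are consistent with this reading except the DYRK1A ratio average
(0.860, vs 0.774/0.848 = 0.913 from the printed channel averages); the
audit reports that inconsistency rather than forcing agreement (its
p-value still validates from the printed ratio Average/St Dev).

No multiple-testing correction is applied by default, matching the
original analysis across 3,432 tests; Benjamini–Hochberg q-values are an
optional annotation (`bh_fdr`).

## Hit-calling thresholds

Significance levels were never printed. The channel threshold defaults to
0.05; the ratio threshold defaults to 0.06 because the published
phospho-specific rows include ratio p-values up to 0.057 while every
channel p-value respects 0.05 — evidently "significant" for the ratio was
not a strict 0.05. Both are explicit fields of `Thresholds`, documented
as reverse-engineered. Under these defaults all 17 phospho-specific and
all 10 dual-effect published rows classify into their own tier with no
cross-tier leakage. Direction (decreaser/increaser) is the sign of
`phospho_avg − 1` and never gates membership — the published tables
contain both directions. Calls are per siRNA; a per-gene
`gene_sirnas_hit` count annotates multi-siRNA support without requiring
it.

## Image quantitation

* **Segmentation** (unstated in the original report): Gaussian smoothing
  (σ = 2 px) → Otsu threshold → hole filling → minimum area 30 px →
  optional distance-transform watershed (seed peaks ≥ 5 px apart) to
  split touching nuclei. Deterministic, adequate for the synthetic
  nuclei; a constant image yields zero nuclei without error.
* **Ring geometry**: the "4 pixel ring" is implemented as 4 iterations of
  3×3 morphological dilation (Chebyshev metric) of the nucleus mask,
  minus *all* nucleus pixels, clipped to the image. A single-pixel
  nucleus therefore has a 9×9 − 1 = 80-pixel ring. Whether the original
  instrument used Chebyshev or Euclidean rings is not recoverable;
  `ring_metric="euclidean"` is provided, Chebyshev is the documented
  default. Pixels reachable from several nuclei are assigned to the
  nucleus with the nearer centroid, ties to the lower label, so rings
  partition the perinuclear pixels deterministically (verified against a
  brute-force distance enumeration in the tests).
* **Border cells** (ring would clip the image edge) are excluded by
  default; cells whose ring is fully enclosed by neighbours are dropped.
  Per-well aggregation is the unweighted mean over retained cells; an
  empty well reports count 0 with missing means and is excluded
  downstream.
* **No background subtraction** by default (none was described);
  intensities are treated as linear counts, coordinates are 0-based
  (row, col).

## Synthetic plate generator

One root seed drives the screen; each well draws from a substream keyed
by SHA-256 of (plate id, well), so well content is independent of
generation order and plate maps/images are bit-reproducible.

* **Layout**: siRNAs are packed onto plate layouts (96 wells, 3 NS wells
  each by default) and each layout is replicated as three physical
  plates, giving every siRNA 3 replicate wells and every plate its own NS
  triplicate. 572 genes × 2 siRNAs × 3 replicates = 3,432 target wells.
* **Cells**: N ~ Poisson(`cell_count_mean`) elliptical nuclei (semi-axes
  uniform in 4–8 px, i.e. full axes 8–16 px), rejection-placed without
  overlap and fully inside the frame. The default `cell_count_mean` is
  300, inside the published per-well range (152–466), interpreted as
  cells analyzed per imaged field; validation runs at 256×256 px use 60
  cells per field, the density that geometry supports at that frame size.
* **Intensity model**: per-cell plateau amplitude =
  `baseline × factor × well_factor × cell_factor`, with baselines 6000
  counts (both tau channels) and 15000 (nuclear). `well_factor` is one
  lognormal draw per well (CV `well_cv`) *shared by both tau channels* —
  it models staining/confluence variation and cancels in the per-well
  ratio; `cell_factor` is lognormal per cell per channel (CV `cell_cv`).
  All lognormals are parameterised to have mean exactly 1. The cytoplasm
  is rendered as a halo around each nucleus: constant at the plateau
  amplitude over the first 4 px (so a 4-px ring samples the per-cell mean
  exactly in the noiseless case) then decaying linearly to zero over a
  per-cell halo width of 6–10 px; overlapping halos combine by maximum.
  Additive background (default 100 counts) and Gaussian read noise
  (default SD 8) are applied per pixel before quantization to uint16.
* **Table path**: `simulate_well_table` draws the same per-well moments
  (Poisson count, shared well factor, mean of N per-cell factors, plus
  background) without rendering pixels; the tests check that both paths
  give interchangeable screen statistics.

### Noise defaults and power

Defaults `cell_cv = 0.25`, `well_cv = 0.04` put the SD of
control-normalized null wells at ≈ 0.05–0.06 (the NS normalization by a
3-well mean inflates the well-level CV by √(4/3)). This is the dispersion
of a well-behaved triplicate screen and sits at the low end of the spread
seen in the published control-like rows (total-tau SDs 0.02–0.20). The
choice is deliberate: a df = 2 t-test at α = 0.05 has power ≥ 0.995 for a
0.33 effect at normalized SD 0.055, but only ≈ 0.8 at SD 0.10, so a
generator parameterised at the top of the plausible range would make
*any* correct implementation of this analysis miss a third of
MARK2-sized effects — a property of triplicate screening at this noise
level, not of the code. The limitation cuts the other way too: on wells
as noisy as the most dispersed published rows, triplicate df = 2 testing
is weak, which is consistent with the original authors' own observation
that the screen underestimated effect magnitudes relative to follow-up
westerns.

### Known small offsets of the percent-of-control readout

Two model-predictable offsets separate the expected normalized readout
from the planted factor f (both are accounted for by
`validation.expected_normalized`):

* additive background pulls readouts toward 1 by `bg·(1−f)/(B+bg)`
  (≈ 0.006 at defaults for f = 0.67), because background is measured but
  never subtracted;
* dividing by the mean of a finite (3-well) control set inflates the
  expectation by its relative variance (delta-method term, ≈ 0.0009).

Segmentation-induced attenuation (the smoothed Otsu mask is slightly
dilated relative to the true ellipse, so rings sample ~2% into the halo
decay) is multiplicative and common to all wells, and cancels exactly
under control normalization.

## Validation experiment

`validation.planted_recovery_runs` renders repeated mini-screens (three
planted genes — phospho-specific decreaser (0.67, 1.0), dual decreaser
(0.61, 0.65), phospho-specific increaser (1.5, 1.0) — plus NS triplicate,
3 replicate plates, 256×256 px, 60 cells/field) through the full imaging
pipeline and scores (a) the fraction of per-gene calls landing in the
true tier and direction, and (b) the pooled recovered averages against
the model expectation within 3 SEM. At 100 runs the observed call
accuracy is ≈ 0.96–0.98. The structural ceiling is worth stating: a
phospho-specific gene requires the truly-null total channel to test
non-significant, which happens with probability 1 − α = 0.95 for an
exact-size test, so per-gene accuracy for tier-1 genes cannot exceed
≈ 0.95 × power no matter the implementation.

## What the generator does not emulate

No optics (PSF, vignetting, autofluorescence), no multi-field stitching,
no death morphology (cytotoxicity enters only through expected cell
count), no spatial plate effects (edge/gradient artifacts), no
cross-channel bleed-through. Passing tests therefore demonstrate the
correctness of the measurement and statistics chain on data satisfying
the stated generative model, not robustness to instrument-specific
artifacts; on real plates, segmentation quality and plate-effect
correction would dominate the error budget long before the statistics.

## Reporting conventions

Summary CSVs use exactly the published column order (`gene, sirna_id,
cell_count, phospho_avg, phospho_sd, phospho_p, total_avg, total_sd,
total_p, ratio_avg, ratio_sd, ratio_p`). The phospho-specific report
lists decreasers then increasers, each ascending by ratio average; the
dual-effect report likewise by phospho average — the published layout.
Every pipeline run writes a manifest (package and library versions, seed,
parameter hash) sufficient to reproduce its outputs bit-for-bit.
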