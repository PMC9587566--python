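# Methods

## Scope and model

spotcoloc quantifies object-based co-localization in 2D: each 3-channel
8-bit z-stack (two signal channels, one nuclear counterstain, ≤30 focal
planes) is collapsed to 2D projections, puncta are detected per channel as
discrete objects with sub-pixel centers, and co-localization is the size of
an optimal one-to-one pairing of centers across channels within a maximum
displacement `r_max`.  The readout per image is the pair count and the
pair count per (fractionally counted) cell.  The analysis is strictly 2D:
objects at similar (x, y) but different z are indistinguishable after
projection, which is a known limitation of the approach.

## Projections

"Stacked" is the plain pixelwise sum over focal planes, kept in a widened
integer range (`[0, 255·n_z]`).  "Saturated" is the same sum clipped at
255; repeated summation drives weakly stained regions toward the 8-bit
ceiling, which evens out staining variation and is why segmentation runs on
the saturated image.  The numeric definition of "saturated" as a clipped
sum (rather than a max projection) is this package's documented
interpretation; a max projection is available behind a method flag.
Detection runs on the stacked sum divided by `n_z`, so intensity and
percentile semantics do not depend on stack depth.  Stacks with more than
8 bits of dynamic range are rejected rather than rescaled, because silent
rescaling would shift every percentile threshold.

## Segmentation

The ROI is either whole-cell bodies ("cyto", for cytoplasmic puncta) or
nuclei ("nuclei").  The backend is pluggable behind a one-method contract
(images + diameter → label image).  The default backend is classical and
fully deterministic: Otsu global threshold, binary hole filling,
distance-transform watershed seeded at local maxima at least
`cell_diameter/2` apart, and a minimum-area filter at 10 % of the nominal
object area `π(cell_diameter/2)²`.  Determinism here is what makes the
pipeline's byte-identical-output guarantee possible and keeps the test
suite independent of downloaded model weights; a Cellpose adapter is
provided as an optional extra for real tissue images, where the classical
backend's global threshold is the first thing to fail.  In cyto mode the
whole cell is kept by default (an `exclude_nuclei` flag excises the nuclear
area), since in a 2D projection cytoplasmic puncta from planes above or
below the nucleus legitimately appear over it.

## De-noising

Order is fixed: mask → wavelet subtraction → Gaussian smoothing →
percentile cut.

**Wavelet background and noise subtraction.**  The masked image is
decomposed with a stationary B3-spline à-trous transform (separable kernel
`[1,4,6,4,1]/16`, dilated by `2^level`, reflective boundaries) to
`L = ceil(log2(wavelet_resolution_px)) + 1` levels.  The level-L
approximation — structure coarser than the expected feature size — is the
background estimate (clamped at ≥0); the sign-symmetrized magnitude of the
finest `noise_levels` detail planes is the noise estimate.  Both are
subtracted and the result clamped at zero.  Defaults:
`wavelet_resolution_px = 3` (about the FWHM of a diffraction-limited
punctum at our synthetic scale), `noise_levels = 1`.  A flat field is
removed exactly; the decomposition reconstructs the input exactly
(property-tested).

**Gaussian smoothing.**  `sigma` is the kernel *standard deviation* in
pixels (default 1.0; 0 disables).  The tool's user-facing description of
sigma as a "noise variance" is common in the field but ambiguous; the
standard-deviation parameterization matches scipy/scikit-image semantics
and is what all magnitudes in this package mean.

**Percentile cut.**  The threshold is the linear-interpolation quantile of
the strictly positive pixels only — masked zeros are excluded so the
threshold does not depend on how much of the frame the ROI covers (the
percentile-over-ROI choice is this package's documented resolution of an
underdetermined point).  Survival is strict (`value > threshold`), with two
degenerate rules: `percentile = 0` uses threshold 0 (all positives kept),
and when the threshold equals the maximum positive value (e.g. a constant
positive region) the maximal pixels are retained rather than emptying the
image.  Default percentile: 90.

## Detection

Crocker–Grier centroid localization, restated from the classical
particle-tracking literature: (1) band-pass = ~1 px Gaussian smoothing
minus a `diameter`-sized boxcar background, clipped at zero, with values
below 1e-12 of the band-pass maximum zeroed (filter residue must not
surface as maxima on empty regions); (2) candidates = grayscale-dilation
local maxima with a `separation`-sized footprint, strictly positive, at
least `diameter/2` from the border; (3) iterative intensity-weighted
centroid within a disk of radius `diameter/2` (≤10 iterations, window
recentered while the offset exceeds 0.6 px); (4) candidates converging
within `separation` of a brighter one are merged, and particles with
integrated mass below `minmass` are dropped.  IDs are assigned 0..n−1 in
descending mass order (ties broken by position) for reproducibility.

Defaults: `diameter = 9` px (odd by construction), `separation =
diameter + 1`, pipeline `minmass = 80`.  The minmass default was chosen by
characterizing the band-passed integrated mass of genuine puncta versus
ROI-edge filter ringing on synthetic scenes: at the default scene scale
genuine spots carry mass ≥ ~100 while mask-edge artifacts stay below ~70,
so 80 separates the two populations with margin on both sides.  On real
data with different spot brightness this knob, like the percentile, is
expected to need adjustment — the sweep exists for exactly that reason.

On noiseless fixtures localization is exact to well under 0.1 px, and
integer image shifts move coordinates exactly (reflective boundaries leave
interior windows untouched).

## Matching

Among one-to-one pairings with all pair distances ≤ `r_max` (inclusive),
the matcher maximizes cardinality, then minimizes total squared
displacement.  This is solved exactly with `scipy.optimize.
linear_sum_assignment` on a cost matrix where infeasible pairs cost
`M = r_max²·min(n,m) + 1` — larger than any feasible total, so cardinality
dominates.  The assignment rule itself is this package's choice (the
operational definition only fixes the distance criterion); it is
well-defined, deterministic, and avoids the double-counting that greedy
nearest-neighbour pairing allows.  An independent memoized enumeration over
all assignments (guarded to ≤12×12) certifies the optimum in tests and in
the acceptance script.  `r_max` defaults to the particle diameter.

A pixel-based Pearson correlation over in-ROI pixels is provided (`--pcc`)
as the conventional intensity-based comparator.

## Cell counting

A nucleus label is border-touching if any pixel lies within `border_margin`
(default 1) of the frame edge.  The average nucleus area is the *mean over
fully contained nuclei* — truncated border areas would bias it downward —
with a median-over-all fallback when every nucleus touches the border.
Border nuclei contribute `min(area/avg, 1)`: the cap stops an unusually
large clipped nucleus from counting as more than one cell.  Both the
mean-vs-median choice and the cap are design decisions on points the
operational description leaves open.

## Percentile sweep and plateau

`sweep_percentiles` re-runs cut → detect → match over a grid (default
{90, 93, 95, 97, 98, 99, 99.5, 99.9}) with everything else fixed.
`estimate_plateau` returns the longest run of consecutive grid points whose
matched counts differ pairwise by ≤ `tolerance · median(run)` (default
tolerance 0.1; ties broken toward higher percentiles), reporting the run's
median count.  If no run of length ≥2 qualifies, the full-range median is
returned flagged as "no plateau".  Grid and tolerance defaults are
package choices, configuration-exposed.

## Synthetic scenes

The generator emulates a desk-scale confocal field of cultured cells:
256×256 px, 8 focal planes, 6 non-overlapping cells (nucleus radius
10–14 px plus a 12 px cytoplasmic halo), 4 puncta per cell per channel,
default co-localized fraction 0.5 with ≤1 px per-axis registration jitter
(well under the 9 px matching radius).  Puncta are Gaussians (σ 1.5 px,
peak 150) spread over 2–3 adjacent planes (weights 1, 0.5); the cytoplasm
adds 20/plane, the background 5/plane, nuclei 110/plane in the counterstain;
per-voxel Poisson shot noise and Gaussian read noise (sd 2) are applied and
the result quantized to 8 bits.  The effective peak-to-local-background
ratio is 150/25 = 6.

Placement constraints make the truth labels consistent with the operational
definition: same-channel spots are ≥13 px apart (so the detector can
resolve them), and non-co-localized spots of opposite channels are ≥10.5 px
apart — beyond `r_max` = 9 plus localization error — because a chance pair
closer than `r_max` *is* co-localized under the definition and must not be
labelled negative.  Spots may sit anywhere within the cell body including
over the nucleus (projection geometry).  Placement uses per-cell
backtracking; a single seeded generator threads through all draws, so equal
seeds give bit-identical scenes.

What the generator does **not** emulate: realistic PSF shape and spectral
bleed-through, intensity heterogeneity between puncta, clustered or
touching puncta, textured cytoplasmic background, border-clipped cells
(cell-count fractions are exercised with constructed masks instead), and
autofluorescence.  Passing the synthetic recovery tests therefore
demonstrates the pipeline's correctness under its own assumptions — clean,
resolvable, mid-SNR puncta — not its robustness to every real acquisition;
on real data the percentile, σ and minmass must be chosen by inspection, as
the sweep supports.

## Problem sizes and numerical choices

Validation runs use 10 seeded scenes at the default scale for end-to-end
recovery, 100 random ≤8×8 instances for matcher/oracle agreement, and an
8-point percentile grid for the plateau — sizes at which every check runs
comfortably on a laptop while leaving no estimator degenerate.  Distances
use squared Euclidean arithmetic; the `≤ r_max` comparison carries a 1e-12
absolute slack so exactly-at-radius pairs are accepted regardless of
rounding.  All image filtering uses reflective boundaries, avoiding
dark-frame edge artifacts that would create spurious thresholds and maxima.

## Known limitations

2D only (a stated limitation of the approach itself); exactly two signal
channels; spherical-spot assumption inherited from the centroid method;
LIF reading requires the optional `readlif` dependency; the classical
segmentation backend assumes roughly convex cells separable by a global
threshold — for densely packed or irregular tissue use the Cellpose
backend.
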