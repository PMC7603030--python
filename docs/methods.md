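# Methods

`secrflux` quantifies four live-cell imaging readouts of secretory-pathway
function — ER-to-Golgi transport, vesicle motility, structure shape, and
ratiometric biosensor signals — and ships a synthetic-microscopy generator
that plants every quantity it later recovers. This note records the models,
the conventions chosen where the underlying workflow left them open, and
what the synthetic benchmarks do and do not establish about real data.

## Transport index

A cell co-expresses a green fluorescent cargo construct (held in the ER by
conditional aggregation domains until a solubilizer ligand releases it) and
a red Golgi-lumen marker. At acquisition times t = 0, 3, 7, 15, 30 min after
solubilizer addition, the Golgi footprint is segmented per timepoint from
the marker channel:

1. rolling-ball background subtraction (default radius 50 px),
2. Otsu threshold computed from the histogram of pixels inside the cell ROI,
3. two binary erosions with a 3×3 cross.

With mask G(t) and cell ROI R, the transport index is

    TI(t) = [ Σ_{G(t)} I_cargo / Σ_{R∖G(t)} I_cargo ] / ratio(0),

the Golgi/non-Golgi integrated-density ratio normalized to the initiation
timepoint, so TI(0) = 1 by construction. The non-Golgi region is restricted
to the ROI (not the whole frame): this is the only reading that makes the
ratio cell-specific.

Cargo-channel offset removal defaults to subtracting the median intensity
outside the ROI — a constant camera-offset/haze estimate. A rolling ball on
the cargo channel is available but not the default: it also removes any
intensity structure wider than the ball, including the diffuse cell-scale ER
pool, which biases the ratio upward; with the constant-offset estimate the
planted closed-form benchmark (below) is recovered to machine precision.

**Closed-form benchmark.** If a fraction f(t) of a cell's total cargo sits in
the Golgi footprint and the rest outside it, then

    TI(t) = f(t)(1 − f0) / (f0 (1 − f(t))).

This holds exactly whenever the segmented mask covers the planted footprint
and no ER cargo leaks into it; the generator is built so both conditions can
be met (see below), making any pipeline deviation from the formula a genuine
defect rather than benchmark slack.

**Classification.** Cells are assigned one of four transport-efficiency
classes from TI at a cargo-specific decision time, with half-open intervals
[lower, upper) so a boundary value goes to the higher class:

| cargo | decision time | very_high | high | moderate | none |
|---|---|---|---|---|---|
| soluble (bulk flow) | 30 min | ≥ 10 | [5, 10) | [2, 5) | < 2 |
| transmembrane (COPII-sorted) | 15 min | ≥ 10 | [7, 10) | [4, 7) | < 4 |

The published figure legends state the bounds as open inequalities and leave
exact boundary values unassigned (borderline cells were resolved by visual
inspection); the half-open convention is the deterministic replacement.

## Vesicle motility

Movies (one channel, default 600 frames at 200 ms ≈ 2 min) pass through a
fixed pipeline: rolling-ball background subtraction (radius 10 px for
vesicle-scale structure) → photobleaching correction → one movie-wide Otsu
threshold → connected components filtered to 5–30 px → greedy linking →
per-ROI summaries.

*Movie-wide threshold.* Otsu's criterion is scale-invariant, so a per-frame
threshold silently renormalizes any frame-wide intensity decay and bleaching
could never affect detection. A single threshold computed from the corrected
stack's (subsampled) histogram treats all frames uniformly and makes the
bleach-correction stage load-bearing: on a strongly bleaching movie
(k = 0.02/frame) skipping the correction loses ≥ 20% of late-frame
detections, a tested sensitivity.

*Bleach model.* Frame means m(t) are fitted with A·exp(−k t) + c by least
squares (log-linear initialization, non-negative bounds); frame t is then
scaled by m̂(0)/m̂(t). Planted rates k ∈ {0.001…0.02}/frame are recovered
within 2% noise-free.

*Linking.* Greedy mutual-nearest-neighbour assignment: repeatedly take the
globally closest (open track end, detection) pair within the gate
(default 5 px), with gap closing across 1 missing frame. Defaults
min_track_len = 5 points. This emulates simple-LAP behaviour for
well-separated spots; merging/splitting and full LAP/Kalman tracking are out
of scope.

*Readouts.* Per track, mean speed = total path length / elapsed frames
(robust to gap-closed links) and displacement = straight-line first-to-last
distance. Per ROI, MeanSpeed and MeanDisplacement are arithmetic means over
eligible tracks; an ROI with no eligible tracks reports missing values, not
zeros. Computation is in px/frame; µm and µm/s are reported when pixel size
and frame interval are calibrated.

## Form factor and microtubule ratio

The form factor of a segmented structure is the circularity 4πA/P², 1 for a
disc and → 0 for elongated shapes, with P the Crofton (4-direction)
perimeter estimate. Values are clamped to 1, since discretization can push
compact discs slightly above the continuum bound. For thin digitized shapes
the Crofton estimate runs below the outer boundary length; against the
closed form computed with the outer boundary (e.g. 0.26 for a 20×2 px
rectangle) agreement is within 20%, the documented thin-shape tolerance.
Relative, time-ordered comparisons are the supported use.

Per cell and timepoint: background-subtract the cargo frame, remove the
Golgi region (same marker-derived mask as the transport index), local Otsu
threshold (default 51 px window) inside the ROI, median circularity over all
structures ≥ 4 px. Setting the excluded pixels to zero before thresholding
guarantees Golgi intensity cannot influence the record.

The microtubule mask is built by background subtraction → 3×3 median filter
→ bandpass → Otsu → binary opening (3×3 disc) → particle filter (≥ 20 px);
the readout is the ratio of mean background-subtracted intensity inside the
mask to that in the rest of the ROI. The bandpass is a difference of
Gaussians with σ = small_px/2 and large_px/2 (defaults 2 and 20 px for
filament work, 3 and 40 px generally); a frequency-domain annulus with
Gaussian rolloff is available behind `method="fft"`. None of these scales
are stated in the original workflow; all are configurable and logged in the
run manifest.

## Biosensor traces

A ratio trace (FRET acceptor/donor for ATP sensors, 340/385 nm excitation
for Fura-2) carries a basal window, default the first 5 min. The maximal
ratio change is basal mean − value at the sample nearest the requested
endpoint (positive = decline from basal; declines are how energy-depletion
responses are reported). `stimulus_response` returns per-epoch min, max, and
maximum deviation from the preceding epoch's final value, capturing ER
Ca²⁺-depletion depth and cytosolic transient height under agonist/SERCA-
inhibitor protocols. Basal uses the window mean rather than a single frame.

## Synthetic generator

The generator defines the study conditions for every benchmark; no raw
recordings are distributed with the original study.

*Transport scenes.* Cells are discs on a grid (radius 0.42× the tile size);
each holds an off-center Golgi disc of radius `golgi_radius_px` (default
20 px at 0.1 µm/px). The marker stains the Golgi disc plus a 2 px halo at
intensity 1000; the halo guarantees that after Otsu and two erosions the
derived mask still covers the cargo's Golgi footprint while staying within
~1 px of it (IoU ≳ 0.9 for radii ≥ 14 px). Cargo at timepoint t places
f(t)·I_total Gaussian-weighted inside the footprint and the remainder in the
ER: `puncta_fraction(t)` in anisotropic Gaussian aggregates (aspect 3 → 1
over the series, the planted disaggregation signal) and the rest as a
uniform diffuse pool, both kept ≥ 4 px clear of the marker halo. Every
component is normalized on its rendered pixels, so per-timepoint cargo sums
equal I_total to machine precision before noise. Kinetics presets invert the
closed form to hit class-center TI targets (e.g. 16 / 7 / 3.2 / 1.1 for
soluble cargo) along a saturating-exponential time course.

*Vesicle movies.* Spots are Gaussian profiles truncated to
`vesicle_area_px` (default 12 px) around sub-pixel centers. Motion models:
directed (constant random heading), Brownian (isotropic Gaussian steps whose
mean length equals the stated speed, σ = speed/√(π/2)), stationary.
Boundaries reflect, so planted tracks never leave the frame; reflected steps
change direction, and near-boundary step lengths are not preserved, so exact
step-length checks use interior segments. Bleaching multiplies whole frames
by exp(−k·frame) before noise.

*Noise.* `poisson` draws each pixel from a Poisson law with the clean image
as mean (intensities are treated as photoelectron counts);
`poisson+gaussian` adds read noise. "SNR ≈ 10" conditions use spot amplitude
110 over background 10 (peak / √(peak+background) ≈ 10). All randomness in
one generator call flows from its single integer seed; equal parameters and
seed give bit-identical output.

*What the benchmarks do not show.* The generator has no PSF, no 3-D
structure, no focus drift, no cell motion or shape change, no marker
bleed-through, and its geometry (disc cells, disc Golgi) is a convention the
original study never parameterized. Passing recovery tests therefore
establishes that the estimators are correct under their stated models — not
that segmentation or tracking is robust to the full variability of real
recordings.

## Problem sizes and numerics

Recovery ensembles run at desk scale as the package's own test design:
128–192 px scenes, 20 cells per class per cargo type for classification,
150-frame movies with 20 vesicles (3 seeds) for speed recovery, 80-frame
movie pairs (20 seeds) for the directed-vs-Brownian comparison. The
600-frame acquisition check always runs at full length, since the frame
count is itself the quantity. Rolling-ball backgrounds for radii > 16 px are
estimated on a downscaled copy (factor ≈ radius/12) and upsampled, with the
background clipped to stay under the image. Degenerate inputs fail loudly:
constant images raise a degenerate-histogram error (movie drivers convert
per-frame failures to "no detections"), empty post-erosion masks raise a
degenerate-mask error, and an SEM over a single cell is reported as 0 with
n = 1 flagged.
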