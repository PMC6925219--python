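# Methods

This note records the quantitative conventions the package implements, the
design choices made where the protocol leaves room, and what the synthetic
phantoms do and do not establish.

## Vessel delineation

Vessel borders are mapped on a maximum-intensity projection of a dextran
channel by Kapur's maximum-entropy threshold: the histogram uses 256
equal-width bins spanning `[min, max]` (the 8-bit convention of the ImageJ
plugin this reproduces), and the chosen cut maximizes the sum of Shannon
entropies of the normalized below- and above-threshold partitions.
Candidate splits that leave either partition empty are skipped; ties
resolve to the smallest threshold, making the result deterministic.  The
returned threshold is the upper edge of the winning bin, so foreground is
strictly `intensity > T`; adding a constant to the image shifts the
threshold by exactly that constant.

Binarization is followed by interior hole filling (a hole is background
not connected to the image border, so dark lumen centers stay inside the
vessel) and removal of 8-connected components smaller than 40 µm².  The
filter is inclusive: a component of exactly 40 µm² survives.  Area is
pixel count × (pixel size)².  Whether thresholding is applied per z-plane
or per projection is not fixed by the protocol; the package thresholds the
projection, and per-plane use is possible by calling the function on
individual slices.

## Leakage index

BBB permeability is the arithmetic mean of intensities over non-vessel
pixels, with the vessel mask always taken from the impermeant 70 kDa
channel so that leak cannot erode its own exclusion mask, and dilated by
1 px (configurable) to keep partial-volume bleed at the wall out of the
parenchymal average.  Indices are sample means divided by the control-group
mean, so the control group's averaged index is 1.00 identically — a
normalization contract, not an estimate.  Rescaling all images by a common
gain leaves indices unchanged.  For time series the reference can instead
be the pre-treatment baseline day (`normalization_reference:
baseline_day`).  Parenchymal means include microglial somata; the protocol
does not specify their exclusion.

## Vessel-associated microglia

The classifier formalizes the manual two-channel line-profile rule.  The
line runs from the soma centroid (intensity centroid of the segmented cell
body, a deterministic surrogate for the "presumed center") to the nearest
vessel-mask pixel, sampled at unit-pixel steps with nearest-pixel lookup so
measured gaps are integers in pixels.  The line overshoots the vessel
boundary by 8 px so the profile crosses the wall into the lumen; without
the overshoot the red profile would contain only dim border pixels, its
standard deviation would be too small to suppress the background offset,
and background would masquerade as vessel signal.

Per channel, the profile's own standard deviation (not the whole-image SD
— the protocol is ambiguous; the profile variant is used and flagged for
sensitivity analysis) is subtracted from every sample and negatives are
clamped to zero, which makes "decreased to zero" and "increased from zero"
well defined.  Walking from the cell toward the vessel, the green
extinction point is the first zero that persists for at least one further
step; the red rise is the first positive sample.  The gap is their
difference; a gap ≤ 0 (overlap) is always a contact, and a positive gap is
a contact only when strictly below 1 µm — equivalently below 4 px at
0.254 µm/px; at other calibrations the criterion is applied in µm.  A
soma centroid inside the vessel mask is a contact with gap 0.  When the
green signal never extinguishes but red rises, the cell overlaps the
vessel (contact); when red never rises the gap is at least the profile
remainder (not a contact); only when both fail is the call indeterminate
and an error raised.

Colocalization is the plain (unthresholded) Pearson correlation of paired
pixel intensities within the ROI; the Costes-thresholded variant is not
implemented.

## Morphometry

Cells are segmented on the projected reporter channel: somas are the
bright blobs surviving a morphological opening with a ~1 µm disk, and each
soma's cell mask is the thresholded connected component containing it
(the original protocol traced cells manually; automation is required for
testability).  Process tracing skeletonizes the cell mask with Lee's
method — the default Zhang thinning erodes the tips of thin diagonal
branches — removes skeleton pixels inside the soma, and treats each
remaining 8-connected component adjacent to the soma as one process.  A
process length is the longest geodesic from its soma-adjacent entry pixel
through the component, with diagonal steps weighted √2, in calibrated µm;
junction-to-junction segments are never double counted.  Soma area is
pixel count × pixel area.

CD68 positivity counts bright connected components of the puncta channel
inside the cell (maximum-entropy threshold on the within-cell intensities,
component areas restricted to 0.1–5 µm²); a cell is positive when the
count strictly exceeds two.  The perivascular-marker-inclusion variant
(e.g. AQP4-positive inclusions) uses the same counter with threshold 0 —
any punctum counts — since no count rule is fixed for that marker.
Pericyte coverage is 100 × |marker ∩ vessel| / |vessel|.

Process motility operationalizes trajectory-based tip tracking: skeleton
endpoints are detected per registered frame, linked frame-to-frame to the
nearest neighbor within a 2 µm gate (above realistic per-frame process
speeds, below inter-tip spacing in the phantoms), and each trajectory's
motility is its mean per-interval displacement in µm/frame.  The source
protocol never defines its motility metric numerically, so absolute
cross-study motility values are not comparable; within-package comparisons
(static vs moving, jittered vs stabilized) are.

## Preprocessing

Registration is translation-only (the lateral-drift case), estimated per
frame against frame 0 by cross-correlation maximization; integer shifts by
default so repeated runs are bit-identical, with optional 1/10-px
refinement.  Vacated border pixels are filled with the frame's modal
intensity (histogram peak) so registration cannot bias extravascular
means.  A constant frame raises an error.  Depth selection keeps slices
whose center depth lies in the half-open window [100, 200) µm from the
pia — below the two superficial 50 µm sections — and records the window
offset on the output stack, making the operation idempotent.  Projection
is a per-pixel maximum over the selected slices.

## Synthetic phantoms

The generator renders what the estimators must recover, not optics:

- **Vessels** — straight cylinders (radius 3 µm, capillary scale) along x,
  centered on the middle z-plane; intravascular intensity 200.
- **Leak** — an exponential halo (length constant 10 µm) outside the tube,
  scaled so its integrated extravascular intensity equals the configured
  leak fraction times the integrated intravascular intensity.  This makes
  the leak fraction an exact, dimensionless ground truth; the ~1 %
  tolerance quoted for recovery is pure discretization.
- **Microglia** — spherical somas (radius 3 µm, intensity 150) at
  requested edge-to-edge gaps from the vessel wall, with 0–5 straight,
  slightly tapering processes (~0.75 µm diameter) drawn at multiples of
  45° pointing away from the vessel, so pixel-chain lengths are exact on
  the lattice and the cell–vessel profile axis stays unobstructed.  When
  gaps are not specified they are drawn so an exact share (default 20 %,
  the baseline proportion of vessel-associated microglia) lies below 1 µm
  and the rest 2–8 µm into the parenchyma.  Same-side cells occupy
  disjoint x slots sized to the full soma+process footprint; requests that
  cannot fit raise an error rather than silently overlapping.
- **Puncta** — disks of radius 0.4 µm placed inside the soma with a
  minimum separation so counts are unambiguous.
- **Noise** — `Poisson(signal·gain)/gain + Gaussian(0, sd)`; off by
  default for exact unit fixtures, with gain 1.0 and sd 2.0 as the
  "default noise" used by integration tests (vessel SNR ≈ 14).
- **Time-lapses** — one 2-D scene per sequence; each frame is translated
  by a recorded integer jitter shift, and the first (along-x) process of
  each cell lengthens by the motility per frame, so the tip displacement
  is exactly the configured rate.
- Default geometry: 384 × 384 px at 0.25 µm/px (near the acquisition
  calibration of 0.254 µm/px, and chosen so the 4 px ≙ 1 µm contact
  equivalence is exact on the lattice), 9 z-slices at 2 µm.  All
  randomness flows from the scene seed; identical configurations render
  bit-identically.

The phantoms omit point-spread blur beyond optional Gaussian smoothing,
photobleaching, vascular flow, curved or branching vessels, and the
textured neuropil of real tissue.  Passing tests therefore demonstrate
that the estimators are correct implementations of the stated rules and
recover known parameters under controlled noise — not that they are robust
to every artifact of in vivo data.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 100 random 64×64 images
for the threshold-vs-exhaustive-search check; 4 noise-free cells at gaps
{0, 0.5, 2, 5} µm plus 500 noisy cells (10 seeds × 2 fields × 25 cells)
for contact classification; 20 noisy seeds for leak-fraction recovery at
fractions {0, 0.1, 0.3}; 6-frame jittered time-lapses for registration;
and single-cell scenes with four 20 µm processes for morphometric
recovery.  These sizes give stable statistics on a single CPU in about a
minute.

## Known limitations

- The contact classifier assumes one dominant vessel per profile; profiles
  crossing a second vessel before the target would measure the nearer one.
- Process tracing reports only soma-rooted branches; a fragmented cell
  mask drops disconnected fragments rather than guessing their parent.
- Tip linking is greedy nearest-neighbor and can swap identities when two
  tips approach within the gate distance in one interval.
- Morphometric accuracy is quoted for the phantom regime (straight
  processes at lattice-friendly angles); real ramified arbors would incur
  additional geodesic discretization error of a few percent.
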