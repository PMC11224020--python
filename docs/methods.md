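# Methods

## Scope and model

`dcmorph` quantifies 2D morphology and intensity read-outs of deforming
cells from binary/label masks and single- or two-channel images. It does
not segment raw fluorescence: masks are inputs (or are generated
synthetically), mirroring workflows in which segmentation is done
interactively and the downstream quantification must be reproducible.
All physical quantities are in µm (pixel size supplied by the caller,
pixel centers at index + 0.5) and minutes.

## Nuclear-envelope statistics

**EOP.** Area is computed by the shoelace formula on the (subpixel)
contour, perimeter by summed segment lengths, and
EOP = (P − 2πR₀)/2πR₀ with R₀ = √(area/π). Contours extracted from masks
use the 0.5-level marching-squares iso-contour rather than pixel-edge
boundaries: raw pixel perimeters overestimate smooth shapes by up to
~27 % and would bias EOP upward; the subpixel contour matches the
smoothed ROI perimeters of interactive tools. A 720-point polygonal
circle carries a discretization EOP of ~3×10⁻⁶, far below biological
signal (~10⁻²–10⁻¹).

**Elliptic Fourier (EFC).** Contours are resampled to 1,024 equally
spaced arc-length points (deterministic, starting at the first vertex)
and the closed-form Kuhl–Giardina piecewise-linear integrals evaluated
for harmonics 1..N (default N = 25, configurable). Per-harmonic ellipse
semi-axes are the singular values of the coefficient block
[[aₖ, bₖ], [cₖ, dₖ]]; singular values are invariant under left/right
rotations of that block, which is exactly why the axes are invariant to
contour rotation, starting vertex and traversal direction (verified to
10⁻⁴ of the dominant axis; axes that are exactly zero in theory move at
the ~10⁻⁶ µm level with resampling and are compared with an absolute
floor).

A point worth documenting: under arc-length parameterization an
*eccentric* ellipse is **not** a single-harmonic curve — traversing an
ellipse at constant speed puts weak energy into odd higher harmonics
(for a 2:1 ellipse the first-harmonic axes are ≈1.83/1.07 and the EFC
ratio ≈9.9). Only a circle (constant-speed ≡ constant-angle) is exactly
degenerate. The degeneracy guard therefore fires for near-circular
contours: when the higher-harmonic axis sum falls below 10⁻⁶ of the
first-harmonic sum, the ratio is flagged degenerate and reported as the
cap 10⁶ rather than infinity, keeping tabular output finite and sortable.

## Diameters, residence times, tracking

Diameter = 2 × (exact Euclidean distance transform) sampled at skeleton
pixels, in µm. Skeletonization is morphological thinning
(`skimage.morphology.skeletonize`), endpoints and branch points kept by
default to match the interactive Skeletonize tools this emulates; an
optional `prune_px` endpoint-pruning flag exists because end-cap spurs
bias the minimum low on blob-like cells. Thinning is not exactly
equivariant under 90° rotation (measured ≈0.15 px discrepancy on a
capsule); rotation robustness is therefore specified as ≤ 2·pixel_size.
On synthetic capsules spanning 2–10 µm at 0.25 µm/px the worst-case
min-diameter error is 0.31 µm with no pruning. Anisotropic pixels are
rejected explicitly; isotropic resampling is the caller's job.

Residence fractions use half-open bins [2, 4) and [4, ∞) µm on the
per-frame minimum diameter (the lower boundary of the upper bin is
closed; the published phrasing "2–4 or higher than 4" leaves it open).
Frames thinner than 2 µm count toward neither bin, so the two fractions
sum to ≤ 1. Tracks shorter than 40 min are rejected by default
(configurable), matching the minimum time scale used for such
measurements.

Tracking is greedy nearest-centroid linking, tracks processed in
creation order, each claiming its nearest unclaimed detection within a
20 µm/frame displacement gate; a track with no admissible detection
terminates and unclaimed detections open new tracks. This is a
deterministic stand-in for manual per-cell tracking and is not meant to
resolve crossings; no gap closing. Speeds are step length over elapsed
time, summarized by median (default) or mean.

## Intensity rules

The quantification plane is the z-plane maximizing nucleus-mask area
(ties → lowest index). Cytosol is defined as cell mask minus nucleus
mask; the nucleus must be contained in the cell mask and the cytosol
non-empty. The ratio is a ratio of region means, not a mean of pixel
ratios — multiplying the image by c > 0 leaves it unchanged, while
adding an offset c moves it to (n + c)/(cy + c) (tested). The background
estimator is the median of pixels outside all cell masks dilated by
5 px (the gate rule "brighter than background" is published; the
estimator itself is this package's choice). The gate keeps cells whose
mean strictly exceeds background, so raising the background is
monotonically non-increasing in cells kept.

## qPCR

ΔCt = Ct_target − Ct_reference per sample (replicate Ct values averaged),
ΔΔCt subtracts the arithmetic mean ΔCt of the control condition —
equivalently the control's geometric-mean fold is exactly 1 — and
fold = 2^−ΔΔCt. Adding a constant to every Ct (a global pipetting
offset) provably cancels. No amplification-efficiency correction
(Pfaffl) is attempted.

## Synthetic generators

The generators define the conditions under which the package is
validated:

- **Nuclei** are star-convex curves r(θ) = R(1 + Σ aₖ cos(kθ + φₖ)).
  Chosen because area has the closed form πR²(1 + Σ aₖ²/2) and perimeter
  a cheap spectrally-accurate quadrature, giving exact ground truth for
  EOP. Simplicity is guaranteed by requiring Σ|aₖ| < 1 and Σ k|aₖ| < 1;
  violations raise. Default folding frequency 8 with amplitudes 0–0.12
  spans smooth to strongly wrinkled envelopes; base radius 5 µm is a
  typical dendritic-cell nucleus in projection.
- **Cells** are capsules (rectangle + semicircular caps) whose exact
  medial axis is the central segment with constant half-width, so the
  skeleton/EDT pipeline has closed-form truth. Width schedules span the
  2–10 µm minimum-diameter range these cells show in tissue; `length` is
  tip-to-tip. Capsules are oriented along the direction of motion.
- **Two-channel images** draw pixels i.i.d. Gaussian around region means
  (nucleus / cytosol / background), clipped at 0. Gaussian rather than
  Poisson noise because ratio recovery, not photon statistics, is the
  target; default noise is 10 % of signal.
- **Ct tables** simulate Ct = base − log₂(expression) + N(0, σ) with
  σ = 0.1 cycles (typical technical-replicate scatter) and a fixed
  reference gene.

All randomness flows from explicit per-spec seeds (numpy `default_rng`);
no global RNG state is touched, and identical specs are bit-reproducible.
What the generators do *not* emulate: segmentation error, uneven
illumination, out-of-focus light, nuclear rupture, 3D effects, or
photobleaching — passing tests demonstrate correctness of the
measurement code on well-segmented inputs, not robustness of upstream
segmentation.

## Pipeline and summaries

A `RunConfig` fixes pixel size (default 0.25 µm/px, a mid-range
confocal sampling), frame interval (2 min), harmonic count (25),
diameter bins ([2, 4] µm), minimum track length (40 min) and one seed.
Default conditions encode the qualitative contrast observed between
permissive confinement (unfolded envelope: a₈ = 0.03, width 3 µm, speed
4 µm/min, nuclear enrichment 2.0) and the control height (folded:
a₈ = 0.10, width 4.5 µm, 2 µm/min, ratio 1.0); per-cell jitter
(amplitude sd 0.01, radius sd 0.3 µm) provides the biological scatter
that makes bootstrap intervals meaningful. Tracks are simulated as
fixed-step random-heading walks reflected at the frame margins, so
programmed speed is recovered exactly regardless of heading. Condition
seeds derive from a CRC of the condition name plus the run seed, keeping
reruns bit-identical. Summaries report per-condition n, median and IQR;
`condition_compare` adds differences of medians with seeded bootstrap
percentile intervals (1,000 reps) — descriptive only, no hypothesis
tests.

Problem sizes throughout (≤ 96–256 px images, ≤ 21 frames, ≤ 10 seeds
per series) were chosen so the entire validation, including 1,000-contour
property sweeps, completes in well under a minute per module on one core.

## Known limitations

- EFC values depend mildly on the resampling density for very spiky
  contours; 1,024 points are ample for band limits ≤ 25 but the count is
  fixed, not adaptive.
- Minimum diameters carry a −0.3 µm worst-case bias at 0.25 µm/px from
  discrete thinning near odd/even width parities; do not interpret
  differences below the pixel scale.
- The tracker is first-order greedy: crossing cells within the gate can
  swap identities (documented, tested against the manifest).
- 2D only; projected areas and in-plane diameters, no volumetric
  envelope metrics.
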