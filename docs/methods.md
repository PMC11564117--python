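# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `beadrim`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic bead scenes

The generator emulates equatorial confocal sections of ligand-coated
agarose beads in a flat well. The noiseless image is

    I(x) = B + Σ_beads [ L·1(d ≤ R) + A·exp(−(d−R)² / 2σ²)·1(arc) ]

where `d` is the distance of pixel center `x` from the bead center, `B`
the flat background, `L` the interior fill above background, `A` the rim
amplitude and `σ` the radial width of the rim (Gaussian cross-section).
`1(arc)` zeroes a contiguous arc of `defect_fraction`·2π starting at a
seeded random angle, modeling unevenly coated beads. Pixel `(i, j)` has
its center at continuous coordinate `(i, j)`; coordinates are (row, col),
0-based. Detector noise is Poisson resampling of the noiseless signal
(`poisson_scale` photons per gray value; 0 disables) followed by additive
Gaussian read noise — the standard shot-plus-read detector model, in that
order.

Defaults, chosen once as a realistic confocal bead field and used as the
study conditions throughout the tests: 512×512 px, background 100,
radius ~ N(20, 3²) px, rim σ = 2 px (a few-pixel rim, marginally
oversampled on the pixel grid), interior +10, rim amplitude 100,
Gaussian read noise σ = 5, `poisson_scale` = 0.5 (≈ 50 photons at
background), minimum center separation 50 px. Bead centers are rejection-
sampled with a margin of 1.6·radius + 4σ from the image edge so the full
profiling reach stays in frame; placement failure after 1000 tries raises
an error naming the bead.

Ground truth per scene: the bead parameter list, and a label image marking
each bead's disk (overlaps resolved to the center nearest relative to its
radius). Rendering is deterministic per (config, seed), translation-
equivariant for integer shifts, and its integrated excess intensity
matches the closed form 2πRAσ√(2π)·(1−defect) + πR²L per bead to <0.5%.

The dose-series helper sets each scene's rim amplitude to
`max_amplitude / (1 + dose/IC50)` — an explicit demo surrogate for a
competition titration, not a fitted binding model.

What the generator does **not** emulate: 3D stacks and out-of-focus light,
point-spread-function blur (rims are drawn directly at their apparent
width), spatially varying background or illumination, bead-to-bead
brightness variation within a condition, autofluorescent debris, and
camera fixed-pattern noise. Passing tests therefore demonstrate correct
recovery of the stated image model, not robustness to every real-world
artifact; on real data the QC rule and manual review of flagged beads
carry that burden.

## Segmentation

The default backend is classical and fully deterministic:

1. Gaussian pre-smoothing (σ = 1 px) — thresholding only; measured
   intensities are never smoothed.
2. Otsu threshold. A contrast guard rejects structure-free images: the
   foreground/background mean separation must exceed 3× the robust
   intensity scale (1.4826·MAD), else the image yields zero beads (an
   Otsu split of pure noise separates the halves by only ~1.6σ).
3. Per-object convex hull. Bright rims threshold as annuli and — for
   unevenly coated beads — as open arcs that hole-filling cannot close;
   the hull recovers one compact object per bead so the downstream QC
   rule, not the segmenter, decides its fate.
4. Watershed. Seeds are h-maxima (depth 2 px) of the Gaussian-smoothed
   (σ = 2) distance transform of the hole-filled threshold mask: one
   seed per bead body, while thin ragged arcs flatten below the depth
   threshold and fall back to a single seed per object. Touching beads
   separate as long as their neck is ≥ 2 px shallower than their radii.
5. Rim circle fit. For labels whose below-threshold (interior) share
   exceeds 20% of their area, an algebraic least-squares circle (Kåsa
   fit) through the label's rim pixels replaces the label with that
   disk. This recovers the true center and rim-peak radius even from
   partial arcs (fits with implausible radius or center are rejected and
   the watershed label kept). On noiseless scenes the fitted radius lands
   within ~0.1 px of truth; an area-equivalent radius of the filled
   annulus alone would overshoot by the half ring thickness (~2 px).
6. Objects below the minimum area (default π·5² ≈ 79 px, rejecting noise
   specks) are dropped; labels are compacted to 1..K.

Any callable `image -> LabelMap` can replace this backend (e.g. an
adapter around a learned instance segmenter); backend parameters are not
interpreted by the pipeline.

Circular ROIs use the intensity-free centroid and the area-equivalent
radius √(area/π). Beads whose fitted circle crosses the image edge are
flagged and, by default, excluded from quantification (configurable) —
their rims cannot be profiled on all sides.

## Line profiling

Per bead, `n_lines` (default 20) rays at angles `start + k·2π/n` are
sampled at distances 0, 0.5, …, 1.5·radius (defaults) by bilinear
interpolation. The interpolator is written in incremental form
(corner + fractional differences) so constant images interpolate exactly
and amplitudes of flat signal are exactly zero. Sampling stops at the
first sample outside the image or inside the combined exclusion mask
(union of all fitted circles dilated by 2 px). A bead never truncates its
own lines: the mask test is skipped within the bead's own fitted radius
plus the dilation margin plus 0.5 px (the nearest-pixel mask lookup can
otherwise land on the bead's own boundary pixel). Lines retaining fewer
than `min_valid_samples` (default 5) samples are invalid.

The line length default of 1.5× the fitted radius realizes "extends past
the ROI border into the inter-bead space" as a radius multiple; it is
configurable (`length_factor`).

A line's amplitude is max − min of its retained raw intensities (no
smoothing). The per-bead measurement is the mean and sample SD (ddof = 1)
of the valid-line amplitudes; the mean of per-line max−min amplitudes is
the composition that uses both the per-line contrast and a per-bead mean
statistic. A bead with a single valid line gets SD 0 and a low-n flag;
zero valid lines marks the bead unmeasurable.

Numerical behavior, measured by the test suite:

- Noiseless accuracy: amplitudes land ~2% below the true rim amplitude
  (bilinear interpolation between pixel samples sags below the ring
  crest; the sag cancels in control normalization since it is
  multiplicative and geometry-independent). Against a 10×-finer
  resampling of the same image the median per-line deviation is ~0.5%,
  with a tail to ~2.5% at unfriendly pixel phases of the σ = 2 rim.
- Noise bias: max−min is positively biased under noise. At SNR 10
  (amplitude/read-noise ratio), the per-bead mean amplitude runs ~+13–14%
  above truth — the line minimum over ~40 effectively independent
  smoothed background samples sits near −1.9 of the interpolated noise
  scale, and the signal-anchored maximum adds a few percent more. The
  bias is an additive noise floor, common to all conditions acquired at
  the same settings, and largely cancels in between-condition ratios near
  the control's amplitude; it compresses ratios for conditions far below
  the control (visible in the README's titration example).

## QC, normalization, statistics

A bead is excluded iff `sd ≥ ratio · mean` with ratio 0.5 by default —
inclusive at the boundary, so a zero-signal bead (0 ≥ 0) is excluded with
its own reason code. Beads failing the rule are flagged for optional
human review; the pipeline never auto-corrects them. The verdict depends
only on the bead's own raw mean/SD, so QC is order-independent and
commutes with normalization.

Normalization divides every passing bead mean by the arithmetic mean of
the control condition's passing beads (passing-only: excluded beads never
feed the control average). Bead values are pooled across replicates by
default, matching designs that plot individual beads pooled over
independent experiments; per-replicate normalization is a config switch
(replicates lacking control beads fall back to the pooled control mean).

Dunnett's two-sided many-to-one test is computed in-package: with
control size n₀ and treatment sizes nᵢ, the comparison statistics are
jointly multivariate t with correlation λᵢλⱼ, λᵢ = √(nᵢ/(nᵢ+n₀)), on
N−K degrees of freedom. The adjusted p-value 1 − P(max|Tⱼ| ≤ |tᵢ|) is
evaluated by conditioning on the shared χ scale (Gauss–Legendre in its
probability scale, 160 nodes) and the shared control factor
(Gauss–Hermite, 128 nodes), making each comparison independent in the
inner product. The quadrature is deterministic and accurate to ~1e-7;
with a single treatment it reproduces the pooled two-sided t-test to
<1e-6, and the all-null familywise error at α = 0.05 calibrates inside
[0.03, 0.07] (1000 simulations, 4 groups of 35). Degenerate zero-variance
input is handled explicitly (identical groups: F = 0, p = 1; distinct
means with zero within-group variance: p = 0). Welch's unequal-variance
t-test covers two-group designs. Stars: * <0.05, ** <0.005, *** <0.001,
**** <0.0001.

Out of scope by design: hierarchical/mixed-effects modeling of replicate
structure, two-way ANOVA, equivalence testing, background subtraction and
flat-field correction, anisotropic pixels, and any learned segmentation
model (only the backend seam is provided).

## Pipeline and reproducibility

A run is a manifest (condition → TIFF files, channels, control flag) plus
a run config (QC ratio, profiling and segmentation parameters, seed,
output directory). Every stage is deterministic, tables are written with
a fixed column order, and identical config+seed reruns are byte-identical
(timestamps live only in `run_record.yaml`). The run record keeps a bead
ledger per condition — found = passed + QC-excluded + edge-excluded +
unmeasurable — which the pipeline verifies before writing. Stage failures
abort with the stage and file named and drop a `FAILED` marker next to
any partial outputs.

Problem sizes in the test suite and acceptance script (320–512 px scenes,
6–12 beads per image, 50–100 beads per measured rate, 1000 null
simulations for the familywise-error calibration) were chosen as the
smallest sizes at which the measured rates are stable to the asserted
tolerances.
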