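# Methods

## Scope and units

All images are single 2-D planes.  Coordinates are (row, col), 0-based,
origin top-left; all radii and distances are in pixels; `pixel_size`
(micrometres per pixel, default 0.5) converts areas to µm² and frame
areas to mm².  Intensities live on a [0, 1] float scale: integer images
are divided by their dtype range at read time, and every threshold
below is expressed on that scale.

## Synthetic scenes

The generator emulates four-laser confocal acquisitions of PNN-stained
material: a nuclear channel (soft discs), the WFA channel (punctate
annuli around a subset of somata), a tag/comparison channel (the same
annulus texture for surface-positive cells, plus vesicle-like somatic
puncta for intracellular-punctate cells), and a PV channel (soma fill).
Defaults follow the acquisitions the pipeline is built for: 1024 × 1024
frames, and per-scene populations with a rank coupling of 0.816 between
the WFA and tag ring intensities and surface-positive / intracellular
fractions of 66% / 29% among PNN cells.

Geometry defaults: nucleus radius 3.5–4.5 px, ring radius 16–22 px with
half-thickness 2.5 px, 4–8 puncta per punctate cell (Gaussian SD
1.2 px).  Centres are placed by dart throwing with a minimum spacing of
2·(r_max + thickness) + 3 px, which guarantees non-overlapping rings; a
scene that cannot hold the requested count raises a placement error
naming how many cells fit.  Absolute intensity scales are not dictated
by any acquisition standard, so ring levels are drawn uniformly —
WFA from (0.30, 0.75), tag from (0.25, 0.65) — and sized so that the
normalised ring texture times the brightest level stays inside the
[0, 1] dynamic range (texture peaks would otherwise clip and bias the
brightest nets).

**Ring texture.** A soft annular base plus a Poisson-disc dot field
(spacing 2.5 px) blurred by a 1.2 px Gaussian, rescaled so its mean
over the exact geometric annulus equals the cell's level.  The
noiseless rendering therefore satisfies mean(ring mask) = level to
within the blur tails of neighbouring rings (≲ 0.5%).  Surface-positive
cells reuse the *identical* normalised texture in the tag channel at
their own level, reflecting that the tagged protein decorates the same
net.

**Rank coupling.** Per-net levels of the two channels are drawn through
a Gaussian copula: correlated standard normals at the latent Pearson
value 2·sin(π·ρ_s/6), pushed through strictly monotone maps onto the
uniform marginals.  Monotone maps preserve ranks, so the population
Spearman among tagged nets equals the requested ρ_s whatever the
marginals; ρ_s = ±1 are handled exactly.  At n = 2000 the realised
truth-table Spearman sits within ±0.03 of the setting (checked against
a brute-force rank-then-Pearson oracle).

**Phenotypes.** Surface-positive and intracellular-punctate labels are
drawn among PNN cells only, since the census denominator downstream is
the PNN-positive population; the two calls are independent (a cell may
be both).  A Bernoulli mode gives binomial spread; the exact-count mode
assigns exactly round(frac·n) positives and is what the recovery
experiments use, so fraction recovery is not confounded by binomial
noise.  Somatic puncta are dart-thrown in the annulus between the
nucleus edge (+1.5 px) and the ring's inner edge minus 5.5 px, keeping
them clear of ring-texture blur; if the zone cannot hold the drawn
count the truth records the number actually rendered.

**Noise.** A constant baseline (0.05) plus Gaussian read noise
(SD 0.01), with optional Poisson shot noise before the additive terms;
images are clipped to [0, 1] at the end.  One seeded generator drives
placement, phenotype draws, levels, textures and noise, so identical
configs give bit-identical scenes and truth tables.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: out-of-focus light and true optics
(no PSF), autofluorescence gradients and uneven illumination, touching
or overlapping nets, partial rings and irregular (non-circular) net
morphology, intensity bleed-through between channels, and 3-D
structure.  Detection parameters that are comfortable on these scenes
(radius range, accumulator threshold) will need re-tuning on real
acquisitions.

## Detection

1. **Nuclei.** The nuclear channel is smoothed (Gaussian, σ 2 px) and
   thresholded at median + 6·MAD; connected components are
   re-thresholded at half their peak height above background (the low
   global threshold otherwise keeps the smoothed skirt and inflates the
   mask), then filtered by area (15–400 px²).  Output is sorted by
   centroid.
2. **Rings.** Canny edges (σ 2) feed `hough_circle` over radii 8–30 px;
   normalised accumulator peaks below 0.35 are discarded; greedy
   non-maximum suppression keeps the better-scoring candidate within
   16 px.  Because the accumulator tends to lock onto the inner or
   outer edge of a thick annulus, each radius is refined to the
   intensity-weighted mean distance from the centre within a ±7 px
   band, iterated twice; on synthetic rings this brings the radius
   error from ~3 px to ~0.3 px.
3. **Gating.** A candidate survives iff some nucleus centroid lies
   within its circle (times `gate_factor`, default 1); the nearest such
   nucleus is linked, and a nucleus backs at most one candidate (best
   detection score wins).  Gating can only remove candidates.
4. **Ring-area segmentation.** Within the annulus radius ± 2.5 px,
   pixels whose WFA intensity exceeds median + 2·MAD of an annular
   background shell outside the ring (gap 2 px, width 5 px) form the
   measurement mask.  An empty mask drops the object with a logged
   reason.

Tie-breaking everywhere is (score desc, row asc, col asc), so identical
inputs give identical object lists.

## Measurement and colocalization

Mean intensity is the plain arithmetic mean over the ring mask — no
background subtraction by default (an optional shell-based subtraction
exists behind a flag), and every channel is measured over the identical
mask.  Spearman's ρ is the Pearson correlation of average-assigned
ranks, exact under ties; fewer than 3 pairs or a constant variable
raises (a degenerate correlation is an error, not a silent 0 or NaN).
No p-value is attached by default; a seeded permutation p (10 000
shuffles) is available on request.  Records pool across images and
subjects by default — one coefficient over the whole sample — since
that is how a single reported coefficient over several animals arises;
per-subject analyses filter records upstream.

## Phenotype classification

Background (median, 1.4826·MAD) of the tag channel is estimated from
pixels outside every detected object's disc.  *Surface-positive*: ring
mean ≥ background + 3 SD.  *Intracellular-punctate*: ≥ 3 local maxima
of the lightly smoothed (σ 1) tag channel inside the soma zone, each ≥
background + 3 SD, separated by ≥ 3 px.  The soma zone is the ring
interior pulled in by 7 px minus the dilated nucleus mask; maxima are
taken over the full local patch rather than the masked zone, because a
brightness gradient sloping up toward the ring would otherwise
manufacture spurious peaks all along the zone boundary.  All thresholds
(k_surface, k_puncta, m, spacings) are exposed in `ClassifyParams`.

The census reports the percentage of detected PNN cells carrying each
phenotype, with the denominator recorded.

## Culture statistics

Density is count × (50 / imaged mm²).  "Relative" size and intensity
are each measurement divided by the control-group mean, so the control
relative mean is 1 by construction.  PV cells are nuclei whose
surrounding soma disc (2 × the nucleus' equivalent radius) exceeds the
PV-channel background by 3 robust SDs; a PV cell "has a PNN" when a
validated object links to its nucleus.  Group comparisons use the
pooled-variance Student's t (Welch is available as an option) or
one-way ANOVA; identical constant groups return the p = 1 convention
with a `degenerate` flag rather than NaN.  The default unit of analysis
is the PNN (pooled per condition) for size/intensity and the dish for
density and PV fractions.

## Recovery experiments and problem sizes

The published coefficients this pipeline shadows come from microscopy
data that was never deposited, so the checks are parameter recovery at
desk scale: 7 × 80 = 560 rank-coupled nets for the colocalization
recovery (tolerance ±0.05 around 0.816) and 13 × 80 = 1040 exact-count
nets for the census recovery (±3 percentage points around 66% / 29%),
each across several 1024 × 1024 frames.  t-test calibration uses 5000
vectorised replicates at n = 20 per group against the noncentral-t
closed form; the enzyme-digestion simulation scales ring levels by 0.3
and expects significant per-channel reductions at ~20 nets per group in
every seed.

## Known limitations

* Circle-based detection assumes roughly circular, non-overlapping
  nets; overlapping or crescent-shaped nets are not resolved.
* The nucleus gate needs a usable nuclear channel; dim or merged nuclei
  cost detections (and gating is all-or-nothing, no soft scores).
* Classification thresholds are z-scores against a global image
  background; strong local background structure in real tissue may
  need the optional background subtraction or per-region statistics.
* The Spearman coefficient is attenuated when untagged nets (tag mean ≈
  background) are pooled with tagged ones; pool the tagged subset, or
  generate/select accordingly, when the coupling itself is the target.
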