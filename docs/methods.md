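# Methods

This note documents the models, numerical choices and limitations behind
`iscatflow`, in the spirit of the methods documentation of packages like
scanpy or statsmodels: enough detail that a user can judge what the
implementation assumes and what passing tests do and do not demonstrate.

## Imaging model

The instrument is a wide-field common-path interferometric microscope: the
camera records |E_r + E_s|², the interference of the reference reflection
from the substrate/water interface with the weak field scattered by a
surface-bound nanoparticle. A bound particle therefore appears as a
diffraction-limited spot riding on a bright background, and the measured
quantity is its *contrast* — the fractional deviation from the local
background. The default geometry (455 nm LED illumination, NA 1.46, 6.5 µm
camera pixels at 100× → 65 nm sample-plane pitch, 1024² frames → 66.6 µm
field of view) is collected in `InstrumentConfig`.

The synthetic generator approximates the in-focus PSF by a 2D Gaussian with
σ = 0.21 λ/NA (≈ 65 nm ≈ 1.0 px at defaults). This is the standard
Airy-core approximation; it reproduces the width and integrated signal of
diffraction-limited spots well, but deliberately renders no interferometric
ring structure or defocus behaviour. Spots are rendered with positive
contrast; the detection stage operates on the magnitude of the processed
image, so dark (destructively interfering) spots are handled identically by
symmetry, and a test covers the inverted case.

Shot noise is Poissonian around background_counts × gain × (1 + Σ spots).
Saved frames on the real instrument are 100-frame time averages; the
generator reproduces this exactly by drawing Poisson(n·µ)/n, which is the
distribution of an n-frame average. The default `n_averaged = 100` in the
scan generator matches that acquisition mode, putting the per-pixel noise at
10⁻³ of background for the default 10⁴-count level.

The illumination/optical-path gain field is a sum of low-order polynomials
(±10% amplitude) under a circular flat-top vignette — smooth by
construction, as real inhomogeneity is after the parasitic-fringe-free
design of the instrument. The gain is *camera-fixed* (identical in every
tile of a scan), which is what makes the flat-field strategy meaningful and
what forbids registering tiles on uncorrected images (the fixed pattern
would lock registration to zero shift).

## Image processing

**Background level.** Frames are normalised to their median rather than the
mean: with up to a few hundred spots per Mpixel the median estimates the
background to < 0.1% regardless of spot brightness.

**Flat-field.** Pixel-wise median over ≥ 60 frames taken at distinct sample
positions (each normalised to its own level first). Sparse per-frame spots
occupy any given pixel in ≪ half the frames and are rejected by the median;
the recovered gain is accurate to ~0.02% RMS in the test conditions. Below
60 frames the function warns but proceeds.

**Large-feature removal.** The 17-px median-filtered image is subtracted,
leaving a zero-baseline contrast image. The kernel is ~7× the PSF sigma, so
spot peaks are attenuated by < 2%; smooth structure (residual gain,
out-of-focus objects) is removed. Boundary handling is reflect padding;
because any padding biases the local median near edges, detection excludes
a border margin (default 8 px = kernel/2 — see below).

**Stitching.** Pairwise shifts between nominally overlapping tiles are
refined by phase correlation on the overlap crops, using plain
(unnormalised) cross-correlation: for sparse spot constellations on a flat
background, spectral whitening would spread the correlation energy into the
noise floor, whereas plain correlation weights the peak by spot energy.
A refined shift is accepted only if (i) it is within `max_shift_px`
(default 16) of the nominal offset — stage encoder errors are a few pixels,
and larger apparent shifts mean the correlator paired up the wrong spots —
and (ii) the Pearson correlation of the re-aligned overlap exceeds 5
standard errors (5/√n_pixels) of a noise-only correlation and improves on
the nominal alignment. Pairs failing the checks fall back to their nominal
offsets with a summary warning. Tile origins are then solved by linear
least squares over all pairwise constraints (anchored at tile 0) and
rounded to integer pixels; overlaps are composited with an unweighted mean.
Sub-pixel registration exists behind `subpixel=True` but is off by default:
integer accuracy (≤ 1 px) is what duplicate-merging needs.

With the defaults (10% overlap) an overlap strip of a 1024² tile holds only
a handful of spots at realistic densities, so registration accuracy is
signal-limited; the acceptance-scale check (3×3 grid, density
2.5 per 100 µm²) recovers all seeded offsets to ≤ 1 px. At very sparse
densities pairs legitimately fall back to nominal offsets and the residual
error equals the stage jitter.

## Spot detection and localisation

**Noise model.** Global σ = 1.4826 × median(|x − median|) (the Gaussian
consistency constant for the MAD); the local noise map is the RMS over a
65-px sliding window of pixels with |value| ≤ 2.5 σ_global, computed with
uniform filters in O(N). Windows with < 10% inliers fall back to σ_global,
and the map is floored at 0.25 σ_global so SNR cannot blow up. The
sliding-window (not block-wise) interpretation is a declared choice.

**Segmentation.** Pixels with |image|/σ_local > 4 are thresholded;
8-connected components qualify when some 3×3 window contains ≥ 3
supra-threshold pixels. Candidates closer than 3 px merge into the
higher-peak-SNR one. An 8-px border margin is excluded: median-filter
padding residuals there mimic spots (in tile scans the margins are covered
by neighbouring tiles, so only the outer mosaic rim — < 1% of area — loses
coverage). With independent pixel noise the expected false-positive rate of
this rule is ≪ 0.01 per frame; the measured rate in the acceptance run is
zero over the tested fields of view.

**Localisation.** The radial-symmetry-centres method: gradients on the
inter-pixel midpoint grid (Roberts-cross derivatives, 3×3 boxcar smoothed)
define lines through each midpoint along the local gradient; for a radially
symmetric spot all lines pass through the centre, which is found as the
weighted least-squares point minimising perpendicular distances (closed-form
2×2 solve). Weights are |∇I|²/d with d the distance to the gradient-weighted
centroid (floored at 0.1 px). The implementation avoids the slope-intercept
form entirely (projection-matrix formulation), so vertical gradients are not
a special case. Accuracy: 4×10⁻⁴ px RMS noiseless, ≈ 0.2 px at peak SNR 8.
Flat or singular ROIs raise a localisation error and the candidate is
dropped.

**Contrast.** The peak contrast is the spot amplitude at its sub-pixel
maximum, from a log-quadratic fit to the 3×3 neighbourhood of the brightest
pixel — exact for a Gaussian profile at any sub-pixel position, while a raw
pixel maximum would under-read off-centre spots by up to 22% and skew the
contrast distribution. Where the fit has no interior maximum (noise-
dominated shapes) the pixel maximum is used. The integrated contrast is the
ROI sum above the zero baseline (contrast·px²). Both are magnitudes.

**Duplicate merging.** Per-tile localisations are mapped through the
stitched tile origins; detections within 2 px keep only the highest-SNR
record. The radius tolerates the ≤ 1 px registration plus ≤ 0.3 px
localisation errors while staying below realistic spot separations.

## Assay quantification

Densities are counts per 100 µm² (10×10 µm reference cell), the unit that
makes different scan sizes comparable. The background/signal contrast
cut-off is 7.5×10⁻³; a contrast exactly at the cut-off counts as background
(conservative tie rule). Classification uses the peak (not integrated)
contrast. Replicate aggregation reports mean or median ± SEM = sd/√N; the
one-way ANOVA uses the classical between/within mean squares with exact
degenerate handling (all-identical data → F = 0, p = 1).

## Binding kinetics

First-order Langmuir kinetics: N(t) = N_eq(1 − e^(−t/τ)),
N_eq = N_max·C/(C+K), τ = 1/(k_on C + k_off), K = k_off/k_on. The
dose-response fit is nonlinear least squares with positivity bounds and
initial guesses N_max = max(N), K = median(C); it is exactly equivariant
under concentration rescaling. The steady-state rule — the earliest
timepoint from which every later 2-h window spans < 5% of its mean — is a
declared operationalisation of "plateauing"; it is meant for count levels
where Poisson noise is below the tolerance (N ≳ 2×10³ per scan; low-count
channels legitimately never trigger it). The linear range is the longest
low-concentration prefix (≥ 3 points) whose zero-intercept fit keeps
R² ≥ 0.99 — zero intercept because densities vanish at zero concentration.
Intra-channel gradients cut the mosaic into equal-length segments along the
flow axis, segment 1 at the entrance. No two-rate or dissociation models
are fitted: unbinding is essentially undetectable in this assay class and
rate constants extracted in the titration regime would be biased.

## Fingerprints

Corrections apply in the stated order: chip-wise IgG1 subtraction first
(negatives floored at 0 — a channel cannot capture less than nothing), then
division by the row mean of CD9/CD63/CD81, which makes that mean exactly 1
and the fingerprint invariant to global density rescaling (concentration and
flow-rate differences). PCA runs on the six specific markers
(tetraspanins + cancer markers, IgG1 excluded), column-centred, z-scoring
available but off by default; component signs are fixed so the
largest-|loading| element is positive, making projections reproducible. A
manual chip-exclusion flag is the intended mechanism for QC outliers (e.g. a
flow-blocked channel); no automatic outlier rejection is performed.

**Positivity calls and replicate counts.** A marker is *positive* when its
mean raw density exceeds the IgG1 mean + 2 SD(IgG1) across chips. With only
3–4 replicates the sample SD of the control is itself noisy (a χ-distributed
estimate with 2–3 degrees of freedom), which raises the family-wise
false-call rate over a 3-marker panel to ~10–15%; at 6 replicates it drops
below 5%. The property test therefore runs at 6 chips, and users drawing
positivity conclusions from 3-chip panels should treat borderline calls with
caution.

## Transport calculators

Stokes–Einstein D = k_B T/(3πηd) with declared defaults (150 nm EVs, 6 nm
proteins, 293 K, 1.0 mPa·s) gives the quoted ~3 vs ~70 µm²/s contrast. The
Damköhler number Da = k_on·b_m/(D/δ) uses the shear-limited depletion-layer
scaling δ = (D L/γ)^{1/3}, γ = 6Q/(H²W). The reference parameter set
(`EV_REFERENCE_TRANSPORT`) uses the probe density 0.08 pmol/cm² and an
*effective per-particle* association rate of 5×10⁶ M⁻¹s⁻¹: a single
antibody–antigen pair associates at ~10⁵–10⁶ M⁻¹s⁻¹, and the avidity of an
EV presenting many antigen copies to a dense antibody lawn multiplies the
effective on-rate of the particle, which is the rate the capture flux sees.
With it, Da ≈ 3.3 at 10.6 µL/h and ≈ 6.7 at 1.3 µL/h — mass-transport
limited, consistent with the flow-rate sensitivity of the measured kinetics.
These calculators are order-of-magnitude screens; no advection–diffusion
PDE is solved.

One unit subtlety: a probe layer of 0.08 pmol/cm² dissolved into a
10-µm-high channel corresponds to 8×10⁻⁸ M = 0.08 µM (not tens of µM); the
calculator returns the dimensionally correct value.

## Problem sizes and what the tests show

The test suite and the acceptance script run at desk scale, chosen to keep
statistical power while completing in minutes on one CPU: the detection
suite uses 10 (suite) / 6 (script) full 1024² frames × 50 isolated spots
with SNR drawn from 8–40; density recovery runs the full chain on a 0.2 mm²
(suite) / 0.05 mm² (script) scan at 1.0 spot per 100 µm²; stitching uses a
3×3 grid of 1024² tiles; Langmuir recovery uses 200 replicate fits at 6
concentrations; fingerprint separation uses 100 seeded datasets of 2 cell
lines × 4 chips.

What passing these suites shows: the chain is internally consistent and
recovers known ground truth under the generator's assumptions — Gaussian
PSF, smooth camera-fixed gain, Poisson noise, well-separated spots, ideal
Langmuir kinetics, Poisson capture statistics. What it does not show:
robustness to real-instrument effects outside the model — interferometric
ring PSFs and defocus, stage drift within an exposure, vibration, detector
fixed-pattern noise beyond smooth gain, crowding near the upper density
limit (~2 per µm², where the SNR-threshold segmentation starts failing by
design), aggregation, or biological variation in marker expression. The
contrast scale is a proxy: the generator's contrast laws are placeholders
for pipeline testing, not a claim about real EV contrast distributions.

## Known limitations

- No time-lapse differential imaging mode and no PSF-model fitting; both
  are explicit non-goals of this read-out design.
- Stitching assumes translation-only offsets (no rotation/scale), valid for
  encoder-driven raster scans.
- The steady-state rule and the positivity rule are operational conventions;
  alternative conventions would shift individual numbers without changing
  the pipeline.
- Absolute particle sizing from contrast is out of scope.
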