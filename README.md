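# iscatflow

Computational read-out for a label-free optofluidic biosensing platform:
wide-field interferometric (iSCAT-type / inline-holography) microscopy of
nanoparticles captured on antibody-functionalised supported lipid bilayers
inside PDMS microfluidic channels. The package takes raw camera frames to
quantitative assay results — substrate defect densities, immunocapture
binding kinetics, and multiplexed extracellular-vesicle (EV) surface-marker
fingerprints — and ships a synthetic-data generator with exact ground truth
so every stage can be benchmarked without an instrument.

Intended users: groups building or analysing surface-sensitive label-free
single-particle assays who need a tested, reusable implementation of the
image-analysis and assay-quantification chain.

## What it computes

A particle bound to the sensor surface appears as a diffraction-limited spot
whose **contrast** — the fractional deviation of intensity from the local
background in the flat-fielded image — scales with particle size and
refractive index. The chain is:

1. **Image processing** (`imgproc`): frames are normalised to the background
   camera counts, divided by a flat-field gain image (pixel-wise median over
   ≥ 60 frames at distinct positions), and a 17-px spatial median filter is
   subtracted to remove smooth large-scale structure. Tiles are stitched by
   phase correlation into channel-scale mosaics.
2. **Localisation** (`locfind`): a global noise level σ = 1.4826 × MAD and a
   local 65-px RMS noise map (excluding |values| > 2.5σ) define an SNR
   image; clusters with ≥ 3 pixels above SNR 4 inside a 3×3 window are
   candidates, localised to sub-pixel precision by the radial-symmetry-centres
   algorithm, and their peak and integrated contrasts are stored.
3. **Quantification** (`quantify`): localisations below the contrast cut-off
   7.5×10⁻³ are *background* (substrate roughness), above it *signal*;
   counts are reported per 100 µm², with replicate statistics and ANOVA.
4. **Kinetics** (`kinetics`): captured-particle counts follow
   N(t) = N_eq (1 − e^(−t/τ)) with the Langmuir equilibrium
   N_eq(C) = N_max·C/(C + K); the module detects steady state, fits the
   isotherm, finds the linear range and resolves intra-channel density
   gradients under mass-transport-limited flow.
5. **Fingerprints** (`fingerprint`): per-channel capture densities over a
   marker panel are corrected chip-by-chip by the IgG1 isotype control,
   normalised to the mean of the tetraspanins CD9/CD63/CD81 (making the
   fingerprint independent of EV concentration and flow rate), and compared
   by 2-component PCA.
6. **Design calculators** (`platform_calc`): deterministic unit-checked
   estimates — field of view, irradiance, biotin surface densities,
   Stokes–Einstein diffusion, channel volumes, Damköhler number.
7. **Synthetic data** (`synthgen`): frames with Gaussian-PSF spots
   (σ = 0.21 λ/NA ≈ 1 px), smooth gain fields, Poisson shot noise,
   overlapping tile scans with stage jitter, Langmuir time courses and
   fingerprint datasets — all with seeded, bit-reproducible ground truth.

## Worked example

`examples/01_simulate_and_localize.py` seeds 40 spots of known contrast into
a shot-noise frame and runs the full detection chain:

```
seeded spots:   40
detected spots: 40
localisation RMS error: 0.026 px
median seeded contrast:   0.0538
median measured contrast: 0.0537
```

All 40 spots are found with no false positives; positions are recovered to
~0.03 px (≈ 2 nm at the 65 nm/px sample-plane pitch) and the measured
contrast distribution matches the seeded one — contrast is the quantity all
downstream densities, kinetics and fingerprints are built on. The other
scripts in `examples/` walk through flat-fielding and stitching, defect
densities, binding kinetics and EV fingerprints the same way.

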