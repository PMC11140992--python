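# Methods

## Coordinate and unit conventions

Rows index axial depth (increasing posteriorly), columns index lateral
position. Traces are 0-based with subpixel depths as real numbers;
thickness in micrometers is (row difference) × `axial_px_um`. Frame
numbers in user-facing configuration are 1-based inclusive (frames
"450:549" select 100 frames); conversion happens only in the CLI layer.
Default geometry is configurable; the test and acceptance runs use a
desk-scale 320 × 480 px raster at 1.6 µm (axial) × 2.8 µm (lateral) per
pixel so that both 350–624 µm analysis regions fit beside a centred
optic nerve head, and 2–20 frames per stack instead of a full
1000 × 1000 acquisition. These sizes are the package's choice of
simulation scale; every algorithmic parameter is independent of them.

## Phantom model

A B-scan is rendered from a continuous axial reflectivity model:
piecewise-constant slabs (vitreous, NFL+GCL, IPL, INL+OPL, ONL, and a
sub-RPE slab) whose interfaces are softened by an error-function edge of
sigma 1.2 µm (an axial PSF stand-in that makes subpixel boundary
positions well defined), plus Gaussian hyperreflective bands for the
ELM (amplitude 20 000 counts, σ 2 µm), the ellipsoid zone
(EZ; 30 000 counts, σ 4 µm × an `ez_elongation` factor) and the RPE
(28 000 counts, σ 5 µm) on a 13 000-count background, in a 16-bit
log-scaled intensity range. Slab reflectivities decrease monotonically
from NFL+GCL (30 000) to ONL (11 000), which is what makes the three
inner boundaries bright-to-dark gradient edges.

Bruch's membrane (BrM) is defined *operationally*, exactly as the
measurement defines the basal RPE: the posterior half-maximum crossing
of the RPE band, centre + √(2 ln 2)·σ. The sub-RPE slab has the same
reflectivity as the band background so this crossing is analytically
exact in the ground truth. `make_retina_layers` solves the RPE band
placement so the ELM-centre→BrM distance equals the requested
`elm_rpe_um` exactly; `ez_elongation` scales the EZ axial sigma at fixed
amplitude, which is the band-shape change the MCP/AR descriptor is
designed to detect.

Lateral structure: a parabolic posterior sag (peak-to-edge
`curvature_um`, default 15–40 µm in tests) and a handful of vessel
shadows (Gaussian lateral attenuation of the retinal signal, up to 35 %)
— real B-scans carry such landmarks, and without them lateral
registration is ill-posed. The shadow positions are drawn once per
phantom from its seed, so ground truth boundaries are unaffected.

Speckle: the stored image is log-scaled, and multiplicative log-normal
speckle on the linear signal is exactly additive Gaussian noise on the
log scale, so each frame receives i.i.d. N(0, (`log_slope` ×
`speckle_sigma`)²) counts with `log_slope` = 65535/8 (the full 16-bit
range spans 8 natural-log units of linear dynamic range). This is a
deliberate simplification: real OCT speckle is spatially correlated at
the PSF scale and non-Gaussian; frame averaging on real data therefore
improves noise somewhat more slowly than the 1/√N the phantom shows.
Per-frame rigid jitter (rotation about the image centre, then
translation) is drawn uniformly within configured caps; frame 1 is
always untouched, and the ground truth stores the *aligning* transform
per frame — directly comparable to registration output.

Cohorts: per mouse, ELM–RPE is normal around the group mean
(between-mouse SD default 0.8 µm), contrast sensitivity is gamma with
the group mean (shape default 30), acuity is normal. The defaults give
confidence intervals commensurate with a small-rodent OKT/OCT study;
both are tunable per group. All draws descend from one `SeedSequence`,
so cohorts are bit-reproducible.

What passing phantom tests does *not* show: robustness to real
segmentation hazards (pathology, shadowing artifacts, detached retina),
to correlated speckle, or to the intensity nonlinearities of a specific
scanner. The phantom validates the measurement chain, not the imaging
physics.

## Registration

The similarity metric is normalized cross-correlation (NCC), computed on
a central crop that excludes the maximum search displacement. The rigid
first pass searches a rotation grid (coarse 0.5°, then 0.1° around the
best, then a parabolic fit over the final three grid points), estimating
the translation at each rotation by FFT cross-correlation with subpixel
upsampling, clipped to the configured cap (default ±10 px, ±3°);
interpolation is bilinear with edge replication. The non-rotational
refinement alternates a per-column axial pass and a per-row lateral pass
(axial first, since axial eye motion dominates OCT jitter), each an
integer ±window NCC search with parabolic subpixel refinement, iterated
three times against the *fixed* reference frame (the first selected
frame by default). A parabolic subpixel step is suppressed when the line
NCC is already 1 (nothing to improve; avoids spurious micro-shifts on
identical inputs). Frames whose post-alignment NCC falls below a
configurable floor (default 0.6) are excluded from the pixel-wise mean
and logged — a numeric stand-in for a visual quality check.

## Segmentation

Seed boundaries come from a classical per-column detector on a
(1.5 px axial × 2 px lateral) Gaussian-smoothed image: the three most
posterior prominent local maxima of each column profile are the ELM, EZ
and RPE; the ILM is the most anterior strong rising edge; the three
strongest falling edges between ILM and ELM are GCL/IPL, IPL/INL and
OPL/ONL. Columns where detection fails are filled by lateral
interpolation and a 9-px median filter (edge-replicating); a layer
missing in more than half the columns raises a segmentation failure. A
truth-perturbation seed mode (ground truth + bias + jitter) exists to
exercise the refinement in isolation, standing in for an external
learned boundary estimator: the shortest-path refinement, not the seed
provider, is the reusable computation here.

Slab boundaries are refined by a dynamic-programming shortest path over
a per-layer cost image — the per-column min-max-scaled signed axial
gradient of the appropriate polarity (bands use inverted intensity) —
constrained to ±12 px around the seed with a ≤2 px column-to-column
jump; ties break toward the seed, then toward the smaller row. The DP
is verified against exhaustive path enumeration on random 6×6 grids. A
final parabolic interpolation of the gradient extremum gives subpixel
slab boundaries. ELM and RPE are re-localized as the highest *local*
maximum within ±6 px of their seeds (3-point parabolic subpixel; exact
ties go to the most anterior), and BrM as the posterior half-maximum
crossing of the RPE band with the background taken as the minimum over a
20-px posterior window. Band smoothing is σ = 1 px axial only; heavier
smoothing widens the RPE band and biases the half-max crossing
posteriorly (~0.2 px at these widths — the one known systematic error,
constant across groups so differences are unaffected). All costs and
peak rules are offset-invariant, so segmentation is unchanged by a
global additive intensity shift.

## Biomarkers

Analysis regions are the columns whose lateral offset from the optic
nerve head lies in [350, 624] µm (inclusive, exact bounds) on each side.
Thicknesses are region means of trace differences. Flattening holds BrM
at a fixed row using integer per-column shifts only — no interpolation,
so column content and thicknesses are exactly preserved, at the cost of
±0.5 px residual ripple. The reflectivity profile is the per-depth mean
over region columns (masked pixels excluded), with depth anchored at the
BrM row.

The band posterior to the ELM is delimited on that profile: first local
maximum posterior to the ELM peak; flanking local minima; baseline =
straight chord between the profile values at those minima (a
horizontal-at-higher-minimum alternative sits behind a config switch).
The planar region between baseline and curve — with intensity mapped to
pixels by a fixed study-wide scale, default 65535 counts ↦ 256 px — is
summarized by its second central moments: the curve and baseline are
treated as piecewise linear, every moment integrand is then a
polynomial of degree ≤ 3 per strip, and 2-point Gauss–Legendre
integration per strip is exact for that polygonal region. The reported
ellipse matches centroid, moment orientation and axis ratio, scaled to
the exact region area; MCP/AR = semi-minor/semi-major ∈ (0, 1]. Absolute
MCP/AR values are only comparable at a fixed intensity scale (the scale
is recorded with the outputs); differences and monotone trends are the
meaningful quantities. The ELM depth used to locate the band is the
region-mean ELM row — per-column band fitting is noisier and the profile
is a region mean anyway. All shape analysis runs on the log-scaled
image; a linearization hook exists but is off by default, since band
shape differences are detectable on either scale.

If the EZ band is elongated far enough that it merges with the ELM peak
(no trough between them at the rendered separation), the band region is
undefined and the measurement raises `BandNotFoundError` rather than
guessing; sweeps in the tests stay within the resolvable regime
(elongation ≤ 1.3 at the default 15 µm ELM–EZ separation).

## Statistics

With one eye per mouse in a cross-sectional design, a mouse random
intercept collapses into between-mouse variance, so the pipeline first
averages within mouse (per side; sides are collapsed when they do not
differ) and then contrasts groups directly: Welch mean differences with
95 % CIs for thicknesses and MCP/AR, and a two-group gamma GLM with log
link (statsmodels IRLS, Pearson-moment dispersion, Wald intervals on the
log scale) for contrast sensitivity — whose point estimate is exactly
the ratio of sample means, a property the tests verify both in closed
form and against the IRLS fit. No multiplicity adjustment is applied;
all contrasts are planned. Degenerate inputs (zero variance everywhere)
return the exact estimate with a zero-width interval instead of failing.
An optional mixed-model route (`mixed_model_contrast`, a linear mixed
model with a random intercept per mouse on the raw eye-side records)
delegates to statsmodels MixedLM and agrees with the summary contrast on
balanced designs; the heavier machinery (e.g. Kenward–Roger degrees of
freedom) is deliberately out of scope. Simulation shows the two-group
contrasts are well calibrated (94–95 % coverage, ~4.5 % type-I error at
α = 0.05).

## Reproducibility

Every random quantity descends from an explicit seed; the pipeline
manifest records the config SHA-256, seed and package version, and a
rerun from the same manifest produces byte-identical outputs. The
acceptance script derives all sub-seeds from its `--seed` argument.
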