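# Methods

This note documents the forward model, the estimators, the defaults and the
known limitations of the package.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Forward model (synthetic_data)

**Geometry.**  An active-gene focus is modelled as a circular (optionally
elliptic) loop: a midline circle of diameter *d* with a Gaussian tube
cross-section of width `tube_sigma` (default 40 nm, chosen so blurred rings
resemble reported SIM foci; the annulus thickness of real UBF rings is not
separately known).  Orientations are uniform on the sphere; centres are
uniform inside a nucleolar ellipsoid with a hard non-overlap spacing of
1.5 × the population mean diameter (rejection sampling, capped attempts).
Diameters follow a normal distribution truncated at zero.  Nested
ellipsoidal cell/nucleus/nucleolus masks share one centre; default semi-axes
are 0.46/0.36/0.22 of the canvas extent.

**Sampling.**  The canvas defaults to 40 × 40 nm lateral and 125 nm axial
voxels, typical of reconstructed 3D-SIM sampling.  Axis order is (Z, Y, X),
physical coordinates are in nm, and a voxel's position is its centre.
Because the 40 nm tube is far below the 125 nm axial pitch, each voxel value
is the tube profile averaged over a sub-voxel grid (step ≤ max(10 nm,
tube_sigma/2)); rendering at voxel centres alone would alias the annulus
into a strong, phase-dependent intensity modulation that no later blur can
remove — real optics blur *before* the detector samples.

**Optics and noise.**  The PSF proxy is an anisotropic Gaussian blur,
default σ_xy = 50 nm / σ_z = 150 nm (≈ 120 nm lateral FWHM, axial ≈ 2.5–3×
worse — SIM-like).  Structured-illumination reconstruction artifacts are
not modelled.  Noise is Poisson photon noise (`photon_scale`, default 1.0
count per intensity unit at the default structure amplitude of 1000, i.e.
peak wall signals of a few tens of counts) plus Gaussian read noise
(default σ = 2) and a constant offset (default 5) — a bright, well-stained
acquisition with visible shot noise.

**Two channels.**  A mixing fraction places that share of channel-2
structures at channel-1 positions with isotropic Gaussian jitter (default
SD 20 nm, well below resolution — two protein labels are never perfectly
coincident); the remainder are placed independently.  Ground-truth
per-structure labels are returned for estimator validation.

What the simulation does *not* emulate: beaded/punctate labelling along the
loop, reconstruction artifacts and structured background, chromatic offsets,
and polymer dynamics.  Passing tests therefore demonstrate correctness of
the estimators under the stated model, not performance on every property of
real data.

## Colocalization

PCC, M1/M2 and MOC follow their standard definitions over the masked
voxels; M1/M2 are the plain split coefficients (the numerator's own channel
is not thresholded; co-occurrence is defined by the partner channel's
threshold).  MOC is the classical overlap coefficient R — a distinct
quantity from M1/M2; both are always reported.  By default M1/M2 are
evaluated at the per-ROI Costes thresholds, with an explicit-threshold
override.

**Costes thresholds.**  The regression line is orthogonal (total least
squares), per the original method.  The scan descends from the channel-1
maximum in steps of one quantization level for integer data and 1/1000 of
the range for floats; it stops at the first pair where the PCC of the
voxels below both thresholds is ≤ 0.  Perfectly correlated inputs never
meet the stop rule; the scan then terminates at the intensity floor and the
result is flagged degenerate rather than raising.  A non-positive
regression slope (anti-correlated channels) is an error.

**Significance.**  Channel 2 is scrambled by permuting complete blocks
(edge `block_nm`, converted per axis to whole voxels) among their positions
inside the mask; partial blocks are frozen.  One-sided
p = (1 + #{r_null ≥ r_obs})/(n_perm + 1).  The default block edge is
240 nm ≈ 2× the lateral FWHM, following the original guidance.  Note a
practical caveat measured during development: block permutation severs
correlations across block faces that the observed statistic retains, so
when the block edge is only a few times the field's correlation length the
test is mildly anticonservative (empirical size up to ~0.1 at nominal 0.05
on smoothed nulls with 5-voxel blocks).  With blocks large relative to the
correlation length the test is exact (size 0.046–0.048 in the suite).  For
sharp inference, choose blocks generously.

**ROI battery.**  One result row per region (cell, nucleus, nucleolus,
extranucleolar = nucleus ∖ nucleolus); a failing region yields a NaN row
with the reason recorded, never an aborted run.  The nucleolar-enrichment
claim is assessed by notched-box-plot non-overlap rather than a formal
test (see Reporting).

## Ring geometry

**Detection.**  Otsu threshold over the intensities inside the nucleolus
mask, 26-connected components, minimum size 27 voxels, sorted brightest
first.  Components larger than 2.5× the median voxel count (with ≥ 5 foci)
are rejected as volume outliers — in practice two structures merged by
blur.

**Plane fit.**  The ring normal is the smallest-eigenvalue direction of the
intensity-weighted covariance of voxel positions.  Moments are taken over a
background-subtracted local window (not the thresholded member voxels,
whose coarse axial quantization corrupts the covariance), softly windowed
by an isotropic Gaussian (σ = 320 nm) to suppress neighbours without
rotating the eigenvectors.  Two exact corrections are subtracted from the
moment matrix: the voxel-integration quadrature covariance diag(v²/12) and,
when the PSF is supplied, the blur covariance diag(σ_z², σ_xy², σ_xy²) —
convolution adds exactly this to the covariance of the full intensity
distribution, which is what makes the fit orientation-blind under
anisotropic blur.  Quality control rejects near-spherical blobs
(λ_small/λ_mid > 0.8).  Blur-free accuracy is ~0.02–3° (limited by the
125 nm axial sampling); under the default anisotropic blur the normal is
then polished by a coarse-to-fine grid search (±24°) maximizing the
worst-direction bimodality of the three measurement profiles.

**Planar view and profiles.**  A cube around the intensity-weighted
centroid is resampled trilinearly onto an isotropic grid at the lateral
pitch; the 2D view is the mean projection over a slab of ±2 pixels about
the fitted plane (the mean preserves wall contrast under the wide axial
PSF while averaging noise; a max projection is available).  Profiles run
through the view centre at 0°, 60° and 120°, anchored at the in-plane
intensity major axis so repeated runs measure identical angles; samples are
one pixel apart.

**Peak pairs.**  Profiles are smoothed (Gaussian, σ = 1 sample).  Without
PSF information, peaks are the per-side maxima (height ≥ 20% of the range
above the minimum, a 5% topographic-prominence floor against noise
wiggles), snapped to the raw profile and refined by 3-point parabolas; ties
break toward the outer edge, which cancels in the pair distance.  With PSF
information the ring signature is first established on the azimuthally
averaged radial profile of the view — averaging around the annulus
suppresses noise several-fold, so the shallow central dip that separates a
ring from a blob is detected reliably — and each line profile's walls are
then localized inside a window around the azimuthal wall radius by the
centroid of the top 30% of the smoothed window.

**Blur correction.**  A circle of radius R convolved with an isotropic
Gaussian σ has radial intensity ∝ exp(−(r²+R²)/2σ²)·I₀(rR/σ²), with the
maximum strictly inside R (at the study conditions the peak-to-peak
distance underestimates a 240 nm midline diameter by ~25–30 nm), and no
off-centre maximum at all once R < σ√2.  When the PSF is supplied, the
measured diameter is corrected by forward-model self-calibration: an ideal
ring with the fitted orientation is rendered at the same sub-voxel phase,
pushed through the identical blur/rotation/profile/peak path, and the trial
diameter iterated until the synthetic measurement matches the observed one.
This absorbs every bias the pipeline shares with the forward model (annulus
peak shift, anisotropic cross-terms, slab projection, grid phase,
estimator-specific pulls).  The analytic annulus inversion initializes the
iteration and is the fallback.  Within the measurable cone this yields
per-ring accuracy of a few nm (the suite asserts |mean error| < 5% at
D = 240 under study blur and noise).

**The measurable cone and selection.**  A profile direction with axial mix
u_z has an effective width σ² = tube² + σ_xy² + (σ_z² − σ_xy²)u_z²; one of
the three profiles always lies near the worst direction.  A ring is
therefore only measurable when D ≳ 2√2·σ along its worst profile — about
180 nm for rings lying in the imaging plane, rising steeply with tilt.
Foci whose fitted plane is tilted more than `max_tilt_deg` (default 25°)
from the imaging plane are rejected outright: beyond the cone, acceptance
would select rings by diameter even more strongly.  Consequences, measured
in the suite: (i) under uniform random orientations only ~10% of rings are
measurable; (ii) the accepted sample is diameter-selected — for a
240 ± 60 nm population the accepted-sample mean runs ~40–50 nm high and its
SD is compressed roughly two-fold relative to the generator.  This is a
property of anisotropic-resolution imaging itself, not of the estimator:
per-ring measurements inside the cone are accurate to a few nm.  Any
population summary from such data should be read as a summary of the
*measurable* subpopulation.  Selection-corrected estimators
(truncated-normal likelihoods, inverse-probability weighting by the
analytic acceptance model) were evaluated and rejected: at the ~10
accepted rings a typical field of view yields, they are unstable or leave
the unobservable lower tail unconstrained.

**Population summary.**  Mean ± sample SD over accepted per-ring diameters,
with n_rings and n_profiles = 3 × n_rings; per-profile distances are
exported for box plotting.  Rejected foci are excluded, never imputed.

## Compaction model

Pure arithmetic, kept exact: contour = L_bp × 0.33 nm/nt; circumference =
π·d; compaction = contour/circumference; genes per loop =
(π·d·compaction)/(L_unit × 0.33) evaluated at both ends of an assumed
compaction interval, reported unrounded.  The 15 kb default region length
and the 0.33 nm/nt contour length are configuration values, not buried
constants — the mouse enhancer is several-fold longer than the human one,
so users must be able to vary the region length.

## Reporting

Box statistics follow the R conventions: quartiles by the type-7 linear
interpolation rule (numpy's default percentile; cross-checked in the suite
against a hand-rolled oracle and an Rscript `quantile(type=7)` call),
whiskers at the most extreme observations within 1.5 × IQR of the
quartiles, notch half-width 1.58·IQR/√n.  Two medians are called distinct
iff their notch intervals are disjoint — roughly 95% confidence.  Figures
are regenerable artifacts; all numbers are written to CSV/JSON first.  The
pipeline (`run_pipeline` / `nucleoring run`) executes
simulate → coloc → rings → compaction → report from one YAML-overridable
configuration, halts naming the failing stage, and writes a manifest with
the seed, a configuration hash and library versions; identical seed and
configuration give identical tabular outputs.

## Problem sizes used in the suite

Unit tests run on single-ring canvases of 32 × 192 × 192 voxels.  The
population-recovery experiment uses 100 rings as ten 10-ring scenes of
32 × 320 × 320 voxels (kept uncrowded at the stated minimum spacing); the
type-I-error experiment uses 500 null datasets of 4 × 64 × 64 voxels with
199 permutations each; the ROI-enrichment check uses 50 scenes of
16 × 96 × 96 voxels.

## Known limitations

- Uniform-intensity tube rings are the hardest case for peak detection;
  real beaded labelling shows deeper dips, so the resolution floor quoted
  above is conservative in that respect.
- The Gaussian PSF proxy ignores reconstruction artifacts and the
  non-Gaussian sidelobes of real SIM transfer functions.
- The Costes significance default block (2× lateral FWHM) is mildly
  anticonservative when the image correlation length approaches the block
  size; see above.
- The orientation cap makes the accepted population explicit rather than
  unbiased; diameter summaries from anisotropic data describe the
  measurable subpopulation.
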