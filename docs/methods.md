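# Methods

`lvste` is an in-silico test bench for 2D speckle tracking echocardiography
(STE).  It answers one question: how small can the strain averaging area be
made before the estimation error exceeds a clinically motivated limit — the
*smallest allowable averaging area* (SAAA).  Everything needed for that
question is generated in the package: a left-ventricle (LV) phantom with
exact motion, synthetic sector-scan RF speckle data of it, a hierarchical
block-matching (HBM) strain estimator, and robust error statistics.

## 1. Kinematic LV phantom (`lvste.kinematics`)

**Geometry.**  The wall is the region between two concentric half-spheroids
cut by the base plane; the long axis (LAX) is the z axis.  At end-systole
(ES) the internal semi-axes are 72 x 15.75 mm and the external ones
85.5 x 29.25 mm.  End-diastole (ED) is calibrated to an internal short
diameter of 46 mm and a cavity volume of 94.5 cm^3 (giving an internal long
semi-axis of 85.29 mm); the ES cavity volume is 37.4 cm^3.

**Wall volume.**  A wall deforming between these reference shapes while
conserving its volume would thicken by 33–40 % at the mid level, far above
the target global radial strain of 20.3 %.  The phantom therefore has a
mildly compressible wall (emulating a nearly incompressible hyperelastic
material with Poisson ratio < 0.5): the wall volume varies smoothly with the
contraction phase, with an ED/ES ratio calibrated to 1.2349.  At every phase
the external semi-axes are solved from the interpolated wall volume with an
equal thickness increment on both axes.

**Material motion.**  A material point is labelled by its normalized wall
depth d, its normalized meridional arc fraction m (0 apex, 1 base) and its
azimuth.  At phase s (the temporal profile value) the point sits at the same
depth and at arc fraction m^(1 + 0.0186 s) of the phase-s wall — the small
exponent redistributes part of the longitudinal shortening along the wall
and is one of the three calibrated constants.  Positions are analytic
(incomplete-elliptic arc-length tables with spline inverses), so the
deformation gradient F is available in closed form; a Richardson-extrapolated
finite-difference check agrees to better than 1e-6 relative.

**Torsion.**  A rotation about the LAX, linear in the LAX coordinate and
scaled by the temporal profile, is superposed with peak level values of
13 deg (apical) and −6.9 deg (basal).  The linear torsion law is implemented
literally; its leading sign is exposed as a flag because the sign convention
of the law and of the reported per-level values are mutually inconsistent.

**AVPD correction.**  Because the base plane is kinematically fixed, the
longitudinal displacement profile is shifted every frame so that its
volume-weighted mean over the band 0.15–0.25 LA above the apex vanishes.
The resulting atrioventricular plane displacement is −8.6 mm at ES, inside
the physiological range; the band position is configurable.

**Temporal profile.**  65 frames at 65 fps; raised-cosine rise to 1 at
369 ms (the frame closest to the nominal 370 ms peak), plateau to 0.55 s,
raised-cosine fall to zero at 0.95 s.  Frame 1 (ED) is the strain reference
configuration, so all strain curves start at zero and the cycle closes.

**Calibration.**  Three constants — the ED/ES wall-volume ratio, the
meridional redistribution exponent and the endo/epi weight of the GLS
readout (0.504) — were fitted once, by one-dimensional root finding, so that
the exact field reproduces the target global strains GLS = −13.6 %,
GCS = −26.5 % (endocardial, at the mid short-axis level) and GRS = +20.3 %
(transmural thickening at the same level), all Lagrangian.  They ship as
frozen defaults and are not adjusted anywhere else.

## 2. Synthetic sector-scan RF data (`lvste.views`, `lvste.simulator`)

Nine acquisition configurations are reproduced from the study design: a full
and three partial mid parasternal short-axis (pSAXM) views and a full plus
four partial apical two-chamber (A2C) views, each with its tabulated depth
range, tilt, width, line count and 65 fps.  The A2C plane contains the LAX
(probe beyond the apex); the pSAXM plane is perpendicular to the LAX 5.2 cm
above the ED apex, viewed from wall azimuth 27 deg — the unique placement for
which all three partial short-axis tilts centre their target segments.

The renderer is a separable point-spread-function convolution: each
scatterer contributes a Gaussian-modulated cosine along the beam
(3.5 MHz centre frequency, 60 % fractional bandwidth, c = 1540 m/s,
25 MHz RF sampling), a Gaussian lateral apodization in beam angle (FWHM =
1.2 x line spacing) and a Gaussian elevation weight over a 3 mm slab
(2.5-D imaging).  No diffraction, attenuation or reverberation is modelled.
Scatterers have i.i.d. normal reflectivities and are seeded uniformly in the
ED wall at 10 per resolution cell, in a slab widened by the maximal
out-of-plane material excursion (up to ~11 mm for pSAXM) so the imaging
plane stays populated while the wall slides through it; they are advected
with the exact material motion.

At 10 scatterers per cell the envelope statistics are slightly
sub-Rayleigh (SNR ~1.73 instead of 1.91, the usual finite-number
K-distribution effect); dense clouds converge to the Rayleigh limit
(1.87 at 40 per cell, 1.92 at 250), which is what the speckle-statistics
test checks.  Wall masks are evaluated from the exact deformed geometry,
never from the images.

**Desk scale.**  `scale = f` reduces the line count, the RF sampling rate
and the centre frequency by the same factor, widening the PSF accordingly.
All shipped tests run at scale 0.25; full scale is a documented
long-running mode.

## 3. Displacement estimation (`lvste.tracking`)

RF lines are linearly interpolated 4x axially.  Three NCC block-matching
iterations run on the polar grid (inputs: envelope, envelope, RF), kernels
overlapping 2/3 in both axes, search windows recentred by the previous
iteration's field (block-level warping, no image resampling).  The
first-iteration kernel/search sizes are 15x/18x the maximal interframe
displacement of the reference motion for that view, shrink 4x per
iteration, and obey the floors (3 wavelengths / 3 lines; search at least
kernel + 4 samples / + 4 lines; integer rounding).  Subpixel lags come from
cubic B-spline interpolation of the NCC map at 16x/32x/64x; a perfect match
(NCC = 1) is never "refined", since spline overshoot around it is an
interpolation artifact.  NCC integer peaks are verified against an
exhaustive-search oracle in the tests.

Forward and backward estimates of each frame pair are fused by
correlation-weighted averaging; nodes failing both directions are left to
the regularization.  Vectors are rotated to Cartesian axes, scattered-
interpolated onto a 0.2 mm grid and regularized with a tensor-product cubic
smoothing spline (`p` fidelity vs `1 - p` roughness).  The coefficient pair
p = 1 − 10^-6.5 (estimates) and p = 1 − 10^-9 (reference) only produces
meaningful smoothing when the spline sites are expressed in meters — the
reference value then smooths at the ~2 mm scale of the mesh artifacts it is
said to remove and the estimate value at centimeter scale — so sites are in
meters throughout.  A consequence worth knowing: even noise-free increments
passed through the estimate coefficient lose part of the transmural radial
strain gradient (a bias of about −0.07 at ES), while longitudinal strain is
essentially untouched (< 0.005).  That asymmetry is the mechanism behind
the large radial errors in the results tables.

## 4. Strain (`lvste.strain`)

Incremental fields are extended ~2 mm beyond the wall with a first-order
smooth extension (nearest border value plus a box-smoothed in-wall
gradient; it continues linear fields exactly), then accumulated: a forward
pass tracks every frame-1 wall grid node through the incremental fields,
a backward pass integrates the inverted increments from the last frame and
is re-anchored to frame 1, and the two displacement curves are averaged
with weights given by the running product of the per-step matching quality
along each trajectory (a plain 50/50 strategy is also available; the exact
weighting used elsewhere is delegated to references without formulas, so this is
a package choice).  The Lagrangian finite strain
E = (grad u + grad u^T + grad u^T grad u)/2 is evaluated from analytic
derivatives of interpolating bicubic splines and projected on anatomical
directions: radial/circumferential from the LAX piercing point (pSAXM) and
longitudinal from wall-border tangents blended across the wall (A2C),
evaluated in the reference configuration.  Reference strain maps feed the
identical chain with exact increments sampled at the tracking nodes and the
reference regularization coefficient.

## 5. Segments, errors, SAAA (`lvste.aha`, `lvste.errors`)

AHA17 labels follow the standard scheme on the half-spheroid: apical cap =
innermost 15 % of the meridional arc (configurable), the rest split into
equal apical/mid/basal thirds with 4/6/6 azimuthal sectors anchored so the
A2C plane shows segments 1, 4, 7, 10, 13, 15, 17.  Labels are material
(frame-1 nodes advected); per-frame subsegment areas use the in-plane
Jacobian of the exact motion.  The ten standard division schemes split
non-apical segments into N_LC equal slices along the in-wall coordinate
times N_R equal depth layers; segment 17 is cut into N_R radial layers and
every layer into subsegments of equal area matched to the outermost layer.
The mean subsegment surface (MSS) averages over subsegments and all 65
frames (the cycle mean, not ED only, reproduces the ~280 mm^2 mean
segment area).

Per subsegment and speckle realization, the estimate and reference curves
give the end-systolic error E_ES, the relative error NE_ES (subsegments
with |reference| < 1e-3 at ES are excluded and counted) and the curve
cross-correlation XCC.  Cells are summarized by median and (unscaled)
median absolute deviation, and the predicted maximal error is
MaxErr = max(|MED − 3 MAD|, |MED + 3 MAD|) = |MED| + 3 MAD, which under the
normal model (SD = 1.4826 MAD) bounds about 95 % of errors.  The SAAA for a
limit (16.7 / 33 / 66 %) is the smallest MSS still meeting the limit before
the first exceedance when scanning coarse to fine; "<" and ">" sentinels
mark the all-pass and all-fail cases.

## 6. Numerical choices and limitations

* NCC ties resolve to the first (scan-order) peak; in practice ties occur
  only on degenerate inputs.
* Trajectories leaving the extension band invalidate their node; invalid
  matching nodes are filled by interpolation/regularization.
* The A2C standoff (12 mm) and the pSAXM centre depth (80 mm) place the
  phantom inside the tabulated sector depth ranges; both are configuration,
  not physics.
* The generator emulates fully developed speckle, speckle decorrelation
  under deformation and through-plane motion, but not attenuation, clutter,
  reverberation, probe-element directivity or electronic noise.  Passing
  tests therefore demonstrate method behaviour under clean speckle, not
  clinical-grade robustness; absolute error levels at desk scale
  (0.25x resolution and frequency) are larger than full-scale ones, which
  is why the shipped checks assert orderings and trends rather than the
  full-resolution error tables.
* Full error tables at native resolution with ten realizations per view are
  a long-running mode, not part of the shipped checks.  The package reproduces the calibrated
  phantom quantities exactly, the machinery properties to tight tolerances
  and the qualitative error structure (longitudinal < circumferential <
  radial error; errors grow as the averaging area shrinks; partial views
  help) at desk scale.

## 7. Problem sizes used by the shipped tests

Tests run two partial views (segment 7 in pSAXM and A2C) at scale 0.25 with
two speckle realizations and division schemes {1, 3, 5}; the acceptance
script builds both full views at scale 0.25 for the geometry/segment-area
quantity.  These sizes were chosen so the whole suite completes in minutes
on one CPU while leaving every pipeline stage exercised end to end.
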