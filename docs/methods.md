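# Methods

This note documents the models, defaults and numerical choices behind
`pocketscope`, and what the synthetic fixtures do and do not establish.

## Ray tracer (`pocketscope.optics`)

**Model.** Sequential exact tracing: rays are straight lines between
axially aligned surfaces; spherical surfaces refract by vector Snell's law;
a signed curvature radius of 0 encodes a plane; a surface with equal
indices is a pure aperture stop; an ideal thin lens applies the slope kick
u′ = u − h/f at its plane. Rays die by vignetting (hit outside the clear
aperture), total internal reflection, or missing a surface, and the
trace records why. Conventions: +z optical axis, object at negative z,
millimetres, degrees at the API surface.

**Stock prescription.** Ball centre at z = 0; two hemispheric surfaces at
∓0.5 mm (default n = 1.5168, a commodity crown-glass value, configurable);
0.8 mm field aperture just behind the ball; phone camera as an ideal thin
lens of EFL 3.36 mm with clear aperture set by f/2.8; sensor
3.55 × 2.68 mm, 2.2 µm pitch, at the lens's focal plane. The phone lens is
kept first-order because every reported metric is first-order dominated;
the ball, where all the aberration lives, is traced exactly.

**Fans.** All fans are deterministic concentric rings (8k rays on ring k,
plus the axial ray), with rings placed at the solid-angle midpoints of
equal-count annuli so equal-weight rays sample the cone uniformly in area.
This removes the rim bias of naive uniform-angle rings; doubling the ray
count moves the on-axis RMS spot radius of the stock train by < 1%.

**Best focus** minimises on-axis RMS spot radius over object distance
(bounded scalar minimisation, 0.1 µm tolerance). The default fan divergence
is 5°, the illumination divergence the instrument is operated with; the
search reports the distance from the ball centre (0.732 mm for the stock
train) and from the front surface, since "distance in front of the lens" is
ambiguous by half a ball radius.

**Numerical aperture.** Two figures are computed. The *paraxial marginal*
NA (default, 0.479 for the stock train) is the sine of the steepest
first-order ray clearing every aperture — the aperture measure of the
image-forming bundle. The *raw survival* NA (0.683) is the steepest
exactly-traced ray that reaches the sensor at all; for a ball lens at this
aperture, strongly spherically-aberrated peripheral rays still thread the
stop while contributing nothing but halo, so the survival figure
overstates the useful aperture and is reported only for transparency.

**Depth of field.** The literal "RMS spot ≤ one pixel" criterion is empty
for this train: spherical aberration puts a ~30 µm RMS floor under the
NA-limited fan even at best focus. The implemented criterion is therefore
*added* blur: the axial range where √(rms² − rms²_min) ≤ one pixel pitch,
which reduces exactly to the plain criterion when the floor is negligible
(verified on an ideal thin lens) and gives 2.0 µm for the stock train,
consistent with the diffraction estimate λ/NA² = 2.4 µm at 550 nm.

## Multifocus fusion and distortion (`pocketscope.restore`)

**Focus measure.** Sum-modified Laplacian with step 1 and a 3×3 window by
default, reflective borders. It is zero on constant images and decreases
monotonically under Gaussian blur of any textured scene.

**Fusion rule.** Frames are decomposed by a pluggable multiscale transform
— separable wavelet (`db2`, 3 levels) by default, with a Laplacian pyramid
alternative. For every subband the per-coefficient winner is the frame
with the largest local SML of that subband; ties go to the lowest frame
index; a single-pass 3×3 majority vote smooths each decision map before
selection. The inverse transform is clipped to the input min/max envelope.
Colour frames fuse on luminance with chrominance copied per pixel from the
winning frame. Frames are assumed co-registered.

**Usable field of view.** The image is tiled into 16 px blocks; a block is
"usable" when its mean SML reaches a threshold fraction (default 50%) of
the peak block; the statistic is the largest centred square of usable
blocks. The measure is meaningful only on scenes whose sharp-state SML is
spatially stationary — see the fixtures section.

**Radial distortion.** r_d = r(1 + k₁ρ² + k₂ρ⁴) about a fitted centre,
with ρ normalised by a reference radius so k₁, k₂ are scale-free. Fitting
is two-stage: k₁, k₂ first by linear least squares at the centroid, then a
bounded trust-region refinement of centre + coefficients (the centre is
confined to the field because a runaway centre is a degenerate local
minimum of the radial model). Undistortion resamples bilinearly through
the forward map; the inverse map for synthesis uses 20 fixed-point
iterations on the radius (≤ 0.05 px round-trip error over the field).

## Spectrometer (`pocketscope.spectro`)

Geometry defaults are the stock build: 1000 lp/mm transmission grating,
77.5 mm tube, 1 mm slits at both ends, first order. Incidence is taken
normal to the grating along the tube axis; the tube's 45° end cut is
treated as mechanical. The two-slit acceptance is the convolution of two
rects — triangular for equal slits — with FWHM max(w₁,w₂)/L, and
Δλ = d cos θₘ · Δθ. Calibration fits an ascending pixel→nm polynomial
(degree 1 or 2) and rejects non-monotonic fits over the valid range; FWHM
measurement interpolates the half-maximum crossings linearly above a local
two-valley background. Transmission ratios mask (rather than divide by)
reference values under 2% of peak; phone cameras autoscale, so all
intensities are relative.

## Cell counting (`pocketscope.counting`)

Background is estimated by grey closing with a disk much larger than a
cell (on a 4× downsampled copy — the background is smooth by assumption)
or by a quadratic surface fit, and divided out mean-preservingly.
Segmentation: Otsu threshold (cells dark by default), hole filling (red
cells have central pallor, and a ring-shaped mask would oversplit), distance
transform smoothed with σ = 1 px, markers from h-maxima at 10% of the
distance maximum, watershed on the negated distance. Counting filters
labels to 20–150 µm² at the object plane (an RBC projects ≈ 50 µm²;
platelets fall well below 20), with defaults configurable and rejects
tallied by reason. Morphometrics (area, eccentricity, mean intensity) are
emitted per cell; classification into cell types is out of scope.

## Synthetic fixtures (`pocketscope.synth`)

All generators are pure functions of (spec, seed); reruns are
bit-identical, and truth tables suffice to score every downstream module.

**Smear protocol** (defaults): 115 cells on a 512² field at 0.5 µm/px,
radius 3.9 ± 0.3 µm with central pallor, 10% of cells in touching pairs
(centres 1.7 r apart), 15 platelet-scale dots (r = 1 µm), a 15% linear
illumination ramp at a seeded angle, Poisson shot noise (800 photons at
full scale) plus Gaussian read noise, 8-bit quantisation last — matching
the 8-bit dynamic range of phone sensors. These values were chosen once as
a realistic wedge-smear monolayer; the radius/noise/clump settings follow
standard human-blood morphology rather than any tuned optimum.

**Field-curvature stacks**: defocus Δz(r) = r²/2R with R defaulting to the
ball-lens focal length (0.734 mm), converted to blur by σ = NA·Δz/pixel
with NA = 0.48 from the traced instrument; blur is applied by interpolating
between uniformly blurred copies at quantised σ levels; an optional radial
warp adds the pincushion. The standard scene is a crossed sinusoidal
grating (period 8 px, seeded orientation and phases): its local contrast is
stationary by construction, so block-SML statistics measure the applied
defocus rather than scene luck. A random-blob texture makes the 50%-of-peak
block threshold a lottery (the peak of ~1000 noisy blocks sits far above
the mean) and is deliberately not used for field-of-view scoring.

**Spectral frames**: lines carry the exact triangular slit profile at
their mapped pixel (plus optional intrinsic Gaussian width), continuum is
Planck times the mapping Jacobian, noise is Gaussian, and the default lamp
lines are the fluorescent triplet 436/546/611 nm.

**What passing these fixtures does not show**: real smears have stain
variability, white cells, rouleaux and debris that the disk model omits;
real phone frames have Bayer demosaicing, JPEG artefacts and uncontrolled
autoscaling; real gratings are not at exactly normal incidence. The
fixtures validate the algorithms under the stated degradations, not the
full acquisition chain.

## Known limitations

- Single-wavelength tracing; no chromatic aberration or wave optics.
- The phone lens is ideal; its real aspheric surfaces would mostly affect
  metrics beyond first order.
- Fusion assumes registered frames; translation alignment is available as
  a pre-step but full mosaicking is out of scope.
- The spectrometer bandwidth depends on an unspecified sensor–grating
  standoff and is not predicted.
- Problem sizes used in tests and the acceptance run (512² scenes, 200-ray
  fans, 10–20 seeds) were chosen as the smallest giving stable statistics.
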