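# Methods

## Scope and model

`panoct` implements the quantitative core of a contact, pivot-scanned
wide-field ("panretinal") OCT system: scan geometry on an idealized
spherical globe, closed-form protocol calculators, optical biometry
(axial length from optical path length), phantom-based field-of-view
calibration, and curvature-aware lesion morphometry.  Because raw
clinical volumes for such systems are not publicly available, every
pipeline is exercised on synthetic fan-beam volumes from the bundled
generator, which is first-class, tested code.

### Spherical-eye scan geometry

The eye is an ideal sphere of radius `r` centred at `C`; the scanning
pivot `P` sits a distance `a` anterior of `C` on the visual axis
(`0 <= a <= r`).  A ray leaving `P` at half-angle `alpha` from the
posterior direction travels a chord

    L(alpha) = a cos(alpha) + sqrt(r^2 - a^2 sin^2(alpha))

before meeting the retina.  Everything else follows from this one
function: the centre-referenced field half-angle
`beta_half = arccos((L cos(alpha) - a)/r)`, the required imaging depth
`max (L(0) - L(alpha))` converting to optical units with the mean
tissue index, the B-scan depth profile the retina traces, and the iris
vignetting limit `arctan(pupil_radius / |a - h|)` for an iris plane a
height `h` anterior of `C`.  Two FOV conventions are kept explicit:
"FOV" unqualified is the full pivot angle `2*alpha_max` (the convention
of a contact scanner pivoting on the iris plane); the centre-referenced
angle is always called `beta`.  With the pivot on the sphere (`a = r`)
the inscribed-angle theorem gives `beta_half = 2*alpha` exactly, which
is why a 140° pivot-angle scan reaches ~111° (and at the grid diagonal
more) of centre-referenced field on the newborn globe, out to the ora
serrata.

Refraction at the cornea and lens is deliberately ignored: the pivot is
the post-optics pivot inside the eye.  This is the model's main
simplification and is shared by the analyses built on it; it makes all
geometry exactly invertible, which the tests exploit (an independent
vector ray-tracer must agree to 1e-9).

The spec's type invariant for the pivot offset is `a < r`, but the
pivot-on-sphere limit `a = r` is exactly the case the inscribed-angle
property and the phantom calibration need, so validation admits
`a <= r`.

### Protocol calculators

Pure closed forms with the standard SS-OCT conventions: volume time
`n_ascans * n_bscans / rate`; Gaussian-spectrum FWHM axial resolution
`(2 ln 2 / pi) lambda0^2 / (n dlambda)` (for 1060 nm / 70 nm this gives
7.08 um in air, 0.3% above the instrument's quoted 7.06 um — the quoted
constant or wavelength is not recoverable, so the gap is documented,
not corrected); sampling-limited depth `lambda0^2 N / (4 sweep_range)`
(the ~96 nm full sweep range reproducing "6 mm at 2048 samples" is the
inversion of this formula — the 6 dB bandwidth is not the sweep range);
Gaussian 1/e^2 focal spot `4 (lambda0/n) f / (pi D)`.  The duty cycle
and digitizer rate are carried as metadata and only validated for
consistency (`samples/sampling_rate <= duty_cycle/ascan_rate`).

### Synthetic fan-beam volumes

The generator emulates the features the downstream analyses rely on:

* **Layered retina on a sphere.**  Each layer is a sphere concentric
  with the globe at an optical depth offset below the inner surface
  (default stack: ILM 0 um / reflectivity 0.4, mid-retina ~101 um /
  0.25, RPE ~202 um / 1.0, the offsets taken from the schematic eye's
  retinal segment).  The RPE is brightest, matching its appearance in
  clinical B-scans and making it the natural anchor for both biometry
  and sphere fitting.
* **Fan-beam sampling.**  Uniform in pivot angle on both axes
  (galvanometer scanning is angle-linear); the two axes compose as
  orthogonal rotations, `cos(alpha_eff) = cos(af) cos(as)`.  The square
  angle grid overscans its corners beyond `alpha_max`; analyses that
  promise per-pixel bounds state them inside the designed FOV cone.
* **Depth axis is optical path.**  A scatterer at chord distance `t`
  appears at `z = n t - O0`, with `O0` fixed by the recorded
  reference-arm stage position: `z = OPL_from_apex + datum_offset -
  opl_factor * stage`.  The constant `O0` is written into the volume
  metadata and is what makes scan conversion and the two-arm biometry
  bookkeeping exact.
* **Lesions.**  Ellipsoidal caps, positioned by central angle and
  azimuth, with geodesic length/width defined on the RPE sphere (the
  surface morphometry measures on) and height along the local normal,
  elevating the whole layer stack inward.  Rendering is a single pass:
  the elevation is looked up where the ray meets the undeformed layer
  sphere and applied along the ray with exact radial magnitude.  True
  first-hit tracing was tried and rejected: the cap's sqrt-shaped rim
  has unbounded slope, so at oblique incidence the apex occludes the
  far flank — a shadow-type artifact that is explicitly outside the
  generator's scope and that truncates footprints by ~10% at 70°
  central angle.  The single-pass form keeps the footprint boundary
  exact at every angle while advecting interior samples slightly toward
  the pivot; the morphometry side accounts for this exactly (below).
* **Noise.**  Fully developed speckle as multiplicative unit-mean
  exponential noise (the simplest faithful OCT statistic; the tests
  verify mean preservation at 1e5 pixels), an exponential incoherent
  noise floor, and depth-dependent sensitivity roll-off
  `10^(-rolloff_db_per_mm * z / 10)`.  No published roll-off figure
  exists for the modelled class of instrument, so it is a free scene
  parameter (default 0.5 dB/mm, a mild value typical of MEMS-VCSEL
  sources).  Default scenes are "realistic clinical": speckle on,
  -30 dB floor; geometry-level studies switch both off explicitly.
* **Determinism.**  Seeds are mandatory explicit fields; identical
  (scene, protocol, seed) give byte-identical volumes, which the
  acceptance checks assert at the file level.

What the generator does *not* emulate — motion artifacts, eyelash
shadows and vignetting shadows, dispersion, k-space/interferogram
physics, per-wavelength refraction — bounds what green tests mean:
they validate the geometry, the estimator algebra and the noise
robustness of the detectors, not performance on real infant data.

### Optical biometry

The axial length is assembled from two volumes acquired with the
reference arm parked at the corneal (P1) and retinal (P2) stage
positions:

    OPL = opl_factor (P2 - P1) + (fovea_depth - apex_depth),
    AL  = OPL / n_avg,   n_avg = sum(n_i d_i) / sum(d_i).

For the newborn Gullstrand segment stack (0.75/1.377, 1.85/1.336,
3.7/1.43, 11.0/1.334, 0.15/1.346) `n_avg = 1.357` at 3 d.p. over a
17.45 mm length measured to the RPE; full precision is used internally
and a `rounded_n_avg` flag reproduces 3-d.p. arithmetic.  An
ILM-referenced mode drops the retinal segment from both ends of the
conversion for comparison against ultrasound-convention lengths.  The
stage-to-OPL factor defaults to 1.0 (encoder calibrated in OPL units)
and is configurable (2.0 for double-pass stages); any fixed contact
lens contribution enters as an additive constant defaulting to 0 since
it cancels between the two arms.

Surface detection: the corneal apex is the minimum over the central
B-scan of per-A-scan thresholded peak depths (noise floor + 6 dB,
axial smoothing over 3 samples, sub-pixel centroid over 5, median over
5 A-scans).  A-scans whose peak falls below 0.35x the cohort's median
peak are dropped as speckle fades — without this, the minimum operator
latches onto noise spikes.  The foveal RPE is found by *flattening*
the profiles of a 5x5 angular neighbourhood to the designated ray
using the geometric B-scan depth profile, averaging them (trading
lateral resolution for speckle diversity, as is standard for layer
finding), and taking the centroid-refined brightest peak.  A plain
median of per-A-scan argmax depths was tried first and rejected: with
~2 speckle looks per A-scan, the argmax confuses the RPE with inner
layers often enough to break the half-pixel bias bound, and the
un-flattened median inherits a curvature bias from the retinal dome.

In the synthetic harness the foveal A-scan is known from scene
metadata; for external volumes the central A-scan is used unless an
angle is supplied.  On noiseless volumes the end-to-end recovery error
is ~1-3 um across 16-24 mm eyes, within the one-depth-pixel geometric
equivalent (pitch / n_avg ~ 3.7 um at 5 um pitch) that the acceptance
suite enforces; under 20 dB speckle the apex stays within 2 pixels and
the seed-averaged RPE bias below half a pixel (50-seed Monte Carlo).

### Morphometry

The loop is segment -> scan-convert -> robust sphere fit -> elevation
-> detect -> measure.

* **Segmentation**: per-A-scan brightest-layer depth (so the map
  follows the RPE), thresholded, centroid-refined, 5x5 median
  filtered.  The median window implies two resolution limits stated
  here rather than hidden: footprints closer than ~the window support
  merge, and footprints smaller than it are suppressed.  More than 50%
  invalid A-scans raise a segmentation error.
* **Scan conversion**: `point = P + t D(af, as)`, `t = (z + O0)/n`;
  exactly invertible (round-trip asserted to 1e-6 mm).
* **Sphere fit**: algebraic (linearized) least squares refined by
  geometric least squares, with two robust passes that exclude
  residuals beyond 3x MAD (floored at 1 um) — on lesioned noiseless
  scenes the baseline residuals are near zero, so the MAD floor lets
  the elevated ~10-20% of points be excluded cleanly and the generator
  radius is recovered to < 1e-3 mm.
* **Elevation**: `radius - |point - center|`, positive toward the
  pivot — tumours elevate inward, so lesion heights are positive.
* **Detection**: elevation threshold (default 0.15 mm), 8-connected
  labelling on the angular grid, on-sphere component area (sum of
  spherical cell areas) with a minimum-area filter (default 1 mm^2).
* **Measurement**: footprint pixels are mapped into geodesic (log-map)
  tangent coordinates at the footprint's area-weighted centroid on the
  fitted sphere.  Length and width are the moment-equivalent extents
  `4 sqrt(eigenvalue)` of the area-weighted second-moment ellipse —
  exact for a uniformly filled elliptical footprint and far less
  sensitive to cell discretization than min/max projections.  The cell
  areas are *signed* (normal component of the grid-step cross
  product): where the generator's along-ray advection folds the
  sampling near a lesion's posterior rim, the signed weights cancel the
  double-covered band, so the weighted moments equal integrals over
  the footprint region itself (the advection map is the identity on
  the rim, hence degree one).  Heights are the maximum elevation in
  the footprint.  Extents are great-circle arcs by default ("fitted
  according to the retinal curvature"); a chord mode is provided for
  comparison since published tumour tables rarely state which
  convention they use.

Recovered accuracy on noiseless 256x256x768 volumes (18 um pitch):
length/width within ~2.5% and heights within ~10 um for caps centred
anywhere from the pole to 100° central angle, including a
6.37 x 3.05 x 1.41 mm cap.  The acceptance suite enforces 5% and one
depth pixel.  A 9 mm-long cap cannot be *centred* at 100°: its
footprint would extend beyond the ~111° maximum reachable central
angle of a 140° scan, so the far-periphery case is covered by a
smaller cap.

### Phantom FOV calibration

A spherical phantom (default radius 12 mm) carries rings extruded at
central-angle intervals (default 40°, i.e. ring k at half-angle 20k°);
with the pivot on the phantom surface the inscribed-angle halving puts
ring k at pivot angle 10k°, so seven rings exactly tile a 140° FOV.
`phantom_ring_angles` produces the ring table (and reports rings
beyond reach); the generator extrudes and brightens the rings so the
en-face projection shows them at the predicted pivot-angle radii, and
`calibrate-fov` writes the table as CSV.

### Autofocus

`autofocus_hill_climb` is the classic loop used during alignment:
step in the improving direction of a scalar en-face brightness metric,
reverse and halve the step on a decrease, stop below a step tolerance.
For a unimodal metric it lands within the final step of the argmax;
the tests check it against exhaustive search on a synthetic defocus
stack (Gaussian blur + sharpness metric).

## Numerical choices

* Angles are degrees at every interface, radians internally; the
  `beta -> alpha` inverse uses bracketed root finding to < 1e-9 deg.
* Axial rendering splats each interface linearly over two depth pixels;
  sub-pixel centroid detection then recovers the exact position on
  noiseless data, which is what makes one-depth-pixel end-to-end
  bounds attainable.
* Volumes are float32; all geometry is float64.
* Degenerate inputs are errors, not warnings: empty segment stacks,
  non-positive OPL/GL, coplanar point clouds, out-of-range angles,
  unreachable central angles (the error names the reachable maximum).
  The one deliberate warning is depth-window aliasing in the
  generator, recorded in the volume metadata (`meta["warnings"]`), as
  a clipped scan is still useful for partial analyses.

## Problem sizes

Defaults were chosen so the whole suite exercises full pipelines at
desk scale: biometry volumes 33 x 7 x 512 at 5 um pitch, morphometry
volumes 256 x 256 x 768 at 18 um pitch (the depth window must hold the
~8.4 mm optical span of a 140° fan on the newborn globe plus the
tallest lesion), Monte-Carlo loops 50 seeds.  These sizes reproduce
every stated bound with comfortable margin; larger grids only shrink
discretization terms.

## Known limitations

* No refraction: pivot angles are post-optics angles inside the eye;
  mapping to scanner drive angles would need the probe's optical
  design.
* The ideal-sphere globe ignores corneal asphericity and staphylomas;
  the sphere fit will average over real local curvature variations.
* Speckle is spatially white; real OCT speckle has a correlation
  length set by the PSF, so Monte-Carlo bounds here are optimistic by
  roughly the square root of the speckle-cell pixel count.
* The fovea is located by scene metadata or the scan centre, not by
  anatomical pit detection.
* Lesion profiles are smooth ellipsoidal caps; irregular or
  mushroom-shaped tumours violate the single-valued elevation model.
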