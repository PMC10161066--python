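# Methods

`mrlqc` implements a daily, semi-automated end-to-end (E2E) quality-control
suite for MR-linac adaptive radiotherapy of the adapt-to-position (ATP) kind:
a rigid phantom carrying seven fiducials (visible as bright dense markers on
MV portal images and as signal voids on MR) is imaged, registered, and
irradiated through the standard adaptive workflow, and the package quantifies
four subcomponents from the resulting images and plan files — image
registration accuracy, couch position consistency, adapted-field delivery
accuracy, and MR-to-MV isocenter alignment.

## Coordinates and projection model

All 3D quantities are in the IEC 61217 machine frame (head-first supine:
x left→right, y inferior→superior, z posterior→anterior, mm). Gantry angle
φ = 0° means the beam enters from anterior and rotates toward +x at 90°.

A fiducial is parameterized by cylindrical coordinates about the gantry
rotation axis, (θ, r, y), with the convention θ = φ meaning "displaced toward
the source", i.e. x = r·sin θ, z = r·cos θ. With source–axis distance SAD, its
projection onto the MV panel, expressed in mm at the isocenter plane relative
to the (vendor-calibrated, gantry-angle-dependent) isocenter pixel, is

    u(φ) = SAD · r · sin(θ − φ) / (SAD − r · cos(θ − φ))
    v(φ) = SAD · y              / (SAD − r · cos(θ − φ))

Panel u increases toward IEC +x at gantry 0 and v toward IEC +y; these signs
are a package convention (enforced by round-trip tests) since only θ − φ is
constrained by the model. Pixel offsets convert to mm at the isocenter plane
by the panel pixel pitch PR = 0.2163 mm/px. SAD is a required configuration
field with no default; it is a machine calibration value (operators may use
the vendor's published value — the bundled simulator uses 1435 mm).

**Triangulation.** (θ, r, y) is fitted jointly to the observed (u, v) tracks
over ≥ 2 gantry angles by bounded nonlinear least squares on the panel
residuals in mm, initialized from a coarse grid over θ (10° steps) with
per-candidate linear estimates of r and y; the lowest-cost candidate seeds the
refinement. The θ periodicity creates local minima, hence the grid. r < 1e-6
mm is reported as r = 0 with θ flagged undefined. A joint fit of u and v was
chosen over a sequential one (θ, r from u then y from v); with ≥ 3 angles the
RMS panel residual is reported as a quality measure.

## MV image analysis

*Field isolation.* Threshold at a configurable fraction (default 0.5) of the
image maximum, keep the largest connected component. No super-threshold
region means "no beam" — an upstream delivery or data-transfer error.

*Fiducial localization.* Gaussian smoothing (σ = 2 px), subtraction of the
in-field row and column background profiles, Sobel edge enhancement, then a
two-stage normalized cross-correlation (NCC) search against a rendered
disk-edge template: coarse at native resolution within a ±5 mm window around
the expected position, then NCC of the ×10 linearly up-sampled neighbourhood
against a ×10 template, with a final parabolic refinement of the correlation
peak. The background statistic defaults to the **median**: a plain mean is
measurably contaminated by the fiducial blobs themselves, which leaves faint
streaks through other fiducials on the same rows/columns and biases their
sub-pixel positions by ~0.1 px; the mean remains available in configuration.
Candidate peaks are restricted to the search window proper; a comparable
secondary peak within the exclusion radius (default 4 mm) raises an ambiguity
failure rather than a silent mis-detection.

*Template.* A disk of the configured fiducial diameter rendered through the
same transmission model the simulator uses (exponential chord attenuation),
smoothed and Sobel-filtered identically to the search image. The template
footprint is kept tight (edge ring + smoothing tail) so a neighbouring
fiducial's ring cannot enter its support.

*Jaw/MLC edge detection.* The coarse field center comes from the threshold
mask's bounding box (the "corner detection" step is implemented as bounding
box corners → midpoint). MLC leaves are stacked along u with a projected
pitch of 7.15 mm and travel along v; leaf 0 is the leaf whose projected
center is nearest the isocenter pixel. For each measurable leaf, 11 adjacent
pixel columns spanning a 2.38 mm strip (11 × PR) centered on the projected
leaf center are analysed; each profile is Gaussian-smoothed (σ = 3 px),
differentiated, spline-up-sampled ×20 and the edge taken at the maximum
gradient signed toward the field interior; the 11 per-profile edges are
averaged. Jaw edges use the same procedure on 11 rows through the field
center, profiles running along u. The edge search spans the full profile half
on each side of the field center rather than a window around the planned
edge, so arbitrarily large delivery errors remain detectable; the planned
aperture supplies only the leaf indexing. Two gradient peaks within 20% of
each other flag the edge as ambiguous and the peak nearer the planned edge
wins. Leaves whose profile strip is jaw-shadowed produce no measurable edge:
they are excluded from the *expected* measurement (silently, since this is
the normal geometry of a rectangular field whose u edges are jaw-defined);
a leaf that was expected to be measurable but turns out shadowed is skipped
with a warning.

*Couch marker.* The index-bar marker is detected on the gantry-0 image by
cropping a configured ROI, removing the separable background (row/column
means — this removes the jaw penumbra and phantom gradients exactly),
smoothing lightly (the blob top is nearly flat), ×10 bilinear up-sampling
and taking the contrast extremum, followed by a parabolic sub-pixel
refinement — a bilinear up-sampling alone cannot place a maximum between
native grid nodes. Dense markers attenuate, so the marker is dark on a
transmission image; polarity is configurable. An extremum on the ROI border
is rejected ("marker not in ROI").

## MR image analysis

The phantom body is bright on the T1-weighted volume; fiducials are
spherical signal voids. Volumes are handled in a canonical IEC axis order
(signed-permutation orientations are canonicalized on load; oblique
acquisitions are not supported).

1. **Corner search.** The inferior-left-posterior corner of the phantom is
   found on maximum-intensity projections thresholded at half the robust
   maximum; the corner seeds all fiducial searches via the characterized
   corner-relative offsets.
2. **Coarse NCC.** A sub-volume (default 3× the void diameter per axis) is
   cropped around each seed, mean-projected along x and along z
   (median available in config), Sobel-filtered and matched against rendered
   void-projection templates (one per orientation) to the nearest voxel.
3. **Half-circle refinement.** The two orthogonal slices through the refined
   center are Sobel-filtered; the void edge appears as two bright half
   circles (superior and inferior). 150 radial profiles cast from the
   center estimate, sampled at 1/20-voxel steps by cubic interpolation,
   locate the edge at the per-profile maximum response; points with response
   below 30% of the slice maximum are excluded. Edge points within ±60° of
   the vertical vertices are fitted with quadratics; the two parabola
   vertices per slice average to the sub-voxel center (averaging the
   superior and inferior vertices cancels the circle-vs-parabola bias in the
   vertical coordinate). One re-centering pass is applied. The x coordinate
   comes from the slice perpendicular to z, z from the slice perpendicular
   to x, and y from the average of both. The mean parabola-fit residual (mm)
   is reported as fit quality; a refinement that moves more than half a void
   diameter from the coarse estimate is flagged.

## Characterization, alignment, and the daily run

*Phantom characterization* turns an arc of MV images (nominally 31 angles at
3° spacing, an operator-chosen list) into the `PhantomModel`: each fiducial
is tracked by predicting its projection from the nominal (design) position,
localized sub-pixel, and triangulated; offsets are stored relative to the
seven-fiducial mean and to the phantom corner. Projection tracks of coplanar
fiducials inevitably cross at gantry angles set by their difference-vector
azimuths; frames where two *predicted* projections approach within the
exclusion radius are skipped for both fiducials, and a fiducial lost in more
than 20% of frames aborts characterization naming it. The inferior/superior
plane labels partition 3 + 4 by the y offsets, and the two targeted fiducials
(most anterior on the superior plane) are recorded in the model rather than
hard-coded.

*MR-to-MV alignment* registers the matched MV (triangulated) and MR
(void-localized) positions of the two targeted fiducials with a
translation-only rigid shift minimizing the RMS residual — the closed form
is the mean difference vector. No outlier rejection is applied; any number
of matched fiducials ≥ 2 is accepted.

*Daily run.* The detected phantom shift is the mean displacement of the
targeted fiducials from their stored reference positions (extracted from the
reference MR with the same algorithms used daily); the plan phantom shift is
the isocenter displacement between the adapted and reference plans in the
reference image frame. Displacement vectors of the targeted fiducials
disagreeing by more than 0.5 mm flag the result as non-rigid/detection
suspect without altering the mean. The four subcomponent rows are gated by
the tolerance table:

| row          | gated quantity                                   | default |
|--------------|--------------------------------------------------|---------|
| registration | detected − plan shift, per axis                  | ±1.5 mm |
| couch        | marker displacement from baseline (u and v)      | ±0.5 mm |
| delivery     | planned vs detected jaw / MLC field centers      | ±1 mm   |
| alignment    | alignment vs reference value, per axis           | ±0.5 mm |

Per-leaf deltas are reported and flagged at the delivery bound but do not
gate the verdict — the gate applies to the field-center averages. A verdict
is *fail* iff a gated delta exceeds its bound (or the row's analysis failed
hard), *flagged* when a detector warning propagated, and *pass* otherwise;
verdicts are a pure function of stored metrics, so tightening a tolerance can
never turn a fail into a pass. Reports serialize deterministically (sorted
keys, floats fixed at 1e-6). Trend summaries report per-metric mean, SD and
the empirical 2.5/97.5 percentile interval (histogram tails, not
normal-theory intervals), with an optional baseline-setting mode over the
first N runs (maximum absolute deviation — the procedure used to set the
couch tolerance from an initial measurement series).

## The synthetic phantom and forward model

The generator defines the study conditions for every test in this
repository. The vendor phantom's internal dimensions are not published, so
the synthetic stand-in is a desk-scale but geometrically representative
choice, made once: a cylinder (radius 60 mm, length 120 mm, axis along y)
carrying three fiducials on an inferior-plane equilateral triangle
(circumradius 24 mm) and four on a superior plane (equilateral triangle plus
one extra), fiducial diameter 6 mm, planes at y = ±25 mm. The in-plane
placement was chosen so that no two same-plane fiducials project within
8 mm of each other at the four cardinal (daily) gantry angles, and the
default characterization arc (31 angles at 3° spacing in four blocks around
the circle, like the vendor set-to-work arc which likewise avoids unusable
regions) keeps every pair ≥ 7.5 mm apart on the panel.

The MV forward model is geometric, not dosimetric: aperture fluence with
analytic error-function penumbra (default σ = 1.5 px, so the true 50% edge
is exact rather than rasterized), exponential chord attenuation through the
body, the divergently projected fiducial spheres and the couch marker
sphere, plus additive Gaussian noise (default σ = 1% of the open-field
intensity). The MR volume (1 mm isotropic, field of view fixed in the MR
frame) is the soft-edged bright cylinder with spherical voids and Rician
noise (default 3% of the body signal). ATP adaptation is emulated by
translating the apertures by the simulated registration result
(`phantom_shift − alignment_delta + registration_error`) with leaf
re-selection keeping the open bank one leaf wider than the jaws;
delivered-vs-planned faults are injected per field on top. Every rendered
ground-truth quantity is recorded in the bundle manifest; tests read truth
only from there.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: MV scatter, panel sag/flex beyond the per-angle
isocenter-pixel table, detector glare/PSF, MR geometric distortion and
susceptibility artifacts, intra-fraction motion, and the vendor registration
software's behaviour (registration error is injected, not modelled). The
couch marker placement (between leaf-center profile strips, below the
jaw-profile rows) mirrors the physical setup constraint that the marker must
not perturb edge detection; a large negative-x aperture adaptation could
move the marker out of the field, as it could physically.

## Problem sizes and numerical choices

The bundled batteries run at desk scale: the aperture-offset battery uses
two seeds × two gantry angles (40 MLC and 80 jaw measurements); the
phantom-shift battery uses 1/3/5 mm per cardinal axis × 5 seeded repeats
(45 bundles); the reference session characterizes from the full 31-image
arc. The panel is 1017 × 439 px (220 × 95 mm at the isocenter); the MR
volume 151³ voxels. Interpolation uses reflective padding for filters,
linear interpolation where the pipeline states it (×10 stages) and cubic
spline for the ×20 edge refinements; up-sampling windows are clipped to
image bounds and fail if degenerate. Ties between gradient peaks break
toward the planned edge, with a flag.

## Known limitations

* Translation-only registration throughout; rotations are out of scope.
* Static (non-dynamic) apertures only; one control point per beam.
* Axial, axis-aligned MR acquisitions only.
* The isocenter-pixel calibration is an input, not a measured quantity; a
  change in it shifts every MV-based metric coherently.
* Sub-pixel MV accuracy degrades to ~0.13 px when another fiducial's edge
  ring enters the template footprint (projected separations below ~9 mm);
  the synthetic layout keeps daily separations at or above 8 mm, where the
  effect is ≤ 0.03 mm and negligible against all gated tolerances.
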