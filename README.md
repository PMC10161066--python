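# mrlqc

Semi-automated daily end-to-end (E2E) quality control for MR-linac
adaptive radiotherapy.

On an integrated MR-linac, beam apertures are adapted at every fraction
from the daily MR image (the adapt-to-position workflow), so the chain
MR acquisition → image registration → plan adaptation → data transfer →
delivery must be verified daily. `mrlqc` analyses one run of that chain
executed on a rigid phantom containing seven fiducials — bright dense
markers on megavoltage (MV) portal images, signal voids on MR — and
quantifies four machine subcomponents:

* **registration** — the isocenter shift reported by the online image
  registration (from the adapted plan) against the phantom shift measured
  independently by triangulating fiducials on the MV images (±1.5 mm);
* **couch** — the couch index-bar marker position against its baseline
  (±0.5 mm);
* **delivery** — planned vs. detected jaw and MLC field positions on the
  four delivered fields (±1 mm);
* **alignment** — the MR-to-MV isocenter alignment, from rigid
  translation-only registration of the fiducial positions measured in both
  modalities, against the commissioned value (±0.5 mm per axis).

At its core is the projection model of a fiducial at cylindrical
coordinates (θ, r, y) about the gantry rotation axis onto the MV panel at
gantry angle φ, in mm at the isocenter plane:

    u(φ) = SAD · r · sin(θ − φ) / (SAD − r · cos(θ − φ))
    v(φ) = SAD · y              / (SAD − r · cos(θ − φ))

Fitting (θ, r, y) to the sub-pixel fiducial positions detected across the
gantry angles (normalized cross-correlation with ×10 up-sampled
refinement) triangulates each fiducial in 3D; on MR, voids are localized
to sub-voxel accuracy by a three-stage coarse-to-fine search ending in
quadratic fits to the Sobel half-circle edges. A bundled synthetic
generator renders the whole input set — MV portal images with penumbra,
attenuation and noise, the MR volume, reference and adapted plans — with
a ground-truth manifest, and every detector in the package is validated
against it. See `docs/methods.md` for the full model description.

## Worked example

Simulate a daily run with a 0.8 mm couch fault, bootstrap the reference
session (phantom characterization from a 31-image MV arc plus reference
MR extraction), and evaluate it:

```
$ mrlqc simulate --out run1 --seed 7 --reference --scenario couch.yaml
bundle written to run1
$ mrlqc run --bundle run1 --reference run1/reference.json --out run1/result.json
daily E2E QC result
  registration   PASS
  couch          FAIL
  delivery       PASS
  alignment      PASS
```

with `couch.yaml` containing `couch_shift_mm: [0.8, 0.0]`. The report
(`run1/result.json`) carries the measured numbers behind the verdicts,
e.g.

```
"couch": {"delta_mm": [0.791669, 0.002339], ...}
"registration": {"detected_shift_mm": [-0.00113, 0.005338, 0.019902], ...}
```

Here the marker displacement of 0.79 mm exceeds the ±0.5 mm couch
tolerance, while the detected phantom shift agrees with the (null) plan
shift to a few microns — the registration, delivery and alignment rows
pass. `mrlqc trend` aggregates a directory of such reports into
per-metric means, SDs and empirical 95% intervals.

The same flows are available as library calls (`build_scenario_bundle`,
`create_reference_data`, `evaluate_daily_run`); real data enters through
DICOM RTIMAGE files, axial DICOM MR series and DICOM-RT plans, or the
documented flat/JSON equivalents.

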