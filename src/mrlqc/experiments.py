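"""Sensitivity experiments for the QC suite, run on synthetic data.

These reproduce, at desk scale, the validation measurements used to
qualify the test suite: known jaw/MLC aperture offsets recovered by the
edge detector, and known phantom translations recovered independently
from the MV projections (fiducial triangulation) and from the MR volume
(void localization).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .geometry import Vec3IEC
from .mv_analysis import MVDetectorConfig, detect_field_edges
from .plan_io import compute_plan_phantom_shift, planned_field_to_panel
from .registration import compute_detected_phantom_shift
from .report import ReferenceData, _triangulate_daily_fiducials
from .synthetic import (
    ApertureError,
    ScenarioSpec,
    SyntheticPhantomSpec,
    _apply_aperture_error,
    build_scenario_bundle,
    default_geometry,
    default_reference_plan,
    render_mv_image,
)

__all__ = [
    "aperture_offset_battery",
    "phantom_shift_battery",
    "OFFSETS_MM",
]

#: introduced aperture offsets, mm
OFFSETS_MM = tuple(float(d) for d in range(1, 11))

#: leaves carrying the introduced MLC offsets (all measurable leaves but one)
_MLC_BATTERY_LEAVES = tuple(range(-5, 5))


def aperture_offset_battery(
    spec: SyntheticPhantomSpec | None = None,
    seeds: Sequence[int] = (0, 1),
    gantry_indices: Sequence[int] = (0, 1),
    cfg: MVDetectorConfig | None = None,
) -> dict:
    """Introduce known jaw and per-leaf MLC offsets (1..10 mm) into the
    delivered fields and recover them with the gradient edge detector.

    Each MLC image carries the ten offsets on ten different leaves
    (applied to the superior leaf tips); each jaw image carries one
    offset magnitude applied inward on both jaw edges.  Returns the
    per-measurement errors (detected minus introduced) in mm.
    """
    spec = spec or SyntheticPhantomSpec.default()
    cfg = cfg or MVDetectorConfig()
    geom = default_geometry()
    plan = default_reference_plan()

    mlc_errors: list[float] = []
    jaw_errors: list[float] = []
    for seed in seeds:
        for gi in gantry_indices:
            beam = plan.beams[gi]
            planned = planned_field_to_panel(beam, geom)
            # --- MLC: ten offsets in one field
            err = ApertureError(
                leaf_offsets={k: (0.0, float(k + 6)) for k in _MLC_BATTERY_LEAVES}
            )
            delivered = _apply_aperture_error(beam, err)
            sc = ScenarioSpec(seed=1000 * seed + gi)
            img = render_mv_image(spec, delivered, sc, geom)
            m = detect_field_edges(img, planned, geom, cfg)
            for k in _MLC_BATTERY_LEAVES:
                introduced = float(k + 6)
                detected = m.mlc_edges[k][1] - planned.mlc_edges[k][1]
                mlc_errors.append(detected - introduced)
            # --- jaws: one inward offset magnitude per image
            for d in OFFSETS_MM:
                err = ApertureError(jaw_offsets=(d, -d))
                delivered = _apply_aperture_error(beam, err)
                sc = ScenarioSpec(seed=1000 * seed + gi + 7 * int(d))
                img = render_mv_image(spec, delivered, sc, geom)
                m = detect_field_edges(img, planned, geom, cfg)
                jaw_errors.append((m.jaw_edges[0] - planned.jaw_edges[0]) - d)
                jaw_errors.append((m.jaw_edges[1] - planned.jaw_edges[1]) - (-d))
    return {
        "mlc_errors_mm": mlc_errors,
        "jaw_errors_mm": jaw_errors,
        "max_abs_mlc_error_mm": float(np.abs(mlc_errors).max()),
        "max_abs_jaw_error_mm": float(np.abs(jaw_errors).max()),
        "jaw_fraction_within_half_mm": float(
            np.mean(np.abs(jaw_errors) <= 0.5)
        ),
    }


def phantom_shift_battery(
    reference: ReferenceData,
    spec: SyntheticPhantomSpec | None = None,
    magnitudes: Sequence[float] = (1.0, 3.0, 5.0),
    n_seeds: int = 5,
    cfg: MVDetectorConfig | None = None,
    base_seed: int = 20000,
) -> dict:
    """Introduce known phantom translations along each cardinal axis and
    recover them from the MV projections (triangulation of the targeted
    fiducials) and from the MR volume (mean displacement of all seven
    localized voids).

    Returns the per-axis standard deviation of (detected - introduced)
    for every (shift case, modality) group and the worst case.
    """
    from .mr_analysis import localize_all_mr_fiducials

    spec = spec or SyntheticPhantomSpec.default()
    cfg = cfg or MVDetectorConfig()
    ref_all = [p.as_array() for p in reference.fiducial_positions_iso]
    ref_targets = reference.targeted_reference_positions()

    stds = {}
    worst = 0.0
    case_id = 0
    for axis in range(3):
        for mag in magnitudes:
            shift = np.zeros(3)
            shift[axis] = mag
            mv_err, mr_err = [], []
            for s in range(n_seeds):
                scen = ScenarioSpec(
                    phantom_shift=Vec3IEC.from_array(shift),
                    seed=base_seed + 97 * case_id + s,
                )
                b = build_scenario_bundle(spec, scen)
                plan_shift = compute_plan_phantom_shift(
                    b.adapted_plan, b.reference_plan
                )
                priors = [p + plan_shift for p in ref_targets]
                daily = _triangulate_daily_fiducials(b.mv_images, priors, cfg)
                detected, _ = compute_detected_phantom_shift(daily, ref_targets)
                mv_err.append(detected.as_array() - shift)
                loc = localize_all_mr_fiducials(
                    b.mr_volume, reference.phantom_model.corner_offsets
                )
                if loc.errors:
                    raise RuntimeError(f"MR localization failed: {loc.errors}")
                daily_mr = np.array(
                    [loc.fiducials[i].position.as_array() for i in range(7)]
                )
                mr_shift = (daily_mr - ref_all).mean(axis=0)
                mr_err.append(mr_shift - shift)
            key = f"axis{'xyz'[axis]}_{mag:g}mm"
            stds[key] = {
                "mv_std_mm": np.std(mv_err, axis=0, ddof=1).tolist(),
                "mr_std_mm": np.std(mr_err, axis=0, ddof=1).tolist(),
            }
            worst = max(
                worst,
                float(np.max(stds[key]["mv_std_mm"])),
                float(np.max(stds[key]["mr_std_mm"])),
            )
            case_id += 1
    return {"cases": stds, "worst_case_std_mm": worst}
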