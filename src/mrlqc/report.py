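"""Daily QC evaluation: run the full analysis chain, gate against
tolerances, and emit deterministic machine-readable reports.

A daily run evaluates four subcomponents:

==========================  ==================================================
registration                plan phantom shift vs. the MV-detected phantom
                            shift (per-axis tolerance, default +/-1.5 mm)
couch                       couch marker displacement from baseline
                            (default +/-0.5 mm)
delivery                    planned vs. detected jaw / MLC field centers
                            (default +/-1 mm; per-leaf deltas are reported
                            and flagged at the same bound but do not gate)
alignment                   MR-to-MV alignment vs. the reference value
                            (per-axis, default +/-0.5 mm)
==========================  ==================================================

A subcomponent verdict is ``fail`` iff one of its gated deltas exceeds
its tolerance, ``flagged`` when any detector warning propagated, and
``pass`` otherwise.  Verdicts are recomputed from stored deltas by
:func:`apply_tolerances`, so tightening a tolerance can never turn a
fail into a pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .geometry import (
    GantryProjectionSet,
    PanelPoint,
    Vec3IEC,
    iec_to_polar,
    project_fiducial,
    triangulate_fiducial,
)
from .mr_analysis import MRDetectorConfig, MRVolume, localize_all_mr_fiducials
from .mv_analysis import (
    MVDetectorConfig,
    MVImage,
    detect_couch_fiducial,
    detect_field_edges,
    localize_mv_fiducials,
    make_fiducial_templates,
)
from .plan_io import (
    RTPlanData,
    compute_plan_phantom_shift,
    parse_rt_plan,
    planned_field_to_panel,
)
from .registration import (
    PhantomModel,
    compute_detected_phantom_shift,
    compute_mr_to_mv_alignment,
)

__all__ = [
    "ToleranceConfig",
    "ReferenceData",
    "QCResult",
    "evaluate_daily_run",
    "apply_tolerances",
    "summarize_history",
    "result_to_json",
]

SUBCOMPONENTS = ("registration", "couch", "delivery", "alignment")


@dataclass(frozen=True)
class ToleranceConfig:
    """Tolerances and baselines for the four daily subcomponents."""

    registration_mm: float = 1.5  # per axis
    couch_mm: float = 0.5
    delivery_mm: float = 1.0  # jaw / MLC field-center deltas
    alignment_mm: float = 0.5  # per axis
    alignment_reference: Vec3IEC = Vec3IEC(0, 0, 0)
    couch_baseline_mm: tuple[float, float] = (0.0, 0.0)
    couch_roi_half_mm: float = 5.0

    def __post_init__(self) -> None:
        for name in ("registration_mm", "couch_mm", "delivery_mm", "alignment_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ReferenceData:
    """Reference-session extraction consumed by every daily run: the
    reference plan, the characterized phantom model, and the seven
    fiducial positions relative to the reference plan isocenter."""

    reference_plan: RTPlanData
    phantom_model: PhantomModel
    fiducial_positions_iso: tuple[Vec3IEC, ...]

    def targeted_reference_positions(self) -> list[Vec3IEC]:
        return [
            self.fiducial_positions_iso[i]
            for i in self.phantom_model.targeted_indices
        ]

    def to_json(self) -> str:
        from .plan_io import _plan_to_dict

        return json.dumps(
            {
                "reference_plan": _plan_to_dict(self.reference_plan),
                "phantom_model": json.loads(self.phantom_model.to_json()),
                "fiducial_positions_iso_mm": [
                    list(p.as_array()) for p in self.fiducial_positions_iso
                ],
            },
            indent=2,
            sort_keys=True,
        )

    @staticmethod
    def from_json(text: str) -> "ReferenceData":
        from .plan_io import _plan_from_dict

        d = json.loads(text)
        return ReferenceData(
            reference_plan=_plan_from_dict(d["reference_plan"]),
            phantom_model=PhantomModel.from_json(
                json.dumps(d["phantom_model"])
            ),
            fiducial_positions_iso=tuple(
                Vec3IEC.from_array(a) for a in d["fiducial_positions_iso_mm"]
            ),
        )


@dataclass
class QCResult:
    """Output of one daily run: per-subcomponent metrics and verdicts."""

    metrics: dict
    verdicts: dict
    flags: dict
    timestamp: str | None = None

    def to_dict(self) -> dict:
        d = {
            "metrics": self.metrics,
            "verdicts": self.verdicts,
            "flags": self.flags,
        }
        if self.timestamp is not None:
            d["timestamp"] = self.timestamp
        return d


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, np.floating):
        return round(float(obj), ndigits)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def result_to_json(result: QCResult) -> str:
    """Deterministic serialization: sorted keys, floats fixed to 1e-6."""
    return json.dumps(_round_floats(result.to_dict()), indent=2, sort_keys=True)


def apply_tolerances(metrics: dict, tol: ToleranceConfig, flags: dict) -> dict:
    """Pure gating function: metrics + tolerances -> verdicts."""
    verdicts = {}

    def verdict(name: str, deltas, bound: float) -> str:
        if metrics.get(name, {}).get("error"):
            return "fail"
        if any(abs(d) > bound for d in deltas):
            return "fail"
        return "flagged" if flags.get(name) else "pass"

    reg = metrics.get("registration", {})
    verdicts["registration"] = verdict(
        "registration", reg.get("delta_mm", []), tol.registration_mm
    )
    couch = metrics.get("couch", {})
    verdicts["couch"] = verdict(
        "couch", couch.get("delta_mm", []), tol.couch_mm
    )
    dlv = metrics.get("delivery", {})
    centers = []
    for f in dlv.get("fields", []):
        centers += [f["jaw_center_delta_mm"], f["mlc_center_delta_mm"]]
    verdicts["delivery"] = verdict("delivery", centers, tol.delivery_mm)
    ali = metrics.get("alignment", {})
    verdicts["alignment"] = verdict(
        "alignment", ali.get("delta_from_reference_mm", []), tol.alignment_mm
    )
    return verdicts


# ---------------------------------------------------------------------------
# the daily run


def _triangulate_daily_fiducials(
    mv: Sequence[MVImage],
    priors: Sequence[Vec3IEC],
    cfg: MVDetectorConfig,
) -> list[Vec3IEC]:
    """Localize and triangulate fiducials across the daily MV images,
    seeding the 2D search from projected prior positions."""
    from .mv_analysis import _fiducial_feature_image

    geom = mv[0].geom
    templates = make_fiducial_templates(geom, cfg)
    features = [_fiducial_feature_image(img, cfg) for img in mv]
    out = []
    for prior in priors:
        polar = iec_to_polar(prior)
        points = []
        for img, feat in zip(mv, features):
            pred = project_fiducial(polar, img.gantry_angle, geom)
            pu, pv = geom.iso_mm_to_pixel(pred.u_iso, pred.v_iso, img.gantry_angle)
            det = localize_mv_fiducials(img, [(pu, pv)], cfg, templates, feature=feat)[0]
            u_mm, v_mm = geom.pixel_to_iso_mm(det.u, det.v, img.gantry_angle)
            points.append(PanelPoint(u_mm, v_mm, img.gantry_angle))
        _, pos, _ = triangulate_fiducial(GantryProjectionSet(tuple(points)), geom)
        out.append(pos)
    return out


def evaluate_daily_run(
    mv: Sequence[MVImage],
    mr: MRVolume,
    adapted_plan,
    reference: ReferenceData,
    tol: ToleranceConfig,
    mv_cfg: MVDetectorConfig | None = None,
    mr_cfg: MRDetectorConfig | None = None,
    timestamp: str | None = None,
) -> QCResult:
    """Run the full daily QC chain and gate it against the tolerances.

    Any subcomponent hard failure yields verdict ``fail`` for that row
    with the diagnostic recorded under ``metrics[row]['error']``; the
    remaining rows are still evaluated.
    """
    mv_cfg = mv_cfg or MVDetectorConfig()
    mr_cfg = mr_cfg or MRDetectorConfig()
    adapted = parse_rt_plan(adapted_plan)
    geom = mv[0].geom
    metrics: dict = {}
    flags: dict = {k: [] for k in SUBCOMPONENTS}

    plan_shift = compute_plan_phantom_shift(adapted, reference.reference_plan)
    ref_targets = reference.targeted_reference_positions()

    # --- registration: detected vs. plan phantom shift
    daily_positions: list[Vec3IEC] | None = None
    try:
        priors = [p + plan_shift for p in ref_targets]
        daily_positions = _triangulate_daily_fiducials(mv, priors, mv_cfg)
        detected, sflags = compute_detected_phantom_shift(daily_positions, ref_targets)
        flags["registration"] += list(sflags)
        delta = detected - plan_shift
        metrics["registration"] = {
            "detected_shift_mm": list(detected.as_array()),
            "plan_shift_mm": list(plan_shift.as_array()),
            "delta_mm": list(delta.as_array()),
        }
    except Exception as exc:  # propagate as a failed row
        metrics["registration"] = {"error": str(exc)}

    # --- couch position consistency (gantry-0 image)
    try:
        img0 = min(mv, key=lambda im: abs((im.gantry_angle + 180) % 360 - 180))
        bu, bv = geom.iso_mm_to_pixel(*tol.couch_baseline_mm, img0.gantry_angle)
        half = int(round(tol.couch_roi_half_mm / geom.pixel_resolution))
        roi = (
            int(round(bv)) - half, int(round(bv)) + half + 1,
            int(round(bu)) - half, int(round(bu)) + half + 1,
        )
        det = detect_couch_fiducial(img0, roi, tol.couch_baseline_mm, mv_cfg)
        metrics["couch"] = {
            "u_px": det.u,
            "v_px": det.v,
            "delta_mm": list(det.delta_from_baseline),
        }
    except Exception as exc:
        metrics["couch"] = {"error": str(exc)}

    # --- field delivery verification
    try:
        fields = []
        for img in mv:
            beam = next(
                b
                for b in adapted.beams
                if abs((b.gantry_angle - img.gantry_angle + 180) % 360 - 180) < 0.5
            )
            planned = planned_field_to_panel(beam, geom)
            measured = detect_field_edges(img, planned, geom, mv_cfg)
            flags["delivery"] += [
                f"gantry {img.gantry_angle:g}: {f}" for f in measured.flags
            ]
            leaf_deltas = {}
            for k, pair in measured.mlc_edges.items():
                if k in planned.mlc_edges:
                    pp = planned.mlc_edges[k]
                    leaf_deltas[str(k)] = 0.5 * (
                        (pair[0] - pp[0]) + (pair[1] - pp[1])
                    )
            for k, d in leaf_deltas.items():
                if abs(d) > tol.delivery_mm:
                    flags["delivery"].append(
                        f"gantry {img.gantry_angle:g}: leaf {k} delta "
                        f"{d:.2f} mm exceeds {tol.delivery_mm} mm"
                    )
            fields.append(
                {
                    "gantry_angle_deg": img.gantry_angle,
                    "jaw_center_delta_mm": measured.field_center[0]
                    - planned.field_center[0],
                    "mlc_center_delta_mm": measured.field_center[1]
                    - planned.field_center[1],
                    "jaw_edges_mm": list(measured.jaw_edges),
                    "leaf_deltas_mm": leaf_deltas,
                }
            )
        metrics["delivery"] = {"fields": fields}
    except Exception as exc:
        metrics["delivery"] = {"error": str(exc)}

    # --- MR-to-MV alignment
    try:
        loc = localize_all_mr_fiducials(
            mr, reference.phantom_model.corner_offsets, mr_cfg
        )
        t0, t1 = reference.phantom_model.targeted_indices
        for i in (t0, t1):
            if i in loc.errors:
                raise RuntimeError(loc.errors[i])
        for i, f in loc.fiducials.items():
            flags["alignment"] += [f"MR fiducial {i}: {fl}" for fl in f.flags]
        if daily_positions is None:
            raise RuntimeError("MV triangulation unavailable for alignment")
        mr_pos = [loc.fiducials[t0].position, loc.fiducials[t1].position]
        ali = compute_mr_to_mv_alignment(daily_positions, mr_pos)
        delta = ali.shift - tol.alignment_reference
        metrics["alignment"] = {
            "shift_mm": list(ali.shift.as_array()),
            "rms_residual_mm": ali.rms_residual,
            "n_fiducials": ali.n_fiducials,
            "delta_from_reference_mm": list(delta.as_array()),
        }
    except Exception as exc:
        metrics["alignment"] = {"error": str(exc)}

    flags = {k: v for k, v in flags.items() if v}
    verdicts = apply_tolerances(metrics, tol, flags)
    return QCResult(metrics=metrics, verdicts=verdicts, flags=flags, timestamp=timestamp)


# ---------------------------------------------------------------------------
# trend history


def _flatten(prefix: str, obj, out: dict) -> None:
    if isinstance(obj, (int, float)) and not isinstance(obj, bool):
        out[prefix] = float(obj)
    elif isinstance(obj, dict):
        for k, v in obj.items():
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, out)
    elif isinstance(obj, (list, tuple)):
        if len(obj) == 3 and all(isinstance(v, (int, float)) for v in obj):
            for ax, v in zip("xyz", obj):
                out[f"{prefix}.{ax}"] = float(v)
        else:
            for i, v in enumerate(obj):
                _flatten(f"{prefix}[{i}]", v, out)


def summarize_history(
    results: Sequence[QCResult | dict], baseline_first_n: int | None = None
) -> dict:
    """Trend statistics over a result history.

    For every numeric metric present in >= 2 results, reports the mean,
    standard deviation and the empirical 2.5th / 97.5th percentile
    interval (the tails of the histogram, not a normal-theory CI).  With
    ``baseline_first_n``, also reports per-metric maximum absolute
    deviations over the first N runs — the procedure used to set the
    couch tolerance from the initial measurement series.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 results to summarize")
    rows = []
    for r in results:
        d = r.to_dict() if isinstance(r, QCResult) else r
        flat: dict = {}
        _flatten("", d.get("metrics", d), flat)
        rows.append(flat)
    keys = sorted(set().union(*rows))
    summary: dict = {"n": len(rows), "metrics": {}}
    for k in keys:
        vals = np.array([row[k] for row in rows if k in row])
        if len(vals) < 2:
            continue
        summary["metrics"][k] = {
            "mean": float(vals.mean()),
            "std": float(vals.std(ddof=1)),
            "p2.5": float(np.percentile(vals, 2.5)),
            "p97.5": float(np.percentile(vals, 97.5)),
        }
    if baseline_first_n:
        base = {}
        for k in keys:
            vals = [row[k] for row in rows[:baseline_first_n] if k in row]
            if vals:
                base[k] = float(np.max(np.abs(vals)))
        summary["baseline_max_abs_first_n"] = {"n": baseline_first_n, "values": base}
    return summary
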