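"""Phantom geometric characterization and MR-to-MV alignment.

Characterization turns an arc of MV images (nominally 31 images at 3 deg
spacing) into a :class:`PhantomModel`: the seven fiducial positions
relative to their mean and to the phantom corner, plus the plane labels
and the identity of the two targeted (most anterior, superior-plane)
fiducials.  The model accounts for manufacturing variation of the
phantom and seeds the MR fiducial search.

MR-to-MV alignment registers matched fiducial positions measured in the
MV frame and the MR frame with a translation-only rigid shift that
minimizes the root-mean-square residual; for an RMS objective the
optimal translation is the mean of the per-fiducial difference vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .geometry import (
    BeamGeometry,
    GantryProjectionSet,
    PanelPoint,
    Vec3IEC,
    iec_to_polar,
    project_fiducial,
    triangulate_fiducial,
)
from .mv_analysis import (
    AmbiguousDetectionError,
    FiducialNotFoundError,
    MVDetectorConfig,
    MVImage,
    _fiducial_feature_image,
    localize_mv_fiducials,
    make_fiducial_templates,
)

__all__ = [
    "PhantomModel",
    "AlignmentResult",
    "ShiftComparison",
    "CharacterizationError",
    "characterize_phantom",
    "compute_mr_to_mv_alignment",
    "compute_detected_phantom_shift",
]


class CharacterizationError(RuntimeError):
    pass


@dataclass
class PhantomModel:
    """Characterized phantom geometry (all offsets in IEC mm)."""

    fiducial_offsets: tuple[Vec3IEC, ...]  # relative to the fiducial mean
    corner_offsets: tuple[Vec3IEC, ...]  # relative to the phantom corner
    plane_assignment: tuple[str, ...]  # "inferior" | "superior"
    targeted_indices: tuple[int, int]  # two most anterior superior fiducials
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.fiducial_offsets)
        if len(self.corner_offsets) != n or len(self.plane_assignment) != n:
            raise ValueError("offset/label lists must have equal length")
        s = np.sum([o.as_array() for o in self.fiducial_offsets], axis=0)
        if np.abs(s).max() > 1e-6:
            raise ValueError("offsets relative to the mean must sum to zero")
        counts = {
            lab: self.plane_assignment.count(lab) for lab in set(self.plane_assignment)
        }
        if counts != {"inferior": 3, "superior": 4}:
            raise ValueError(f"plane labels must partition 3 + 4, got {counts}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "units": "mm, IEC 61217",
                "fiducial_offsets_from_mean": [
                    list(o.as_array()) for o in self.fiducial_offsets
                ],
                "corner_offsets": [list(o.as_array()) for o in self.corner_offsets],
                "plane_assignment": list(self.plane_assignment),
                "targeted_indices": list(self.targeted_indices),
                "metadata": self.metadata,
            },
            indent=2,
            sort_keys=True,
        )

    @staticmethod
    def from_json(text: str) -> "PhantomModel":
        d = json.loads(text)
        return PhantomModel(
            tuple(Vec3IEC.from_array(a) for a in d["fiducial_offsets_from_mean"]),
            tuple(Vec3IEC.from_array(a) for a in d["corner_offsets"]),
            tuple(d["plane_assignment"]),
            tuple(d["targeted_indices"]),
            d.get("metadata", {}),
        )


@dataclass(frozen=True)
class AlignmentResult:
    """Translation-only MR-to-MV registration output."""

    shift: Vec3IEC  # applied to the MV positions to best match the MR ones
    rms_residual: float
    n_fiducials: int


@dataclass(frozen=True)
class ShiftComparison:
    """Plan phantom shift vs. the MV-detected phantom shift."""

    detected_shift: Vec3IEC
    plan_shift: Vec3IEC
    flags: tuple[str, ...] = ()

    @property
    def delta(self) -> Vec3IEC:
        return self.detected_shift - self.plan_shift


def characterize_phantom(
    arc: Sequence[MVImage],
    nominal_positions: Sequence[Vec3IEC],
    corner_to_mean: Vec3IEC,
    cfg: MVDetectorConfig | None = None,
    max_lost_fraction: float = 0.2,
) -> PhantomModel:
    """Build a :class:`PhantomModel` from a multi-angle MV arc.

    Each fiducial is tracked across the arc by predicting its projection
    from the nominal (design) position, localizing it with the sub-pixel
    NCC detector, and triangulating the resulting 2D track.  Offsets are
    then stored relative to the seven-fiducial mean and to the phantom
    corner (``corner_to_mean`` is the design vector from the corner to
    the fiducial mean, a property of the phantom body, not of the
    fiducial placement).

    A fiducial lost in more than ``max_lost_fraction`` of the frames
    aborts characterization naming that fiducial.
    """
    cfg = cfg or MVDetectorConfig()
    if len(arc) < 2:
        raise CharacterizationError("need >= 2 arc images")
    geom = arc[0].geom
    templates = make_fiducial_templates(geom, cfg)
    angles = sorted({img.gantry_angle % 360.0 for img in arc})
    if len(angles) < len(arc):
        raise CharacterizationError("arc gantry angles must be distinct")

    # predicted projections for overlap screening: frames where two
    # fiducial projections approach within the exclusion radius cannot be
    # trusted and count as lost for both fiducials involved
    preds = np.empty((len(nominal_positions), len(arc), 2))
    for i, nominal in enumerate(nominal_positions):
        polar = iec_to_polar(nominal)
        for j, img in enumerate(arc):
            p = project_fiducial(polar, img.gantry_angle, geom)
            preds[i, j] = (p.u_iso, p.v_iso)

    features = [_fiducial_feature_image(img, cfg) for img in arc]
    positions: list[Vec3IEC] = []
    residuals: list[float] = []
    for i, nominal in enumerate(nominal_positions):
        polar = iec_to_polar(nominal)
        points: list[PanelPoint] = []
        lost = 0
        for j, img in enumerate(arc):
            sep = np.hypot(*(preds[:, j] - preds[i, j]).T)
            sep[i] = np.inf
            if sep.min() < cfg.exclusion_radius_mm:
                lost += 1
                continue
            pu, pv = geom.iso_mm_to_pixel(*preds[i, j], img.gantry_angle)
            try:
                det = localize_mv_fiducials(
                    img, [(pu, pv)], cfg, templates, feature=features[j]
                )[0]
            except (FiducialNotFoundError, AmbiguousDetectionError):
                lost += 1
                continue
            u_mm, v_mm = geom.pixel_to_iso_mm(det.u, det.v, img.gantry_angle)
            points.append(PanelPoint(u_mm, v_mm, img.gantry_angle))
        if lost > max_lost_fraction * len(arc):
            raise CharacterizationError(
                f"fiducial {i} lost in {lost}/{len(arc)} arc frames"
            )
        _, pos, rms = triangulate_fiducial(GantryProjectionSet(tuple(points)), geom)
        positions.append(pos)
        residuals.append(rms)

    mean = Vec3IEC.from_array(np.mean([p.as_array() for p in positions], axis=0))
    raw_offsets = [p - mean for p in positions]
    # remove numerical residue so the zero-sum invariant holds exactly
    resid = np.mean([o.as_array() for o in raw_offsets], axis=0)
    offsets = tuple(Vec3IEC.from_array(o.as_array() - resid) for o in raw_offsets)
    corner = mean - corner_to_mean
    corner_offsets = tuple(p - corner for p in positions)

    y_med = float(np.median([o.y for o in offsets]))
    labels = tuple("inferior" if o.y < y_med else "superior" for o in offsets)
    if labels.count("superior") != 4:
        # tie-break: the four largest y values are the superior plane
        order = np.argsort([o.y for o in offsets])
        labels = tuple(
            "superior" if i in set(order[-4:]) else "inferior"
            for i in range(len(offsets))
        )
    superior = [i for i, lab in enumerate(labels) if lab == "superior"]
    targeted = tuple(sorted(superior, key=lambda i: -offsets[i].z)[:2])

    return PhantomModel(
        fiducial_offsets=offsets,
        corner_offsets=corner_offsets,
        plane_assignment=labels,
        targeted_indices=(int(targeted[0]), int(targeted[1])),
        metadata={
            "gantry_angles_deg": [float(a) for a in angles],
            "triangulation_rms_mm": [float(r) for r in residuals],
            "n_images": len(arc),
        },
    )


def compute_mr_to_mv_alignment(
    mv_positions: Sequence[Vec3IEC], mr_positions: Sequence[Vec3IEC]
) -> AlignmentResult:
    """Register matched MV and MR fiducial positions by a rigid shift.

    Minimizes the RMS of ``mv + shift - mr`` over the translation, whose
    closed form is the mean difference vector.
    """
    if len(mv_positions) != len(mr_positions):
        raise ValueError(
            f"mismatched fiducial lists ({len(mv_positions)} vs {len(mr_positions)})"
        )
    if len(mv_positions) < 2:
        raise ValueError("alignment needs >= 2 matched fiducials")
    mv = np.array([p.as_array() for p in mv_positions])
    mr = np.array([p.as_array() for p in mr_positions])
    diff = mr - mv
    shift = diff.mean(axis=0)
    resid = diff - shift
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AlignmentResult(Vec3IEC.from_array(shift), rms, len(mv_positions))


def compute_detected_phantom_shift(
    daily_mv_fiducials: Sequence[Vec3IEC],
    reference_positions: Sequence[Vec3IEC],
    disagreement_flag_mm: float = 0.5,
) -> tuple[Vec3IEC, tuple[str, ...]]:
    """Detected phantom shift: mean displacement of the targeted
    fiducials from their stored reference positions.

    When the per-fiducial displacement vectors disagree by more than
    ``disagreement_flag_mm`` the result is flagged (possible non-rigid
    setup or detection fault); the mean is never altered.
    """
    if len(daily_mv_fiducials) != len(reference_positions):
        raise ValueError("daily and reference fiducial lists must match")
    diffs = np.array(
        [
            (d - r).as_array()
            for d, r in zip(daily_mv_fiducials, reference_positions)
        ]
    )
    shift = Vec3IEC.from_array(diffs.mean(axis=0))
    flags: tuple[str, ...] = ()
    if len(diffs) >= 2:
        spread = np.linalg.norm(diffs.max(axis=0) - diffs.min(axis=0))
        if spread > disagreement_flag_mm:
            flags = (
                f"non-rigid/detection suspect: fiducial displacements "
                f"disagree by {spread:.2f} mm",
            )
    return shift, flags
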