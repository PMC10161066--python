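"""Reading and writing of the RT plans used by the QC suite.

Two interchangeable representations are supported:

* DICOM-RT Plan objects (via :mod:`pydicom`) with static apertures — one
  control point per beam, jaw pair along IEC X (the panel ``u`` axis)
  and an MLCY bank whose leaves travel along the panel ``v`` axis;
* a documented JSON mirror carrying the same content, which is also the
  native output format of the synthetic-data generator.

All parsed positions are millimetres.  DICOM patient coordinates are
mapped into the IEC 61217 machine frame with the standard head-first
supine mapping (x_IEC = x_pat, y_IEC = z_pat, z_IEC = -y_pat); any other
patient position is rejected — this is a phantom-QA context only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import generate_uid

from .geometry import BeamGeometry, Vec3IEC
from .mv_analysis import FieldMeasurement

__all__ = [
    "PlannedField",
    "RTPlanData",
    "PlanParseError",
    "parse_rt_plan",
    "write_plan_json",
    "write_plan_dicom",
    "compute_plan_phantom_shift",
    "planned_field_to_panel",
]

#: projected MLC leaf width at the isocenter plane, mm
MLC_PITCH_MM = 7.15

#: leaves closer than this are treated as closed
_CLOSED_LEAF_GAP_MM = 0.5


class PlanParseError(ValueError):
    pass


@dataclass(frozen=True)
class PlannedField:
    """One static treatment field.

    ``jaw_edges`` are the two field edges along u; ``leaf_positions``
    maps leaf index (leaf 0 centered on the beam axis, increasing toward
    +u) to the pair of leaf-tip positions along v.  Only open leaves are
    stored.
    """

    gantry_angle: float
    jaw_edges: tuple[float, float]
    leaf_positions: Mapping[int, tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.jaw_edges[0] < self.jaw_edges[1]:
            raise ValueError("jaw edge_1 must be < edge_2")
        for k, (a, b) in self.leaf_positions.items():
            if not a < b:
                raise ValueError(f"leaf {k}: edge_1 must be < edge_2")

    @property
    def field_center(self) -> tuple[float, float]:
        return FieldMeasurement.center_of(self.jaw_edges, dict(self.leaf_positions))


@dataclass
class RTPlanData:
    """Everything the QC suite needs from an RT plan."""

    isocenter: Vec3IEC  # IEC mm, in the reference-image frame
    beams: list[PlannedField]
    plan_label: str = ""
    frame_uid: str = ""

    def __post_init__(self) -> None:
        if not self.beams:
            raise ValueError("plan must contain >= 1 beam")


# ---------------------------------------------------------------------------
# JSON mirror


def _plan_to_dict(plan: RTPlanData) -> dict:
    return {
        "format": "mrlqc-rtplan-json/1",
        "plan_label": plan.plan_label,
        "frame_uid": plan.frame_uid,
        "isocenter_iec_mm": list(plan.isocenter.as_array()),
        "beams": [
            {
                "gantry_angle_deg": b.gantry_angle,
                "jaw_edges_mm": list(b.jaw_edges),
                "leaf_positions_mm": {
                    str(k): list(v) for k, v in sorted(b.leaf_positions.items())
                },
            }
            for b in plan.beams
        ],
    }


def write_plan_json(plan: RTPlanData, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_plan_to_dict(plan), indent=2, sort_keys=True))


def _plan_from_dict(d: dict) -> RTPlanData:
    try:
        beams = []
        for i, b in enumerate(d["beams"]):
            if "leaf_positions_mm" not in b:
                raise PlanParseError(f"beam {i}: missing leaf_positions_mm")
            beams.append(
                PlannedField(
                    gantry_angle=float(b["gantry_angle_deg"]),
                    jaw_edges=tuple(float(x) for x in b["jaw_edges_mm"]),
                    leaf_positions={
                        int(k): (float(v[0]), float(v[1]))
                        for k, v in b["leaf_positions_mm"].items()
                    },
                )
            )
        return RTPlanData(
            isocenter=Vec3IEC.from_array(d["isocenter_iec_mm"]),
            beams=beams,
            plan_label=d.get("plan_label", ""),
            frame_uid=d.get("frame_uid", ""),
        )
    except KeyError as exc:
        raise PlanParseError(f"plan JSON missing element {exc}") from exc


# ---------------------------------------------------------------------------
# DICOM


def _pat_to_iec(xyz: Sequence[float]) -> Vec3IEC:
    x, y, z = (float(v) for v in xyz)
    return Vec3IEC(x, z, -y)


def _iec_to_pat(p: Vec3IEC) -> list[float]:
    return [p.x, -p.z, p.y]


def _leaf_boundaries(k_min: int, k_max: int) -> list[float]:
    return [(k - 0.5) * MLC_PITCH_MM for k in range(k_min, k_max + 2)]


def write_plan_dicom(plan: RTPlanData, path: str | Path) -> None:
    """Serialize the plan as a minimal static-aperture DICOM-RT Plan."""
    ds = Dataset()
    ds.SOPClassUID = pydicom.uid.RTPlanStorage
    ds.SOPInstanceUID = generate_uid()
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = plan.plan_label
    ds.FrameOfReferenceUID = plan.frame_uid or generate_uid()
    ds.PatientPosition = "HFS"

    beam_seq = []
    for n, b in enumerate(plan.beams):
        leaves = dict(b.leaf_positions)
        k_min, k_max = min(leaves), max(leaves)
        bank1, bank2 = [], []
        for k in range(k_min, k_max + 1):
            if k in leaves:
                bank1.append(leaves[k][0])
                bank2.append(leaves[k][1])
            else:  # closed leaf, parked
                bank1.append(0.0)
                bank2.append(0.0)

        beam = Dataset()
        beam.BeamNumber = n + 1
        beam.BeamName = f"Field {n + 1}"
        beam.RadiationType = "PHOTON"

        bld_jaw = Dataset()
        bld_jaw.RTBeamLimitingDeviceType = "ASYMX"
        bld_jaw.NumberOfLeafJawPairs = 1
        bld_mlc = Dataset()
        bld_mlc.RTBeamLimitingDeviceType = "MLCY"
        bld_mlc.NumberOfLeafJawPairs = len(bank1)
        bld_mlc.LeafPositionBoundaries = [
            f"{v:.4f}" for v in _leaf_boundaries(k_min, k_max)
        ]
        beam.BeamLimitingDeviceSequence = [bld_jaw, bld_mlc]

        cp = Dataset()
        cp.ControlPointIndex = 0
        cp.GantryAngle = b.gantry_angle
        cp.IsocenterPosition = [f"{v:.4f}" for v in _iec_to_pat(plan.isocenter)]
        pos_jaw = Dataset()
        pos_jaw.RTBeamLimitingDeviceType = "ASYMX"
        pos_jaw.LeafJawPositions = [f"{v:.4f}" for v in b.jaw_edges]
        pos_mlc = Dataset()
        pos_mlc.RTBeamLimitingDeviceType = "MLCY"
        pos_mlc.LeafJawPositions = [f"{v:.4f}" for v in bank1 + bank2]
        cp.BeamLimitingDevicePositionSequence = [pos_jaw, pos_mlc]
        beam.ControlPointSequence = [cp]
        beam_seq.append(beam)
    ds.BeamSequence = beam_seq

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
    ds.file_meta = meta
    ds.save_as(path, enforce_file_format=True)


def _parse_dicom(ds: Dataset) -> RTPlanData:
    pos = getattr(ds, "PatientPosition", "HFS")
    if pos not in ("", "HFS"):
        raise PlanParseError(f"unsupported patient position {pos!r} (HFS only)")
    if "BeamSequence" not in ds:
        raise PlanParseError("plan has no BeamSequence")
    beams = []
    isocenter = None
    for beam in ds.BeamSequence:
        name = getattr(beam, "BeamName", f"beam {getattr(beam, 'BeamNumber', '?')}")
        if "ControlPointSequence" not in beam or len(beam.ControlPointSequence) == 0:
            raise PlanParseError(f"{name}: missing ControlPointSequence")
        cp = beam.ControlPointSequence[0]
        if "IsocenterPosition" in cp and isocenter is None:
            isocenter = _pat_to_iec([float(v) for v in cp.IsocenterPosition])
        if "BeamLimitingDevicePositionSequence" not in cp:
            raise PlanParseError(f"{name}: missing aperture definition")
        jaw = mlc = None
        for item in cp.BeamLimitingDevicePositionSequence:
            t = item.RTBeamLimitingDeviceType
            vals = [float(v) for v in item.LeafJawPositions]
            if t in ("X", "ASYMX"):
                jaw = (vals[0], vals[1])
            elif t in ("MLCY", "MLCX"):
                mlc = vals
        if jaw is None:
            raise PlanParseError(f"{name}: missing jaw positions")
        if mlc is None:
            raise PlanParseError(f"{name}: missing MLC leaf positions")
        boundaries = None
        for bld in getattr(beam, "BeamLimitingDeviceSequence", []):
            if bld.RTBeamLimitingDeviceType.startswith("MLC"):
                boundaries = [float(v) for v in bld.LeafPositionBoundaries]
        if boundaries is None:
            raise PlanParseError(f"{name}: missing MLC leaf boundaries")
        n = len(boundaries) - 1
        bank1, bank2 = mlc[:n], mlc[n:]
        leaves = {}
        for j in range(n):
            a, b = bank1[j], bank2[j]
            if b - a < _CLOSED_LEAF_GAP_MM:
                continue
            center = 0.5 * (boundaries[j] + boundaries[j + 1])
            leaves[int(round(center / MLC_PITCH_MM))] = (a, b)
        beams.append(
            PlannedField(
                gantry_angle=float(cp.GantryAngle),
                jaw_edges=jaw,
                leaf_positions=leaves,
            )
        )
    if isocenter is None:
        raise PlanParseError("no IsocenterPosition in any control point")
    return RTPlanData(
        isocenter=isocenter,
        beams=beams,
        plan_label=str(getattr(ds, "RTPlanLabel", "")),
        frame_uid=str(getattr(ds, "FrameOfReferenceUID", "")),
    )


def parse_rt_plan(source) -> RTPlanData:
    """Parse a plan from a DICOM-RT Plan (dataset or file path), a JSON
    mirror (dict or file path), or pass an :class:`RTPlanData` through."""
    if isinstance(source, RTPlanData):
        return source
    if isinstance(source, Dataset):
        return _parse_dicom(source)
    if isinstance(source, dict):
        return _plan_from_dict(source)
    path = Path(source)
    if path.suffix.lower() == ".json":
        return _plan_from_dict(json.loads(path.read_text()))
    return _parse_dicom(pydicom.dcmread(path))


# ---------------------------------------------------------------------------
# derived quantities


def compute_plan_phantom_shift(
    adapted: RTPlanData, reference: RTPlanData
) -> Vec3IEC:
    """Plan phantom shift: the displacement of the adapted isocenter from
    the reference isocenter, both in the reference image frame."""
    if adapted.frame_uid and reference.frame_uid:
        if adapted.frame_uid != reference.frame_uid:
            raise PlanParseError(
                "plans reference different frames of reference: "
                f"{adapted.frame_uid!r} vs {reference.frame_uid!r}"
            )
    return adapted.isocenter - reference.isocenter


def planned_field_to_panel(
    field: PlannedField, geom: BeamGeometry, jaw_margin_mm: float = 2.0
) -> FieldMeasurement:
    """Express the planned aperture as the expected panel measurement.

    Static plan apertures are already defined in mm at the isocenter
    plane, so the mapping is an identity on the edge values.  Leaves whose
    projected center falls outside the panel coverage are excluded with a
    warning flag; jaw-shadowed leaves (profile strip not fully inside the
    jaw opening) produce no measurable edge and are excluded silently —
    they are not part of the expected measurement.
    """
    from .mv_analysis import N_EDGE_PROFILES

    half_u = 0.5 * geom.panel_fov_u
    strip_half = 0.5 * N_EDGE_PROFILES * geom.pixel_resolution
    flags = []
    leaves = {}
    for k, pair in field.leaf_positions.items():
        center = k * MLC_PITCH_MM
        if abs(center) > half_u:
            flags.append(f"leaf {k} outside panel coverage, excluded")
            continue
        if (
            center - strip_half - jaw_margin_mm < field.jaw_edges[0]
            or center + strip_half + jaw_margin_mm > field.jaw_edges[1]
        ):
            continue  # jaw-shadowed: no measurable edge
        leaves[k] = tuple(pair)
    if not leaves:
        raise PlanParseError("no planned leaf inside panel coverage")
    return FieldMeasurement(
        jaw_edges=tuple(field.jaw_edges),
        mlc_edges=leaves,
        field_center=FieldMeasurement.center_of(field.jaw_edges, leaves),
        flags=flags,
    )
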