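"""Configuration file handling.

One YAML (or JSON) document carries everything a site needs to fix about
its machine and its test: the beam geometry (SAD, panel pixel pitch, the
vendor-calibrated isocenter pixel per gantry angle), the detector
parameters, and the tolerance table with its baselines.  ``sad_mm`` has
no default — it is a machine calibration value the operator must supply
(the vendor's published value may be used).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .geometry import BeamGeometry, Vec3IEC
from .mr_analysis import MRDetectorConfig
from .mv_analysis import MVDetectorConfig
from .report import ToleranceConfig

__all__ = ["SuiteConfig", "load_config", "save_config", "geometry_to_dict", "geometry_from_dict"]


def geometry_to_dict(geom: BeamGeometry) -> dict:
    return {
        "sad_mm": geom.sad,
        "pixel_resolution_mm": geom.pixel_resolution,
        "panel_size_px": list(geom.panel_size_px),
        "isocenter_pixel": {
            str(angle): [float(u), float(v)]
            for angle, (u, v) in sorted(geom.isocenter_pixel.items())
        },
        "fov_margin_mm": geom.fov_margin_mm,
    }


def geometry_from_dict(d: dict) -> BeamGeometry:
    if "sad_mm" not in d:
        raise KeyError("geometry config must supply sad_mm (no default exists)")
    return BeamGeometry(
        sad=float(d["sad_mm"]),
        pixel_resolution=float(d["pixel_resolution_mm"]),
        isocenter_pixel={
            float(k): (float(v[0]), float(v[1]))
            for k, v in d["isocenter_pixel"].items()
        },
        panel_size_px=tuple(int(v) for v in d["panel_size_px"]),
        fov_margin_mm=float(d.get("fov_margin_mm", 5.0)),
    )


@dataclasses.dataclass
class SuiteConfig:
    geometry: BeamGeometry
    tolerances: ToleranceConfig = ToleranceConfig()
    mv_detector: MVDetectorConfig = MVDetectorConfig()
    mr_detector: MRDetectorConfig = MRDetectorConfig()


def _tol_to_dict(t: ToleranceConfig) -> dict:
    d = dataclasses.asdict(t)
    d["alignment_reference"] = [float(v) for v in t.alignment_reference.as_array()]
    d["couch_baseline_mm"] = [float(v) for v in t.couch_baseline_mm]
    return d


def _tol_from_dict(d: dict) -> ToleranceConfig:
    d = dict(d)
    if "alignment_reference" in d:
        d["alignment_reference"] = Vec3IEC.from_array(d["alignment_reference"])
    if "couch_baseline_mm" in d:
        d["couch_baseline_mm"] = tuple(d["couch_baseline_mm"])
    return ToleranceConfig(**d)


def save_config(cfg: SuiteConfig, path: str | Path) -> None:
    doc = {
        "geometry": geometry_to_dict(cfg.geometry),
        "tolerances": _tol_to_dict(cfg.tolerances),
        "mv_detector": dataclasses.asdict(cfg.mv_detector),
        "mr_detector": dataclasses.asdict(cfg.mr_detector),
    }
    text = (
        json.dumps(doc, indent=2, sort_keys=True)
        if str(path).endswith(".json")
        else yaml.safe_dump(doc, sort_keys=True)
    )
    Path(path).write_text(text)


def load_config(path: str | Path) -> SuiteConfig:
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return SuiteConfig(
        geometry=geometry_from_dict(doc["geometry"]),
        tolerances=_tol_from_dict(doc.get("tolerances", {})),
        mv_detector=MVDetectorConfig(**doc.get("mv_detector", {})),
        mr_detector=MRDetectorConfig(**doc.get("mr_detector", {})),
    )
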