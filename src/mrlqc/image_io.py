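"""File formats for MV images and MR volumes.

Two interchangeable on-disk representations are supported for each
modality:

* DICOM — RTIMAGE objects for MV portal images (pixel data, gantry angle
  and rescale tags) and an axial MR slice series (per-slice position /
  orientation tags; head-first supine, axis-aligned acquisitions only);
* a flat format — a raw little-endian float32 grid next to a JSON sidecar
  carrying the grid shape and geometry.  This is the native format of
  the synthetic-data generator.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import generate_uid

from .geometry import BeamGeometry, Vec3IEC
from .mr_analysis import MRVolume
from .mv_analysis import MVImage

__all__ = [
    "save_mv_flat",
    "load_mv_flat",
    "save_mv_dicom",
    "load_mv_image",
    "save_mr_flat",
    "load_mr_flat",
    "save_mr_dicom_series",
    "load_mr_dicom_series",
    "load_mr_volume",
]


# ---------------------------------------------------------------------------
# MV portal images


def save_mv_flat(img: MVImage, prefix: str | Path) -> Path:
    """Write ``<prefix>.bin`` (float32, row-major) + ``<prefix>.json``."""
    prefix = Path(prefix)
    img.pixels.astype("<f4").tofile(prefix.with_suffix(".bin"))
    sidecar = {
        "format": "mrlqc-mv-flat/1",
        "shape_vu": list(img.pixels.shape),
        "dtype": "<f4",
        "gantry_angle_deg": img.gantry_angle,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return prefix.with_suffix(".json")


def load_mv_flat(sidecar_path: str | Path, geom: BeamGeometry) -> MVImage:
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    shape = tuple(meta["shape_vu"])
    raw = np.fromfile(sidecar_path.with_suffix(".bin"), dtype=meta.get("dtype", "<f4"))
    return MVImage(
        pixels=raw.reshape(shape).astype(float),
        gantry_angle=float(meta["gantry_angle_deg"]),
        geom=geom,
    )


def save_mv_dicom(img: MVImage, path: str | Path) -> None:
    """Write an RTIMAGE with 16-bit pixels and rescale tags."""
    ds = Dataset()
    ds.SOPClassUID = pydicom.uid.RTImageStorage
    ds.SOPInstanceUID = generate_uid()
    ds.Modality = "RTIMAGE"
    ds.GantryAngle = img.gantry_angle
    lo, hi = float(img.pixels.min()), float(img.pixels.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    ds.Rows, ds.Columns = img.pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = scale
    ds.RescaleIntercept = lo
    ds.PixelData = np.round((img.pixels - lo) / scale).astype("<u2").tobytes()
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
    ds.file_meta = meta
    ds.save_as(path, enforce_file_format=True)


def load_mv_image(path: str | Path, geom: BeamGeometry) -> MVImage:
    """Load an MV image from an RTIMAGE file or a flat-format sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return load_mv_flat(path, geom)
    ds = pydicom.dcmread(path)
    px = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return MVImage(
        pixels=px * slope + intercept,
        gantry_angle=float(ds.GantryAngle),
        geom=geom,
    )


# ---------------------------------------------------------------------------
# MR volumes


def save_mr_flat(vol: MRVolume, prefix: str | Path) -> Path:
    prefix = Path(prefix)
    vol.voxels.astype("<f4").tofile(prefix.with_suffix(".bin"))
    sidecar = {
        "format": "mrlqc-mr-flat/1",
        "shape_xyz": list(vol.voxels.shape),
        "dtype": "<f4",
        "spacing_mm": list(vol.spacing),
        "origin_iec_mm": list(vol.origin.as_array()),
        "orientation": list(vol.orientation),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return prefix.with_suffix(".json")


def load_mr_flat(sidecar_path: str | Path) -> MRVolume:
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    shape = tuple(meta["shape_xyz"])
    raw = np.fromfile(sidecar_path.with_suffix(".bin"), dtype=meta.get("dtype", "<f4"))
    return MRVolume(
        voxels=raw.reshape(shape).astype(float),
        spacing=tuple(meta["spacing_mm"]),
        origin=Vec3IEC.from_array(meta["origin_iec_mm"]),
        orientation=tuple(meta.get("orientation", ("x", "y", "z"))),
    )


def save_mr_dicom_series(vol: MRVolume, directory: str | Path) -> None:
    """Write the volume as an axial DICOM series (HFS patient coords:
    one file per z_patient = y_IEC slice, rows along y_pat = -z_IEC,
    columns along x_pat = x_IEC)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vol = vol.canonical()
    series_uid = generate_uid()
    sx, sy, sz = vol.spacing
    nx, ny, nz = vol.voxels.shape
    o = vol.origin
    for iy in range(ny):
        # slice plane at IEC y; pixel grid (row=-z descending in IEC z)
        sl = vol.voxels[:, iy, ::-1].T  # (rows=z reversed, cols=x)
        ds = Dataset()
        ds.SOPClassUID = pydicom.uid.MRImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "MR"
        ds.PatientPosition = "HFS"
        ds.InstanceNumber = iy + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        z_top = o.z + (nz - 1) * sz  # most anterior voxel -> y_pat minimum
        ds.ImagePositionPatient = [o.x, -z_top, o.y + iy * sy]
        ds.PixelSpacing = [sz, sx]  # [row, col]
        ds.SliceThickness = sy
        lo, hi = float(sl.min()), float(sl.max())
        scale = (hi - lo) / 65535.0 if hi > lo else 1.0
        ds.Rows, ds.Columns = sl.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = scale
        ds.RescaleIntercept = lo
        ds.PixelData = np.round((sl - lo) / scale).astype("<u2").tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
        ds.file_meta = meta
        ds.save_as(directory / f"mr_{iy:04d}.dcm", enforce_file_format=True)


def load_mr_dicom_series(directory: str | Path) -> MRVolume:
    """Read an axis-aligned axial HFS MR series into the IEC frame.

    Oblique acquisitions (non-axis-aligned direction cosines) are
    rejected.
    """
    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    slices = [pydicom.dcmread(f) for f in files]
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    first = slices[0]
    iop = np.round(np.array(first.ImageOrientationPatient, float)).astype(int)
    if not (list(iop) == [1, 0, 0, 0, 1, 0]):
        raise ValueError("only axis-aligned axial acquisitions are supported")
    if getattr(first, "PatientPosition", "HFS") != "HFS":
        raise ValueError("only head-first supine series are supported")
    sy = float(slices[1].ImagePositionPatient[2]) - float(
        first.ImagePositionPatient[2]
    )
    sz, sx = (float(v) for v in first.PixelSpacing)
    stack = []
    for s in slices:
        slope = float(getattr(s, "RescaleSlope", 1.0))
        inter = float(getattr(s, "RescaleIntercept", 0.0))
        stack.append(s.pixel_array.astype(float) * slope + inter)
    arr = np.stack(stack, axis=0)  # (y, row=-z, col=x)
    vox = np.transpose(arr, (2, 0, 1))[:, :, ::-1]  # (x, y, z ascending)
    x0, ypat0, zpat0 = (float(v) for v in first.ImagePositionPatient)
    n_rows = arr.shape[1]
    origin = Vec3IEC(x0, zpat0, -(ypat0 + (n_rows - 1) * sz))
    return MRVolume(
        voxels=np.ascontiguousarray(vox),
        spacing=(sx, abs(sy), sz),
        origin=origin,
    )


def load_mr_volume(path: str | Path) -> MRVolume:
    """Load an MR volume from a flat sidecar file or a DICOM directory."""
    path = Path(path)
    if path.is_dir():
        return load_mr_dicom_series(path)
    return load_mr_flat(path)


# ---------------------------------------------------------------------------
# scenario bundles (a complete daily-run input set on disk)


def write_bundle(bundle, directory: str | Path) -> Path:
    """Write a simulated daily-run bundle: flat MV images, flat MR
    volume, the adapted and reference plans (JSON mirror), the machine
    geometry and the ground-truth manifest."""
    from .config import geometry_to_dict
    from .plan_io import write_plan_json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, img in enumerate(bundle.mv_images):
        save_mv_flat(img, directory / f"mv_{i}")
    save_mr_flat(bundle.mr_volume, directory / "mr")
    write_plan_json(bundle.adapted_plan, directory / "adapted_plan.json")
    write_plan_json(bundle.reference_plan, directory / "reference_plan.json")
    (directory / "geometry.json").write_text(
        json.dumps(geometry_to_dict(bundle.geom), indent=2, sort_keys=True)
    )
    (directory / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True)
    )
    return directory


def load_bundle(directory: str | Path):
    """Load a daily-run bundle written by :func:`write_bundle`."""
    from .config import geometry_from_dict
    from .plan_io import parse_rt_plan
    from .synthetic import ScenarioBundle

    directory = Path(directory)
    geom = geometry_from_dict(json.loads((directory / "geometry.json").read_text()))
    mv = [
        load_mv_flat(p, geom)
        for p in sorted(directory.glob("mv_*.json"))
        if not p.name.endswith(".bin")
    ]
    manifest = {}
    mpath = directory / "manifest.json"
    if mpath.exists():
        manifest = json.loads(mpath.read_text())
    return ScenarioBundle(
        mv_images=mv,
        mr_volume=load_mr_flat(directory / "mr.json"),
        adapted_plan=parse_rt_plan(directory / "adapted_plan.json"),
        reference_plan=parse_rt_plan(directory / "reference_plan.json"),
        manifest=manifest,
        geom=geom,
    )
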