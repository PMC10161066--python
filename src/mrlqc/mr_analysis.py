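"""Sub-voxel localization of signal-void fiducials in the 3D MR volume.

The phantom body gives bright signal on the T1-weighted volume while the
zirconium fiducials appear as spherical signal voids.  Each void is
localized by a three-stage coarse-to-fine procedure:

1. a sub-volume is cropped around an approximate position (seeded from
   the phantom corner plus the characterized fiducial offsets),
2. the sub-volume is averaged along x and along z to give two 2D images;
   after Sobel edge enhancement, 2D normalized cross-correlation against
   rendered void templates refines the center to the nearest voxel,
3. the two orthogonal slices through the refined center are Sobel
   filtered and sampled at 1/20 voxel resolution along 150 radial
   profiles; the void edge appears as two bright half circles (superior
   and inferior) whose points are fitted with quadratics — the parabola
   vertices give the sub-voxel center.

Volumes are stored in canonical IEC order: ``voxels[ix, iy, iz]`` with
``origin`` the IEC position (mm) of voxel (0, 0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import filters
from skimage.feature import match_template

from .geometry import Vec3IEC

__all__ = [
    "MRVolume",
    "MRFiducial",
    "MRDetectorConfig",
    "MRLocalizationResult",
    "PhantomNotFoundError",
    "MRFiducialNotFoundError",
    "find_phantom_corner",
    "localize_mr_fiducial",
    "localize_all_mr_fiducials",
]


class PhantomNotFoundError(RuntimeError):
    pass


class MRFiducialNotFoundError(RuntimeError):
    pass


_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class MRVolume:
    """A 3D MR intensity volume with its IEC geometry.

    ``orientation`` maps stored array axes to IEC axes as a signed
    permutation, e.g. ``("x", "y", "z")`` (canonical) or
    ``("-z", "x", "y")``; :meth:`canonical` reorders and flips the voxel
    grid into the canonical layout, adjusting origin and spacing.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: Vec3IEC
    orientation: tuple[str, str, str] = ("x", "y", "z")

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacings must be positive")
        names = [a.lstrip("-") for a in self.orientation]
        if sorted(names) != ["x", "y", "z"]:
            raise ValueError("orientation must be a signed permutation of x, y, z")

    def canonical(self) -> "MRVolume":
        """Return the volume reordered/flipped into (x, y, z) axis order."""
        if self.orientation == ("x", "y", "z"):
            return self
        vox = self.voxels
        spacing = list(self.spacing)
        origin = list(self.origin.as_array())
        # first flip reversed axes in place
        ori = list(self.orientation)
        for ax, name in enumerate(ori):
            if name.startswith("-"):
                vox = np.flip(vox, axis=ax)
                iec = _AXES[name[1:]]
                origin[iec] = origin[iec] - (vox.shape[ax] - 1) * spacing[ax]
                ori[ax] = name[1:]
        perm = [ori.index(a) for a in ("x", "y", "z")]
        vox = np.transpose(vox, perm)
        spacing = [spacing[p] for p in perm]
        return MRVolume(
            vox, tuple(spacing), Vec3IEC.from_array(origin), ("x", "y", "z")
        )

    # --- mm <-> index helpers (canonical volumes) ---
    def mm_to_index(self, p: Vec3IEC) -> np.ndarray:
        return (p.as_array() - self.origin.as_array()) / np.asarray(self.spacing)

    def index_to_mm(self, idx: Sequence[float]) -> Vec3IEC:
        a = self.origin.as_array() + np.asarray(idx, float) * np.asarray(self.spacing)
        return Vec3IEC.from_array(a)


@dataclass(frozen=True)
class MRFiducial:
    """A localized fiducial void: sub-voxel IEC position plus the RMS
    residual (mm) of the parabola fits used in the final stage."""

    position: Vec3IEC
    fit_quality: float
    flags: tuple[str, ...] = ()


@dataclass
class MRLocalizationResult:
    fiducials: dict[int, MRFiducial] = dc_field(default_factory=dict)
    errors: dict[int, str] = dc_field(default_factory=dict)


@dataclass(frozen=True)
class MRDetectorConfig:
    fiducial_diameter_mm: float = 6.0
    crop_factor: float = 3.0  # crop half-size = crop_factor/2 * diameter
    corner_threshold_fraction: float = 0.5
    ncc_floor: float = 0.3
    n_profiles: int = 150
    upsample_factor: int = 20
    profile_gradient_floor: float = 0.3  # fraction of slice max gradient
    vertex_half_angle_deg: float = 60.0  # profile angles used per half circle
    fit_quality_flag_mm: float = 0.3
    projection: str = "mean"  # or "median"


# ---------------------------------------------------------------------------
# phantom corner


def find_phantom_corner(
    vol: MRVolume, cfg: MRDetectorConfig | None = None
) -> Vec3IEC:
    """Locate the inferior-left-posterior corner of the phantom.

    The volume is flattened by maximum-intensity projection along each of
    two axes and thresholded at the configured fraction of the robust
    maximum; the minimal super-threshold extent along x, y and z gives
    the corner (the smallest coordinate on each IEC axis).
    """
    cfg = cfg or MRDetectorConfig()
    vol = vol.canonical()
    v = vol.voxels
    top = float(np.percentile(v, 99.9))
    if top <= 0:
        raise PhantomNotFoundError("phantom not found: no signal in volume")
    thr = cfg.corner_threshold_fraction * top
    proj_yz = v.max(axis=0)  # (iy, iz)
    proj_xz = v.max(axis=1)  # (ix, iz)
    if not (proj_yz > thr).any():
        raise PhantomNotFoundError("phantom not found: nothing above threshold")
    iy = int(np.nonzero((proj_yz > thr).any(axis=1))[0].min())
    iz = int(np.nonzero((proj_yz > thr).any(axis=0))[0].min())
    ix = int(np.nonzero((proj_xz > thr).any(axis=1))[0].min())
    return vol.index_to_mm((ix, iy, iz))


# ---------------------------------------------------------------------------
# void templates


def _void_projection_template(radius_vox: float, depth_vox: float) -> np.ndarray:
    """Sobel edge image of the mean projection of a spherical void."""
    n = 2 * int(np.ceil(radius_vox * 1.5)) + 1
    c = n // 2
    a, b = np.mgrid[0:n, 0:n]
    rho2 = (a - c) ** 2.0 + (b - c) ** 2.0
    chord = 2.0 * np.sqrt(np.maximum(radius_vox**2 - rho2, 0.0))
    dip = -chord / max(depth_vox, 1.0)  # darker where the void is
    return filters.sobel(dip)


# ---------------------------------------------------------------------------
# per-fiducial localization


def _ncc_peak(image: np.ndarray, template: np.ndarray, floor: float):
    if image.std() < 1e-12:
        return None
    ncc = match_template(image, template, pad_input=True, mode="constant")
    i, j = np.unravel_index(int(np.argmax(ncc)), ncc.shape)
    score = float(ncc[i, j])
    if score < floor:
        return None
    return (i, j, score)


def _half_circle_center(
    sob: np.ndarray,
    center_idx: tuple[float, float],
    spacing: tuple[float, float],
    radius_mm: float,
    cfg: MRDetectorConfig,
):
    """Sub-voxel void center on one Sobel slice from radial edge profiles.

    ``sob`` is indexed (h, vert) where vert is the inferior-superior (y)
    axis.  150 radial profiles are cast from the current center estimate;
    the edge radius on each is the maximum Sobel response sampled at a
    1/20-voxel step (cubic interpolation).  Edge points on the superior
    and inferior half circles near the vertical vertices are each fitted
    with a quadratic vert = f(h); the vertex abscissae average to the
    horizontal center and the vertex ordinates to the vertical center.

    Returns ((h_mm, vert_mm) center relative to slice origin, RMS fit
    residual mm) or None when too few valid edge points exist.
    """
    angles = np.linspace(0.0, 2 * np.pi, cfg.n_profiles, endpoint=False)
    step = min(spacing) / cfg.upsample_factor
    radii = np.arange(0.35 * radius_mm, 1.8 * radius_mm + step, step)
    ch, cv = center_idx
    # sample all profiles at once: coords in index units
    hh = (ch * spacing[0] + np.outer(np.cos(angles), radii)) / spacing[0]
    vv = (cv * spacing[1] + np.outer(np.sin(angles), radii)) / spacing[1]
    prof = ndimage.map_coordinates(sob, [hh, vv], order=3, mode="nearest")
    peak_idx = prof.argmax(axis=1)
    peak_val = prof[np.arange(len(angles)), peak_idx]
    good = peak_val >= cfg.profile_gradient_floor * peak_val.max()
    edge_r = radii[peak_idx]
    h_mm = ch * spacing[0] + edge_r * np.cos(angles)
    v_mm = cv * spacing[1] + edge_r * np.sin(angles)

    results = []
    resid = []
    for sign in (1.0, -1.0):  # superior, inferior half circles
        near_vertex = (
            np.abs(((np.degrees(angles) - sign * 90.0 + 180.0) % 360.0) - 180.0)
            <= cfg.vertex_half_angle_deg
        )
        sel = good & near_vertex
        if sel.sum() < 6:
            return None
        coeff, res, *_ = np.polyfit(h_mm[sel], v_mm[sel], 2, full=True)
        a, b, c = coeff
        if abs(a) < 1e-9:
            return None
        h_star = -b / (2 * a)
        v_star = c - b * b / (4 * a)
        results.append((h_star, v_star))
        resid.append(np.sqrt(res[0] / sel.sum()) if len(res) else 0.0)
    h_c = 0.5 * (results[0][0] + results[1][0])
    v_c = 0.5 * (results[0][1] + results[1][1])
    return (h_c, v_c), float(np.mean(resid))


def localize_mr_fiducial(
    vol: MRVolume, approx: Vec3IEC, cfg: MRDetectorConfig | None = None
) -> MRFiducial:
    """Localize one signal-void fiducial near ``approx`` (IEC mm)."""
    cfg = cfg or MRDetectorConfig()
    vol = vol.canonical()
    sp = np.asarray(vol.spacing)
    half_mm = 0.5 * cfg.crop_factor * cfg.fiducial_diameter_mm
    ci = vol.mm_to_index(approx)
    lo = np.floor(ci - half_mm / sp).astype(int)
    hi = np.ceil(ci + half_mm / sp).astype(int) + 1
    if (lo < 0).any() or (hi > np.asarray(vol.voxels.shape)).any():
        raise MRFiducialNotFoundError(
            f"crop window around {approx} extends outside the volume"
        )
    crop = vol.voxels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]

    proj = np.median if cfg.projection == "median" else np.mean
    radius_mm = 0.5 * cfg.fiducial_diameter_mm

    # ---- stage 2: projections along x and z, Sobel + NCC
    proj_x = proj(crop, axis=0)  # (iy, iz)
    proj_z = proj(crop, axis=2)  # (ix, iy)
    flags: list[str] = []
    centers = {}
    for name, img2d, axes in (("x", proj_x, (1, 2)), ("z", proj_z, (0, 1))):
        r_vox = radius_mm / float(np.mean(sp[list(axes)]))
        depth = crop.shape[0 if name == "x" else 2]
        tmpl = _void_projection_template(r_vox, depth)
        peak = _ncc_peak(filters.sobel(img2d), tmpl, cfg.ncc_floor)
        if peak is None:
            raise MRFiducialNotFoundError(
                f"fiducial near {approx} not found (projection along {name})"
            )
        centers[name] = peak
    # combine: x from the z-projection, z from the x-projection, y averaged
    stage2 = np.array(
        [
            centers["z"][0],
            0.5 * (centers["x"][0] + centers["z"][1]),
            centers["x"][1],
        ],
        dtype=float,
    )

    # ---- stage 3: orthogonal slices through the refined center
    est = stage2.copy()
    fit_q = 0.0
    for _ in range(2):  # one re-centering pass
        i0 = np.clip(np.round(est).astype(int), 0, np.asarray(crop.shape) - 1)
        slice_x = crop[i0[0], :, :]  # axes (y, z) -> (vert, h): transpose
        slice_z = crop[:, :, i0[2]]  # axes (x, y) = (h, vert)
        got = []
        for sob, h_ax, cidx, spc in (
            (filters.sobel(slice_x.T), 2, (est[2], est[1]), (sp[2], sp[1])),
            (filters.sobel(slice_z), 0, (est[0], est[1]), (sp[0], sp[1])),
        ):
            res = _half_circle_center(sob, cidx, spc, radius_mm, cfg)
            if res is None:
                raise MRFiducialNotFoundError(
                    f"void edge profiles unusable near {approx}"
                )
            (h_mm, v_mm), q = res
            got.append((h_ax, h_mm / spc[0], v_mm / spc[1], q))
        est = np.array(
            [
                got[1][1],  # x from the z-slice
                0.5 * (got[0][2] + got[1][2]),  # y from both slices
                got[0][1],  # z from the x-slice
            ]
        )
        fit_q = float(np.mean([g[3] for g in got]))

    if np.linalg.norm((est - stage2) * sp) > radius_mm:
        flags.append("stage-3 refinement moved > half void diameter from stage 2")
    if fit_q > cfg.fit_quality_flag_mm:
        flags.append(f"low-quality parabola fit (RMS {fit_q:.2f} mm)")
    pos = vol.index_to_mm(lo + est)
    return MRFiducial(position=pos, fit_quality=fit_q, flags=tuple(flags))


def localize_all_mr_fiducials(
    vol: MRVolume,
    model,
    cfg: MRDetectorConfig | None = None,
) -> MRLocalizationResult:
    """Localize every phantom fiducial, seeding each search from the
    phantom corner plus the characterized corner-relative offsets.

    ``model`` is a characterized phantom model (anything exposing
    ``corner_offsets``) or the offset sequence itself.
    """
    corner_offsets: Sequence[Vec3IEC] = getattr(model, "corner_offsets", model)
    cfg = cfg or MRDetectorConfig()
    vol = vol.canonical()
    corner = find_phantom_corner(vol, cfg)
    out = MRLocalizationResult()
    for i, off in enumerate(corner_offsets):
        try:
            out.fiducials[i] = localize_mr_fiducial(vol, corner + off, cfg)
        except MRFiducialNotFoundError as exc:
            out.errors[i] = f"fiducial {i}: {exc}"
    return out
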