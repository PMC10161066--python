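"""Machine coordinate conventions, the fiducial projection model, and
multi-angle triangulation.

All 3D quantities live in the IEC 61217 machine frame: for a head-first
supine patient, ``x`` runs left to right, ``y`` inferior to superior and
``z`` posterior to anterior, all in millimetres.  Gantry angles are IEC
61217 degrees (0 deg = beam entering from anterior, source above the
patient, rotating toward +x at 90 deg).

A fiducial (BB) inside the phantom is parameterised by cylindrical
coordinates about the gantry rotation axis: azimuth ``theta`` in the x-z
plane, radius ``r`` and longitudinal offset ``y``.  The convention,
enforced by the round-trip tests, is that ``theta == gantry_angle`` means
"fiducial displaced toward the source", i.e.::

    x = r * sin(theta),   z = r * cos(theta)

With the source at distance SAD from the isocenter, the projection of the
fiducial onto the MV panel, expressed in mm *at the isocenter plane*
relative to the gantry-angle-dependent isocenter pixel, is::

    u(phi) = SAD * r * sin(theta - phi) / (SAD - r * cos(theta - phi))
    v(phi) = SAD * y                    / (SAD - r * cos(theta - phi))

Panel ``u`` increases toward IEC +x at gantry 0 and ``v`` toward IEC +y.
Fitting (theta, r, y) to the observed (u, v) tracks across >= 2 gantry
angles recovers the 3D fiducial position (triangulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Vec3IEC",
    "BeamGeometry",
    "FiducialPolar",
    "PanelPoint",
    "TriangulationError",
    "project_fiducial",
    "pixels_to_isocenter_mm",
    "polar_to_iec",
    "iec_to_polar",
    "triangulate_fiducial",
]


class TriangulationError(RuntimeError):
    """Raised when a fiducial fit fails (degenerate angles, divergence)."""


@dataclass(frozen=True)
class Vec3IEC:
    """A point or displacement in the IEC 61217 frame, millimetres."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError("Vec3IEC components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @staticmethod
    def from_array(a: Sequence[float]) -> "Vec3IEC":
        a = np.asarray(a, dtype=float)
        return Vec3IEC(float(a[0]), float(a[1]), float(a[2]))

    def __add__(self, other: "Vec3IEC") -> "Vec3IEC":
        return Vec3IEC(self.x + other.x, self.y + other.y, self.z + other.z)

    def __sub__(self, other: "Vec3IEC") -> "Vec3IEC":
        return Vec3IEC(self.x - other.x, self.y - other.y, self.z - other.z)


@dataclass(frozen=True)
class BeamGeometry:
    """Projection geometry of the MV imaging chain.

    Parameters
    ----------
    sad:
        Source-axis distance in mm.  There is no default: it is a machine
        calibration value that must come from configuration (operators of
        a given machine use the vendor's published value).
    pixel_resolution:
        Panel pixel size expressed in mm/pixel *at the isocenter plane*.
    isocenter_pixel:
        Mapping gantry angle (deg) -> (u_px, v_px), the vendor-calibrated
        panel pixel onto which a fiducial at the isocenter projects.
    panel_size_px:
        (n_u, n_v) panel dimensions in pixels; pixel (0, 0) is the first
        column/row, pixel centers sit at integer coordinates.
    """

    sad: float
    pixel_resolution: float
    isocenter_pixel: Mapping[float, tuple[float, float]]
    panel_size_px: tuple[int, int]
    fov_margin_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.sad <= 0:
            raise ValueError("sad must be positive")
        if self.pixel_resolution <= 0:
            raise ValueError("pixel_resolution must be positive")

    @property
    def panel_fov_u(self) -> float:
        """Panel field of view along u at the isocenter plane, mm."""
        return self.panel_size_px[0] * self.pixel_resolution

    @property
    def panel_fov_v(self) -> float:
        return self.panel_size_px[1] * self.pixel_resolution

    def iso_pixel(self, gantry_angle: float) -> tuple[float, float]:
        key = _angle_key(gantry_angle, self.isocenter_pixel)
        if key is None:
            raise KeyError(
                f"no isocenter pixel calibrated for gantry angle {gantry_angle}"
            )
        u, v = self.isocenter_pixel[key]
        return float(u), float(v)

    def pixel_to_iso_mm(
        self, u_px: float, v_px: float, gantry_angle: float
    ) -> tuple[float, float]:
        """Panel pixel indices -> mm at the isocenter plane, relative to
        the isocenter pixel."""
        iu, iv = self.iso_pixel(gantry_angle)
        return (
            pixels_to_isocenter_mm(u_px - iu, self),
            pixels_to_isocenter_mm(v_px - iv, self),
        )

    def iso_mm_to_pixel(
        self, u_mm: float, v_mm: float, gantry_angle: float
    ) -> tuple[float, float]:
        iu, iv = self.iso_pixel(gantry_angle)
        return (u_mm / self.pixel_resolution + iu, v_mm / self.pixel_resolution + iv)


def _angle_key(angle: float, table: Mapping[float, tuple[float, float]], tol=0.01):
    """Match a gantry angle against the calibration table modulo 360."""
    for key in table:
        d = (float(key) - float(angle) + 180.0) % 360.0 - 180.0
        if abs(d) <= tol:
            return key
    return None


@dataclass(frozen=True)
class FiducialPolar:
    """Cylindrical fiducial coordinates about the gantry rotation axis."""

    theta: float  # deg, azimuth in the x-z plane (theta = 0 -> +z)
    r: float  # mm, radial distance from the rotation axis
    y: float  # mm, longitudinal (inferior-superior) offset
    theta_defined: bool = True  # False when r ~ 0 (azimuth unidentifiable)

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("radial distance r must be non-negative")
        object.__setattr__(self, "theta", float(self.theta) % 360.0)


@dataclass(frozen=True)
class PanelPoint:
    """A fiducial projection on the MV panel, mm at the isocenter plane."""

    u_iso: float
    v_iso: float
    gantry_angle: float


@dataclass(frozen=True)
class GantryProjectionSet:
    """Projections of one physical fiducial across >= 2 gantry angles."""

    points: tuple[PanelPoint, ...]

    def __post_init__(self) -> None:
        angles = [p.gantry_angle % 360.0 for p in self.points]
        if len(set(np.round(angles, 6))) < 2:
            raise ValueError("need projections from >= 2 distinct gantry angles")


def pixels_to_isocenter_mm(pixel_offset: float, geom: BeamGeometry) -> float:
    """Convert a panel pixel offset to mm at the isocenter plane."""
    return float(pixel_offset) * geom.pixel_resolution


def project_fiducial(
    f: FiducialPolar, gantry_angle: float, geom: BeamGeometry
) -> PanelPoint:
    """Project a fiducial onto the MV panel at one gantry angle.

    Returns the projection in mm at the isocenter plane relative to the
    isocenter pixel.  Requires ``r < SAD`` (the fiducial must sit between
    the source and the panel).
    """
    if f.r >= geom.sad:
        raise ValueError(f"r={f.r} mm >= SAD={geom.sad} mm: degenerate projection")
    u, v = _project_arrays(f.theta, f.r, f.y, np.asarray([gantry_angle]), geom.sad)
    return PanelPoint(float(u[0]), float(v[0]), float(gantry_angle))


def _project_arrays(theta, r, y, phi_deg, sad):
    d = np.radians(np.asarray(theta) - np.asarray(phi_deg))
    denom = sad - r * np.cos(d)
    return sad * r * np.sin(d) / denom, sad * np.asarray(y) / denom


def polar_to_iec(f: FiducialPolar) -> Vec3IEC:
    """Cylindrical -> Cartesian IEC: x = r sin(theta), z = r cos(theta)."""
    t = np.radians(f.theta)
    return Vec3IEC(f.r * np.sin(t), f.y, f.r * np.cos(t))


def iec_to_polar(p: Vec3IEC) -> FiducialPolar:
    """Inverse of :func:`polar_to_iec` (theta undefined at r = 0)."""
    r = float(np.hypot(p.x, p.z))
    if r == 0.0:
        return FiducialPolar(0.0, 0.0, p.y, theta_defined=False)
    theta = float(np.degrees(np.arctan2(p.x, p.z))) % 360.0
    return FiducialPolar(theta, r, p.y)


# radial distances below this are reported as r = 0 with theta undefined
_R_DEGENERATE_MM = 1e-6


def triangulate_fiducial(
    projections: GantryProjectionSet | Iterable[PanelPoint],
    geom: BeamGeometry,
) -> tuple[FiducialPolar, Vec3IEC, float]:
    """Fit (theta, r, y) to panel projections observed at >= 2 gantry angles.

    The fit is a joint bounded nonlinear least squares on the (u, v)
    residuals in mm, initialised from a coarse grid over theta (10 deg
    steps) with per-candidate linear estimates of r and y; the candidate
    with the lowest residual seeds the refinement.  Returns the fitted
    cylindrical coordinates, their Cartesian conversion and the RMS fit
    residual in mm on the panel.
    """
    if isinstance(projections, GantryProjectionSet):
        pts = projections.points
    else:
        pts = tuple(projections)
        GantryProjectionSet(pts)  # validates distinct angles

    phi = np.array([p.gantry_angle for p in pts], dtype=float)
    u = np.array([p.u_iso for p in pts], dtype=float)
    v = np.array([p.v_iso for p in pts], dtype=float)
    sad = geom.sad

    def residuals(params):
        theta, r, y = params
        um, vm = _project_arrays(theta, r, y, phi, sad)
        return np.concatenate([um - u, vm - v])

    # Coarse grid over theta; linear small-r/SAD estimates of r and y.
    best = None
    for theta0 in np.arange(0.0, 360.0, 10.0):
        s = np.sin(np.radians(theta0 - phi))
        ss = float(s @ s)
        r0 = float(s @ u / ss) if ss > 1e-12 else 0.0
        if r0 < 0:
            continue  # the mirrored candidate theta0+180 covers this
        r0 = min(r0, 0.9 * sad)
        y0 = float(np.mean(v))
        cost = float(np.sum(residuals([theta0, r0, y0]) ** 2))
        if best is None or cost < best[0]:
            best = (cost, [theta0, r0, y0])
    assert best is not None

    sol = least_squares(
        residuals,
        best[1],
        bounds=([-360.0, 0.0, -np.inf], [720.0, 0.95 * sad, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        raise TriangulationError(f"triangulation failed to converge: {sol.message}")

    theta, r, y = sol.x
    res = sol.fun
    rms = float(np.sqrt(np.mean(res**2)))
    if r < _R_DEGENERATE_MM:
        polar = FiducialPolar(0.0, 0.0, y, theta_defined=False)
    else:
        polar = FiducialPolar(theta % 360.0, r, y)
    return polar, polar_to_iec(polar), rms
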