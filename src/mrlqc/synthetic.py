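"""Synthetic phantom, image and plan generator.

Everything the QC suite consumes can be generated here with known ground
truth: a parametric 7-fiducial phantom (three fiducials on an equilateral
triangle on an inferior plane, four on a superior plane), forward
projected MV portal images with rectangular apertures, penumbra and
attenuation, an MR volume with signal-void fiducials, a couch index-bar
marker on the gantry-0 image, and matching reference / adapted plans.

The forward model is deliberately geometric rather than dosimetric: the
aperture fluence has analytic error-function penumbra (so the true 50%
edge position is exact, not rasterized), attenuation is an exponential
line integral through the cylindrical body and the dense fiducials with
no scatter, and the couch marker is a small dense sphere.  MV noise is
additive Gaussian; MR noise is Rician (magnitude of a complex Gaussian).

Every rendered ground-truth quantity is recorded in the scenario
manifest; tests read truth from the manifest, never from anywhere else.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .geometry import BeamGeometry, Vec3IEC, iec_to_polar, project_fiducial
from .mr_analysis import MRVolume
from .mv_analysis import MVImage
from .plan_io import MLC_PITCH_MM, PlannedField, RTPlanData

__all__ = [
    "SyntheticPhantomSpec",
    "ApertureError",
    "ScenarioSpec",
    "ScenarioBundle",
    "default_geometry",
    "default_reference_field",
    "render_mv_image",
    "render_mr_volume",
    "render_characterization_arc",
    "build_scenario_bundle",
    "adapt_plan",
]

_REFERENCE_FRAME_UID = "2.25.730462832872385573299832385017"


# ---------------------------------------------------------------------------
# specs


def _triangle(
    center: tuple[float, float], rot_deg: float, circumradius: float, y: float
) -> list[Vec3IEC]:
    """Equilateral triangle in the x-z plane at height y."""
    return [
        Vec3IEC(
            center[0] + circumradius * math.sin(math.radians(rot_deg + k * 120)),
            y,
            center[1] + circumradius * math.cos(math.radians(rot_deg + k * 120)),
        )
        for k in range(3)
    ]


@dataclass(frozen=True)
class SyntheticPhantomSpec:
    """Parametric MR-to-MV phantom.

    ``fiducial_positions`` are in the phantom frame (origin at the body
    center, IEC axis orientation).  The defaults are a desk-scale but
    geometrically representative stand-in for the vendor phantom: a
    bright/attenuating cylinder (axis along y) carrying three fiducials
    on an inferior-plane equilateral triangle and four on a superior
    plane (an equilateral triangle plus one offset fiducial); the in-plane
    placement keeps the two targeted (most anterior superior) fiducials
    well separated from every other fiducial on the panel at the cardinal
    gantry angles.
    """

    fiducial_positions: tuple[Vec3IEC, ...]
    fiducial_diameter: float = 6.0  # mm
    body_radius: float = 60.0  # mm
    body_length: float = 120.0  # mm, along y
    body_attenuation: float = 0.005  # per mm (MV)
    fiducial_attenuation: float = 0.08  # per mm (MV)
    mr_signal: float = 1.0
    setup_offset: Vec3IEC = Vec3IEC(0.0, -18.0, 0.0)  # phantom center rel. isocenter

    @staticmethod
    def default() -> "SyntheticPhantomSpec":
        # The in-plane placement is chosen so that no two same-plane
        # fiducials project onto nearby panel positions at the four
        # cardinal (daily) gantry angles, and so that the default
        # characterization arc below keeps every pair well separated
        # (projection tracks of coplanar fiducials inevitably cross at
        # gantry angles set by their difference-vector azimuths).
        inferior = _triangle((0.0, -11.0), 49.0, 24.0, -25.0)
        superior = _triangle((9.0, -6.0), 42.0, 24.0, 25.0) + [
            Vec3IEC(-34.0, 25.0, -10.0)
        ]
        return SyntheticPhantomSpec(fiducial_positions=tuple(inferior + superior))

    @property
    def corner(self) -> Vec3IEC:
        """Inferior-left-posterior corner of the body (phantom frame)."""
        return Vec3IEC(-self.body_radius, -0.5 * self.body_length, -self.body_radius)

    @property
    def corner_offsets(self) -> tuple[Vec3IEC, ...]:
        return tuple(p - self.corner for p in self.fiducial_positions)

    @property
    def corner_to_mean(self) -> Vec3IEC:
        mean = Vec3IEC.from_array(
            np.mean([p.as_array() for p in self.fiducial_positions], axis=0)
        )
        return mean - self.corner

    def __post_init__(self) -> None:
        ys = sorted({round(p.y, 6) for p in self.fiducial_positions})
        if len(self.fiducial_positions) != 7 or len(ys) != 2:
            raise ValueError("phantom needs 7 fiducials on exactly two planes")
        inferior = [p for p in self.fiducial_positions if round(p.y, 6) == ys[0]]
        superior = [p for p in self.fiducial_positions if round(p.y, 6) == ys[1]]
        if len(inferior) != 3 or len(superior) != 4:
            raise ValueError("planes must carry 3 (inferior) + 4 (superior) fiducials")
        sides = sorted(
            math.hypot(a.x - b.x, a.z - b.z)
            for a, b in itertools.combinations(inferior, 2)
        )
        if sides[-1] - sides[0] > 1e-3:
            raise ValueError("inferior fiducials must form an equilateral triangle")
        for p in self.fiducial_positions:
            if math.hypot(p.x, p.z) > self.body_radius or abs(p.y) > self.body_length / 2:
                raise ValueError(f"fiducial {p} outside the phantom body")


@dataclass(frozen=True)
class ApertureError:
    """Delivered-vs-planned aperture faults for one field (mm)."""

    jaw_offsets: tuple[float, float] = (0.0, 0.0)
    mlc_bank_offset: float = 0.0  # both edges of every leaf
    leaf_offsets: Mapping[int, tuple[float, float]] = dc_field(default_factory=dict)


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulated daily run.

    ``phantom_shift`` is the true physical phantom translation from the
    reference setup (IEC mm).  The simulated online registration detects
    ``phantom_shift - alignment_delta + registration_error`` (a change of
    the MR-to-MV alignment displaces the phantom in the MR frame), and
    the adapt-to-position plan translates the apertures by that amount.
    ``aperture_errors`` (keyed by field index) apply to the *delivered*
    fields only, emulating transfer or positioning faults.
    """

    phantom_shift: Vec3IEC = Vec3IEC(0, 0, 0)
    couch_shift: tuple[float, float] = (0.0, 0.0)  # (du, dv) mm
    registration_error: Vec3IEC = Vec3IEC(0, 0, 0)
    alignment_delta: Vec3IEC = Vec3IEC(0, 0, 0)
    aperture_errors: Mapping[int, ApertureError] = dc_field(default_factory=dict)
    mv_noise_sigma: float = 0.01  # fraction of open-field intensity
    mr_noise_sigma: float = 0.03  # fraction of body signal
    penumbra_sigma_px: float = 1.5
    seed: int = 0


# ---------------------------------------------------------------------------
# machine / plan defaults

#: IEC panel field of view at the isocenter plane: 220 mm left-right (u),
#: 95 mm superior-inferior (v); pixel pitch 0.2163 mm at the isocenter.
PIXEL_RESOLUTION_MM = 0.2163
PANEL_SIZE_PX = (1017, 439)  # (n_u, n_v)
SAD_MM = 1435.0
PLAN_GANTRY_ANGLES = (0.0, 90.0, 180.0, 270.0)

#: default characterization arc: 31 gantry angles at 3 deg spacing in four
#: blocks around the circle, chosen (like the vendor set-to-work arc, which
#: avoids unusable regions) so no two coplanar fiducial projections approach
#: within 7.5 mm on the panel at any arc angle
DEFAULT_ARC_ANGLES = tuple(
    float(a)
    for block in ((90, 102), (153, 180), (210, 225), (330, 357))
    for a in range(block[0], block[1] + 1, 3)
)

#: couch marker baseline sits between MLC leaf-center profile strips and
#: below the jaw-profile rows so it never perturbs edge detection
COUCH_MARKER_BASELINE_MM = (3.575, -10.0)  # (u, v) at the isocenter plane
COUCH_MARKER_DIAMETER_MM = 2.0
COUCH_MARKER_ATTENUATION = 0.5  # per mm


def default_geometry(angles: Sequence[float] = PLAN_GANTRY_ANGLES) -> BeamGeometry:
    """Beam geometry of the simulated machine; the isocenter pixel sits
    at the panel center for every gantry angle."""
    center = ((PANEL_SIZE_PX[0] - 1) / 2.0, (PANEL_SIZE_PX[1] - 1) / 2.0)
    return BeamGeometry(
        sad=SAD_MM,
        pixel_resolution=PIXEL_RESOLUTION_MM,
        isocenter_pixel={float(a) % 360.0: center for a in angles},
        panel_size_px=PANEL_SIZE_PX,
    )


def default_reference_field(gantry_angle: float) -> PlannedField:
    """The reference rectangular field: jaws at +/-40 mm (u), leaves -6..6
    open with tips at (-20, +20) mm (v).  The open leaf bank extends past
    the jaws so the u field edges are jaw-defined; the outermost leaves
    are jaw-shadowed and not expected to be measurable."""
    return PlannedField(
        gantry_angle=gantry_angle,
        jaw_edges=(-40.0, 40.0),
        leaf_positions={k: (-20.0, 20.0) for k in range(-6, 7)},
    )


def default_reference_plan(isocenter: Vec3IEC = Vec3IEC(0, 0, 0)) -> RTPlanData:
    """Reference plan; ``isocenter`` is the machine isocenter expressed
    in the reference MR image frame (non-zero when the commissioned
    MR-to-MV alignment is non-zero)."""
    return RTPlanData(
        isocenter=isocenter,
        beams=[default_reference_field(a) for a in PLAN_GANTRY_ANGLES],
        plan_label="E2E reference",
        frame_uid=_REFERENCE_FRAME_UID,
    )


def _panel_shift(shift: Vec3IEC, gantry_angle: float) -> tuple[float, float]:
    """An IEC translation expressed on the panel at one gantry angle."""
    phi = math.radians(gantry_angle)
    return (shift.x * math.cos(phi) - shift.z * math.sin(phi), shift.y)


def adapt_plan(
    reference: RTPlanData, registration_shift: Vec3IEC
) -> RTPlanData:
    """Adapt-to-position: translate every aperture to follow the
    registration shift (jaws continuously along u, leaf re-selection for
    the u component, leaf tips along v) and move the plan isocenter by
    the shift in the reference image frame."""
    beams = []
    for b in reference.beams:
        du, dv = _panel_shift(registration_shift, b.gantry_angle)
        jaw = (b.jaw_edges[0] + du, b.jaw_edges[1] + du)
        v_pairs = {k: v for k, v in b.leaf_positions.items()}
        # representative leaf opening (reference fields share one pair)
        vals = list(v_pairs.values())
        leaves = {}
        for k in range(-30, 31):
            center = k * MLC_PITCH_MM
            # keep the open bank one leaf wider than the jaws so the u
            # field edges stay jaw-defined, as in the reference plan
            if jaw[0] - MLC_PITCH_MM <= center <= jaw[1] + MLC_PITCH_MM:
                pair = v_pairs.get(k, vals[0])
                leaves[k] = (pair[0] + dv, pair[1] + dv)
        beams.append(PlannedField(b.gantry_angle, jaw, leaves))
    return RTPlanData(
        isocenter=reference.isocenter + registration_shift,
        beams=beams,
        plan_label=reference.plan_label + " (ATP)",
        frame_uid=reference.frame_uid,
    )


def _apply_aperture_error(field: PlannedField, err: ApertureError) -> PlannedField:
    jaw = (
        field.jaw_edges[0] + err.jaw_offsets[0],
        field.jaw_edges[1] + err.jaw_offsets[1],
    )
    leaves = {}
    for k, (a, b) in field.leaf_positions.items():
        da, db = err.leaf_offsets.get(k, (0.0, 0.0))
        leaves[k] = (a + err.mlc_bank_offset + da, b + err.mlc_bank_offset + db)
    return PlannedField(field.gantry_angle, jaw, leaves)


# ---------------------------------------------------------------------------
# MV rendering


def _smooth_step(x: np.ndarray, sigma: float) -> np.ndarray:
    """0 -> 1 transition with the 50% point at x = 0 (Gaussian-blurred
    ideal edge)."""
    return 0.5 * (1.0 + erf(x / (math.sqrt(2.0) * sigma)))


def render_mv_image(
    spec: SyntheticPhantomSpec,
    field: PlannedField,
    scenario: ScenarioSpec,
    geom: BeamGeometry,
    phantom_center: Vec3IEC | None = None,
    include_couch_marker: bool | None = None,
    rng: np.random.Generator | None = None,
    truth: dict | None = None,
) -> MVImage:
    """Forward-project one MV portal image of the delivered ``field``.

    ``field`` is the aperture actually delivered (aperture errors already
    applied).  ``phantom_center`` is the phantom body center in the
    machine frame; it defaults to the reference setup plus the scenario's
    phantom shift.  When ``truth`` is supplied, per-image ground-truth
    quantities are appended to it.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    if phantom_center is None:
        phantom_center = spec.setup_offset + scenario.phantom_shift
    phi = field.gantry_angle
    if include_couch_marker is None:
        include_couch_marker = abs(phi % 360.0) < 1e-6

    n_u, n_v = geom.panel_size_px
    iso_u, iso_v = geom.iso_pixel(phi)
    pr = geom.pixel_resolution
    u_mm = (np.arange(n_u) - iso_u) * pr  # (n_u,)
    v_mm = (np.arange(n_v) - iso_v) * pr  # (n_v,)
    sig = scenario.penumbra_sigma_px * pr

    # aperture fluence with analytic penumbra
    jaw = _smooth_step(u_mm - field.jaw_edges[0], sig) * _smooth_step(
        field.jaw_edges[1] - u_mm, sig
    )
    v1 = np.full(n_u, np.inf)
    v2 = np.full(n_u, -np.inf)
    leaf_idx = np.round(u_mm / MLC_PITCH_MM).astype(int)
    for k, (a, b) in field.leaf_positions.items():
        sel = leaf_idx == k
        v1[sel], v2[sel] = a, b
    with np.errstate(invalid="ignore"):
        mlc = _smooth_step(v_mm[:, None] - v1[None, :], sig) * _smooth_step(
            v2[None, :] - v_mm[:, None], sig
        )
    mlc[:, ~np.isfinite(v1)] = 0.0
    fluence = mlc * jaw[None, :]

    # phantom body: chord through a cylinder (axis along y), parallel-beam
    # approximation for the broad background
    cphi = math.cos(math.radians(phi))
    sphi = math.sin(math.radians(phi))
    u_c = phantom_center.x * cphi - phantom_center.z * sphi
    du = u_mm - u_c
    chord = 2.0 * np.sqrt(np.maximum(spec.body_radius**2 - du**2, 0.0))
    in_y = (np.abs(v_mm - phantom_center.y) <= spec.body_length / 2).astype(float)
    trans = np.exp(-spec.body_attenuation * chord[None, :] * in_y[:, None])

    # fiducials: divergent projection of dense spheres
    fid_truth = []
    r_f = spec.fiducial_diameter / 2.0
    for p in spec.fiducial_positions:
        pos = p + phantom_center
        polar = iec_to_polar(pos)
        proj = project_fiducial(polar, phi, geom)
        mag = geom.sad / (geom.sad - polar.r * math.cos(math.radians(polar.theta - phi)))
        _attenuate_sphere(
            trans, u_mm, v_mm, proj.u_iso, proj.v_iso, mag, r_f,
            spec.fiducial_attenuation,
        )
        inside = (
            field.jaw_edges[0] + r_f * mag < proj.u_iso < field.jaw_edges[1] - r_f * mag
        )
        if np.isfinite(v1).any():
            k = int(round(proj.u_iso / MLC_PITCH_MM))
            pair = field.leaf_positions.get(k)
            inside = inside and pair is not None and (
                pair[0] + r_f * mag < proj.v_iso < pair[1] - r_f * mag
            )
        fid_truth.append(
            {
                "u_iso_mm": proj.u_iso,
                "v_iso_mm": proj.v_iso,
                "u_px": proj.u_iso / pr + iso_u,
                "v_px": proj.v_iso / pr + iso_v,
                "inside_aperture": bool(inside),
            }
        )

    marker_truth = None
    if include_couch_marker:
        mu = COUCH_MARKER_BASELINE_MM[0] + scenario.couch_shift[0]
        mv = COUCH_MARKER_BASELINE_MM[1] + scenario.couch_shift[1]
        _attenuate_sphere(
            trans, u_mm, v_mm, mu, mv, 1.0,
            COUCH_MARKER_DIAMETER_MM / 2.0, COUCH_MARKER_ATTENUATION,
        )
        marker_truth = {
            "u_iso_mm": mu,
            "v_iso_mm": mv,
            "u_px": mu / pr + iso_u,
            "v_px": mv / pr + iso_v,
        }

    img = fluence * trans
    if scenario.mv_noise_sigma > 0:
        img = img + rng.normal(0.0, scenario.mv_noise_sigma, img.shape)

    if truth is not None:
        truth.setdefault("mv_images", []).append(
            {
                "gantry_angle_deg": phi,
                "fiducials": fid_truth,
                "couch_marker": marker_truth,
                "delivered_jaw_edges_mm": list(field.jaw_edges),
                "delivered_mlc_edges_mm": {
                    str(k): list(v) for k, v in sorted(field.leaf_positions.items())
                },
            }
        )
    return MVImage(pixels=img, gantry_angle=phi, geom=geom)


def _attenuate_sphere(trans, u_mm, v_mm, u0, v0, mag, radius, mu) -> None:
    """Multiply ``trans`` in place by the transmission of a dense sphere
    projected at (u0, v0) with magnification ``mag``; the impact
    parameter of a panel ray is the isocenter-plane distance divided by
    the magnification."""
    r_iso = radius * mag
    pad = r_iso + 1.0
    ui = np.nonzero(np.abs(u_mm - u0) <= pad)[0]
    vi = np.nonzero(np.abs(v_mm - v0) <= pad)[0]
    if ui.size == 0 or vi.size == 0:
        return
    uu = (u_mm[ui][None, :] - u0) / mag
    vv = (v_mm[vi][:, None] - v0) / mag
    b2 = uu**2 + vv**2
    chord = 2.0 * np.sqrt(np.maximum(radius**2 - b2, 0.0))
    trans[np.ix_(vi, ui)] *= np.exp(-mu * chord)


def render_characterization_arc(
    spec: SyntheticPhantomSpec,
    angles: Sequence[float] = DEFAULT_ARC_ANGLES,
    noise_sigma: float = 0.01,
    seed: int = 0,
) -> tuple[list[MVImage], BeamGeometry, dict]:
    """Render the phantom-characterization arc (default: the vendor-style
    31 images, 3 deg apart) with the phantom centered on the isocenter
    and a wide-open field."""
    geom = default_geometry(angles)
    rng = np.random.default_rng(seed)
    scenario = ScenarioSpec(mv_noise_sigma=noise_sigma, seed=seed)
    wide = PlannedField(
        gantry_angle=0.0,
        jaw_edges=(-65.0, 65.0),
        leaf_positions={k: (-40.0, 40.0) for k in range(-9, 10)},
    )
    truth: dict = {}
    images = []
    for a in angles:
        f = replace_angle(wide, a)
        images.append(
            render_mv_image(
                spec, f, scenario, geom,
                phantom_center=Vec3IEC(0, 0, 0),
                include_couch_marker=False,
                rng=rng, truth=truth,
            )
        )
    return images, geom, truth


def replace_angle(field: PlannedField, angle: float) -> PlannedField:
    return PlannedField(angle, field.jaw_edges, dict(field.leaf_positions))


# ---------------------------------------------------------------------------
# MR rendering

MR_SPACING_MM = (1.0, 1.0, 1.0)
MR_MARGIN_MM = 15.0
MR_EDGE_SIGMA_MM = 0.6


def render_mr_volume(
    spec: SyntheticPhantomSpec,
    scenario: ScenarioSpec,
    alignment: Vec3IEC = Vec3IEC(0, 0, 0),
    rng: np.random.Generator | None = None,
    truth: dict | None = None,
) -> MRVolume:
    """Render the daily MR volume in the MR frame.

    The MR frame is the machine frame displaced by the MR-to-MV
    ``alignment``: a point at machine coordinates p appears at p -
    alignment in the image.  The field of view is fixed relative to the
    MR frame (centered on the reference phantom position) so phantom
    translations move the phantom within the volume.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 104729)
    center_machine = spec.setup_offset + scenario.phantom_shift
    center = center_machine - alignment  # MR frame
    ref_center = spec.setup_offset  # FOV anchored at the reference setup
    half = np.array(
        [
            spec.body_radius + MR_MARGIN_MM,
            spec.body_length / 2 + MR_MARGIN_MM,
            spec.body_radius + MR_MARGIN_MM,
        ]
    )
    sp = np.asarray(MR_SPACING_MM)
    origin = ref_center.as_array() - half
    shape = np.ceil(2 * half / sp).astype(int) + 1

    if np.abs(center.as_array() - ref_center.as_array()).max() > MR_MARGIN_MM - 5.0:
        raise ValueError(
            "scenario moves the phantom by more than the volume margin: clipped FOV"
        )

    xs = origin[0] + sp[0] * np.arange(shape[0])
    ys = origin[1] + sp[1] * np.arange(shape[1])
    zs = origin[2] + sp[2] * np.arange(shape[2])
    rho = np.sqrt(
        (xs[:, None] - center.x) ** 2 + (zs[None, :] - center.z) ** 2
    )  # (nx, nz)
    radial = _smooth_step(spec.body_radius - rho, MR_EDGE_SIGMA_MM)
    axial = _smooth_step(
        spec.body_length / 2 - np.abs(ys - center.y), MR_EDGE_SIGMA_MM
    )
    vol = spec.mr_signal * radial[:, None, :] * axial[None, :, None]

    r_f = spec.fiducial_diameter / 2.0
    for p in spec.fiducial_positions:
        c = (p + center).as_array()
        _carve_void(vol, xs, ys, zs, c, r_f)

    if scenario.mr_noise_sigma > 0:
        s = scenario.mr_noise_sigma * spec.mr_signal
        vol = np.hypot(vol + rng.normal(0, s, vol.shape), rng.normal(0, s, vol.shape))

    if truth is not None:
        truth["mr"] = {
            "fiducial_positions_mr_mm": [
                list((p + center).as_array()) for p in spec.fiducial_positions
            ],
            "phantom_corner_mr_mm": list((spec.corner + center).as_array()),
            "alignment_mm": list(alignment.as_array()),
        }
    return MRVolume(
        voxels=vol,
        spacing=tuple(float(s) for s in sp),
        origin=Vec3IEC.from_array(origin),
    )


def _carve_void(vol, xs, ys, zs, c, radius) -> None:
    pad = radius + 3.0
    ix = np.nonzero(np.abs(xs - c[0]) <= pad)[0]
    iy = np.nonzero(np.abs(ys - c[1]) <= pad)[0]
    iz = np.nonzero(np.abs(zs - c[2]) <= pad)[0]
    if min(ix.size, iy.size, iz.size) == 0:
        return
    d = np.sqrt(
        (xs[ix][:, None, None] - c[0]) ** 2
        + (ys[iy][None, :, None] - c[1]) ** 2
        + (zs[iz][None, None, :] - c[2]) ** 2
    )
    vol[np.ix_(ix, iy, iz)] *= _smooth_step(d - radius, MR_EDGE_SIGMA_MM)


# ---------------------------------------------------------------------------
# full scenario bundles


@dataclass
class ScenarioBundle:
    """A complete simulated daily-run input set plus its ground truth."""

    mv_images: list[MVImage]
    mr_volume: MRVolume
    adapted_plan: RTPlanData
    reference_plan: RTPlanData
    manifest: dict
    geom: BeamGeometry


def build_scenario_bundle(
    spec: SyntheticPhantomSpec,
    scenario: ScenarioSpec,
    alignment_reference: Vec3IEC = Vec3IEC(0, 0, 0),
) -> ScenarioBundle:
    """Simulate one daily run end to end.

    The online registration result is ``phantom_shift - alignment_delta +
    registration_error`` (the phantom as seen in the MR frame); the
    adapted plan encodes it, and the delivered fields are the adapted
    apertures plus any per-field aperture errors.
    """
    rng = np.random.default_rng(scenario.seed)
    geom = default_geometry(PLAN_GANTRY_ANGLES)
    reference_plan = default_reference_plan(Vec3IEC(0, 0, 0) - alignment_reference)
    registration = (
        scenario.phantom_shift - scenario.alignment_delta + scenario.registration_error
    )
    adapted = adapt_plan(reference_plan, registration)

    truth: dict = {
        "scenario": {
            "phantom_shift_mm": list(scenario.phantom_shift.as_array()),
            "registration_shift_mm": list(registration.as_array()),
            "couch_shift_mm": list(scenario.couch_shift),
            "alignment_delta_mm": list(scenario.alignment_delta.as_array()),
            "seed": scenario.seed,
        }
    }
    mv_images = []
    conflicts = []
    for i, beam in enumerate(adapted.beams):
        delivered = _apply_aperture_error(
            beam, scenario.aperture_errors.get(i, ApertureError())
        )
        img = render_mv_image(spec, delivered, scenario, geom, rng=rng, truth=truth)
        mv_images.append(img)
        for j, f in enumerate(truth["mv_images"][-1]["fiducials"]):
            if not f["inside_aperture"]:
                conflicts.append((i, j))
    targeted_out = [
        (i, j) for (i, j) in conflicts if j in _targeted_indices(spec)
    ]
    if targeted_out:
        raise ValueError(
            f"scenario moves targeted fiducials out of the field: {targeted_out}"
        )

    alignment = alignment_reference + scenario.alignment_delta
    mr = render_mr_volume(spec, scenario, alignment=alignment, rng=rng, truth=truth)
    return ScenarioBundle(
        mv_images=mv_images,
        mr_volume=mr,
        adapted_plan=adapted,
        reference_plan=reference_plan,
        manifest=truth,
        geom=geom,
    )


def _targeted_indices(spec: SyntheticPhantomSpec) -> tuple[int, int]:
    """Design-truth targeted fiducials: the two most anterior on the
    superior plane."""
    ys = [p.y for p in spec.fiducial_positions]
    y_sup = max(ys)
    sup = [i for i, p in enumerate(spec.fiducial_positions) if p.y == y_sup]
    return tuple(sorted(sup, key=lambda i: -spec.fiducial_positions[i].z)[:2])


# ---------------------------------------------------------------------------
# reference-session simulation


def create_reference_data(
    spec: SyntheticPhantomSpec | None = None,
    seed: int = 0,
    arc_angles: Sequence[float] = DEFAULT_ARC_ANGLES,
    alignment_reference: Vec3IEC = Vec3IEC(0, 0, 0),
):
    """Simulate the offline reference session and extract its products.

    Runs the actual analysis chain on synthetic data: the phantom is
    characterized from a rendered MV arc, and the seven fiducial
    positions relative to the plan isocenter are extracted from a
    rendered reference MR volume with the same localization algorithms
    used daily.  Returns a :class:`mrlqc.report.ReferenceData`.
    """
    from .mr_analysis import localize_all_mr_fiducials
    from .registration import characterize_phantom
    from .report import ReferenceData

    spec = spec or SyntheticPhantomSpec.default()
    arc, _, _ = render_characterization_arc(spec, arc_angles, seed=seed)
    model = characterize_phantom(arc, spec.fiducial_positions, spec.corner_to_mean)

    ref_scenario = ScenarioSpec(seed=seed + 1)
    vol = render_mr_volume(spec, ref_scenario, alignment=alignment_reference)
    loc = localize_all_mr_fiducials(vol, model.corner_offsets)
    if loc.errors:
        raise RuntimeError(f"reference MR extraction failed: {loc.errors}")
    iso_mr = Vec3IEC(0, 0, 0) - alignment_reference  # machine iso in MR coords
    plan = default_reference_plan(iso_mr)
    positions = tuple(
        loc.fiducials[i].position - iso_mr for i in range(len(spec.fiducial_positions))
    )
    return ReferenceData(
        reference_plan=plan,
        phantom_model=model,
        fiducial_positions_iso=positions,
    )
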