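"""2D analysis of MV portal images.

Covers the four image-analysis tasks performed on every daily run of the
QC suite:

* isolation of the irradiated (radiation field) region,
* sub-pixel fiducial localization via normalized cross-correlation,
* jaw / MLC field-edge detection from gradient profiles,
* couch index-bar marker detection on the gantry-0 image.

Dense objects (zirconium fiducials, couch marker) attenuate the beam and
therefore appear as dark spots on the transmission image; edge features
are extracted with a Sobel filter, which makes the pipeline insensitive
to display polarity and global intensity scale.

Pixel convention: 0-based indices, pixel centers at integer coordinates,
``pixels[v, u]`` (row = v, column = u); sub-pixel positions are
real-valued in this frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure
from skimage.feature import match_template

from .geometry import BeamGeometry, pixels_to_isocenter_mm

__all__ = [
    "MVImage",
    "FiducialDetection2D",
    "FieldMeasurement",
    "CouchDetection",
    "MVDetectorConfig",
    "NoBeamError",
    "FiducialNotFoundError",
    "AmbiguousDetectionError",
    "CouchMarkerError",
    "N_EDGE_PROFILES",
    "profile_strip_width_mm",
    "isolate_field_region",
    "localize_mv_fiducials",
    "detect_field_edges",
    "detect_couch_fiducial",
    "make_fiducial_templates",
]

#: number of adjacent profiles averaged per field edge / per MLC leaf
N_EDGE_PROFILES = 11


def profile_strip_width_mm(geom: BeamGeometry) -> float:
    """Width at the isocenter plane of the strip of adjacent profiles
    averaged for each detected edge (``N_EDGE_PROFILES`` pixel rows or
    columns)."""
    return pixels_to_isocenter_mm(N_EDGE_PROFILES, geom)


class NoBeamError(RuntimeError):
    """No irradiated region found: delivery or data-transfer failure."""


class FiducialNotFoundError(RuntimeError):
    pass


class AmbiguousDetectionError(RuntimeError):
    pass


class CouchMarkerError(RuntimeError):
    pass


@dataclass
class MVImage:
    """One MV portal image with its acquisition geometry."""

    pixels: np.ndarray  # shape (n_v, n_u)
    gantry_angle: float
    geom: BeamGeometry

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        n_u, n_v = self.geom.panel_size_px
        if self.pixels.shape != (n_v, n_u):
            raise ValueError(
                f"pixel grid {self.pixels.shape} does not match panel "
                f"dimensions (n_v={n_v}, n_u={n_u})"
            )
        self.geom.iso_pixel(self.gantry_angle)  # must be calibrated


@dataclass(frozen=True)
class FiducialDetection2D:
    """Sub-pixel fiducial position on the panel, pixel units."""

    u: float
    v: float
    ncc_score: float


@dataclass
class FieldMeasurement:
    """Detected (or planned) field-defining edges, mm at the isocenter
    plane relative to the isocenter pixel.

    Jaws define the two edges along u; each MLC leaf pair defines a pair
    of edges along v (the leaf-travel axis), keyed by leaf index (leaf 0
    is the leaf whose projected center is nearest the isocenter pixel,
    indices increasing toward +u).
    """

    jaw_edges: tuple[float, float]
    mlc_edges: dict[int, tuple[float, float]]
    field_center: tuple[float, float]
    flags: list[str] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.jaw_edges[0] < self.jaw_edges[1]:
            raise ValueError("jaw edges must satisfy edge_1 < edge_2")
        for k, (a, b) in self.mlc_edges.items():
            if not a < b:
                raise ValueError(f"leaf {k}: edge_1 must be < edge_2")

    @staticmethod
    def center_of(jaw_edges, mlc_edges) -> tuple[float, float]:
        """Field center: jaw-edge midpoint along u, mean of open-leaf
        pair centers along v."""
        u_c = 0.5 * (jaw_edges[0] + jaw_edges[1])
        v_c = float(np.mean([0.5 * (a + b) for a, b in mlc_edges.values()]))
        return (u_c, v_c)


@dataclass(frozen=True)
class CouchDetection:
    """Couch index-bar marker detection on the gantry-0 image."""

    u: float  # pixels, sub-pixel
    v: float
    delta_from_baseline: tuple[float, float]  # (du, dv) mm at isocenter


@dataclass(frozen=True)
class MVDetectorConfig:
    """Tunable parameters of the MV detectors (all lengths in the units
    noted)."""

    field_threshold_fraction: float = 0.5
    min_field_area_px: int = 200
    fiducial_diameter_mm: float = 6.0
    fiducial_attenuation_per_mm: float = 0.08
    smoothing_sigma_px: float = 2.0  # pre-NCC Gaussian
    edge_smoothing_sigma_px: float = 3.0  # pre-gradient Gaussian (profiles)
    search_window_mm: float = 5.0
    background_statistic: str = "median"  # or "mean"; in-field row/column profile
    ncc_floor: float = 0.2
    exclusion_radius_mm: float = 4.0
    ambiguity_ratio: float = 0.8
    upsample_factor: int = 10
    edge_upsample_factor: int = 20
    mlc_pitch_mm: float = 7.15
    jaw_strip_margin_mm: float = 2.0
    couch_marker_dark: bool = True
    couch_border_margin_px: int = 2
    couch_smoothing_sigma_px: float = 3.0  # regularizes the flat blob top


# ---------------------------------------------------------------------------
# field-region isolation


def isolate_field_region(
    img: MVImage, threshold_fraction: float = 0.5, min_area_px: int = 200
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Threshold the image to isolate the irradiated region.

    Returns ``(mask, bbox)`` with ``bbox = (v_min, v_max, u_min, u_max)``
    in pixel indices (inclusive).  Raises :class:`NoBeamError` when no
    contiguous super-threshold region exists, which signals a delivery or
    data-transfer error upstream.
    """
    px = img.pixels
    mx = float(px.max(initial=0.0))
    if mx <= 0:
        raise NoBeamError("no beam detected: image contains no positive signal")
    mask = px >= threshold_fraction * mx
    labels = measure.label(mask)
    if labels.max() == 0:
        raise NoBeamError("no beam detected: nothing above threshold")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    biggest = int(sizes.argmax())
    if sizes[biggest] < min_area_px:
        raise NoBeamError(
            f"no beam detected: largest region {sizes[biggest]} px "
            f"< {min_area_px} px"
        )
    region = labels == biggest
    vs, us = np.nonzero(region)
    bbox = (int(vs.min()), int(vs.max()), int(us.min()), int(us.max()))
    return region, bbox


# ---------------------------------------------------------------------------
# fiducial localization


def _disk_contrast(shape_px, center, radius_px, mu_px):
    """Transmission dip of a dense disk: 1 - exp(-mu * chord)."""
    v, u = np.mgrid[0 : shape_px[0], 0 : shape_px[1]]
    rho2 = (u - center[1]) ** 2 + (v - center[0]) ** 2
    chord = 2.0 * np.sqrt(np.maximum(radius_px**2 - rho2, 0.0))
    return 1.0 - np.exp(-mu_px * chord)


def make_fiducial_templates(
    geom: BeamGeometry, cfg: MVDetectorConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Render the NCC templates for fiducial search.

    The template is the Sobel edge image of the transmission dip of a
    dense disk of the configured diameter, smoothed exactly like the
    search image.  Returned at native resolution and at the configured
    up-sampling factor (for the sub-pixel refinement stage).
    """
    radius_px = 0.5 * cfg.fiducial_diameter_mm / geom.pixel_resolution
    mu_px = cfg.fiducial_attenuation_per_mm * geom.pixel_resolution

    def render(scale: int) -> np.ndarray:
        # footprint: edge ring plus the smoothing tail -- kept tight so a
        # neighbouring fiducial's ring cannot enter the template support
        half = int(np.ceil(radius_px + 3 * cfg.smoothing_sigma_px + 2)) * scale
        n = 2 * half + 1
        dip = _disk_contrast((n, n), (half, half), radius_px * scale, mu_px / scale)
        sm = ndimage.gaussian_filter(dip, cfg.smoothing_sigma_px * scale, mode="reflect")
        return filters.sobel(sm)

    return render(1), render(cfg.upsample_factor)


def _masked_profile(arr: np.ndarray, mask: np.ndarray, axis: int, stat: str):
    if stat == "mean":
        m = mask.astype(float)
        cnt = np.maximum(m.sum(axis=axis), 1.0)
        prof = (arr * m).sum(axis=axis) / cnt
        total = (arr * m).sum() / max(m.sum(), 1.0)
        return prof, total
    w = np.where(mask, arr, np.nan)
    any_mask = mask.any(axis=axis)
    prof = np.zeros(arr.shape[1 - axis])
    sub = w[any_mask, :] if axis == 1 else w[:, any_mask]
    prof[any_mask] = np.nanmedian(sub, axis=axis)
    total = float(np.median(arr[mask])) if mask.any() else 0.0
    return prof, total


def _fiducial_feature_image(img: MVImage, cfg: MVDetectorConfig) -> np.ndarray:
    """Gaussian smooth, subtract the in-field row/column background
    profiles, Sobel.

    The row/column background statistic defaults to the median: it is
    insensitive to the fiducial blobs themselves, which would otherwise
    leave faint self-subtraction streaks through every other fiducial on
    the same row or column (the plain average is available via config).
    """
    mask, _ = isolate_field_region(
        img, cfg.field_threshold_fraction, cfg.min_field_area_px
    )
    sm = ndimage.gaussian_filter(img.pixels, cfg.smoothing_sigma_px, mode="reflect")
    row, _ = _masked_profile(sm, mask, 1, cfg.background_statistic)
    col, total = _masked_profile(sm, mask, 0, cfg.background_statistic)
    bg_sub = sm - row[:, None] - col[None, :] + total
    return filters.sobel(bg_sub * mask)


def _upsample_window(arr, v0, v1, u0, u1, factor):
    """Linear-interpolation up-sampling of arr[v0:v1, u0:u1] on an exact
    1/factor grid; returns (fine image, v coords, u coords)."""
    vs = np.arange(v0, v1 - 1 + 1e-9, 1.0 / factor)
    us = np.arange(u0, u1 - 1 + 1e-9, 1.0 / factor)
    vv, uu = np.meshgrid(vs, us, indexing="ij")
    fine = ndimage.map_coordinates(arr, [vv, uu], order=1, mode="nearest")
    return fine, vs, us


def _quadratic_peak_2d(surface, iv, iu):
    """Sub-grid refinement of an argmax by a separable parabola fit."""

    def refine_1d(triple):
        a, b, c = triple
        denom = a - 2 * b + c
        if denom >= -1e-12:
            return 0.0
        return float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))

    dv = du = 0.0
    if 0 < iv < surface.shape[0] - 1:
        dv = refine_1d(surface[iv - 1 : iv + 2, iu])
    if 0 < iu < surface.shape[1] - 1:
        du = refine_1d(surface[iv, iu - 1 : iu + 2])
    return iv + dv, iu + du


def localize_mv_fiducials(
    img: MVImage,
    expected: Sequence[tuple[float, float]],
    cfg: MVDetectorConfig | None = None,
    templates: tuple[np.ndarray, np.ndarray] | None = None,
    feature: np.ndarray | None = None,
) -> list[FiducialDetection2D]:
    """Localize fiducials near the expected (u, v) pixel positions.

    Two-stage search: normalized cross-correlation against the disk-edge
    template at native resolution within a window around each expected
    position, then NCC of the x10 linearly up-sampled neighbourhood of
    the coarse peak against the high-resolution template, with a final
    parabolic refinement of the correlation peak.

    ``feature`` may carry a precomputed :func:`_fiducial_feature_image`
    of this image (callers localizing many fiducials per image cache it).
    """
    cfg = cfg or MVDetectorConfig()
    if templates is None:
        templates = make_fiducial_templates(img.geom, cfg)
    tmpl, tmpl_hi = templates
    feat = feature if feature is not None else _fiducial_feature_image(img, cfg)
    pr = img.geom.pixel_resolution
    search_px = int(np.ceil(cfg.search_window_mm / pr))
    win = search_px + tmpl.shape[0] // 2
    excl_px = cfg.exclusion_radius_mm / pr

    out: list[FiducialDetection2D] = []
    for (eu, ev) in expected:
        v0 = max(int(round(ev)) - win, 0)
        v1 = min(int(round(ev)) + win + 1, feat.shape[0])
        u0 = max(int(round(eu)) - win, 0)
        u1 = min(int(round(eu)) + win + 1, feat.shape[1])
        window = feat[v0:v1, u0:u1]
        ncc = match_template(window, tmpl, pad_input=True, mode="constant")
        # candidate peaks must lie inside the search window proper (the
        # extra margin exists only to keep the correlation valid there)
        gv, gu = np.mgrid[v0:v1, u0:u1]
        ncc = np.where(
            (np.abs(gv - ev) <= search_px) & (np.abs(gu - eu) <= search_px),
            ncc,
            -np.inf,
        )
        iv, iu = np.unravel_index(int(np.argmax(ncc)), ncc.shape)
        score = float(ncc[iv, iu])
        if score < cfg.ncc_floor:
            raise FiducialNotFoundError(
                f"fiducial near ({eu:.0f}, {ev:.0f}) px not found "
                f"(NCC {score:.2f} < {cfg.ncc_floor})"
            )
        # ambiguity: a comparable secondary peak within the exclusion radius
        suppress = ncc.copy()
        rr = int(np.ceil(min(3.0, excl_px / 2)))
        suppress[
            max(iv - rr, 0) : iv + rr + 1, max(iu - rr, 0) : iu + rr + 1
        ] = -np.inf
        jv, ju = np.unravel_index(int(np.argmax(suppress)), suppress.shape)
        if (
            suppress[jv, ju] >= cfg.ambiguity_ratio * score
            and np.hypot(jv - iv, ju - iu) <= excl_px
        ):
            raise AmbiguousDetectionError(
                f"two correlation peaks within {cfg.exclusion_radius_mm} mm "
                f"near ({eu:.0f}, {ev:.0f}) px"
            )
        cv, cu = v0 + iv, u0 + iu
        # refinement window around the coarse peak
        half = tmpl.shape[0] // 2 + 3
        rv0, rv1 = max(cv - half, 0), min(cv + half + 1, feat.shape[0])
        ru0, ru1 = max(cu - half, 0), min(cu + half + 1, feat.shape[1])
        if rv1 - rv0 < 5 or ru1 - ru0 < 5:
            raise FiducialNotFoundError(
                "refinement window degenerate at the panel border"
            )
        fine, vs, us = _upsample_window(feat, rv0, rv1, ru0, ru1, cfg.upsample_factor)
        ncc_hi = match_template(fine, tmpl_hi, pad_input=True, mode="constant")
        kv, ku = np.unravel_index(int(np.argmax(ncc_hi)), ncc_hi.shape)
        fv, fu = _quadratic_peak_2d(ncc_hi, kv, ku)
        step = 1.0 / cfg.upsample_factor
        out.append(
            FiducialDetection2D(
                u=float(us[0] + fu * step),
                v=float(vs[0] + fv * step),
                ncc_score=float(ncc_hi[kv, ku]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# jaw / MLC field-edge detection


def _edge_on_profile(profile, lo, hi, rising, cfg, planned_px=None):
    """Locate one field edge on a 1D profile by the extremum of the
    smoothed, spline-up-sampled gradient within ``[lo, hi)``.

    Returns (edge position in fractional pixels, ambiguous flag).  When
    two candidate gradient peaks agree within ``1 - cfg.ambiguity_ratio``
    the one nearer the planned edge wins and the edge is flagged.
    """
    from scipy.interpolate import make_interp_spline

    sm = ndimage.gaussian_filter1d(
        np.asarray(profile, float), cfg.edge_smoothing_sigma_px, mode="reflect"
    )
    grad = np.gradient(sm)
    if not rising:
        grad = -grad
    n = len(grad)
    lo = max(int(lo), 0)
    hi = min(int(hi), n)
    if hi - lo < 5:
        raise ValueError("edge search segment too short")
    x = np.arange(lo, hi)
    spline = make_interp_spline(x, grad[lo:hi], k=3)
    xf = np.arange(lo, hi - 1 + 1e-9, 1.0 / cfg.edge_upsample_factor)
    gf = spline(xf)
    i = int(np.argmax(gf))
    # secondary peak check on the native-resolution grid
    seg = grad[lo:hi]
    peaks = [
        j
        for j in range(1, len(seg) - 1)
        if seg[j] >= seg[j - 1] and seg[j] >= seg[j + 1]
    ]
    peaks.sort(key=lambda j: -seg[j])
    ambiguous = False
    if len(peaks) >= 2 and seg[peaks[1]] >= cfg.ambiguity_ratio * seg[peaks[0]]:
        ambiguous = True
        if planned_px is not None:
            cands = [lo + peaks[0], lo + peaks[1]]
            best = min(cands, key=lambda c: abs(c - planned_px))
            j0 = int((best - lo - 1) * cfg.edge_upsample_factor)
            j1 = int((best - lo + 1) * cfg.edge_upsample_factor)
            i = j0 + int(np.argmax(gf[j0 : j1 + 1]))
    return float(xf[i]), ambiguous


def detect_field_edges(
    img: MVImage,
    planned: "FieldMeasurement",
    geom: BeamGeometry | None = None,
    cfg: MVDetectorConfig | None = None,
) -> FieldMeasurement:
    """Detect the delivered jaw and per-leaf MLC edges on an MV image.

    The coarse field center comes from thresholding and the bounding box
    of the irradiated region.  For each planned leaf, ``N_EDGE_PROFILES``
    adjacent columns spanning a 2.38 mm strip centered on the projected
    leaf center are analysed; each profile is Gaussian-smoothed
    (sigma = 3 px), differentiated, spline-up-sampled x20 and the edge
    taken at the maximum gradient (signed toward the field interior).
    The per-profile edges are averaged.  Jaw edges use the same procedure
    on ``N_EDGE_PROFILES`` rows through the field center.  All outputs
    are mm at the isocenter plane relative to the isocenter pixel.

    The ``planned`` measurement supplies the leaf indexing and strip
    positions only; edge search itself runs over the full profile halves
    so that arbitrarily large delivery errors remain detectable.
    """
    cfg = cfg or MVDetectorConfig()
    geom = geom or img.geom
    _, bbox = isolate_field_region(
        img, cfg.field_threshold_fraction, cfg.min_field_area_px
    )
    v_c = 0.5 * (bbox[0] + bbox[1])
    u_c = 0.5 * (bbox[2] + bbox[3])
    pr = geom.pixel_resolution
    iso_u, iso_v = geom.iso_pixel(img.gantry_angle)
    flags: list[str] = []

    # --- jaw edges: profiles along u, adjacent rows about the center row
    rows = np.arange(
        int(round(v_c)) - N_EDGE_PROFILES // 2,
        int(round(v_c)) + N_EDGE_PROFILES // 2 + 1,
    )
    e1s, e2s = [], []
    planned_jaw_px = [e / pr + iso_u for e in planned.jaw_edges]
    for row in rows:
        p = img.pixels[row, :]
        e1, a1 = _edge_on_profile(
            p, 0, int(u_c) + 1, True, cfg, planned_px=planned_jaw_px[0]
        )
        e2, a2 = _edge_on_profile(
            p, int(u_c), len(p), False, cfg, planned_px=planned_jaw_px[1]
        )
        if a1 or a2:
            flags.append(f"jaw edge ambiguous on row {row}")
        e1s.append(e1)
        e2s.append(e2)
    jaw_edges = (
        pixels_to_isocenter_mm(float(np.mean(e1s)) - iso_u, geom),
        pixels_to_isocenter_mm(float(np.mean(e2s)) - iso_u, geom),
    )

    # --- MLC edges: per planned leaf, profiles along v, adjacent columns
    pitch_px = cfg.mlc_pitch_mm / pr
    margin_px = cfg.jaw_strip_margin_mm / pr
    jaw_lo_px = min(planned_jaw_px) + margin_px
    jaw_hi_px = max(planned_jaw_px) - margin_px
    mlc_edges: dict[int, tuple[float, float]] = {}
    for leaf, planned_pair in sorted(planned.mlc_edges.items()):
        center_u = iso_u + leaf * pitch_px
        cols = np.arange(
            int(round(center_u)) - N_EDGE_PROFILES // 2,
            int(round(center_u)) + N_EDGE_PROFILES // 2 + 1,
        )
        if cols[0] < jaw_lo_px or cols[-1] > jaw_hi_px:
            flags.append(f"leaf {leaf}: profile strip outside open field, skipped")
            continue
        p1 = [e / pr + iso_v for e in planned_pair]
        f1s, f2s = [], []
        for col in cols:
            p = img.pixels[:, col]
            f1, a1 = _edge_on_profile(p, 0, int(v_c) + 1, True, cfg, planned_px=p1[0])
            f2, a2 = _edge_on_profile(
                p, int(v_c), len(p), False, cfg, planned_px=p1[1]
            )
            if a1 or a2:
                flags.append(f"leaf {leaf}: edge ambiguous on column {col}")
            f1s.append(f1)
            f2s.append(f2)
        mlc_edges[leaf] = (
            pixels_to_isocenter_mm(float(np.mean(f1s)) - iso_v, geom),
            pixels_to_isocenter_mm(float(np.mean(f2s)) - iso_v, geom),
        )
    if not mlc_edges:
        raise NoBeamError("no MLC leaf strip inside the open field")
    return FieldMeasurement(
        jaw_edges=jaw_edges,
        mlc_edges=mlc_edges,
        field_center=FieldMeasurement.center_of(jaw_edges, mlc_edges),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# couch marker detection


def detect_couch_fiducial(
    img0: MVImage,
    roi: tuple[int, int, int, int],
    baseline_mm: tuple[float, float],
    cfg: MVDetectorConfig | None = None,
) -> CouchDetection:
    """Detect the couch index-bar marker on the gantry-0 image.

    Crops the configured ROI ``(v_min, v_max, u_min, u_max)``, removes
    the background by subtracting the row and column mean profiles,
    up-samples x10 with bilinear interpolation and takes the contrast
    extremum as the marker position.  The displacement from the baseline
    is returned in mm at the isocenter plane.
    """
    cfg = cfg or MVDetectorConfig()
    v0, v1, u0, u1 = roi
    crop = img0.pixels[v0:v1, u0:u1]
    if crop.size == 0:
        raise CouchMarkerError("empty couch ROI")
    bg = (
        crop
        - crop.mean(axis=1, keepdims=True)
        - crop.mean(axis=0, keepdims=True)
        + crop.mean()
    )
    contrast = -bg if cfg.couch_marker_dark else bg
    # the blob top is nearly flat; a light smoothing makes its intensity
    # maximum well defined in the presence of noise
    contrast = ndimage.gaussian_filter(
        contrast, cfg.couch_smoothing_sigma_px, mode="reflect"
    )
    zoom = cfg.upsample_factor
    vsf = np.arange(0, crop.shape[0] - 1 + 1e-9, 1.0 / zoom)
    usf = np.arange(0, crop.shape[1] - 1 + 1e-9, 1.0 / zoom)
    vv, uu = np.meshgrid(vsf, usf, indexing="ij")
    hi = ndimage.map_coordinates(contrast, [vv, uu], order=1, mode="nearest")
    iv, iu = np.unravel_index(int(np.argmax(hi)), hi.shape)
    mv, mu = vsf[iv], usf[iu]
    m = cfg.couch_border_margin_px
    if not (m <= mv <= crop.shape[0] - 1 - m and m <= mu <= crop.shape[1] - 1 - m):
        raise CouchMarkerError("marker not in ROI (extremum at the ROI border)")
    # parabolic refinement of the smoothed peak (a bilinear up-sampling
    # alone cannot place a maximum between native grid nodes)
    mv, mu = _quadratic_peak_2d(contrast, int(round(mv)), int(round(mu)))
    u_px, v_px = u0 + mu, v0 + mv
    u_mm, v_mm = img0.geom.pixel_to_iso_mm(u_px, v_px, img0.gantry_angle)
    return CouchDetection(
        u=float(u_px),
        v=float(v_px),
        delta_from_baseline=(u_mm - baseline_mm[0], v_mm - baseline_mm[1]),
    )
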