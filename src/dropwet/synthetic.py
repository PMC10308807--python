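"""Synthetic droplet imagery and signals with exact ground truth.

Every input the analysis chain consumes can be generated here: side-view
sessile-drop images shaped by the axisymmetric Young-Laplace equation,
evaporation time series with pinned or depinning contact lines, centrifugal
rotation-ramp frame series, power-law flow curves, and two-channel
(live/dead) cell fields.  Each artefact carries a ground-truth record so
that every downstream estimator can be validated by round-trip.

Rendering conventions: raster origin top-left, row index increasing
downward; the substrate occupies rows >= ``baseline_row``; physical height
``z`` increases upward from the substrate surface, which sits on the
boundary between rows ``baseline_row - 1`` and ``baseline_row`` (continuous
row coordinate ``baseline_row - 0.5``).  Droplets are rendered dark on a
light background (emulating dye-stained drops), with the substrate a darker
grey band; edges are anti-aliased by 4x supersampling so that the true
boundary position is recoverable to subpixel precision from the intensity
ramp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.draw import polygon as draw_polygon
from skimage.draw import ellipse as draw_ellipse
from skimage.transform import downscale_local_mean

from .fluids import FluidProperties, G_STANDARD
from .drop_shape import (
    YLShape,
    ShapeSolverError,
    integrate_shape,
    shape_metrics,
    solve_for,
    spherical_cap_radius_from_volume,
)

__all__ = [
    "SyntheticScene",
    "GroundTruth",
    "CellGroundTruth",
    "RampTargets",
    "gen_sessile_image",
    "gen_asymmetric_sessile_image",
    "gen_evaporation_series",
    "gen_rotation_ramp",
    "gen_flow_curve",
    "gen_cell_image",
    "gen_footprint_image",
    "noisy_linear_volumes",
    "save_series",
]

_BG = 230.0  # background intensity
_FG = 25.0  # droplet intensity (dye-stained, dark)
_SUBSTRATE = 80.0  # substrate band intensity
_SS = 4  # supersampling factor for anti-aliased silhouettes


@dataclass(frozen=True)
class SyntheticScene:
    """Camera/scene description for rendered side-view frames."""

    pixel_scale: float = 0.015  # mm per pixel
    image_size: tuple[int, int] = (480, 720)  # (rows, cols)
    baseline_row: int = 420
    noise_sd: float = 0.0  # additive Gaussian sd, 8-bit intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if not (0 < self.baseline_row < self.image_size[0]):
            raise ValueError("baseline_row must lie inside the image")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Exact geometry of one rendered droplet frame (physical units)."""

    volume_uL: float
    theta_left: float  # degrees; rear flank in ramp frames
    theta_right: float  # degrees; front flank in ramp frames
    length_mm: float
    height_mm: float
    edge_left_mm: float
    edge_right_mm: float
    cross_section_mm2: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def _rng_for(scene_seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(scene_seed) & 0x7FFFFFFF, *stream])


def _finish_image(coverage: np.ndarray, scene: SyntheticScene, rng) -> np.ndarray:
    """Composite droplet coverage over background + substrate, add noise."""
    rows, cols = scene.image_size
    base = np.full((rows, cols), _BG, dtype=float)
    base[scene.baseline_row:, :] = _SUBSTRATE
    img = (1.0 - coverage) * base + coverage * _FG
    if scene.noise_sd > 0:
        img = img + rng.normal(0.0, scene.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _render_silhouette(
    flank_left: np.ndarray,
    flank_right: np.ndarray,
    scene: SyntheticScene,
) -> np.ndarray:
    """Fill the closed droplet silhouette given two flanks in mm.

    ``flank_left``/``flank_right`` are (N, 2) arrays of (u_mm, z_mm) from the
    contact point up to the apex (left) and apex down to the contact point
    (right); z = 0 is the substrate surface.  Returns per-pixel coverage.
    """
    verts = np.vstack([flank_left, flank_right])
    u_all = verts[:, 0] / scene.pixel_scale  # continuous col coordinate
    z_all = verts[:, 1] / scene.pixel_scale
    rr_all = (scene.baseline_row - 0.5) - z_all  # continuous row coordinate
    rows, cols = scene.image_size
    if u_all.min() < 0.5 or u_all.max() > cols - 1.5 or rr_all.min() < 0.5:
        raise ValueError(
            "droplet silhouette does not fit in the scene "
            f"(u range {u_all.min():.1f}..{u_all.max():.1f} px, "
            f"top row {rr_all.min():.1f})"
        )
    # z-monotone flank polylines (z increases contact -> apex on both sides)
    zl = flank_left[:, 1] / scene.pixel_scale
    ul = flank_left[:, 0] / scene.pixel_scale
    zr = flank_right[::-1, 1] / scene.pixel_scale
    ur = flank_right[::-1, 0] / scene.pixel_scale
    h_px = zl[-1]

    # scanline fill: supersample rows, analytic fractional coverage in columns
    r_lo = max(int(np.floor(rr_all.min())) - 1, 0)
    r_hi = scene.baseline_row
    n_ss = (r_hi - r_lo) * _SS
    rr_c = r_lo + (np.arange(n_ss) + 0.5) / _SS - 0.5  # supersampled row centres
    z_c = (scene.baseline_row - 0.5) - rr_c
    inside = (z_c >= 0.0) & (z_c <= h_px)
    c_lo = max(int(np.floor(u_all.min())) - 1, 0)
    c_hi = min(int(np.ceil(u_all.max())) + 2, cols)
    span_l = np.interp(z_c, zl, ul)
    span_r = np.interp(z_c, zr, ur)
    centres = np.arange(c_lo, c_hi, dtype=float)
    # per supersampled row, fraction of each pixel column inside [span_l, span_r]
    left = np.maximum(span_l[:, None], centres[None, :] - 0.5)
    right = np.minimum(span_r[:, None], centres[None, :] + 0.5)
    frac = np.clip(right - left, 0.0, 1.0) * inside[:, None]
    box = frac.reshape(r_hi - r_lo, _SS, -1).mean(axis=1)
    coverage = np.zeros((rows, cols), dtype=float)
    coverage[r_lo:r_hi, c_lo:c_hi] = box
    return coverage


def _yl_flanks(shape: YLShape, theta_deg: float, center_mm: float, n: int = 600):
    """Left/right flank polylines (mm) of a Young-Laplace shape above z=0."""
    theta = np.deg2rad(theta_deg)
    phi = np.linspace(0.0, theta, n)
    x_mm = np.interp(phi, shape.phi, shape.x, left=0.0) * 1e3
    z_below = np.interp(phi, shape.phi, shape.z, left=0.0) * 1e3
    h_mm = z_below[-1]
    z_mm = h_mm - z_below
    right = np.column_stack([center_mm + x_mm, z_mm])  # apex -> contact
    left = np.column_stack([center_mm - x_mm, z_mm])[::-1]  # contact -> apex
    return left, right, h_mm, x_mm[-1]


def gen_sessile_image(
    volume_uL: float,
    theta_deg: float,
    fluid: FluidProperties,
    scene: SyntheticScene,
    gravity: float = G_STANDARD,
    center_col: float | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a Young-Laplace sessile drop of given volume and contact angle.

    Returns the 8-bit grayscale frame and the exact rendered geometry.  Pass
    ``gravity=0`` for the spherical-cap (zero Bond number) limit.
    """
    if volume_uL <= 0:
        raise ValueError("volume must be positive")
    try:
        shape = solve_for(volume_uL, theta_deg, fluid, gravity=gravity)
    except ShapeSolverError as exc:
        raise ShapeSolverError(
            f"shape solve failed for V={volume_uL} uL, theta={theta_deg} deg: {exc}"
        ) from exc
    center_mm = (
        (scene.image_size[1] / 2.0) if center_col is None else center_col
    ) * scene.pixel_scale
    left, right, h_mm, rc_mm = _yl_flanks(shape, theta_deg, center_mm)
    coverage = _render_silhouette(left, right, scene)
    rng = _rng_for(scene.seed, 0)
    img = _finish_image(coverage, scene, rng)
    m = shape_metrics(shape, theta_deg)
    truth = GroundTruth(
        volume_uL=volume_uL,
        theta_left=theta_deg,
        theta_right=theta_deg,
        length_mm=2.0 * rc_mm,
        height_mm=h_mm,
        edge_left_mm=center_mm - rc_mm,
        edge_right_mm=center_mm + rc_mm,
        cross_section_mm2=m.cross_section_mm2,
    )
    return img, truth


# ---------------------------------------------------------------------------
# circular-arc (spherical-cap) composition for asymmetric drops
# ---------------------------------------------------------------------------

def _arc_flank(theta_deg: float, h_mm: float, n: int = 400):
    """Circular-arc flank of cap height h and contact angle theta.

    Returns (x_mm, z_mm) from apex (x=0, z=h) to contact (x=rc, z=0).
    """
    th = np.deg2rad(theta_deg)
    R = h_mm / (1.0 - np.cos(th))
    phi = np.linspace(0.0, th, n)
    return R * np.sin(phi), h_mm - R * (1.0 - np.cos(phi))


def _cap_rc(theta_deg: float, h_mm: float) -> float:
    th = np.deg2rad(theta_deg)
    return h_mm * np.sin(th) / (1.0 - np.cos(th))


def _half_cap_volume_uL(theta_deg: float, h_mm: float) -> float:
    th = np.deg2rad(theta_deg)
    R = h_mm / (1.0 - np.cos(th))  # mm
    return 0.5 * np.pi / 3.0 * R**3 * (1.0 - np.cos(th)) ** 2 * (2.0 + np.cos(th))


def _half_segment_area_mm2(theta_deg: float, h_mm: float) -> float:
    th = np.deg2rad(theta_deg)
    R = h_mm / (1.0 - np.cos(th))
    return 0.5 * R**2 * (th - np.sin(th) * np.cos(th))


def _asym_geometry(theta_left: float, theta_right: float, length_mm: float):
    """Cap height and per-side contact radii for a two-arc composite drop."""
    cot = lambda t: 1.0 / np.tan(np.deg2rad(t) / 2.0)
    h = length_mm / (cot(theta_left) + cot(theta_right))
    return h, _cap_rc(theta_left, h), _cap_rc(theta_right, h)


def gen_asymmetric_sessile_image(
    theta_left: float,
    theta_right: float,
    length_mm: float,
    scene: SyntheticScene,
    edge_left_mm: float | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a drop whose two flanks are circular arcs with distinct angles.

    The two arcs share the apex height; the footprint length fixes the
    height in closed form.  Used for asymmetric-drop and rotation-ramp
    frames, where the analysis consumes angles and edge positions rather
    than a gravity-corrected profile.
    """
    h, rc_l, rc_r = _asym_geometry(theta_left, theta_right, length_mm)
    if edge_left_mm is None:
        center = scene.image_size[1] / 2.0 * scene.pixel_scale
        edge_left_mm = center - length_mm / 2.0
    apex_u = edge_left_mm + rc_l
    xl, zl = _arc_flank(theta_left, h)
    xr, zr = _arc_flank(theta_right, h)
    left = np.column_stack([apex_u - xl, zl])[::-1]
    right = np.column_stack([apex_u + xr, zr])
    coverage = _render_silhouette(left, right, scene)
    img = _finish_image(coverage, scene, _rng_for(scene.seed, 1))
    truth = GroundTruth(
        volume_uL=_half_cap_volume_uL(theta_left, h) + _half_cap_volume_uL(theta_right, h),
        theta_left=theta_left,
        theta_right=theta_right,
        length_mm=length_mm,
        height_mm=h,
        edge_left_mm=edge_left_mm,
        edge_right_mm=edge_left_mm + length_mm,
        cross_section_mm2=_half_segment_area_mm2(theta_left, h)
        + _half_segment_area_mm2(theta_right, h),
    )
    return img, truth


# ---------------------------------------------------------------------------
# evaporation series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvapFrame:
    time_s: float
    image: np.ndarray | None
    truth: GroundTruth


def gen_evaporation_series(
    v0_uL: float,
    slope_uL_per_s: float,
    dt_s: float,
    duration_s: float,
    mode: str,
    scene: SyntheticScene,
    fluid: FluidProperties,
    theta0_deg: float = 40.0,
    theta_depin_deg: float = 25.0,
    gravity: float = G_STANDARD,
    render: bool = True,
) -> list[EvapFrame]:
    """Generate a drying-droplet time series with exactly linear volume decay.

    ``mode='pinned'`` keeps the contact-line length at its initial value and
    lets the contact angle fall; ``mode='depinning'`` pins the line until the
    angle reaches ``theta_depin_deg``, then holds the angle and shrinks the
    length.  Volume at each frame is exactly ``v0 + slope*t``.

    With ``render=False`` only the ground-truth geometry is computed (frames
    carry ``image=None``), which is much faster for value-level studies.
    """
    if mode not in ("pinned", "depinning"):
        raise ValueError(f"mode must be 'pinned' or 'depinning', got {mode!r}")
    if v0_uL <= 0:
        raise ValueError("v0 must be positive")
    if slope_uL_per_s > 0:
        raise ValueError("evaporation slope must be <= 0")
    times = np.arange(0.0, duration_s + 0.5 * dt_s, dt_s)
    volumes = v0_uL + slope_uL_per_s * times
    if np.any(volumes < 0.05 * v0_uL - 1e-12):
        t_bad = times[np.argmax(volumes < 0.05 * v0_uL)]
        raise ValueError(
            f"volume drops below 5% of v0 at t={t_bad:.0f} s "
            f"(v={v0_uL + slope_uL_per_s * t_bad:.3g} uL); shorten the duration"
        )

    # initial pinned radius from the full Young-Laplace shape
    shape0 = solve_for(v0_uL, theta0_deg, fluid, gravity=gravity)
    rc0_mm = shape_metrics(shape0, theta0_deg).contact_radius_mm

    # geometry for every frame before any rendering, so that a parameter set
    # that drives theta too low fails fast
    geoms: list[tuple[float, float]] = []  # (theta_deg, shape cache key)
    shapes: list[YLShape] = []
    theta_prev = theta0_deg
    pinned_phase = True
    from scipy.optimize import brentq

    for v in volumes:
        if pinned_phase:
            def rc_err(th, v=v):
                shp = solve_for(v, th, fluid, gravity=gravity)
                return shape_metrics(shp, th).contact_radius_mm - rc0_mm

            lo = max(5.0, theta_prev - 20.0)
            hi = min(175.0, theta_prev + 2.0)
            f_lo, f_hi = rc_err(lo), rc_err(hi)
            if f_lo < 0:
                # even at the bracket floor the pinned radius is not reached
                raise ValueError(
                    f"pinned contact line drives theta below {lo:.0f} deg at "
                    f"v={v:.3g} uL; series parameters out of range"
                )
            th = brentq(rc_err, lo, hi, xtol=1e-3) if f_hi < 0 else hi
            if mode == "depinning" and th <= theta_depin_deg:
                pinned_phase = False
                th = theta_depin_deg
        else:
            th = theta_depin_deg
        if th < 2.0:
            raise ValueError(f"theta fell below 2 deg at v={v:.3g} uL")
        shp = solve_for(v, th, fluid, gravity=gravity)
        shapes.append(shp)
        geoms.append((th, v))
        theta_prev = th

    center_mm = scene.image_size[1] / 2.0 * scene.pixel_scale
    frames: list[EvapFrame] = []
    for k, (t, (th, v), shp) in enumerate(zip(times, geoms, shapes)):
        m = shape_metrics(shp, th)
        truth = GroundTruth(
            volume_uL=float(v),
            theta_left=th,
            theta_right=th,
            length_mm=2.0 * m.contact_radius_mm,
            height_mm=m.height_mm,
            edge_left_mm=center_mm - m.contact_radius_mm,
            edge_right_mm=center_mm + m.contact_radius_mm,
            cross_section_mm2=m.cross_section_mm2,
        )
        img = None
        if render:
            left, right, _, _ = _yl_flanks(shp, th, center_mm)
            coverage = _render_silhouette(left, right, scene)
            img = _finish_image(coverage, scene, _rng_for(scene.seed, 2, k))
        frames.append(EvapFrame(time_s=float(t), image=img, truth=truth))
    return frames


# ---------------------------------------------------------------------------
# rotation ramp
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RampTargets:
    """Kinematic targets a synthetic rotation ramp should realise."""

    theta0_deg: float = 40.0
    theta_adv_deg: float = 53.0
    rs_spread_rpm: float = 40.0
    theta_rec_deg: float = 15.0
    rs_slide_rpm: float | None = 50.0  # None = permanently pinned rear
    rs_rear_plateau_rpm: float = 65.0  # where theta_rear bottoms out if pinned
    volume_uL: float = 35.0
    advance_rate_mm_per_rpm: float = 0.25

    def __post_init__(self) -> None:
        if self.theta_adv_deg <= self.theta_rec_deg:
            raise ValueError(
                "advancing angle must exceed receding angle (positive hysteresis)"
            )
        if self.rs_slide_rpm is not None and not (
            0 < self.rs_spread_rpm < self.rs_slide_rpm
        ):
            raise ValueError("need 0 < rs_spread < rs_slide")


@dataclass(frozen=True)
class RampFrameTruth:
    rs_rpm: float
    image: np.ndarray | None
    truth: GroundTruth

    @property
    def theta_front(self) -> float:
        return self.truth.theta_right

    @property
    def theta_rear(self) -> float:
        return self.truth.theta_left


def gen_rotation_ramp(
    targets: RampTargets,
    scene: SyntheticScene,
    fluid: FluidProperties,
    ramp_rate_rpm_per_s: float = 1.0,
    rs_max_rpm: float = 100.0,
    render: bool = True,
) -> list[RampFrameTruth]:
    """Generate a centrifugal-ramp frame series, one frame per second.

    The centrifugal force points toward increasing column index, so the
    right flank is the front (advancing) side.  The front angle rises
    linearly from the static angle to the advancing plateau reached at
    ``rs_spread_rpm``; the rear angle falls to the receding plateau at
    ``rs_slide_rpm`` (or ``rs_rear_plateau_rpm`` in pinned-rear mode).  The
    front edge advances only past the spreading onset; the rear edge moves
    only past the sliding onset, and never in pinned-rear mode.
    """
    t = targets
    if t.rs_slide_rpm is not None and t.rs_slide_rpm > rs_max_rpm:
        raise ValueError("rs_slide must not exceed rs_max")
    rs_values = np.arange(0.0, rs_max_rpm + 1e-9, ramp_rate_rpm_per_s)

    # initial symmetric footprint from the target volume at the static angle
    r0_m = spherical_cap_radius_from_volume(t.volume_uL * 1e-9, t.theta0_deg)
    rc0_mm = r0_m * np.sin(np.deg2rad(t.theta0_deg)) * 1e3
    L0 = 2.0 * rc0_mm
    center = scene.image_size[1] / 2.0 * scene.pixel_scale
    # leave room for front-edge advance
    e_rear0 = center - L0 / 2.0 - 0.25 * (
        t.advance_rate_mm_per_rpm * max(rs_max_rpm - t.rs_spread_rpm, 0.0)
    )
    e_front0 = e_rear0 + L0

    rs_rear_knee = t.rs_slide_rpm if t.rs_slide_rpm is not None else t.rs_rear_plateau_rpm
    frames: list[RampFrameTruth] = []
    for k, rs in enumerate(rs_values):
        f_front = min(rs / t.rs_spread_rpm, 1.0)
        th_f = t.theta0_deg + (t.theta_adv_deg - t.theta0_deg) * f_front
        f_rear = min(rs / rs_rear_knee, 1.0)
        th_r = t.theta0_deg + (t.theta_rec_deg - t.theta0_deg) * f_rear
        e_front = e_front0 + t.advance_rate_mm_per_rpm * max(rs - t.rs_spread_rpm, 0.0)
        if t.rs_slide_rpm is None:
            e_rear = e_rear0
        else:
            e_rear = e_rear0 + t.advance_rate_mm_per_rpm * max(rs - t.rs_slide_rpm, 0.0)
        L = e_front - e_rear
        h, rc_rear, rc_front = _asym_geometry(th_r, th_f, L)
        truth = GroundTruth(
            volume_uL=_half_cap_volume_uL(th_r, h) + _half_cap_volume_uL(th_f, h),
            theta_left=th_r,
            theta_right=th_f,
            length_mm=L,
            height_mm=h,
            edge_left_mm=e_rear,
            edge_right_mm=e_front,
            cross_section_mm2=_half_segment_area_mm2(th_r, h)
            + _half_segment_area_mm2(th_f, h),
        )
        img = None
        if render:
            apex_u = e_rear + rc_rear
            xl, zl = _arc_flank(th_r, h)
            xr, zr = _arc_flank(th_f, h)
            left = np.column_stack([apex_u - xl, zl])[::-1]
            right = np.column_stack([apex_u + xr, zr])
            coverage = _render_silhouette(left, right, scene)
            img = _finish_image(coverage, scene, _rng_for(scene.seed, 3, k))
        frames.append(RampFrameTruth(rs_rpm=float(rs), image=img, truth=truth))
    return frames


# ---------------------------------------------------------------------------
# flow curves, cell fields, value-level helpers
# ---------------------------------------------------------------------------

def gen_flow_curve(
    K: float,
    n: float,
    rate_range: tuple[float, float] = (10.0, 100.0),
    points: int = 20,
    noise_rel: float = 0.0,
    seed: int = 0,
    temperature_C: float = 25.0,
):
    """Power-law flow curve eta = K*gamma_dot**(n-1) with relative noise.

    Shear rates are log-spaced across ``rate_range`` (the measured decade is
    10-100 1/s); returns a :class:`dropwet.rheology.FlowCurve`.
    """
    from .rheology import FlowCurve

    if K <= 0:
        raise ValueError("consistency K must be positive")
    if not (0 < n <= 1.5):
        raise ValueError("flow index n must be in (0, 1.5]")
    lo, hi = rate_range
    if lo <= 0 or hi <= lo:
        raise ValueError("rate_range must be positive and increasing")
    rates = np.logspace(np.log10(lo), np.log10(hi), points)
    eta = K * rates ** (n - 1.0)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        eta = eta * (1.0 + noise_rel * rng.standard_normal(points))
    return FlowCurve(shear_rate=rates, viscosity=eta, temperature_C=temperature_C)


@dataclass(frozen=True)
class CellGroundTruth:
    n_green: int
    n_red: int
    objects: list  # (channel, centroid_row, centroid_col, area_px)


def gen_cell_image(
    n_green: int,
    n_red: int,
    area_range_px: tuple[float, float] = (10.0, 30.0),
    field_px: tuple[int, int] = (512, 512),
    pixel_scale_um: float = 0.566,
    seed: int = 0,
    min_gap_px: int = 2,
) -> tuple[np.ndarray, CellGroundTruth]:
    """Render rod-shaped cells (3:1 ellipses) in green and red channels.

    Cells are placed uniformly at random without overlap (a ``min_gap_px``
    exclusion margin keeps objects separable); drawn pixel areas are
    guaranteed to fall inside ``area_range_px``.  Returns a (2, H, W) uint8
    stack, channel order (green, red), and the exact per-channel truth.
    """
    rows, cols = field_px
    a_min, a_max = area_range_px
    if a_min >= a_max:
        raise ValueError("area range must be increasing")
    mean_area = 0.5 * (a_min + a_max)
    if (n_green + n_red) * mean_area > 0.3 * rows * cols:
        raise ValueError("total cell area exceeds 30% of the field")
    rng = np.random.default_rng(seed)
    img = np.full((2, rows, cols), 10, dtype=np.uint8)
    occupied = np.zeros((rows, cols), dtype=bool)
    objects = []
    for channel, count in ((0, n_green), (1, n_red)):
        placed = 0
        attempts = 0
        while placed < count:
            attempts += 1
            if attempts > 2000 * max(count, 1):
                raise RuntimeError("could not place all cells without overlap")
            area = rng.uniform(a_min, a_max)
            b_semi = np.sqrt(area / (3.0 * np.pi))
            a_semi = 3.0 * b_semi
            ori = rng.uniform(0.0, np.pi)
            r0 = rng.uniform(a_semi + 1, rows - a_semi - 2)
            c0 = rng.uniform(a_semi + 1, cols - a_semi - 2)
            rr, cc = draw_ellipse(r0, c0, a_semi, b_semi, rotation=ori)
            if rr.size < a_min or rr.size > a_max:
                continue
            # exclusion zone: the ellipse dilated by the gap
            rr_g, cc_g = draw_ellipse(
                r0, c0, a_semi + min_gap_px, b_semi + min_gap_px, rotation=ori,
                shape=(rows, cols),
            )
            if occupied[rr_g, cc_g].any():
                continue
            img[channel, rr, cc] = 200
            occupied[rr_g, cc_g] = True
            objects.append((channel, float(rr.mean()), float(cc.mean()), int(rr.size)))
            placed += 1
    return img, CellGroundTruth(n_green=n_green, n_red=n_red, objects=objects)


def gen_footprint_image(
    semi_major_mm: float,
    semi_minor_mm: float,
    scene: SyntheticScene,
) -> np.ndarray:
    """Top-view footprint: a dark filled ellipse on light background."""
    rows, cols = scene.image_size
    r0, c0 = rows / 2.0 - 0.5, cols / 2.0 - 0.5
    mask = np.zeros((rows * _SS, cols * _SS), dtype=float)
    rr, cc = draw_ellipse(
        r0 * _SS + (_SS - 1) / 2.0,
        c0 * _SS + (_SS - 1) / 2.0,
        semi_minor_mm / scene.pixel_scale * _SS,
        semi_major_mm / scene.pixel_scale * _SS,
        shape=mask.shape,
    )
    mask[rr, cc] = 1.0
    coverage = downscale_local_mean(mask, (_SS, _SS))
    img = (1.0 - coverage) * _BG + coverage * _FG
    rng = _rng_for(scene.seed, 4)
    if scene.noise_sd > 0:
        img = img + rng.normal(0.0, scene.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def noisy_linear_volumes(
    v0_uL: float,
    slope_uL_per_s: float,
    times_s: np.ndarray,
    noise_rel: float,
    seed: int,
) -> np.ndarray:
    """Volumes on the line v0 + slope*t, each scaled by (1 + N(0, noise_rel))."""
    times_s = np.asarray(times_s, dtype=float)
    v = v0_uL + slope_uL_per_s * times_s
    rng = np.random.default_rng(seed)
    return v * (1.0 + noise_rel * rng.standard_normal(times_s.shape))


def save_series(frames, out_dir: str | Path, index_name: str, index_values) -> Path:
    """Write a frame series as PNGs + JSON sidecars + a CSV manifest."""
    import imageio.v3 as iio
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for k, (frame, idx) in enumerate(zip(frames, index_values)):
        name = f"frame_{k:04d}.png"
        if frame.image is not None:
            iio.imwrite(out / name, frame.image)
        (out / f"frame_{k:04d}.json").write_text(frame.truth.to_json())
        records.append({"frame_id": k, index_name: idx, "file": name})
    manifest = out / "manifest.csv"
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest
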