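"""Forced wetting under a centrifugal ramp: onsets, plateaus and retention.

A droplet on a rotating horizontal substrate experiences a tangential
acceleration a_T = omega^2 * r (omega = 2*pi*RS/60).  As the rotation
speed RS rises along the ramp, the front contact angle climbs to the
advancing plateau theta_a (spreading onset: the front edge depins), then
the rear angle falls to the receding plateau theta_r and the rear edge
depins (sliding onset).  The critical acceleration at sliding gives the
tangential Bond number Bo_T = rho*L^2*a_T/sigma and, multiplied by the
drop mass, the Furmidge retention force

    F_s = k * R * sigma * (cos theta_r - cos theta_a)

from which the retention factor k is extracted for a characteristic length
R taken as either the initial drop length (k1) or the length at sliding
(k2).  By construction k1*L_initial = k2*L_sliding exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fluids import FluidProperties
from .imaging import DropGeometry

__all__ = [
    "RigConfig",
    "RampFrame",
    "WettingEvents",
    "rs_to_aT",
    "bond_number",
    "retention_force",
    "furmidge_k",
    "detect_events",
    "frames_from_truths",
]


@dataclass(frozen=True)
class RigConfig:
    """Rotating-stage geometry and ramp protocol."""

    r_radial_m: float = 0.25  # radial distance of the drop from the axis
    ramp_rate_rpm_per_s: float = 1.0
    rs_max_rpm: float = 100.0
    char_length_Bo_m: float = 0.001  # characteristic length for Bo_T

    def __post_init__(self) -> None:
        if min(self.r_radial_m, self.ramp_rate_rpm_per_s, self.rs_max_rpm,
               self.char_length_Bo_m) <= 0:
            raise ValueError("all rig parameters must be positive")


@dataclass(frozen=True)
class RampFrame:
    """One frame of a rotation ramp: speed plus measured geometry."""

    rs_rpm: float
    geometry: DropGeometry

    @property
    def a_T(self) -> float:
        raise AttributeError("a_T depends on the rig radius; use rs_to_aT")


@dataclass(frozen=True)
class WettingEvents:
    """Kinematic events and retention quantities of one ramp experiment."""

    theta_adv_deg: float | None
    theta_rec_deg: float | None
    rs_spread_rpm: float | None
    rs_slide_rpm: float | None  # None: rear permanently pinned
    L_initial_mm: float
    L_sliding_mm: float | None
    static: bool = False  # no edge ever moved
    aT_crit: float | None = None  # m/s^2 at sliding (or disappearance)
    Bo_T: float | None = None
    F_s: float | None = None  # N
    k1: float | None = None
    k2: float | None = None


def rs_to_aT(rs_rpm: float, r_radial_m: float) -> float:
    """Tangential acceleration a_T = (2*pi*RS/60)^2 * r, m/s^2."""
    if rs_rpm < 0 or r_radial_m <= 0:
        raise ValueError("rotation speed must be >= 0 and radius > 0")
    omega = 2.0 * np.pi * rs_rpm / 60.0
    return float(omega * omega * r_radial_m)


def bond_number(fluid: FluidProperties, L_m: float, a_T: float) -> float:
    """Tangential Bond number Bo_T = rho*L^2*a_T/sigma (dimensionless)."""
    if L_m <= 0 or a_T < 0:
        raise ValueError("need L > 0 and a_T >= 0")
    return fluid.density * L_m * L_m * a_T / fluid.surface_tension


def retention_force(fluid: FluidProperties, volume_uL: float, aT_crit: float) -> float:
    """Critical tangential (adhesion) force F_s = rho*V*a_T, newtons."""
    if volume_uL <= 0:
        raise ValueError("volume must be positive")
    return fluid.density * volume_uL * 1e-9 * aT_crit


def furmidge_k(
    F_s: float, R_m: float, sigma: float, theta_a_deg: float, theta_r_deg: float
) -> float:
    """Retention factor k = F_s / (R*sigma*(cos theta_r - cos theta_a)).

    Requires strictly positive hysteresis (theta_a > theta_r).
    """
    if theta_a_deg <= theta_r_deg:
        raise ValueError(
            f"zero or negative contact-angle hysteresis "
            f"(theta_a={theta_a_deg} <= theta_r={theta_r_deg})"
        )
    if R_m <= 0 or sigma <= 0:
        raise ValueError("R and sigma must be positive")
    hyst = np.cos(np.deg2rad(theta_r_deg)) - np.cos(np.deg2rad(theta_a_deg))
    return float(F_s / (R_m * sigma * hyst))


def frames_from_truths(ramp_frames) -> list[RampFrame]:
    """Adapt synthetic ramp ground truth into analysis frames."""
    out = []
    for f in ramp_frames:
        t = f.truth
        out.append(
            RampFrame(
                rs_rpm=f.rs_rpm,
                geometry=DropGeometry(
                    theta_left=t.theta_left,
                    theta_right=t.theta_right,
                    length_mm=t.length_mm,
                    height_mm=t.height_mm,
                    edge_left_mm=t.edge_left_mm,
                    edge_right_mm=t.edge_right_mm,
                    volume_uL=t.volume_uL,
                ),
            )
        )
    return out


def _onset(
    rs: np.ndarray, displacement_mm: np.ndarray, thr_mm: float, persistence: int
) -> int | None:
    """Index of the first frame of a persistent displacement run."""
    moved = displacement_mm > thr_mm
    run = 0
    for i, m in enumerate(moved):
        run = run + 1 if m else 0
        if run >= persistence:
            return i - persistence + 1
    return None


def _plateau_mask(
    rs: np.ndarray, theta: np.ndarray, tol_deg_per_rpm: float, window: int = 5
) -> np.ndarray:
    """Frames where the local d(theta)/d(rs) slope magnitude is below tol."""
    n = rs.size
    half = window // 2
    mask = np.zeros(n, dtype=bool)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        if hi - lo < 2:
            continue
        slope = np.polyfit(rs[lo:hi], theta[lo:hi], 1)[0]
        mask[i] = abs(slope) < tol_deg_per_rpm
    return mask


def detect_events(
    frames: list[RampFrame],
    plateau_tol_deg_per_rpm: float = 0.1,
    motion_threshold: float = 0.02,
    persistence: int = 2,
    fluid: FluidProperties | None = None,
    rig: RigConfig = RigConfig(),
    volume_uL: float | None = None,
) -> WettingEvents:
    """Extract spreading/sliding onsets and angle plateaus from a ramp.

    The spreading onset is the first rotation speed at which the front edge
    has advanced by more than ``motion_threshold`` of the initial length
    with ``persistence``-frame persistence; the advancing angle is the mean
    front angle over the post-onset plateau (local angle-vs-speed slope
    below ``plateau_tol_deg_per_rpm``).  The sliding onset and receding
    angle follow symmetrically from the rear edge and rear angle; a rear
    edge that never depins yields ``rs_slide = None`` with the receding
    angle taken from the trailing rear-angle plateau.

    When ``fluid`` (and optionally ``volume_uL``, defaulting to the first
    frame's fitted volume) is given, the retention quantities a_T, Bo_T,
    F_s, k1 and k2 are filled in at the sliding onset.
    """
    if len(frames) < 10:
        raise ValueError(f"need >= 10 frames, got {len(frames)}")
    rs = np.array([f.rs_rpm for f in frames])
    if np.any(np.diff(rs) <= 0):
        raise ValueError("frames must be ordered by increasing rotation speed")
    th_front = np.array([f.geometry.theta_right for f in frames])
    th_rear = np.array([f.geometry.theta_left for f in frames])
    e_front = np.array([f.geometry.edge_right_mm for f in frames])
    e_rear = np.array([f.geometry.edge_left_mm for f in frames])
    L = np.array([f.geometry.length_mm for f in frames])
    L0 = L[0]
    thr_mm = motion_threshold * L0

    # force points toward +r: front advances outward, rear follows
    i_spread = _onset(rs, e_front - e_front[0], thr_mm, persistence)
    i_slide = _onset(rs, e_rear - e_rear[0], thr_mm, persistence)

    if i_spread is None:
        return WettingEvents(
            theta_adv_deg=None,
            theta_rec_deg=None,
            rs_spread_rpm=None,
            rs_slide_rpm=None,
            L_initial_mm=float(L0),
            L_sliding_mm=None,
            static=True,
        )

    plateau_front = _plateau_mask(rs, th_front, plateau_tol_deg_per_rpm)
    sel_a = plateau_front & (np.arange(rs.size) >= i_spread)
    if not sel_a.any():
        raise ValueError("no advancing-angle plateau found after spreading onset")
    theta_a = float(th_front[sel_a].mean())

    plateau_rear = _plateau_mask(rs, th_rear, plateau_tol_deg_per_rpm)
    if i_slide is not None:
        sel_r = plateau_rear & (np.arange(rs.size) >= i_slide)
        if not sel_r.any():
            raise ValueError("no receding-angle plateau found after sliding onset")
        rs_slide = float(rs[i_slide])
        L_slide = float(L[i_slide])
    else:
        # permanently pinned rear: receding angle from the trailing plateau
        tail = np.flatnonzero(plateau_rear)
        if tail.size == 0:
            raise ValueError("no receding-angle plateau found (pinned rear)")
        # last contiguous plateau run
        breaks = np.flatnonzero(np.diff(tail) > 1)
        start = tail[breaks[-1] + 1] if breaks.size else tail[0]
        sel_r = np.zeros(rs.size, dtype=bool)
        sel_r[start:] = plateau_rear[start:]
        rs_slide = None
        L_slide = None
    theta_r = float(th_rear[sel_r].mean())
    if theta_a <= theta_r:
        raise ValueError(
            f"detected advancing angle {theta_a:.1f} <= receding {theta_r:.1f}"
        )

    aT = Bo = Fs = k1 = k2 = None
    if fluid is not None and rs_slide is not None:
        aT = rs_to_aT(rs_slide, rig.r_radial_m)
        Bo = bond_number(fluid, rig.char_length_Bo_m, aT)
        vol = volume_uL if volume_uL is not None else frames[0].geometry.volume_uL
        if vol is not None:
            Fs = retention_force(fluid, vol, aT)
            k1 = furmidge_k(Fs, L0 * 1e-3, fluid.surface_tension, theta_a, theta_r)
            k2 = furmidge_k(Fs, L_slide * 1e-3, fluid.surface_tension, theta_a, theta_r)

    return WettingEvents(
        theta_adv_deg=theta_a,
        theta_rec_deg=theta_r,
        rs_spread_rpm=float(rs[i_spread]),
        rs_slide_rpm=rs_slide,
        L_initial_mm=float(L0),
        L_sliding_mm=L_slide,
        static=False,
        aT_crit=aT,
        Bo_T=Bo,
        F_s=Fs,
        k1=k1,
        k2=k2,
    )
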