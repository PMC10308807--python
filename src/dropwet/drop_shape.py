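"""Axisymmetric Young-Laplace sessile-drop shapes.

The equilibrium profile of an axisymmetric sessile drop satisfies, in
arc-length parametrisation measured from the apex,

    dx/ds   = cos(phi)
    dz/ds   = sin(phi)
    dphi/ds = 2*b + c*z - sin(phi)/x

where ``x`` is the radial coordinate, ``z`` the depth below the apex
(increasing downward into the drop), ``phi`` the tangent angle, ``b`` the
apex curvature (1/m) and ``c = rho*g/sigma`` the capillary parameter
(1/m^2).  At the apex the last term is singular; the series limit gives
``dphi/ds -> b`` as ``s -> 0``, which is used to start the integration a
small step off the apex.

For ``c = 0`` the solution is an exact sphere of radius ``1/b``; all
metrics then reduce to the spherical-cap closed forms, which the tests use
as an oracle.

Internally the system is integrated in units of ``1/b`` (so the reduced
apex curvature is 1 and gravity enters through the reduced Bond parameter
``C = c/b**2``), with the drop volume and cross-section area carried along
as extra quadrature states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .fluids import FluidProperties, G_STANDARD

__all__ = [
    "YLShape",
    "ShapeMetrics",
    "integrate_shape",
    "shape_metrics",
    "solve_for",
    "spherical_cap_volume",
    "spherical_cap_radius_from_volume",
    "ShapeSolverError",
]


class ShapeSolverError(RuntimeError):
    """Raised when the Young-Laplace integration or inverse solve fails."""


@dataclass(frozen=True)
class YLShape:
    """Sampled Young-Laplace profile from the apex down to ``phi_max``.

    Arrays are sampled densely along the arc; ``x`` and ``z`` are in metres
    (``z`` is depth below the apex), ``phi`` in radians.  ``volume`` and
    ``area`` are the cumulative solid-of-revolution volume (m^3) and planar
    cross-section area (m^2) of the drop truncated at each sample.
    """

    b: float
    c: float
    s: np.ndarray
    x: np.ndarray
    z: np.ndarray
    phi: np.ndarray
    volume: np.ndarray
    area: np.ndarray

    def at_phi(self, phi: float) -> tuple[float, float, float, float]:
        """Interpolate (x, z, volume, area) at tangent angle ``phi`` (rad)."""
        if not (self.phi[0] <= phi <= self.phi[-1]):
            raise ValueError(
                f"phi={phi:.4f} rad outside integrated range "
                f"[{self.phi[0]:.4f}, {self.phi[-1]:.4f}]"
            )
        return (
            float(np.interp(phi, self.phi, self.x)),
            float(np.interp(phi, self.phi, self.z)),
            float(np.interp(phi, self.phi, self.volume)),
            float(np.interp(phi, self.phi, self.area)),
        )

    def radius_at_depth(self, depth: np.ndarray) -> np.ndarray:
        """Flank radius x (m) at given depth z below the apex (m)."""
        return np.interp(depth, self.z, self.x)

    def to_frame(self):
        """Export as a pandas DataFrame with columns (s, x, z, phi)."""
        import pandas as pd

        return pd.DataFrame({"s": self.s, "x": self.x, "z": self.z, "phi": self.phi})


@dataclass(frozen=True)
class ShapeMetrics:
    """Geometry of a shape truncated at a contact angle."""

    volume_uL: float
    contact_radius_mm: float
    height_mm: float
    cross_section_mm2: float


def _rhs(u, y, C):
    X, Z, phi, W, A = y
    sphi = np.sin(phi)
    return [
        np.cos(phi),
        sphi,
        2.0 + C * Z - sphi / X,
        np.pi * X * X * sphi,
        2.0 * X * sphi,
    ]


def integrate_shape(
    b: float,
    c: float,
    phi_max: float,
    rtol: float = 1e-9,
    n_samples: int = 4001,
) -> YLShape:
    """Integrate the axisymmetric Young-Laplace profile from the apex.

    Parameters
    ----------
    b : float
        Apex curvature, 1/m (> 0).
    c : float
        Capillary parameter rho*g/sigma, 1/m^2 (>= 0 for a sessile drop).
    phi_max : float
        Tangent angle (rad) at which to stop, in (0, pi].
    rtol : float
        Relative tolerance of the adaptive integrator.
    n_samples : int
        Number of dense samples returned along the arc.

    Raises
    ------
    ShapeSolverError
        If the tangent angle fails to reach ``phi_max`` (re-entrant or
        truncated shape) or becomes non-monotone along the arc.
    """
    if b <= 0:
        raise ValueError(f"apex curvature b must be positive, got {b}")
    if c < 0:
        raise ValueError(f"capillary parameter c must be >= 0, got {c}")
    if not (0 < phi_max <= np.pi):
        raise ValueError(f"phi_max must be in (0, pi], got {phi_max}")

    C = c / (b * b)
    u0 = 1e-8  # reduced arc-length offset from the singular apex
    y0 = [u0, 0.5 * u0 * u0, u0, 0.25 * np.pi * u0**4, 2.0 / 3.0 * u0**3]

    def reach(u, y, C):
        return y[2] - phi_max

    reach.terminal = True
    reach.direction = 1

    # Flattened (large-C) drops accumulate arc length; generous span, the
    # event terminates far earlier for every physical shape.
    u_max = 4.0 * np.pi * (1.0 + np.sqrt(max(C, 1.0)))
    sol = solve_ivp(
        _rhs,
        (u0, u_max),
        y0,
        args=(C,),
        events=reach,
        rtol=rtol,
        atol=1e-12,
        dense_output=True,
        method="RK45",
    )
    if not sol.success or sol.t_events[0].size == 0:
        raise ShapeSolverError(
            f"Young-Laplace integration did not reach phi={phi_max:.3f} rad "
            f"(b={b:.4g} 1/m, c={c:.4g} 1/m^2): tangent angle stalled at "
            f"{sol.y[2, -1]:.3f} rad"
        )
    u_end = float(sol.t_events[0][0])
    u = np.linspace(u0, u_end, n_samples)
    X, Z, phi, W, A = sol.sol(u)
    if np.any(np.diff(phi) <= 0):
        k = int(np.argmax(np.diff(phi) <= 0))
        raise ShapeSolverError(
            f"tangent angle non-monotone at reduced arc position u={u[k]:.4f} "
            f"(phi={phi[k]:.4f} rad): re-entrant shape"
        )
    # back to physical units
    return YLShape(
        b=b,
        c=c,
        s=u / b,
        x=X / b,
        z=Z / b,
        phi=phi,
        volume=W / b**3,
        area=A / b**2,
    )


def shape_metrics(shape: YLShape, theta_deg: float) -> ShapeMetrics:
    """Truncate ``shape`` at contact angle ``theta_deg`` and report geometry.

    Volume is the solid of revolution integral(pi * x^2 dz) from the apex to
    the contact line, the contact radius is x at phi = theta and the height
    is the corresponding depth of the contact line below the apex.
    """
    theta = np.deg2rad(theta_deg)
    x, z, vol, area = shape.at_phi(theta)
    return ShapeMetrics(
        volume_uL=vol * 1e9,
        contact_radius_mm=x * 1e3,
        height_mm=z * 1e3,
        cross_section_mm2=area * 1e6,
    )


def spherical_cap_volume(radius_m: float, theta_deg: float) -> float:
    """Closed-form spherical-cap volume (m^3) for sphere radius and contact angle."""
    th = np.deg2rad(theta_deg)
    return np.pi / 3.0 * radius_m**3 * (1.0 - np.cos(th)) ** 2 * (2.0 + np.cos(th))


def spherical_cap_radius_from_volume(volume_m3: float, theta_deg: float) -> float:
    """Invert :func:`spherical_cap_volume` for the sphere radius (m)."""
    th = np.deg2rad(theta_deg)
    denom = np.pi / 3.0 * (1.0 - np.cos(th)) ** 2 * (2.0 + np.cos(th))
    return float((volume_m3 / denom) ** (1.0 / 3.0))


def solve_for(
    volume_uL: float,
    theta_deg: float,
    fluid: FluidProperties,
    gravity: float = G_STANDARD,
    rtol: float = 1e-5,
) -> YLShape:
    """Find the Young-Laplace shape with the given volume at a contact angle.

    Searches the apex curvature ``b`` (bracketing around the spherical-cap
    inverse, then Brent refinement) so that the shape truncated at
    ``theta_deg`` encloses ``volume_uL`` within 0.1% relative.

    Parameters
    ----------
    volume_uL : float
        Target drop volume, microlitres (> 0).
    theta_deg : float
        Contact angle in degrees, within [5, 175].
    fluid : FluidProperties
        Supplies density and surface tension for c = rho*g/sigma.
    gravity : float
        Gravitational acceleration; pass 0 for the zero-gravity
        (spherical-cap) limit.
    """
    if volume_uL <= 0:
        raise ValueError(f"volume must be positive, got {volume_uL}")
    if not (5.0 <= theta_deg <= 175.0):
        raise ValueError(f"theta must be within [5, 175] degrees, got {theta_deg}")
    c = fluid.capillary_parameter(gravity)
    v_target = volume_uL * 1e-9

    b0 = 1.0 / spherical_cap_radius_from_volume(v_target, theta_deg)
    phi_max = min(np.deg2rad(theta_deg) * 1.02 + 1e-3, np.pi)

    def vol_err(b):
        shp = integrate_shape(b, c, phi_max, rtol=1e-8, n_samples=1201)
        _, _, vol, _ = shp.at_phi(np.deg2rad(theta_deg))
        return vol - v_target

    lo, hi = b0 / 2.0, b0 * 2.0
    f_lo, f_hi = vol_err(lo), vol_err(hi)
    # volume decreases with b: want f(lo) > 0 > f(hi)
    expansions = 0
    while f_lo < 0 and expansions < 6:
        lo /= 2.0
        f_lo = vol_err(lo)
        expansions += 1
    while f_hi > 0 and expansions < 12:
        hi *= 2.0
        f_hi = vol_err(hi)
        expansions += 1
    if f_lo < 0 or f_hi > 0:
        raise ShapeSolverError(
            f"no apex-curvature bracket found for V={volume_uL} uL, "
            f"theta={theta_deg} deg in b range [{lo:.4g}, {hi:.4g}] 1/m"
        )
    b = brentq(vol_err, lo, hi, rtol=rtol)
    return integrate_shape(b, c, phi_max, rtol=1e-9)
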