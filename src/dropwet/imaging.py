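"""Contour, baseline and contact-angle extraction from droplet images.

Side-view frames yield a subpixel droplet profile above an automatically
detected substrate baseline; contact angles come from quadratic flank fits
over the near-baseline region (tangent evaluated at the contact line,
measured through the liquid), the conventional polynomial-goniometry
estimator.  Top-view frames yield a closed footprint contour with perimeter
and projected area.

All interface quantities are physical (mm, degrees); pixels are internal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "DropProfile",
    "DropGeometry",
    "ImagingError",
    "detect_baseline",
    "extract_profile",
    "contact_angles",
    "contact_points",
    "measure_frame",
    "top_contour",
    "TopContour",
]


class ImagingError(RuntimeError):
    """Raised when an image does not contain a measurable droplet/baseline."""


@dataclass(frozen=True)
class DropProfile:
    """Ordered droplet contour above the baseline, left to right.

    ``r`` and ``z`` are in mm with z = 0 on the substrate surface; points
    run along the interface from the left contact region over the apex to
    the right contact region.
    """

    r: np.ndarray
    z: np.ndarray
    pixel_scale: float
    source_frame: str = ""

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        z = np.asarray(self.z, dtype=float)
        if r.shape != z.shape or r.ndim != 1:
            raise ValueError("r and z must be equal-length 1-D arrays")
        if np.any(z < -1e-9):
            raise ValueError("profile points must lie above the baseline (z >= 0)")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "z", np.maximum(z, 0.0))

    @property
    def apex_index(self) -> int:
        return int(np.argmax(self.z))

    @property
    def height_mm(self) -> float:
        return float(self.z.max())

    def flanks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(r_left, z_left, r_right, z_right), each ordered from baseline up."""
        k = self.apex_index
        return self.r[: k + 1], self.z[: k + 1], self.r[k:][::-1], self.z[k:][::-1]

    def mirrored(self, width_mm: float) -> "DropProfile":
        return DropProfile(
            r=(width_mm - self.r)[::-1],
            z=self.z[::-1],
            pixel_scale=self.pixel_scale,
            source_frame=self.source_frame,
        )


@dataclass(frozen=True)
class DropGeometry:
    """Per-frame droplet measurements (front = right flank in ramp frames)."""

    theta_left: float
    theta_right: float
    length_mm: float
    height_mm: float
    edge_left_mm: float
    edge_right_mm: float
    volume_uL: float | None = None

    @property
    def theta_front(self) -> float:
        return self.theta_right

    @property
    def theta_rear(self) -> float:
        return self.theta_left


def detect_baseline(image: np.ndarray, min_prominence: float = 10.0) -> int:
    """Locate the substrate surface row from the vertical intensity gradient.

    Returns the row index maximizing the horizontally integrated absolute
    row-to-row intensity step (the first substrate row); ties break to the
    bottom-most row.  Raises :class:`ImagingError` if no step exceeds
    ``min_prominence`` intensity units.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    # mean absolute row-to-row step per column; a substrate edge steps across
    # the full width, so it dominates any droplet-boundary gradient
    grad = np.abs(np.diff(img, axis=0)).mean(axis=1)
    if grad.size == 0 or grad.max() < min_prominence:
        raise ImagingError(
            f"no horizontal edge with prominence >= {min_prominence} found; "
            "supply the baseline row manually"
        )
    best = np.flatnonzero(grad == grad.max())[-1]
    return int(best + 1)


def _droplet_mask(above: np.ndarray) -> tuple[np.ndarray, float]:
    """Threshold the above-baseline region and keep the droplet component."""
    thr = float(threshold_otsu(above))
    dark = above < thr
    labels = measure.label(dark, connectivity=2)
    touching = np.unique(labels[-1, :])
    touching = touching[touching != 0]
    if touching.size == 0:
        raise ImagingError("no dark region touching the baseline (0 candidates)")
    sizes = [(labels == lab).sum() for lab in touching]
    keep = touching[int(np.argmax(sizes))]
    return labels == keep, thr


def extract_profile(
    image: np.ndarray,
    baseline_row: int,
    pixel_scale: float,
    source_frame: str = "",
) -> DropProfile:
    """Trace the droplet interface above the baseline to subpixel precision.

    The above-baseline region is thresholded (Otsu); the marching-squares
    contour of the largest dark component touching the baseline is taken at
    the threshold level, which linearly interpolates the intensity crossing
    between pixels.  Coordinates are converted to mm with z = 0 on the
    substrate surface (half a pixel below the last air row).
    """
    img = np.asarray(image, dtype=float)
    above = img[:baseline_row, :]
    mask, thr = _droplet_mask(above)

    def _cross(values: np.ndarray, offset: int, near: float) -> float | None:
        """Subpixel threshold crossing in a 1-D window, nearest to ``near``."""
        d = values - thr
        sign_change = np.flatnonzero(d[:-1] * d[1:] <= 0)
        sign_change = sign_change[d[sign_change] != d[sign_change + 1]]
        if sign_change.size == 0:
            return None
        pos = sign_change + d[sign_change] / (d[sign_change] - d[sign_change + 1])
        return float(offset + pos[np.argmin(np.abs(offset + pos - near))])

    rows_any = np.flatnonzero(mask.any(axis=1))
    r_pts: list[float] = []
    z_pts: list[float] = []
    pad = 5
    ncols = above.shape[1]
    # flank samples: one left and one right crossing per row
    left_set, right_set = [], []
    for r in rows_any:
        cols = np.flatnonzero(mask[r])
        cl, cr = cols[0], cols[-1]
        lo, hi = max(cl - pad, 0), min(cl + pad + 1, ncols)
        xl = _cross(above[r, lo:hi], lo, cl - 0.5)
        lo, hi = max(cr - pad, 0), min(cr + pad + 1, ncols)
        xr = _cross(above[r, lo:hi], lo, cr + 0.5)
        z = (baseline_row - 0.5 - r) * pixel_scale
        if xl is not None:
            left_set.append((xl * pixel_scale, z))
        if xr is not None:
            right_set.append((xr * pixel_scale, z))
    # apex samples: one top crossing per column, kept only in the flat cap
    # region (z > 0.5 h) where column-wise interpolation is accurate
    heights = []
    top_set = []
    cols_any = np.flatnonzero(mask.any(axis=0))
    for c in cols_any:
        rt = np.flatnonzero(mask[:, c])[0]
        lo, hi = max(rt - pad, 0), min(rt + pad + 1, baseline_row)
        rz = _cross(above[lo:hi, c], lo, rt - 0.5)
        if rz is not None:
            top_set.append((c * pixel_scale, (baseline_row - 0.5 - rz) * pixel_scale))
    if not (left_set and right_set):
        raise ImagingError("droplet component produced no flank crossings")
    h_est = max(
        max(z for _, z in left_set + right_set),
        max((z for _, z in top_set), default=0.0),
    )
    top_set = [(r_, z_) for r_, z_ in top_set if z_ > 0.5 * h_est]
    pts = sorted(left_set + top_set + right_set)
    r = np.array([p[0] for p in pts])
    z = np.array([p[1] for p in pts])
    return DropProfile(r=r, z=z, pixel_scale=pixel_scale, source_frame=source_frame)


def _flank_tangent(
    r: np.ndarray, z: np.ndarray, z_cut: float, side: str
) -> tuple[float, float]:
    """Quadratic fit r(z) over z <= z_cut; return (theta_deg, r at z=0)."""
    sel = z <= z_cut
    if sel.sum() < 10:
        raise ImagingError(
            f"too few near-baseline points on the {side} flank "
            f"({int(sel.sum())} < 10); raise fit_height_frac"
        )
    coef = np.polyfit(z[sel], r[sel], 2)
    drdz = coef[1]
    r0 = coef[2]
    if side == "left":
        theta = np.degrees(np.arctan2(1.0, drdz))
    else:
        theta = np.degrees(np.arctan2(1.0, -drdz))
    return float(theta), float(r0)


def contact_angles(
    profile: DropProfile, fit_height_frac: float = 0.15
) -> tuple[float, float]:
    """Left and right contact angles (degrees, measured inside the liquid).

    Each flank is fit with a quadratic r(z) over the points with
    z <= fit_height_frac * height and the tangent is evaluated at z = 0.
    """
    rl, zl, rr, zr = profile.flanks()
    z_cut = fit_height_frac * profile.height_mm
    th_l, _ = _flank_tangent(rl, zl, z_cut, "left")
    th_r, _ = _flank_tangent(rr, zr, z_cut, "right")
    return th_l, th_r


def contact_points(
    profile: DropProfile, fit_height_frac: float = 0.15
) -> tuple[float, float]:
    """Left/right contact-line positions (mm) from the flank fits at z = 0."""
    rl, zl, rr, zr = profile.flanks()
    z_cut = fit_height_frac * profile.height_mm
    _, e_l = _flank_tangent(rl, zl, z_cut, "left")
    _, e_r = _flank_tangent(rr, zr, z_cut, "right")
    return e_l, e_r


def measure_frame(
    image: np.ndarray,
    pixel_scale: float,
    baseline_row: int | None = None,
    fit_height_frac: float = 0.15,
    source_frame: str = "",
) -> tuple[DropGeometry, DropProfile]:
    """Full side-view measurement: baseline, profile, angles, length, height."""
    if baseline_row is None:
        baseline_row = detect_baseline(image)
    profile = extract_profile(image, baseline_row, pixel_scale, source_frame)
    th_l, th_r = contact_angles(profile, fit_height_frac)
    e_l, e_r = contact_points(profile, fit_height_frac)
    geom = DropGeometry(
        theta_left=th_l,
        theta_right=th_r,
        length_mm=e_r - e_l,
        height_mm=profile.height_mm,
        edge_left_mm=e_l,
        edge_right_mm=e_r,
    )
    return geom, profile


@dataclass(frozen=True)
class TopContour:
    contour_mm: np.ndarray  # (N, 2) closed boundary, (row, col) in mm
    perimeter_mm: float
    area_mm2: float


def top_contour(image: np.ndarray, pixel_scale: float) -> TopContour:
    """Closed footprint contour of the largest dark region in a top view.

    Perimeter is the polygon arc length of the subpixel contour; projected
    area comes from the shoelace formula.
    """
    img = np.asarray(image, dtype=float)
    thr = float(threshold_otsu(img))
    dark = img < thr
    if not dark.any() or dark.mean() < 1e-4 or img.std() < 1.0:
        raise ImagingError("no dark footprint region found")
    labels = measure.label(dark, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = int(np.argmax(sizes))
    work = np.where(labels == keep, img, 255.0)
    contours = measure.find_contours(work, level=thr)
    if not contours:
        raise ImagingError("footprint produced no contour")
    contour = max(contours, key=lambda c: len(c))
    # short circular moving average suppresses marching-squares zigzag,
    # which otherwise inflates the arc length by a few percent
    if len(contour) >= 16:
        win = 5
        pad = np.vstack([contour[-win:], contour, contour[:win]])
        kernel = np.ones(win) / win
        contour = np.column_stack(
            [np.convolve(pad[:, k], kernel, mode="same")[win:-win] for k in (0, 1)]
        )
    pts = contour * pixel_scale
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    perimeter = float(np.sqrt((seg**2).sum(axis=1)).sum())
    y, x = closed[:, 0], closed[:, 1]
    area = float(abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])) / 2.0)
    return TopContour(contour_mm=pts, perimeter_mm=perimeter, area_mm2=area)
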