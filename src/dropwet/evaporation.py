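"""Evaporation kinetics from per-frame droplet geometry.

Drop volume versus time is summarised by an ordinary-least-squares line
(the volume decay is close to linear over the first ~50 min of drying);
contact-line pinning is monitored through normalized length/height
trajectories and an edge-displacement depinning detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EvapResult",
    "fit_linear_volume",
    "normalize_trajectories",
    "detect_depinning",
    "DEFAULT_FIT_WINDOW_S",
]

#: Default fit window: volume decay is linear up to ~50 min (3000 s); at
#: larger times the volume flattens out and the line no longer applies.
DEFAULT_FIT_WINDOW_S = (0.0, 3000.0)


@dataclass(frozen=True)
class EvapResult:
    slope_uL_per_s: float
    intercept_uL: float
    r_squared: float
    normalized_length: np.ndarray
    normalized_height: np.ndarray
    depin_time_s: float | None


def fit_linear_volume(
    times_s: np.ndarray,
    volumes_uL: np.ndarray,
    window_s: tuple[float, float] | None = DEFAULT_FIT_WINDOW_S,
) -> tuple[float, float, float]:
    """OLS fit of volume on time; returns (slope, intercept, R^2).

    ``window_s`` restricts the fit to a time range (inclusive); pass None
    to use every point.  A response with zero variance yields slope 0 and
    R^2 = 0 by convention.
    """
    t = np.asarray(times_s, dtype=float)
    v = np.asarray(volumes_uL, dtype=float)
    if window_s is not None:
        sel = (t >= window_s[0]) & (t <= window_s[1])
        t, v = t[sel], v[sel]
    if t.size < 3:
        raise ValueError(f"need >= 3 points in the fit window, got {t.size}")
    if np.ptp(t) == 0:
        raise ValueError("all times identical; cannot fit a line")
    if np.ptp(v) == 0:
        return 0.0, float(v[0]), 0.0
    res = stats.linregress(t, v)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def normalize_trajectories(
    lengths_mm: np.ndarray, heights_mm: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Divide length and height series by their first-frame values."""
    L = np.asarray(lengths_mm, dtype=float)
    h = np.asarray(heights_mm, dtype=float)
    if L[0] <= 0 or h[0] <= 0:
        raise ValueError("first frame must have positive length and height")
    return L / L[0], h / h[0]


def detect_depinning(
    times_s: np.ndarray,
    edge_left_mm: np.ndarray,
    edge_right_mm: np.ndarray,
    rel_threshold: float = 0.02,
    persistence: int = 2,
) -> float | None:
    """Earliest time either contact line has retracted inward and stayed.

    An edge counts as depinned once it has moved inward by more than
    ``rel_threshold`` of the initial length for at least ``persistence``
    consecutive frames; returns the first time of that run, or None.
    Invariant to a uniform translation of all edge positions.
    """
    t = np.asarray(times_s, dtype=float)
    el = np.asarray(edge_left_mm, dtype=float)
    er = np.asarray(edge_right_mm, dtype=float)
    if t.size < persistence + 1:
        raise ValueError(f"need >= {persistence + 1} frames")
    L0 = er[0] - el[0]
    if L0 <= 0:
        raise ValueError("initial length must be positive")
    inward = np.maximum(el - el[0], er[0] - er)  # mm moved toward the centre
    moved = inward > rel_threshold * L0
    run = 0
    for i, m in enumerate(moved):
        run = run + 1 if m else 0
        if run >= persistence:
            return float(t[i - persistence + 1])
    return None
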