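"""Power-law (shear-thinning) rheology of cell suspensions.

Apparent viscosity over the measured shear-rate decade (10-100 1/s) is
described by eta = K * gamma_dot**(n - 1); the fit is ordinary least
squares of ln(eta) on ln(gamma_dot), the field convention for flow indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["FlowCurve", "PowerLawFit", "fit_power_law", "classify_newtonian"]


@dataclass(frozen=True)
class FlowCurve:
    """Measured viscosity (Pa*s) versus shear rate (1/s)."""

    shear_rate: np.ndarray
    viscosity: np.ndarray
    temperature_C: float = 25.0

    def __post_init__(self) -> None:
        g = np.asarray(self.shear_rate, dtype=float)
        e = np.asarray(self.viscosity, dtype=float)
        if g.shape != e.shape or g.ndim != 1:
            raise ValueError("shear_rate and viscosity must be equal-length 1-D")
        if np.any(g <= 0) or np.any(np.diff(g) <= 0):
            raise ValueError("shear rates must be positive and strictly increasing")
        object.__setattr__(self, "shear_rate", g)
        object.__setattr__(self, "viscosity", e)


@dataclass(frozen=True)
class PowerLawFit:
    K: float  # consistency, Pa*s^n
    n: float  # flow index
    r_squared: float


def fit_power_law(curve: FlowCurve) -> PowerLawFit:
    """Fit eta = K*gamma_dot**(n-1) by OLS in log-log space.

    Requires >= 4 points spanning at least half a decade of shear rate.
    """
    g, e = curve.shear_rate, curve.viscosity
    if g.size < 4:
        raise ValueError(f"need >= 4 points, got {g.size}")
    if np.log10(g[-1] / g[0]) < 0.5:
        raise ValueError("shear rates must span >= 0.5 decades")
    if np.any(e <= 0):
        raise ValueError("non-positive viscosity in flow curve")
    res = stats.linregress(np.log(g), np.log(e))
    return PowerLawFit(
        K=float(np.exp(res.intercept)),
        n=float(res.slope + 1.0),
        r_squared=float(res.rvalue**2),
    )


def classify_newtonian(fit: PowerLawFit, n_tol: float = 0.1) -> bool:
    """True if the flow index is within ``n_tol`` of 1 (Newtonian)."""
    return abs(fit.n - 1.0) <= n_tol
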