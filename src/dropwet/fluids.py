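"""Physical properties of the wetting agents.

Densities and surface tensions are in SI units; the optional power-law
parameters describe shear-thinning viscosity eta = K * gamma_dot**(n - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

#: Standard gravity, m/s^2.  All experiments run at 1 g (no tilting).
G_STANDARD = 9.81


@dataclass(frozen=True)
class FluidProperties:
    """Bulk properties of a droplet liquid.

    Parameters
    ----------
    density : float
        Mass density rho, kg/m^3.
    surface_tension : float
        Liquid-vapour surface tension sigma, N/m.
    power_law_K : float, optional
        Power-law consistency K, Pa*s^n.  ``None`` if not characterised.
    power_law_n : float, optional
        Power-law flow index n (dimensionless; n = 1 is Newtonian).
    """

    density: float
    surface_tension: float
    power_law_K: float | None = None
    power_law_n: float | None = None

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if self.surface_tension <= 0:
            raise ValueError(
                f"surface_tension must be positive, got {self.surface_tension}"
            )
        if self.power_law_K is not None and self.power_law_K <= 0:
            raise ValueError("power_law_K must be positive when given")
        if self.power_law_n is not None and self.power_law_n <= 0:
            raise ValueError("power_law_n must be positive when given")

    def capillary_parameter(self, gravity: float = G_STANDARD) -> float:
        """Return c = rho*g/sigma (1/m^2), the inverse capillary length squared."""
        return self.density * gravity / self.surface_tension


# Presets for the systems studied.  Densities/surface tensions follow the
# measured/assumed values for the minimal medium (water-like, 72 mN/m) and the
# P. fluorescens-laden suspension (1200 kg/m^3, 69 mN/m).  The consistency K of
# the suspensions is nominal (order-of-magnitude for dense cell suspensions);
# the flow indices are the fitted ones per optical density.
WATER = FluidProperties(density=1000.0, surface_tension=0.072)
MINIMAL_MEDIUM = FluidProperties(density=1000.0, surface_tension=0.072)
SUPERNATANT = FluidProperties(density=1000.0, surface_tension=0.072, power_law_K=1.2e-3, power_law_n=1.0)
BACTERIA_OD2 = FluidProperties(density=1200.0, surface_tension=0.069, power_law_K=5e-3, power_law_n=0.8)
BACTERIA_OD10 = FluidProperties(density=1200.0, surface_tension=0.069, power_law_K=2e-2, power_law_n=0.5)
BACTERIA_OD20 = FluidProperties(density=1200.0, surface_tension=0.069, power_law_K=5e-2, power_law_n=0.4)
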