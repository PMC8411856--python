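"""Canopy temperature from the energy budget.

The canopy (sunlit and shaded fractions share one temperature) is warmed or
cooled by the residual of measured net radiation against sensible and latent
heat flux, scaled by the canopy heat capacity.  When the tower does not
report all three fluxes, the caller falls back to air temperature.
"""

from __future__ import annotations

import logging
import math

log = logging.getLogger(__name__)

__all__ = ["canopy_heat_capacity", "canopy_temperature", "T_CLAMP"]

T_CLAMP = (250.0, 330.0)  # K


def canopy_heat_capacity(lai: float, sla: float, cdry: float = 1.4,
                         cwat: float = 4.18,
                         water_mass_fraction: float = 0.7) -> float:
    """Canopy heat capacity per ground area (J m-2 K-1).

    Dry mass per ground area is ``lai / sla`` (g C m-2 with SLA in
    m2 (g C)-1); water held in the foliage adds ``cwat * w/(1-w)`` per unit
    dry mass, with ``w`` the fresh-mass water fraction.
    """
    if lai < 0:
        raise ValueError("lai must be >= 0")
    if sla <= 0 or cdry <= 0 or cwat <= 0:
        raise ValueError("sla, cdry, cwat must be positive")
    if not 0 <= water_mass_fraction < 1:
        raise ValueError("water_mass_fraction must be in [0, 1)")
    dry_mass = lai / sla
    per_gram = cdry + cwat * water_mass_fraction / (1.0 - water_mass_fraction)
    return dry_mass * per_gram


def canopy_temperature(t_prev: float, rnet: float, h: float, le: float,
                       capacity: float, dt: float) -> float:
    """One explicit energy-budget step.

    ``t = t_prev + dt * (rnet - h - le) / capacity``, clamped to the
    physical range (250, 330) K with a logged warning when the clamp fires.
    Any missing (NaN) flux makes the budget undefined; the caller should
    substitute air temperature in that case (see the canopy pipeline).
    """
    if capacity <= 0 or dt <= 0:
        raise ValueError("capacity and dt must be positive")
    if any(map(math.isnan, (rnet, h, le, t_prev))):
        raise ValueError("energy fluxes must be present; use air temperature "
                         "as fallback when a flux is missing")
    t = t_prev + dt * (rnet - h - le) / capacity
    lo, hi = T_CLAMP
    if t <= lo or t >= hi:
        clamped = min(max(t, lo + 1e-6), hi - 1e-6)
        log.warning("canopy temperature %.1f K clamped to %.1f K", t, clamped)
        return clamped
    return t
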