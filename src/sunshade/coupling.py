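"""Coupling assimilation to CO2 supply: boundary-layer and Ball-Berry
stomatal conductance, and the hybrid Newton-Raphson/bisection solver for
intercellular CO2.

The demand side is the biochemical assimilation An(Ci); the supply side is
diffusion down the mole-fraction gradient, ``Ci' = Ca - An (1.37/gb +
1.65/gs)`` with the usual water-to-CO2 diffusivity factors and mesophyll
conductance omitted.  The fixed point Ci = Ci'(Ci) is found with Newton
steps on the residual f(Ci) = Ci' - Ci, guarded by bisection on the bracket
[0, 1.5 Ca]; iteration stops when successive iterates differ by less than
the tolerance (default 0.001 umol mol-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import GAS_CONSTANT, defaults
from .kinetics import AdjustedParams, Pathway
from .leafphys import c3_rates, c4_rates, electron_transport, net_assimilation

__all__ = ["CouplingResult", "ball_berry", "boundary_layer", "air_molar_density",
           "saturation_vapour_pressure", "solve_ci", "ci_residual"]

DIFF_BL = 1.37   # boundary-layer H2O -> CO2 diffusivity factor
DIFF_ST = 1.65   # stomatal H2O -> CO2 diffusivity factor


@dataclass(frozen=True)
class CouplingResult:
    ci: float            # umol mol-1
    an: float            # umol m-2 s-1
    gs: float            # mol H2O m-2 s-1
    iterations: int
    converged: bool
    delta: float         # |ci_new - ci_old| at termination


def saturation_vapour_pressure(t_k):
    """Tetens saturation vapour pressure (kPa) at temperature ``t_k`` (K)."""
    t_c = np.asarray(t_k, dtype=float) - 273.15
    out = 0.61078 * np.exp(17.27 * t_c / (t_c + 237.3))
    return float(out) if out.ndim == 0 else out


def air_molar_density(pressure_kpa: float, t_k: float) -> float:
    """Molar density of air (mol m-3) from the ideal gas law."""
    return pressure_kpa * 1000.0 / (GAS_CONSTANT * t_k)


def ball_berry(an, cs, hs, g0: float = 0.01, g1: float = 9.0):
    """Ball-Berry stomatal conductance ``gs = g0 + g1 An hs / cs``.

    ``cs`` is the CO2 mole fraction and ``hs`` the fractional relative
    humidity, both at the leaf surface.  Non-positive assimilation closes
    the stomata to the floor g0.
    """
    cs = np.asarray(cs, dtype=float)
    if np.any(cs <= 0):
        raise ValueError("cs must be positive")
    hs = np.asarray(hs, dtype=float)
    if np.any((hs < 0) | (hs > 1)):
        raise ValueError("hs must be in [0, 1]")
    out = g0 + g1 * np.maximum(np.asarray(an, float), 0.0) * hs / cs
    return float(out) if out.ndim == 0 else out


def boundary_layer(wind: float, dleaf: float = 0.04, cv: float = 0.01,
                   rho_mol: float = 41.0, u_min: float = 0.1) -> float:
    """Leaf boundary-layer conductance ``gb = cv sqrt(u/dleaf) rho``
    (mol m-2 s-1), with a wind floor ``u_min`` so calm air never gives zero
    conductance."""
    if wind < 0 or dleaf <= 0:
        raise ValueError("wind must be >= 0 and dleaf > 0")
    return cv * math.sqrt(max(wind, u_min) / dleaf) * rho_mol


def _demand(ci, params: AdjustedParams, pathway: Pathway, apar, leaf_cfg,
            theta1=None, theta2=None):
    """Biochemical An(Ci); broadcasts over ci arrays."""
    if pathway is Pathway.C4:
        ac, aj, ap = c4_rates(ci, params.vcmax, apar, params.kp,
                              alpha_c4=leaf_cfg["alpha_c4"])
        t1 = leaf_cfg["theta1_c4"] if theta1 is None else theta1
        t2 = leaf_cfg["theta2_c4"] if theta2 is None else theta2
        return net_assimilation(ac, aj, ap, params.rd, Pathway.C4, t1, t2)
    j = electron_transport(apar, params.jmax, theta_psii=leaf_cfg["theta_psii"],
                          phi_psii=leaf_cfg["phi_psii"])
    ac, aj, ap = c3_rates(ci, params.vcmax, j, params.gamma_star, params.kc21)
    t1 = leaf_cfg["theta1_c3"] if theta1 is None else theta1
    t2 = leaf_cfg["theta2_c3"] if theta2 is None else theta2
    return net_assimilation(ac, aj, ap, params.rd, Pathway.C3, t1, t2)


def _surface_state(an, ca, gb, g0, g1, rh, t_leaf, t_air):
    """Leaf-surface CO2, humidity and stomatal conductance.

    cs = ca - 1.37 An / gb; the surface humidity follows from vapour-flux
    continuity gs (e_i - e_s) = gb (e_s - e_a), which combined with the
    Ball-Berry relation gives a quadratic in gs (positive root taken).
    Broadcasts over arrays of ``an``.
    """
    an = np.asarray(an, dtype=float)
    cs = np.maximum(ca - DIFF_BL * an / gb, 1.0)
    e_i = saturation_vapour_pressure(t_leaf)
    e_a = rh * saturation_vapour_pressure(t_air)
    ha = min(e_a / e_i, 1.0)

    term = g1 * np.maximum(an, 0.0) / cs
    # gs^2 + (gb - g0 - term) gs - (g0 gb + term gb ha) = 0
    bq = gb - g0 - term
    cq = -(g0 * gb + term * gb * ha)
    gs = 0.5 * (-bq + np.sqrt(bq * bq - 4.0 * cq))
    gs = np.maximum(gs, g0)
    e_s = (gb * e_a + gs * e_i) / (gb + gs)
    hs = np.clip(e_s / e_i, 0.0, 1.0)
    return cs, hs, gs


def ci_residual(ci, *, ca, apar, t_leaf, t_air, rh, gb,
                params: AdjustedParams, pathway: Pathway,
                g0: float, g1: float, leaf_cfg: dict,
                theta1=None, theta2=None):
    """Residual f(Ci) = supply-recomputed Ci minus Ci.  Vectorised over ci.

    The same function drives the Newton/bisection solver and any brute-force
    grid scan, so a root of one is a root of the other by construction.
    """
    an = _demand(ci, params, pathway, apar, leaf_cfg, theta1, theta2)
    cs, hs, gs = _surface_state(an, ca, gb, g0, g1, rh, t_leaf, t_air)
    ci_new = ca - np.asarray(an, float) * (DIFF_BL / gb + DIFF_ST / gs)
    out = ci_new - np.asarray(ci, float)
    return float(out) if np.ndim(out) == 0 else out


def solve_ci(forcing: dict, params: AdjustedParams,
             pathway: Pathway | str = Pathway.C3,
             tolerance: float | None = None, max_iter: int | None = None,
             g0: float | None = None, g1: float | None = None,
             lai_scale: float = 1.0, config: dict | None = None) -> CouplingResult:
    """Solve the coupled assimilation/diffusion fixed point for one leaf
    (or one big-leaf fraction when ``lai_scale`` spreads the conductance
    floor over the fraction's leaf area).

    ``forcing`` carries ca (umol mol-1), apar (umol m-2 s-1), t_canopy (K),
    t_air (K, optional, defaults to t_canopy), rh (fraction), wind (m s-1)
    and pressure (kPa).  Returns a :class:`CouplingResult`; non-convergence
    is flagged, never raised.
    """
    cfg = config or defaults()
    cpl = cfg["coupling"]
    leaf_cfg = cfg["leafphys"]
    pathway = Pathway(pathway)
    c4 = pathway is Pathway.C4

    tolerance = cpl["tolerance"] if tolerance is None else tolerance
    max_iter = cpl["max_iter"] if max_iter is None else max_iter
    g0 = cpl["g0"] if g0 is None else g0
    if g1 is None:
        g1 = cpl["g1_c4"] if c4 else cpl["g1_c3"]
    g1 = g1 * cpl.get("beta_soil", 1.0)
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")

    ca = float(forcing["ca"])
    apar = float(forcing.get("apar", 0.0))
    t_leaf = float(forcing.get("t_canopy", 298.15))
    t_air = float(forcing.get("t_air", t_leaf))
    rh = float(forcing.get("rh", 0.7))
    wind = float(forcing.get("wind", 2.0))
    pressure = float(forcing.get("pressure", 101.325))
    for name, v in (("ca", ca), ("apar", apar), ("t_canopy", t_leaf),
                    ("rh", rh), ("wind", wind), ("pressure", pressure)):
        if not math.isfinite(v):
            raise ValueError(f"non-finite forcing value for {name}")
    if ca <= 0:
        raise ValueError("ca must be positive")

    rho_mol = air_molar_density(pressure, t_air)
    gb = boundary_layer(wind, dleaf=cpl["dleaf"], cv=cpl["cv"],
                        rho_mol=rho_mol, u_min=cpl["u_min"]) * lai_scale
    g0_eff = g0 * lai_scale

    def f(ci):
        return ci_residual(ci, ca=ca, apar=apar, t_leaf=t_leaf, t_air=t_air,
                           rh=rh, gb=gb, params=params, pathway=pathway,
                           g0=g0_eff, g1=g1, leaf_cfg=leaf_cfg)

    lo, hi = 0.0, 1.5 * ca
    f_lo, f_hi = f(lo), f(hi)
    ci = (cpl["ci0_frac_c4"] if c4 else cpl["ci0_frac_c3"]) * ca
    f_ci = f(ci)
    have_bracket = f_lo * f_hi <= 0

    delta = math.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        # Newton step with a finite-difference slope
        eps = max(1e-3, abs(ci) * 1e-4)
        slope = (f(ci + eps) - f_ci) / eps
        newton_ok = slope != 0 and math.isfinite(slope)
        ci_new = ci - f_ci / slope if newton_ok else math.nan

        if not (newton_ok and lo <= ci_new <= hi):
            if have_bracket:
                ci_new = 0.5 * (lo + hi)  # bisection fallback
            else:
                ci_new = min(max(ci - f_ci / max(abs(slope), 1.0), lo), hi)
        f_new = f(ci_new)

        # keep the bracket tight around the sign change
        if have_bracket:
            if f_lo * f_new <= 0:
                hi, f_hi = ci_new, f_new
            else:
                lo, f_lo = ci_new, f_new
            if abs(f_new) > abs(f_ci):  # Newton not contracting: bisect next
                ci_mid = 0.5 * (lo + hi)
                f_mid = f(ci_mid)
                if f_lo * f_mid <= 0:
                    hi, f_hi = ci_mid, f_mid
                else:
                    lo, f_lo = ci_mid, f_mid
                ci_new, f_new = ci_mid, f_mid

        delta = abs(ci_new - ci)
        ci, f_ci = ci_new, f_new
        if delta < tolerance:
            break

    converged = delta < tolerance
    an = float(_demand(ci, params, pathway, apar, leaf_cfg))
    _, _, gs = _surface_state(an, ca, gb, g0_eff, g1, rh, t_leaf, t_air)
    return CouplingResult(ci=float(ci), an=an, gs=float(gs),
                          iterations=iterations, converged=converged,
                          delta=float(delta))
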