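"""Leaf biochemistry: Farquhar C3 and Collatz C4 rate equations.

Gross assimilation is the co-limited combination of a Rubisco-limited rate
Ac, a light-limited rate Aj and an export/PEP-carboxylase-limited rate Ap;
net assimilation subtracts dark respiration.  Transitions between limiting
rates are smoothed with the usual quadratic ("theta") functions rather than
a hard minimum; theta = 1 recovers min() exactly.  All functions broadcast
over numpy arrays.
"""

from __future__ import annotations

import numpy as np

from .kinetics import Pathway

__all__ = ["electron_transport", "c3_rates", "c4_rates", "smooth_colimit",
           "net_assimilation", "LeafRates"]

from dataclasses import dataclass


@dataclass(frozen=True)
class LeafRates:
    """Candidate gross rates and the resulting net assimilation
    (umol CO2 m-2 s-1)."""

    ac: float
    aj: float
    ap: float
    an: float


def smooth_colimit(a1, a2, theta):
    """Smaller root of ``theta x^2 - (a1+a2) x + a1 a2 = 0``.

    Evaluated in the cancellation-stable form ``2 a1 a2 / (B + sqrt(B^2 -
    4 theta a1 a2))``.  The result never exceeds min(a1, a2); theta = 1
    returns the minimum exactly.  When either rate is non-positive the
    minimum is returned directly (smoothing applies to the transition
    between positive limiting rates only).
    """
    if np.any(np.asarray(theta) <= 0) or np.any(np.asarray(theta) > 1):
        raise ValueError("theta must be in (0, 1]")
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    b = a1 + a2
    disc = b * b - 4.0 * theta * a1 * a2
    disc = np.maximum(disc, 0.0)
    denom = b + np.sqrt(disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        root = np.where(denom > 0, 2.0 * a1 * a2 / np.where(denom > 0, denom, 1.0), 0.0)
    out = np.where((a1 <= 0) | (a2 <= 0), np.minimum(a1, a2), root)
    return float(out) if out.ndim == 0 else out


def electron_transport(apar, jmax_t, theta_psii: float = 0.7,
                       phi_psii: float = 0.85):
    """Electron transport rate J (umol m-2 s-1).

    Light usable by PSII is ``I2 = 0.5 * phi_psii * apar`` (half the
    absorbed quanta reach PSII); J is the smaller root of
    ``theta J^2 - (I2 + Jmax) J + I2 Jmax = 0``, saturating at Jmax.
    """
    apar = np.asarray(apar, dtype=float)
    if np.any(apar < 0):
        raise ValueError("apar must be non-negative")
    if np.any(np.asarray(jmax_t) <= 0):
        raise ValueError("jmax_t must be positive")
    i2 = 0.5 * phi_psii * apar
    return smooth_colimit(i2, jmax_t, theta_psii)


def c3_rates(ci, vcmax_t, j, gamma_star_t, kc21_t):
    """Farquhar C3 gross rate candidates at intercellular CO2 ``ci``.

    Ac = Vcmax (ci - G*) / (ci + Kc21);  Aj = J (ci - G*) / (4 ci + 8 G*);
    Ap = 0.5 Vcmax.  With Kc at 21% O2 the oxygen inhibition term is already
    folded into the denominator.  Negative values below the compensation
    point are permitted.
    """
    ci = np.asarray(ci, dtype=float)
    ac = vcmax_t * (ci - gamma_star_t) / (ci + kc21_t)
    aj = j * (ci - gamma_star_t) / (4.0 * ci + 8.0 * gamma_star_t)
    ap = 0.5 * vcmax_t * np.ones_like(ci)
    if ci.ndim == 0:
        return float(ac), float(aj), float(ap)
    return ac, aj, ap


def c4_rates(ci, vcmax_t, apar, kp_t, alpha_c4: float = 0.05):
    """Collatz C4 gross rate candidates.

    Ac = Vcmax (CO2-saturated by the carbon-concentrating mechanism);
    Aj = alpha * APAR (quantum-efficiency limited);
    Ap = Kp * ci * 1e-6 (PEP-carboxylase limited, ci as a mole fraction).
    """
    ci = np.asarray(ci, dtype=float)
    ac = vcmax_t * np.ones_like(ci)
    aj = alpha_c4 * apar * np.ones_like(ci)
    ap = kp_t * ci * 1e-6
    if ci.ndim == 0:
        return float(ac), float(aj), float(ap)
    return ac, aj, ap


def net_assimilation(ac, aj, ap, rd_t, pathway: Pathway | str,
                     theta1: float | None = None,
                     theta2: float | None = None):
    """Net assimilation An = colimit(colimit(Ac, Aj), Ap) - Rd.

    The smoothing parameters default per pathway: (0.98, 0.95) for C3 hosts
    and (0.80, 0.95) for C4.  theta1 = theta2 = 1 reduces exactly to
    ``min(Ac, Aj, Ap) - Rd``.
    """
    pathway = Pathway(pathway)
    if theta1 is None:
        theta1 = 0.80 if pathway is Pathway.C4 else 0.98
    if theta2 is None:
        theta2 = 0.95
    ai = smooth_colimit(ac, aj, theta1)
    a = smooth_colimit(ai, ap, theta2)
    out = a - rd_t
    return float(out) if np.ndim(out) == 0 else out
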