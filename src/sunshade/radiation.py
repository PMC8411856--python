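"""Solar geometry, canopy extinction, two-stream radiative transfer, and the
sunlit/shaded partition of absorbed PAR.

The canopy is treated as a horizontally uniform turbid medium with leaf-angle
distribution summarised by the Ross index ``xl``.  Direct-beam extinction
follows the Goudriaan G-function; diffuse radiation is solved with the
two-stream approximation (Sellers/CLM form).  The two coupled first-order
ODEs for upward and downward diffuse flux are linear with constant
coefficients, so they are solved exactly by eigen-decomposition plus a
particular solution driven by the exponentially attenuated direct beam; no
layered discretisation is involved.  Absorbed flux is then split between the
sunlit and shaded leaf populations: unscattered beam absorption goes wholly
to sunlit leaves, while absorption of diffuse (incident plus scattered-beam)
flux is integrated against the sunlit-fraction profile ``exp(-Kb*L)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CanopyOptics",
    "RadiationPartition",
    "solar_zenith",
    "solar_declination",
    "daylight_mean_cosz",
    "daylength_hours",
    "beam_extinction",
    "leaf_projection",
    "sunlit_partition",
    "two_stream",
    "to_par",
]

PAR_PER_WATT = 4.6  # umol photons per J of visible radiation


@dataclass(frozen=True)
class CanopyOptics:
    """Leaf-angle and optical properties of the canopy (visible band)."""

    xl: float            # Ross index in [-0.4, 0.6]
    rho_leaf: float      # leaf reflectance
    tau_leaf: float      # leaf transmittance
    albedo_soil: float   # soil albedo

    def __post_init__(self):
        if not -0.4 - 1e-9 <= self.xl <= 0.6 + 1e-9:
            raise ValueError(f"Ross index {self.xl} outside [-0.4, 0.6]")
        for name in ("rho_leaf", "tau_leaf", "albedo_soil"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name}={v} not in [0, 1)")
        if self.rho_leaf + self.tau_leaf >= 1:
            raise ValueError("rho_leaf + tau_leaf must be < 1")

    @property
    def omega(self) -> float:
        """Leaf scattering coefficient rho + tau."""
        return self.rho_leaf + self.tau_leaf


@dataclass(frozen=True)
class RadiationPartition:
    """Absorbed visible flux split between sunlit and shaded big leaves.

    ``apar_sun``/``apar_sha`` are per unit sunlit/shaded *leaf* area, in the
    units of the incident fluxes (W m-2 until converted with :func:`to_par`).
    ``reflected`` leaves the top of the canopy; ``to_soil`` is the flux
    absorbed by the ground.
    """

    apar_sun: float
    apar_sha: float
    lai_sun: float
    lai_sha: float
    reflected: float
    to_soil: float
    absorbed_total: float  # canopy-absorbed flux per ground area


def solar_declination(day_of_year: int) -> float:
    """Solar declination (radians), Cooper's formula."""
    return math.radians(23.45) * math.sin(2 * math.pi * (284 + day_of_year) / 365)


def solar_zenith(latitude: float, day_of_year: int, hour: float) -> float:
    """Solar zenith angle (radians) at local solar ``hour``.

    Clamped to pi/2 when the sun is below the horizon.
    """
    if not -90 <= latitude <= 90:
        raise ValueError("latitude outside [-90, 90]")
    if not 1 <= day_of_year <= 366:
        raise ValueError("day_of_year outside [1, 366]")
    if not 0 <= hour <= 24:
        raise ValueError("hour outside [0, 24]")
    lat = math.radians(latitude)
    dec = solar_declination(day_of_year)
    hour_angle = math.radians(15.0 * (hour - 12.0))
    cosz = (math.sin(lat) * math.sin(dec)
            + math.cos(lat) * math.cos(dec) * math.cos(hour_angle))
    if cosz <= 0:
        return math.pi / 2
    return math.acos(min(cosz, 1.0))


def _sunset_hour_angle(latitude: float, day_of_year: int) -> float:
    lat = math.radians(latitude)
    dec = solar_declination(day_of_year)
    x = -math.tan(lat) * math.tan(dec)
    return math.acos(min(1.0, max(-1.0, x)))


def daylength_hours(latitude: float, day_of_year: int) -> float:
    """Day length in hours from sunrise to sunset."""
    return 2.0 * _sunset_hour_angle(latitude, day_of_year) * 12.0 / math.pi


def daylight_mean_cosz(latitude: float, day_of_year: int) -> float:
    """Mean cosine of the solar zenith over the daylight period."""
    lat = math.radians(latitude)
    dec = solar_declination(day_of_year)
    hs = _sunset_hour_angle(latitude, day_of_year)
    if hs <= 0:
        return 0.0
    return (math.sin(lat) * math.sin(dec)
            + math.cos(lat) * math.cos(dec) * math.sin(hs) / hs)


def leaf_projection(xl: float, cosz: float) -> float:
    """Goudriaan projected leaf area G(mu) = phi1 + phi2 * mu."""
    phi1 = 0.5 - 0.633 * xl - 0.33 * xl * xl
    phi2 = 0.877 * (1.0 - 2.0 * phi1)
    return phi1 + phi2 * cosz


def beam_extinction(xl: float, zenith: float) -> float:
    """Direct-beam extinction coefficient Kb = G(mu)/mu.

    Returns ``inf`` (flagged night, no exception) when the zenith is at or
    beyond the horizon.
    """
    if zenith < 0:
        raise ValueError("zenith must be >= 0")
    if zenith >= math.pi / 2:
        return math.inf
    cosz = math.cos(zenith)
    return leaf_projection(xl, cosz) / cosz


def sunlit_partition(lai: float, kb: float) -> tuple[float, float]:
    """Split LAI into sunlit and shaded: ``lai_sun = (1 - exp(-Kb*LAI))/Kb``."""
    if lai < 0 or kb <= 0:
        raise ValueError("lai must be >= 0 and kb > 0")
    if math.isinf(kb):
        return 0.0, lai
    lai_sun = (1.0 - math.exp(-kb * lai)) / kb
    return lai_sun, lai - lai_sun


def to_par(flux_visible):
    """Convert a visible flux (W m-2) to PAR (umol photons m-2 s-1), x 4.6."""
    flux = np.asarray(flux_visible, dtype=float)
    if np.any(flux < 0):
        raise ValueError("flux must be non-negative")
    out = PAR_PER_WATT * flux
    return float(out) if out.ndim == 0 else out


# --- two-stream internals -------------------------------------------------

def _phi12(xl: float) -> tuple[float, float]:
    phi1 = 0.5 - 0.633 * xl - 0.33 * xl * xl
    phi2 = 0.877 * (1.0 - 2.0 * phi1)
    return phi1, phi2


def average_inverse_optical_depth(xl: float) -> float:
    """mubar, the average inverse diffuse optical depth per unit LAI."""
    phi1, phi2 = _phi12(xl)
    if abs(phi2) < 1e-8:
        return 1.0 / (2.0 * phi1)
    return (1.0 / phi2) * (1.0 - (phi1 / phi2) * math.log((phi1 + phi2) / phi1))


def two_stream_coefficients(optics: CanopyOptics, cosz: float) -> dict:
    """Scattering coefficients shared by the closed-form solver and any
    numerical oracle: omega, diffuse upscatter beta, beam upscatter beta0,
    mubar and the beam extinction K."""
    omega = optics.omega
    phi1, phi2 = _phi12(optics.xl)
    g_mu = phi1 + phi2 * cosz
    kb = g_mu / cosz
    mubar = average_inverse_optical_depth(optics.xl)

    # diffuse upscatter: mean leaf inclination via chi_l
    cos2 = ((1.0 + optics.xl) / 2.0) ** 2
    beta = 0.5 * (omega + (optics.rho_leaf - optics.tau_leaf) * cos2) / omega \
        if omega > 0 else 0.5

    # beam upscatter from the single-scattering albedo a_s(mu)
    if omega > 0:
        denom = cosz * phi2 + g_mu
        a_s = (omega / 2.0) * (g_mu / denom) * (
            1.0 - (cosz * phi1 / denom)
            * math.log((cosz * phi1 + denom) / max(cosz * phi1, 1e-12)))
        beta0 = (1.0 + mubar * kb) / (omega * mubar * kb) * a_s
        beta0 = min(max(beta0, 0.0), 1.0)
    else:
        beta0 = 0.5
    return {"omega": omega, "beta": beta, "beta0": beta0,
            "mubar": mubar, "kb": kb}


def _two_stream_solution(omega, beta, beta0, mubar, kb, lai, albedo_soil,
                         beam_in, diff_in):
    """Exact solution of the two-stream ODEs on L in [0, lai].

    State x = (Idown, Iup) diffuse fluxes;  dx/dL = A x + s exp(-kb L) with
    A = (1/mubar) [[-b, c], [-c, b]], b = 1 - omega(1-beta), c = omega*beta,
    and beam-scattering source s = (omega*(1-beta0)*kb, -omega*beta0*kb) *
    beam_in.  Returns the coefficients needed for flux and absorption
    integrals.
    """
    b = 1.0 - omega * (1.0 - beta)
    c = omega * beta
    A = np.array([[-b, c], [-c, b]]) / mubar

    # particular solution p*exp(-kb L): (A + kb I) p = -s
    s = np.array([omega * (1.0 - beta0) * kb,
                  -omega * beta0 * kb]) * beam_in
    M = A + kb * np.eye(2)
    if abs(np.linalg.det(M)) < 1e-10:
        kb = kb * (1.0 + 1e-6)  # detune the resonance K == h
        s = np.array([omega * (1.0 - beta0) * kb,
                      -omega * beta0 * kb]) * beam_in
        M = A + kb * np.eye(2)
    p = np.linalg.solve(M, -s) if beam_in > 0 else np.zeros(2)

    eigvals, eigvecs = np.linalg.eig(A)

    # boundary conditions: Idown(0) = diff_in;
    # Iup(lai) = albedo_soil * (Idown(lai) + beam_in * exp(-kb*lai))
    e_l = np.exp(eigvals * lai)
    beam_soil = beam_in * math.exp(-kb * lai)
    row_top = eigvecs[0, :]
    row_bot = (eigvecs[1, :] - albedo_soil * eigvecs[0, :]) * e_l
    B = np.vstack([row_top, row_bot])
    rhs = np.array([
        diff_in - p[0],
        albedo_soil * (p[0] * math.exp(-kb * lai) + beam_soil)
        - p[1] * math.exp(-kb * lai),
    ])
    coef = np.linalg.solve(B, rhs)
    return {"p": p, "coef": coef, "eigvals": eigvals, "eigvecs": eigvecs,
            "kb": kb, "beam_soil": beam_soil}


def _exp_integral(rate: float, lai: float) -> float:
    """Integral of exp(rate * L) over [0, lai]."""
    if abs(rate) < 1e-12:
        return lai
    return (math.exp(rate * lai) - 1.0) / rate


def two_stream(beam: float, diffuse: float, lai: float, kb: float,
               optics: CanopyOptics, cosz: float | None = None) -> RadiationPartition:
    """Absorbed visible flux per sunlit/shaded big leaf from the two-stream
    approximation.

    ``beam`` and ``diffuse`` are incident direct and diffuse visible fluxes
    (W m-2 on the horizontal).  ``kb`` is the direct-beam extinction from
    :func:`beam_extinction`; ``cosz`` may be supplied to avoid re-inverting
    kb for the beam geometry.  Energy is conserved: absorbed_total +
    reflected + to_soil equals beam + diffuse up to round-off.
    """
    if beam < 0 or diffuse < 0 or lai < 0:
        raise ValueError("fluxes and lai must be non-negative")
    incident = beam + diffuse
    if lai == 0:
        rho_s = optics.albedo_soil
        return RadiationPartition(0.0, 0.0, 0.0, 0.0,
                                  reflected=rho_s * incident,
                                  to_soil=(1 - rho_s) * incident,
                                  absorbed_total=0.0)
    if incident <= 0 or not math.isfinite(kb) or kb <= 0:
        return RadiationPartition(0.0, 0.0, *sunlit_partition(lai, max(kb, 1e9)),
                                  reflected=0.0, to_soil=0.0, absorbed_total=0.0)

    phi1, phi2 = _phi12(optics.xl)
    if cosz is None:
        # recover mu from Kb*mu = phi1 + phi2*mu
        cosz = phi1 / (kb - phi2)
        cosz = min(max(cosz, 1e-3), 1.0)
    coeffs = two_stream_coefficients(optics, cosz)
    omega, beta, beta0, mubar = (coeffs["omega"], coeffs["beta"],
                                 coeffs["beta0"], coeffs["mubar"])

    sol = _two_stream_solution(omega, beta, beta0, mubar, kb, lai,
                               optics.albedo_soil, beam, diffuse)
    p, coef, lam, V = sol["p"], sol["coef"], sol["eigvals"], sol["eigvecs"]
    kb_eff = sol["kb"]

    def flux_at(L):
        x = p * math.exp(-kb_eff * L)
        for i in range(2):
            x = x + coef[i] * V[:, i] * math.exp(lam[i] * L)
        return x  # (Idown, Iup)

    down_bot, _ = flux_at(lai)
    _, up_top = flux_at(0.0)
    beam_soil = sol["beam_soil"]
    to_soil = (1.0 - optics.albedo_soil) * (down_bot + beam_soil)

    # canopy absorption, integrated analytically:
    #   unscattered beam: (1-omega) * beam * (1 - exp(-kb*lai))
    #   diffuse streams:  (1-omega)/mubar * integral (Idown + Iup) dL
    absorb_beam = (1.0 - omega) * beam * (1.0 - math.exp(-kb_eff * lai))
    sum_p = p[0] + p[1]
    diff_integral = sum_p * _exp_integral(-kb_eff, lai)
    for i in range(2):
        diff_integral += coef[i] * (V[0, i] + V[1, i]) * _exp_integral(lam[i], lai)
    absorb_diff = (1.0 - omega) / mubar * float(np.real(diff_integral))
    absorbed_total = absorb_beam + absorb_diff

    # sunlit share of the diffuse-type absorption: weight the absorption
    # profile by the sunlit fraction exp(-kb*L)
    sun_integral = sum_p * _exp_integral(-2.0 * kb_eff, lai)
    for i in range(2):
        sun_integral += coef[i] * (V[0, i] + V[1, i]) * _exp_integral(lam[i] - kb_eff, lai)
    absorb_diff_sun = (1.0 - omega) / mubar * float(np.real(sun_integral))
    absorb_diff_sun = min(max(absorb_diff_sun, 0.0), max(absorb_diff, 0.0))

    lai_sun, lai_sha = sunlit_partition(lai, kb)
    absorbed_sun = absorb_beam + absorb_diff_sun
    absorbed_sha = max(absorbed_total - absorbed_sun, 0.0)

    return RadiationPartition(
        apar_sun=absorbed_sun / lai_sun if lai_sun > 0 else 0.0,
        apar_sha=absorbed_sha / lai_sha if lai_sha > 0 else 0.0,
        lai_sun=lai_sun, lai_sha=lai_sha,
        reflected=float(np.real(up_top)),
        to_soil=float(np.real(to_soil)),
        absorbed_total=absorbed_total,
    )
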