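"""The two-big-leaf canopy model: capacity scaling, single time steps,
season runs, and the Rubisco substitution screen.

A time step chains solar geometry, two-stream absorbed PAR per fraction,
canopy temperature from the energy budget, temperature-adjusted kinetics
(one canopy temperature, Sc/o and Kc shared by both fractions), nitrogen-
weighted partition of Vcmax/Jmax into the sunlit and shaded big leaves, a
coupled Ci solve per fraction, and finally the sum of the two per-ground-
area fraction fluxes.  Seasons integrate the step over daily (or
half-hourly) forcing; the screen repeats a season per Rubisco variant under
identical forcing and reports totals as a percentage of the native enzyme.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import energy, radiation
from .config import defaults
from .coupling import solve_ci
from .kinetics import (AdjustedParams, Pathway, PhotoParams, RubiscoKinetics,
                       c3_temperature_scaling, c4_temperature_scaling,
                       derive_photoparams, leaf_nitrogen, vcmax25_from_kcat)
from .radiation import CanopyOptics

log = logging.getLogger(__name__)

__all__ = ["CanopyTraits", "ScreenResult", "BigLeafCapacities",
           "partition_capacity", "two_big_leaf_step", "run_season",
           "substitution_screen", "traits_from_config"]


@dataclass(frozen=True)
class CanopyTraits:
    """Architecture and nitrogen economy of the host crop canopy."""

    lai_max: float            # m2 m-2
    sla: float                # m2 (g C)-1
    flnr: float               # fraction of leaf N in Rubisco
    cn_ratio: float           # g C (g N)-1
    optics: CanopyOptics
    latitude: float           # degrees
    pathway: Pathway
    kn: float = 0.3           # nitrogen extinction coefficient (all crops)
    dleaf: float = 0.04       # m

    def __post_init__(self):
        if self.lai_max <= 0 or self.kn <= 0:
            raise ValueError("lai_max and kn must be positive")
        if not 0 < self.flnr < 0.5:
            raise ValueError("flnr must be in (0, 0.5)")
        if not isinstance(self.pathway, Pathway):
            object.__setattr__(self, "pathway", Pathway(self.pathway))

    @property
    def na(self) -> float:
        """Leaf nitrogen per area (g N m-2) from SLA and leaf C:N."""
        return leaf_nitrogen(self.sla, self.cn_ratio)


@dataclass(frozen=True)
class ScreenResult:
    species_name: str
    pathway: Pathway
    total_uptake: float   # umol CO2 m-2 season-1
    pct_change: float     # vs native


@dataclass(frozen=True)
class BigLeafCapacities:
    """Per-ground-area capacities integrated over each big leaf (25 C)."""

    vcmax_sun: float
    vcmax_sha: float
    jmax_sun: float
    jmax_sha: float

    @property
    def vcmax_total(self) -> float:
        return self.vcmax_sun + self.vcmax_sha


def partition_capacity(v0: float, j0: float, lai: float, kn: float,
                       kb: float) -> BigLeafCapacities:
    """Integrate the nitrogen-weighted capacity profile over each big leaf.

    With canopy-top capacity ``v0`` declining as ``exp(-kn L)`` and sunlit
    fraction ``exp(-kb L)``:

    ``Vsun = v0 (1 - exp(-(kn+kb) LAI)) / (kn + kb)``
    ``Vtot = v0 (1 - exp(-kn LAI)) / kn``, ``Vsha = Vtot - Vsun``.
    """
    if lai <= 0 or kn <= 0 or kb <= 0:
        raise ValueError("lai, kn, kb must be positive")
    def integral(k):
        return (1.0 - math.exp(-k * lai)) / k
    vtot = v0 * integral(kn)
    vsun = v0 * integral(kn + kb) if math.isfinite(kb) else 0.0
    jtot = j0 * integral(kn)
    jsun = j0 * integral(kn + kb) if math.isfinite(kb) else 0.0
    return BigLeafCapacities(vcmax_sun=vsun, vcmax_sha=vtot - vsun,
                             jmax_sun=jsun, jmax_sha=jtot - jsun)


def _total_capacity(v0: float, lai: float, kn: float) -> float:
    return v0 * (1.0 - math.exp(-kn * lai)) / kn


def _adjust(params25: PhotoParams, kin: RubiscoKinetics, pathway: Pathway,
            t: float, o2: float) -> AdjustedParams:
    if pathway is Pathway.C4:
        return c4_temperature_scaling(params25, kin, t, o2)
    return c3_temperature_scaling(params25, kin, t, o2)


def _canopy_temp(met: dict, traits: CanopyTraits, lai_t: float, dt: float,
                 cfg: dict) -> float:
    """Air temperature anchored energy-budget canopy temperature.

    The measured flux imbalance Rnet - H - LE warms (or cools) the canopy
    relative to air over the averaging interval; with any flux missing the
    canopy is taken at air temperature.
    """
    t_air = float(met["t_air"])
    fluxes = [met.get(k) for k in ("rnet", "h", "le")]
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in fluxes):
        return t_air
    e_cfg = cfg["energy"]
    cap = energy.canopy_heat_capacity(
        max(lai_t, 1e-6), traits.sla, cdry=e_cfg["cdry"], cwat=e_cfg["cwat"],
        water_mass_fraction=e_cfg["water_mass_fraction"])
    if cap <= 0:
        return t_air
    return energy.canopy_temperature(t_air, float(met["rnet"]), float(met["h"]),
                                     float(met["le"]), cap, dt)


def two_big_leaf_step(met: dict | pd.Series, traits: CanopyTraits,
                      kin: RubiscoKinetics, lai_t: float,
                      config: dict | None = None,
                      dt: float | None = None) -> dict:
    """One model time step; returns canopy net assimilation plus diagnostics.

    ``met`` needs doy, sw_in, t_air, rh, wind, pressure, ca and optionally
    hour (half-hourly mode), rnet, h, le.  Daily records (no ``hour``) use
    the daylight-mean solar geometry and dt = daylength; half-hourly records
    use the instantaneous zenith and dt = 1800 s.
    """
    cfg = config or defaults()
    rad_cfg = cfg["radiation"]
    met = dict(met) if not isinstance(met, dict) else met

    if lai_t <= 0:
        return {"an": 0.0, "an_sun": 0.0, "an_sha": 0.0, "dt": dt or 0.0,
                "t_canopy": float(met.get("t_air", np.nan)), "night": False,
                "lai": 0.0}

    doy = int(met["doy"])
    hour = met.get("hour")
    if hour is None or (isinstance(hour, float) and math.isnan(hour)):
        cosz = radiation.daylight_mean_cosz(traits.latitude, doy)
        zenith = math.acos(cosz) if cosz > 0 else math.pi / 2
        if dt is None:
            dt = radiation.daylength_hours(traits.latitude, doy) * 3600.0
    else:
        zenith = radiation.solar_zenith(traits.latitude, doy, float(hour))
        cosz = math.cos(zenith)
        if dt is None:
            dt = 1800.0

    sw_in = float(met["sw_in"])
    t_canopy = _canopy_temp(met, traits, lai_t, dt, cfg)

    # leaf capacities at the canopy top from the variant's kcat
    kin_cfg = cfg["kinetics"]
    v0 = vcmax25_from_kcat(kin.kcat25, traits.na, traits.flnr,
                           fnr=kin_cfg["fnr"],
                           sites_per_gram=kin_cfg["sites_per_gram"])
    params25 = derive_photoparams(v0, traits.pathway, cfg)
    o2 = kin_cfg["o2"]

    night = (zenith >= math.pi / 2 - 1e-9
             or sw_in < rad_cfg["sw_night_threshold"])
    if night:
        # dark respiration of the whole canopy, no Ci solve needed
        vtot25 = _total_capacity(v0, lai_t, traits.kn)
        rd_ratio = (kin_cfg["rd_ratio_c4"] if traits.pathway is Pathway.C4
                    else kin_cfg["rd_ratio_c3"])
        params_tot = derive_photoparams(max(vtot25, 1e-12), traits.pathway, cfg)
        adj = _adjust(params_tot, kin, traits.pathway, t_canopy, o2)
        an = -adj.rd
        return {"an": an, "an_sun": 0.0, "an_sha": an, "dt": dt,
                "t_canopy": t_canopy, "night": True, "lai": lai_t,
                "rd": adj.rd, "rd_ratio": rd_ratio}

    kb = radiation.beam_extinction(traits.optics.xl, zenith)
    vis = rad_cfg["vis_fraction"] * sw_in
    beam = rad_cfg["beam_fraction"] * vis
    diffuse = vis - beam
    part = radiation.two_stream(beam, diffuse, lai_t, kb, traits.optics,
                                cosz=cosz)
    caps = partition_capacity(v0, params25.jmax25, lai_t, traits.kn, kb)

    results = {}
    an_total = 0.0
    for frac, lai_f, apar_leaf, v25, j25 in (
            ("sun", part.lai_sun, part.apar_sun, caps.vcmax_sun, caps.jmax_sun),
            ("sha", part.lai_sha, part.apar_sha, caps.vcmax_sha, caps.jmax_sha)):
        if lai_f <= 0 or v25 <= 0:
            results[f"an_{frac}"] = 0.0
            continue
        params_f = derive_photoparams(v25, traits.pathway, cfg)
        adj = _adjust(params_f, kin, traits.pathway, t_canopy, o2)
        apar_ground = radiation.to_par(apar_leaf) * lai_f  # umol m-2 ground s-1
        forcing = {"ca": float(met["ca"]), "apar": apar_ground,
                   "t_canopy": t_canopy, "t_air": float(met["t_air"]),
                   "rh": float(met["rh"]), "wind": float(met["wind"]),
                   "pressure": float(met.get("pressure", 101.325))}
        res = solve_ci(forcing, adj, traits.pathway, lai_scale=lai_f,
                       config=cfg)
        results[f"an_{frac}"] = res.an
        results[f"ci_{frac}"] = res.ci
        results[f"converged_{frac}"] = res.converged
        an_total += res.an

    return {"an": an_total, "dt": dt, "t_canopy": t_canopy, "night": False,
            "lai": lai_t, "apar_sun": part.apar_sun, "apar_sha": part.apar_sha,
            "lai_sun": part.lai_sun, "lai_sha": part.lai_sha, **results}


REQUIRED_MET = ["doy", "sw_in", "t_air", "rh", "wind", "ca"]


def run_season(met: pd.DataFrame, traits: CanopyTraits, kin: RubiscoKinetics,
               lai: pd.Series | np.ndarray,
               config: dict | None = None) -> tuple[pd.DataFrame, float]:
    """Run the model over a season of aligned met and LAI records.

    Records with any required field missing are skipped as gaps (counted and
    logged, mirroring flux-tower data availability).  Returns a per-record
    DataFrame (an in umol m-2 s-1, dt in s, uptake in umol m-2 per record)
    and the seasonal total uptake (umol m-2).
    """
    if len(met) == 0:
        raise ValueError("empty meteorology series")
    lai = np.asarray(lai, dtype=float)
    if len(lai) != len(met):
        raise ValueError("lai series must align with met series")
    cfg = config or defaults()

    rows = []
    gaps = 0
    for i, (_, rec) in enumerate(met.iterrows()):
        if any(pd.isna(rec.get(k)) for k in REQUIRED_MET):
            gaps += 1
            rows.append({"doy": rec.get("doy", np.nan), "an": np.nan,
                         "dt": np.nan, "uptake": np.nan, "gap": True})
            continue
        out = two_big_leaf_step(rec, traits, kin, float(lai[i]), cfg)
        rows.append({"doy": rec["doy"], "an": out["an"], "dt": out["dt"],
                     "uptake": out["an"] * out["dt"], "gap": False,
                     "t_canopy": out["t_canopy"]})
    if gaps:
        log.info("run_season: skipped %d gap records of %d", gaps, len(met))
    df = pd.DataFrame(rows)
    total = float(df.loc[~df["gap"], "uptake"].sum())
    return df, total


def substitution_screen(native: RubiscoKinetics,
                        variants: list[RubiscoKinetics],
                        met: pd.DataFrame, traits: CanopyTraits,
                        lai: pd.Series | np.ndarray,
                        config: dict | None = None) -> list[ScreenResult]:
    """Screen foreign Rubisco variants against the native enzyme.

    Each variant is run through an identical season; totals are compared with
    the native total and reported as a percentage change, sorted descending.
    The native enzyme screened against itself gives exactly 0%.  Variants
    failing validation are excluded with a logged reason.
    """
    _, total_native = run_season(met, traits, native, lai, config)
    if total_native == 0:
        raise ValueError("native seasonal total is zero; cannot compare")

    results = []
    for kin in variants:
        try:
            if kin.species_name == native.species_name:
                total = total_native  # identical forcing: reuse, exact 0%
            else:
                _, total = run_season(met, traits, kin, lai, config)
        except (ValueError, FloatingPointError) as exc:
            log.warning("variant %s excluded: %s", kin.species_name, exc)
            continue
        pct = 100.0 * (total - total_native) / abs(total_native)
        results.append(ScreenResult(species_name=kin.species_name,
                                    pathway=kin.pathway,
                                    total_uptake=total, pct_change=pct))
    results.sort(key=lambda r: r.pct_change, reverse=True)
    return results


def traits_from_config(crop: str, config: dict | None = None) -> CanopyTraits:
    """Build :class:`CanopyTraits` for a named crop section of the config."""
    cfg = config or defaults()
    try:
        c = cfg["crops"][crop]
    except KeyError:
        raise KeyError(f"no crop section '{crop}' in config; "
                       f"have {sorted(cfg['crops'])}") from None
    optics = CanopyOptics(xl=c["xl"], rho_leaf=c["rho_leaf"],
                          tau_leaf=c["tau_leaf"], albedo_soil=c["albedo_soil"])
    return CanopyTraits(lai_max=c["lai_max"], sla=c["sla"], flnr=c["flnr"],
                        cn_ratio=c["cn_ratio"], optics=optics,
                        latitude=c["latitude"], pathway=Pathway(c["pathway"]),
                        kn=cfg["canopy"]["kn"], dleaf=c["dleaf"])
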