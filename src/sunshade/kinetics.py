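"""Rubisco kinetics: loading, unit bases, derived leaf capacities, and
temperature responses.

Each Rubisco variant is characterised by its 25 C catalytic turnover
(``kcat25``, s-1 per active site), its Michaelis-Menten constant for CO2
measured at ambient 21% O2 (``kc21_25``, gas-phase mole fraction, which folds
the competitive O2 inhibition into a single constant so Ko is never needed),
its CO2/O2 specificity (``sco25``, gas-phase), and an Arrhenius activation
energy Ha for each of the three.  Leaf-level capacities (Vcmax, Jmax, Rd, Kp)
are derived from kcat and leaf nitrogen, then adjusted for temperature with
pathway-specific high/low-temperature inhibition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GAS_CONSTANT, T_REF, defaults

log = logging.getLogger(__name__)

__all__ = [
    "Pathway",
    "RubiscoKinetics",
    "PhotoParams",
    "AdjustedParams",
    "load_kinetics_table",
    "packaged_kinetics",
    "arrhenius_adjust",
    "gamma_star",
    "vcmax25_from_kcat",
    "leaf_nitrogen",
    "derive_photoparams",
    "peaked_factor",
    "c3_temperature_scaling",
    "c4_temperature_scaling",
    "liquid_to_gas_basis",
]

KINETICS_COLUMNS = ["species", "pathway", "kcat25", "kc21_25", "sco25",
                    "ha_kcat", "ha_kc21", "ha_sco"]

T_MIN, T_MAX = 250.0, 330.0  # K, physical validity range for leaf temperature


class Pathway(str, Enum):
    """Photosynthetic pathway of the Rubisco's source species."""

    C3 = "C3"
    C4 = "C4"
    C3C4 = "C3C4_intermediate"


@dataclass(frozen=True)
class RubiscoKinetics:
    """One Rubisco variant's 25 C kinetics (gas-phase basis) and Ha values."""

    species_name: str
    pathway: Pathway
    kcat25: float      # s-1
    kc21_25: float     # umol mol-1 at 21% O2
    sco25: float       # dimensionless, gas-phase
    ha_kcat: float     # J mol-1
    ha_kc21: float     # J mol-1
    ha_sco: float      # J mol-1

    def __post_init__(self):
        for name in ("kcat25", "kc21_25", "sco25", "ha_kcat", "ha_kc21", "ha_sco"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(
                    f"{self.species_name}: {name} must be positive, got {value!r}")
        if not isinstance(self.pathway, Pathway):
            object.__setattr__(self, "pathway", Pathway(self.pathway))


@dataclass(frozen=True)
class PhotoParams:
    """Leaf capacities at 25 C derived from Vcmax25 plus the parameters of
    the pathway temperature functions."""

    vcmax25: float
    jmax25: float
    rd25: float
    kp25: float | None          # C4 only
    gamma_star25: float
    ha_jmax: float
    hd: float
    delta_s: float
    q10: float
    s1: float
    s2: float
    s3: float
    s4: float


@dataclass(frozen=True)
class AdjustedParams:
    """All leaf parameters evaluated at one leaf temperature."""

    t: float
    vcmax: float
    jmax: float
    rd: float
    kp: float | None
    gamma_star: float
    kc21: float
    sco: float


def _check_t(t) -> None:
    t = np.asarray(t, dtype=float)
    if np.any(t <= T_MIN) or np.any(t >= T_MAX):
        raise ValueError(f"leaf temperature {t} K outside ({T_MIN}, {T_MAX})")


def arrhenius_adjust(k25, ha, t):
    """Arrhenius temperature adjustment of a 25 C parameter.

    ``k25 * exp(ha * (t - 298.15) / (298.15 * R * t))`` — equal to ``k25``
    at 298.15 K for any activation energy.
    """
    _check_t(t)
    t = np.asarray(t, dtype=float)
    out = k25 * np.exp(ha * (t - T_REF) / (T_REF * GAS_CONSTANT * t))
    return float(out) if np.isscalar(k25) and out.ndim == 0 else out


def gamma_star(sco_gas, o2=209000.0):
    """CO2 compensation point without dark respiration, ``0.5 * O2 / Sc/o``.

    Both the O2 mole fraction (umol mol-1) and Sc/o are on a gas-phase basis,
    so the result is a CO2 mole fraction in umol mol-1.
    """
    sco_gas = np.asarray(sco_gas, dtype=float)
    if np.any(sco_gas <= 0):
        raise ValueError("sco_gas must be positive")
    if not (0 < o2 < 1e6):
        raise ValueError("o2 mole fraction out of range")
    out = 0.5 * o2 / sco_gas
    return float(out) if out.ndim == 0 else out


def leaf_nitrogen(sla: float, cn_ratio: float) -> float:
    """Leaf nitrogen per area Na = 1 / (SLA * C:N), g N m-2.

    SLA in m2 (g C)-1 and C:N in g C (g N)-1.
    """
    if sla <= 0 or cn_ratio <= 0:
        raise ValueError("sla and cn_ratio must be positive")
    return 1.0 / (sla * cn_ratio)


def vcmax25_from_kcat(kcat25, na, flnr, fnr=None, sites_per_gram=None):
    """Canopy-top Vcmax25 from the variant's turnover and leaf nitrogen.

    ``Vcmax25 = Na * Flnr * Fnr * sites_per_gram * kcat25`` where Fnr converts
    nitrogen in Rubisco to Rubisco mass and sites_per_gram converts Rubisco
    mass to catalytic sites (defaults: 7.16 g g-1 and 14.545 umol g-1, i.e.
    8 sites per 550 kDa holoenzyme).
    """
    kin_cfg = defaults()["kinetics"]
    fnr = kin_cfg["fnr"] if fnr is None else fnr
    sites_per_gram = kin_cfg["sites_per_gram"] if sites_per_gram is None else sites_per_gram
    if min(na, flnr, fnr, sites_per_gram) <= 0 or kcat25 < 0:
        raise ValueError("all factors must be positive (kcat25 may be 0)")
    return na * flnr * fnr * sites_per_gram * kcat25


def derive_photoparams(vcmax25: float, pathway: Pathway | str,
                       config: dict | None = None,
                       gamma_star25: float | None = None) -> PhotoParams:
    """Derive Jmax25, Rd25 and Kp25 from Vcmax25 by the prescribed ratios.

    Jmax25 = 1.67 Vcmax25 for all hosts; Rd25 = 0.015 Vcmax25 (C3 hosts,
    intermediates treated as C3) or 0.025 Vcmax25 (C4); Kp25 = 20000 Vcmax25
    for C4 hosts only.  Ratios are config-overridable.
    """
    if vcmax25 <= 0:
        raise ValueError("vcmax25 must be positive")
    pathway = Pathway(pathway)
    cfg = (config or defaults())["kinetics"]
    c4 = pathway is Pathway.C4
    return PhotoParams(
        vcmax25=vcmax25,
        jmax25=cfg["jmax_ratio"] * vcmax25,
        rd25=(cfg["rd_ratio_c4"] if c4 else cfg["rd_ratio_c3"]) * vcmax25,
        kp25=cfg["kp_ratio"] * vcmax25 if c4 else None,
        gamma_star25=float("nan") if gamma_star25 is None else gamma_star25,
        ha_jmax=cfg["ha_jmax"],
        hd=cfg["hd"],
        delta_s=cfg["delta_s"],
        q10=cfg["q10"],
        s1=cfg["s1"], s2=cfg["s2"], s3=cfg["s3"], s4=cfg["s4"],
    )


def peaked_factor(t, hd, delta_s):
    """High-temperature deactivation factor, normalised to 1 at 25 C.

    ``(1 + exp((298.15*dS - Hd)/(298.15*R))) / (1 + exp((t*dS - Hd)/(t*R)))``
    """
    t = np.asarray(t, dtype=float)
    num = 1.0 + np.exp((T_REF * delta_s - hd) / (T_REF * GAS_CONSTANT))
    den = 1.0 + np.exp((t * delta_s - hd) / (t * GAS_CONSTANT))
    out = num / den
    return float(out) if out.ndim == 0 else out


def c3_temperature_scaling(params: PhotoParams, kin: RubiscoKinetics, t,
                           o2: float = 209000.0) -> AdjustedParams:
    """C3 leaf parameters at leaf temperature ``t`` (K).

    Vcmax follows Arrhenius (with the variant's kcat Ha) times a peaked
    deactivation; Jmax uses the shared host Ha with the same peaked factor;
    Kc21 and Sc/o follow plain Arrhenius with their own Ha; Rd co-varies with
    Vcmax.  Gamma* is recomputed from the temperature-adjusted Sc/o.
    """
    _check_t(t)
    peak = peaked_factor(t, params.hd, params.delta_s)
    vcmax = arrhenius_adjust(params.vcmax25, kin.ha_kcat, t) * peak
    jmax = arrhenius_adjust(params.jmax25, params.ha_jmax, t) * peak
    rd = params.rd25 * (vcmax / params.vcmax25)
    kc21 = arrhenius_adjust(kin.kc21_25, kin.ha_kc21, t)
    sco = arrhenius_adjust(kin.sco25, kin.ha_sco, t)
    return AdjustedParams(t=float(t), vcmax=vcmax, jmax=jmax, rd=rd, kp=None,
                          gamma_star=gamma_star(sco, o2), kc21=kc21, sco=sco)


def c4_temperature_scaling(params: PhotoParams, kin: RubiscoKinetics, t,
                           o2: float = 209000.0) -> AdjustedParams:
    """C4 (Collatz) leaf parameters at leaf temperature ``t`` (K).

    ``Vcmax(t) = Vcmax25 * Q10^((t-298.15)/10) /
    ([1 + exp(s1*(t - s2))] * [1 + exp(s3*(s4 - t))])`` — a Q10 base response
    damped by high- (s1, s2) and low- (s3, s4) temperature inhibition.  Rd and
    Kp co-vary with Vcmax; Kc21 and Sc/o follow plain Arrhenius.
    """
    _check_t(t)
    t_arr = np.asarray(t, dtype=float)
    q10_factor = params.q10 ** ((t_arr - T_REF) / 10.0)
    inhibition = ((1.0 + np.exp(params.s1 * (t_arr - params.s2)))
                  * (1.0 + np.exp(params.s3 * (params.s4 - t_arr))))
    scale = q10_factor / inhibition
    vcmax = params.vcmax25 * scale
    jmax = arrhenius_adjust(params.jmax25, params.ha_jmax, t)
    rd = params.rd25 * scale
    kp = None if params.kp25 is None else params.kp25 * scale
    kc21 = arrhenius_adjust(kin.kc21_25, kin.ha_kc21, t)
    sco = arrhenius_adjust(kin.sco25, kin.ha_sco, t)
    return AdjustedParams(t=float(t), vcmax=float(vcmax), jmax=jmax, rd=float(rd),
                          kp=kp, gamma_star=gamma_star(sco, o2), kc21=kc21, sco=sco)


def liquid_to_gas_basis(kc_uM, sco_solution, t=T_REF,
                        sol_co2: float | None = None,
                        sol_o2: float | None = None,
                        pressure_bar: float = 1.01325):
    """Convert solution-phase assay values to the gas-phase basis.

    In vitro assays report Kc as a dissolved concentration (uM) and Sc/o on a
    dissolved basis; the simulator consumes gas-phase mole fractions.  Using
    Henry's-law solubilities (defaults at 25 C: CO2 0.0334, O2 0.00126
    mol L-1 bar-1): ``kc_gas = kc_uM / (sol_co2 * P)`` in umol mol-1 and
    ``sco_gas = sco_solution * sol_co2 / sol_o2`` (ratio ~26.5 at 25 C).
    """
    kin_cfg = defaults()["kinetics"]
    sol_co2 = kin_cfg["sol_co2"] if sol_co2 is None else sol_co2
    sol_o2 = kin_cfg["sol_o2"] if sol_o2 is None else sol_o2
    if min(np.min(np.asarray(kc_uM, float)), np.min(np.asarray(sco_solution, float)),
           sol_co2, sol_o2) <= 0:
        raise ValueError("all inputs must be positive")
    kc_gas = np.asarray(kc_uM, float) * 1e-6 / (sol_co2 * pressure_bar) * 1e6
    sco_gas = np.asarray(sco_solution, float) * (sol_co2 / sol_o2)
    if np.ndim(kc_gas) == 0:
        return float(kc_gas), float(sco_gas)
    return kc_gas, sco_gas


def load_kinetics_table(path: str | Path) -> list[RubiscoKinetics]:
    """Read a delimited kinetics table into a list of :class:`RubiscoKinetics`.

    Required header: species, pathway, kcat25, kc21_25, sco25, ha_kcat,
    ha_kc21, ha_sco.  Rows with any missing kinetic or Ha value are excluded
    from the result and reported through the module logger, never silently
    dropped.  Non-positive values raise naming the row and field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing_cols = [c for c in KINETICS_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"kinetics table {path} missing columns: {missing_cols}")

    numeric = KINETICS_COLUMNS[2:]
    variants: list[RubiscoKinetics] = []
    for idx, row in df.iterrows():
        if row[KINETICS_COLUMNS].isna().any():
            bad = [c for c in KINETICS_COLUMNS if pd.isna(row[c])]
            log.warning("row %d (%s): incomplete kinetics, excluded (missing %s)",
                        idx, row.get("species", "?"), ", ".join(bad))
            continue
        for col in numeric:
            if float(row[col]) <= 0:
                raise ValueError(
                    f"row {idx} ({row['species']}): {col} must be positive, "
                    f"got {row[col]}")
        variants.append(RubiscoKinetics(
            species_name=str(row["species"]),
            pathway=Pathway(str(row["pathway"])),
            **{c: float(row[c]) for c in numeric}))
    return variants


def packaged_kinetics() -> list[RubiscoKinetics]:
    """The packaged 27-variant kinetics table (synthetic stand-in values).

    The species list and pathway composition (16 C3, 10 C4, 1 C3/C4
    intermediate) follow the published survey of fully characterised
    Rubiscos; the numeric values are realistic synthetic placeholders on a
    gas-phase basis, intended for testing and demonstration.  Substitute a
    measured table via :func:`load_kinetics_table` for real screening.
    """
    with resources.as_file(
            resources.files("sunshade").joinpath(
                "data/rubisco_kinetics_synthetic.csv")) as p:
        return load_kinetics_table(p)
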