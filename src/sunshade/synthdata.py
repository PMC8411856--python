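"""Seeded synthetic meteorology and flux generator.

Emulates a half-hourly cropland growing season — a cosine-of-zenith
radiation envelope, seasonal plus diurnal temperature sinusoids (diurnal
peak lagging solar noon by two hours), humidity anticorrelated with
temperature, light-saturating GPP, and a Bowen-ratio partition of net
radiation — so that every downstream stage (reading, averaging, GDP-LAI,
season runs, screening) can be exercised without tower downloads.  One seed
drives everything through independent per-field substreams, so the output is
bit-reproducible and adding a field never shifts the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import radiation

__all__ = ["SynthConfig", "synth_season"]

FIELD_STREAMS = ["sw", "t", "rh", "wind", "gpp"]  # fixed spawn order


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic season."""

    seed: int = 0
    n_days: int = 30
    latitude: float = 42.0
    start_doy: int = 152            # early June
    sw_peak: float = 900.0          # W m-2 clear-sky noon shortwave
    t_mean: float = 291.15          # K season mean
    t_amplitude_seasonal: float = 4.0   # K
    t_amplitude_diurnal: float = 6.0    # K
    rh_mean: float = 0.70
    wind_mean: float = 2.5          # m s-1
    pressure: float = 101.325       # kPa
    ca: float = 400.0               # umol mol-1
    lai_max: float = 4.0
    gpp_max: float = 30.0           # umol m-2 s-1 light-saturated GPP
    gpp_half_sat: float = 800.0     # umol m-2 s-1 PAR at half saturation
    reco_base: float = 2.0          # umol m-2 s-1 respiration at t_mean
    bowen_ratio: float = 0.3
    closure: float = 1.0            # (H+LE)/Rnet energy-balance closure
    noise_sd: dict = field(default_factory=lambda: {
        "sw": 0.05,    # multiplicative, fraction of the envelope
        "t": 0.6,      # K
        "rh": 0.04,    # fraction
        "wind": 0.7,   # m s-1
        "gpp": 0.5,    # umol m-2 s-1
    })

    def __post_init__(self):
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.sw_peak <= 0:
            raise ValueError("sw_peak must be positive")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise sd values must be >= 0")


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(FIELD_STREAMS))
    return {name: np.random.default_rng(ss)
            for name, ss in zip(FIELD_STREAMS, children)}


def synth_season(config: SynthConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a half-hourly met/flux season and the daily GPP series.

    Returns ``(records, gpp_daily)`` where ``records`` follows the fluxio
    met schema (timestamp, doy, hour, sw_in, t_air, rh, wind, pressure, ca,
    rnet, h, le, nee, gpp) and ``gpp_daily`` integrates GPP per day in
    umol CO2 m-2 d-1 (the GDP-LAI input).  Identical seeds give identical
    output.
    """
    rng = _substreams(config.seed)
    steps_per_day = 48
    n = config.n_days * steps_per_day

    day_idx = np.repeat(np.arange(config.n_days), steps_per_day)
    doy = config.start_doy + day_idx
    hour = np.tile(np.arange(steps_per_day) / 2.0 + 0.25, config.n_days)

    cosz = np.array([
        max(0.0, np.cos(radiation.solar_zenith(
            config.latitude, int(min(d, 366)), h)))
        for d, h in zip(doy, hour)])

    sw_noise = 1.0 + config.noise_sd["sw"] * rng["sw"].standard_normal(n)
    sw_in = np.maximum(0.0, config.sw_peak * cosz * np.maximum(sw_noise, 0.0))

    season_phase = 2 * np.pi * (doy - config.start_doy) / 365.0
    t_season = config.t_amplitude_seasonal * np.sin(season_phase)
    t_diurnal = config.t_amplitude_diurnal * np.cos(
        2 * np.pi * (hour - 14.0) / 24.0)  # peak 2 h after solar noon
    t_air = (config.t_mean + t_season + t_diurnal
             + config.noise_sd["t"] * rng["t"].standard_normal(n))

    rh = (config.rh_mean
          - 0.02 * (t_air - config.t_mean)   # warmer air is drier
          + config.noise_sd["rh"] * rng["rh"].standard_normal(n))
    rh = np.clip(rh, 0.2, 1.0)

    wind = np.maximum(
        0.1, config.wind_mean
        + config.noise_sd["wind"] * rng["wind"].standard_normal(n))

    par = 4.6 * 0.5 * sw_in  # umol photons m-2 s-1
    gpp = config.gpp_max * par / (config.gpp_half_sat + par)
    gpp = np.maximum(0.0, gpp + np.where(
        par > 0, config.noise_sd["gpp"] * rng["gpp"].standard_normal(n), 0.0))
    reco = config.reco_base * 2.0 ** ((t_air - config.t_mean) / 10.0)
    nee = reco - gpp  # tower sign convention: uptake negative

    rnet = 0.8 * sw_in
    le = config.closure * rnet / (1.0 + config.bowen_ratio)
    h = config.closure * rnet * config.bowen_ratio / (1.0 + config.bowen_ratio)

    start = pd.Timestamp("2020-01-01") + pd.Timedelta(days=config.start_doy - 1)
    timestamp = start + pd.to_timedelta(day_idx, unit="D") \
        + pd.to_timedelta(hour, unit="h")

    records = pd.DataFrame({
        "timestamp": timestamp, "doy": doy, "hour": hour,
        "sw_in": sw_in, "t_air": t_air, "rh": rh, "wind": wind,
        "pressure": np.full(n, config.pressure), "ca": np.full(n, config.ca),
        "rnet": rnet, "h": h, "le": le, "nee": nee, "gpp": gpp,
    })

    gpp_daily = pd.Series(
        gpp.reshape(config.n_days, steps_per_day).sum(axis=1) * 1800.0,
        index=pd.Index(config.start_doy + np.arange(config.n_days),
                       name="doy"),
        name="gpp_daily")
    return records, gpp_daily


def write_csv(records: pd.DataFrame, path) -> None:
    """Write a synthetic season in the CSV dialect read_halfhourly consumes."""
    out = pd.DataFrame({
        "TIMESTAMP_START": records["timestamp"].dt.strftime("%Y%m%d%H%M"),
        "SW_IN": records["sw_in"],
        "TA": records["t_air"] - 273.15,
        "RH": records["rh"] * 100.0,
        "WS": records["wind"],
        "PA": records["pressure"],
        "CO2": records["ca"],
        "NETRAD": records["rnet"],
        "H": records["h"],
        "LE": records["le"],
        "NEE": records["nee"],
        "GPP": records["gpp"],
    })
    out.to_csv(path, index=False)
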