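"""Flux-tower CSV ingestion, filtering/averaging rules, and validation
metrics.

Half-hourly AmeriFlux/FLUXNET-style files are read into a pandas DataFrame
with a fixed column schema (the in-memory MetRecord contract): ``timestamp,
doy, hour, sw_in (W m-2), t_air (K), rh (fraction), wind (m s-1), pressure
(kPa), ca (umol mol-1)`` plus optional ``rnet, h, le (W m-2), nee, gpp
(umol CO2 m-2 s-1)``.  The sentinel -9999 marks missing values.  Daily
averaging applies the daytime solar-radiation filter (>= 5 W m-2) used to
remove night-time observations before daily model driving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coupling import saturation_vapour_pressure

__all__ = ["DEFAULT_COLUMN_MAP", "MET_SCHEMA", "read_halfhourly",
           "daily_average", "diurnal_bin_average", "validation_metrics",
           "ValidationMetrics"]

MISSING = -9999

# network column name -> schema field
DEFAULT_COLUMN_MAP = {
    "TIMESTAMP_START": "timestamp",
    "SW_IN": "sw_in",
    "TA": "t_air",
    "RH": "rh",
    "VPD": "vpd",
    "WS": "wind",
    "PA": "pressure",
    "CO2": "ca",
    "NETRAD": "rnet",
    "H": "h",
    "LE": "le",
    "NEE": "nee",
    "GPP": "gpp",
}

MET_SCHEMA = ["timestamp", "doy", "hour", "sw_in", "t_air", "rh", "wind",
              "pressure", "ca", "rnet", "h", "le", "nee", "gpp"]

NUMERIC_FIELDS = ["sw_in", "t_air", "rh", "vpd", "wind", "pressure", "ca",
                  "rnet", "h", "le", "nee", "gpp"]


def read_halfhourly(path, column_map: dict | None = None,
                    ta_unit: str = "C", rh_unit: str = "percent",
                    vpd_unit: str = "kPa") -> pd.DataFrame:
    """Read a half-hourly tower CSV into the met schema.

    ``column_map`` binds file column names to schema fields (default:
    FLUXNET2015/AmeriFlux BASE names).  Timestamps are YYYYMMDDHHMM local
    standard time.  -9999 becomes NaN.  Air temperature is converted C -> K
    (``ta_unit="K"`` disables), RH percent -> fraction, and when RH is
    absent it is recovered from VPD via the Tetens saturation pressure:
    ``rh = 1 - VPD / esat(TA)``.
    """
    column_map = column_map or DEFAULT_COLUMN_MAP
    raw = pd.read_csv(path)
    df = pd.DataFrame()
    for src, dst in column_map.items():
        if src in raw.columns:
            df[dst] = raw[src]
    if "timestamp" not in df.columns:
        raise ValueError("no timestamp column bound; check column_map")

    try:
        ts = pd.to_datetime(df["timestamp"].astype("Int64").astype(str),
                            format="%Y%m%d%H%M")
    except (ValueError, TypeError) as exc:
        bad = df["timestamp"].iloc[0] if len(df) else "?"
        raise ValueError(f"unparseable timestamp (first row value {bad!r}): "
                         f"{exc}") from exc
    df["timestamp"] = ts
    if not ts.is_monotonic_increasing:
        raise ValueError("timestamps must be strictly increasing")

    for col in NUMERIC_FIELDS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
            df.loc[df[col] == MISSING, col] = np.nan

    if "t_air" in df.columns and ta_unit == "C":
        df["t_air"] = df["t_air"] + 273.15
    if "rh" in df.columns and rh_unit == "percent":
        df["rh"] = df["rh"] / 100.0
    if "rh" not in df.columns or df["rh"].isna().all():
        if "vpd" in df.columns and "t_air" in df.columns:
            vpd = df["vpd"] * (0.1 if vpd_unit == "hPa" else 1.0)
            esat = saturation_vapour_pressure(df["t_air"].to_numpy())
            df["rh"] = (1.0 - vpd / esat).clip(0.0, 1.0)
    if "rh" in df.columns:
        df["rh"] = df["rh"].clip(0.0, 1.0)
    if "sw_in" in df.columns:
        df["sw_in"] = df["sw_in"].clip(lower=0.0)

    df["doy"] = ts.dt.dayofyear
    df["hour"] = ts.dt.hour + ts.dt.minute / 60.0
    for col in MET_SCHEMA:
        if col not in df.columns:
            df[col] = np.nan
    return df[MET_SCHEMA + [c for c in df.columns if c not in MET_SCHEMA]]


def daily_average(records: pd.DataFrame, sw_min: float = 5.0) -> pd.DataFrame:
    """Daytime daily means: average records with ``sw_in >= sw_min`` per
    calendar day (the >= 5 W m-2 filter removes night-time observations).

    Days with no qualifying record are emitted as gap rows (all-NaN fields,
    ``gap=True``) so the season keeps its calendar.  ``hour`` is dropped:
    daily records drive the model in daylight-mean mode.
    """
    if "timestamp" not in records.columns:
        raise ValueError("records need a timestamp column")
    date = records["timestamp"].dt.floor("D")
    day_ok = records["sw_in"] >= sw_min
    fields = [c for c in records.columns
              if c not in ("timestamp", "hour") and records[c].dtype != object]

    out = []
    for day, group in records.groupby(date):
        sel = group[day_ok.loc[group.index]]
        row = {"date": day, "doy": int(day.dayofyear), "gap": len(sel) == 0}
        for col in fields:
            if col == "doy":
                continue
            row[col] = sel[col].mean() if len(sel) else np.nan
        out.append(row)
    df = pd.DataFrame(out).sort_values("date").reset_index(drop=True)
    df["hour"] = np.nan  # daylight-mean mode marker
    return df


def diurnal_bin_average(records: pd.DataFrame) -> pd.DataFrame:
    """Bin-average every field by hour of day over the whole series.

    Returns 24 rows (hour 0..23); empty bins carry NaN.  Used by
    sensitivity analyses to collapse a growing season onto one averaged
    diurnal cycle.
    """
    if "hour" not in records.columns:
        raise ValueError("records need an hour column")
    hour_bin = records["hour"].astype(float).astype(int) % 24
    numeric = records.select_dtypes(include=[np.number]).drop(
        columns=["hour"], errors="ignore")
    grouped = numeric.groupby(hour_bin).mean()
    return grouped.reindex(range(24)).rename_axis("hour").reset_index()


@dataclass(frozen=True)
class ValidationMetrics:
    rmse: float
    mae: float
    r2: float
    n: int
    r2_defined: bool = True


def validation_metrics(observed, modelled) -> ValidationMetrics:
    """RMSE, MAE and R2 between observed and modelled series.

    Pairs with a missing value on either side are dropped; at least two
    complete pairs are required.  R2 = 1 - SSres/SStot is flagged undefined
    when the observed series has zero variance.
    """
    o = np.asarray(observed, dtype=float)
    m = np.asarray(modelled, dtype=float)
    if o.shape != m.shape:
        raise ValueError("series must have equal length")
    ok = np.isfinite(o) & np.isfinite(m)
    o, m = o[ok], m[ok]
    if len(o) < 2:
        raise ValueError("need at least 2 complete pairs")
    resid = o - m
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        return ValidationMetrics(rmse, mae, float("nan"), len(o), False)
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return ValidationMetrics(rmse, mae, r2, len(o), True)
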