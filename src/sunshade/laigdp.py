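"""Retrospective LAI from GPP: the growing-production-day (GDP) method.

Flux sites rarely report daily LAI, so the seasonal LAI trajectory is
reconstructed from the partitioned GPP series: GPP is used as a proxy of
canopy size, scaled so that the seasonal GPP maximum maps onto the site's
maximum reported LAI, and lagged with a one-step weighted mean because
photosynthesis does not turn into leaf area instantaneously.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["gdp_lai"]


def gdp_lai(gpp_daily: pd.Series | np.ndarray, lai_max: float,
            lag_weight: float = 0.5) -> pd.Series:
    """LAI series from daily GPP by the GDP construction.

    The conversion ratio is ``r = max(GPP) / lai_max`` (umol CO2 d-1 per
    unit LAI); the instantaneous series is ``gpp_t / r`` and the final
    series is the causal recurrence ``lai_t = w lai_{t-1} + (1-w)
    lai_inst_t`` with ``lai_0 = lai_inst_0``, clamped at ``lai_max``.

    Parameters
    ----------
    gpp_daily : non-negative daily GPP (umol CO2 m-2 d-1), at least one
        positive value.
    lai_max : maximum reported LAI of the site (m2 m-2).
    lag_weight : w in [0, 1); 0 disables the lag.
    """
    values = np.asarray(gpp_daily, dtype=float)
    index = gpp_daily.index if isinstance(gpp_daily, pd.Series) else None
    if lai_max <= 0:
        raise ValueError("lai_max must be positive")
    if not 0 <= lag_weight < 1:
        raise ValueError("lag_weight must be in [0, 1)")
    if np.any(values < 0):
        raise ValueError("gpp series must be non-negative")
    peak = np.nanmax(values) if len(values) else 0.0
    if not peak > 0:
        raise ValueError("gpp series has no positive value")

    ratio = peak / lai_max
    lai_inst = values / ratio

    lai = np.empty_like(lai_inst)
    prev = lai_inst[0]
    lai[0] = prev
    w = lag_weight
    for t in range(1, len(lai_inst)):
        prev = w * prev + (1.0 - w) * lai_inst[t]
        lai[t] = prev
    lai = np.minimum(lai, lai_max)
    return pd.Series(lai, index=index, name="lai")
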