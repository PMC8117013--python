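"""Assembly of the per-year covariate table for the growth model.

Columns (fixed names, complete over the analysis span):

* ``trend`` — integer long-term trend, year − 1977;
* ``season_length`` — mean April+September temperature anomaly (°C);
* ``summer_heat`` — mean June–August temperature anomaly (°C);
* ``budworm`` — spruce budworm epidemic intensity (0–1);
* ``caterpillar`` — forest tent caterpillar epidemic intensity (0–1).
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .climate import MonthlyClimate, monthly_anomalies, season_length_index, summer_heat_index
from .epidemics import EpidemicCalendar, build_ftc_covariate, build_sbw_covariate, build_trend_covariate

__all__ = ["COVARIATE_COLUMNS", "build_covariate_table"]

COVARIATE_COLUMNS = ["trend", "season_length", "summer_heat", "budworm", "caterpillar"]


def build_covariate_table(climate: Optional[MonthlyClimate],
                          calendar: Optional[EpidemicCalendar] = None,
                          span: tuple[int, int] = (1950, 2005),
                          ref_span: Optional[tuple[int, int]] = None,
                          years: Optional[Iterable[int]] = None) -> pd.DataFrame:
    """Build the covariate table over ``years`` (default: the span).

    Anomalies are taken relative to ``ref_span`` (default: the analysis
    span clipped to the climate record).  Years outside the climate
    record get zero temperature anomalies (climatological conditions);
    this only matters when simulating growth before the climate record
    starts.  Passing ``climate=None`` likewise zeroes both temperature
    proxies.
    """
    if calendar is None:
        calendar = EpidemicCalendar()
    if years is None:
        years = range(span[0], span[1] + 1)
    idx = pd.Index(np.asarray(list(years), dtype=int), name="year")

    table = pd.DataFrame(index=idx)
    table["trend"] = build_trend_covariate(idx).to_numpy()
    if climate is not None:
        if ref_span is None:
            clo, chi = climate.span
            ref_span = (max(span[0], clo), min(span[1], chi))
        anom = monthly_anomalies(climate, ref_span=ref_span, var="tavg_c")
        table["season_length"] = season_length_index(anom).reindex(idx).fillna(0.0)
        table["summer_heat"] = summer_heat_index(anom).reindex(idx).fillna(0.0)
    else:
        table["season_length"] = 0.0
        table["summer_heat"] = 0.0
    table["budworm"] = build_sbw_covariate(calendar, idx).to_numpy()
    table["caterpillar"] = build_ftc_covariate(calendar, idx).to_numpy()
    return table[COVARIATE_COLUMNS]
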