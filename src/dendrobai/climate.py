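"""Monthly climate handling and bootstrapped climate-growth correlations.

The climate table has one row per (year, month) with minimum, average and
maximum temperature (°C) and total precipitation (mm).  Growth proxies are
built from average-temperature anomalies (departures from the per-month
mean over a reference span): the April+September mean anomaly indexes
growing-season length, the June–August mean anomaly indexes summer heat.

Correlation functions pair a mean BAI chronology with monthly predictors
(January–September of the ring-formation year, plus the two composite
windows) and attach 95% percentile confidence intervals from a pairs
bootstrap; a coefficient is flagged significant when its interval
excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MonthlyClimate",
    "monthly_anomalies",
    "season_length_index",
    "summer_heat_index",
    "BootstrapCorrelation",
    "bootstrap_correlation",
    "correlation_function",
    "MONTH_WINDOWS",
]

CLIMATE_COLUMNS = ["year", "month", "tmin_c", "tavg_c", "tmax_c", "prcp_mm"]

_MONTH_ABBR = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]

#: analysis windows of the formation year: single months Jan–Sep plus the
#: growing-season-length (Apr+Sep) and summer (Jun–Aug) composites
MONTH_WINDOWS: dict[str, tuple[int, ...]] = {
    **{_MONTH_ABBR[m - 1]: (m,) for m in range(1, 10)},
    "AprSep": (4, 9),
    "JunAug": (6, 7, 8),
}

#: extended window set including the previous year's April–December
#: (encoded as month − 12, e.g. −8 = previous April); off by default
#: because formation-year months carry the reported signal
MONTH_WINDOWS_WITH_PREVIOUS_YEAR: dict[str, tuple[int, ...]] = {
    **{f"prev{_MONTH_ABBR[m - 1]}": (m - 12,) for m in range(4, 13)},
    **MONTH_WINDOWS,
}


@dataclass
class MonthlyClimate:
    """Validated monthly climate table."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = set(CLIMATE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"climate table missing columns {sorted(missing)}")
        df = df[CLIMATE_COLUMNS].sort_values(["year", "month"]).reset_index(drop=True)
        if not df["month"].isin(range(1, 13)).all():
            raise ValueError("months must be 1..12")
        counts = df.groupby("year")["month"].nunique()
        if (counts != 12).any():
            bad = counts[counts != 12].index[0]
            raise ValueError(f"year {bad}: incomplete months")
        if (df["tmin_c"] > df["tavg_c"]).any() or (df["tavg_c"] > df["tmax_c"]).any():
            raise ValueError("require tmin <= tavg <= tmax")
        if (df["prcp_mm"] < 0).any():
            raise ValueError("precipitation must be >= 0")
        self.data = df

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.data["year"].to_numpy())

    @property
    def span(self) -> tuple[int, int]:
        y = self.years
        return int(y.min()), int(y.max())

    def pivot(self, var: str) -> pd.DataFrame:
        """Year × month table of one variable."""
        return self.data.pivot(index="year", columns="month", values=var)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "MonthlyClimate":
        return cls(pd.read_csv(path))


def monthly_anomalies(climate: MonthlyClimate,
                      ref_span: tuple[int, int] = (1950, 2005),
                      var: str = "tavg_c") -> pd.DataFrame:
    """Year × month anomalies: value minus the month's mean over ``ref_span``.

    By construction each month's anomalies average to zero over the
    reference span.
    """
    lo, hi = ref_span
    years = climate.years
    if lo < years.min() or hi > years.max():
        raise ValueError(f"reference span {ref_span} outside climate span {climate.span}")
    wide = climate.pivot(var)
    ref_mean = wide.loc[lo:hi].mean(axis=0)
    return wide - ref_mean


def season_length_index(anomalies: pd.DataFrame,
                        year: Optional[int] = None) -> Union[float, pd.Series]:
    """Mean of April and September temperature anomalies (°C).

    Proxy for growing-season length: warm Aprils advance its start, warm
    Septembers delay its end.  Without ``year`` the full yearly series is
    returned.
    """
    for m in (4, 9):
        if m not in anomalies.columns:
            raise ValueError(f"month {m} missing from anomaly table")
    series = anomalies[[4, 9]].mean(axis=1)
    return float(series.loc[year]) if year is not None else series.rename("season_length")


def summer_heat_index(anomalies: pd.DataFrame,
                      year: Optional[int] = None) -> Union[float, pd.Series]:
    """Mean June–August temperature anomaly (°C), a summer heat-stress proxy."""
    for m in (6, 7, 8):
        if m not in anomalies.columns:
            raise ValueError(f"month {m} missing from anomaly table")
    series = anomalies[[6, 7, 8]].mean(axis=1)
    return float(series.loc[year]) if year is not None else series.rename("summer_heat")


# ---------------------------------------------------------------------------
# bootstrapped correlation functions


@dataclass
class BootstrapCorrelation:
    """Pearson correlation with a bootstrap percentile interval."""

    r: float
    ci_lo: float
    ci_hi: float
    significant: bool
    n_boot: int
    level: float


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r along axis 1 of two equally shaped 2-d arrays."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def bootstrap_correlation(chronology: pd.Series, predictor: pd.Series,
                          n_boot: int = 1000, level: float = 0.95,
                          seed: Optional[int] = None,
                          rng: Optional[np.random.Generator] = None
                          ) -> BootstrapCorrelation:
    """Pearson correlation with a pairs-bootstrap percentile CI.

    The point estimate uses the full pairing of complete years; the CI is
    the percentile interval of the correlation over ``n_boot`` resamples
    of (year, chronology, predictor) tuples drawn with replacement, pairs
    kept intact.  Significance means the interval excludes zero.
    """
    pair = pd.concat([chronology, predictor], axis=1).dropna()
    if len(pair) < 10:
        raise ValueError(f"need >= 10 complete paired years, got {len(pair)}")
    x = pair.iloc[:, 0].to_numpy(dtype=float)
    y = pair.iloc[:, 1].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance chronology or predictor")
    r = float(sps.pearsonr(x, y).statistic)

    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = _rowwise_pearson(x[idx], y[idx])
    boots = boots[np.isfinite(boots)]
    alpha = (1.0 - level) / 2.0
    ci_lo, ci_hi = np.quantile(boots, [alpha, 1.0 - alpha])
    significant = bool(ci_lo > 0 or ci_hi < 0)
    return BootstrapCorrelation(r=r, ci_lo=float(ci_lo), ci_hi=float(ci_hi),
                                significant=significant, n_boot=n_boot, level=level)


def correlation_function(chronology: pd.Series, climate: MonthlyClimate,
                         group: str = "", variables: Sequence[str] = ("tavg", "prcp"),
                         windows: Optional[dict[str, tuple[int, ...]]] = None,
                         span: Optional[tuple[int, int]] = None,
                         n_boot: int = 1000, level: float = 0.95,
                         seed: Optional[int] = None) -> pd.DataFrame:
    """Correlation-function table for one chronology.

    For each climate variable (monthly mean temperature ``tavg``, monthly
    precipitation total ``prcp``) and each analysis window the chronology
    is correlated with the window mean for that year.  Month numbers
    ``<= 0`` address the previous calendar year (``m − 12`` encoding), so
    passing :data:`MONTH_WINDOWS_WITH_PREVIOUS_YEAR` extends the analysis
    back to the previous April.  Returns a tidy table
    (chronology_group, variable, window, r, ci_lo, ci_hi, significant),
    reproducible under ``seed``.
    """
    if windows is None:
        windows = MONTH_WINDOWS
    rng = np.random.default_rng(seed)
    if span is not None:
        chronology = chronology.loc[span[0]:span[1]]
    rows = []
    for var in variables:
        wide = climate.pivot(f"{var}_c" if var != "prcp" else "prcp_mm")
        for win_name, months in windows.items():
            cols = []
            for m in months:
                if m <= 0:      # previous year's month, aligned to ring year
                    shifted = wide[m + 12].copy()
                    shifted.index = shifted.index + 1
                    cols.append(shifted)
                else:
                    cols.append(wide[m])
            predictor = pd.concat(cols, axis=1).mean(axis=1)
            bc = bootstrap_correlation(chronology, predictor,
                                       n_boot=n_boot, level=level, rng=rng)
            rows.append({"chronology_group": group, "variable": var,
                         "window": win_name, "r": bc.r,
                         "ci_lo": bc.ci_lo, "ci_hi": bc.ci_hi,
                         "significant": bc.significant})
    return pd.DataFrame(rows)
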