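"""Insect-epidemic covariates and first-difference growth-anomaly ranking.

Two defoliator histories enter the growth model as intensity series on a
0–1 scale.  The spruce budworm (SBW, a black spruce defoliator) epidemic
of the 1970s is encoded as a 9-year triangular impact centred on 1974;
the forest tent caterpillar (FTC, a trembling aspen defoliator) epidemics
are point events at 1980 and 2001 (intensity 1) and 2000 (intensity 0.5).

The ranking operation orders year-to-year changes of a mean BAI
chronology (first differences) separately for decreases and increases,
so the largest growth anomalies can be confronted with the recorded
epidemic years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chronology import MeanChronology

__all__ = [
    "EpidemicCalendar",
    "build_sbw_covariate",
    "build_ftc_covariate",
    "build_trend_covariate",
    "rank_first_differences",
]


@dataclass
class EpidemicCalendar:
    """Recorded defoliator epidemics of the study region."""

    sbw_center_year: int = 1974
    sbw_weights: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0, 0.8, 0.6, 0.4, 0.2)
    ftc_intensity: Mapping[int, float] = field(
        default_factory=lambda: {1980: 1.0, 2000: 0.5, 2001: 1.0})

    def __post_init__(self) -> None:
        w = tuple(float(v) for v in self.sbw_weights)
        if len(w) % 2 == 0:
            raise ValueError("SBW weight vector must have odd length")
        mid = len(w) // 2
        if w[mid] != max(w):
            raise ValueError("peak SBW weight must sit at the centre year")
        if any(v < 0 or v > 1 for v in w):
            raise ValueError("SBW weights must lie in [0, 1]")
        if any(v < 0 or v > 1 for v in self.ftc_intensity.values()):
            raise ValueError("FTC intensities must lie in [0, 1]")
        self.sbw_weights = w

    @property
    def sbw_years(self) -> range:
        half = len(self.sbw_weights) // 2
        return range(self.sbw_center_year - half, self.sbw_center_year + half + 1)

    @property
    def ftc_years(self) -> tuple[int, ...]:
        return tuple(sorted(self.ftc_intensity))


def _as_years(years: Iterable[int]) -> np.ndarray:
    y = np.asarray(list(years), dtype=int)
    if y.size == 0:
        raise ValueError("empty year range")
    return y


def build_sbw_covariate(calendar: EpidemicCalendar,
                        years: Iterable[int]) -> pd.Series:
    """Spruce budworm intensity per year (triangular impact, 0 outside)."""
    y = _as_years(years)
    half = len(calendar.sbw_weights) // 2
    vals = np.zeros(y.size)
    for k, w in zip(range(-half, half + 1), calendar.sbw_weights):
        vals[y == calendar.sbw_center_year + k] = w
    return pd.Series(vals, index=y, name="budworm")


def build_ftc_covariate(calendar: EpidemicCalendar,
                        years: Iterable[int]) -> pd.Series:
    """Forest tent caterpillar intensity per year (map lookup, 0 elsewhere)."""
    y = _as_years(years)
    vals = np.array([calendar.ftc_intensity.get(int(yy), 0.0) for yy in y])
    return pd.Series(vals, index=y, name="caterpillar")


def build_trend_covariate(years: Iterable[int] = range(1950, 2006),
                          zero_year: int = 1977) -> pd.Series:
    """Long-term linear trend regressor: year − 1977.

    Over the default 1950–2005 span this runs in unit steps from −27 to
    +28 (mean 0.5).
    """
    y = _as_years(years)
    if y.size > 1 and not np.all(np.diff(y) == 1):
        raise ValueError("trend covariate requires contiguous years")
    return pd.Series(y - zero_year, index=y, name="trend")


def rank_first_differences(chronology: MeanChronology,
                           calendar: EpidemicCalendar) -> pd.DataFrame:
    """Rank year-to-year mean BAI changes against the epidemic calendar.

    The difference ``BAI_t − BAI_{t−1}`` is assigned to the later year
    ``t`` (a drop *into* an epidemic year is that year's anomaly).
    Decreases are ranked ascending (rank 1 = largest drop), increases
    descending (rank 1 = largest rise); ties go to the earlier calendar
    year.  Each year is flagged when it falls inside the SBW triangular
    window or is a recorded FTC year.
    """
    bai = chronology.series
    if len(bai) < 2:
        raise ValueError("chronology must have at least 2 years")
    diff = bai.diff().dropna()
    df = pd.DataFrame({"year": diff.index.astype(int), "diff_cm2": diff.to_numpy()})

    dec = df[df["diff_cm2"] < 0].sort_values(["diff_cm2", "year"],
                                             ascending=[True, True])
    inc = df[df["diff_cm2"] > 0].sort_values(["diff_cm2", "year"],
                                             ascending=[False, True])
    df["rank_decrease"] = pd.Series(
        np.arange(1, len(dec) + 1), index=dec.index).reindex(df.index)
    df["rank_increase"] = pd.Series(
        np.arange(1, len(inc) + 1), index=inc.index).reindex(df.index)
    sbw_years = set(calendar.sbw_years)
    df["sbw_year"] = df["year"].isin(sbw_years)
    df["ftc_year"] = df["year"].isin(set(calendar.ftc_years))
    df.insert(0, "group", chronology.group)
    return df.reset_index(drop=True)
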