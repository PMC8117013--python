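"""Basal-area-increment (BAI) chronologies from ring-width series.

The pipeline is: estimate the distance to pith for cores that missed it,
convert cumulative ring widths to annual BAI (cm² yr⁻¹), drop juvenile
rings below a minimum cambial age, and average trees of a species ×
stand-composition group into a mean chronology with its SEM and sample
depth.  Descriptive statistics (mean sensitivity, first-order
autocorrelation, leave-one-out series intercorrelation) summarise
crossdating quality and year-to-year variability.

Units: ring widths and radii in mm, BAI in cm² (1 cm² = 100 mm²).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .series import RingWidthSeries, group_label

__all__ = [
    "MeanChronology",
    "ChronologyStats",
    "estimate_distance_to_pith",
    "estimate_missing_rings",
    "ring_widths_to_bai",
    "filter_cambial_age",
    "build_mean_chronology",
    "chronology_stats",
]

MM2_PER_CM2 = 100.0


def estimate_distance_to_pith(series: RingWidthSeries,
                              expected_missing_rings: int = 5) -> float:
    """Distance (mm) from the innermost measured ring to the pith.

    Cores that hit the pith return 0.  Otherwise, if the curvature of the
    innermost visible ring was recorded, the radius of the circle through
    that arc is ``chord²/(8·height) + height/2``.  Without arc geometry a
    crude fallback multiplies the mean of the five innermost widths by the
    expected number of missing rings.
    """
    if series.has_pith:
        return 0.0
    if series.est_pith_offset_mm is not None:
        return float(series.est_pith_offset_mm)
    if series.arc_chord_mm is not None:
        c, h = series.arc_chord_mm, series.arc_height_mm
        if h <= 0 or c <= 0:
            raise ValueError("arc chord and height must be > 0")
        return c * c / (8.0 * h) + h / 2.0
    if series.n_rings < 5:
        raise ValueError(
            f"series {series.tree_id!r}: need arc geometry or >= 5 rings "
            "to estimate distance to pith")
    inner = series.widths_mm[:5]
    if inner.mean() <= 0:
        raise ValueError(f"series {series.tree_id!r}: innermost widths are all zero")
    return float(inner.mean()) * expected_missing_rings


def estimate_missing_rings(series: RingWidthSeries, pith_offset_mm: float,
                           expected_missing_rings: int = 5) -> int:
    """Number of rings lost between pith and the innermost measured ring.

    0 when the pith is present.  With an estimated offset, the count is the
    offset divided by the mean of the five innermost widths (the local
    growth rate), rounded to the nearest integer.
    """
    if series.has_pith or pith_offset_mm <= 0:
        return 0
    inner = series.widths_mm[:min(5, series.n_rings)]
    rate = inner[inner > 0].mean() if np.any(inner > 0) else np.nan
    if not np.isfinite(rate) or rate <= 0:
        return expected_missing_rings
    return int(round(pith_offset_mm / rate))


def ring_widths_to_bai(series: RingWidthSeries,
                       pith_offset_mm: float) -> pd.Series:
    """Annual basal area increments (cm²) from cumulative ring widths.

    With cumulative radius ``r_t = offset + Σ_{s<=t} w_s`` the increment is
    ``π (r_t² − r_{t−1}²)`` mm², converted to cm².  The series telescopes:
    the BAI sum equals ``π (r_n² − offset²) / 100`` exactly.
    """
    if pith_offset_mm < 0:
        raise ValueError("pith_offset_mm must be >= 0")
    w = series.widths_mm
    if np.any(w < 0):
        raise ValueError("negative ring width")
    r = pith_offset_mm + np.cumsum(w)
    r_prev = np.concatenate(([pith_offset_mm], r[:-1]))
    bai = np.pi * (r ** 2 - r_prev ** 2) / MM2_PER_CM2
    return pd.Series(bai, index=series.years, name=series.tree_id)


def filter_cambial_age(bai: pd.Series, min_age: int = 15,
                       missing_rings: int = 0) -> pd.Series:
    """Drop rings with cambial age below ``min_age``.

    The cambial age of ring ``i`` (0-based from the innermost measured
    ring) is ``i + 1 + missing_rings``, where ``missing_rings`` accounts
    for rings between the pith and the start of the core.  At the default
    ``min_age=15`` a complete-to-pith series loses its first 14 rings.
    """
    age = np.arange(1, len(bai) + 1) + missing_rings
    return bai[age >= min_age]


def tree_bai(series: RingWidthSeries, min_age: int = 15,
             expected_missing_rings: int = 5) -> pd.Series:
    """Pith estimate → BAI → cambial-age filter for one tree."""
    offset = estimate_distance_to_pith(series, expected_missing_rings)
    missing = estimate_missing_rings(series, offset, expected_missing_rings)
    return filter_cambial_age(ring_widths_to_bai(series, offset),
                              min_age=min_age, missing_rings=missing)


@dataclass
class ChronologyStats:
    """Descriptive statistics of a group of ring-width series."""

    n_trees: int
    mean_ring_width_mm: float
    mean_sensitivity: float
    sd_mm: float
    ar1: float
    series_intercorrelation: float
    mean_bai_cm2: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class MeanChronology:
    """Mean BAI chronology of one species × stand-composition group."""

    species: str
    stand_type: str
    years: np.ndarray
    mean_bai: np.ndarray          # cm² yr⁻¹
    sem: np.ndarray               # cm², across trees, n−1 denominator
    sample_depth: np.ndarray      # trees contributing per year
    stats: Optional[ChronologyStats] = None

    @property
    def group(self) -> str:
        return group_label(self.species, self.stand_type)

    @property
    def series(self) -> pd.Series:
        return pd.Series(self.mean_bai, index=self.years, name=self.group)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": self.group, "year": self.years,
            "mean_bai_cm2": self.mean_bai, "sem_cm2": self.sem,
            "n_trees": self.sample_depth,
        })


def build_mean_chronology(series_list: Sequence[RingWidthSeries],
                          span: tuple[int, int] = (1950, 2005),
                          min_age: int = 15,
                          min_depth: int = 2,
                          expected_missing_rings: int = 5,
                          compute_stats: bool = True) -> MeanChronology:
    """Average per-tree BAI into a mean chronology over ``span``.

    Every year of the span must keep at least ``min_depth`` contributing
    trees after the cambial-age filter.  The SEM is the across-tree
    standard deviation (n−1) divided by √n.
    """
    if not series_list:
        raise ValueError("empty group: no ring-width series")
    species = series_list[0].species
    stand = series_list[0].stand_type
    if any(s.species != species or s.stand_type != stand for s in series_list):
        raise ValueError("all series in a group must share species and stand type")

    bais = []
    for s in series_list:
        b = tree_bai(s, min_age=min_age, expected_missing_rings=expected_missing_rings)
        b = b.loc[(b.index >= span[0]) & (b.index <= span[1])]
        if not b.empty:
            bais.append(b)
    if not bais:
        raise ValueError("no tree has rings inside the analysis span after filtering")
    wide = pd.concat(bais, axis=1)
    years = np.arange(span[0], span[1] + 1)
    wide = wide.reindex(years)

    depth = wide.notna().sum(axis=1).to_numpy()
    if np.any(depth < min_depth):
        bad = years[depth < min_depth][0]
        raise ValueError(
            f"year {bad}: only {int(depth[depth < min_depth][0])} trees "
            f"contribute (need >= {min_depth})")
    mean = wide.mean(axis=1).to_numpy()
    sem = (wide.std(axis=1, ddof=1) / np.sqrt(depth)).to_numpy()

    stats = (chronology_stats(series_list, skip_juvenile=min_age - 1)
             if compute_stats and len(series_list) >= 2 else None)
    if stats is not None:
        stats.mean_bai_cm2 = float(np.nanmean(mean))
    return MeanChronology(species=species, stand_type=stand, years=years,
                          mean_bai=mean, sem=sem, sample_depth=depth,
                          stats=stats)


# ---------------------------------------------------------------------------
# descriptive statistics


def _mean_sensitivity(w: np.ndarray) -> float:
    w = w[np.isfinite(w)]
    num = 2.0 * np.abs(np.diff(w))
    den = w[1:] + w[:-1]
    ok = den > 0
    if not ok.any():
        return np.nan
    return float(np.mean(num[ok] / den[ok]))


def _ar1(w: np.ndarray) -> float:
    if len(w) < 3 or np.std(w[:-1]) == 0 or np.std(w[1:]) == 0:
        return np.nan
    return float(np.corrcoef(w[:-1], w[1:])[0, 1])


def chronology_stats(series_list: Sequence[RingWidthSeries],
                     skip_juvenile: int = 0) -> ChronologyStats:
    """Table-style descriptive statistics of a group of series.

    Mean sensitivity is the mean relative year-to-year width change
    ``2|w_{t+1}−w_t| / (w_{t+1}+w_t)``, averaged over series.  AR1 is the
    per-series lag-1 Pearson autocorrelation (constant series excluded).
    The series intercorrelation is computed on first-differenced widths:
    each series' differences are correlated against the mean difference
    series of all other trees (leave-one-out), and the correlations
    averaged.  First differencing removes the shared age trend so the
    statistic reflects year-to-year agreement.

    ``skip_juvenile`` drops that many innermost rings per series first,
    so the statistics describe the rings that enter the chronology
    rather than the steep juvenile decline.
    """
    if len(series_list) < 2:
        raise ValueError("need at least two series")
    series_list = [s for s in series_list if s.n_rings - skip_juvenile >= 3]
    if len(series_list) < 2:
        raise ValueError("need at least two series with >= 3 post-juvenile rings")

    widths = [s.widths_mm[skip_juvenile:] for s in series_list]
    ms = float(np.nanmean([_mean_sensitivity(w) for w in widths]))
    ar1_vals = np.asarray([_ar1(w) for w in widths])
    ar1 = float(np.nanmean(ar1_vals)) if np.isfinite(ar1_vals).any() else np.nan

    diffs = pd.concat(
        [pd.Series(np.diff(w), index=s.years[skip_juvenile + 1:], name=i)
         for i, (s, w) in enumerate(zip(series_list, widths))], axis=1)
    rbars = []
    for i in range(diffs.shape[1]):
        own = diffs[i]
        others = diffs.drop(columns=i).mean(axis=1)
        pair = pd.concat([own, others], axis=1).dropna()
        if len(pair) >= 3 and pair.iloc[:, 0].std() > 0 and pair.iloc[:, 1].std() > 0:
            rbars.append(float(np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1]))
    intercorr = float(np.mean(rbars)) if rbars else np.nan

    all_w = np.concatenate(widths)
    return ChronologyStats(
        n_trees=len(series_list),
        mean_ring_width_mm=float(all_w.mean()),
        mean_sensitivity=ms,
        sd_mm=float(all_w.std(ddof=1)),
        ar1=ar1,
        series_intercorrelation=intercorr,
        mean_bai_cm2=np.nan,
    )
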