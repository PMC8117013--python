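"""Synthetic tree-ring, climate and epidemic data with known ground truth.

The generator emulates the study system — five mean-BAI chronology groups
(black spruce in pure spruce, mixed and pure aspen stands; trembling
aspen in pure aspen and mixed stands) over a boreal 1950–2005 analysis
window — so every downstream stage (chronology building, correlation
functions, Bayesian attribution) can be tested against known generating
parameters.

Structure of the simulation:

1. monthly climate is drawn around a fixed climatology (independent
   Gaussian months; La Sarre-like normals, July 16.9 °C, January
   −18.2 °C), precipitation from a gamma law;
2. each group's mean BAI is the linear predictor of the growth model
   (baseline + trend + season-length + summer-heat + budworm +
   caterpillar terms) plus AR(1) Gaussian noise of marginal sd σ;
3. per-tree ring widths are obtained by inverting cumulative-area
   growth: each tree gets a multiplicative lognormal growth factor
   (unit mean), a uniform 0–10 mm pith offset, and widths
   ``w_t = sqrt(A_t/π) − sqrt(A_{t−1}/π)``.

Averaging the trees' recomputed BAIs recovers the group series up to
between-tree scatter, which is the round-trip property the tests lean on.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .climate import MonthlyClimate
from .covariates import COVARIATE_COLUMNS, build_covariate_table
from .epidemics import EpidemicCalendar
from .series import RingWidthSeries, group_label, parse_group_label

__all__ = [
    "GroupParams",
    "SyntheticTruth",
    "ClimateGenParams",
    "default_truth",
    "generate_monthly_climate",
    "simulate_group_bai",
    "simulate_tree_ring_widths",
    "SyntheticDataset",
    "simulate_dataset",
]


@dataclass
class GroupParams:
    """True model coefficients of one chronology group.

    Units: baseline, budworm, caterpillar effects in cm²; trend in
    cm²/yr; season_length and summer_heat in cm²/°C; sigma in cm².
    """

    baseline: float
    trend: float
    season_length: float
    summer_heat: float
    budworm: float
    caterpillar: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def as_alpha_vector(self) -> np.ndarray:
        return np.array([self.baseline, self.trend, self.season_length,
                         self.summer_heat, self.budworm, self.caterpillar])


@dataclass
class ClimateGenParams:
    """Generating parameters of the synthetic monthly climate.

    Temperatures are independent Gaussians around a 12-value monthly
    climatology; precipitation is gamma with a monthly mean and a common
    dispersion (variance = dispersion · mean²).  ``warming_slope``
    (°C/yr, default 0) adds an optional linear trend to all months.
    """

    tavg_climatology_c: tuple[float, ...] = (
        -18.2, -16.2, -9.4, -0.4, 7.8, 13.9, 16.9, 15.4, 10.1, 3.5, -4.9, -14.1)
    tavg_sd_c: tuple[float, ...] = (1.5,) * 12
    diurnal_half_range_c: float = 5.5
    prcp_mean_mm: tuple[float, ...] = (
        55., 42., 55., 55., 75., 90., 100., 95., 90., 80., 75., 62.)
    prcp_dispersion: float = 0.15
    warming_slope_c_per_yr: float = 0.0
    warming_ref_year: int = 1950

    def __post_init__(self) -> None:
        if len(self.tavg_climatology_c) != 12 or len(self.tavg_sd_c) != 12 \
                or len(self.prcp_mean_mm) != 12:
            raise ValueError("monthly parameter vectors must have 12 entries")
        if any(s < 0 for s in self.tavg_sd_c):
            raise ValueError("temperature sds must be >= 0")
        if any(p < 0 for p in self.prcp_mean_mm) or self.prcp_dispersion < 0:
            raise ValueError("precipitation parameters must be >= 0")
        if self.diurnal_half_range_c <= 0:
            raise ValueError("diurnal half range must be > 0")


#: default group truths.  Baselines follow the observed mean BAI ordering
#: (spruce ≈ 2–3 cm², aspen ≈ 9 cm²); signs encode the study system:
#: spruce gains from long growing seasons, loses under summer heat and
#: budworm epidemics (more strongly outside pure spruce stands) and gains
#: from caterpillar outbreaks on neighbouring aspen; aspen growth is
#: roughly halved by caterpillar epidemics and insensitive to budworm.
_DEFAULT_GROUPS: dict[str, GroupParams] = {
    "BS_PBS": GroupParams(2.5, 0.000, 0.30, -0.40, -0.40, 0.00, 0.30),
    "BS_M":   GroupParams(3.0, -0.020, 0.40, -0.20, -0.80, 0.50, 0.30),
    "BS_PTA": GroupParams(2.2, 0.020, 0.30, -0.30, -0.70, 0.60, 0.30),
    "TA_PTA": GroupParams(9.3, -0.060, 0.00, -0.20, 0.00, -4.50, 1.40),
    "TA_M":   GroupParams(8.8, 0.020, 0.00, -0.20, 0.00, -4.40, 1.40),
}

_DEFAULT_N_TREES = {"BS_PBS": 20, "BS_M": 20, "BS_PTA": 15, "TA_PTA": 15, "TA_M": 11}


@dataclass
class SyntheticTruth:
    """Complete generating configuration of a synthetic study."""

    group_params: Mapping[str, GroupParams] = field(
        default_factory=lambda: dict(_DEFAULT_GROUPS))
    ar1_coef: float = 0.0
    tree_sd: float = 0.2
    tree_year_sd: float = 0.08
    n_trees: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_N_TREES))
    first_year: int = 1925
    last_year: int = 2005
    analysis_span: tuple[int, int] = (1950, 2005)
    max_pith_offset_mm: float = 10.0
    arc_noise_frac: float = 0.05
    seed: int = 0
    climate: ClimateGenParams = field(default_factory=ClimateGenParams)
    calendar: EpidemicCalendar = field(default_factory=EpidemicCalendar)

    def __post_init__(self) -> None:
        if not -1.0 < self.ar1_coef < 1.0:
            raise ValueError("|ar1_coef| must be < 1")
        if any(n < 2 for n in self.n_trees.values()):
            raise ValueError("need at least 2 trees per group")
        if self.first_year > self.analysis_span[0] or self.last_year < self.analysis_span[1]:
            raise ValueError("year span must cover the analysis span")
        if self.tree_sd < 0:
            raise ValueError("tree_sd must be >= 0")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_params"] = {k: dataclasses.asdict(v) if not isinstance(v, dict) else v
                             for k, v in self.group_params.items()}
        d["calendar"] = {
            "sbw_center_year": self.calendar.sbw_center_year,
            "sbw_weights": list(self.calendar.sbw_weights),
            "ftc_intensity": {str(k): v for k, v in self.calendar.ftc_intensity.items()},
        }
        return d


def default_truth(**overrides) -> SyntheticTruth:
    """The default synthetic study configuration."""
    return SyntheticTruth(**overrides)


# ---------------------------------------------------------------------------
# climate


def generate_monthly_climate(params: ClimateGenParams,
                             years: Iterable[int],
                             seed: Optional[int] = None,
                             rng: Optional[np.random.Generator] = None
                             ) -> MonthlyClimate:
    """Draw a monthly climate table over ``years``.

    Months are independent; tavg ~ N(climatology, sd), tmin/tmax sit a
    fixed half-range below/above tavg, precipitation is gamma (exactly
    its mean when the dispersion is 0).  Deterministic under a fixed
    seed; with all sds zero the output equals the climatology.
    """
    yrs = np.asarray(list(years), dtype=int)
    if yrs.size == 0:
        raise ValueError("years must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for y in yrs:
        warm = params.warming_slope_c_per_yr * (y - params.warming_ref_year)
        for m in range(1, 13):
            mu = params.tavg_climatology_c[m - 1] + warm
            sd = params.tavg_sd_c[m - 1]
            tavg = mu + sd * rng.standard_normal() if sd > 0 else mu
            pm = params.prcp_mean_mm[m - 1]
            if params.prcp_dispersion > 0 and pm > 0:
                shape = 1.0 / params.prcp_dispersion
                prcp = rng.gamma(shape, pm / shape)
            else:
                prcp = pm
            rows.append((int(y), m, tavg - params.diurnal_half_range_c, tavg,
                         tavg + params.diurnal_half_range_c, prcp))
    return MonthlyClimate(pd.DataFrame(rows, columns=[
        "year", "month", "tmin_c", "tavg_c", "tmax_c", "prcp_mm"]))


# ---------------------------------------------------------------------------
# group-level BAI


def simulate_group_bai(truth: SyntheticTruth, covariates: pd.DataFrame,
                       group: str, seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None) -> pd.Series:
    """Mean BAI series of one group: linear predictor + AR(1) noise.

    The noise has marginal sd σ and lag-1 autocorrelation ``ar1_coef``
    (innovation sd σ·√(1−φ²)); with σ effectively 0 the series equals
    the deterministic predictor.
    """
    if group not in truth.group_params:
        raise KeyError(f"unknown group {group!r}")
    gp = truth.group_params[group]
    missing = [c for c in COVARIATE_COLUMNS if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table missing columns {missing}")
    X = covariates[COVARIATE_COLUMNS].to_numpy(dtype=float)
    mu = gp.baseline + X @ gp.as_alpha_vector()[1:]
    n = len(mu)
    if rng is None:
        rng = np.random.default_rng(seed)
    phi, sigma = truth.ar1_coef, gp.sigma
    eps = np.empty(n)
    innov_sd = sigma * math.sqrt(1.0 - phi * phi)
    eps[0] = sigma * rng.standard_normal()
    z = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    for t in range(1, n):
        eps[t] = phi * eps[t - 1] + innov_sd * z[t - 1]
    return pd.Series(mu + eps, index=covariates.index, name=group)


# ---------------------------------------------------------------------------
# per-tree ring widths


def simulate_tree_ring_widths(truth: SyntheticTruth, group_bai: pd.Series,
                              group: str, seed: Optional[int] = None,
                              rng: Optional[np.random.Generator] = None
                              ) -> list[RingWidthSeries]:
    """Invert a group BAI series into per-tree ring-width series.

    Each tree draws a lognormal growth factor with unit mean (sd
    ≈ ``tree_sd``), a pith offset uniform on (0, ``max_pith_offset_mm``)
    and a start year in the first decade of the span, then accumulates
    basal area ``A_t = A_{t−1} + factor·BAI_t`` and emits widths
    ``w_t = sqrt(A_t/π) − sqrt(A_{t−1}/π)`` (all in mm and mm²).  Cores
    with a sizeable offset record noisy arc geometry of the innermost
    ring; the smallest offsets are declared pith-complete.
    """
    if group not in truth.group_params:
        raise KeyError(f"unknown group {group!r}")
    bai = group_bai.dropna()
    if (bai <= 0).any():
        raise ValueError("group BAI must be strictly positive to invert to widths")
    if rng is None:
        rng = np.random.default_rng(seed)
    species, stand = parse_group_label(group)
    n_trees = truth.n_trees.get(group, 10)
    years = bai.index.to_numpy(dtype=int)

    out = []
    for k in range(n_trees):
        if truth.tree_sd > 0:
            factor = float(rng.lognormal(-0.5 * truth.tree_sd ** 2, truth.tree_sd))
        else:
            factor = 1.0
        offset = float(rng.uniform(0.0, truth.max_pith_offset_mm))
        has_pith = offset < 0.5
        if has_pith:
            offset = 0.0
        start = int(years[0] + rng.integers(0, min(10, max(1, len(years) - 40))))
        tree_bai_cm2 = factor * bai.loc[start:].to_numpy()
        if truth.tree_year_sd > 0:
            # idiosyncratic tree-year noise (unit-mean lognormal): cores
            # disagree year to year, so the intercorrelation sits below 1
            s = truth.tree_year_sd
            tree_bai_cm2 = tree_bai_cm2 * rng.lognormal(
                -0.5 * s * s, s, size=tree_bai_cm2.size)
        area_mm2 = math.pi * offset ** 2 + np.cumsum(tree_bai_cm2) * 100.0
        r = np.sqrt(area_mm2 / math.pi)
        widths = np.diff(np.concatenate(([offset], r)))
        arc_chord = arc_height = None
        if not has_pith:
            h = min(2.0, offset)
            chord_true = math.sqrt(max((offset - h / 2.0) * 8.0 * h, 1e-9))
            noise = 1.0 + truth.arc_noise_frac * rng.standard_normal()
            arc_chord = max(chord_true * noise, 1e-3)
            arc_height = h
        out.append(RingWidthSeries(
            tree_id=f"{group.replace('_', '')}{k:03d}"[:8],
            species=species, stand_type=stand, first_year=start,
            widths_mm=widths, has_pith=has_pith,
            arc_chord_mm=arc_chord, arc_height_mm=arc_height,
            est_pith_offset_mm=None))
        out[-1].true_pith_offset_mm = offset          # truth sidecar, not serialized
        out[-1].true_growth_factor = factor
    return out


# ---------------------------------------------------------------------------
# full dataset


@dataclass
class SyntheticDataset:
    """Bundle of everything one synthetic study generates."""

    truth: SyntheticTruth
    climate: MonthlyClimate
    covariates: pd.DataFrame
    group_bai: dict[str, pd.Series]
    trees: dict[str, list[RingWidthSeries]]

    def all_trees(self) -> list[RingWidthSeries]:
        return [s for trees in self.trees.values() for s in trees]

    def write(self, out_dir) -> dict[str, str]:
        """Write .rwl, long CSV, metadata CSV, climate CSV and truth JSON."""
        from . import rwl as _rwl

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trees = self.all_trees()
        paths = {
            "rwl": str(out / "ring_widths.rwl"),
            "long_csv": str(out / "ring_widths.csv"),
            "metadata_csv": str(out / "tree_metadata.csv"),
            "climate_csv": str(out / "climate.csv"),
            "truth_json": str(out / "truth.json"),
        }
        _rwl.write_rwl(trees, paths["rwl"])
        _rwl.write_long_csv(trees, paths["long_csv"])
        _rwl.write_metadata_csv(trees, paths["metadata_csv"])
        self.climate.to_csv(paths["climate_csv"])
        sidecar = self.truth.to_json_dict()
        sidecar["true_pith_offset_mm"] = {
            s.tree_id: getattr(s, "true_pith_offset_mm", None) for s in trees}
        sidecar["true_growth_factor"] = {
            s.tree_id: getattr(s, "true_growth_factor", None) for s in trees}
        Path(paths["truth_json"]).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        return paths


def simulate_dataset(truth: Optional[SyntheticTruth] = None,
                     seed: Optional[int] = None) -> SyntheticDataset:
    """Run the full generator: climate → covariates → group BAI → trees.

    All randomness flows from a single seed (``seed`` argument wins over
    ``truth.seed``); sub-streams are spawned per stage so the pieces are
    individually reproducible.
    """
    truth = truth or default_truth()
    root = np.random.default_rng(truth.seed if seed is None else seed)
    climate_rng, bai_rng, tree_rng = root.spawn(3)

    clim_years = range(truth.analysis_span[0], truth.analysis_span[1] + 1)
    climate = generate_monthly_climate(truth.climate, clim_years, rng=climate_rng)
    covariates = build_covariate_table(climate, truth.calendar,
                                       span=truth.analysis_span,
                                       years=truth.years)
    group_bai = {}
    trees = {}
    for group in truth.group_params:
        gb = simulate_group_bai(truth, covariates, group, rng=bai_rng)
        gb = gb.clip(lower=0.05)      # inversion to widths needs positivity
        group_bai[group] = gb
        trees[group] = simulate_tree_ring_widths(truth, gb, group, rng=tree_rng)
    return SyntheticDataset(truth=truth, climate=climate, covariates=covariates,
                            group_bai=group_bai, trees=trees)
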