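"""Bayesian linear growth model for mean BAI chronologies.

The model explains the mean basal area increment of a chronology ``y``
in year ``t`` as a linear combination of a stand baseline, a long-term
trend, two temperature proxies and two insect-epidemic intensities::

    BAI_t = a_baseline + trend_t·a_trend + season_length_t·a_season_length
            + summer_heat_t·a_summer_heat + budworm_t·a_budworm
            + caterpillar_t·a_caterpillar + e_t,    e_t ~ N(0, σ²)

Priors are uniform (flat within wide bounds) on the six coefficients and
Jeffreys, p(σ) ∝ 1/σ, on the residual scale.  The posterior is sampled
with a component-wise Gaussian random-walk Metropolis-Hastings chain;
proposal scales adapt only during burn-in (targeting 20–45% acceptance)
and are frozen afterwards so the retained chain satisfies detailed
balance.  Under these priors the coefficient posterior is the classical
multivariate-t centred on the least-squares solution, which the test
suite uses as an analytic oracle.

Chronology parameters are compared across stand-composition groups with
the overlapping coefficient (OVL = ∫ min of the two posterior densities);
an overlap below 10% is read as a significant difference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .covariates import COVARIATE_COLUMNS

__all__ = [
    "PARAM_NAMES",
    "BaiLinearModel",
    "BaiLinearResults",
    "OverlapResult",
    "posterior_overlap",
    "ConvergenceReport",
]

ALPHA_NAMES = ("alpha_baseline", "alpha_trend", "alpha_season_length",
               "alpha_summer_heat", "alpha_budworm", "alpha_caterpillar")
PARAM_NAMES = ALPHA_NAMES + ("sigma",)


class BaiLinearModel:
    """Six-coefficient linear BAI model for one chronology.

    Parameters
    ----------
    bai : pandas.Series
        Mean BAI (cm²) indexed by calendar year.
    covariates : pandas.DataFrame
        Table with columns ``trend, season_length, summer_heat, budworm,
        caterpillar`` indexed by year; must cover the chronology years.
    group : str, optional
        Chronology label carried into results.
    """

    def __init__(self, bai: pd.Series, covariates: pd.DataFrame,
                 group: str = "") -> None:
        bai = bai.dropna()
        missing = [c for c in COVARIATE_COLUMNS if c not in covariates.columns]
        if missing:
            raise ValueError(f"covariate table missing columns {missing}")
        if not set(bai.index).issubset(set(covariates.index)):
            raise ValueError("covariates do not cover all chronology years")
        cov = covariates.loc[bai.index, COVARIATE_COLUMNS]
        if not np.all(np.isfinite(bai.to_numpy())) or not np.all(np.isfinite(cov.to_numpy())):
            raise ValueError("non-finite values in BAI or covariates")
        if len(bai) < 8:
            raise ValueError("need at least 8 years to fit")
        self.group = group
        self.years = bai.index.to_numpy(dtype=int)
        self.endog = bai.to_numpy(dtype=float)
        self.exog = np.column_stack([np.ones(len(bai)), cov.to_numpy(dtype=float)])
        if np.std(self.endog) == 0:
            raise ValueError("zero-variance BAI series")
        self._ls_cache: Optional[tuple[np.ndarray, float]] = None

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_chronology(cls, chronology, covariates: pd.DataFrame) -> "BaiLinearModel":
        """Build from a :class:`~dendrobai.chronology.MeanChronology`."""
        return cls(chronology.series, covariates, group=chronology.group)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, bai_col: str = "mean_bai_cm2",
                       year_col: str = "year", group: str = "") -> "BaiLinearModel":
        """Build from a tidy frame holding both BAI and covariate columns."""
        df = df.set_index(year_col) if year_col in df.columns else df
        return cls(df[bai_col], df[COVARIATE_COLUMNS], group=group)

    # -- classical reference fit ------------------------------------------
    def least_squares(self) -> tuple[np.ndarray, float]:
        """OLS coefficients and residual sd (ddof = n − p).

        Centre of the flat-prior coefficient posterior.
        """
        if self._ls_cache is None:
            beta, *_ = np.linalg.lstsq(self.exog, self.endog, rcond=None)
            resid = self.endog - self.exog @ beta
            dof = max(len(self.endog) - self.exog.shape[1], 1)
            s = math.sqrt(float(resid @ resid) / dof)
            self._ls_cache = (beta, s)
        return self._ls_cache

    def default_bounds(self) -> np.ndarray:
        """Wide uniform prior bounds, (7, 2) array of (low, high).

        Coefficient bounds are symmetric about zero with half-width
        max(10·|OLS estimate|, 10·sd(BAI)/sd(covariate)); the intercept
        uses 10·(|mean| + sd) of the BAI series.  σ is bounded in
        (1e-6, 10·sd(BAI)).  The bounds are meant not to bind;
        :meth:`fit` warns when draws pile up near them.
        """
        beta, _ = self.least_squares()
        y = self.endog
        sd_y = float(np.std(y, ddof=1))
        bounds = np.empty((7, 2))
        for j in range(6):
            sd_x = float(np.std(self.exog[:, j], ddof=1)) if j > 0 else 0.0
            if j == 0:
                spread = 10.0 * (abs(float(np.mean(y))) + sd_y)
            elif sd_x > 0:
                spread = 10.0 * sd_y / sd_x
            else:
                warnings.warn(f"covariate {COVARIATE_COLUMNS[j-1]!r} is constant; "
                              "its coefficient is prior-dominated")
                spread = 10.0 * sd_y
            half = max(10.0 * abs(float(beta[j])), spread)
            bounds[j] = (-half, half)
        bounds[6] = (1e-6, 10.0 * sd_y)
        return bounds

    # -- posterior ---------------------------------------------------------
    def log_posterior(self, params: Sequence[float],
                      bounds: Optional[np.ndarray] = None) -> float:
        """Unnormalised log posterior density at ``params``.

        ``params`` is (a_baseline, …, a_caterpillar, σ).  Inside the
        uniform bounds the value is the Gaussian log likelihood plus the
        Jeffreys term −log σ; outside it is −inf.
        """
        p = np.asarray(params, dtype=float)
        if p.shape != (7,):
            raise ValueError("params must have 7 entries (6 coefficients + sigma)")
        if not np.all(np.isfinite(p)):
            raise ValueError("non-finite parameter value")
        if bounds is None:
            bounds = self.default_bounds()
        if np.any(p < bounds[:, 0]) or np.any(p > bounds[:, 1]):
            return -np.inf
        sigma = p[6]
        resid = self.endog - self.exog @ p[:6]
        n = len(resid)
        loglik = (-0.5 * n * math.log(2.0 * math.pi) - n * math.log(sigma)
                  - float(resid @ resid) / (2.0 * sigma * sigma))
        return loglik - math.log(sigma)

    def fit(self, n_iter: int = 60_000, burn_in: int = 10_000,
            seed: Optional[int] = None,
            bounds: Optional[np.ndarray] = None,
            initial_scales: Optional[np.ndarray] = None,
            target_accept: tuple[float, float] = (0.20, 0.45),
            adapt_batch: int = 100) -> "BaiLinearResults":
        """Sample the posterior by component-wise random-walk MH.

        ``n_iter`` total iterations; the first ``burn_in`` are discarded
        (and are the only phase in which proposal scales adapt).  One
        iteration sweeps all seven parameters.  Reproducible under
        ``seed``.
        """
        if burn_in >= n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if bounds is None:
            bounds = self.default_bounds()
        bounds = np.asarray(bounds, dtype=float)
        beta0, s0 = self.least_squares()
        X, y = self.exog, self.endog
        n = len(y)

        # start at the least-squares solution, clipped inside the bounds
        theta = np.empty(7)
        theta[:6] = np.clip(beta0, bounds[:6, 0] * 0.99, bounds[:6, 1] * 0.99)
        theta[6] = min(max(s0, bounds[6, 0] * 2), bounds[6, 1] * 0.5)

        # proposal scales: roughly the conditional posterior sds
        if initial_scales is None:
            XtX = X.T @ X
            try:
                se = np.sqrt(np.diag(np.linalg.inv(XtX))) * max(s0, 1e-8)
            except np.linalg.LinAlgError:
                se = np.full(6, max(s0, 1e-8))
            initial_scales = np.concatenate([
                2.4 * np.where(se > 0, se, max(s0, 1e-8)),
                [max(s0, 1e-8) / math.sqrt(2 * n) * 2.4],
            ])
        scales = np.asarray(initial_scales, dtype=float).copy()

        rng = np.random.default_rng(seed)
        cols = [np.ascontiguousarray(X[:, j]) for j in range(7 - 1)]
        xx = [float(c @ c) for c in cols]
        lo = bounds[:, 0].tolist()
        hi = bounds[:, 1].tolist()

        resid = y - X @ theta[:6]
        sse = float(resid @ resid)
        sigma = float(theta[6])
        log_sigma = math.log(sigma)

        draws = np.empty((n_iter, 7))
        acc = np.zeros(7, dtype=np.int64)
        batch_acc = np.zeros(7, dtype=np.int64)
        near_bound = np.zeros(7, dtype=np.int64)
        t_lo, t_hi = target_accept

        # pre-generated innovations keep the inner loop cheap
        block = 10_000
        th = theta.tolist()
        for start in range(0, n_iter, block):
            stop = min(start + block, n_iter)
            m = stop - start
            norm = rng.standard_normal((m, 7))
            logu = np.log(rng.random((m, 7)))
            for i in range(m):
                it = start + i
                for j in range(6):
                    prop = th[j] + scales[j] * norm[i, j]
                    if prop < lo[j] or prop > hi[j]:
                        continue
                    d = prop - th[j]
                    cr = float(cols[j] @ resid)
                    sse_new = sse - 2.0 * d * cr + d * d * xx[j]
                    if (sse - sse_new) / (2.0 * sigma * sigma) >= logu[i, j]:
                        th[j] = prop
                        resid -= d * cols[j]
                        sse = sse_new
                        acc[j] += 1
                        batch_acc[j] += 1
                # sigma: log target = −(n+1)·log σ − SSE/(2σ²)
                prop = sigma + scales[6] * norm[i, 6]
                if lo[6] < prop < hi[6]:
                    lp_new = math.log(prop)
                    dlog = (-(n + 1) * (lp_new - log_sigma)
                            - 0.5 * sse * (1.0 / (prop * prop) - 1.0 / (sigma * sigma)))
                    if dlog >= logu[i, 6]:
                        sigma = prop
                        log_sigma = lp_new
                        acc[6] += 1
                        batch_acc[6] += 1
                draws[it, :6] = th[:6]
                draws[it, 6] = sigma

                if it < burn_in and (it + 1) % adapt_batch == 0:
                    rate = batch_acc / adapt_batch
                    scales *= np.where(rate < t_lo, 0.7,
                                       np.where(rate > t_hi, 1.4, 1.0))
                    batch_acc[:] = 0

        retained = draws[burn_in:]
        # flag prior bounds that visibly constrain the posterior
        for j in range(7):
            width = hi[j] - lo[j]
            frac = np.mean((retained[:, j] - lo[j] < 0.01 * width) |
                           (hi[j] - retained[:, j] < 0.01 * width))
            if frac > 1e-3:
                warnings.warn(
                    f"{PARAM_NAMES[j]}: {frac:.1%} of draws within 1% of a "
                    "prior bound; widen the bounds")
        accept_rate = acc / n_iter
        return BaiLinearResults(model=self, draws=retained,
                                acceptance_rates=accept_rate,
                                n_iter=n_iter, burn_in=burn_in,
                                bounds=bounds, proposal_scales=scales)


class BaiLinearResults:
    """Posterior sample and summaries of a fitted :class:`BaiLinearModel`."""

    def __init__(self, model: BaiLinearModel, draws: np.ndarray,
                 acceptance_rates: np.ndarray, n_iter: int, burn_in: int,
                 bounds: np.ndarray, proposal_scales: np.ndarray) -> None:
        self.model = model
        self.draws = pd.DataFrame(draws, columns=list(PARAM_NAMES))
        self.acceptance_rates = pd.Series(acceptance_rates, index=list(PARAM_NAMES))
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.bounds = bounds
        self.proposal_scales = proposal_scales

    # -- point summaries ---------------------------------------------------
    @property
    def params(self) -> pd.Series:
        """Posterior means."""
        return self.draws.mean()

    @property
    def medians(self) -> pd.Series:
        return self.draws.median()

    @property
    def sd(self) -> pd.Series:
        """Posterior standard deviations."""
        return self.draws.std(ddof=1)

    def credible_interval(self, level: float = 0.95) -> pd.DataFrame:
        a = (1.0 - level) / 2.0
        return self.draws.quantile([a, 1.0 - a]).T.rename(
            columns={a: "lower", 1.0 - a: "upper"})

    @property
    def n_retained(self) -> int:
        return len(self.draws)

    # -- fit quality --------------------------------------------------------
    @property
    def fittedvalues(self) -> pd.Series:
        """Predicted mean BAI at the posterior-mean coefficients."""
        alpha = self.params[list(ALPHA_NAMES)].to_numpy()
        return pd.Series(self.model.exog @ alpha, index=self.model.years,
                         name="sim_bai")

    @property
    def resid(self) -> pd.Series:
        return pd.Series(self.model.endog, index=self.model.years) - self.fittedvalues

    @property
    def rsquared(self) -> float:
        """1 − SSE/SST with predictions at posterior-mean coefficients."""
        y = self.model.endog
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0:
            raise ValueError("zero-variance BAI series, R² undefined")
        sse = float(np.sum(self.resid.to_numpy() ** 2))
        return 1.0 - sse / sst

    def predict(self, covariates: pd.DataFrame) -> pd.Series:
        X = np.column_stack([np.ones(len(covariates)),
                             covariates[COVARIATE_COLUMNS].to_numpy(dtype=float)])
        alpha = self.params[list(ALPHA_NAMES)].to_numpy()
        return pd.Series(X @ alpha, index=covariates.index, name="sim_bai")

    # -- diagnostics ---------------------------------------------------------
    def convergence_report(self) -> "ConvergenceReport":
        return ConvergenceReport.from_draws(self.draws, self.bounds)

    def summary(self) -> str:
        ci = self.credible_interval()
        lines = [
            f"Bayesian linear BAI model — group {self.model.group or '?'}",
            f"  years: {self.model.years.min()}–{self.model.years.max()} "
            f"(n = {len(self.model.years)})",
            f"  retained draws: {self.n_retained} "
            f"(of {self.n_iter}, burn-in {self.burn_in})",
            f"  R² = {self.rsquared:.3f}   mean acceptance = "
            f"{self.acceptance_rates.mean():.2f}",
            "",
            f"  {'parameter':<22}{'mean':>10}{'sd':>10}{'2.5%':>10}{'97.5%':>10}",
        ]
        for name in PARAM_NAMES:
            lines.append(
                f"  {name:<22}{self.params[name]:>10.4f}{self.sd[name]:>10.4f}"
                f"{ci.loc[name, 'lower']:>10.4f}{ci.loc[name, 'upper']:>10.4f}")
        return "\n".join(lines)

    def to_summary_dict(self) -> dict:
        ci = self.credible_interval()
        return {
            "group": self.model.group,
            "n_years": int(len(self.model.years)),
            "n_retained": int(self.n_retained),
            "r_squared": float(self.rsquared),
            "acceptance_rates": {k: float(v) for k, v in self.acceptance_rates.items()},
            "posterior_mean": {k: float(v) for k, v in self.params.items()},
            "posterior_sd": {k: float(v) for k, v in self.sd.items()},
            "ci95_lower": {k: float(ci.loc[k, "lower"]) for k in PARAM_NAMES},
            "ci95_upper": {k: float(ci.loc[k, "upper"]) for k in PARAM_NAMES},
        }

    def plot_posterior(self, params: Optional[Sequence[str]] = None, ax=None):
        """Histogram panel of the marginal posteriors (matplotlib)."""
        import matplotlib.pyplot as plt

        params = list(params or PARAM_NAMES)
        if ax is None:
            fig, axes = plt.subplots(1, len(params),
                                     figsize=(2.2 * len(params), 2.4))
        else:
            axes = np.atleast_1d(ax)
        for a, name in zip(np.ravel(axes), params):
            a.hist(self.draws[name], bins=50, density=True)
            a.set_title(name, fontsize=8)
        return np.ravel(axes)


# ---------------------------------------------------------------------------
# posterior comparison across groups


@dataclass
class OverlapResult:
    """Overlapping coefficient of two posterior samples."""

    parameter: str
    group_a: str
    group_b: str
    overlap: float
    significant: bool   # overlap < 0.10


def posterior_overlap(draws_a: np.ndarray, draws_b: np.ndarray,
                      n_bins: int = 100, parameter: str = "",
                      group_a: str = "a", group_b: str = "b",
                      threshold: float = 0.10) -> OverlapResult:
    """Overlapping coefficient (OVL) of two marginal posteriors.

    Both samples are binned on a shared grid spanning the pooled
    0.1–99.9 percentile range; OVL = Σ min(density_a, density_b)·width.
    Identical samples give 1, disjoint supports 0.  ``significant`` is
    True when the overlap is below ``threshold`` (strict).
    """
    a = np.asarray(draws_a, dtype=float).ravel()
    b = np.asarray(draws_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty draw set")
    pooled = np.concatenate([a, b])
    lo, hi = np.percentile(pooled, [0.1, 99.9])
    if lo == hi:                       # both samples (nearly) constant
        ovl = 1.0 if (np.median(a) == np.median(b)) else 0.0
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        width = edges[1] - edges[0]
        pa, _ = np.histogram(a, bins=edges)
        pb, _ = np.histogram(b, bins=edges)
        da = pa / (a.size * width)
        db = pb / (b.size * width)
        ovl = float(np.sum(np.minimum(da, db)) * width)
        ovl = min(ovl, 1.0)
    return OverlapResult(parameter=parameter, group_a=group_a, group_b=group_b,
                         overlap=ovl, significant=bool(ovl < threshold))


def overlap_matrix(results: dict[str, BaiLinearResults],
                   parameters: Sequence[str] = ALPHA_NAMES,
                   n_bins: int = 100, threshold: float = 0.10) -> pd.DataFrame:
    """All pairwise OVLs across fitted groups, as a tidy table."""
    groups = list(results)
    rows = []
    for p in parameters:
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                r = posterior_overlap(results[ga].draws[p].to_numpy(),
                                      results[gb].draws[p].to_numpy(),
                                      n_bins=n_bins, parameter=p,
                                      group_a=ga, group_b=gb,
                                      threshold=threshold)
                rows.append({"parameter": p, "group_a": ga, "group_b": gb,
                             "overlap": r.overlap, "significant": r.significant})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# convergence diagnostics


@dataclass
class ConvergenceReport:
    """Advisory MCMC diagnostics per parameter.

    ``split_half_z``: difference of first- and second-half means in
    posterior-sd units (flag when > 0.2 — chain still drifting).
    ``shrinkage``: posterior sd over prior range (small values mean the
    data, not the prior, constrain the parameter).
    ``unimodal``: histogram heuristic — a smoothed 30-bin histogram must
    show a single dominant mode.
    """

    split_half_z: pd.Series
    shrinkage: pd.Series
    unimodal: pd.Series
    stable: pd.Series

    @property
    def all_ok(self) -> bool:
        return bool(self.stable.all() and self.unimodal.all())

    @classmethod
    def from_draws(cls, draws: pd.DataFrame,
                   bounds: Optional[np.ndarray] = None,
                   stability_tol: float = 0.2) -> "ConvergenceReport":
        z, shrink, uni, stable = {}, {}, {}, {}
        for j, name in enumerate(draws.columns):
            x = draws[name].to_numpy()
            half = len(x) // 2
            sd = x.std(ddof=1)
            if half < 5 or sd == 0:
                z[name] = np.inf if sd else 0.0
            else:
                z[name] = abs(x[:half].mean() - x[half:].mean()) / sd
            stable[name] = z[name] <= stability_tol
            if bounds is not None and j < len(bounds):
                rng_w = bounds[j, 1] - bounds[j, 0]
                shrink[name] = sd / rng_w if rng_w > 0 else np.nan
            else:
                shrink[name] = np.nan
            uni[name] = _is_unimodal(x)
        return cls(split_half_z=pd.Series(z), shrinkage=pd.Series(shrink),
                   unimodal=pd.Series(uni), stable=pd.Series(stable))


def _is_unimodal(x: np.ndarray, n_bins: int = 30, rel_height: float = 0.2) -> bool:
    """True when a smoothed histogram has one dominant local maximum."""
    if np.ptp(x) == 0:
        return True
    counts, _ = np.histogram(x, bins=n_bins)
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    peaks = 0
    for i in range(len(smooth)):
        left = smooth[i - 1] if i > 0 else -1.0
        right = smooth[i + 1] if i < len(smooth) - 1 else -1.0
        if smooth[i] > left and smooth[i] >= right and smooth[i] > rel_height * smooth.max():
            peaks += 1
    return peaks <= 1
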