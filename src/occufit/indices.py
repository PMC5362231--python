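"""Occupancy indices, parametric-bootstrap uncertainty and weighted trends.

The annual index is the mean predicted occupancy over the index site set.
Uncertainty comes from drawing coefficient vectors from a multivariate
Normal at the MLE (parametric bootstrap, 1000 replicates by default) and
recomputing the index per draw; trends are weighted linear regressions of
the index on year with inverse bootstrap standard deviations as weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .model import FitResult, _occupancy_design_new

__all__ = [
    "OccupancyIndex",
    "TrendEstimate",
    "occupancy_index",
    "draw_coefficients",
    "parametric_bootstrap_indices",
    "index_confidence_interval",
    "weighted_trend",
    "regional_indices",
]

DEFAULT_B = 1000


@dataclass
class OccupancyIndex:
    """Annual (or regional) occupancy index with bootstrap replicates."""

    index: float
    n_sites: int
    replicates: np.ndarray
    ci_low: float
    ci_high: float
    year: int | None = None
    region: str | None = None

    def to_row(self) -> dict:
        return {
            "year": self.year,
            "region": self.region,
            "n_sites": self.n_sites,
            "index": self.index,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


@dataclass
class TrendEstimate:
    """Weighted-regression trend of an index series."""

    slope: float
    slope_ci: tuple[float, float]
    percent_change: float
    percent_change_ci: tuple[float, float]
    window: tuple[int, int]
    weights: np.ndarray

    def to_row(self) -> dict:
        return {
            "year_from": self.window[0],
            "year_to": self.window[1],
            "slope": self.slope,
            "slope_ci_low": self.slope_ci[0],
            "slope_ci_high": self.slope_ci[1],
            "percent_change": self.percent_change,
            "percent_change_ci_low": self.percent_change_ci[0],
            "percent_change_ci_high": self.percent_change_ci[1],
        }


def occupancy_index(psi_hat) -> float:
    """Mean occupancy over the index site set."""
    psi_hat = np.asarray(psi_hat, dtype=float)
    if psi_hat.size == 0:
        raise ValueError("empty occupancy vector")
    return float(psi_hat.mean())


def draw_coefficients(fit: FitResult, B: int, seed=None) -> np.ndarray:
    """B draws of the full coefficient vector from MVN(theta_hat, vcov)."""
    rng = np.random.default_rng(seed)
    vcov = 0.5 * (fit.vcov + fit.vcov.T)
    if fit.vcov_degenerate:
        warnings.warn(
            "bootstrap uses a degenerate covariance matrix", stacklevel=2
        )
    return rng.multivariate_normal(fit.theta, vcov, size=B, method="svd")


def _replicate_psi(fit: FitResult, W_index, thetas: np.ndarray) -> np.ndarray:
    """(S, B) matrix of replicate occupancy probabilities."""
    X = _occupancy_design_new(fit, W_index)
    betas = thetas[:, : fit.beta.size]
    return expit(X @ betas.T)


def parametric_bootstrap_indices(
    fit: FitResult, W_index_sites, B: int = DEFAULT_B, seed=None
) -> np.ndarray:
    """Bootstrap replicate indices over the given index site set."""
    thetas = draw_coefficients(fit, B, seed=seed)
    return _replicate_psi(fit, W_index_sites, thetas).mean(axis=0)


def index_confidence_interval(replicates, level: float = 0.95) -> tuple[float, float]:
    """Empirical equal-tailed interval from bootstrap replicates (type-7 quantiles)."""
    replicates = np.asarray(replicates, dtype=float)
    if replicates.size < 2:
        raise ValueError("need at least 2 replicates")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(replicates, [tail, 1.0 - tail])
    return float(lo), float(hi)


def annual_index(
    fit: FitResult, W_index_sites, B: int = DEFAULT_B, seed=None, year=None
) -> OccupancyIndex:
    """Point index plus parametric bootstrap for one year's fit."""
    psi = expit(_occupancy_design_new(fit, W_index_sites) @ fit.beta)
    reps = parametric_bootstrap_indices(fit, W_index_sites, B=B, seed=seed)
    lo, hi = index_confidence_interval(reps)
    return OccupancyIndex(
        index=occupancy_index(psi),
        n_sites=psi.size,
        replicates=reps,
        ci_low=lo,
        ci_high=hi,
        year=year,
    )


def _wls_slope_matrix(years_centred: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """(2, n) matrix A with beta = A @ y for WLS on [1, centred year]."""
    X = np.column_stack([np.ones_like(years_centred), years_centred])
    Xw = X * weights[:, None]
    return np.linalg.solve(X.T @ Xw, Xw.T)


def weighted_trend(
    years,
    index_series,
    replicate_matrix,
    window: tuple[int, int] | None = None,
) -> TrendEstimate:
    """Weighted linear trend of the index with bootstrap-quantile intervals.

    Weights are the inverse standard deviations of each year's bootstrap
    replicates (a zero SD is capped at the largest finite weight, with a
    warning).  The percent change over the window is computed from the
    fitted regression values at the window endpoints.  Confidence
    intervals are the 2.5/97.5% quantiles of slopes and percent changes
    refit to every bootstrap replicate series.
    """
    years = np.asarray(years)
    index_series = np.asarray(index_series, dtype=float)
    replicate_matrix = np.asarray(replicate_matrix, dtype=float)
    if replicate_matrix.shape[1] != years.size:
        raise ValueError("replicate matrix must be (B, n_years)")
    if window is None:
        window = (int(years.min()), int(years.max()))
    in_window = (years >= window[0]) & (years <= window[1])
    if in_window.sum() < 2:
        raise ValueError("need at least 2 years in the trend window")
    yr = years[in_window]
    idx = index_series[in_window]
    reps = replicate_matrix[:, in_window]

    sd = reps.std(axis=0, ddof=1)
    # SDs at floating-noise level count as zero (degenerate bootstrap)
    tol = np.nanmax(np.where(np.isfinite(sd), sd, 0.0)) * 1e-8
    usable = np.isfinite(sd) & (sd > tol)
    if not usable.any():
        weights = np.ones_like(sd)
    else:
        weights = np.empty_like(sd)
        weights[usable] = 1.0 / sd[usable]
        if (~usable).any():
            warnings.warn(
                "zero/non-finite bootstrap SD: weight capped at the largest "
                "finite weight",
                stacklevel=2,
            )
            weights[~usable] = weights[usable].max()

    yr_c = yr.astype(float) - yr.mean()  # centred for conditioning
    X = np.column_stack([np.ones_like(yr_c), yr_c])
    wls = sm.WLS(idx, X, weights=weights).fit()
    intercept, slope = wls.params

    def pct_change(b0, b1):
        start = b0 + b1 * (window[0] - yr.mean())
        end = b0 + b1 * (window[1] - yr.mean())
        return (end - start) / start * 100.0

    A = _wls_slope_matrix(yr_c, weights)
    rep_coefs = reps @ A.T  # (B, 2)
    rep_slopes = rep_coefs[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        rep_pct = pct_change(rep_coefs[:, 0], rep_coefs[:, 1])

    slope_ci = tuple(np.quantile(rep_slopes, [0.025, 0.975]))
    pct_ci = tuple(np.quantile(rep_pct[np.isfinite(rep_pct)], [0.025, 0.975]))
    return TrendEstimate(
        slope=float(slope),
        slope_ci=(float(slope_ci[0]), float(slope_ci[1])),
        percent_change=float(pct_change(intercept, slope)),
        percent_change_ci=(float(pct_ci[0]), float(pct_ci[1])),
        window=window,
        weights=weights,
    )


def regional_indices(
    fit: FitResult,
    site_table: pd.DataFrame,
    B: int = DEFAULT_B,
    seed=None,
    year=None,
) -> list[OccupancyIndex]:
    """Per-region indices from a single national fit (no refitting).

    ``site_table`` needs a ``region`` column plus the fit's (standardised)
    occupancy covariate columns, one row per site.  All regions share one
    set of coefficient draws, so the national index equals the site-count-
    weighted mean of regional indices exactly.
    """
    if "region" not in site_table.columns:
        raise ValueError("site_table must have a 'region' column")
    if site_table["region"].isna().any():
        raise ValueError("every site needs exactly one region label")
    psi = expit(_occupancy_design_new(fit, site_table) @ fit.beta)
    thetas = draw_coefficients(fit, B, seed=seed)
    psi_reps = _replicate_psi(fit, site_table, thetas)  # (S, B)

    out = []
    regions = site_table["region"].to_numpy()
    for region in pd.unique(regions):
        sel = regions == region
        reps = psi_reps[sel].mean(axis=0)
        lo, hi = index_confidence_interval(reps)
        out.append(
            OccupancyIndex(
                index=float(psi[sel].mean()),
                n_sites=int(sel.sum()),
                replicates=reps,
                ci_low=lo,
                ci_high=hi,
                year=year,
                region=str(region),
            )
        )
    return out
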