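"""Mean-squared-displacement estimation, diffusivity fits and anomalous-
diffusion diagnostics.

The empirical MSD at each recorded time is the ensemble mean of per-walk
squared displacements.  Normal diffusion in 3-D has MSD = 6 D t, so the
effective diffusivity is the through-origin slope of MSD versus t divided
by 6.  The 95% confidence interval comes from per-walk slope statistics:
each walk contributes its own through-origin slope and the interval is
mean +/- 1.96 SD/sqrt(N) (a bootstrap variant is available).

``loglog_diagnostic`` fits a continuous piecewise-linear model to
ln(MSD/t) versus ln t: segment slopes are the anomalous exponents minus
one, and the two expected plateaus for obstructed normal diffusion are
ln(6 D0) and ln(6 De).  Logarithms are natural throughout.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .montecarlo import EnsembleRecord

__all__ = [
    "MSDCurve",
    "DiffusivityEstimate",
    "AnomalousFit",
    "estimate_msd",
    "fit_de",
    "confidence_interval",
    "loglog_diagnostic",
]


@dataclass
class MSDCurve:
    times: np.ndarray
    msd: np.ndarray
    stderr: np.ndarray
    n_walks: int

    def __post_init__(self):
        if not (len(self.times) == len(self.msd) == len(self.stderr)):
            raise ValueError("times, msd and stderr must have equal length")


@dataclass
class DiffusivityEstimate:
    slope: float
    de: float  # slope / 6
    ci95: tuple  # (lo, hi) for de
    fit_range: tuple

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= self.de <= hi):
            raise ValueError("confidence interval must contain the estimate")

    @property
    def ci_halfwidth(self) -> float:
        return (self.ci95[1] - self.ci95[0]) / 2.0

    @property
    def relative_ci_width(self) -> float:
        """Full CI width as a fraction of the estimate."""
        return (self.ci95[1] - self.ci95[0]) / self.de


@dataclass
class AnomalousFit:
    """Continuous piecewise power-law description MSD = C_i t^alpha_i."""

    breakpoints: np.ndarray  # segment edge times, length n_segments + 1
    exponents: np.ndarray  # alpha_i per segment
    amplitudes: np.ndarray  # C_i per segment
    sse: float


def estimate_msd(ensemble: EnsembleRecord) -> MSDCurve:
    """Ensemble-mean squared displacement with its standard error."""
    sq = ensemble.sq_disp
    n = sq.shape[0]
    if n < 2:
        raise ValueError("need at least 2 walks")
    msd = sq.mean(axis=0)
    stderr = sq.std(axis=0, ddof=1) / np.sqrt(n)
    return MSDCurve(times=np.asarray(ensemble.times), msd=msd, stderr=stderr, n_walks=n)


def _range_mask(times, fit_range):
    if fit_range is None:
        return np.ones(len(times), dtype=bool)
    lo, hi = fit_range
    return (times >= lo) & (times <= hi)


def _through_origin_slope(t, y):
    denom = float(np.dot(t, t))
    if denom == 0:
        raise ValueError("degenerate fit: all times zero")
    return float(np.dot(t, y)) / denom


def fit_de(curve: MSDCurve, fit_range=None) -> DiffusivityEstimate:
    """Least-squares MSD-vs-t slope constrained through the origin; De = slope/6.

    The interval is propagated from the curve's standard errors; prefer
    :func:`confidence_interval` (per-walk slopes) when the ensemble is
    available.
    """
    mask = _range_mask(curve.times, fit_range)
    t = curve.times[mask]
    y = curve.msd[mask]
    if len(t) < 3:
        raise ValueError("need at least 3 points in the fit range")
    if np.all(y == 0):
        raise ValueError("degenerate all-zero MSD curve")
    slope = _through_origin_slope(t, y)
    denom = float(np.dot(t, t))
    var = float(np.dot(t**2, curve.stderr[mask] ** 2)) / denom**2
    half = 1.96 * np.sqrt(var) / 6.0
    de = slope / 6.0
    rng = (float(t.min()), float(t.max()))
    return DiffusivityEstimate(slope=slope, de=de, ci95=(de - half, de + half), fit_range=rng)


def confidence_interval(
    ensemble: EnsembleRecord, fit_range=None, method: str = "perwalk", n_boot: int = 500
) -> DiffusivityEstimate:
    """De with a 95% CI from per-walk through-origin slopes.

    Each walk yields an individual slope estimate s_i; the ensemble slope is
    their mean and the interval is mean +/- 1.96 SD/sqrt(N).  With
    ``method="bootstrap"`` the interval is the 2.5-97.5 percentile range of
    walk-resampled ensemble slopes.
    """
    times = np.asarray(ensemble.times)
    mask = _range_mask(times, fit_range)
    t = times[mask]
    denom = float(np.dot(t, t))
    if denom == 0:
        raise ValueError("fit range contains no positive times")
    slopes = ensemble.sq_disp[:, mask] @ t / denom
    n = len(slopes)
    slope = float(slopes.mean())
    de = slope / 6.0
    if n < 30:
        warnings.warn("N < 30: normal approximation is poor; widening by t-factor")
    if method == "perwalk":
        half = 1.96 * float(slopes.std(ddof=1)) / np.sqrt(n) / 6.0
        if n < 30:
            from scipy import stats

            half *= stats.t.ppf(0.975, n - 1) / 1.96
    elif method == "bootstrap":
        rng = np.random.default_rng(ensemble.config.seed + 1)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot = slopes[idx].mean(axis=1) / 6.0
        lo, hi = np.percentile(boot, [2.5, 97.5])
        return DiffusivityEstimate(
            slope=slope, de=de, ci95=(min(lo, de), max(hi, de)),
            fit_range=(float(t.min()), float(t.max())),
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return DiffusivityEstimate(
        slope=slope, de=de, ci95=(de - half, de + half),
        fit_range=(float(t.min()), float(t.max())),
    )


# ---------------------------------------------------------------------------
# anomalous-diffusion diagnostics


def _piecewise_design(x, knots):
    cols = [np.ones_like(x), x]
    for kn in knots:
        cols.append(np.clip(x - kn, 0.0, None))
    return np.column_stack(cols)


def loglog_diagnostic(curve: MSDCurve, n_segments: int = 1, n_candidates: int = 15) -> AnomalousFit:
    """Continuous piecewise-linear fit of ln(MSD/t) against ln t.

    Interior breakpoints are chosen by grid search over candidate knots
    (quantiles of ln t) minimizing the SSE of the continuous fit.  Segment
    slopes are alpha_i - 1 and intercepts ln C_i.
    """
    pos = curve.times > 0
    t = curve.times[pos]
    m = curve.msd[pos]
    if np.any(m <= 0):
        raise ValueError("msd must be strictly positive for t > 0")
    x = np.log(t)
    y = np.log(m / t)
    if len(x) < 2 * n_segments:
        raise ValueError("fewer points than 2 x segments")
    if n_segments < 1:
        raise ValueError("need at least one segment")

    def solve(knots):
        X = _piecewise_design(x, knots)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((X @ beta - y) ** 2))
        return beta, sse

    if n_segments == 1:
        best_knots, (best_beta, best_sse) = (), solve(())
    else:
        qs = np.linspace(0.05, 0.95, n_candidates)
        cand = np.unique(np.quantile(x, qs))
        best_sse = np.inf
        best_knots = best_beta = None
        for knots in itertools.combinations(cand, n_segments - 1):
            beta, sse = solve(knots)
            if sse < best_sse:
                best_sse, best_knots, best_beta = sse, knots, beta
    # segment slopes/intercepts from the hinge coefficients
    slopes = np.cumsum(np.concatenate([[best_beta[1]], best_beta[2:]]))
    edges = np.concatenate([[x.min()], list(best_knots), [x.max()]])
    intercepts = [best_beta[0]]
    for i, kn in enumerate(best_knots):
        # continuity: intercept_{i+1} = intercept_i + (s_i - s_{i+1}) * knot
        intercepts.append(intercepts[-1] + (slopes[i] - slopes[i + 1]) * kn)
    return AnomalousFit(
        breakpoints=np.exp(edges),
        exponents=slopes + 1.0,
        amplitudes=np.exp(np.asarray(intercepts)),
        sse=best_sse,
    )
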