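"""Closed-form comparator models for obstructed diffusion.

Four model curves for De/D0 as a function of the obstruction parameter rho:

* ``exp_formula`` — the single-parameter law De/D0 = exp(-k rho^3) fitted to
  the homogenization curve (``fit_k``);
* ``maxwell`` — Maxwell's effective-medium formula for a dilute array of
  spherical inclusions of interior/exterior diffusivity ratio delta;
* ``scaled_maxwell`` — Maxwell's formula divided by the accessible volume
  fraction (1 - phi), the convention matching a tracer that is excluded
  from the obstructions;
* ``naive_average`` — the straightforward volume average 1 - phi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .geometry import SQRT2, obstructed_fraction

__all__ = [
    "ModelCurve",
    "ExpFit",
    "exp_formula",
    "fit_k",
    "maxwell",
    "scaled_maxwell",
    "naive_average",
]


@dataclass
class ModelCurve:
    """An ordered (rho, De/D0) relationship from one model."""

    rho_values: np.ndarray
    de_over_d0: np.ndarray
    source: str = "homogenization"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rho_values = np.asarray(self.rho_values, dtype=float)
        self.de_over_d0 = np.asarray(self.de_over_d0, dtype=float)
        if self.rho_values.shape != self.de_over_d0.shape:
            raise ValueError("rho and De/D0 arrays must have equal length")
        if np.any(np.diff(self.rho_values) < 0):
            raise ValueError("rho values must be ascending")


@dataclass(frozen=True)
class ExpFit:
    """Fitted exponent of De/D0 = exp(-k rho^3) and its fit-domain error."""

    k: float
    rho_max: float
    max_abs_error: float


def exp_formula(rho, k: float):
    """De/D0 = exp(-k rho^3)."""
    if k <= 0:
        raise ValueError("k must be positive")
    rho = np.asarray(rho, dtype=float)
    out = np.exp(-k * rho**3)
    return float(out) if out.ndim == 0 else out


def fit_k(curve: ModelCurve, rho_max: float = 0.92, criterion: str = "lsq") -> ExpFit:
    """Fit the exponent k to a De/D0 curve over rho <= rho_max.

    ``criterion`` is ``"lsq"`` (unweighted least squares on De/D0, the
    default) or ``"minimax"`` (minimize the maximum absolute deviation).
    Reports the maximum absolute error of the fitted law on the domain.
    """
    mask = curve.rho_values <= rho_max + 1e-12
    rho = curve.rho_values[mask]
    de = curve.de_over_d0[mask]
    if len(rho) < 5:
        raise ValueError("need at least 5 curve points with rho <= rho_max")

    def maxerr(k):
        return float(np.max(np.abs(np.exp(-k * rho**3) - de)))

    if criterion == "lsq":
        res = least_squares(lambda p: np.exp(-p[0] * rho**3) - de, x0=[0.25])
        k = float(res.x[0])
    elif criterion == "minimax":
        k = float(minimize_scalar(maxerr, bounds=(1e-6, 5.0), method="bounded").x)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return ExpFit(k=k, rho_max=rho_max, max_abs_error=maxerr(k))


def maxwell(rho, delta: float = 0.0):
    """Maxwell's effective-medium formula.

    De/D0 = (1 - L rho^3/12) / (1 + L rho^3/24) with
    L = 4 pi (1 - delta) / (2 + delta); delta is the diffusivity inside the
    inclusion relative to outside (0 for impenetrable obstacles, giving
    L = 2 pi).  Breaks down (goes non-positive) at large rho.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho must be non-negative")
    L_maxwell = 4.0 * np.pi * (1.0 - delta) / (2.0 + delta)
    out = (1.0 - L_maxwell * rho**3 / 12.0) / (1.0 + L_maxwell * rho**3 / 24.0)
    if np.any(out <= 0):
        import warnings

        warnings.warn("Maxwell formula non-positive: outside its domain of validity")
    return float(out) if out.ndim == 0 else out


def scaled_maxwell(rho):
    """Maxwell's impenetrable-sphere formula rescaled by 1/(1 - phi).

    The bare formula describes the whole-volume (De (1 - phi)) convention;
    dividing by the accessible volume fraction converts it to the
    fluid-average convention of the unit-cell solver.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho >= SQRT2):
        raise ValueError("rho must be < sqrt(2)")
    out = maxwell(rho, 0.0) / (1.0 - obstructed_fraction(rho))
    return float(out) if np.ndim(out) == 0 else out


def naive_average(rho):
    """The straightforward average: the accessible volume fraction 1 - phi."""
    out = 1.0 - np.asarray(obstructed_fraction(rho))
    return float(out) if np.ndim(out) == 0 else out
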