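"""Fluorescence correlation spectroscopy: model, fitting and synthesis.

The normalized autocorrelation of fluorescence fluctuations for a single
monodisperse species in 3-D normal diffusion through a Gaussian confocal
volume is

    G(tau) = 1 + (1/N) (1 + tau/tau_d)^-1 (1 + p tau/tau_d)^-1/2,

with N the mean occupancy of the detection volume, tau_d the diffusion
time and p = (r0/z0)^2 the instrumental structure constant.  tau_d maps to
a diffusivity through D = r0^2 / (4 tau_d), and the normalized effective
diffusivity of a crowded sample is De/D0 = tau_0/tau_d against the free
diffusion time tau_0.

Only (N, tau_d) are fitted; p is a calibration constant held fixed, as in
standard single-component FCS practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FCSCurve",
    "InstrumentSpec",
    "FCSFit",
    "FitError",
    "autocorrelation_model",
    "fit_autocorrelation",
    "diffusion_time_to_diffusivity",
    "diffusivity_to_diffusion_time",
    "normalized_diffusivity",
    "r_squared",
    "synthesize_curve",
    "read_curve",
    "write_curve",
]

#: default structure constant (r0/z0)^2 for a typical confocal geometry with
#: an axial-to-radial ratio of ~5; supply the calibrated value when known.
DEFAULT_P = 0.04


class FitError(RuntimeError):
    pass


@dataclass
class FCSCurve:
    delays: np.ndarray  # s
    g_values: np.ndarray

    def __post_init__(self):
        self.delays = np.asarray(self.delays, dtype=float)
        self.g_values = np.asarray(self.g_values, dtype=float)
        if self.delays.shape != self.g_values.shape:
            raise ValueError("delays and G values must have equal length")
        if np.any(self.delays <= 0) or np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be positive and strictly increasing")
        if not np.all(np.isfinite(self.g_values)):
            raise ValueError("G values must be finite")


@dataclass(frozen=True)
class InstrumentSpec:
    """Confocal geometry: radial waist r0 (nm) and structure constant p."""

    r0: float = 208.0  # nm
    z0: float | None = None  # nm
    p: float | None = None

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")

    @property
    def p_value(self) -> float:
        if self.p is not None:
            return self.p
        if self.z0 is not None:
            return (self.r0 / self.z0) ** 2
        return DEFAULT_P


@dataclass
class FCSFit:
    n_particles: float
    tau_d: float  # s
    p: float
    residual_ss: float
    r_squared: float

    def __post_init__(self):
        if self.n_particles <= 0 or self.tau_d <= 0:
            raise ValueError("fitted N and tau_d must be positive")


def autocorrelation_model(tau, n: float, tau_d: float, p: float):
    """G(tau) for single-component 3-D diffusion (see module docstring)."""
    if n <= 0 or tau_d <= 0 or p < 0:
        raise ValueError("parameters must be positive (p non-negative)")
    tau = np.asarray(tau, dtype=float)
    g = 1.0 + (1.0 / n) / (1.0 + tau / tau_d) / np.sqrt(1.0 + p * tau / tau_d)
    return float(g) if g.ndim == 0 else g


def fit_autocorrelation(curve: FCSCurve, instrument: InstrumentSpec = InstrumentSpec()) -> FCSFit:
    """Nonlinear least squares for (N, tau_d) with fixed p.

    Initial guesses: N from the zero-lag amplitude ``1/(G(tau_min) - 1)``
    and tau_d from the delay at half-decay.
    """
    if len(curve.delays) < 10:
        raise FitError("need at least 10 points spanning the decay")
    p = instrument.p_value
    g0 = curve.g_values[0] - 1.0
    n0 = 1.0 / g0 if g0 > 0 else 1.0
    half = 1.0 + 0.5 * g0
    below = np.nonzero(curve.g_values <= half)[0]
    tau0 = curve.delays[below[0]] if len(below) else np.median(curve.delays)

    def model(tau, n, tau_d):
        return 1.0 + (1.0 / n) / (1.0 + tau / tau_d) / np.sqrt(1.0 + p * tau / tau_d)

    try:
        popt, _ = curve_fit(
            model,
            curve.delays,
            curve.g_values,
            p0=[max(n0, 1e-6), max(tau0, curve.delays[0])],
            bounds=([1e-12, 1e-300], [np.inf, np.inf]),
            maxfev=20_000,
        )
    except RuntimeError as exc:  # pragma: no cover - solver pathologies
        raise FitError(
            f"autocorrelation fit failed (initial guesses N={n0:.3g}, "
            f"tau_d={tau0:.3g}): {exc}"
        ) from exc
    pred = model(curve.delays, *popt)
    ss_res = float(np.sum((curve.g_values - pred) ** 2))
    try:
        r2 = r_squared(curve.g_values, pred)
    except ValueError:
        r2 = float("nan")
    return FCSFit(
        n_particles=float(popt[0]), tau_d=float(popt[1]), p=p,
        residual_ss=ss_res, r_squared=r2,
    )


def diffusion_time_to_diffusivity(tau_d: float, r0: float = 208.0) -> float:
    """D = r0^2 / (4 tau_d); r0 in nm, tau_d in s, D in m^2/s."""
    if tau_d <= 0 or r0 <= 0:
        raise ValueError("tau_d and r0 must be positive")
    return (r0 * 1.0e-9) ** 2 / (4.0 * tau_d)


def diffusivity_to_diffusion_time(d: float, r0: float = 208.0) -> float:
    """Inverse of :func:`diffusion_time_to_diffusivity` (D in m^2/s)."""
    if d <= 0 or r0 <= 0:
        raise ValueError("D and r0 must be positive")
    return (r0 * 1.0e-9) ** 2 / (4.0 * d)


def normalized_diffusivity(tau_0: float, tau_d: float) -> float:
    """Experimental De/D0 = tau_0 / tau_d."""
    if tau_0 <= 0 or tau_d <= 0:
        raise ValueError("diffusion times must be positive")
    out = tau_0 / tau_d
    if out > 1:
        warnings.warn("tau_0/tau_d > 1: faster than free diffusion, check inputs")
    return out


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (may be negative)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need equal-length arrays of >= 2 values")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: observed values are constant")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def synthesize_curve(
    n: float,
    tau_d: float,
    p: float = DEFAULT_P,
    delays=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FCSCurve:
    """Model curve on a delay grid plus zero-mean Gaussian noise.

    Default grid: 128 log-spaced delays from tau_d/100 to 1000 tau_d,
    emulating a correlator's quasi-logarithmic lag spacing.
    """
    if delays is None:
        delays = np.logspace(np.log10(tau_d / 100.0), np.log10(tau_d * 1000.0), 128)
    delays = np.asarray(delays, dtype=float)
    g = autocorrelation_model(delays, n, tau_d, p)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        g = g + rng.normal(0.0, noise_sd, size=delays.shape)
    return FCSCurve(delays=delays, g_values=np.asarray(g))


def read_curve(path) -> FCSCurve:
    """Read a two-column CSV (delay_s, G)."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    if "delay_s" in cols and "g" in cols:
        d = df[df.columns[cols.index("delay_s")]].to_numpy()
        g = df[df.columns[cols.index("g")]].to_numpy()
    else:
        d, g = df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy()
    return FCSCurve(delays=d, g_values=g)


def write_curve(curve: FCSCurve, path) -> None:
    pd.DataFrame({"delay_s": curve.delays, "G": curve.g_values}).to_csv(path, index=False)
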