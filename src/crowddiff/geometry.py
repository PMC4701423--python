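"""Dimensionless geometry of a periodically crowded solution.

A solute of hydrodynamic radius ``a`` diffusing among polymer coils of
hydrodynamic radius ``R`` at mass concentration ``c`` is reduced, under a
simple-cubic placement assumption, to a single dimensionless obstruction
parameter

    rho = 2 (R + a) / L,

where ``L = (M_W / (c N_A))^(1/3)`` is the center-to-center spacing of the
polymer molecules.  The center of the solute is excluded from spheres of
radius ``(R + a)`` around each lattice point, so the obstructed volume
fraction per unit cell is ``phi = pi rho^3 / 6`` for ``rho <= 1`` and, for
``1 < rho < sqrt(2)``, the volume of the union of the overlapping periodic
spheres (pairwise spherical-cap correction).  Above ``rho = sqrt(2)`` the
void space disconnects and no diffusive transport is possible.

All lengths are handled in nanometres, concentrations are normalized to
g/cm^3, and molecular weights to g/mol.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "AVOGADRO",
    "SQRT2",
    "PolymerSpec",
    "SoluteSpec",
    "SystemGeometry",
    "InvalidParameterError",
    "MissingParameterError",
    "DisconnectedVoidError",
    "parse_concentration",
    "center_spacing",
    "rho",
    "obstructed_fraction",
    "overlap_concentration",
    "geometric_overlap_concentration",
    "system_geometry",
    "load_library",
]

#: Avogadro constant as printed in the source tables (particles/mol).
AVOGADRO = 6.022e23

SQRT2 = math.sqrt(2.0)

#: nm per cm.
_NM_PER_CM = 1.0e7


class InvalidParameterError(ValueError):
    """A physical parameter is out of its valid range."""


class MissingParameterError(ValueError):
    """A required optional parameter (e.g. gyration radius) is absent."""


class DisconnectedVoidError(ValueError):
    """rho >= sqrt(2): the void space between obstructions is disconnected."""


@dataclass(frozen=True)
class PolymerSpec:
    """A polymer species: molecular weight and hydrodynamic (and optionally
    gyration) radius."""

    name: str
    molecular_weight: float  # g/mol
    hydrodynamic_radius: float  # nm
    gyration_radius: float | None = None  # nm

    def __post_init__(self):
        if self.molecular_weight <= 0:
            raise InvalidParameterError("molecular_weight must be positive")
        if self.hydrodynamic_radius <= 0:
            raise InvalidParameterError("hydrodynamic_radius must be positive")
        if self.gyration_radius is not None and self.gyration_radius <= 0:
            raise InvalidParameterError("gyration_radius must be positive")


@dataclass(frozen=True)
class SoluteSpec:
    """A solute species (tracer), with hydrodynamic radius ``a``."""

    name: str
    molecular_weight: float  # g/mol
    hydrodynamic_radius: float  # nm

    def __post_init__(self):
        if self.hydrodynamic_radius <= 0:
            raise InvalidParameterError("hydrodynamic_radius must be positive")


@dataclass(frozen=True)
class SystemGeometry:
    """Derived dimensionless geometry of one polymer-solute-concentration
    system."""

    spacing: float  # L, nm
    rho: float
    obstructed_fraction: float
    concentration: float  # g/cm^3
    free_diffusivity: float = 1.0  # D0, arbitrary area/time units

    def __post_init__(self):
        if self.spacing <= 0:
            raise InvalidParameterError("spacing must be positive")
        if not (0 <= self.rho < SQRT2):
            raise DisconnectedVoidError(
                f"rho={self.rho:.4f} outside [0, sqrt(2)): void disconnected"
            )


# ---------------------------------------------------------------------------
# unit handling

_CONC_UNITS = {
    "g/cm3": 1.0,
    "g/cm^3": 1.0,
    "g/ml": 1.0,
    "mg/ml": 1.0e-3,
    "%": 1.0e-2,  # % w/v == g per 100 ml
    "% w/v": 1.0e-2,
    "%w/v": 1.0e-2,
}


def parse_concentration(value, unit: str = "g/cm3") -> float:
    """Normalize a concentration to g/cm^3.

    ``value`` may be a number (interpreted in ``unit``) or a string with a
    trailing unit, e.g. ``"5mg/ml"`` or ``"2.5% w/v"``.
    """
    if isinstance(value, str):
        m = re.fullmatch(r"\s*([0-9.eE+-]+)\s*(.*?)\s*", value)
        if not m:
            raise InvalidParameterError(f"cannot parse concentration {value!r}")
        value, unit = float(m.group(1)), (m.group(2) or unit)
    unit = unit.strip().lower()
    if unit not in _CONC_UNITS:
        raise InvalidParameterError(f"unknown concentration unit {unit!r}")
    c = float(value) * _CONC_UNITS[unit]
    if c <= 0:
        raise InvalidParameterError("concentration must be positive")
    return c


# ---------------------------------------------------------------------------
# core relations


def center_spacing(polymer: PolymerSpec, concentration, unit: str = "g/cm3") -> float:
    """Center-to-center spacing L (nm) of polymers in simple-cubic arrangement.

    L = (M_W / (c N_A))^(1/3) with c in g/cm^3; the cube root is in cm and is
    returned in nm.
    """
    c = parse_concentration(concentration, unit)
    mw = polymer.molecular_weight
    if mw <= 0:
        raise InvalidParameterError("molecular weight must be positive")
    return (mw / (c * AVOGADRO)) ** (1.0 / 3.0) * _NM_PER_CM


def rho(R: float, a: float, L: float) -> float:
    """Dimensionless obstruction parameter rho = 2 (R + a) / L."""
    if L <= 0:
        raise InvalidParameterError("L must be positive")
    if R < 0 or a < 0:
        raise InvalidParameterError("radii must be non-negative")
    return 2.0 * (R + a) / L


def obstructed_fraction(rho_value):
    """Obstructed volume fraction phi(rho) of the unit cell.

    For rho <= 1 the exclusion spheres do not overlap and phi = pi rho^3 / 6.
    For 1 < rho < sqrt(2) each sphere overlaps its six axis neighbours and
    the per-cell union volume subtracts the six lens caps (pairwise
    inclusion-exclusion, exact below rho = sqrt(2) where no triple overlaps
    occur):

        phi = (4/3) pi r^3 - 6 * pi h^2 (3 r - h) / 3,   r = rho/2, h = r - 1/2.

    Accepts scalars or arrays.
    """
    r_arr = np.asarray(rho_value, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr >= SQRT2):
        raise DisconnectedVoidError("rho must lie in [0, sqrt(2))")
    r = r_arr / 2.0
    simple = np.pi * r_arr**3 / 6.0
    h = np.clip(r - 0.5, 0.0, None)
    cap = np.pi * h**2 * (3.0 * r - h) / 3.0
    phi = np.where(r_arr <= 1.0, simple, 4.0 / 3.0 * np.pi * r**3 - 6.0 * cap)
    return float(phi) if np.isscalar(rho_value) or phi.ndim == 0 else phi


def overlap_concentration(polymer: PolymerSpec) -> float:
    """Coil overlap concentration c* = M_W / ((4/3) pi R_g^3 N_A), in % w/v."""
    if polymer.gyration_radius is None:
        raise MissingParameterError(f"{polymer.name}: gyration radius required for c*")
    rg_cm = polymer.gyration_radius / _NM_PER_CM
    c_gcm3 = polymer.molecular_weight / (4.0 / 3.0 * math.pi * rg_cm**3 * AVOGADRO)
    return c_gcm3 * 100.0  # g/cm^3 -> % w/v


def geometric_overlap_concentration(polymer: PolymerSpec) -> float:
    """Geometric overlap concentration c_theta = M_W / (8 R_h^3 N_A), in % w/v.

    At c_theta the equivalent hard spheres of radius R_h touch on the cubic
    lattice (rho = 1 for a point solute).
    """
    rh_cm = polymer.hydrodynamic_radius / _NM_PER_CM
    c_gcm3 = polymer.molecular_weight / (8.0 * rh_cm**3 * AVOGADRO)
    return c_gcm3 * 100.0


def system_geometry(
    polymer: PolymerSpec,
    solute: SoluteSpec,
    concentration,
    unit: str = "g/cm3",
    free_diffusivity: float = 1.0,
) -> SystemGeometry:
    """Assemble the full dimensionless geometry for one concentration."""
    c = parse_concentration(concentration, unit)
    L = center_spacing(polymer, c)
    r = rho(polymer.hydrodynamic_radius, solute.hydrodynamic_radius, L)
    if r >= SQRT2:
        raise DisconnectedVoidError(
            f"rho={r:.4f} >= sqrt(2) at c={c:g} g/cm^3: void disconnected"
        )
    return SystemGeometry(
        spacing=L,
        rho=r,
        obstructed_fraction=obstructed_fraction(r),
        concentration=c,
        free_diffusivity=free_diffusivity,
    )


# ---------------------------------------------------------------------------
# species library


def load_library() -> dict:
    """Load the bundled polymer/solute library.

    Returns a dict with keys ``polymers`` and ``solutes`` mapping lower-case
    names to :class:`PolymerSpec` / :class:`SoluteSpec`.
    """
    with resources.files("crowddiff.data").joinpath("species.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    polymers = {
        key: PolymerSpec(
            name=entry.get("name", key),
            molecular_weight=float(entry["molecular_weight_kda"]) * 1000.0,
            hydrodynamic_radius=float(entry["hydrodynamic_radius_nm"]),
            gyration_radius=entry.get("gyration_radius_nm"),
        )
        for key, entry in raw["polymers"].items()
    }
    solutes = {
        key: SoluteSpec(
            name=entry.get("name", key),
            molecular_weight=float(entry["molecular_weight_kda"]) * 1000.0,
            hydrodynamic_radius=float(entry["hydrodynamic_radius_nm"]),
        )
        for key, entry in raw["solutes"].items()
    }
    return {"polymers": polymers, "solutes": solutes}
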