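"""Obstructed random-walk simulators.

Two microscopic models of a point tracer (the solute center) moving among
impenetrable spheres of radius ``rho L / 2`` centered on a simple-cubic
lattice of spacing ``L``:

* ``wiener`` — Euler discretization of the reflected Wiener process:
  Gaussian increments of variance ``2 D0 dt`` per axis, with specular
  reflection wherever the straight sub-step crosses an obstacle surface
  (the crossing point is found by exact ray-sphere intersection and the
  residual path length is reflected, iterated up to a cap);
* ``kinetic`` — a velocity-jump walk with i.i.d. exponential step lengths
  (mean ``lambda``), exponential durations (mean ``tau``) and isotropic
  directions, moving rectilinearly with specular reflections and consuming
  each step's duration uniformly along its (possibly reflected) path.

Ensembles record per-walk squared displacements at equidistant times and
are exactly reproducible from a seed (per-walk substreams).  Geometry
queries are O(1): the nearest obstruction center is the nearest lattice
point, and ray tracing scans the 27 surrounding lattice images, which is
exhaustive for rho < sqrt(2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from numba import njit

from .geometry import SQRT2, InvalidParameterError

__all__ = [
    "WalkConfig",
    "EnsembleRecord",
    "ConfigurationError",
    "ReflectionError",
    "simulate",
    "simulate_wiener",
    "simulate_kinetic",
    "reflect_segment",
    "initial_position",
    "save_ensemble",
    "load_ensemble",
]

_MAX_REFLECTIONS = 1000
_SURF_EPS = 1.0e-12


class ConfigurationError(ValueError):
    """Simulation parameters violate a validity precondition."""


class ReflectionError(RuntimeError):
    """Reflection resolution failed (cap exceeded or invariant violated)."""


def _gap_width(rho: float, L: float) -> float:
    """Width of the narrowest void passage: along the cube edge for rho < 1,
    through the face center beyond."""
    if rho < 1.0:
        return L * (1.0 - rho)
    return L * (SQRT2 - rho)


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of one ensemble.

    Defaults follow the reference simulation conditions: lattice spacing
    ``L = 5`` (length units of nm), free diffusivity ``D0 = 1``, kinetic
    mean free path ``lambda = 0.20`` with mean step duration
    ``tau = lambda^2 / (3 D0)``, 100,000 walks and 250 equidistant
    recording times.  ``t_max`` defaults to the time for an RMS free
    displacement of four lattice spacings; the Euler time step ``dt``
    defaults to an RMS sub-step of one tenth of the narrowest gap.
    """

    model: str = "wiener"
    rho: float = 0.0
    L: float = 5.0
    D0: float = 1.0
    lam: float = 0.20
    tau: float | None = None
    n_walks: int = 100_000
    n_record: int = 250
    t_max: float | None = None
    dt: float | None = None
    init: str = "midpoint"
    seed: int = 0
    keep_positions: bool = False

    def __post_init__(self):
        if self.model not in ("wiener", "kinetic"):
            raise ConfigurationError(f"unknown model {self.model!r}")
        if self.init not in ("midpoint", "uniform_outside"):
            raise ConfigurationError(f"unknown init mode {self.init!r}")
        if not (0 <= self.rho < 2.0):
            raise ConfigurationError("rho must lie in [0, 2)")
        if self.rho >= SQRT2:
            import warnings

            warnings.warn(
                f"rho={self.rho:.3f} >= sqrt(2): void disconnected, walkers are caged"
            )
        if self.L <= 0 or self.D0 <= 0 or self.lam <= 0:
            raise ConfigurationError("L, D0 and lambda must be positive")
        if self.n_walks < 1 or self.n_record < 2:
            raise ConfigurationError("need n_walks >= 1 and n_record >= 2")

    @property
    def obstruction_radius(self) -> float:
        return self.rho * self.L / 2.0

    @property
    def tau_value(self) -> float:
        # mean step duration chosen so the unobstructed large-t MSD slope
        # lambda^2/tau equals 6 D0 / ... (lambda^2 t / tau = 2 d D t in 3-D
        # requires tau = lambda^2 / (6 D); the reference choice lambda^2/(3 D0)
        # instead matches E|step|^2 = 2 lambda^2 over mean duration tau:
        # MSD slope = 2 lambda^2 / tau = 6 D0).
        return self.tau if self.tau is not None else self.lam**2 / (3.0 * self.D0)

    @property
    def t_max_value(self) -> float:
        if self.t_max is not None:
            return self.t_max
        return (4.0 * self.L) ** 2 / (6.0 * self.D0)

    @property
    def dt_value(self) -> float:
        if self.dt is not None:
            return self.dt
        if self.rho == 0:
            return self.t_max_value / (self.n_record - 1)
        step = _gap_width(self.rho, self.L) / 10.0
        return step**2 / (6.0 * self.D0)

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.t_max_value, self.n_record)


@dataclass
class EnsembleRecord:
    """Recorded trajectories of one ensemble."""

    config: WalkConfig
    times: np.ndarray
    sq_disp: np.ndarray = field(repr=False, default=None)  # (n_walks, n_record)
    positions: np.ndarray | None = field(repr=False, default=None)
    n_inside_violations: int = 0
    n_reflection_failures: int = 0


# ---------------------------------------------------------------------------
# numba geometry kernels


@njit(cache=True)
def _dist_nearest_center(px, py, pz, L):
    """Distance to the nearest lattice obstruction center."""
    wx = px - L * round(px / L)
    wy = py - L * round(py / L)
    wz = pz - L * round(pz / L)
    return math.sqrt(wx * wx + wy * wy + wz * wz)


@njit(cache=True)
def _first_hit(px, py, pz, ux, uy, uz, smax, L, r):
    """Earliest ray-sphere intersection within arc length smax.

    Scans the 27 lattice images around the ray origin (exhaustive for
    smax <= L/2 and r < L/sqrt(2)).  Returns (s_hit, cx, cy, cz); s_hit < 0
    when there is no hit.
    """
    bx = L * round(px / L)
    by = L * round(py / L)
    bz = L * round(pz / L)
    best = -1.0
    hx = hy = hz = 0.0
    for i in range(-1, 2):
        for j in range(-1, 2):
            for k in range(-1, 2):
                cx = bx + i * L
                cy = by + j * L
                cz = bz + k * L
                ox = px - cx
                oy = py - cy
                oz = pz - cz
                b = ox * ux + oy * uy + oz * uz
                c = ox * ox + oy * oy + oz * oz - r * r
                if c <= 0.0 and b >= 0.0:
                    continue  # on the surface, moving outward
                disc = b * b - c
                if disc <= 0.0:
                    continue
                sq = math.sqrt(disc)
                s = -b - sq
                if s <= _SURF_EPS * L:
                    s = -b + sq
                    if c > 0.0 or s <= _SURF_EPS * L:
                        continue
                if s <= smax and (best < 0.0 or s < best):
                    best = s
                    hx, hy, hz = cx, cy, cz
    return best, hx, hy, hz


@njit(cache=True)
def _advance(px, py, pz, dx, dy, dz, L, r):
    """Move along displacement (dx,dy,dz) with specular reflections.

    Returns (x, y, z, n_reflections); n_reflections = -1 flags that the
    reflection cap was reached and the (tiny) residual path was dropped —
    this happens only in the cusp between touching spheres (rho >= 1),
    where specular bounces accumulate without bound.  The returned position
    is always valid (outside all obstructions).
    """
    rem = math.sqrt(dx * dx + dy * dy + dz * dz)
    if rem == 0.0:
        return px, py, pz, 0
    ux, uy, uz = dx / rem, dy / rem, dz / rem
    nrefl = 0
    while rem > 0.0:
        # free-flight shortcut: nearest surface farther than remaining path
        dfree = _dist_nearest_center(px, py, pz, L) - r
        if dfree > rem:
            px += ux * rem
            py += uy * rem
            pz += uz * rem
            break
        smax = rem if rem < 0.45 * L else 0.45 * L
        s, cx, cy, cz = _first_hit(px, py, pz, ux, uy, uz, smax, L, r)
        if s < 0.0:
            px += ux * smax
            py += uy * smax
            pz += uz * smax
            rem -= smax
            continue
        # move to the surface, renormalized onto it, and reflect
        px += ux * s
        py += uy * s
        pz += uz * s
        nx, ny, nz = px - cx, py - cy, pz - cz
        nn = math.sqrt(nx * nx + ny * ny + nz * nz)
        nx, ny, nz = nx / nn, ny / nn, nz / nn
        px = cx + nx * r * (1.0 + _SURF_EPS)
        py = cy + ny * r * (1.0 + _SURF_EPS)
        pz = cz + nz * r * (1.0 + _SURF_EPS)
        dot = ux * nx + uy * ny + uz * nz
        ux -= 2.0 * dot * nx
        uy -= 2.0 * dot * ny
        uz -= 2.0 * dot * nz
        rem -= s
        nrefl += 1
        if nrefl > _MAX_REFLECTIONS:
            return px, py, pz, -1
    return px, py, pz, nrefl


@njit(cache=True)
def _sample_start(mode_uniform, L, r):
    """Start point: cell body-center, or uniform rejection sampling in the
    cell (uses the current RNG substream)."""
    if not mode_uniform:
        return 0.5 * L, 0.5 * L, 0.5 * L, True
    for _ in range(1_000_000):
        x = np.random.uniform(0.0, L)
        y = np.random.uniform(0.0, L)
        z = np.random.uniform(0.0, L)
        if _dist_nearest_center(x, y, z, L) >= r:
            return x, y, z, True
    return 0.0, 0.0, 0.0, False


@njit(cache=True)
def _wiener_kernel(seeds, n_rec, m, dt, L, r, D0, mode_uniform, sq, pos, keep_pos):
    sigma = math.sqrt(2.0 * D0 * dt)
    n_walks = len(seeds)
    n_start_fail = 0
    n_trunc = 0
    n_inside = 0
    for w in range(n_walks):
        np.random.seed(seeds[w])
        x0, y0, z0, ok = _sample_start(mode_uniform, L, r)
        if not ok:
            n_start_fail += 1
            continue
        px, py, pz = x0, y0, z0
        sq[w, 0] = 0.0
        if keep_pos:
            pos[w, 0, 0] = px
            pos[w, 0, 1] = py
            pos[w, 0, 2] = pz
        for j in range(1, n_rec):
            for _ in range(m):
                dx = sigma * np.random.normal(0.0, 1.0)
                dy = sigma * np.random.normal(0.0, 1.0)
                dz = sigma * np.random.normal(0.0, 1.0)
                px, py, pz, nr = _advance(px, py, pz, dx, dy, dz, L, r)
                if nr < 0:
                    n_trunc += 1
            ddx, ddy, ddz = px - x0, py - y0, pz - z0
            sq[w, j] = ddx * ddx + ddy * ddy + ddz * ddz
            if r > 0.0 and _dist_nearest_center(px, py, pz, L) < r * (1.0 - 1e-9):
                n_inside += 1
            if keep_pos:
                pos[w, j, 0] = px
                pos[w, j, 1] = py
                pos[w, j, 2] = pz
    return n_start_fail, n_trunc, n_inside


@njit(cache=True)
def _kinetic_kernel(seeds, times, lam, tau, L, r, mode_uniform, sq, pos, keep_pos):
    n_walks = len(seeds)
    n_rec = len(times)
    t_end = times[n_rec - 1]
    n_start_fail = 0
    n_trunc = 0
    n_inside = 0
    for w in range(n_walks):
        np.random.seed(seeds[w])
        x0, y0, z0, ok = _sample_start(mode_uniform, L, r)
        if not ok:
            n_start_fail += 1
            continue
        px, py, pz = x0, y0, z0
        sq[w, 0] = 0.0
        if keep_pos:
            pos[w, 0, 0] = px
            pos[w, 0, 1] = py
            pos[w, 0, 2] = pz
        t = 0.0
        rec = 1
        while rec < n_rec and t < t_end:
            ell = np.random.exponential(lam)
            dur = np.random.exponential(tau)
            if dur <= 0.0:
                continue
            # isotropic direction
            ux = np.random.normal(0.0, 1.0)
            uy = np.random.normal(0.0, 1.0)
            uz = np.random.normal(0.0, 1.0)
            un = math.sqrt(ux * ux + uy * uy + uz * uz)
            if un == 0.0:
                continue
            ux, uy, uz = ux / un, uy / un, uz / un
            # traverse the (possibly reflected) polyline of length ell,
            # recording pending times at constant speed ell/dur
            rem = ell
            s_done = 0.0
            nrefl = 0
            while True:
                # next straight sub-segment
                dfree = _dist_nearest_center(px, py, pz, L) - r
                if dfree > rem:
                    seg = rem
                    hit = False
                    hx = hy = hz = 0.0
                else:
                    smax = rem if rem < 0.45 * L else 0.45 * L
                    s, hx, hy, hz = _first_hit(px, py, pz, ux, uy, uz, smax, L, r)
                    if s < 0.0:
                        seg = smax
                        hit = False
                    else:
                        seg = s
                        hit = True
                # record times whose arc position falls inside this segment
                while rec < n_rec:
                    trec = times[rec]
                    if trec > t + dur:
                        break
                    s_rec = ell * (trec - t) / dur
                    if s_rec > s_done + seg:
                        break
                    a = s_rec - s_done
                    qx = px + ux * a
                    qy = py + uy * a
                    qz = pz + uz * a
                    ddx, ddy, ddz = qx - x0, qy - y0, qz - z0
                    sq[w, rec] = ddx * ddx + ddy * ddy + ddz * ddz
                    if r > 0.0 and _dist_nearest_center(qx, qy, qz, L) < r * (1.0 - 1e-9):
                        n_inside += 1
                    if keep_pos:
                        pos[w, rec, 0] = qx
                        pos[w, rec, 1] = qy
                        pos[w, rec, 2] = qz
                    rec += 1
                px += ux * seg
                py += uy * seg
                pz += uz * seg
                s_done += seg
                rem -= seg
                if hit:
                    nx, ny, nz = px - hx, py - hy, pz - hz
                    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
                    nx, ny, nz = nx / nn, ny / nn, nz / nn
                    px = hx + nx * r * (1.0 + _SURF_EPS)
                    py = hy + ny * r * (1.0 + _SURF_EPS)
                    pz = hz + nz * r * (1.0 + _SURF_EPS)
                    dot = ux * nx + uy * ny + uz * nz
                    ux -= 2.0 * dot * nx
                    uy -= 2.0 * dot * ny
                    uz -= 2.0 * dot * nz
                    nrefl += 1
                    if nrefl > _MAX_REFLECTIONS:
                        n_trunc += 1
                        rem = 0.0  # drop the residual cusp path
                if rem <= 0.0:
                    break
            # flush any pending record times of this step (truncated paths,
            # or a final arc position lost to roundoff) at the endpoint
            while rec < n_rec and times[rec] <= t + dur:
                ddx, ddy, ddz = px - x0, py - y0, pz - z0
                sq[w, rec] = ddx * ddx + ddy * ddy + ddz * ddz
                if keep_pos:
                    pos[w, rec, 0] = px
                    pos[w, rec, 1] = py
                    pos[w, rec, 2] = pz
                rec += 1
            t += dur
    return n_start_fail, n_trunc, n_inside


# ---------------------------------------------------------------------------
# public API


def _walk_seeds(config: WalkConfig) -> np.ndarray:
    ss = np.random.SeedSequence(config.seed)
    return ss.generate_state(config.n_walks).astype(np.int64)


def simulate_wiener(config: WalkConfig) -> EnsembleRecord:
    """Euler reflected-Wiener ensemble."""
    if config.model != "wiener":
        config = replace(config, model="wiener")
    r = config.obstruction_radius
    dt = config.dt_value
    if config.rho > 0 and config.dt is not None:
        if math.sqrt(6.0 * config.D0 * dt) > _gap_width(config.rho, config.L) / 10.0 * (1 + 1e-9):
            raise ConfigurationError(
                "dt too large: RMS Euler step exceeds one tenth of the gap width"
            )
    rec_dt = config.t_max_value / (config.n_record - 1)
    m = max(1, int(math.ceil(rec_dt / dt - 1e-12)))
    dt_eff = rec_dt / m
    seeds = _walk_seeds(config)
    sq = np.zeros((config.n_walks, config.n_record))
    pos = (
        np.zeros((config.n_walks, config.n_record, 3))
        if config.keep_positions
        else np.zeros((1, 1, 3))
    )
    n_start_fail, n_trunc, n_inside = _wiener_kernel(
        seeds,
        config.n_record,
        m,
        dt_eff,
        config.L,
        r,
        config.D0,
        config.init == "uniform_outside",
        sq,
        pos,
        config.keep_positions,
    )
    if n_start_fail:
        raise ConfigurationError(f"{n_start_fail} start-sampling failures: void fraction ~ 0")
    return EnsembleRecord(
        config=config,
        times=config.times,
        sq_disp=sq,
        positions=pos if config.keep_positions else None,
        n_inside_violations=int(n_inside),
        n_reflection_failures=int(n_trunc),
    )


def simulate_kinetic(config: WalkConfig) -> EnsembleRecord:
    """Exponential-step velocity-jump (kinetic) ensemble."""
    if config.model != "kinetic":
        config = replace(config, model="kinetic")
    if config.tau_value <= 0:
        raise ConfigurationError("tau must be positive")
    seeds = _walk_seeds(config)
    sq = np.zeros((config.n_walks, config.n_record))
    pos = (
        np.zeros((config.n_walks, config.n_record, 3))
        if config.keep_positions
        else np.zeros((1, 1, 3))
    )
    n_start_fail, n_trunc, n_inside = _kinetic_kernel(
        seeds,
        config.times,
        config.lam,
        config.tau_value,
        config.L,
        config.obstruction_radius,
        config.init == "uniform_outside",
        sq,
        pos,
        config.keep_positions,
    )
    if n_start_fail:
        raise ConfigurationError(f"{n_start_fail} start-sampling failures: void fraction ~ 0")
    return EnsembleRecord(
        config=config,
        times=config.times,
        sq_disp=sq,
        positions=pos if config.keep_positions else None,
        n_inside_violations=int(n_inside),
        n_reflection_failures=int(n_trunc),
    )


def simulate(config: WalkConfig) -> EnsembleRecord:
    """Dispatch on ``config.model``."""
    if config.model == "wiener":
        return simulate_wiener(config)
    return simulate_kinetic(config)


def reflect_segment(start, displacement, obstruction_radius: float, L: float):
    """Endpoint of a straight segment after specular reflections.

    ``start`` must be strictly outside all obstructions; total path length
    is preserved.  Grazing (tangent) contacts are treated as no collision.
    """
    start = np.asarray(start, dtype=float)
    displacement = np.asarray(displacement, dtype=float)
    if obstruction_radius < 0 or L <= 0:
        raise InvalidParameterError("radius must be >= 0 and L > 0")
    if obstruction_radius > 0:
        d = _dist_nearest_center(start[0], start[1], start[2], L)
        if d < obstruction_radius * (1.0 - 1e-12):
            raise ReflectionError("start point lies inside an obstruction")
    x, y, z, nr = _advance(
        start[0], start[1], start[2],
        displacement[0], displacement[1], displacement[2],
        L, obstruction_radius,
    )
    if nr < 0:
        raise ReflectionError("reflection cap exceeded")
    return np.array([x, y, z])


def initial_position(config: WalkConfig, rng: np.random.Generator):
    """Draw one start point in the configured mode."""
    L = config.L
    r = config.obstruction_radius
    if config.init == "midpoint":
        return np.full(3, L / 2.0)
    for _ in range(1_000_000):
        p = rng.uniform(0.0, L, size=3)
        if _dist_nearest_center(p[0], p[1], p[2], L) >= r:
            return p
    raise ConfigurationError("rejection sampling failed: void fraction ~ 0")


# ---------------------------------------------------------------------------
# HDF5 persistence


def save_ensemble(record: EnsembleRecord, path) -> None:
    """Store an ensemble (datasets times/sq_disp, config in attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=record.times)
        f.create_dataset("sq_disp", data=record.sq_disp, compression="gzip")
        if record.positions is not None:
            f.create_dataset("positions", data=record.positions, compression="gzip")
        cfg = record.config
        for k in (
            "model", "rho", "L", "D0", "lam", "n_walks", "n_record", "init", "seed",
        ):
            f.attrs[k] = getattr(cfg, k)
        f.attrs["tau"] = cfg.tau_value
        f.attrs["t_max"] = cfg.t_max_value
        f.attrs["dt"] = cfg.dt_value
        f.attrs["n_inside_violations"] = record.n_inside_violations


def load_ensemble(path) -> EnsembleRecord:
    with h5py.File(path, "r") as f:
        cfg = WalkConfig(
            model=str(f.attrs["model"]),
            rho=float(f.attrs["rho"]),
            L=float(f.attrs["L"]),
            D0=float(f.attrs["D0"]),
            lam=float(f.attrs["lam"]),
            tau=float(f.attrs["tau"]),
            n_walks=int(f.attrs["n_walks"]),
            n_record=int(f.attrs["n_record"]),
            t_max=float(f.attrs["t_max"]),
            dt=float(f.attrs["dt"]),
            init=str(f.attrs["init"]),
            seed=int(f.attrs["seed"]),
        )
        rec = EnsembleRecord(
            config=cfg,
            times=f["times"][:],
            sq_disp=f["sq_disp"][:],
            positions=f["positions"][:] if "positions" in f else None,
            n_inside_violations=int(f.attrs.get("n_inside_violations", 0)),
        )
    return rec
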