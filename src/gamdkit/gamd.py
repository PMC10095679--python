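"""Langevin sampling of toy potentials, conventional and boosted.

The boosted stage adds a harmonic lift below a threshold energy E::

    V*(r) = V(r) + dV(r)
    dV(r) = 0                    if V(r) >= E
          = (k/2) (E - V(r))^2   if V(r) <  E

with E and k derived from the potential-energy statistics of a preceding
conventional run (frozen; no on-the-fly updating):

    Vmax <= E <= Vmin + 1/k,     k = k0 / (Vmax - Vmin)

lower bound (E = Vmax):   k0 = min(1, (s0/sV) (Vmax-Vmin)/(Vmax-Vavg))
upper bound (E = Vmin + 1/k):  k0 = (1 - s0/sV) (Vmax-Vmin)/(Vavg-Vmin)

where s0 is the user ceiling on the boost standard deviation and sV the
standard deviation of the conventional-run potential energies.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from gamdkit.toy_systems.potentials import PotentialSpec
from gamdkit.units import KB_KCAL, KCAL_PER_MOL_TO_AKMA

logger = logging.getLogger(__name__)

DEFAULT_FRICTION = 2.0  # ps^-1, Langevin collision frequency
DEFAULT_MASS = 12.011  # amu
ENERGY_DIVERGENCE_LIMIT = 1e8  # kcal/mol


@dataclass(frozen=True)
class PotentialStats:
    """Potential-energy statistics of a conventional run."""

    v_max: float
    v_min: float
    v_avg: float
    sigma_v: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples for potential statistics")
        if not self.v_min <= self.v_avg <= self.v_max:
            raise ValueError(
                f"require v_min <= v_avg <= v_max, got "
                f"{self.v_min}, {self.v_avg}, {self.v_max}"
            )
        if self.sigma_v < 0:
            raise ValueError("sigma_v must be non-negative")

    @classmethod
    def from_series(cls, v_series: np.ndarray) -> "PotentialStats":
        v = np.asarray(v_series, dtype=float)
        return cls(
            v_max=float(v.max()),
            v_min=float(v.min()),
            v_avg=float(v.mean()),
            sigma_v=float(v.std()),
            n_samples=v.size,
        )


@dataclass(frozen=True)
class BoostParams:
    """Derived boost state: threshold energy E, force constant k, and k0."""

    sigma0: float
    bound_mode: Literal["lower", "upper"]
    k0: float
    k: float
    threshold_e: float
    stats: PotentialStats

    def __post_init__(self) -> None:
        if not 0.0 <= self.k0 <= 1.0:
            raise ValueError(f"k0 must lie in [0, 1], got {self.k0}")
        if self.k < 0:
            raise ValueError("k must be non-negative")
        upper = self.stats.v_min + (1.0 / self.k if self.k > 0 else math.inf)
        if not (self.stats.v_max - 1e-9 <= self.threshold_e <= upper + 1e-9):
            raise ValueError(
                f"threshold E={self.threshold_e} outside "
                f"[{self.stats.v_max}, {upper}]"
            )


@dataclass
class BoostedTrajectory:
    """Stored coordinate series with per-frame V and dV (both kcal/mol)."""

    positions: np.ndarray  # (n_frames, dimension)
    v_series: np.ndarray
    dv_series: np.ndarray
    temperature: float
    seed: int
    timestep: float  # ps between stored frames
    params: BoostParams | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.ndim == 2 and self.positions.shape[0] == 1:
            pass
        n = self.positions.shape[0]
        if len(self.v_series) != n or len(self.dv_series) != n:
            raise ValueError("v_series and dv_series must match the frame count")
        if np.any(np.asarray(self.dv_series) < 0):
            raise ValueError("dv_series must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


def compute_boost_params(
    stats: PotentialStats,
    sigma0: float,
    bound_mode: Literal["lower", "upper"] = "lower",
) -> BoostParams:
    """Derive (E, k, k0) from conventional-run statistics.

    An upper-bound request whose k0 falls outside (0, 1] falls back to the
    lower bound with a logged warning.
    """
    if bound_mode not in ("lower", "upper"):
        raise ValueError(f"bound_mode must be 'lower' or 'upper', got {bound_mode!r}")
    if sigma0 < 0:
        raise ValueError("sigma0 must be non-negative")
    span = stats.v_max - stats.v_min
    if span <= 0:
        raise ValueError("degenerate statistics: v_max == v_min")
    if stats.sigma_v <= 0:
        raise ValueError("degenerate statistics: sigma_v must be positive")

    if bound_mode == "upper":
        k0 = (1.0 - sigma0 / stats.sigma_v) * span / (stats.v_avg - stats.v_min)
        if not 0.0 < k0 <= 1.0:
            logger.warning(
                "upper-bound k0=%.4g outside (0, 1]; falling back to lower bound", k0
            )
            bound_mode = "lower"
        else:
            k = k0 / span
            e = stats.v_min + 1.0 / k
            return BoostParams(
                sigma0=sigma0, bound_mode="upper", k0=k0, k=k,
                threshold_e=e, stats=stats,
            )

    k0 = min(1.0, (sigma0 / stats.sigma_v) * span / (stats.v_max - stats.v_avg))
    k = k0 / span
    return BoostParams(
        sigma0=sigma0, bound_mode="lower", k0=k0, k=k,
        threshold_e=stats.v_max, stats=stats,
    )


def boost_energy(v, params: BoostParams):
    """Harmonic boost dV at potential energy ``v`` (vectorized)."""
    v = np.asarray(v, dtype=float)
    below = v < params.threshold_e
    dv = np.where(below, 0.5 * params.k * (params.threshold_e - v) ** 2, 0.0)
    return dv if dv.ndim else float(dv)


# ---------------------------------------------------------------------------
# BAOAB Langevin integration


def _integrate(
    potential: PotentialSpec,
    temperature: float,
    friction: float,
    dt: float,
    n_steps: int,
    stride: int,
    seed: int,
    mass: float,
    x0,
    boost: BoostParams | None,
):
    """Shared BAOAB loop; returns (positions, v_series, dv_series)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_steps < stride or stride < 1:
        raise ValueError("need n_steps >= stride >= 1")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if friction < 0:
        raise ValueError("friction must be non-negative")

    d = potential.dimension
    kt_akma = KB_KCAL * temperature * KCAL_PER_MOL_TO_AKMA  # amu A^2/ps^2
    fscale = KCAL_PER_MOL_TO_AKMA / mass  # kcal/mol/A -> A/ps^2
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(kt_akma * (1.0 - c1 * c1) / mass)
    v_thermal = math.sqrt(kt_akma / mass)
    half_dt = 0.5 * dt

    rng = random.Random(seed)
    n_stored = n_steps // stride
    positions = np.empty((n_stored, d))
    v_series = np.empty(n_stored)
    dv_series = np.zeros(n_stored)

    if boost is not None and boost.k > 0:
        bk, be = boost.k, boost.threshold_e
    else:
        bk, be = 0.0, -math.inf

    energy = potential.scalar_energy
    grad = potential.scalar_gradient

    def diverged(v):
        raise RuntimeError(
            f"potential energy diverged (|V|={v:.3g} kcal/mol); "
            f"reduce dt (currently {dt} ps)"
        )

    if d == 1:
        x = 0.0 if x0 is None else float(np.asarray(x0).ravel()[0])
        vel = v_thermal * rng.gauss(0.0, 1.0)
        g = grad(x)
        v_pot = energy(x)
        if bk > 0.0 and v_pot < be:
            g *= 1.0 - bk * (be - v_pot)
        store = 0
        for step in range(1, n_steps + 1):
            vel -= half_dt * fscale * g
            x += half_dt * vel
            vel = c1 * vel + c2 * rng.gauss(0.0, 1.0)
            x += half_dt * vel
            v_pot = energy(x)
            g = grad(x)
            if bk > 0.0 and v_pot < be:
                g *= 1.0 - bk * (be - v_pot)
            vel -= half_dt * fscale * g
            if abs(v_pot) > ENERGY_DIVERGENCE_LIMIT:
                diverged(v_pot)
            if step % stride == 0:
                positions[store, 0] = x
                v_series[store] = v_pot
                if bk > 0.0 and v_pot < be:
                    dv_series[store] = 0.5 * bk * (be - v_pot) ** 2
                store += 1
    else:
        if x0 is None:
            x, y = 0.0, 0.0
        else:
            x, y = (float(c) for c in np.asarray(x0).ravel()[:2])
        vx = v_thermal * rng.gauss(0.0, 1.0)
        vy = v_thermal * rng.gauss(0.0, 1.0)
        gx, gy = grad(x, y)
        v_pot = energy(x, y)
        if bk > 0.0 and v_pot < be:
            s = 1.0 - bk * (be - v_pot)
            gx, gy = s * gx, s * gy
        store = 0
        for step in range(1, n_steps + 1):
            vx -= half_dt * fscale * gx
            vy -= half_dt * fscale * gy
            x += half_dt * vx
            y += half_dt * vy
            vx = c1 * vx + c2 * rng.gauss(0.0, 1.0)
            vy = c1 * vy + c2 * rng.gauss(0.0, 1.0)
            x += half_dt * vx
            y += half_dt * vy
            v_pot = energy(x, y)
            gx, gy = grad(x, y)
            if bk > 0.0 and v_pot < be:
                s = 1.0 - bk * (be - v_pot)
                gx, gy = s * gx, s * gy
            vx -= half_dt * fscale * gx
            vy -= half_dt * fscale * gy
            if abs(v_pot) > ENERGY_DIVERGENCE_LIMIT:
                diverged(v_pot)
            if step % stride == 0:
                positions[store, 0] = x
                positions[store, 1] = y
                v_series[store] = v_pot
                if bk > 0.0 and v_pot < be:
                    dv_series[store] = 0.5 * bk * (be - v_pot) ** 2
                store += 1

    return positions, v_series, dv_series


def run_cmd(
    potential: PotentialSpec,
    temperature: float,
    friction: float = DEFAULT_FRICTION,
    dt: float = 0.01,
    n_steps: int = 100_000,
    stride: int = 10,
    seed: int = 0,
    mass: float = DEFAULT_MASS,
    x0=None,
    burn_in_fraction: float = 0.1,
) -> tuple[BoostedTrajectory, PotentialStats]:
    """Conventional Langevin run; statistics over post-burn-in stored frames."""
    positions, v_series, dv_series = _integrate(
        potential, temperature, friction, dt, n_steps, stride, seed, mass, x0, None
    )
    burn = int(burn_in_fraction * len(v_series))
    stats = PotentialStats.from_series(v_series[burn:])
    traj = BoostedTrajectory(
        positions=positions,
        v_series=v_series,
        dv_series=dv_series,
        temperature=temperature,
        seed=seed,
        timestep=dt * stride,
        params=None,
        metadata={"mode": "cmd", "burn_in_frames": burn, "mass": mass},
    )
    return traj, stats


def run_gamd(
    potential: PotentialSpec,
    params: BoostParams,
    temperature: float,
    friction: float = DEFAULT_FRICTION,
    dt: float = 0.01,
    n_steps: int = 100_000,
    stride: int = 10,
    seed: int = 0,
    mass: float = DEFAULT_MASS,
    x0=None,
) -> BoostedTrajectory:
    """Boosted run on V* with per-frame V and dV recorded for reweighting."""
    positions, v_series, dv_series = _integrate(
        potential, temperature, friction, dt, n_steps, stride, seed, mass, x0, params
    )
    return BoostedTrajectory(
        positions=positions,
        v_series=v_series,
        dv_series=dv_series,
        temperature=temperature,
        seed=seed,
        timestep=dt * stride,
        params=params,
        metadata={"mode": "gamd", "mass": mass},
    )


def count_well_transitions(
    positions: np.ndarray, left: float = -0.5, right: float = 0.5
) -> int:
    """Number of complete well-to-well transitions of a 1-D coordinate series,
    with hysteresis: a transition is counted only when the coordinate crosses
    from beyond ``left`` to beyond ``right`` (or vice versa)."""
    if left >= right:
        raise ValueError("need left < right")
    x = np.asarray(positions, dtype=float).ravel()
    state = 0  # -1 left well, +1 right well, 0 undecided
    count = 0
    for xi in x:
        if xi <= left:
            if state == 1:
                count += 1
            state = -1
        elif xi >= right:
            if state == -1:
                count += 1
            state = 1
    return count
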