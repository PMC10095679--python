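"""Analytic toy potentials with exact Boltzmann references.

Each :class:`PotentialSpec` exposes a vectorized energy/gradient (kcal/mol,
kcal/mol/A over angstrom coordinates) together with the closed-form
``-kT ln p`` of its normalized Boltzmann density, which downstream modules
use as ground truth when validating reweighted free-energy surfaces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate


@dataclass
class PotentialSpec:
    """An analytic energy function over 1- or 2-D coordinates.

    ``energy`` and ``gradient`` accept an array of shape ``(d,)`` or
    ``(n, d)`` (for ``dimension == 1`` plain scalars / 1-D arrays are also
    accepted).  ``reference_pmf`` maps coordinates to ``-kT ln p`` of the
    normalized Boltzmann density at the spec's ``kt``.  ``scalar_energy`` /
    ``scalar_gradient`` are allocation-free fast paths used by the
    integrator hot loop (floats in, floats out).
    """

    dimension: int
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    params: dict
    kt: float
    domain: tuple[tuple[float, float], ...]
    scalar_energy: Callable = None
    scalar_gradient: Callable = None
    _log_z: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.dimension not in (1, 2):
            raise ValueError("dimension must be 1 or 2")
        if self.kt <= 0:
            raise ValueError("kT must be positive")

    # -- Boltzmann reference ------------------------------------------------

    def log_partition(self) -> float:
        """ln Z over the stated domain, by adaptive quadrature (cached)."""
        if self._log_z is None:
            beta = 1.0 / self.kt
            if self.dimension == 1:
                (lo, hi), = self.domain
                z, _ = integrate.quad(
                    lambda x: math.exp(-beta * float(self.energy(x))), lo, hi,
                    limit=200,
                )
            else:
                (xlo, xhi), (ylo, yhi) = self.domain
                z, _ = integrate.dblquad(
                    lambda y, x: math.exp(
                        -beta * float(self.energy(np.array([x, y])))
                    ),
                    xlo, xhi, ylo, yhi,
                )
            self._log_z = math.log(z)
        return self._log_z

    def reference_pmf(self, coords) -> np.ndarray:
        """``-kT ln p_Boltzmann`` at ``coords`` (not min-shifted)."""
        v = np.asarray(self.energy(coords), dtype=float)
        return v + self.kt * self.log_partition()

    def boltzmann_density(self, coords) -> np.ndarray:
        """Normalized Boltzmann density at ``coords``."""
        return np.exp(-np.asarray(self.reference_pmf(coords)) / self.kt)


def make_double_well(
    barrier_height: float, well_separation: float, kt: float = 0.5961612
) -> PotentialSpec:
    """Symmetric quartic double well ``V(x) = h ((x/a)^2 - 1)^2``.

    Minima at +-``well_separation`` (V = 0), barrier of ``barrier_height``
    at the origin.  Default ``kt`` corresponds to 300 K.
    """
    if barrier_height <= 0 or well_separation <= 0:
        raise ValueError("barrier_height and well_separation must be positive")
    h, a = float(barrier_height), float(well_separation)

    def energy(x):
        x = np.asarray(x, dtype=float)
        u = (x / a) ** 2 - 1.0
        return h * u * u

    def gradient(x):
        x = np.asarray(x, dtype=float)
        return 4.0 * h * x * ((x / a) ** 2 - 1.0) / a**2

    def scalar_energy(x: float) -> float:
        u = (x / a) ** 2 - 1.0
        return h * u * u

    def scalar_gradient(x: float) -> float:
        return 4.0 * h * x * ((x / a) ** 2 - 1.0) / (a * a)

    # beyond ~3a the Boltzmann weight is negligible for any h >= kT
    half_width = 3.0 * a
    return PotentialSpec(
        dimension=1,
        energy=energy,
        gradient=gradient,
        params={"barrier_height": h, "well_separation": a},
        kt=float(kt),
        domain=((-half_width, half_width),),
        scalar_energy=scalar_energy,
        scalar_gradient=scalar_gradient,
    )


def make_multiwell_2d(
    n_wells: int,
    depths,
    centers,
    width: float,
    kt: float = 0.5961612,
    wall_height: float = 10.0,
) -> PotentialSpec:
    """Sum of inverted Gaussian wells plus a confining quartic wall.

    ``V(r) = -sum_i d_i exp(-|r - c_i|^2 / 2 w^2) + W ((x/L)^4 + (y/L)^4)``
    with ``L`` set so the wall stays soft over the well region.
    """
    depths = np.asarray(depths, dtype=float)
    centers = np.asarray(centers, dtype=float).reshape(-1, 2)
    if n_wells < 2:
        raise ValueError("n_wells must be >= 2")
    if len(depths) != n_wells or len(centers) != n_wells:
        raise ValueError("depths and centers must both have length n_wells")
    if width <= 0:
        raise ValueError("width must be positive")
    w2 = float(width) ** 2
    dmat = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
    if np.any(dmat[np.triu_indices(n_wells, k=1)] < width):
        warnings.warn("well centers closer than width: wells will merge")

    scale = max(1.0, float(np.max(np.abs(centers)))) + 3.0 * width
    wall = float(wall_height)

    def energy(xy):
        xy = np.asarray(xy, dtype=float)
        pts = xy.reshape(-1, 2)
        d2 = np.sum((pts[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
        v = -np.sum(depths * np.exp(-d2 / (2.0 * w2)), axis=-1)
        v = v + wall * np.sum((pts / scale) ** 4, axis=-1)
        return v.reshape(xy.shape[:-1])

    def gradient(xy):
        xy = np.asarray(xy, dtype=float)
        pts = xy.reshape(-1, 2)
        diff = pts[:, None, :] - centers[None, :, :]
        d2 = np.sum(diff**2, axis=-1)
        g = np.sum(
            (depths * np.exp(-d2 / (2.0 * w2)) / w2)[:, :, None] * diff, axis=1
        )
        g = g + 4.0 * wall * pts**3 / scale**4
        return g.reshape(xy.shape)

    cx, cy = centers[:, 0], centers[:, 1]
    dep = depths.copy()

    def scalar_energy(x: float, y: float) -> float:
        v = wall * ((x / scale) ** 4 + (y / scale) ** 4)
        for i in range(len(dep)):
            dx, dy = x - cx[i], y - cy[i]
            v -= dep[i] * math.exp(-(dx * dx + dy * dy) / (2.0 * w2))
        return v

    def scalar_gradient(x: float, y: float) -> tuple[float, float]:
        gx = 4.0 * wall * x**3 / scale**4
        gy = 4.0 * wall * y**3 / scale**4
        for i in range(len(dep)):
            dx, dy = x - cx[i], y - cy[i]
            f = dep[i] * math.exp(-(dx * dx + dy * dy) / (2.0 * w2)) / w2
            gx += f * dx
            gy += f * dy
        return gx, gy

    lim = scale * 1.5
    return PotentialSpec(
        dimension=2,
        energy=energy,
        gradient=gradient,
        params={
            "depths": depths,
            "centers": centers,
            "width": float(width),
            "wall_height": wall,
            "wall_scale": scale,
        },
        kt=float(kt),
        domain=((-lim, lim), (-lim, lim)),
        scalar_energy=scalar_energy,
        scalar_gradient=scalar_gradient,
    )
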