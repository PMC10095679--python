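"""Protein-like ensembles with planted collective modes.

The generated trajectories have a covariance whose eigenstructure is known
in closed form (mode variances ``amplitude**2`` on top of an isotropic
``noise_sigma**2`` floor), providing ground truth for PCA and
cross-correlation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gamdkit.toy_systems.trajectory import (
    TrajectoryEnsemble,
    generic_labels,
    uniform_masses,
)

_ORTHO_TOL = 1e-10


@dataclass
class PlantedModeSpec:
    """Ground-truth collective modes planted into a synthetic ensemble.

    ``mode_vectors`` has shape (n_modes, n_particles, 3) and must be
    mutually orthonormal when flattened.  ``amplitudes`` are the stationary
    standard deviations (A) of the per-mode AR(1) coefficients,
    ``autocorrelation`` their lag-1 coefficients in [0, 1), and
    ``noise_sigma`` the isotropic per-coordinate noise (A).
    """

    mode_vectors: np.ndarray
    amplitudes: np.ndarray
    autocorrelation: np.ndarray
    noise_sigma: float
    seed: int
    mean_structure: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mode_vectors = np.asarray(self.mode_vectors, dtype=float)
        if self.mode_vectors.ndim != 3 or self.mode_vectors.shape[2] != 3:
            raise ValueError("mode_vectors must have shape (n_modes, n_particles, 3)")
        n_modes = self.mode_vectors.shape[0]
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        self.autocorrelation = np.broadcast_to(
            np.asarray(self.autocorrelation, dtype=float), (n_modes,)
        ).copy()
        if self.amplitudes.shape != (n_modes,):
            raise ValueError("amplitudes must match the number of modes")
        if n_modes and np.any(self.amplitudes <= 0):
            raise ValueError("amplitudes must be positive")
        if np.any((self.autocorrelation < 0) | (self.autocorrelation >= 1)):
            raise ValueError("autocorrelation coefficients must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if n_modes:
            flat = self.mode_vectors.reshape(n_modes, -1)
            gram = flat @ flat.T
            if not np.allclose(gram, np.eye(n_modes), atol=_ORTHO_TOL):
                raise ValueError("mode vectors must be mutually orthonormal")

    @property
    def n_modes(self) -> int:
        return self.mode_vectors.shape[0]

    @property
    def n_particles(self) -> int:
        return self.mode_vectors.shape[1]

    def population_covariance(self) -> np.ndarray:
        """Exact 3N x 3N covariance of the generated process."""
        n3 = 3 * self.n_particles
        flat = self.mode_vectors.reshape(self.n_modes, n3)
        cov = self.noise_sigma**2 * np.eye(n3)
        for s, u in zip(self.amplitudes, flat):
            cov += s**2 * np.outer(u, u)
        return cov


def rigid_body_basis(structure: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6 x 3N, or fewer if degenerate) of rigid translations
    and infinitesimal rotations about the structure's centroid."""
    structure = np.asarray(structure, dtype=float)
    n = structure.shape[0]
    centred = structure - structure.mean(axis=0)
    gens = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        gens.append(t.ravel())
    for axis in np.eye(3):
        gens.append(np.cross(axis, centred).ravel())
    q, r = np.linalg.qr(np.array(gens).T)
    keep = np.abs(np.diag(r)) > 1e-10
    return q.T[keep]


def random_orthonormal_modes(
    n_particles: int,
    n_modes: int,
    seed: int,
    mean_structure: np.ndarray | None = None,
    remove_rigid_body: bool = True,
) -> np.ndarray:
    """Random mutually orthonormal mode vectors, by default orthogonal to the
    rigid-body subspace of ``mean_structure`` so least-squares alignment leaves
    the planted signal intact."""
    rng = np.random.default_rng(seed)
    n3 = 3 * n_particles
    raw = rng.standard_normal((n_modes, n3))
    if remove_rigid_body and mean_structure is not None:
        basis = rigid_body_basis(mean_structure)
        raw = raw - (raw @ basis.T) @ basis
    q, _ = np.linalg.qr(raw.T)
    return q.T[:n_modes].reshape(n_modes, n_particles, 3)


def generate_planted_trajectory(
    n_particles: int, n_frames: int, spec: PlantedModeSpec
) -> TrajectoryEnsemble:
    """``x_t = mean + sum_m a_m(t) u_m + eps_t`` with stationary AR(1) mode
    coefficients and iid Gaussian noise; bitwise deterministic given the seed."""
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    if spec.n_particles != n_particles:
        raise ValueError(
            f"spec is for {spec.n_particles} particles, requested {n_particles}"
        )
    if spec.n_modes == 0 and spec.noise_sigma == 0:
        raise ValueError("degenerate ensemble: no modes and no noise")

    rng = np.random.default_rng(spec.seed)
    if spec.mean_structure is not None:
        mean = np.asarray(spec.mean_structure, dtype=float)
        if mean.shape != (n_particles, 3):
            raise ValueError("mean_structure must have shape (n_particles, 3)")
    else:
        mean = 5.0 * rng.standard_normal((n_particles, 3))

    coords = np.broadcast_to(mean, (n_frames, n_particles, 3)).copy()
    for m in range(spec.n_modes):
        s = spec.amplitudes[m]
        phi = spec.autocorrelation[m]
        innov = rng.standard_normal(n_frames)
        a = np.empty(n_frames)
        a[0] = s * innov[0]
        drive = s * np.sqrt(1.0 - phi**2)
        for t in range(1, n_frames):
            a[t] = phi * a[t - 1] + drive * innov[t]
        coords += a[:, None, None] * spec.mode_vectors[m][None, :, :]
    if spec.noise_sigma > 0:
        coords += spec.noise_sigma * rng.standard_normal(coords.shape)

    return TrajectoryEnsemble(
        coordinates=coords,
        labels=generic_labels(n_particles, element="C", name="CA", resname="ALA"),
        masses=uniform_masses(n_particles),
        timestep=1.0,
        metadata={"generator": "planted_modes", "seed": spec.seed},
    )
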