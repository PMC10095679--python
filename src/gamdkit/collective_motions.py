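"""Coordinate-covariance PCA and dynamic cross-correlation maps.

The covariance is built from least-squares-aligned Cartesian coordinates
with ensemble-average (1/n) normalization; eigenvectors are the collective
motion modes, and the cross-correlation matrix is the normalized
displacement-vector dot product

    C_ij = <dr_i . dr_j> / (<dr_i^2> <dr_j^2>)^{1/2}
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from gamdkit.structure_metrics import _resolve, iterative_mean_structure
from gamdkit.toy_systems.trajectory import TrajectoryEnsemble


@dataclass
class CovarianceMatrix:
    matrix: np.ndarray  # (3N, 3N), A^2
    mean_structure: np.ndarray  # (N, 3)
    indices: np.ndarray
    n_frames: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")


@dataclass
class EigenDecomposition:
    eigenvalues: np.ndarray  # A^2, descending
    eigenvectors: np.ndarray  # (3N, 3N), columns orthonormal
    mean_structure: np.ndarray

    @property
    def n_particles(self) -> int:
        return self.mean_structure.shape[0]


@dataclass
class DCCMatrix:
    matrix: np.ndarray  # (N, N) in [-1, 1]
    indices: np.ndarray
    zero_variance: np.ndarray | None = None  # flagged particles


def _aligned_displacements(traj, selection, align):
    idx = _resolve(traj, selection)
    if idx.size < 2:
        raise ValueError("need at least 2 selected particles")
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    coords = traj.coordinates[:, idx, :]
    if align:
        mean, coords = iterative_mean_structure(coords)
    else:
        mean = coords.mean(axis=0)
    return idx, mean, coords - mean


def build_covariance(
    traj: TrajectoryEnsemble, selection=None, align: bool = True
) -> CovarianceMatrix:
    """3N x 3N coordinate covariance of the aligned ensemble (1/n norm)."""
    idx, mean, disp = _aligned_displacements(traj, selection, align)
    flat = disp.reshape(traj.n_frames, -1)
    cov = flat.T @ flat / traj.n_frames
    cov = 0.5 * (cov + cov.T)
    return CovarianceMatrix(
        matrix=cov,
        mean_structure=mean,
        indices=idx,
        n_frames=traj.n_frames,
        metadata={"normalization": "1/n", "aligned": align},
    )


def diagonalize(cov: CovarianceMatrix) -> EigenDecomposition:
    """Full symmetric eigendecomposition, eigenvalues descending.

    Sign convention: each eigenvector's largest-magnitude component is
    positive (ties broken by the first such component).
    """
    m = cov.matrix
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("covariance is not symmetric within tolerance")
    evals, evecs = np.linalg.eigh(m)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return EigenDecomposition(
        eigenvalues=evals, eigenvectors=evecs, mean_structure=cov.mean_structure
    )


def variance_fraction(eig: EigenDecomposition, n_modes: int) -> float:
    """Fraction of total positional variance carried by the first ``n_modes``."""
    total = eig.eigenvalues.size
    if not 1 <= n_modes <= total:
        raise ValueError(f"n_modes must lie in [1, {total}]")
    return float(eig.eigenvalues[:n_modes].sum() / eig.eigenvalues.sum())


def mode_displacements(
    eig: EigenDecomposition, mode_index: int, scale: float = 1.0
) -> np.ndarray:
    """Per-particle displacement arrows (N, 3) for one mode."""
    if not 0 <= mode_index < eig.eigenvalues.size:
        raise ValueError(f"mode_index {mode_index} out of range")
    return scale * eig.eigenvectors[:, mode_index].reshape(-1, 3)


def export_porcupine(
    eig: EigenDecomposition,
    mode_index: int,
    path: str,
    scale: float = 1.0,
) -> None:
    """Write a two-model PDB (mean structure, mean + scaled mode) for
    porcupine-style rendering."""
    from gamdkit.toy_systems.io import write_trajectory
    from gamdkit.toy_systems.trajectory import generic_labels, uniform_masses

    arrows = mode_displacements(eig, mode_index, scale)
    n = eig.n_particles
    coords = np.stack([eig.mean_structure, eig.mean_structure + arrows])
    traj = TrajectoryEnsemble(
        coordinates=coords,
        labels=generic_labels(n, element="C", name="CA", resname="ALA"),
        masses=uniform_masses(n),
    )
    write_trajectory(traj, path, format="pdb")


def dccm(
    traj: TrajectoryEnsemble, selection=None, align: bool = True
) -> DCCMatrix:
    """Dynamic cross-correlation matrix over the selected particles.

    A particle with zero positional variance gets a zeroed row/column
    (diagonal kept at 1) and is flagged.
    """
    idx, _, disp = _aligned_displacements(traj, selection, align)
    # <dr_i . dr_j> across frames
    inner = np.einsum("fic,fjc->ij", disp, disp) / traj.n_frames
    var = np.diag(inner).copy()
    zero = var <= 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} selected particle(s) have zero variance; "
            "their correlations are set to 0"
        )
    denom = np.sqrt(np.where(zero, 1.0, var))
    c = inner / denom[:, None] / denom[None, :]
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip(0.5 * (c + c.T), -1.0, 1.0)
    return DCCMatrix(matrix=c, indices=idx, zero_variance=zero if zero.any() else None)
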