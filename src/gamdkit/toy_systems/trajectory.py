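"""The universal analysis input: frames x particles x 3 coordinates with labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default mass (amu) by element symbol; unknown elements fall back to carbon.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "F": 18.998,
    "CL": 35.45,
    "NA": 22.990,
    "MG": 24.305,
    "K": 39.098,
    "CA": 40.078,
    "ZN": 65.38,
    "FE": 55.845,
}

DEFAULT_MASS = 12.011


@dataclass(frozen=True)
class ParticleLabels:
    """Per-particle identity: atom name, residue id (0-based), residue name, element."""

    name: str
    resid: int
    resname: str
    element: str


def mass_for_element(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), DEFAULT_MASS)


@dataclass
class TrajectoryEnsemble:
    """A conformational ensemble: ``coordinates`` is (n_frames, n_particles, 3) in angstrom.

    ``masses`` are amu, ``timestep`` is the ps spacing between stored frames, and
    ``box`` is an optional (3,) array of periodic box lengths (carried but unused
    by the analyses — toy systems are unwrapped).
    """

    coordinates: np.ndarray
    labels: list[ParticleLabels]
    masses: np.ndarray
    timestep: float = 1.0
    box: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError(
                f"coordinates must be (frames, particles, 3), got {self.coordinates.shape}"
            )
        if self.n_frames < 1:
            raise ValueError("trajectory must contain at least one frame")
        self.masses = np.asarray(self.masses, dtype=float)
        if len(self.labels) != self.n_particles or self.masses.shape != (self.n_particles,):
            raise ValueError(
                "label count and mass count must both equal the particle count "
                f"({len(self.labels)}, {self.masses.shape}, {self.n_particles})"
            )
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coordinates[i]

    def with_coordinates(self, coordinates: np.ndarray) -> "TrajectoryEnsemble":
        """A copy sharing labels/masses but with new coordinates."""
        return TrajectoryEnsemble(
            coordinates=np.asarray(coordinates, dtype=float),
            labels=self.labels,
            masses=self.masses.copy(),
            timestep=self.timestep,
            box=None if self.box is None else self.box.copy(),
            metadata=dict(self.metadata),
        )


def generic_labels(
    n_particles: int,
    element: str = "C",
    name: str | None = None,
    resname: str = "TOY",
) -> list[ParticleLabels]:
    """Uniform labels for generated ensembles, one residue per particle."""
    return [
        ParticleLabels(
            name=name if name is not None else element,
            resid=i,
            resname=resname,
            element=element,
        )
        for i in range(n_particles)
    ]


def uniform_masses(n_particles: int, element: str = "C") -> np.ndarray:
    return np.full(n_particles, mass_for_element(element))
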