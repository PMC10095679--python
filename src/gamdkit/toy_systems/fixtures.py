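"""Small molecular fixtures with controllable interaction geometry."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from gamdkit.toy_systems.trajectory import (
    ParticleLabels,
    TrajectoryEnsemble,
    mass_for_element,
)

#: canonical donor-hydrogen bond length used by generated fixtures, A
DH_BOND_LENGTH = 1.0


@dataclass
class MolecularFixture:
    """A trajectory plus the index bookkeeping interaction analyses need.

    All indices are 0-based and refer to particles of ``trajectory``.
    """

    trajectory: TrajectoryEnsemble
    hbond_triplets: list[tuple[int, int, int]] = field(default_factory=list)
    charged_pairs: list[tuple[int, int]] = field(default_factory=list)
    ring_groups: list[list[int]] = field(default_factory=list)
    ion_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.trajectory.n_particles
        flat = [i for t in self.hbond_triplets for i in t]
        flat += [i for p in self.charged_pairs for i in p]
        flat += [i for g in self.ring_groups for i in g]
        flat += list(self.ion_indices)
        if any(i < 0 or i >= n for i in flat):
            raise ValueError("fixture contains out-of-range particle indices")
        if any(len(g) < 3 for g in self.ring_groups):
            raise ValueError("each ring group needs at least 3 members")


def make_hbond_fixture(
    distance: float,
    angle: float,
    n_frames: int = 1,
    jitter: float = 0.0,
    seed: int = 0,
) -> MolecularFixture:
    """Three-particle donor-H-acceptor fixture.

    Frame 0 realizes the acceptor-donor ``distance`` (A) and the
    acceptor-H-donor ``angle`` (degrees, measured at the hydrogen) exactly;
    later frames add iid Gaussian ``jitter`` to every coordinate.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    if not 0 < angle <= 180:
        raise ValueError("angle must lie in (0, 180] degrees")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")

    theta = math.radians(angle)
    dh = DH_BOND_LENGTH
    disc = distance**2 - (dh * math.sin(theta)) ** 2
    if disc <= 0:
        raise ValueError(
            f"distance {distance} A unreachable at angle {angle} deg "
            f"with a {dh} A donor-H bond"
        )
    # acceptor placed in the xy-plane so that the angle at H is exact
    r_ha = dh * math.cos(theta) + math.sqrt(disc)
    donor = np.array([0.0, 0.0, 0.0])
    hydrogen = np.array([dh, 0.0, 0.0])
    acceptor = hydrogen + r_ha * np.array([-math.cos(theta), math.sin(theta), 0.0])

    base = np.stack([donor, hydrogen, acceptor])
    coords = np.broadcast_to(base, (n_frames, 3, 3)).copy()
    if jitter > 0 and n_frames > 1:
        rng = np.random.default_rng(seed)
        coords[1:] += jitter * rng.standard_normal((n_frames - 1, 3, 3))

    labels = [
        ParticleLabels(name="N", resid=0, resname="DON", element="N"),
        ParticleLabels(name="H", resid=0, resname="DON", element="H"),
        ParticleLabels(name="O", resid=1, resname="ACC", element="O"),
    ]
    masses = np.array([mass_for_element(lb.element) for lb in labels])
    traj = TrajectoryEnsemble(
        coordinates=coords,
        labels=labels,
        masses=masses,
        metadata={
            "generator": "hbond_fixture",
            "distance": distance,
            "angle": angle,
            "jitter": jitter,
            "seed": seed,
        },
    )
    return MolecularFixture(trajectory=traj, hbond_triplets=[(0, 1, 2)])


def make_two_state_ensemble(
    n_frames: int,
    populations: tuple[float, float] = (0.7, 0.3),
    centers: tuple[float, float] = (10.0, 14.0),
    width: float = 0.3,
    seed: int = 0,
) -> TrajectoryEnsemble:
    """Two-particle ensemble whose inter-particle distance is a two-component
    Gaussian mixture with known state populations.

    The distance between particles 0 and 1 is the reaction coordinate; its
    exact stationary density is ``p1 N(c1, w) + p2 N(c2, w)``.
    """
    p1, p2 = populations
    if not math.isclose(p1 + p2, 1.0, abs_tol=1e-9) or p1 <= 0 or p2 <= 0:
        raise ValueError("populations must be positive and sum to 1")
    if width <= 0:
        raise ValueError("width must be positive")
    rng = np.random.default_rng(seed)
    state = rng.random(n_frames) < p2
    d = rng.normal(np.where(state, centers[1], centers[0]), width)

    coords = np.zeros((n_frames, 2, 3))
    coords[:, 1, 0] = d
    labels = [
        ParticleLabels(name="CA", resid=0, resname="ALA", element="C"),
        ParticleLabels(name="CA", resid=1, resname="ALA", element="C"),
    ]
    return TrajectoryEnsemble(
        coordinates=coords,
        labels=labels,
        masses=np.array([12.011, 12.011]),
        metadata={
            "generator": "two_state",
            "populations": populations,
            "centers": centers,
            "width": width,
            "seed": seed,
            "state_series": state,
        },
    )
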