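import numpy as np
import pytest

from gamdkit.toy_systems import (
    PlantedModeSpec,
    generate_planted_trajectory,
    random_orthonormal_modes,
)
from gamdkit.toy_systems.trajectory import (
    ParticleLabels,
    TrajectoryEnsemble,
    generic_labels,
    uniform_masses,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_trajectory(n_frames, n_particles, seed=0, scale=3.0):
    """Unstructured Gaussian-blob ensemble used by oracle-equivalence tests."""
    r = np.random.default_rng(seed)
    base = scale * r.standard_normal((n_particles, 3))
    coords = base + 0.5 * r.standard_normal((n_frames, n_particles, 3))
    return TrajectoryEnsemble(
        coordinates=coords,
        labels=generic_labels(n_particles),
        masses=uniform_masses(n_particles),
    )


@pytest.fixture
def small_random_traj():
    return random_trajectory(n_frames=10, n_particles=5, seed=1)


def planted_system(n_particles, n_modes, amplitudes, noise_sigma, seed,
                   autocorr=0.0, n_frames=2000):
    """A planted-mode ensemble plus its spec, rigid-body-free modes."""
    r = np.random.default_rng(seed + 1000)
    mean = 5.0 * r.standard_normal((n_particles, 3))
    modes = random_orthonormal_modes(
        n_particles, n_modes, seed, mean_structure=mean
    )
    spec = PlantedModeSpec(
        mode_vectors=modes,
        amplitudes=np.asarray(amplitudes, dtype=float),
        autocorrelation=autocorr,
        noise_sigma=noise_sigma,
        seed=seed,
        mean_structure=mean,
    )
    traj = generate_planted_trajectory(n_particles, n_frames, spec)
    return traj, spec


def make_traj(coords, element="C"):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    return TrajectoryEnsemble(
        coordinates=coords,
        labels=generic_labels(n, element=element),
        masses=uniform_masses(n, element=element),
    )
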