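import numpy as np
import pytest

from gamdkit.structure_metrics import (
    DistributionSummary,
    Selection,
    delta_rmsf,
    kabsch_superpose,
    probability_distribution,
    radius_of_gyration,
    rc_distance_series,
    rc_from_selection_pair,
    rmsd_series,
    rmsf,
    select,
)
from gamdkit.toy_systems.trajectory import (
    ParticleLabels,
    TrajectoryEnsemble,
)

from conftest import make_traj, planted_system, random_trajectory


def rotation_z(deg):
    t = np.radians(deg)
    return np.array([
        [np.cos(t), -np.sin(t), 0.0],
        [np.sin(t), np.cos(t), 0.0],
        [0.0, 0.0, 1.0],
    ])


def quaternion_grid_rmsd(mobile, reference, n=40):
    """Brute-force oracle: minimize RMSD over a dense grid of unit
    quaternions (independent of the Kabsch path)."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    rng = np.random.default_rng(123)
    best = np.inf
    # dense random cover of SO(3) plus local refinement
    quats = rng.standard_normal((n**3, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    radius = 0.05
    for _ in range(5):
        for q in quats:
            w, x, y, z = q
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])
            r = np.sqrt(np.mean(np.sum((mob @ rot.T - ref) ** 2, axis=1)))
            if r < best:
                best = r
                best_q = q
        # refine around the best quaternion with a shrinking radius
        quats = best_q + radius * rng.standard_normal((2000, 4))
        quats /= np.linalg.norm(quats, axis=1, keepdims=True)
        radius *= 0.1
    return best


class TestKabsch:
    def test_identity_case(self):
        ref = np.random.default_rng(0).standard_normal((6, 3))
        rot, trans, rmsd = kabsch_superpose(ref, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-10)
        assert np.allclose(trans, 0.0, atol=1e-10)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        ref = rng.standard_normal((8, 3))
        mob = ref @ rotation_z(37.0).T + np.array([1.0, -2.0, 3.0])
        rot, trans, rmsd = kabsch_superpose(mob, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(mob @ rot.T + trans, ref, atol=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)

    def test_quaternion_grid_oracle(self):
        rng = np.random.default_rng(2)
        ref = rng.standard_normal((5, 3)) * 2.0
        mob = ref.copy()
        mob[2] += np.array([1.0, 0.0, 0.0])  # one particle displaced 1 A
        mob = mob @ rotation_z(25.0).T + 0.5
        _, _, rmsd = kabsch_superpose(mob, ref)
        oracle = quaternion_grid_rmsd(mob, ref, n=25)
        assert rmsd <= oracle + 1e-9  # Kabsch is the true optimum
        assert rmsd == pytest.approx(oracle, abs=1e-6)

    def test_reflection_excluded(self):
        rng = np.random.default_rng(3)
        ref = rng.standard_normal((10, 3))
        mob = ref * np.array([1.0, 1.0, -1.0])  # mirrored
        rot, _, rmsd = kabsch_superpose(mob, ref)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)
        assert rmsd > 0.1

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            kabsch_superpose(line, line)
        two = np.random.default_rng(0).standard_normal((2, 3))
        with pytest.raises(ValueError):
            kabsch_superpose(two, two)

    def test_weighted_fit(self):
        rng = np.random.default_rng(4)
        ref = rng.standard_normal((6, 3))
        mob = ref.copy()
        mob[0] += 5.0
        w = np.array([0.0, 1, 1, 1, 1, 1])
        _, _, rmsd = kabsch_superpose(mob, ref, weights=w)
        assert rmsd == pytest.approx(0.0, abs=1e-9)


class TestSelection:
    def _traj(self):
        labels = [
            ParticleLabels("CA", 0, "ALA", "C"),
            ParticleLabels("N", 0, "ALA", "N"),
            ParticleLabels("H", 0, "ALA", "H"),
            ParticleLabels("CA", 1, "GLY", "C"),
            ParticleLabels("O", 1, "GLY", "O"),
        ]
        coords = np.zeros((2, 5, 3))
        return TrajectoryEnsemble(coords, labels, np.ones(5))

    def test_name(self):
        assert select(self._traj(), "name CA").indices.tolist() == [0, 3]

    def test_not_element(self):
        got = select(self._traj(), "protein and not element H")
        assert got.indices.tolist() == [0, 1, 3, 4]

    def test_resid_range_one_based(self):
        assert select(self._traj(), "resid 2-2").indices.tolist() == [3, 4]

    def test_boolean_combinations(self):
        got = select(self._traj(), "name CA or (element O and resid 2)")
        assert got.indices.tolist() == [0, 3, 4]

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            select(self._traj(), "name XX")


class TestRMSD:
    def test_identical_frames_zero(self):
        base = np.random.default_rng(22).standard_normal((5, 3))
        traj = make_traj(np.broadcast_to(base, (4, 5, 3)).copy())
        assert np.allclose(rmsd_series(traj), 0.0, atol=1e-12)

    def test_rigid_motions_zero(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal((6, 3)) * 3
        frames = [base]
        for deg in (10, 120, 250):
            frames.append(base @ rotation_z(deg).T + rng.standard_normal(3))
        traj = make_traj(np.stack(frames))
        assert np.allclose(rmsd_series(traj), 0.0, atol=1e-9)

    def test_matches_per_frame_oracle(self):
        traj = random_trajectory(10, 6, seed=6)
        series = rmsd_series(traj, reference_frame=0)
        for f in range(10):
            _, _, r = kabsch_superpose(
                traj.coordinates[f], traj.coordinates[0]
            )
            assert series[f] == pytest.approx(r, abs=1e-12)


class TestRMSF:
    def test_static_zero(self):
        coords = np.broadcast_to(
            np.random.default_rng(0).standard_normal((5, 3)), (4, 5, 3)
        ).copy()
        prof = rmsf(make_traj(coords))
        assert np.allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_single_oscillator_closed_form(self):
        # anchor particles well spread so there is no net rigid-body motion
        base = np.array([
            [0.0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10], [5, 5, 5.0],
        ])
        d = 0.3
        coords = np.broadcast_to(base, (100, 5, 3)).copy()
        coords[::2, 4, 0] += d
        coords[1::2, 4, 0] -= d
        prof = rmsf(make_traj(coords), align=False)
        assert prof.rmsf[4] == pytest.approx(d, abs=1e-12)
        assert np.allclose(prof.rmsf[:4], 0.0, atol=1e-12)

    def test_planted_generator_oracle(self):
        # oracle: per-particle std from the generator's own records
        traj, spec = planted_system(12, 1, [0.8], 0.05, seed=8,
                                    n_frames=12000)
        disp = traj.coordinates - spec.mean_structure
        oracle = np.sqrt((disp**2).sum(axis=2).mean(axis=0))
        prof = rmsf(traj, align=True)
        assert np.allclose(prof.rmsf, oracle, rtol=0.08)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            rmsf(make_traj(np.zeros((1, 4, 3))))

    def test_scale_equivariance(self):
        traj = random_trajectory(20, 5, seed=9)
        a = rmsf(traj, align=False).rmsf
        b = rmsf(traj.with_coordinates(3.0 * traj.coordinates),
                 align=False).rmsf
        assert np.allclose(b, 3.0 * a, rtol=1e-10)


class TestDeltaRMSF:
    def test_self_difference_zero_and_antisymmetric(self):
        traj = random_trajectory(10, 5, seed=10)
        a = rmsf(traj)
        assert np.all(delta_rmsf(a, a) == 0.0)
        b = rmsf(random_trajectory(10, 5, seed=11))
        assert np.allclose(delta_rmsf(a, b), -delta_rmsf(b, a))

    def test_constant_offset(self):
        traj = random_trajectory(10, 5, seed=12)
        a = rmsf(traj)
        b = rmsf(traj)
        b.rmsf = a.rmsf + 0.5
        assert np.allclose(delta_rmsf(b, a), 0.5)

    def test_planted_known_stds(self):
        # closed form: isotropic noise gives rmsf sqrt(3) sigma per particle
        t1, _ = planted_system(8, 0, [], 0.2, seed=13, n_frames=8000)
        t2, _ = planted_system(8, 0, [], 0.1, seed=14, n_frames=8000)
        d = delta_rmsf(rmsf(t1, align=False), rmsf(t2, align=False))
        expected = np.sqrt(3) * (0.2 - 0.1)
        assert np.allclose(d, expected, atol=0.02)

    def test_length_mismatch(self):
        a = rmsf(random_trajectory(5, 4, seed=0))
        b = rmsf(random_trajectory(5, 6, seed=0))
        with pytest.raises(ValueError):
            delta_rmsf(a, b)


class TestRadiusOfGyration:
    def test_coincident_zero(self):
        traj = make_traj(np.zeros((3, 4, 3)))
        assert np.allclose(radius_of_gyration(traj), 0.0)

    def test_two_equal_masses(self):
        d = 1.7
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 2 * d
        traj = make_traj(coords)
        assert radius_of_gyration(traj)[0] == pytest.approx(d, abs=1e-12)

    def test_direct_sum_oracle(self):
        traj = random_trajectory(3, 20, seed=15)
        rg = radius_of_gyration(traj, mass_weighted=True)
        for f in range(3):
            m = traj.masses
            r = traj.coordinates[f]
            com = (m[:, None] * r).sum(axis=0) / m.sum()
            oracle = np.sqrt(
                (m * ((r - com) ** 2).sum(axis=1)).sum() / m.sum()
            )
            assert rg[f] == pytest.approx(oracle, abs=1e-10)

    def test_rigid_motion_invariance(self):
        traj = random_trajectory(2, 8, seed=16)
        moved = traj.with_coordinates(
            traj.coordinates @ rotation_z(77.0).T + np.array([4.0, 5.0, 6.0])
        )
        assert np.allclose(
            radius_of_gyration(traj), radius_of_gyration(moved), atol=1e-9
        )


class TestDistanceSeries:
    def test_coincident(self):
        traj = make_traj(np.zeros((2, 2, 3)))
        assert np.all(rc_distance_series(traj, 0, 1) == 0.0)

    def test_3_4_5(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1] = [3.0, 4.0, 0.0]
        assert rc_distance_series(make_traj(coords), 0, 1)[0] == pytest.approx(5.0)

    def test_jittered_oracle(self):
        traj = random_trajectory(50, 4, seed=17)
        d = rc_distance_series(traj, 1, 3)
        oracle = np.array([
            np.sqrt(((traj.coordinates[f, 1] - traj.coordinates[f, 3]) ** 2).sum())
            for f in range(50)
        ])
        assert np.allclose(d, oracle, atol=1e-12)

    def test_lookup_by_residue_and_name(self):
        labels = [
            ParticleLabels("CA", 31, "TYR", "C"),
            ParticleLabels("CA", 60, "GLN", "C"),
        ]
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 7.0
        traj = TrajectoryEnsemble(coords, labels, np.ones(2))
        d = rc_from_selection_pair(traj, 32, "CA", 61, "CA")
        assert d[0] == pytest.approx(7.0)
        with pytest.raises(LookupError, match="Q99"):
            rc_from_selection_pair(traj, 99, "Q99", 61, "CA")

    def test_invalid_index(self):
        with pytest.raises(IndexError):
            rc_distance_series(make_traj(np.zeros((1, 2, 3))), 0, 5)


class TestProbabilityDistribution:
    def test_gaussian_single_peak(self):
        rng = np.random.default_rng(18)
        x = rng.normal(2.08, 0.05, 100_000)
        dist = probability_distribution(x, bin_width=0.02)
        assert len(dist.peak_positions) >= 1
        assert dist.peak_positions[0] == pytest.approx(2.08, abs=0.02)

    def test_balanced_bimodal_two_peaks(self):
        rng = np.random.default_rng(19)
        x = np.concatenate([
            rng.normal(1.9, 0.1, 50_000), rng.normal(4.56, 0.1, 50_000)
        ])
        dist = probability_distribution(x, bin_width=0.05, smooth=True)
        top2 = sorted(dist.peak_positions[:2])
        assert top2[0] == pytest.approx(1.9, abs=0.05)
        assert top2[1] == pytest.approx(4.56, abs=0.05)

    def test_constant_series_single_delta_bin(self):
        dist = probability_distribution(np.full(100, 3.3))
        assert len(dist.peak_positions) == 1
        assert dist.peak_positions[0] == pytest.approx(3.3)

    def test_unit_area(self):
        rng = np.random.default_rng(20)
        dist = probability_distribution(rng.exponential(1.0, 5000), 0.1)
        width = np.diff(dist.bin_edges)
        assert (dist.density * width).sum() == pytest.approx(1.0, abs=1e-9)

    def test_peaks_sorted_by_height(self):
        rng = np.random.default_rng(21)
        x = np.concatenate([
            rng.normal(0.0, 0.1, 70_000), rng.normal(2.0, 0.1, 30_000)
        ])
        dist = probability_distribution(x, bin_width=0.05, smooth=True)
        assert dist.peak_positions[0] == pytest.approx(0.0, abs=0.05)
        assert np.all(np.diff(dist.peak_heights) <= 1e-12)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            probability_distribution(np.arange(5), 0.1)
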