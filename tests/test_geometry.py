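import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mesopath.geometry import (
    DegenerateGeometryError,
    DistanceMatrix,
    Frame,
    SelectionPair,
    Trajectory,
    classify_binding_ensemble,
    kabsch_superpose,
    pairwise_rmsd_matrix,
    rmsd,
    rmsd_to_reference_series,
)

from conftest import random_rotation_matrix


def grid_search_min_rmsd(P, Q, coarse_deg=10, fine_deg=1):
    """Rotation-grid oracle: minimum RMSD between centered point sets.

    Sweeps all Euler-angle triples at a coarse step, then refines at
    ``fine_deg`` resolution around the best coarse triple.
    """
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def sweep(grids):
        angles = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
        R = Rotation.from_euler("zyx", angles, degrees=True).as_matrix()
        moved = np.einsum("rij,aj->rai", R, Pc)
        msd = ((moved - Qc) ** 2).sum(axis=2).mean(axis=1)
        best = int(np.argmin(msd))
        return np.sqrt(msd[best]), angles[best]

    coarse = [np.arange(-180, 180, coarse_deg)] * 3
    _, a0 = sweep(coarse)
    fine = [a + np.arange(-coarse_deg, coarse_deg + fine_deg, fine_deg) for a in a0]
    val, _ = sweep(fine)
    return val


class TestKabsch:
    def test_identity_when_frames_equal(self, random_frame):
        f = random_frame(6)
        R, t, aligned = kabsch_superpose(f, f, np.arange(6))
        assert np.allclose(R, np.eye(3), atol=1e-10)
        assert np.allclose(t, 0.0, atol=1e-10)
        assert np.allclose(aligned.coords, f.coords, atol=1e-10)

    def test_recovers_rigid_motion(self, random_frame):
        f = random_frame(7)
        R37 = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        moved = Frame(coords=f.coords @ R37.T + np.array([1.0, -2.0, 0.5]))
        _, _, aligned = kabsch_superpose(moved, f, np.arange(7))
        assert np.abs(aligned.coords - f.coords).max() < 1e-10

    def test_rotation_is_proper(self, rng, random_frame):
        for _ in range(5):
            a, b = random_frame(5), random_frame(5)
            R, _, _ = kabsch_superpose(a, b, np.arange(5))
            assert np.isclose(np.linalg.det(R), 1.0, atol=1e-10)

    @pytest.mark.parametrize("n_atoms", [4, 6])
    def test_matches_rotation_grid_oracle(self, rng, full_selection, n_atoms):
        """Kabsch minimum equals a brute-force Euler-grid search."""
        for _ in range(3):
            P = rng.normal(0.0, 2.0, size=(n_atoms, 3))
            Q = rng.normal(0.0, 2.0, size=(n_atoms, 3))
            fitted = rmsd(Frame(P), Frame(Q), full_selection(n_atoms))
            bruteforce = grid_search_min_rmsd(P, Q)
            assert bruteforce >= fitted - 1e-9  # oracle cannot beat the optimum
            assert abs(fitted - bruteforce) < 1e-3

    def test_collinear_alignment_rejected(self):
        line = Frame(coords=np.c_[np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line, np.arange(5))


class TestRmsd:
    def test_zero_for_identical_frames(self, random_frame, full_selection):
        f = random_frame(5)
        assert rmsd(f, f, full_selection(5)) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_displacement_of_measure_set(self, rng):
        # align on atoms 0-3, measure atoms 4-6 displaced by (1,0,0)
        coords = rng.normal(0.0, 3.0, size=(7, 3))
        sel = SelectionPair(align_set=np.arange(4), measure_set=np.arange(4, 7))
        shifted = coords.copy()
        shifted[4:] += np.array([1.0, 0.0, 0.0])
        assert rmsd(Frame(shifted), Frame(coords), sel) == pytest.approx(1.0, abs=1e-10)

    def test_symmetric_in_arguments(self, random_frame, full_selection):
        a, b = random_frame(6), random_frame(6)
        sel = full_selection(6)
        assert rmsd(a, b, sel) == pytest.approx(rmsd(b, a, sel), abs=1e-9)

    def test_matches_explicit_arithmetic_after_grid_alignment(self, rng, full_selection):
        """sqrt(mean squared deviation) computed independently agrees."""
        P = rng.normal(0.0, 2.0, size=(5, 3))
        Q = rng.normal(0.0, 2.0, size=(5, 3))
        assert rmsd(Frame(P), Frame(Q), full_selection(5)) == pytest.approx(
            grid_search_min_rmsd(P, Q), abs=1e-3
        )

    def test_invariant_under_common_rigid_motion(self, rng, random_frame, full_selection):
        a, b = random_frame(6), random_frame(6)
        sel = full_selection(6)
        base = rmsd(a, b, sel)
        for _ in range(5):
            R = random_rotation_matrix(rng)
            t = rng.uniform(-10, 10, 3)
            a2 = Frame(coords=a.coords @ R.T + t)
            b2 = Frame(coords=b.coords @ R.T + t)
            assert abs(rmsd(a2, b2, sel) - base) < 1e-8


class TestPairwiseMatrix:
    def test_identical_frames_give_zero_matrix(self, rng, full_selection):
        f = rng.normal(0.0, 2.0, size=(6, 3))
        traj = Trajectory(coords=np.repeat(f[None], 4, axis=0))
        D = pairwise_rmsd_matrix(traj, full_selection(6))
        assert np.abs(D.values).max() < 1e-10

    def test_matches_individual_rmsd_calls(self, rng, full_selection):
        traj = Trajectory(coords=rng.normal(0.0, 2.0, size=(3, 6, 3)))
        sel = full_selection(6)
        D = pairwise_rmsd_matrix(traj, sel)
        for i in range(3):
            for j in range(i + 1, 3):
                expected = rmsd(traj.frame(i), traj.frame(j), sel)
                assert D.values[i, j] == pytest.approx(expected, abs=1e-9)

    def test_rigid_copies_collapse_to_zero(self, rng, full_selection):
        base = rng.normal(0.0, 2.0, size=(6, 3))
        frames = [
            base @ random_rotation_matrix(rng).T + rng.uniform(-10, 10, 3) for _ in range(5)
        ]
        D = pairwise_rmsd_matrix(Trajectory(coords=np.stack(frames)), full_selection(6))
        assert np.abs(D.values).max() < 1e-8

    def test_symmetry_and_zero_diagonal_validated(self, rng):
        bad = rng.uniform(1, 2, size=(4, 4))
        with pytest.raises(ValueError):
            DistanceMatrix(values=bad)

    def test_msd_metric_is_squared_rmsd(self, rng, full_selection):
        traj = Trajectory(coords=rng.normal(0.0, 2.0, size=(3, 5, 3)))
        sel = full_selection(5)
        Dr = pairwise_rmsd_matrix(traj, sel, metric="RMSD")
        Dm = pairwise_rmsd_matrix(traj, sel, metric="MSD")
        assert np.allclose(Dm.values, Dr.values**2, atol=1e-9)


class TestReferenceSeries:
    def test_repeated_reference_gives_zeros(self, rng, full_selection):
        ref = rng.normal(0.0, 2.0, size=(6, 3))
        traj = Trajectory(coords=np.repeat(ref[None], 5, axis=0))
        series = rmsd_to_reference_series(traj, Frame(ref), full_selection(6))
        assert series.shape == (5,)
        assert np.abs(series).max() < 1e-10

    def test_bound_state_noise_stays_small(self, rng, full_selection):
        ref = rng.normal(0.0, 3.0, size=(20, 3))
        noisy = ref[None] + rng.normal(0.0, 0.2, size=(50, 20, 3))
        series = rmsd_to_reference_series(Trajectory(coords=noisy), Frame(ref), full_selection(20))
        assert series.mean() < 0.5


class TestEnsembleClassifier:
    @pytest.mark.parametrize(
        "tail_mean,label",
        [
            (0.59, "A"),
            (1.5, "intermediate"),
            (2.8, "B"),
            (3.5, "C"),
            (5.0, "unbound"),
        ],
    )
    def test_threshold_mapping(self, tail_mean, label):
        series = np.full(100, tail_mean)
        assert classify_binding_ensemble(series) == label

    def test_only_tail_matters(self):
        series = np.concatenate([np.full(90, 8.0), np.full(10, 0.5)])
        assert classify_binding_ensemble(series, tail_fraction=0.1) == "A"
        assert classify_binding_ensemble(series, tail_fraction=1.0) == "unbound"

    def test_rejects_negative_series_and_bad_fraction(self):
        with pytest.raises(ValueError):
            classify_binding_ensemble(np.array([1.0, -0.1]))
        with pytest.raises(ValueError):
            classify_binding_ensemble(np.array([1.0]), tail_fraction=0.0)
        with pytest.raises(ValueError):
            classify_binding_ensemble(np.array([]))
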