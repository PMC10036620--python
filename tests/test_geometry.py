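import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from gpcrdyn.geometry import (
    activation_cv,
    angle_deg,
    centroid,
    cv_table,
    ecl2_cv,
    kabsch_superpose,
    rmsf_profile,
)
from gpcrdyn.synthetic import SyntheticSpec, generate_receptor_trajectory
from gpcrdyn.traj_model import Trajectory, default_bw_map

from conftest import make_topology, random_rigid_transform


class TestCentroid:
    def test_single_atom(self):
        assert np.allclose(centroid(np.array([[1.0, 2, 3]]), [0]), [1, 2, 3])

    def test_equal_mass_midpoint(self):
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert np.allclose(centroid(frame, [0, 1]), [1, 0, 0])

    def test_square_symmetry(self):
        frame = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        assert np.allclose(centroid(frame, [0, 1, 2, 3]), [0.5, 0.5, 0])

    def test_mass_weighting(self):
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        masses = np.array([1.0, 3.0])
        assert np.allclose(centroid(frame, [0, 1], masses), [0.75, 0, 0])

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError):
            centroid(np.zeros((2, 3)), [])


class TestAngle:
    @pytest.mark.parametrize(
        "p1,v,p2,expected",
        [
            ([-1, 0, 0], [0, 0, 0], [1, 0, 0], 180.0),
            ([1, 0, 0], [0, 0, 0], [0, 1, 0], 90.0),
            ([1, 0, 0], [0.5, np.sqrt(3) / 2, 0], [0, 0, 0], 60.0),
        ],
    )
    def test_reference_angles(self, p1, v, p2, expected):
        assert angle_deg(np.array(p1, float), np.array(v, float), np.array(p2, float)) == pytest.approx(expected)

    def test_zero_arm_errors(self):
        with pytest.raises(ValueError):
            angle_deg(np.zeros(3), np.zeros(3), np.ones(3))


class TestKabsch:
    def test_identical_structures_zero_rmsd(self, rng):
        X = rng.normal(size=(10, 3))
        _, val = kabsch_superpose(X, X)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_recovered(self, rng):
        X = rng.normal(size=(12, 3)) * 5
        R, t = random_rigid_transform(rng)
        _, val = kabsch_superpose(X @ R.T + t, X)
        assert val <= 1e-6

    def test_matches_quaternion_minimization(self, rng):
        """Independent oracle: best-of-random rotations refined by
        Nelder-Mead over the rotation vector, translation by centroids."""
        P = rng.normal(size=(10, 3)) * 3
        Q = rng.normal(size=(10, 3)) * 3
        _, kabsch_val = kabsch_superpose(P, Q)

        P0 = P - P.mean(axis=0)
        Q0 = Q - Q.mean(axis=0)

        def cost(rotvec):
            Rm = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(((P0 @ Rm.T - Q0) ** 2).sum(axis=1).mean())

        rots = Rotation.random(2000, random_state=np.random.RandomState(7))
        vals = [cost(r.as_rotvec()) for r in rots]
        best = rots[int(np.argmin(vals))].as_rotvec()
        res = minimize(cost, best, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        assert kabsch_val == pytest.approx(res.fun, abs=1e-3)
        assert kabsch_val <= res.fun + 1e-9

    def test_beats_random_rigid_transforms(self, rng):
        P = rng.normal(size=(8, 3)) * 4
        Q = rng.normal(size=(8, 3)) * 4
        _, kabsch_val = kabsch_superpose(P, Q)
        for _ in range(50):
            R, t = random_rigid_transform(rng)
            alt = np.sqrt(((P @ R.T + t - Q) ** 2).sum(axis=1).mean())
            assert kabsch_val <= alt + 1e-9

    def test_too_few_or_collinear_atoms_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestCollectiveVariables:
    def test_constructed_delta_is_exact(self):
        # tip placed exactly 30 A from the TM centroid by the generator
        spec = SyntheticSpec(n_frames=1, p_closed=1.0, noise_sd=0.0, closed_geometry=(30.0, 38.5), seed=0)
        traj, _ = generate_receptor_trajectory(spec)
        d, b = ecl2_cv(traj, default_bw_map())
        assert d.values[0] == pytest.approx(30.0, abs=1e-9)
        assert b.values[0] == pytest.approx(38.5, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        spec = SyntheticSpec(n_frames=3, p_closed=0.5, seed=5)
        traj, _ = generate_receptor_trajectory(spec)
        bw = default_bw_map()
        d1, b1 = ecl2_cv(traj, bw)
        a1, t1 = activation_cv(traj)
        R, t = random_rigid_transform(rng)
        moved = Trajectory(traj.topology, traj.coords @ R.T + t)
        d2, b2 = ecl2_cv(moved, bw)
        a2, t2 = activation_cv(moved)
        for x, y in [(d1, d2), (b1, b2), (a1, a2), (t1, t2)]:
            assert np.abs(x.values - y.values).max() <= 1e-6

    def test_activation_distance_by_construction(self):
        specs = [("CA", "C", "CYS", r, "A") for r in (80, 225, 255, 268, 305)]
        coords = np.array(
            [[[0, 10, 0], [0.0, 0, 0], [5, 5, 0], [0, 5, 0], [19.0, 0, 0]]]
        )
        traj = Trajectory(make_topology(specs), coords)
        d, theta = activation_cv(traj)
        assert d.values[0] == pytest.approx(19.0)

    def test_collinear_activation_angle_is_180(self):
        specs = [("CA", "C", "CYS", r, "A") for r in (80, 225, 255, 268, 305)]
        # 255, 268, 80 collinear with 268 between the other two
        coords = np.array([[[2.0, 0, 0], [9, 9, 9], [-2.0, 0, 0], [0.0, 0, 0], [5, 5, 5]]])
        traj = Trajectory(make_topology(specs), coords)
        _, theta = activation_cv(traj)
        assert theta.values[0] == pytest.approx(180.0)

    def test_missing_residue_named_in_error(self):
        specs = [("CA", "C", "CYS", r, "A") for r in (80, 225, 255, 268)]  # no 305
        traj = Trajectory(make_topology(specs), np.zeros((1, 4, 3)) + np.arange(4)[None, :, None])
        with pytest.raises(ValueError, match="305"):
            activation_cv(traj)

    def test_frame_reordering_permutes_values(self):
        spec = SyntheticSpec(n_frames=6, p_closed=0.5, seed=9)
        traj, _ = generate_receptor_trajectory(spec)
        bw = default_bw_map()
        d1, _ = ecl2_cv(traj, bw)
        perm = np.array([3, 0, 5, 1, 4, 2])
        d2, _ = ecl2_cv(Trajectory(traj.topology, traj.coords[perm]), bw)
        assert np.allclose(d2.values, d1.values[perm])


def _four_atom_fluctuation_traj(a):
    """Three fixed (non-collinear) anchor residues plus one residue
    alternating x = +a / -a."""
    specs = [("CA", "C", "ALA", r, "A") for r in (1, 2, 3, 4)]
    base = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [5, 5, 5]])
    f1 = base.copy()
    f2 = base.copy()
    f1[3, 0] += a
    f2[3, 0] -= a
    return Trajectory(make_topology(specs), np.stack([f1, f2]))


class TestRMSF:
    def test_static_trajectory_zero_profile(self):
        traj = _four_atom_fluctuation_traj(0.0)
        prof = rmsf_profile(traj, [0, 1, 2], [0, 1, 2, 3])
        assert np.allclose(prof.rmsf, 0)
        assert prof.integral == 0.0

    def test_two_point_alternation_gives_amplitude(self):
        a = 0.8
        traj = _four_atom_fluctuation_traj(a)
        prof = rmsf_profile(traj, [0, 1, 2], [3])
        assert prof.rmsf[0] == pytest.approx(a, abs=1e-9)

    def test_constant_profile_integral_closed_form(self):
        # N residues all fluctuating with amplitude a -> integral a*(N-1)
        a, N = 0.5, 6
        specs = [("CA", "C", "ALA", r, "A") for r in range(1, N + 4)]
        base = np.zeros((N + 3, 3))
        base[:3] = [[0, 0, 0], [10, 0, 0], [0, 10, 0]]
        base[3:] = [[5.0 + 3 * i, 20, 0] for i in range(N)]
        f1, f2 = base.copy(), base.copy()
        f1[3:, 2] += a
        f2[3:, 2] -= a
        traj = Trajectory(make_topology(specs), np.stack([f1, f2]))
        prof = rmsf_profile(traj, [0, 1, 2], list(range(3, N + 3)))
        assert np.allclose(prof.rmsf, a)
        assert prof.integral == pytest.approx(a * (N - 1))

    def test_homogeneous_scaling(self):
        p1 = rmsf_profile(_four_atom_fluctuation_traj(0.4), [0, 1, 2], [3])
        p2 = rmsf_profile(_four_atom_fluctuation_traj(0.8), [0, 1, 2], [3])
        assert p2.rmsf[0] == pytest.approx(2 * p1.rmsf[0])

    def test_single_frame_errors(self):
        traj = _four_atom_fluctuation_traj(0.1)[0]
        with pytest.raises(ValueError):
            rmsf_profile(traj, [0, 1, 2], [3])


def test_cv_table_is_tidy():
    spec = SyntheticSpec(n_frames=4, p_closed=0.5, seed=2)
    traj, _ = generate_receptor_trajectory(spec)
    d, b = ecl2_cv(traj, default_bw_map(), replica_id=7)
    df = cv_table([d, b])
    assert list(df.columns) == ["replica", "frame", "cv_name", "value"]
    assert len(df) == 8
    assert set(df["replica"]) == {7}
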