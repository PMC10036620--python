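import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gpcrdyn.cluster import (
    hierarchical_cluster,
    pairwise_ligand_rmsd,
    representative_rmsd_to_reference,
)
from gpcrdyn.traj_model import Trajectory

from conftest import make_topology, random_rigid_transform


def brute_force_agglomerate(D, k, linkage="average"):
    """Naive reference agglomeration: clusters as frozensets, inter-cluster
    distance recomputed from the original matrix at every step."""
    clusters = [frozenset([i]) for i in range(len(D))]

    def dist(a, b):
        vals = [D[i, j] for i in a for j in b]
        if linkage == "average":
            return float(np.mean(vals))
        if linkage == "complete":
            return float(np.max(vals))
        return float(np.min(vals))

    while len(clusters) > k:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = dist(clusters[x], clusters[y])
                if best is None or d < best[0]:
                    best = (d, x, y)
        _, x, y = best
        merged = clusters[x] | clusters[y]
        clusters = [c for i, c in enumerate(clusters) if i not in (x, y)] + [merged]
    labels = np.empty(len(D), dtype=int)
    for ci, c in enumerate(clusters):
        for i in c:
            labels[i] = ci
    return labels


def same_partition(a, b):
    return len(set(zip(a, b))) == len(set(a)) == len(set(b))


def _ligand_traj(rng, n_frames=4):
    """Receptor of 4 CA anchors plus a 3-atom ligand; ligand jitters, each
    frame additionally carries a random rigid motion of everything."""
    specs = [("CA", "C", "ALA", r, "A") for r in (1, 2, 3, 4)] + [
        ("C1", "C", "LIG", 10, "L"), ("C2", "C", "LIG", 10, "L"), ("N1", "N", "LIG", 10, "L")
    ]
    base = np.array(
        [[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10], [5, 5, 5], [6, 5, 5], [5, 6, 5]]
    )
    frames = []
    for _ in range(n_frames):
        f = base.copy()
        f[4:] += rng.normal(scale=1.0, size=(3, 3))
        R, t = random_rigid_transform(rng)
        frames.append(f @ R.T + t)
    return Trajectory(make_topology(specs), np.stack(frames))


class TestPairwiseRMSD:
    def test_symmetric_zero_diagonal(self, rng):
        traj = _ligand_traj(rng, 5)
        D = pairwise_ligand_rmsd(traj, [4, 5, 6], [0, 1, 2, 3])
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_duplicated_frame_pair_entry_zero(self, rng):
        traj = _ligand_traj(rng, 3)
        coords = np.concatenate([traj.coords, traj.coords[:1]], axis=0)
        dup = Trajectory(traj.topology, coords)
        D = pairwise_ligand_rmsd(dup, [4, 5, 6], [0, 1, 2, 3])
        assert D[0, 3] == pytest.approx(0.0, abs=1e-9)

    def test_matches_per_pair_recomputation(self, rng):
        """Independent oracle via scipy's rotation alignment per pair."""
        traj = _ligand_traj(rng, 4)
        lig, fit = [4, 5, 6], [0, 1, 2, 3]
        D = pairwise_ligand_rmsd(traj, lig, fit)
        for i in range(4):
            for j in range(4):
                A = traj.coords[i]
                B = traj.coords[j]
                rot, _ = Rotation.align_vectors(
                    A[fit] - A[fit].mean(axis=0), B[fit] - B[fit].mean(axis=0)
                )
                moved = rot.apply(B - B[fit].mean(axis=0)) + A[fit].mean(axis=0)
                expected = np.sqrt(((moved[lig] - A[lig]) ** 2).sum(axis=1).mean())
                assert D[i, j] == pytest.approx(expected, abs=1e-6)

    def test_empty_ligand_selection_errors(self, rng):
        with pytest.raises(ValueError):
            pairwise_ligand_rmsd(_ligand_traj(rng), [], [0, 1, 2, 3])


class TestHierarchicalCluster:
    def test_k_equals_n_singletons(self, rng):
        n = 5
        X = rng.normal(size=(n, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        res = hierarchical_cluster(D, k=n)
        assert sorted(res.labels) == list(range(1, n + 1))
        assert np.allclose(res.populations, 100.0 / n)
        for c in range(1, n + 1):
            assert res.labels[res.representatives[c - 1]] == c

    def test_planted_two_bundle_split(self, rng):
        n1, n2 = 6, 4
        D = np.zeros((n1 + n2, n1 + n2))
        for i in range(n1 + n2):
            for j in range(i + 1, n1 + n2):
                same = (i < n1) == (j < n1)
                D[i, j] = D[j, i] = rng.uniform(0.1, 0.9) if same else rng.uniform(10, 20)
        res = hierarchical_cluster(D, k=2)
        assert same_partition(res.labels, [0] * n1 + [1] * n2)
        assert res.populations[0] == pytest.approx(60.0)

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_six_frame_toy_matches_brute_force(self, linkage):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(6, 3))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        res = hierarchical_cluster(D, k=3, linkage_method=linkage)
        oracle = brute_force_agglomerate(D, 3, linkage)
        assert same_partition(res.labels, oracle)

    def test_average_linkage_equals_brute_force_over_many_seeds(self):
        for seed in range(120):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 9))
            k = int(rng.integers(2, n))
            X = rng.normal(size=(n, 3))
            D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
            res = hierarchical_cluster(D, k=k)
            oracle = brute_force_agglomerate(D, k)
            assert same_partition(res.labels, oracle), f"seed {seed}"

    def test_label_permutation_invariance(self, rng):
        X = rng.normal(size=(8, 3))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        res1 = hierarchical_cluster(D, k=3)
        perm = rng.permutation(8)
        res2 = hierarchical_cluster(D[np.ix_(perm, perm)], k=3)
        assert same_partition(res1.labels[perm], res2.labels)
        assert sorted(res1.populations) == pytest.approx(sorted(res2.populations))

    def test_representative_minimizes_mean_distance(self, rng):
        X = rng.normal(size=(7, 3))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        res = hierarchical_cluster(D, k=2)
        for c in range(1, 3):
            members = np.nonzero(res.labels == c)[0]
            rep = res.representatives[c - 1]
            rep_mean = D[rep, members].sum() / max(len(members) - 1, 1)
            for m in members:
                alt = D[m, members].sum() / max(len(members) - 1, 1)
                assert rep_mean <= alt + 1e-12

    def test_errors(self, rng):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError):
            hierarchical_cluster(D, k=4)
        bad = rng.normal(size=(3, 3))
        with pytest.raises(ValueError, match="symmetric"):
            hierarchical_cluster(bad, k=2)


class TestRepresentativeRMSD:
    def test_reference_equals_representative_gives_zero(self, rng):
        traj = _ligand_traj(rng, 4)
        D = pairwise_ligand_rmsd(traj, [4, 5, 6], [0, 1, 2, 3])
        res = hierarchical_cluster(D, k=2)
        ref = traj.coords[res.representatives[0]]
        vals = representative_rmsd_to_reference(res, traj, ref, [4, 5, 6], [0, 1, 2, 3])
        assert vals[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigidly_displaced_reference_gives_zero(self, rng):
        traj = _ligand_traj(rng, 3)
        D = pairwise_ligand_rmsd(traj, [4, 5, 6], [0, 1, 2, 3])
        res = hierarchical_cluster(D, k=1)
        R, t = random_rigid_transform(rng)
        ref = traj.coords[res.representatives[0]] @ R.T + t
        vals = representative_rmsd_to_reference(res, traj, ref, list(range(7)))
        assert vals[0] == pytest.approx(0.0, abs=1e-6)

    def test_toy_matches_hand_kabsch(self, rng):
        traj = _ligand_traj(rng, 3)
        D = pairwise_ligand_rmsd(traj, [4, 5, 6], [0, 1, 2, 3])
        res = hierarchical_cluster(D, k=1)
        ref = _ligand_traj(rng, 1).coords[0]
        sel = list(range(7))
        vals = representative_rmsd_to_reference(res, traj, ref, sel)
        A = traj.coords[res.representatives[0]]
        rot, _ = Rotation.align_vectors(ref - ref.mean(axis=0), A - A.mean(axis=0))
        moved = rot.apply(A - A.mean(axis=0)) + ref.mean(axis=0)
        expected = np.sqrt(((moved - ref) ** 2).sum(axis=1).mean())
        assert vals[0] == pytest.approx(expected, abs=1e-6)

    def test_shape_mismatch_errors(self, rng):
        traj = _ligand_traj(rng, 3)
        D = pairwise_ligand_rmsd(traj, [4, 5, 6], [0, 1, 2, 3])
        res = hierarchical_cluster(D, k=1)
        with pytest.raises(ValueError, match="shape"):
            representative_rmsd_to_reference(res, traj, traj.coords[0][:5], [0, 1, 2])
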