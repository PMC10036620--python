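"""Hierarchical agglomerative clustering of trajectory frames on ligand
RMSD, cluster populations and representative frames.

Replica trajectories are concatenated before clustering; each frame's
(replica, local frame) provenance can be carried alongside the flat frame
index. The default of four average-linkage clusters mirrors common
practice for grouping ligand binding modes from multi-copy simulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .geometry import kabsch_superpose, rmsd
from .traj_model import Trajectory

__all__ = [
    "ClusterResult",
    "pairwise_ligand_rmsd",
    "hierarchical_cluster",
    "representative_rmsd_to_reference",
]


@dataclass
class ClusterResult:
    """Frame labels (1..k), per-cluster populations (%), representatives."""

    labels: np.ndarray
    populations: np.ndarray
    representatives: np.ndarray
    linkage: str
    k: int

    def to_frame(self, provenance: Sequence[tuple[int, int]] | None = None) -> pd.DataFrame:
        if provenance is None:
            return pd.DataFrame({"frame": np.arange(len(self.labels)), "cluster": self.labels})
        reps = [p[0] for p in provenance]
        local = [p[1] for p in provenance]
        return pd.DataFrame({"replica": reps, "frame": local, "cluster": self.labels})

    def summary(self) -> dict:
        return {
            "k": self.k,
            "linkage": self.linkage,
            "populations_percent": [float(p) for p in self.populations],
            "representative_frames": [int(r) for r in self.representatives],
        }


def pairwise_ligand_rmsd(
    traj: Trajectory,
    ligand_selection: Sequence[int] | np.ndarray,
    fit_selection: Sequence[int] | np.ndarray,
) -> np.ndarray:
    """Symmetric frame-by-frame ligand RMSD matrix (Angstrom).

    For every frame pair the mobile frame is superposed on the other using
    ``fit_selection`` (receptor alpha-carbons), then RMSD is measured over
    ``ligand_selection`` (ligand heavy atoms).
    """
    lig = np.asarray(ligand_selection, dtype=int)
    fit = np.asarray(fit_selection, dtype=int)
    if lig.size == 0:
        raise ValueError("empty ligand selection")
    n = traj.n_frames
    if n < 2:
        raise ValueError("need at least 2 frames")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tr, _ = kabsch_superpose(traj.coords[j], traj.coords[i], fit)
            moved = tr.apply(traj.coords[j])
            D[i, j] = D[j, i] = rmsd(moved, traj.coords[i], lig)
    return D


def hierarchical_cluster(dist_matrix: np.ndarray, k: int, linkage_method: str = "average") -> ClusterResult:
    """Agglomerative clustering of a distance matrix into ``k`` clusters.

    Labels are 1..k ordered by decreasing population (ties broken by the
    lowest member frame index). The representative of a cluster is the
    member frame minimizing the mean distance to its co-members (ties to
    the lowest frame index).
    """
    D = np.asarray(dist_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if k > n:
        raise ValueError(f"cannot form {k} clusters from {n} frames")
    if linkage_method not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    if k == n:
        raw = np.arange(n)
    else:
        Z = linkage(squareform(D, checks=False), method=linkage_method)
        raw = cut_tree(Z, n_clusters=k).ravel()

    # relabel by decreasing population, ties by lowest member index
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.nonzero(raw == c)[0][0])),
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = np.array([remap[c] for c in raw], dtype=int)

    populations = np.array([100.0 * (labels == c).sum() / n for c in range(1, k + 1)])
    representatives = np.empty(k, dtype=int)
    for c in range(1, k + 1):
        members = np.nonzero(labels == c)[0]
        if members.size == 1:
            representatives[c - 1] = members[0]
        else:
            sub = D[np.ix_(members, members)]
            mean_d = sub.sum(axis=1) / (members.size - 1)
            representatives[c - 1] = members[int(np.argmin(mean_d))]  # argmin ties -> lowest index
    return ClusterResult(
        labels=labels, populations=populations, representatives=representatives, linkage=linkage_method, k=k
    )


def representative_rmsd_to_reference(
    result: ClusterResult,
    traj: Trajectory,
    reference_frame: np.ndarray,
    selection: Sequence[int] | np.ndarray,
    fit_selection: Sequence[int] | np.ndarray | None = None,
) -> np.ndarray:
    """Heavy-atom RMSD of each cluster representative to a reference
    structure after Kabsch superposition.

    ``fit_selection`` defaults to ``selection``; the reference must have
    the same atom count as the trajectory frames.
    """
    ref = np.asarray(reference_frame, dtype=float)
    if ref.shape != traj.coords[0].shape:
        raise ValueError(
            f"reference has shape {ref.shape}, expected {traj.coords[0].shape}"
        )
    sel = np.asarray(selection, dtype=int)
    fit = sel if fit_selection is None else np.asarray(fit_selection, dtype=int)
    out = np.empty(len(result.representatives))
    for i, f in enumerate(result.representatives):
        tr, _ = kabsch_superpose(traj.coords[f], ref, fit)
        out[i] = rmsd(tr.apply(traj.coords[f]), ref, sel)
    return out
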