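"""Core geometry: centroids, angles, Kabsch superposition, RMSD, RMSF
profiles with their integral flexibility score, and the two collective-
variable pairs used to track loop gating and receptor activation.

The ECL2 gating pair is (delta, beta): delta is the distance from the loop
tip (centroid of the Q187/W188/G189 alpha-carbons) to the centroid of all
TM-helix alpha-carbons; beta is the angle at the ECL2 base (A181/I195
centroid) between the W188 alpha-carbon and the ECL3 base (S281/P288
centroid). The activation pair is (d, theta): the C225-S305 alpha-carbon
distance and the T255-C268-I80 angle with its vertex at C268.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .traj_model import BWMap, Trajectory

__all__ = [
    "CVSeries",
    "RMSFProfile",
    "Transform",
    "centroid",
    "angle_deg",
    "ecl2_cv",
    "activation_cv",
    "kabsch_superpose",
    "superpose_trajectory",
    "rmsd",
    "rmsf_profile",
    "cv_table",
]


@dataclass
class CVSeries:
    """Named per-frame scalar collective-variable values."""

    name: str
    values: np.ndarray
    replica_id: int = 0
    frame_indices: np.ndarray | None = None
    unit: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_indices is None:
            self.frame_indices = np.arange(len(self.values))
        else:
            self.frame_indices = np.asarray(self.frame_indices, dtype=int)
            if len(self.frame_indices) != len(self.values):
                raise ValueError("frame_indices length must equal values length")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class RMSFProfile:
    """Per-residue RMSF (Angstrom) and its integral over residue index."""

    resids: np.ndarray
    rmsf: np.ndarray
    integral: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"resid": self.resids, "rmsf": self.rmsf})


@dataclass(frozen=True)
class Transform:
    """Rigid-body transform x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def centroid(frame: np.ndarray, selection: Sequence[int] | np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    """Mass-weighted centroid of selected atoms of one frame.

    With equal masses (e.g. an all-alpha-carbon selection) this is the
    plain geometric mean.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty selection has no centroid")
    pts = np.asarray(frame, dtype=float)[sel]
    if masses is None:
        return pts.mean(axis=0)
    w = np.asarray(masses, dtype=float)[sel]
    return (pts * w[:, None]).sum(axis=0) / w.sum()


def angle_deg(p1: np.ndarray, vertex: np.ndarray, p2: np.ndarray) -> float:
    """Interior angle at ``vertex`` between points p1 and p2, in degrees."""
    a = np.asarray(p1, dtype=float) - np.asarray(vertex, dtype=float)
    b = np.asarray(p2, dtype=float) - np.asarray(vertex, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("angle undefined: zero-length arm at vertex")
    c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _require_ca(traj: Trajectory, resid: int, chain: str | None = None) -> int:
    idx = traj.topology.ca_indices(resid=resid, chain=chain)
    if idx.size == 0:
        raise ValueError(f"required residue {resid} has no alpha-carbon in the topology")
    return int(idx[0])


def ecl2_cv(traj: Trajectory, bw_map: BWMap, chain: str | None = None, replica_id: int = 0) -> tuple[CVSeries, CVSeries]:
    """Per-frame ECL2 gating variables (delta in Angstrom, beta in degrees)."""
    masses = traj.topology.masses
    tip_idx = np.array([_require_ca(traj, r, chain) for r in (187, 188, 189)])
    w188 = _require_ca(traj, 188, chain)
    base_ecl2 = np.array([_require_ca(traj, r, chain) for r in (181, 195)])
    base_ecl3 = np.array([_require_ca(traj, r, chain) for r in (281, 288)])

    tm_resids = bw_map.tm_resids()
    tm_idx = traj.topology.ca_indices(resid=tm_resids, chain=chain)
    missing = set(tm_resids) - {traj.topology.atoms[i].resid for i in tm_idx}
    if missing:
        raise ValueError(f"TM residues missing an alpha-carbon: {sorted(missing)[:5]}...")

    delta = np.empty(traj.n_frames)
    beta = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        tip = centroid(frame, tip_idx, masses)
        tm_c = centroid(frame, tm_idx, masses)
        delta[f] = np.linalg.norm(tip - tm_c)
        b2 = centroid(frame, base_ecl2, masses)
        b3 = centroid(frame, base_ecl3, masses)
        beta[f] = angle_deg(frame[w188], b2, b3)
    return (
        CVSeries("delta", delta, replica_id, unit="angstrom"),
        CVSeries("beta", beta, replica_id, unit="degrees"),
    )


def activation_cv(traj: Trajectory, chain: str | None = None, replica_id: int = 0) -> tuple[CVSeries, CVSeries]:
    """Per-frame activation variables: C225-S305 distance and the
    T255-C268-I80 angle (vertex at C268)."""
    i225 = _require_ca(traj, 225, chain)
    i305 = _require_ca(traj, 305, chain)
    i255 = _require_ca(traj, 255, chain)
    i268 = _require_ca(traj, 268, chain)
    i80 = _require_ca(traj, 80, chain)
    d = np.linalg.norm(traj.coords[:, i225] - traj.coords[:, i305], axis=1)
    theta = np.array(
        [angle_deg(traj.coords[f, i255], traj.coords[f, i268], traj.coords[f, i80]) for f in range(traj.n_frames)]
    )
    return (
        CVSeries("activation_distance", d, replica_id, unit="angstrom"),
        CVSeries("activation_angle", theta, replica_id, unit="degrees"),
    )


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_selection: Sequence[int] | np.ndarray | None = None,
) -> tuple[Transform, float]:
    """Optimal least-squares rigid superposition (Kabsch, via SVD).

    Returns the proper-rotation transform mapping ``mobile`` onto
    ``reference`` and the post-fit RMSD over the fit selection.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have equal shapes")
    sel = np.arange(len(mobile)) if fit_selection is None else np.asarray(fit_selection, dtype=int)
    if sel.size < 3:
        raise ValueError("superposition needs at least 3 fit atoms")
    P = mobile[sel]
    Q = reference[sel]
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) fit selection")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    fitted = P @ R.T + t
    val = float(np.sqrt(((fitted - Q) ** 2).sum(axis=1).mean()))
    return Transform(R, t), val


def rmsd(a: np.ndarray, b: np.ndarray, selection: Sequence[int] | np.ndarray | None = None) -> float:
    """Plain (no-fit) RMSD between two coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sel = np.arange(len(a)) if selection is None else np.asarray(selection, dtype=int)
    return float(np.sqrt(((a[sel] - b[sel]) ** 2).sum(axis=1).mean()))


def superpose_trajectory(
    traj: Trajectory,
    fit_selection: Sequence[int] | np.ndarray,
    reference_frame: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose every frame onto a reference frame by the fit selection.

    Returns (superposed coordinates, per-frame RMSD over the fit
    selection).
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    ref = traj.coords[reference_frame]
    out = np.empty_like(traj.coords)
    series = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        tr, val = kabsch_superpose(traj.coords[f], ref, fit_selection)
        out[f] = tr.apply(traj.coords[f])
        series[f] = val
    return out, series


def rmsf_profile(
    traj: Trajectory,
    fit_selection: Sequence[int] | np.ndarray,
    measure_selection: Sequence[int] | np.ndarray,
) -> RMSFProfile:
    """Per-residue alpha-carbon RMSF after superposition, plus its
    trapezoidal integral over residue index (unit spacing).

    Each frame is first superposed on frame 0 using ``fit_selection`` (a
    rigid core, typically the TM-bundle alpha-carbons) so that loop motion
    is measured rather than absorbed into the fit. The RMSF of an atom is
    the root-mean-square deviation from its time-average position.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = np.asarray(measure_selection, dtype=int)
    coords, _ = superpose_trajectory(traj, fit_selection)
    pts = coords[:, sel]  # frames x sel x 3
    mean = pts.mean(axis=0)
    fluct = np.sqrt(((pts - mean) ** 2).sum(axis=2).mean(axis=0))
    resids = np.array([traj.topology.atoms[i].resid for i in sel])
    integral = float(np.trapezoid(fluct)) if len(fluct) > 1 else 0.0
    return RMSFProfile(resids=resids, rmsf=fluct, integral=integral)


def cv_table(series: Iterable[CVSeries]) -> pd.DataFrame:
    """Tidy long-form table: replica, frame, cv_name, value."""
    rows = []
    for s in series:
        for fi, v in zip(s.frame_indices, s.values):
            rows.append((s.replica_id, int(fi), s.name, float(v)))
    return pd.DataFrame(rows, columns=["replica", "frame", "cv_name", "value"])
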