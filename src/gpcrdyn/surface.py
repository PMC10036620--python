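"""Molecular surface areas by numerical point sampling.

Two modes are provided:

* ``SASA`` — the Shrake-Rupley solvent-accessible surface: for each atom,
  quasi-uniform points are placed on a sphere of radius r_i + probe and the
  accessible fraction (points not inside any other inflated sphere) scales
  the sphere area.
* ``SES`` — an approximation of the Connolly solvent-excluded surface:
  the accessible points of each atom are projected back from the expanded
  sphere onto the van der Waals sphere, so each accessible patch
  contributes with area scaled by (r_i / (r_i + probe))^2. This captures
  the contact patches of the molecular surface; reentrant (probe-concave)
  patches are not triangulated, so SES totals are a contact-surface
  approximation.

Defaults: probe radius 1.4 Angstrom and Bondi-type van der Waals radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .traj_model import Trajectory

__all__ = ["VDW_RADII", "SASASeries", "sphere_points", "surface_area", "surface_series"]

# Bondi-type van der Waals radii (Angstrom)
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}

DEFAULT_PROBE = 1.4


def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def surface_area(
    frame: np.ndarray,
    selection: Sequence[int] | np.ndarray | None = None,
    radii: dict[str, float] | None = None,
    elements: Sequence[str] | None = None,
    probe: float = DEFAULT_PROBE,
    mode: str = "SASA",
    n_points: int = 1000,
) -> tuple[np.ndarray, float]:
    """Per-atom and total surface area (Angstrom^2) of one frame.

    ``elements`` gives the element symbol per selected atom (or per atom of
    the frame when ``selection`` is None). Raises when a selected element
    has no radius in ``radii``.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for usable accuracy")
    if mode not in ("SASA", "SES"):
        raise ValueError(f"unknown surface mode {mode!r}")
    frame = np.asarray(frame, dtype=float)
    sel = np.arange(len(frame)) if selection is None else np.asarray(selection, dtype=int)
    if elements is None:
        raise ValueError("element symbols are required to assign radii")
    elements = [str(e).upper() for e in elements]
    if len(elements) == len(frame):
        elements = [elements[i] for i in sel]
    elif len(elements) != len(sel):
        raise ValueError("elements must match either the frame or the selection")
    table = VDW_RADII if radii is None else radii
    try:
        r = np.array([table[e] for e in elements], dtype=float)
    except KeyError as exc:
        raise ValueError(f"no van der Waals radius for element {exc.args[0]!r}") from exc

    pts = sphere_points(n_points)
    centers = frame[sel]
    inflated = r + probe
    tree = cKDTree(centers)
    per_atom = np.zeros(len(sel))
    max_r = inflated.max()
    for i in range(len(sel)):
        # neighbours whose inflated spheres could clip this atom's surface
        nbrs = [j for j in tree.query_ball_point(centers[i], inflated[i] + max_r) if j != i]
        surf = centers[i] + inflated[i] * pts
        if nbrs:
            nbr_centers = centers[nbrs]
            nbr_r = inflated[np.asarray(nbrs)]
            d2 = ((surf[:, None, :] - nbr_centers[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nbr_r**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        area_radius = inflated[i] if mode == "SASA" else r[i]
        per_atom[i] = frac * 4.0 * np.pi * area_radius**2
    return per_atom, float(per_atom.sum())


@dataclass
class SASASeries:
    """Per-frame surface-area series over a trajectory selection."""

    totals: np.ndarray
    per_atom: np.ndarray  # frames x atoms
    probe: float
    n_points: int
    mode: str = "SASA"

    @property
    def mean(self) -> float:
        return float(self.totals.mean())

    @property
    def sd(self) -> float:
        return float(self.totals.std(ddof=1)) if len(self.totals) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "probe": self.probe,
            "n_frames": int(len(self.totals)),
            "mean_area": self.mean,
            "sd_area": self.sd,
        }


def surface_series(
    traj: Trajectory,
    selection: Sequence[int] | np.ndarray,
    radii: dict[str, float] | None = None,
    probe: float = DEFAULT_PROBE,
    mode: str = "SASA",
    n_points: int = 1000,
) -> SASASeries:
    """Surface-area series for a selection (typically the free ligand)
    over all frames, with mean and standard deviation across frames."""
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty selection")
    elements = [traj.topology.atoms[i].element for i in sel]
    totals = np.empty(traj.n_frames)
    per_atom = np.empty((traj.n_frames, sel.size))
    for f in range(traj.n_frames):
        pa, tot = surface_area(
            traj.coords[f], sel, radii=radii, elements=elements, probe=probe, mode=mode, n_points=n_points
        )
        per_atom[f] = pa
        totals[f] = tot
    return SASASeries(totals=totals, per_atom=per_atom, probe=probe, n_points=n_points, mode=mode)
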