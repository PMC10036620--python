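"""Aggregation of externally computed end-point binding-energy tables.

The generalized-Born energy evaluation itself happens upstream (in the MD
engine's MM-GBSA machinery); this module defines the exchange format and
the two aggregations applied to its outputs: the cluster-population-
weighted binding free energy, and the per-residue decomposition report
filtered at a contribution threshold (default -1.0 kcal/mol, i.e. keep a
residue when at least one ligand's contribution is that favourable or
more).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fingerprints import REGION_ORDER, PocketRegionMap

__all__ = [
    "EnergyTable",
    "EnergyTableError",
    "weighted_binding_energy",
    "per_residue_report",
    "read_energy_tables",
    "write_energy_tables",
]

WEIGHT_TOL = 1e-3


class EnergyTableError(ValueError):
    """Malformed or inconsistent energy-table input."""


@dataclass
class EnergyTable:
    """Per-cluster binding energies plus optional per-residue decomposition.

    ``clusters`` columns: cluster, weight, dg_mean, dg_sd (kcal/mol).
    ``decomposition`` columns: residue, ligand, contribution (kcal/mol).
    """

    clusters: pd.DataFrame
    decomposition: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        w = self.clusters["weight"].to_numpy(dtype=float)
        if (w < 0).any():
            raise EnergyTableError("cluster weights must be non-negative")
        if abs(w.sum() - 1.0) > WEIGHT_TOL:
            raise EnergyTableError(
                f"cluster weights sum to {w.sum():.6f}, expected 1 within {WEIGHT_TOL}"
            )
        if "dg_sd" in self.clusters and (self.clusters["dg_sd"].to_numpy(dtype=float) < 0).any():
            raise EnergyTableError("standard deviations must be non-negative")

    def weighted_energy(self) -> tuple[float, float]:
        sds = self.clusters["dg_sd"].to_numpy(dtype=float) if "dg_sd" in self.clusters else None
        return weighted_binding_energy(
            self.clusters["dg_mean"].to_numpy(dtype=float),
            self.clusters["weight"].to_numpy(dtype=float),
            sds,
        )


def weighted_binding_energy(
    cluster_means: Sequence[float],
    weights: Sequence[float],
    cluster_sds: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Population-weighted mean binding free energy (kcal/mol).

    The spread is propagated as the weighted root-mean-square of the
    per-cluster standard deviations: sqrt(sum_i w_i * sd_i^2).
    """
    m = np.asarray(cluster_means, dtype=float)
    w = np.asarray(weights, dtype=float)
    if m.shape != w.shape:
        raise ValueError("means and weights must have equal lengths")
    if abs(w.sum() - 1.0) > WEIGHT_TOL:
        raise EnergyTableError(f"weights sum to {w.sum():.6f}, expected 1 within {WEIGHT_TOL}")
    mean = float(np.dot(w, m))
    if cluster_sds is None:
        return mean, 0.0
    s = np.asarray(cluster_sds, dtype=float)
    return mean, float(np.sqrt(np.dot(w, s**2)))


def per_residue_report(
    decompositions: Mapping[str, Mapping[int, float]] | pd.DataFrame,
    threshold: float = -1.0,
    regions: PocketRegionMap | None = None,
) -> pd.DataFrame:
    """Filtered per-residue contribution table across ligands.

    A residue is kept when its most favourable contribution over the
    ligands reaches the threshold (contribution <= threshold, both in
    kcal/mol). With a region map the rows are grouped top, middle, bottom
    and ordered by residue number within a region; otherwise by residue
    number.
    """
    if isinstance(decompositions, pd.DataFrame):
        wide = decompositions.pivot_table(index="residue", columns="ligand", values="contribution")
    else:
        wide = pd.DataFrame(decompositions)
        wide.index.name = "residue"
    kept = wide[wide.min(axis=1) <= threshold].copy()
    kept = kept.reset_index()
    if regions is not None:
        missing = [r for r in kept["residue"] if r not in regions]
        kept["region"] = [regions.region_of(r) if r in regions else None for r in kept["residue"]]
        if missing:
            kept["region"] = kept["region"].fillna("unassigned")
        order = {r: i for i, r in enumerate(REGION_ORDER + ("unassigned",))}
        kept["__o"] = kept["region"].map(order)
        kept = kept.sort_values(["__o", "residue"]).drop(columns="__o").reset_index(drop=True)
        cols = ["region", "residue"] + [c for c in kept.columns if c not in ("region", "residue")]
        kept = kept[cols]
    else:
        kept = kept.sort_values("residue").reset_index(drop=True)
    return kept


def read_energy_tables(
    cluster_path: str | Path,
    decomposition_path: str | Path | None = None,
) -> EnergyTable:
    """Read delimited-text energy tables (comma or tab separated).

    The cluster table must carry cluster, weight, dg_mean columns (dg_sd
    and n_frames optional); the decomposition table residue, ligand,
    contribution. Parse problems are reported with row numbers.
    """
    clusters = _read_table(cluster_path, required=("cluster", "weight", "dg_mean"))
    decomposition = None
    if decomposition_path is not None:
        decomposition = _read_table(decomposition_path, required=("residue", "ligand", "contribution"))
    return EnergyTable(clusters=clusters, decomposition=decomposition)


def _read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise EnergyTableError(f"{path}: missing required column(s) {missing}")
    numeric = [c for c in required if c not in ("cluster", "ligand")]
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()].tolist()
        if bad or parsed.isna().any():
            rows = [int(i) + 2 for i in df.index[parsed.isna()]]  # +2: header + 1-based
            raise EnergyTableError(f"{path}: non-numeric value(s) in column {col!r} at line(s) {rows}")
        df[col] = parsed
    return df


def write_energy_tables(table: EnergyTable, cluster_path: str | Path, decomposition_path: str | Path | None = None) -> None:
    table.clusters.to_csv(cluster_path, index=False)
    if decomposition_path is not None and table.decomposition is not None:
        table.decomposition.to_csv(decomposition_path, index=False)
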