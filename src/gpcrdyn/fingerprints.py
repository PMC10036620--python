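"""Geometric protein-ligand interaction fingerprints and persistence.

Five interaction types are detected per (receptor residue, ligand residue)
pair and frame, from atom geometry alone:

* hydrophobic — any pair of template-hydrophobic heavy atoms within cutoff;
* hbond — donor-acceptor distance within cutoff and, when the donor's
  hydrogens are present, donor-H...acceptor angle above threshold (without
  hydrogens a distance-only fallback applies and is flagged);
* pipi — aromatic ring centroids within cutoff with the inter-plane angle
  inside the parallel or T-shaped window;
* saltbridge — a cationic group atom within cutoff of an anionic one;
* cationpi — a cationic nitrogen within cutoff of a ring centroid.

Detections are pooled across replicas into persistence: the percentage of
all frames in which a given (pair, type) event occurs. The reported view
drops entries below a persistence threshold (default 10%), matching the
usual presentation of fingerprint heat maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .traj_model import BWMap, Topology, Trajectory

__all__ = [
    "InteractionParams",
    "ResidueTemplate",
    "ChemTemplates",
    "FingerprintMatrix",
    "PocketRegionMap",
    "detect_interactions",
    "persistence",
    "shared_residue_fraction",
    "partition_report",
    "default_templates",
    "default_regions",
]

INTERACTION_TYPES = ("hydrophobic", "hbond", "pipi", "saltbridge", "cationpi")


@dataclass(frozen=True)
class InteractionParams:
    """Geometric criteria (Angstrom / degrees) for each interaction type.

    Defaults follow widely used fingerprint conventions; all are
    configurable so results can be matched against other detectors.
    """

    hydrophobic_cutoff: float = 4.5
    hbond_dist: float = 3.5
    hbond_angle: float = 130.0
    pipi_centroid_cutoff: float = 5.5
    pipi_parallel_max: float = 35.0
    pipi_tshape_min: float = 60.0
    pipi_tshape_max: float = 90.0
    saltbridge_cutoff: float = 4.0
    cationpi_cutoff: float = 4.5

    def __post_init__(self) -> None:
        for name in (
            "hydrophobic_cutoff", "hbond_dist", "pipi_centroid_cutoff",
            "saltbridge_cutoff", "cationpi_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hbond_angle", "pipi_parallel_max", "pipi_tshape_min", "pipi_tshape_max"):
            v = getattr(self, name)
            if not 0 <= v <= 180:
                raise ValueError(f"{name} must lie in [0, 180] degrees")

    @property
    def max_cutoff(self) -> float:
        return max(
            self.hydrophobic_cutoff, self.hbond_dist, self.pipi_centroid_cutoff,
            self.saltbridge_cutoff, self.cationpi_cutoff,
        )


@dataclass(frozen=True)
class ResidueTemplate:
    """Chemistry template for one residue name."""

    hydrophobic: frozenset[str] = frozenset()
    rings: tuple[tuple[str, ...], ...] = ()
    cations: tuple[tuple[str, ...], ...] = ()
    anions: tuple[tuple[str, ...], ...] = ()
    donors: tuple[tuple[str, tuple[str, ...]], ...] = ()  # (heavy donor, H names)
    acceptors: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for ring in self.rings:
            if len(ring) < 5:
                raise ValueError("aromatic ring templates need at least 5 atoms")


class ChemTemplates:
    """Residue-name -> chemistry template lookup with alias support.

    D-amino acids reuse the corresponding L-residue chemistry (chirality
    does not change interaction typing); bespoke templates cover
    threoninol, the acetyl cap and nitro-phenylalanine.
    """

    def __init__(self, templates: Mapping[str, ResidueTemplate], aliases: Mapping[str, str] | None = None):
        self._templates = dict(templates)
        self._aliases = dict(aliases or {})

    def get(self, resname: str) -> ResidueTemplate:
        key = resname.strip().upper()
        key = self._aliases.get(key, key)
        if key not in self._templates:
            raise KeyError(f"no chemistry template for residue {resname!r}")
        return self._templates[key]

    def has(self, resname: str) -> bool:
        key = resname.strip().upper()
        return self._aliases.get(key, key) in self._templates

    def with_template(self, resname: str, template: ResidueTemplate) -> "ChemTemplates":
        new = dict(self._templates)
        new[resname.upper()] = template
        return ChemTemplates(new, self._aliases)


_BB_DONOR = (("N", ("H", "H1", "H2", "H3", "HN")),)
_BB_ACC = {"O", "OXT"}


def _tpl(
    hydrophobic=(), rings=(), cations=(), anions=(), donors=(), acceptors=(),
) -> ResidueTemplate:
    return ResidueTemplate(
        hydrophobic=frozenset(hydrophobic),
        rings=tuple(tuple(r) for r in rings),
        cations=tuple(tuple(c) for c in cations),
        anions=tuple(tuple(a) for a in anions),
        donors=_BB_DONOR + tuple(donors),
        acceptors=frozenset(_BB_ACC | set(acceptors)),
    )


def default_templates() -> ChemTemplates:
    """Templates for the standard amino acids plus the non-standard
    residues found in somatostatin-analogue peptides."""
    phe_ring = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    tyr_ring = phe_ring
    trp_ring5 = ("CG", "CD1", "CD2", "NE1", "CE2")
    trp_ring6 = ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")
    his_ring = ("CG", "ND1", "CD2", "CE1", "NE2")
    t: dict[str, ResidueTemplate] = {
        "ALA": _tpl(hydrophobic=("CB",)),
        "GLY": _tpl(),
        "VAL": _tpl(hydrophobic=("CB", "CG1", "CG2")),
        "LEU": _tpl(hydrophobic=("CB", "CG", "CD1", "CD2")),
        "ILE": _tpl(hydrophobic=("CB", "CG1", "CG2", "CD1")),
        "PRO": _tpl(hydrophobic=("CB", "CG", "CD")),
        "MET": _tpl(hydrophobic=("CB", "CG", "SD", "CE")),
        "PHE": _tpl(hydrophobic=("CB",) + phe_ring, rings=(phe_ring,)),
        "TYR": _tpl(
            hydrophobic=("CB",) + tyr_ring,
            rings=(tyr_ring,),
            donors=((("OH", ("HH",))),),
            acceptors=("OH",),
        ),
        "TRP": _tpl(
            hydrophobic=("CB",) + trp_ring5 + trp_ring6,
            rings=(trp_ring5, trp_ring6),
            donors=(("NE1", ("HE1",)),),
        ),
        "SER": _tpl(donors=(("OG", ("HG",)),), acceptors=("OG",)),
        "THR": _tpl(hydrophobic=("CG2",), donors=(("OG1", ("HG1",)),), acceptors=("OG1",)),
        "CYS": _tpl(hydrophobic=("CB", "SG"), donors=(("SG", ("HG",)),)),
        "ASN": _tpl(donors=(("ND2", ("HD21", "HD22")),), acceptors=("OD1",)),
        "GLN": _tpl(donors=(("NE2", ("HE21", "HE22")),), acceptors=("OE1",)),
        "ASP": _tpl(anions=(("OD1", "OD2"),), acceptors=("OD1", "OD2")),
        "GLU": _tpl(anions=(("OE1", "OE2"),), acceptors=("OE1", "OE2")),
        "LYS": _tpl(
            hydrophobic=("CB", "CG", "CD"),
            cations=(("NZ",),),
            donors=(("NZ", ("HZ1", "HZ2", "HZ3")),),
        ),
        "ARG": _tpl(
            hydrophobic=("CB", "CG"),
            cations=(("NH1", "NH2", "NE", "CZ"),),
            donors=(("NE", ("HE",)), ("NH1", ("HH11", "HH12")), ("NH2", ("HH21", "HH22"))),
        ),
        "HIS": _tpl(
            rings=(his_ring,),
            donors=(("ND1", ("HD1",)), ("NE2", ("HE2",))),
            acceptors=("ND1", "NE2"),
        ),
        # acetyl N-terminal cap: a hydrophobic methyl and a carbonyl acceptor
        "ACE": ResidueTemplate(hydrophobic=frozenset({"CH3"}), acceptors=frozenset({"O"})),
        # threoninol (reduced C-terminal threonine): hydroxyls, no carbonyl
        "THL": ResidueTemplate(
            hydrophobic=frozenset({"CG2"}),
            donors=_BB_DONOR + (("OG1", ("HG1",)), ("OXT", ("HXT",))),
            acceptors=frozenset({"OG1", "OXT"}),
        ),
        # 4-nitro-phenylalanine: aromatic and hydrophobic like PHE; the
        # nitro oxygens are excluded as acceptors by default (weak)
        "PPN": _tpl(hydrophobic=("CB",) + phe_ring, rings=(phe_ring,)),
    }
    aliases = {
        # D-amino acids (Amber-style names) reuse the L chemistry
        "DAL": "ALA", "DPN": "PHE", "DPH": "PHE", "DTR": "TRP", "DCY": "CYS",
        "DTY": "TYR", "DLY": "LYS", "DSE": "SER", "DTH": "THR",
        "HID": "HIS", "HIE": "HIS", "HIP": "HIS", "CYX": "CYS",
        "NIT": "PPN",
    }
    return ChemTemplates(t, aliases)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


class _Residue:
    __slots__ = ("chain", "resid", "resname", "atoms", "coords", "template")

    def __init__(self, chain, resid, resname, atoms, coords, template):
        self.chain = chain
        self.resid = resid
        self.resname = resname
        self.atoms = atoms  # name -> row in coords
        self.coords = coords
        self.template = template

    def pos(self, name: str) -> np.ndarray | None:
        i = self.atoms.get(name)
        return None if i is None else self.coords[i]

    def present(self, names: Iterable[str]) -> list[np.ndarray]:
        return [self.coords[self.atoms[n]] for n in names if n in self.atoms]


def _group_residues(
    frame: np.ndarray, topology: Topology, selection: np.ndarray, templates: ChemTemplates
) -> list[_Residue]:
    by_res: dict[tuple[str, int], list[int]] = {}
    for i in selection:
        a = topology.atoms[i]
        by_res.setdefault((a.chain, a.resid), []).append(i)
    out = []
    for (chain, resid), idx in by_res.items():
        resname = topology.atoms[idx[0]].resname
        try:
            tpl = templates.get(resname)
        except KeyError as exc:
            raise KeyError(
                f"residue {resname}{resid} (chain {chain!r}) has no chemistry template"
            ) from exc
        names = {topology.atoms[i].name: k for k, i in enumerate(idx)}
        out.append(_Residue(chain, resid, resname, names, frame[idx], tpl))
    return out


def _ring_geometry(res: _Residue, ring: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray] | None:
    pts = res.present(ring)
    if len(pts) < len(ring):
        return None
    P = np.array(pts)
    c = P.mean(axis=0)
    _, _, vt = np.linalg.svd(P - c)
    return c, vt[2]  # centroid, unit normal


def _plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    c = abs(float(np.clip(np.dot(n1, n2), -1.0, 1.0)))
    return float(np.degrees(np.arccos(c)))


def _min_dist(a: list[np.ndarray], b: list[np.ndarray]) -> float:
    if not a or not b:
        return np.inf
    return float(cdist(np.array(a), np.array(b)).min())


def _angle(a: np.ndarray, v: np.ndarray, b: np.ndarray) -> float:
    x, y = a - v, b - v
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return 0.0
    return float(np.degrees(np.arccos(np.clip(np.dot(x, y) / (nx * ny), -1, 1))))


def _hbond_between(donor_res: _Residue, acceptor_res: _Residue, params: InteractionParams) -> bool:
    for dname, hnames in donor_res.template.donors:
        d = donor_res.pos(dname)
        if d is None:
            continue
        hs = donor_res.present(hnames)
        for aname in acceptor_res.template.acceptors:
            a = acceptor_res.pos(aname)
            if a is None:
                continue
            if np.linalg.norm(d - a) > params.hbond_dist:
                continue
            if hs:
                if any(_angle(d, h, a) >= params.hbond_angle for h in hs):
                    return True
            else:
                # heavy-atom fallback: distance criterion only
                return True
    return False


def _detect_pair(r: _Residue, l: _Residue, params: InteractionParams) -> set[str]:
    found: set[str] = set()
    # hydrophobic
    if _min_dist(r.present(r.template.hydrophobic), l.present(l.template.hydrophobic)) <= params.hydrophobic_cutoff:
        found.add("hydrophobic")
    # hydrogen bond, both directions
    if _hbond_between(l, r, params) or _hbond_between(r, l, params):
        found.add("hbond")
    # ring geometries, computed once
    r_rings = [g for ring in r.template.rings if (g := _ring_geometry(r, ring))]
    l_rings = [g for ring in l.template.rings if (g := _ring_geometry(l, ring))]
    for rc, rn in r_rings:
        for lc, ln in l_rings:
            if np.linalg.norm(rc - lc) <= params.pipi_centroid_cutoff:
                ang = _plane_angle(rn, ln)
                if ang <= params.pipi_parallel_max or params.pipi_tshape_min <= ang <= params.pipi_tshape_max:
                    found.add("pipi")
    # salt bridge, both directions
    r_cat = [p for g in r.template.cations for p in r.present(g)]
    r_ani = [p for g in r.template.anions for p in r.present(g)]
    l_cat = [p for g in l.template.cations for p in l.present(g)]
    l_ani = [p for g in l.template.anions for p in l.present(g)]
    if (
        _min_dist(r_cat, l_ani) <= params.saltbridge_cutoff
        or _min_dist(r_ani, l_cat) <= params.saltbridge_cutoff
    ):
        found.add("saltbridge")
    # cation-pi, both directions
    for cat in r_cat:
        if any(np.linalg.norm(cat - lc) <= params.cationpi_cutoff for lc, _ in l_rings):
            found.add("cationpi")
    for cat in l_cat:
        if any(np.linalg.norm(cat - rc) <= params.cationpi_cutoff for rc, _ in r_rings):
            found.add("cationpi")
    return found


def detect_interactions(
    frame: np.ndarray,
    topology: Topology,
    receptor_selection: Sequence[int] | np.ndarray,
    ligand_selection: Sequence[int] | np.ndarray,
    templates: ChemTemplates | None = None,
    params: InteractionParams | None = None,
) -> set[tuple[int, int, str]]:
    """Interactions present in one frame.

    Returns a set of (receptor resid, ligand resid, interaction type).
    Every residue name appearing in either selection must have a template.
    """
    templates = templates or default_templates()
    params = params or InteractionParams()
    rsel = np.asarray(receptor_selection, dtype=int)
    lsel = np.asarray(ligand_selection, dtype=int)
    receptor = _group_residues(frame, topology, rsel, templates)
    ligand = _group_residues(frame, topology, lsel, templates)
    out: set[tuple[int, int, str]] = set()
    margin = params.max_cutoff + 2.0
    for r in receptor:
        for l in ligand:
            # cheap residue-level prefilter on full-atom bounding distance
            if cdist(r.coords, l.coords).min() > margin:
                continue
            for typ in _detect_pair(r, l, params):
                out.add((r.resid, l.resid, typ))
    return out


# ---------------------------------------------------------------------------
# Persistence aggregation
# ---------------------------------------------------------------------------


@dataclass
class FingerprintMatrix:
    """Pooled interaction persistences with per-replica breakdown.

    ``counts`` maps (receptor resid, ligand resid, type) to the number of
    pooled frames containing the event; persistences are percentages of
    the pooled frame total. Entries below the report threshold are hidden
    from the reported view but retained internally.
    """

    counts: dict[tuple[int, int, str], int]
    n_frames: int
    report_threshold: float = 10.0
    per_replica: dict[int, tuple[dict[tuple[int, int, str], int], int]] = field(default_factory=dict)

    def persistence_of(self, entry: tuple[int, int, str]) -> float:
        return 100.0 * self.counts.get(entry, 0) / self.n_frames

    def reported(self) -> dict[tuple[int, int, str], float]:
        """Entries at or above the report threshold, as percentages."""
        out = {}
        for entry, c in self.counts.items():
            p = 100.0 * c / self.n_frames
            if p >= self.report_threshold:
                out[entry] = p
        return out

    def receptor_residues(self) -> set[int]:
        """Receptor residues with at least one reported interaction."""
        return {e[0] for e in self.reported()}

    def to_frame(
        self,
        bw_map: BWMap | None = None,
        regions: "PocketRegionMap | None" = None,
        receptor_names: Mapping[int, str] | None = None,
        ligand_names: Mapping[int, str] | None = None,
    ) -> pd.DataFrame:
        rows = []
        for (rres, lres, typ), p in sorted(self.reported().items()):
            rows.append(
                {
                    "receptor_res": (receptor_names or {}).get(rres, ""),
                    "receptor_resid": rres,
                    "bw_label": bw_map.bw_label(rres) if bw_map else None,
                    "region": regions.region_of(rres) if regions and rres in regions else None,
                    "ligand_res": (ligand_names or {}).get(lres, ""),
                    "ligand_resid": lres,
                    "type": typ,
                    "persistence": p,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "receptor_res", "receptor_resid", "bw_label", "region",
                "ligand_res", "ligand_resid", "type", "persistence",
            ],
        )


def persistence(
    detections: Sequence[Iterable[tuple[int, int, str]]] | Mapping[int, Sequence[Iterable[tuple[int, int, str]]]],
    report_threshold: float = 10.0,
) -> FingerprintMatrix:
    """Aggregate per-frame detections into persistences.

    ``detections`` is either a flat sequence of per-frame event sets
    (pooled) or a mapping replica -> sequence of per-frame event sets.
    Persistence = 100 x frames containing the event / total pooled frames.
    """
    if isinstance(detections, Mapping):
        per_rep = detections
    else:
        per_rep = {0: detections}
    total = sum(len(v) for v in per_rep.values())
    if total == 0:
        raise ValueError("persistence needs at least one frame")
    counts: dict[tuple[int, int, str], int] = {}
    breakdown: dict[int, tuple[dict[tuple[int, int, str], int], int]] = {}
    for rep, frames in per_rep.items():
        rc: dict[tuple[int, int, str], int] = {}
        for events in frames:
            for e in set(events):
                rc[e] = rc.get(e, 0) + 1
        breakdown[rep] = (rc, len(frames))
        for e, c in rc.items():
            counts[e] = counts.get(e, 0) + c
    return FingerprintMatrix(
        counts=counts, n_frames=total, report_threshold=report_threshold, per_replica=breakdown
    )


def shared_residue_fraction(matrix_a: FingerprintMatrix, matrix_b: FingerprintMatrix) -> float:
    """Percentage of A's interacting receptor residues also interacting
    in B (reported entries only)."""
    ra = matrix_a.receptor_residues()
    if not ra:
        raise ValueError("matrix_a reports no interacting receptor residues")
    rb = matrix_b.receptor_residues()
    return 100.0 * len(ra & rb) / len(ra)


# ---------------------------------------------------------------------------
# Pocket regions
# ---------------------------------------------------------------------------

REGION_ORDER = ("top", "middle", "bottom")


class PocketRegionMap:
    """Disjoint assignment of pocket residues to top/middle/bottom."""

    def __init__(self, assignment: Mapping[int, str]):
        bad = {r: v for r, v in assignment.items() if v not in REGION_ORDER}
        if bad:
            raise ValueError(f"unknown region names: {bad}")
        self._map = dict(assignment)

    @classmethod
    def from_lists(cls, by_region: Mapping[str, Iterable[int]]) -> "PocketRegionMap":
        assignment: dict[int, str] = {}
        for region, resids in by_region.items():
            for r in resids:
                if r in assignment:
                    raise ValueError(f"residue {r} assigned to both {assignment[r]!r} and {region!r}")
                assignment[int(r)] = region
        return cls(assignment)

    @classmethod
    def from_json(cls, path: str | Path) -> "PocketRegionMap":
        return cls.from_lists(json.loads(Path(path).read_text()))

    def region_of(self, resid: int) -> str:
        return self._map[resid]

    def __contains__(self, resid: int) -> bool:
        return resid in self._map

    def __len__(self) -> int:
        return len(self._map)


def default_regions() -> PocketRegionMap:
    """Bundled (partial) SSTR2 pocket-region map; user-overridable."""
    ref = resources.files("gpcrdyn.data").joinpath("sstr2_pocket_regions.json")
    return PocketRegionMap.from_lists(json.loads(ref.read_text()))


def partition_report(matrix: FingerprintMatrix, regions: PocketRegionMap) -> pd.DataFrame:
    """Reported entries grouped by pocket region, ordered top, middle,
    bottom and by residue number within a region."""
    reported = matrix.reported()
    missing = sorted({e[0] for e in reported} - {e[0] for e in reported if e[0] in regions})
    if missing:
        raise ValueError(f"residues missing from the pocket-region map: {missing}")
    rows = [
        {
            "region": regions.region_of(rres),
            "receptor_resid": rres,
            "ligand_resid": lres,
            "type": typ,
            "persistence": p,
        }
        for (rres, lres, typ), p in reported.items()
    ]
    df = pd.DataFrame(rows, columns=["region", "receptor_resid", "ligand_resid", "type", "persistence"])
    if df.empty:
        return df
    df["__order"] = df["region"].map({r: i for i, r in enumerate(REGION_ORDER)})
    df = df.sort_values(["__order", "receptor_resid", "ligand_resid", "type"]).drop(columns="__order")
    return df.reset_index(drop=True)
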