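"""Topology/trajectory data model, multi-model PDB and binary trajectory I/O,
and Ballesteros-Weinstein residue labelling.

Coordinates are stored in Angstrom and times in picoseconds throughout.
Residue numbers are 1-based as in the PDB format; insertion codes are not
supported and files containing them are rejected with a clear error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Topology",
    "Trajectory",
    "BWMap",
    "PDBParseError",
    "TrajectoryFormatError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_binary_trajectory",
    "write_binary_trajectory",
    "infer_element",
    "default_bw_map",
]

# Standard atomic weights (Da), used when a file carries no masses.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845, "MN": 54.938, "SE": 78.971,
}

_TWO_LETTER_ELEMENTS = {"CL", "BR", "NA", "MG", "ZN", "FE", "MN", "SE"}


class PDBParseError(ValueError):
    """Raised on malformed or unsupported PDB content."""


class TrajectoryFormatError(ValueError):
    """Raised on binary-trajectory problems (e.g. atom-count mismatch)."""


def infer_element(name: str, resname: str = "") -> str:
    """Infer an element symbol from a PDB atom name.

    Standard fallback rules: strip digits and primes, prefer a two-letter
    match for halogens/metals, otherwise the first alphabetic character.
    ``CA`` is carbon (an alpha-carbon) unless the residue itself is a
    calcium ion.
    """
    stripped = "".join(ch for ch in name if ch.isalpha()).upper()
    if not stripped:
        raise PDBParseError(f"cannot infer element from atom name {name!r}")
    if stripped == "CA":
        return "CA" if resname.strip().upper() == "CA" else "C"
    if stripped[:2] in _TWO_LETTER_ELEMENTS:
        return stripped[:2]
    return stripped[0]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a topology."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    mass: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial} ({self.name}): mass must be > 0")


class Topology:
    """Ordered collection of atoms with a derived residue table.

    The residue table partitions the atom list: every atom belongs to
    exactly one (chain, resid, resname) residue, and atoms of one residue
    are contiguous.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serial numbers must be unique within a topology")
        self._build_residues()

    def _build_residues(self) -> None:
        residues: list[tuple[str, int, str, int, int]] = []  # chain, resid, resname, start, stop
        seen: set[tuple[str, int]] = set()
        for i, a in enumerate(self.atoms):
            key = (a.chain, a.resid)
            if residues and (residues[-1][0], residues[-1][1]) == key:
                ch, ri, rn, start, _ = residues[-1]
                if rn != a.resname:
                    raise ValueError(
                        f"residue {ch}:{ri} has conflicting names {rn!r} and {a.resname!r}"
                    )
                residues[-1] = (ch, ri, rn, start, i + 1)
            else:
                if key in seen:
                    raise ValueError(f"atoms of residue {key} are not contiguous")
                seen.add(key)
                residues.append((a.chain, a.resid, a.resname, i, i + 1))
        self.residues: tuple[tuple[str, int, str, int, int], ...] = tuple(residues)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def select(
        self,
        chain: str | None = None,
        resid: int | Iterable[int] | None = None,
        name: str | None = None,
        element: str | None = None,
    ) -> np.ndarray:
        """Indices of atoms matching all given criteria (AND-combined)."""
        resids: set[int] | None
        if resid is None:
            resids = None
        elif isinstance(resid, int):
            resids = {resid}
        else:
            resids = set(resid)
        out = [
            i
            for i, a in enumerate(self.atoms)
            if (chain is None or a.chain == chain)
            and (resids is None or a.resid in resids)
            and (name is None or a.name == name)
            and (element is None or a.element == element)
        ]
        return np.array(out, dtype=int)

    def ca_indices(self, resid: int | Iterable[int] | None = None, chain: str | None = None) -> np.ndarray:
        """Alpha-carbon indices: atom name ``CA`` with element carbon.

        The element guard distinguishes alpha-carbons from calcium ions.
        """
        return self.select(chain=chain, resid=resid, name="CA", element="C")

    def resids(self, chain: str | None = None) -> list[int]:
        return [r[1] for r in self.residues if chain is None or r[0] == chain]


class Trajectory:
    """A topology plus per-frame Cartesian coordinates (Angstrom)."""

    def __init__(self, topology: Topology, coords: np.ndarray, frame_spacing: float = 1.0):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] and coords.shape[1] != topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {coords.shape[1]} != topology atom count {topology.n_atoms}"
            )
        if coords.size and not np.isfinite(coords).all():
            raise ValueError("coordinates must be finite")
        self.topology = topology
        self.coords = coords
        self.frame_spacing = float(frame_spacing)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def __getitem__(self, frames) -> "Trajectory":
        idx = np.atleast_1d(np.arange(self.n_frames)[frames])
        return Trajectory(self.topology, self.coords[idx], self.frame_spacing)


# ---------------------------------------------------------------------------
# Ballesteros-Weinstein labelling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TMRange:
    tm: int
    start_resid: int
    start_label: str
    end_resid: int
    end_label: str

    def __post_init__(self) -> None:
        t1, m1 = self.start_label.split(".")
        t2, m2 = self.end_label.split(".")
        if int(t1) != self.tm or int(t2) != self.tm:
            raise ValueError(f"TM{self.tm}: labels {self.start_label}/{self.end_label} disagree with helix index")
        if int(m2) - int(m1) != self.end_resid - self.start_resid:
            raise ValueError(
                f"TM{self.tm}: minor numbers {self.start_label}..{self.end_label} do not "
                f"increment by one per residue over {self.start_resid}..{self.end_resid}"
            )


@dataclass(frozen=True)
class BWMap:
    """Ballesteros-Weinstein numbering map for a class A GPCR.

    Within each TM helix the minor number increments by one per residue;
    loop residues carry no BW label but a retrievable loop name.
    """

    tm_ranges: tuple[TMRange, ...]
    loop_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        spans = sorted((r.start_resid, r.end_resid) for r in self.tm_ranges)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("TM ranges must be non-overlapping")

    def bw_label(self, resid: int) -> str | None:
        """BW label ``t.mm`` for a TM residue, ``None`` otherwise."""
        for r in self.tm_ranges:
            if r.start_resid <= resid <= r.end_resid:
                minor = int(r.start_label.split(".")[1]) + (resid - r.start_resid)
                return f"{r.tm}.{minor}"
        return None

    def loop_of(self, resid: int) -> str | None:
        """Loop name for a loop residue, ``None`` otherwise."""
        for name, (lo, hi) in self.loop_ranges.items():
            if lo <= resid <= hi:
                return name
        return None

    def assigned(self, resid: int) -> bool:
        return self.bw_label(resid) is not None or self.loop_of(resid) is not None

    def tm_resids(self) -> list[int]:
        """All residue numbers inside the seven TM ranges, ascending."""
        out: list[int] = []
        for r in sorted(self.tm_ranges, key=lambda r: r.start_resid):
            out.extend(range(r.start_resid, r.end_resid + 1))
        return out

    @classmethod
    def from_json(cls, path: str | Path) -> "BWMap":
        data = json.loads(Path(path).read_text())
        return cls._from_dict(data)

    @classmethod
    def _from_dict(cls, data: dict) -> "BWMap":
        tm = tuple(
            TMRange(int(e["tm"]), int(e["start_resid"]), e["start_label"], int(e["end_resid"]), e["end_label"])
            for e in data["tm_ranges"]
        )
        loops = {k: (int(v[0]), int(v[1])) for k, v in data.get("loop_ranges", {}).items()}
        return cls(tm, loops)

    def to_json(self, path: str | Path) -> None:
        data = {
            "tm_ranges": [
                {
                    "tm": r.tm,
                    "start_resid": r.start_resid,
                    "start_label": r.start_label,
                    "end_resid": r.end_resid,
                    "end_label": r.end_label,
                }
                for r in self.tm_ranges
            ],
            "loop_ranges": {k: list(v) for k, v in self.loop_ranges.items()},
        }
        Path(path).write_text(json.dumps(data, indent=2))


def bw_label(resid: int, bw_map: BWMap) -> str | None:
    """Functional form of :meth:`BWMap.bw_label`."""
    return bw_map.bw_label(resid)


def default_bw_map() -> BWMap:
    """The bundled SSTR2 map (helix endpoints and loop spans)."""
    ref = resources.files("gpcrdyn.data").joinpath("sstr2_bw.json")
    return BWMap._from_dict(json.loads(ref.read_text()))


# ---------------------------------------------------------------------------
# Multi-model PDB I/O
# ---------------------------------------------------------------------------


def _prescan_pdb(path: Path) -> list[int]:
    """Validate MODEL structure; return per-model atom counts.

    Rejects insertion codes and mismatched per-model atom counts with
    errors naming the offending model.
    """
    counts: list[int] = []
    current: int | None = None
    model_no: list[int] = []
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                if current is not None:
                    counts.append(current)
                current = 0
                try:
                    model_no.append(int(line[10:14]))
                except ValueError:
                    model_no.append(len(model_no) + 1)
            elif rec in ("ATOM  ", "HETATM"):
                if len(line) > 26 and line[26] not in (" ", ""):
                    raise PDBParseError(
                        f"{path}: insertion code {line[26]!r} at serial {line[6:11].strip()} "
                        "is not supported"
                    )
                if current is None:
                    current = 0
                    model_no.append(1)
                current += 1
            elif rec == "ENDMDL":
                if current is not None:
                    counts.append(current)
                    current = None
    if current is not None:
        counts.append(current)
    if not counts or all(c == 0 for c in counts):
        raise PDBParseError(f"{path}: no atoms found")
    first = counts[0]
    for i, c in enumerate(counts):
        if c != first:
            label = model_no[i] if i < len(model_no) else i + 1
            raise PDBParseError(
                f"{path}: MODEL {label} has {c} atoms, expected {first} "
                "(atom count must match across models)"
            )
    if saw_model and 0 in counts:
        raise PDBParseError(f"{path}: empty MODEL present")
    return counts


def read_multimodel_pdb(path: str | Path) -> Trajectory:
    """Read a (possibly multi-model) PDB file into a :class:`Trajectory`.

    One frame per MODEL; atom order, chain, resid and resname are
    preserved. Element symbols come from the element column when present
    and are otherwise inferred from the atom name.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), in_memory=True)

    names = u.atoms.names
    resnames = u.atoms.resnames
    resids = u.atoms.resids
    try:
        chains = u.atoms.chainIDs
    except AttributeError:
        chains = np.array([""] * len(u.atoms))
    try:
        file_elements = [e.strip().upper() for e in u.atoms.elements]
    except AttributeError:
        file_elements = [""] * len(u.atoms)

    atoms = []
    for i in range(len(u.atoms)):
        elem = file_elements[i] or infer_element(names[i], resnames[i])
        mass = ATOMIC_MASSES.get(elem)
        if mass is None:
            raise PDBParseError(f"{path}: no standard atomic mass for element {elem!r}")
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name=str(names[i]),
                element=elem,
                resname=str(resnames[i]),
                resid=int(resids[i]),
                chain=str(chains[i]).strip(),
                mass=mass,
            )
        )
    top = Topology(atoms)
    coords = np.stack([ts.positions.astype(float) for ts in u.trajectory], axis=0)
    return Trajectory(top, coords)


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL records)."""
    path = Path(path)
    top = traj.topology
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i, a in enumerate(top.atoms):
                x, y, z = traj.coords[f, i]
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {a.serial % 100000:5d} {name:<4s}{a.resname:>4s} "
                    f"{(a.chain or 'A')[:1]}{a.resid:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{a.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Binary trajectories (DCD / XTC) via MDAnalysis readers
# ---------------------------------------------------------------------------

_FORMATS = {"DCD", "XTC"}


def read_binary_trajectory(topology: Topology, path: str | Path, format: str) -> Trajectory:
    """Read a DCD or XTC file against an existing topology.

    Coordinates are returned in Angstrom (XTC nm are converted). The file's
    atom count must match the topology; a mismatch raises carrying both
    counts. A zero-frame file yields an empty trajectory.
    """
    import MDAnalysis as mda

    fmt = format.upper()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported trajectory format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.load_new(str(path), format=fmt)
    except Exception as exc:  # MDAnalysis raises format-specific errors
        msg = str(exc)
        if "empty file" in msg.lower() or "no frames" in msg.lower():
            return Trajectory(topology, np.zeros((0, topology.n_atoms, 3)))
        if "atom" in msg.lower() or "natoms" in msg.lower():
            raise TrajectoryFormatError(
                f"{path}: atom count in file does not match topology count {topology.n_atoms}: {msg}"
            ) from exc
        raise
    n_in_file = u.trajectory.n_atoms
    if n_in_file != topology.n_atoms:
        raise TrajectoryFormatError(
            f"{path}: file has {n_in_file} atoms but topology has {topology.n_atoms}"
        )
    frames = [ts.positions.astype(float).copy() for ts in u.trajectory]
    if frames:
        coords = np.stack(frames, axis=0)
        spacing = float(getattr(u.trajectory, "dt", 1.0) or 1.0)
    else:
        coords = np.zeros((0, topology.n_atoms, 3))
        spacing = 1.0
    return Trajectory(topology, coords, frame_spacing=spacing)


def write_binary_trajectory(traj: Trajectory, path: str | Path, format: str) -> None:
    """Write frames to DCD or XTC (Angstrom in; XTC stored as nm)."""
    import MDAnalysis as mda

    fmt = format.upper()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported trajectory format {format!r}")
    n = traj.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    u.trajectory.ts.dt = traj.frame_spacing
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n, format=fmt, dt=traj.frame_spacing) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coords[f]
                u.trajectory.ts.frame = f
                w.write(u.atoms)
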