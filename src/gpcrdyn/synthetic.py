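"""Ground-truth synthetic data: a seven-helix pseudo-receptor whose
flexible loop switches between two metastable geometric states under a
two-state Markov chain, and a posable toy ligand realizing chosen
interaction types.

The pseudo-receptor is alpha-carbon resolution, numbered 44..315 so the
bundled SSTR2 Ballesteros-Weinstein map applies. The ECL2 tip (residues
187-189) is placed so the gating variables (delta, beta) hit chosen
closed- and open-state targets exactly in the noise-free anchors; frames
interpolate between the anchors per the hidden Markov state plus isotropic
Gaussian noise. The hidden states are returned, so occupancy estimators
can be tested under realistic frame-to-frame correlation rather than
i.i.d. sampling.

Ligand poses carry proxy side-chain atoms on their receptor partners, so
the fingerprint detectors see real chemistry; everything else stays
alpha-carbon only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .fingerprints import ChemTemplates, InteractionParams, default_templates
from .states import StateThresholds
from .traj_model import ATOMIC_MASSES, AtomRecord, Topology, Trajectory

__all__ = [
    "SyntheticSpec",
    "SyntheticSpecError",
    "generate_receptor_trajectory",
    "generate_ligand_pose",
    "generate_complex_trajectory",
    "occupancy_interval",
]

RESID_FIRST, RESID_LAST = 44, 315
HELIX_RADIUS = 11.0  # Angstrom, bundle circle radius
CA_RISE = 1.5  # Angstrom per residue along a helix axis
LOOP_BULGE = 4.0

# residues referenced by the collective variables and fingerprint examples
_SPECIAL_RESNAMES = {
    80: "ILE", 122: "ASP", 126: "GLN", 177: "ILE", 181: "ALA", 187: "GLN",
    188: "TRP", 189: "GLY", 195: "ILE", 200: "GLU", 201: "SER", 225: "CYS",
    255: "THR", 268: "CYS", 281: "SER", 286: "PRO", 288: "PRO", 305: "SER",
}

_TM_SPANS = [(44, 70), (77, 104), (112, 145), (150, 181), (202, 237), (245, 280), (288, 315)]
# alternating membrane crossing: odd helices run top->bottom
_TM_DOWN = [True, False, True, False, True, False, True]


class SyntheticSpecError(ValueError):
    """Invalid synthetic-trajectory specification."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic system.

    ``p_closed`` is the stationary closed-state probability of the loop's
    two-state Markov chain; ``dwell_closed`` its mean closed dwell time in
    frames, which sets the chain's autocorrelation. Anchor geometries are
    (delta, beta) targets in Angstrom/degrees and must sit inside
    (closed) / outside (open) the classifier box with a safety margin.
    """

    n_frames: int = 1000
    frame_spacing: float = 1.0  # ps between saved frames
    p_closed: float = 0.5
    dwell_closed: float = 20.0  # frames
    noise_sd: float = 0.25  # Angstrom, isotropic per atom
    closed_geometry: tuple[float, float] = (28.5, 38.5)
    open_geometry: tuple[float, float] = (40.0, 85.0)
    delta_margin: float = 0.5  # Angstrom, anchor clearance from box edges
    beta_margin: float = 2.0  # degrees
    ligand_plan: tuple[tuple[str, int], ...] = ()
    contact_margin: float = 0.5  # Angstrom satisfied-by margin of planted contacts
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_closed <= 1.0:
            raise SyntheticSpecError("p_closed must lie in [0, 1]")
        if self.noise_sd < 0:
            raise SyntheticSpecError("noise_sd must be >= 0")
        if self.dwell_closed < 1:
            raise SyntheticSpecError("dwell_closed must be >= 1 frame")

    def validate_anchors(self, thresholds: StateThresholds | None = None) -> None:
        t = thresholds or StateThresholds()
        dc, bc = self.closed_geometry
        if not (
            dc - t.delta_min >= self.delta_margin
            and t.delta_max - dc >= self.delta_margin
            and bc - t.beta_min >= self.beta_margin
            and t.beta_max - bc >= self.beta_margin
        ):
            raise SyntheticSpecError(
                f"closed anchor (delta={dc}, beta={bc}) is not inside the closed box "
                f"with margins ({self.delta_margin} A, {self.beta_margin} deg)"
            )
        do, bo = self.open_geometry
        delta_out = do >= t.delta_max + self.delta_margin or do <= t.delta_min - self.delta_margin
        beta_out = bo >= t.beta_max + self.beta_margin or bo <= t.beta_min - self.beta_margin
        if not (delta_out or beta_out):
            raise SyntheticSpecError(
                f"open anchor (delta={do}, beta={bo}) is not outside the closed box with margin"
            )


# ---------------------------------------------------------------------------
# Receptor scaffold
# ---------------------------------------------------------------------------


def _helix_positions() -> dict[int, np.ndarray]:
    """Noise-free alpha-carbon anchors for all TM residues."""
    pos: dict[int, np.ndarray] = {}
    for k, ((lo, hi), down) in enumerate(zip(_TM_SPANS, _TM_DOWN)):
        ang = 2.0 * np.pi * k / 7.0
        x, y = HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang)
        n = hi - lo + 1
        half = 0.5 * (n - 1) * CA_RISE
        for j, resid in enumerate(range(lo, hi + 1)):
            z = half - j * CA_RISE if down else -half + j * CA_RISE
            pos[resid] = np.array([x, y, z])
    return pos


def _loop_fill(pos: dict[int, np.ndarray], lo: int, hi: int) -> None:
    """Interpolate a loop between its flanking helix anchors with an
    outward bulge (simple arc; no physics intended)."""
    a, b = pos[lo - 1], pos[hi + 1]
    mid_dir = (a + b) / 2.0
    xy = mid_dir[:2]
    outward = np.array([*(xy / (np.linalg.norm(xy) + 1e-12)), 0.0])
    z_dir = np.array([0.0, 0.0, 1.0 if mid_dir[2] > 0 else -1.0])
    m = hi - lo + 1
    for j, resid in enumerate(range(lo, hi + 1)):
        t = (j + 1) / (m + 1)
        bulge = LOOP_BULGE * np.sin(np.pi * t)
        pos[resid] = (1 - t) * a + t * b + bulge * (0.7 * outward + 0.7 * z_dir)


def _segment(p_from: np.ndarray, p_to: np.ndarray, resids: range, pos: dict[int, np.ndarray]) -> None:
    m = len(resids)
    for j, resid in enumerate(resids):
        t = (j + 1) / (m + 1)
        pos[resid] = (1 - t) * p_from + t * p_to


def _solve_tip(delta: float, beta: float, B2: np.ndarray, E: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Point P with |P - C| = delta and angle(P, B2, E) = beta.

    P is sought in the plane through B2 spanned by the ECL3-base direction
    and the outward (away-from-bundle-centre) direction, at distance r
    from B2; the angle constraint is satisfied exactly by construction and
    r is solved for the distance constraint.
    """
    u = E - B2
    u = u / np.linalg.norm(u)
    v = B2 - C
    w = v - np.dot(v, u) * u
    wn = np.linalg.norm(w)
    if wn < 1e-9:
        raise SyntheticSpecError("degenerate scaffold: loop base is collinear with bundle centre")
    w = w / wn

    # Either in-plane orientation of the tip satisfies the angle exactly;
    # collect all radii satisfying the distance and keep the one with a
    # comfortable lever arm (|P - B2| near 12 A), so small positional
    # noise does not blow up into large angle noise.
    candidates: list[tuple[float, np.ndarray]] = []
    for sign in (+1.0, -1.0):
        direction = np.cos(np.radians(beta)) * u + sign * np.sin(np.radians(beta)) * w

        def f(r: float, d=direction) -> float:
            return float(np.linalg.norm(B2 + r * d - C)) - delta

        rs = np.linspace(0.05, 80.0, 800)
        vals = [f(r) for r in rs]
        for (r1, f1), (r2, f2) in zip(zip(rs, vals), zip(rs[1:], vals[1:])):
            if f1 == 0:
                candidates.append((r1, direction))
            elif f1 * f2 < 0:
                candidates.append((brentq(f, r1, r2), direction))
    if not candidates:
        raise SyntheticSpecError(
            f"tip geometry (delta={delta}, beta={beta}) unreachable on this scaffold"
        )
    # a short tip-to-base lever arm amplifies positional noise into angle
    # noise, so insist on r >= 8 A when such a root exists
    long_arm = [c for c in candidates if c[0] >= 8.0]
    pool = long_arm or candidates
    r, direction = min(pool, key=lambda c: abs(c[0] - 12.0))
    return B2 + r * direction


def _build_anchor(state_geometry: tuple[float, float]) -> tuple[list[int], np.ndarray]:
    """Full-receptor anchor coordinates for one loop state."""
    pos = _helix_positions()
    # loops other than ECL2 are state-independent
    for lo, hi in ((71, 76), (105, 111), (146, 149), (238, 244), (281, 287)):
        _loop_fill(pos, lo, hi)

    tm_pts = np.array([pos[r] for span in _TM_SPANS for r in range(span[0], span[1] + 1)])
    C = tm_pts.mean(axis=0)
    # I195 is pinned near the TM5 end of the loop so the ECL2 base (A181,
    # I195 midpoint) does not move with the tip
    p202 = pos[202]
    xy = p202[:2] / np.linalg.norm(p202[:2])
    pos[195] = p202 + np.array([3.0 * xy[0], 3.0 * xy[1], 2.0])
    B2 = 0.5 * (pos[181] + pos[195])
    E = 0.5 * (pos[281] + pos[288])

    delta, beta = state_geometry
    P = _solve_tip(delta, beta, B2, E, C)
    u = E - B2
    u = u / np.linalg.norm(u)
    v = B2 - C
    w = v - np.dot(v, u) * u
    w = w / np.linalg.norm(w)
    normal = np.cross(u, w)
    pos[188] = P
    pos[187] = P + 1.2 * normal
    pos[189] = P - 1.2 * normal
    _segment(pos[181], pos[187], range(182, 187), pos)
    _segment(pos[189], pos[195], range(190, 195), pos)
    _segment(pos[195], pos[202], range(196, 202), pos)

    resids = list(range(RESID_FIRST, RESID_LAST + 1))
    coords = np.array([pos[r] for r in resids])
    return resids, coords


def _receptor_topology(resids: list[int]) -> Topology:
    atoms = [
        AtomRecord(
            serial=i + 1,
            name="CA",
            element="C",
            resname=_SPECIAL_RESNAMES.get(r, "ALA"),
            resid=r,
            chain="A",
            mass=ATOMIC_MASSES["C"],
        )
        for i, r in enumerate(resids)
    ]
    return Topology(atoms)


def _markov_states(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Hidden closed(1)/open(0) states of the stationary two-state chain."""
    p = spec.p_closed
    n = spec.n_frames
    if p == 0.0:
        return np.zeros(n, dtype=int)
    if p == 1.0:
        return np.ones(n, dtype=int)
    p_co = min(1.0, 1.0 / spec.dwell_closed)  # closed -> open
    p_oc = p * p_co / (1.0 - p)  # open -> closed, from detailed balance
    if p_oc > 1.0:
        raise SyntheticSpecError(
            f"dwell_closed={spec.dwell_closed} is incompatible with p_closed={p}"
        )
    states = np.empty(n, dtype=int)
    states[0] = int(rng.random() < p)
    u = rng.random(n - 1)
    for i in range(1, n):
        if states[i - 1] == 1:
            states[i] = 0 if u[i - 1] < p_co else 1
        else:
            states[i] = 1 if u[i - 1] < p_oc else 0
    return states


def generate_receptor_trajectory(
    spec: SyntheticSpec, thresholds: StateThresholds | None = None
) -> tuple[Trajectory, np.ndarray]:
    """Synthetic receptor trajectory plus the exact hidden state labels.

    Returns ``(trajectory, labels)`` with labels in {"closed", "open"}.
    Anchor geometries are validated against the classifier box before any
    frame is produced; the same seed yields a bit-identical trajectory.
    """
    spec.validate_anchors(thresholds)
    rng = np.random.default_rng(spec.seed)
    resids, closed_anchor = _build_anchor(spec.closed_geometry)
    _, open_anchor = _build_anchor(spec.open_geometry)
    top = _receptor_topology(resids)
    states = _markov_states(spec, rng)
    anchors = np.stack([open_anchor, closed_anchor])  # index by state
    coords = anchors[states]
    if spec.noise_sd > 0:
        coords = coords + rng.normal(0.0, spec.noise_sd, size=coords.shape)
    labels = np.where(states == 1, "closed", "open")
    return Trajectory(top, coords, frame_spacing=spec.frame_spacing), labels


def occupancy_interval(
    p: float, n_frames: int, dwell_closed: float = 20.0, level: float = 0.99
) -> tuple[float, float]:
    """Confidence interval (percent) for the closed-state occupancy
    estimated from a stationary two-state Markov chain of given length.

    The binomial variance is inflated by the chain's autocorrelation
    factor (1 + rho) / (1 - rho) with rho = 1 - p_co - p_oc. Degenerate
    chains (p of 0 or 1) have a zero-width interval.
    """
    if p in (0.0, 1.0):
        return 100.0 * p, 100.0 * p
    p_co = min(1.0, 1.0 / dwell_closed)
    p_oc = p * p_co / (1.0 - p)
    rho = 1.0 - p_co - p_oc
    var = p * (1.0 - p) / n_frames * (1.0 + rho) / (1.0 - rho)
    z = norm.ppf(0.5 + level / 2.0)
    half = 100.0 * z * np.sqrt(var)
    return max(0.0, 100.0 * p - half), min(100.0, 100.0 * p + half)


# ---------------------------------------------------------------------------
# Ligand poses with planted interactions
# ---------------------------------------------------------------------------

_PLANT_TYPES = ("hydrophobic", "hbond", "pipi", "saltbridge", "cationpi")


def _hexagon(center: np.ndarray, normal: np.ndarray, tangent: np.ndarray, radius: float = 1.39) -> list[np.ndarray]:
    t2 = np.cross(normal, tangent)
    return [
        center + radius * (np.cos(a) * tangent + np.sin(a) * t2)
        for a in np.linspace(0.0, 2 * np.pi, 6, endpoint=False)
    ]


def _plant_geometry(
    typ: str, ca: np.ndarray, outward: np.ndarray, params: InteractionParams, margin: float
) -> tuple[str, list[tuple[str, str, np.ndarray]], str, list[tuple[str, str, np.ndarray]]]:
    """Proxy atoms for one planted contact.

    Returns (receptor resname, receptor atoms, ligand resname, ligand
    atoms); atoms are (name, element, position). Distances are chosen to
    satisfy the detector criterion with at least ``margin`` clearance and
    to avoid tripping any other detector.
    """
    o = outward
    z = np.array([0.0, 0.0, 1.0])
    t = np.cross(z, o)
    t = t / np.linalg.norm(t)
    if typ == "saltbridge":
        cb, cg = ca + 1.5 * o, ca + 3.0 * o
        od1 = cg + 1.2 * (np.cos(0.9) * o + np.sin(0.9) * z)
        od2 = cg + 1.2 * (np.cos(0.9) * o - np.sin(0.9) * z)
        d = params.saltbridge_cutoff - 1.0
        nz = od1 + d * o
        hz = nz + 1.0 * o  # points away: the H-bond angle criterion fails
        ce = nz + 1.5 * (0.5 * o + 0.87 * z)
        return (
            "ASP", [("CB", "C", cb), ("CG", "C", cg), ("OD1", "O", od1), ("OD2", "O", od2)],
            "LYS", [("NZ", "N", nz), ("HZ1", "H", hz), ("CE", "C", ce)],
        )
    if typ == "hbond":
        cb, og = ca + 1.5 * o, ca + 2.9 * o
        d = params.hbond_dist - 0.6
        og_l = og + d * o
        hg_l = og_l - 1.0 * o  # on the donor-acceptor line: angle 180 deg
        cb_l = og_l + 1.5 * o
        return (
            "SER", [("CB", "C", cb), ("OG", "O", og)],
            "SER", [("OG", "O", og_l), ("HG", "H", hg_l), ("CB", "C", cb_l)],
        )
    if typ == "hydrophobic":
        cb, cg, cd1 = ca + 1.5 * o, ca + 3.0 * o, ca + 4.5 * o
        d = params.hydrophobic_cutoff - 0.7
        cd1_l = cd1 + d * o
        cg_l = cd1_l + 1.5 * o
        cb_l = cg_l + 1.5 * o
        return (
            "LEU", [("CB", "C", cb), ("CG", "C", cg), ("CD1", "C", cd1)],
            "LEU", [("CD1", "C", cd1_l), ("CG", "C", cg_l), ("CB", "C", cb_l)],
        )
    if typ == "pipi":
        cb = ca + 1.5 * o
        center = ca + 3.2 * o
        ring = _hexagon(center, o, t)
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        # centroid offset: inside the pi-pi cutoff with margin, but far
        # enough that no atom pair is inside the hydrophobic cutoff
        lo = params.hydrophobic_cutoff + margin
        hi = params.pipi_centroid_cutoff - margin
        if lo > hi:
            raise SyntheticSpecError(
                "pi-pi plant infeasible: cannot separate the stacking cutoff from "
                "the hydrophobic cutoff at this contact margin"
            )
        d = 0.5 * (lo + hi)
        ring_l = [p + d * o for p in ring]
        return (
            "PHE", [("CB", "C", cb)] + [(n, "C", p) for n, p in zip(names, ring)],
            "PHE", [(n, "C", p) for n, p in zip(names, ring_l)],
        )
    if typ == "cationpi":
        cb = ca + 1.5 * o
        center = ca + 3.2 * o
        ring = _hexagon(center, o, t)
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        d = params.cationpi_cutoff - margin
        nz = center + d * o
        hz = nz + 1.0 * o
        ce = nz + 1.5 * (0.5 * o + 0.87 * z)
        return (
            "PHE", [("CB", "C", cb)] + [(n, "C", p) for n, p in zip(names, ring)],
            "LYS", [("NZ", "N", nz), ("HZ1", "H", hz), ("CE", "C", ce)],
        )
    raise SyntheticSpecError(f"no geometric recipe for interaction type {typ!r}")


def generate_ligand_pose(
    spec: SyntheticSpec,
    templates: ChemTemplates | None = None,
    params: InteractionParams | None = None,
) -> tuple[Trajectory, list[tuple[int, int, str]]]:
    """Single-frame receptor-ligand complex realizing the planted contacts.

    Each plan entry (interaction type, receptor resid) gains proxy
    side-chain atoms on the receptor residue and a ligand residue (chain
    ``L``, resids 1..n) posed to satisfy exactly that detector criterion.
    Returns the complex and the expected (receptor resid, ligand resid,
    type) manifest. Mutually conflicting plants (geometry of one plant
    encroaching on another's partner) are rejected.
    """
    params = params or InteractionParams()
    for typ, _ in spec.ligand_plan:
        if typ not in _PLANT_TYPES:
            raise SyntheticSpecError(f"unknown interaction type in ligand plan: {typ!r}")
    resids, closed_anchor = _build_anchor(spec.closed_geometry)
    pos = {r: closed_anchor[i] for i, r in enumerate(resids)}

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = 0
    plant_by_resid: dict[int, tuple[str, int]] = {}
    for i, (typ, rr) in enumerate(spec.ligand_plan):
        if rr not in pos:
            raise SyntheticSpecError(f"ligand plan references residue {rr} outside the receptor")
        if rr in plant_by_resid:
            raise SyntheticSpecError(f"residue {rr} used by two plants")
        plant_by_resid[rr] = (typ, i + 1)

    ligand_atoms: dict[int, tuple[str, list[tuple[str, str, np.ndarray]]]] = {}
    receptor_proxy: dict[int, tuple[str, list[tuple[str, str, np.ndarray]]]] = {}
    for rr, (typ, lig_resid) in plant_by_resid.items():
        ca = pos[rr]
        xy = ca[:2]
        nrm = np.linalg.norm(xy)
        if nrm < 1e-9:
            raise SyntheticSpecError(f"residue {rr} lies on the bundle axis; cannot orient a plant")
        outward = np.array([xy[0] / nrm, xy[1] / nrm, 0.0])
        r_name, r_atoms, l_name, l_atoms = _plant_geometry(typ, ca, outward, params, spec.contact_margin)
        receptor_proxy[rr] = (r_name, r_atoms)
        ligand_atoms[lig_resid] = (l_name, l_atoms)

    # conflict check: every ligand residue must be clear of all receptor
    # residues other than its own partner
    clearance = params.max_cutoff + spec.contact_margin
    for lig_resid, (_, l_atoms) in ligand_atoms.items():
        lpts = np.array([p for _, _, p in l_atoms])
        for rr2, (_, r_atoms2) in receptor_proxy.items():
            if plant_by_resid[rr2][1] == lig_resid:
                continue
            rpts = np.array([p for _, _, p in r_atoms2] + [pos[rr2]])
            d = np.linalg.norm(lpts[:, None, :] - rpts[None, :, :], axis=2).min()
            if d < clearance:
                raise SyntheticSpecError(
                    f"conflicting plants: ligand residue {lig_resid} comes within "
                    f"{d:.2f} A of receptor residue {rr2} (needs >= {clearance:.2f} A)"
                )

    for r in resids:
        typ_plant = plant_by_resid.get(r)
        resname = receptor_proxy[r][0] if typ_plant else _SPECIAL_RESNAMES.get(r, "ALA")
        serial += 1
        atoms.append(AtomRecord(serial, "CA", "C", resname, r, "A", ATOMIC_MASSES["C"]))
        coords.append(pos[r])
        if typ_plant:
            for name, elem, p in receptor_proxy[r][1]:
                serial += 1
                atoms.append(AtomRecord(serial, name, elem, resname, r, "A", ATOMIC_MASSES[elem]))
                coords.append(p)
    for lig_resid in sorted(ligand_atoms):
        l_name, l_atoms = ligand_atoms[lig_resid]
        for name, elem, p in l_atoms:
            serial += 1
            atoms.append(AtomRecord(serial, name, elem, l_name, lig_resid, "L", ATOMIC_MASSES[elem]))
            coords.append(p)

    top = Topology(atoms)
    traj = Trajectory(top, np.array(coords)[None, :, :], frame_spacing=spec.frame_spacing)
    manifest = [(rr, lig, typ) for rr, (typ, lig) in sorted(plant_by_resid.items())]
    return traj, manifest


def generate_complex_trajectory(
    spec: SyntheticSpec,
    templates: ChemTemplates | None = None,
    params: InteractionParams | None = None,
    pose_noise_sd: float = 0.05,
) -> tuple[Trajectory, list[tuple[int, int, str]]]:
    """Tile the planted pose over ``spec.n_frames`` with small positional
    noise (kept well inside the contact margins), for persistence tests."""
    pose, manifest = generate_ligand_pose(spec, templates, params)
    rng = np.random.default_rng(spec.seed)
    base = pose.coords[0]
    coords = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    if pose_noise_sd > 0:
        coords = coords + rng.normal(0.0, pose_noise_sd, size=coords.shape)
    return Trajectory(pose.topology, coords, frame_spacing=spec.frame_spacing), manifest
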