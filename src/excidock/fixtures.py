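"""Deterministic toy systems with planted ground truth.

Everything the tests and the demo dock is generated here: compact
pseudo-protein receptors with a concave polar pocket whose location is
known by construction, four classes of excipient-like ligand topologies
(amino-acid-, disaccharide-, polyol- and surfactant-like), pairs of
proteins with geometrically and electrostatically complementary flat
patches, and multi-model snapshot trajectories with controlled contact
persistence.  Fixtures use simplified pseudo-atom chemistry (one C-alpha
plus one side-chain pseudo-atom per residue) rather than real amino-acid
geometry: the algorithms under test operate on distances, types and
charges, not force-field realism.  Every generator is bit-reproducible
from its seed and returns its planted ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flex_dock import LigandTopology, detect_rotatable_bonds
from .scoring import ScoringContext, SearchBox, AtomTyping, DEFAULT_SCORING
from .structio import AtomRecord, ResidueKey, Structure, contact_residues
from .traj_analysis import Trajectory


@dataclass(frozen=True)
class PocketRequest:
    """Requested lining composition of the planted pocket."""

    n_donor: int = 0      # SER OG pseudo-atoms
    n_acceptor: int = 0   # ASN OD1 pseudo-atoms
    n_negative: int = 4   # ASP OD2 pseudo-atoms (-1)
    n_positive: int = 0   # LYS NZ pseudo-atoms (+1)

    @property
    def total(self) -> int:
        return self.n_donor + self.n_acceptor + self.n_negative + self.n_positive


@dataclass
class PocketSpec:
    """Planted pocket ground truth."""

    residues: list[ResidueKey]
    center: np.ndarray
    request: PocketRequest


@dataclass(frozen=True)
class FixtureSeed:
    seed: int
    n_residues: int = 30
    n_frames: int = 20
    noise_sigma: float = 0.1


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors, index 0 nearest the +z pole."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _atom(serial: int, name: str, element: str, res_name: str, chain: str,
          res_seq: int, xyz, charge: int = 0, het: bool = False) -> AtomRecord:
    return AtomRecord(serial=serial, name=name, element=element,
                      res_name=res_name, chain_id=chain, res_seq=res_seq,
                      coords=tuple(float(v) for v in xyz),
                      formal_charge=charge, het=het)


_LINING_TEMPLATES = {
    "donor": ("SER", "OG", "O", 0),
    "acceptor": ("ASN", "OD1", "O", 0),
    "negative": ("ASP", "OD2", "O", 0),
    "positive": ("LYS", "NZ", "N", 0),
}


def make_toy_receptor(
    seed: int,
    n_residues: int = 30,
    pocket: PocketRequest = PocketRequest(),
    radius: float = 8.0,
    verify: bool = True,
) -> tuple[Structure, PocketSpec]:
    """Globular pseudo-protein with a concave polar pocket at the +z pole.

    Residues sit on a quasi-uniform spherical shell (C-alpha at the shell,
    side pseudo-atom pointing outward); the pocket lining side atoms are
    re-placed on a ring around the pocket center, realising the requested
    donor/acceptor/charged composition.  The surface away from the pocket
    is alanine-like (apolar), so for a polar/charged probe the global
    energy optimum lies inside the pocket; with verify=True a coarse grid
    scan of a charged donor probe asserts this at build time.
    """
    if n_residues < 8:
        raise ValueError("need at least 8 residues")
    if pocket.total > n_residues // 2:
        raise ValueError("infeasible pocket request: too many lining residues")
    if pocket.total < 1:
        raise ValueError("pocket needs at least one lining atom")
    rng = np.random.default_rng(seed)
    units = _fibonacci_sphere(n_residues)
    # small deterministic jitter so different seeds give different receptors
    jitter = rng.normal(0.0, 0.12, size=units.shape)
    units = units + jitter
    units /= np.linalg.norm(units, axis=1, keepdims=True)
    order = np.argsort(-units[:, 2])  # pole-first
    units = units[order]

    center = np.array([0.0, 0.0, radius + 3.5])
    # polar (donor/acceptor) lining atoms sit on a ring around the centre at
    # hydrogen-bond distance; charged lining atoms sit on the pocket axis
    # just below the centre, so the electrostatic optimum for a
    # complementary probe is the pocket centre itself, in simultaneous
    # hydrogen-bond range of the whole ring
    ring_kinds = ["donor"] * pocket.n_donor + ["acceptor"] * pocket.n_acceptor
    axis_kinds = ["negative"] * pocket.n_negative + ["positive"] * pocket.n_positive
    lining_kinds = ring_kinds + axis_kinds
    k = len(lining_kinds)
    positions = []
    p = max(len(ring_kinds), 1)
    theta = 2.0 * np.pi * (np.arange(p) + 0.25) / p
    for j in range(len(ring_kinds)):
        positions.append(center + 2.6 * np.array(
            [np.cos(theta[j]), np.sin(theta[j]), 0.0]))
    m = max(len(axis_kinds), 1)
    for j in range(len(axis_kinds)):
        ang = 2.0 * np.pi * (j + 0.5) / m
        positions.append(center + np.array(
            [0.9 * np.cos(ang), 0.9 * np.sin(ang), -0.25 + 0.5 * (j % 2)]))
    ring = np.array(positions)

    atoms: list[AtomRecord] = []
    pocket_keys: list[ResidueKey] = []
    serial = 1
    for i in range(n_residues):
        ca = radius * units[i]
        if i < k:
            res_name, side_name, side_el, q = _LINING_TEMPLATES[lining_kinds[i]]
            side = ring[i]
        else:
            res_name, side_name, side_el, q = "ALA", "CB", "C", 0
            side = (radius + 1.5) * units[i]
        res_seq = i + 1
        atoms.append(_atom(serial, "CA", "C", res_name, "A", res_seq, ca))
        serial += 1
        atoms.append(_atom(serial, side_name, side_el, res_name, "A", res_seq, side, q))
        serial += 1
        if i < k:
            pocket_keys.append(ResidueKey("A", res_name, res_seq, ""))
    receptor = Structure(atoms)
    spec = PocketSpec(residues=pocket_keys, center=center, request=pocket)
    if verify:
        _verify_pocket(receptor, spec)
    return receptor, spec


def _verify_pocket(receptor: Structure, spec: PocketSpec) -> None:
    """Coarse 2-A grid scan of a charged donor probe; the optimum must lie
    within 3 A of the planted pocket center."""
    box = SearchBox.around(receptor, margin=5.0)
    probe_type = [AtomTyping(donor=True, acceptor=True, charge=+1)]
    ctx = ScoringContext(receptor, probe_type, box)
    lo, hi = np.asarray(box.lo), np.asarray(box.hi)
    axes = [np.arange(lo[k], hi[k], 2.0) for k in range(3)]
    grid = np.stack([g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=1)
    energies = np.array([ctx.score(p[None, :]).e_total for p in grid])
    best = grid[int(np.argmin(energies))]
    if np.linalg.norm(best - spec.center) > 3.0:
        raise ValueError(
            "pocket construction failed: probe optimum at "
            f"{best} not within 3 A of planted center {spec.center}"
        )


# ---------------------------------------------------------------------------
# Ligand topologies
# ---------------------------------------------------------------------------

_BOND = 1.5
_ZIG = np.array([1.2247, 0.0, 0.8660]) * (_BOND / 1.5)
_ZAG = np.array([1.2247, 0.0, -0.8660]) * (_BOND / 1.5)


def _chain_coords(n: int, start=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Zig-zag heavy-atom chain with 1.5-A bonds, ~109.5-degree angles."""
    pts = [np.asarray(start, float)]
    for k in range(n - 1):
        pts.append(pts[-1] + (_ZIG if k % 2 == 0 else _ZAG))
    return np.array(pts)


def _hexagon(center, normal_axis: int = 2, radius: float = _BOND) -> np.ndarray:
    ang = np.pi / 3.0 * np.arange(6)
    ring = np.zeros((6, 3))
    axes = [a for a in range(3) if a != normal_axis]
    ring[:, axes[0]] = radius * np.cos(ang)
    ring[:, axes[1]] = radius * np.sin(ang)
    return ring + np.asarray(center, float)


LIGAND_KINDS = ("amino-acid-like", "disaccharide-like", "polyol-like",
                "surfactant-like")


def make_ligand(kind: str, max_torsions: int = 5) -> LigandTopology:
    """Small heavy-atom excipient topology with the class's hallmark features.

    amino-acid-like: one positive charge, several donors, 3-5 torsions;
    disaccharide-like: two rings bridged by a glycosidic link, many
    donors/acceptors, 1-3 torsions; polyol-like: linear carbon chain fully
    hydroxylated, no charge, >= 4 torsions; surfactant-like: polar head and
    long apolar tail, more than 5 rotatable bonds before the cap.
    """
    if kind == "amino-acid-like":
        chain = _chain_coords(5, start=(1.3, 0.0, 0.0))
        coords = [(0.0, 0.0, -0.5)] + [tuple(p) for p in chain] + [(1.3, 1.4, 0.5)]
        names = ["N1", "C1", "C2", "C3", "C4", "N2", "O1"]
        elements = ["N", "C", "C", "C", "C", "N", "O"]
        charges = [1, 0, 0, 0, 0, 0, 0]
        bonds = [(0, 1, 1), (1, 2, 1), (2, 3, 1), (3, 4, 1), (4, 5, 1), (1, 6, 1)]
        res = "EAA"
    elif kind == "disaccharide-like":
        ring1 = _hexagon((0.0, 0.0, 0.0))
        ring2 = _hexagon((5.2, 0.0, 0.0))
        link = np.array([2.6, 0.0, 0.75])
        oh1 = [ring1[2] + (0.0, 1.4, 0.5), ring1[4] + (0.0, -1.4, 0.5)]
        oh2 = [ring2[1] + (0.0, 1.4, 0.5), ring2[5] + (0.0, -1.4, 0.5)]
        coords = [tuple(p) for p in
                  list(ring1) + list(ring2) + [link] + oh1 + oh2]
        names = (["C1A", "C2A", "C3A", "C4A", "C5A", "O5A"]
                 + ["C1B", "C2B", "C3B", "C4B", "C5B", "O5B"]
                 + ["OG", "O2A", "O3A", "O2B", "O3B"])
        elements = ["C", "C", "C", "C", "C", "O"] * 2 + ["O", "O", "O", "O", "O"]
        charges = [0] * 17
        ring_bonds = [(i, (i + 1) % 6, 1) for i in range(6)]
        bonds = (ring_bonds
                 + [(6 + i, 6 + (i + 1) % 6, 1) for i in range(6)]
                 + [(0, 12, 1), (12, 6, 1),          # glycosidic bridge
                    (2, 13, 1), (4, 14, 1), (7, 15, 1), (11, 16, 1)])
        res = "DSC"
    elif kind == "polyol-like":
        chain = _chain_coords(6)
        oh = [tuple(p + (0.0, 1.4, 0.0)) for p in chain]
        coords = [tuple(p) for p in chain] + oh
        names = [f"C{i+1}" for i in range(6)] + [f"O{i+1}" for i in range(6)]
        elements = ["C"] * 6 + ["O"] * 6
        charges = [0] * 12
        bonds = ([(i, i + 1, 1) for i in range(5)]
                 + [(i, 6 + i, 1) for i in range(6)])
        res = "POL"
    elif kind == "surfactant-like":
        head = [(0.0, 1.4, 0.0), (0.0, 0.0, 0.0)]  # OH on head carbon
        chain = _chain_coords(9, start=(1.3, 0.0, 0.4))  # ether O + C8 tail
        coords = head + [tuple(p) for p in chain]
        names = ["O1", "CH"] + ["O2"] + [f"C{i+1}" for i in range(8)]
        elements = ["O", "C", "O"] + ["C"] * 8
        charges = [0] * 11
        bonds = [(0, 1, 1), (1, 2, 1)] + [(i, i + 1, 1) for i in range(2, 10)]
        res = "SRF"
    else:
        raise ValueError(f"unknown ligand kind {kind!r}")
    atoms = [
        _atom(i + 1, n, el, res, "X", 1, xyz, charge=q, het=True)
        for i, (n, el, xyz, q) in enumerate(zip(names, elements, coords, charges))
    ]
    topo = LigandTopology(atoms=atoms, bonds=bonds, name=kind)
    topo.rotatable = detect_rotatable_bonds(topo, max_torsions=max_torsions)
    return topo


# ---------------------------------------------------------------------------
# Complementary protein pair
# ---------------------------------------------------------------------------


def _slab(chain: str, face_res: list[tuple[float, float, str]], seed_jitter: np.ndarray,
          serial0: int = 1) -> tuple[list[AtomRecord], list[ResidueKey]]:
    atoms: list[AtomRecord] = []
    face_keys: list[ResidueKey] = []
    serial = serial0
    res_seq = 1
    for (x, y, res_name) in face_res:
        side_name, el, q = {
            "LYS": ("NZ", "N", 0), "ASP": ("OD2", "O", 0), "ALA": ("CB", "C", 0),
        }[res_name]
        atoms.append(_atom(serial, "CA", "C", res_name, chain, res_seq, (x, y, 0.0)))
        serial += 1
        atoms.append(_atom(serial, side_name, el, res_name, chain, res_seq, (x, y, 1.2), q))
        serial += 1
        face_keys.append(ResidueKey(chain, res_name, res_seq, ""))
        res_seq += 1
    # smaller, rough back layer breaks front/back symmetry
    back = [(-2.2, -2.2), (-2.2, 2.2), (2.2, -2.2), (2.2, 2.2)]
    for bi, (x, y) in enumerate(back):
        z = -4.0 + seed_jitter[bi]
        atoms.append(_atom(serial, "CA", "C", "ALA", chain, res_seq, (x, y, z)))
        serial += 1
        atoms.append(_atom(serial, "CB", "C", "ALA", chain, res_seq, (x, y, z - 1.2)))
        serial += 1
        res_seq += 1
    return atoms, face_keys


def make_ppi_pair(seed: int) -> tuple[Structure, Structure, tuple[set[ResidueKey], set[ResidueKey]]]:
    """Two pseudo-proteins with complementary flat patches.

    Each body is a 3x3 polar-face slab backed by a smaller rough layer; the
    faces carry complementary formal charges (lysine-like + on one side,
    aspartate-like - on the other) so face-to-face packing is the energy
    optimum under the soft-LJ + electrostatic rigid score.  Returns the two
    structures and the planted (receptor-face, ligand-face) residue sets.
    """
    rng = np.random.default_rng(seed)
    grid = [-4.5, 0.0, 4.5]
    face_a: list[tuple[float, float, str]] = []
    face_b: list[tuple[float, float, str]] = []
    for x in grid:
        for y in grid:
            name_a = "LYS" if (x, y) in ((0.0, 0.0), (4.5, 4.5)) else "ALA"
            name_b = "ASP" if (x, y) in ((0.0, 0.0), (4.5, -4.5)) else "ALA"
            face_a.append((x, y, name_a))
            face_b.append((x, y, name_b))
    jit_a = rng.normal(0.0, 0.3, size=4)
    jit_b = rng.normal(0.0, 0.3, size=4)
    atoms_a, keys_a = _slab("A", face_a, jit_a)
    atoms_b, keys_b = _slab("B", face_b, jit_b)
    receptor = Structure(atoms_a)
    ligand = Structure(atoms_b)
    return receptor, ligand, (set(keys_a), set(keys_b))


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryTruth:
    contact_residues: set[ResidueKey]
    expected_persistence: float
    ligand_res_name: str = "LIG"


def make_trajectory(
    base: Structure,
    ligand_pose: Structure,
    n_frames: int = 20,
    noise_sigma: float = 0.1,
    hold_contact: bool = True,
    seed: int = 0,
    ligand_res_name: str = "LIG",
) -> tuple[Trajectory, TrajectoryTruth]:
    """Snapshot series of receptor + ligand with controlled contact.

    Gaussian positional noise is applied per frame; with hold_contact the
    ligand-residue minimum distance is rescaled each frame to stay <= 4 A,
    otherwise the ligand drifts beyond 4 A after the first half of the
    frames, so the expected contact persistence is exactly
    ceil(n/2)/n.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    lig_atoms = [
        AtomRecord(serial=10000 + i, name=a.name, element=a.element,
                   res_name=ligand_res_name, chain_id="X", res_seq=999,
                   coords=a.coords, formal_charge=a.formal_charge, het=True)
        for i, a in enumerate(ligand_pose.atoms)
    ]
    lig_ref = np.array([a.coords for a in lig_atoms])
    targets = contact_residues(base, lig_ref, cutoff=4.0)
    if not targets:
        # nearest residue fallback so the truth selection is never empty
        d = np.linalg.norm(base.heavy_coords()[:, None, :] - lig_ref[None, :, :], axis=2)
        i = int(np.unravel_index(np.argmin(d), d.shape)[0])
        targets = {base.atoms[base.heavy_indices[i]].residue_key}
    res_idx = np.array([i for i, a in enumerate(base.atoms)
                        if a.is_heavy and a.residue_key in targets])
    base_coords = base.coords
    n_contact = (n_frames + 1) // 2
    frames: list[Structure] = []
    for f in range(n_frames):
        rc = base_coords + rng.normal(0.0, noise_sigma, size=base_coords.shape)
        lc = lig_ref + rng.normal(0.0, min(noise_sigma, 0.1), size=lig_ref.shape)
        want_contact = hold_contact or f < n_contact
        lc = _enforce_gap(rc[res_idx], lc, want_contact)
        all_atoms = list(base.atoms) + lig_atoms
        frame = Structure(all_atoms, model_id=f + 1).with_coords(
            np.vstack([rc, lc])
        )
        frames.append(frame)
    truth = TrajectoryTruth(
        contact_residues=set(targets),
        expected_persistence=1.0 if hold_contact else n_contact / n_frames,
        ligand_res_name=ligand_res_name,
    )
    return Trajectory(frames, frame_interval_ps=5.0), truth


def _enforce_gap(res_coords: np.ndarray, lig: np.ndarray, contact: bool,
                 target_in: float = 3.0, target_out: float = 6.0,
                 max_iter: int = 8) -> np.ndarray:
    """Translate the ligand along the closest-pair axis until the minimum
    distance satisfies the contact condition (<= 4 held at ~3 A; > 4 pushed
    to ~6 A)."""
    lig = lig.copy()
    for _ in range(max_iter):
        d = np.linalg.norm(res_coords[:, None, :] - lig[None, :, :], axis=2)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        dmin = d[i, j]
        ok = dmin <= 4.0 if contact else dmin > 4.0
        near_target = abs(dmin - (target_in if contact else target_out)) < 1.5
        if ok and near_target:
            return lig
        axis = lig[j] - res_coords[i]
        norm = np.linalg.norm(axis)
        axis = axis / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        shift = ((target_in if contact else target_out) - dmin)
        lig = lig + shift * axis
    return lig


# ---------------------------------------------------------------------------
# Demo melting-temperature table
# ---------------------------------------------------------------------------


def make_tm_table(mean_e: dict[str, float], seed: int = 0,
                  tm0: float = 79.4, slope: float = -0.08,
                  noise: float = 0.05) -> pd.DataFrame:
    """Synthetic Tm table linearly coupled to mean binding energy.

    Stand-in for an instrument melt-curve readout: Tm = tm0 + slope *
    mean_E + small seeded noise.  Used by the demo pipeline only.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name, e in sorted(mean_e.items()):
        rows.append({
            "excipient": name,
            "concentration": "n/a",
            "tm_c": round(tm0 + slope * e + rng.normal(0.0, noise), 2),
        })
    return pd.DataFrame(rows)
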