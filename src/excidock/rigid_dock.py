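"""Blind rigid-body protein-protein docking.

Exhaustive orientation/translation search under a softened Lennard-Jones +
weighted electrostatic score, followed by local coordinate-descent
refinement of the kept solutions and greedy energy-ordered clustering with
a C-alpha RMSD threshold.  The direct scan replaces FFT correlation: at the
problem sizes this package targets (tens of residues per body) it is
tractable and exact by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .scoring import (
    COULOMB_CONSTANT,
    COULOMB_MIN_R,
    SoftLJParams,
    assign_atom_types,
    soft_lj_from_r2,
)
from .structio import ResidueKey, Structure, coords_rmsd

logger = logging.getLogger(__name__)


@dataclass
class RigidDockConfig:
    n_orientations: int = 60
    grid_spacing: float = 1.0  # A
    n_keep: int = 100
    cluster_threshold: float = 3.0  # A, C-alpha RMSD
    n_report_clusters: int = 10
    electrostatic_weight: float = 0.1
    interaction_cutoff: float = 8.0  # A
    box_margin: float = 10.0  # A beyond the receptor bounding box
    lj: SoftLJParams = field(default_factory=SoftLJParams)
    dielectric_slope: float = 4.0

    def __post_init__(self) -> None:
        for name in ("n_orientations", "grid_spacing", "n_keep",
                     "cluster_threshold", "n_report_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RigidSolution:
    """One docked placement of the mobile molecule.

    `rotation` acts about the original ligand centroid and `translation` is
    the new centroid position: x -> R (x - c0) + t.
    """

    rotation: np.ndarray
    translation: np.ndarray
    energy: float
    rank: int
    cluster_id: int = -1
    orientation_index: int = -1


def _group_closure(generators: list[Rotation], order: int) -> list[np.ndarray]:
    """Finite rotation group from generators, deterministically ordered."""
    quats = [np.array([0.0, 0.0, 0.0, 1.0])]
    gens = [g.as_quat() for g in generators]
    changed = True
    while changed:
        changed = False
        for q in list(quats):
            for g in gens:
                prod = (Rotation.from_quat(q) * Rotation.from_quat(g)).as_quat()
                lead = next(v for v in prod[::-1] if abs(v) > 1e-6)
                if lead < 0:
                    prod = -prod
                prod[np.abs(prod) < 1e-12] = 0.0
                if not any(np.allclose(prod, x, atol=1e-9) for x in quats):
                    quats.append(prod)
                    changed = True
        if len(quats) > order:
            raise RuntimeError("group closure exceeded expected order")
    quats.sort(key=lambda q: tuple(np.round(q, 9)))
    return [Rotation.from_quat(q).as_matrix() for q in quats]


def _exact_group(n: int) -> list[np.ndarray] | None:
    if n == 12:  # tetrahedral
        gens = [Rotation.from_rotvec(2 * np.pi / 3 * np.array([1, 1, 1]) / np.sqrt(3)),
                Rotation.from_rotvec([0, 0, np.pi])]
    elif n == 24:  # octahedral
        gens = [Rotation.from_rotvec([0, 0, np.pi / 2]),
                Rotation.from_rotvec(2 * np.pi / 3 * np.array([1, 1, 1]) / np.sqrt(3))]
    elif n == 60:  # icosahedral
        phi = (1 + np.sqrt(5.0)) / 2
        v5 = np.array([0.0, 1.0, phi])
        gens = [Rotation.from_rotvec(2 * np.pi / 5 * v5 / np.linalg.norm(v5)),
                Rotation.from_rotvec([0, 0, np.pi])]
    else:
        return None
    return _group_closure(gens, n)


def orientation_set(n: int) -> list[np.ndarray]:
    """Deterministic quasi-uniform rotation matrices.

    n = 1 returns only the identity.  At n = 12, 24 and 60 the exact
    tetrahedral, octahedral and icosahedral rotation groups are used (their
    minimum pairwise geodesic angle is near the sphere-packing optimum);
    other n fall back to a super-Fibonacci quaternion spiral.  Identical
    across runs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return [np.eye(3)]
    exact = _exact_group(n)
    if exact is not None:
        return exact
    phi = np.sqrt(2.0)
    psi = 1.533751168755204288118041
    i = np.arange(n, dtype=float)
    s = i + 0.5
    t = s / n
    d = 2.0 * np.pi * s
    r = np.sqrt(t)
    big_r = np.sqrt(1.0 - t)
    alpha = d / phi
    beta = d / psi
    quats = np.stack(
        [r * np.sin(alpha), r * np.cos(alpha), big_r * np.sin(beta), big_r * np.cos(beta)],
        axis=1,
    )
    return [m for m in Rotation.from_quat(quats).as_matrix()]


def _charges(s: Structure) -> np.ndarray:
    types = assign_atom_types(s)
    heavy = s.heavy_indices
    return np.array([types[i].charge for i in heavy], dtype=float)


def rigid_score(
    receptor: Structure,
    ligand: Structure,
    cfg: RigidDockConfig = RigidDockConfig(),
) -> float:
    """Soft-LJ + weighted electrostatics over intermolecular heavy pairs <= 8 A."""
    a = receptor.heavy_coords()
    b = ligand.heavy_coords()
    qa = _charges(receptor)
    qb = _charges(ligand)
    return _score_pairs(a, b, qa, qb, cfg)


def _score_pairs(a: np.ndarray, b: np.ndarray, qa: np.ndarray, qb: np.ndarray,
                 cfg: RigidDockConfig) -> float:
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    mask = d2 <= cfg.interaction_cutoff ** 2
    e = float(soft_lj_from_r2(d2[mask], cfg.lj).sum())
    qq = qa[:, None] * qb[None, :]
    qmask = mask & (qq != 0)
    if np.any(qmask):
        r2_eff = np.maximum(d2[qmask], COULOMB_MIN_R ** 2)
        e += cfg.electrostatic_weight * float(
            (COULOMB_CONSTANT * qq[qmask] / (cfg.dielectric_slope * r2_eff)).sum()
        )
    return e


def _place(lig_rel: np.ndarray, rotation: np.ndarray, t: np.ndarray) -> np.ndarray:
    return lig_rel @ rotation.T + t


def _scan_energies(rec: np.ndarray, qa: np.ndarray, lig_rot: np.ndarray,
                   qb: np.ndarray, trans: np.ndarray, cfg: RigidDockConfig,
                   chunk: int = 2048) -> np.ndarray:
    """Energies for all centroid translations of one rotated ligand frame."""
    # pair offsets c_ij = rec_i - ligrot_j; |pair - t| is the pair distance
    c = (rec[:, None, :] - lig_rot[None, :, :]).reshape(-1, 3)
    qq = (qa[:, None] * qb[None, :]).reshape(-1)
    has_q = qq != 0
    out = np.empty(len(trans))
    cut2 = cfg.interaction_cutoff ** 2
    s6 = cfg.lj.sigma ** 6
    four_eps = 4.0 * cfg.lj.epsilon
    for start in range(0, len(trans), chunk):
        tblk = trans[start:start + chunk]
        diff = c[None, :, :] - tblk[:, None, :]
        r2 = np.einsum("ijk,ijk->ij", diff, diff)
        u = cfg.lj.alpha * s6 + r2 ** 3
        with np.errstate(divide="ignore"):
            v = (four_eps * s6 * s6 / u - four_eps * s6) / u
        v[r2 > cut2] = 0.0
        e = v.sum(axis=1)
        if has_q.any():
            r2q = np.maximum(r2[:, has_q], COULOMB_MIN_R ** 2)
            eq = COULOMB_CONSTANT * qq[has_q][None, :] / (cfg.dielectric_slope * r2q)
            eq[r2[:, has_q] > cut2] = 0.0
            e = e + cfg.electrostatic_weight * eq.sum(axis=1)
        out[start:start + chunk] = e
    return out


def _translation_grid(rec: np.ndarray, cfg: RigidDockConfig) -> np.ndarray:
    lo = rec.min(axis=0) - cfg.box_margin
    hi = rec.max(axis=0) + cfg.box_margin
    axes = [np.arange(lo[k], hi[k] + 0.5 * cfg.grid_spacing, cfg.grid_spacing)
            for k in range(3)]
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack([x.ravel() for x in g], axis=1)


def _refine(rec: np.ndarray, qa: np.ndarray, lig_rel: np.ndarray, qb: np.ndarray,
            rotation: np.ndarray, t: np.ndarray, cfg: RigidDockConfig,
            max_sweeps: int = 20) -> tuple[np.ndarray, np.ndarray, float]:
    """Coordinate descent: translation steps halving from grid_spacing to
    0.125 A, orientation steps from 10 to 1.25 degrees."""

    def energy(R, tt):
        return _score_pairs(rec, _place(lig_rel, R, tt), qa, qb, cfg)

    best_e = energy(rotation, t)
    R, tt = rotation, t.copy()
    step_t = cfg.grid_spacing
    step_r = 10.0
    while step_t >= 0.125 - 1e-12:
        improved = True
        sweeps = 0
        while improved and sweeps < max_sweeps:
            improved = False
            sweeps += 1
            for axis in range(3):
                for sign in (+1.0, -1.0):
                    cand_t = tt.copy()
                    cand_t[axis] += sign * step_t
                    e = energy(R, cand_t)
                    if e < best_e - 1e-12:
                        best_e, tt = e, cand_t
                        improved = True
            for axis_vec in np.eye(3):
                for sign in (+1.0, -1.0):
                    dR = Rotation.from_rotvec(
                        np.deg2rad(sign * step_r) * axis_vec).as_matrix()
                    cand_R = dR @ R
                    e = energy(cand_R, tt)
                    if e < best_e - 1e-12:
                        best_e, R = e, cand_R
                        improved = True
        step_t /= 2.0
        step_r /= 2.0
    return R, tt, best_e


def rigid_dock(
    receptor: Structure,
    ligand: Structure,
    cfg: RigidDockConfig = RigidDockConfig(),
) -> list[RigidSolution]:
    """Exhaustive blind rigid docking.

    For every orientation the ligand centroid is scanned over a lattice
    covering the receptor bounding box plus a margin; the best `n_keep`
    placements are locally refined and returned sorted ascending by energy.
    Ties break toward the lower orientation index, then lexicographic
    translation.
    """
    if not receptor.atoms or not ligand.atoms:
        raise ValueError("empty structure")
    rec = receptor.heavy_coords()
    qa = _charges(receptor)
    lig = ligand.heavy_coords()
    qb = _charges(ligand)
    c0 = lig.mean(axis=0)
    lig_rel = lig - c0
    rotations = orientation_set(cfg.n_orientations)
    trans = _translation_grid(rec, cfg)
    logger.info("rigid_dock: %d orientations x %d translations",
                len(rotations), len(trans))

    cand_e: list[np.ndarray] = []
    cand_t: list[np.ndarray] = []
    cand_o: list[np.ndarray] = []
    for oi, R in enumerate(rotations):
        e = _scan_energies(rec, qa, lig_rel @ R.T, qb, trans, cfg)
        k = min(cfg.n_keep, len(e))
        idx = np.argpartition(e, k - 1)[:k]
        cand_e.append(e[idx])
        cand_t.append(trans[idx])
        cand_o.append(np.full(k, oi))
    e_all = np.concatenate(cand_e)
    t_all = np.concatenate(cand_t)
    o_all = np.concatenate(cand_o)
    order = np.lexsort((t_all[:, 2], t_all[:, 1], t_all[:, 0], o_all, e_all))
    order = order[: cfg.n_keep]

    sols: list[RigidSolution] = []
    for i in order:
        R, t, e = _refine(rec, qa, lig_rel, qb, rotations[o_all[i]], t_all[i], cfg)
        sols.append(RigidSolution(rotation=R, translation=t, energy=e, rank=-1,
                                  orientation_index=int(o_all[i])))
    sols.sort(key=lambda s: (s.energy, s.orientation_index,
                             tuple(np.round(s.translation, 9))))
    for rank, s in enumerate(sols, start=1):
        s.rank = rank
    return sols


def solution_pose(ligand: Structure, sol: RigidSolution) -> Structure:
    """Ligand Structure placed according to a rigid solution."""
    lig = ligand.coords
    c0 = ligand.heavy_coords().mean(axis=0)
    return ligand.with_coords((lig - c0) @ sol.rotation.T + sol.translation)


def cluster_solutions(
    ligand: Structure,
    sols: list[RigidSolution],
    threshold: float = 3.0,
) -> list[int]:
    """Greedy leader clustering of energy-sorted solutions.

    A solution joins the first existing cluster whose leader's ligand
    C-alpha RMSD (common receptor frame) is <= threshold, else it founds a
    new cluster.  Cluster ids are ordered by leader energy (0 = best).  For
    ligands without C-alpha atoms all heavy atoms are used.
    """
    energies = [s.energy for s in sols]
    if any(energies[i] > energies[i + 1] + 1e-12 for i in range(len(energies) - 1)):
        raise ValueError("solutions must be sorted ascending by energy")
    ca_idx = [i for i, a in enumerate(ligand.atoms) if a.name == "CA" and a.is_heavy]
    sel = np.array(ca_idx if ca_idx else list(ligand.heavy_indices), dtype=int)
    lig = ligand.coords
    c0 = ligand.heavy_coords().mean(axis=0)
    placed = [((lig - c0) @ s.rotation.T + s.translation)[sel] for s in sols]
    leaders: list[int] = []
    for i, s in enumerate(sols):
        assigned = False
        for cid, lead in enumerate(leaders):
            if coords_rmsd(placed[i], placed[lead]) <= threshold:
                s.cluster_id = cid
                assigned = True
                break
        if not assigned:
            s.cluster_id = len(leaders)
            leaders.append(i)
    return [s.cluster_id for s in sols]


def cluster_leaders(sols: list[RigidSolution], n_report: int = 10) -> list[RigidSolution]:
    """First (lowest-energy) structure of each of the first n_report clusters."""
    seen: dict[int, RigidSolution] = {}
    for s in sols:
        if s.cluster_id < 0:
            raise ValueError("cluster_solutions must be run first")
        seen.setdefault(s.cluster_id, s)
    return [seen[cid] for cid in sorted(seen)[:n_report]]


def interface_residues(
    receptor: Structure,
    ligand_pose: Structure,
    cutoff: float = 4.0,
) -> tuple[set[ResidueKey], set[ResidueKey]]:
    """Residues of each molecule within `cutoff` (closed) of the other."""
    ra = receptor.heavy_indices
    la = ligand_pose.heavy_indices
    rc = receptor.coords[ra]
    lc = ligand_pose.coords[la]
    rkeys = receptor.atom_residue_keys()
    lkeys = ligand_pose.atom_residue_keys()
    pairs = cKDTree(rc).query_ball_tree(cKDTree(lc), r=cutoff)
    rec_side: set[ResidueKey] = set()
    lig_side: set[ResidueKey] = set()
    for i, hits in enumerate(pairs):
        if hits:
            rec_side.add(rkeys[ra[i]])
            for j in hits:
                lig_side.add(lkeys[la[j]])
    return rec_side, lig_side
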