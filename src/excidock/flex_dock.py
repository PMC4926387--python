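"""Blind flexible-ligand docking by a genetic algorithm.

The whole protein surface is searched (no binding-site prior): the search
box is the target bounding box plus a 5 A margin, and a generational GA
optimises ligand translation, rigid orientation (unit quaternion) and active
torsion angles against the empirical score of :mod:`excidock.scoring`.
Defaults follow the screening protocol this package reproduces: population
800, 10 generations, 10 reported solutions, at most 100 distinct sites,
at most 5 active torsions, and an energy magnitude bound of 100 kcal/mol
rejecting unphysical scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.transform import Rotation, Slerp

from .scoring import (
    AtomTyping,
    PharmacophoreSpec,
    ScoreBreakdown,
    ScoringConfig,
    ScoringContext,
    SearchBox,
    DEFAULT_SCORING,
    assign_atom_types,
)
from .structio import AtomRecord, Structure

import logging

logger = logging.getLogger(__name__)


@dataclass
class LigandTopology:
    """Heavy-atom ligand: atoms, bond list with orders, active torsions."""

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int, int]]  # (i, j, order)
    rotatable: list[int] = field(default_factory=list)  # indices into bonds
    name: str = "LIG"

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("bond references missing atom")
        if n > 1 and connected_components(self._adjacency(), directed=False)[0] != 1:
            raise ValueError("ligand bond graph is disconnected")

    def _adjacency(self) -> csr_matrix:
        n = len(self.atoms)
        if not self.bonds:
            return csr_matrix((n, n))
        i, j, _ = zip(*self.bonds)
        data = np.ones(len(self.bonds))
        m = csr_matrix((data, (i, j)), shape=(n, n))
        return m + m.T

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.atoms), dtype=int)
        for i, j, _ in self.bonds:
            deg[i] += 1
            deg[j] += 1
        return deg

    def bond_distances(self) -> np.ndarray:
        """Matrix of graph distances in bonds between all atom pairs."""
        return shortest_path(self._adjacency(), directed=False, unweighted=True)

    def long_range_pairs(self) -> np.ndarray:
        """(k, 2) atom pairs separated by >= 4 bonds (intramolecular score)."""
        d = self.bond_distances()
        i, j = np.where(np.triu(d, k=1) >= 4)
        keep = np.isfinite(d[i, j])
        return np.stack([i[keep], j[keep]], axis=1)

    def moving_side(self, bond_index: int, root: int = 0) -> np.ndarray:
        """Atom indices rotated by this torsion: the side not containing root."""
        i, j, _ = self.bonds[bond_index]
        adj = self._adjacency().tolil()
        adj[i, j] = 0
        adj[j, i] = 0
        _, labels = connected_components(csr_matrix(adj), directed=False)
        far = j if labels[j] != labels[root] else i
        return np.where(labels == labels[far])[0]

    def as_structure(self, coords: np.ndarray | None = None, model_id: int = 1) -> Structure:
        s = Structure(list(self.atoms), model_id=model_id)
        return s if coords is None else s.with_coords(coords)


def detect_rotatable_bonds(t: LigandTopology, max_torsions: int = 5) -> list[int]:
    """Indices of rotatable bonds: single, acyclic, between non-terminal atoms.

    If more than `max_torsions` qualify, the bonds whose rotation moves the
    most atoms are kept (ties broken toward the lower bond index).
    """
    n = len(t.atoms)
    if n > 1 and connected_components(t._adjacency(), directed=False)[0] != 1:
        raise ValueError("ligand bond graph is disconnected")
    deg = t.degrees()
    candidates: list[tuple[int, int]] = []  # (-moved, index) for sorting
    for idx, (i, j, order) in enumerate(t.bonds):
        if order != 1 or deg[i] < 2 or deg[j] < 2:
            continue
        # acyclic (bridge) test: removing the bond must disconnect the graph
        adj = t._adjacency().tolil()
        adj[i, j] = 0
        adj[j, i] = 0
        ncomp, labels = connected_components(csr_matrix(adj), directed=False)
        if ncomp == 1:
            continue  # ring bond
        moved = int(min(np.sum(labels == labels[i]), np.sum(labels == labels[j])))
        candidates.append((idx, moved))
    candidates.sort(key=lambda c: (-c[1], c[0]))
    kept = sorted(idx for idx, _ in candidates[:max_torsions])
    return kept


@dataclass
class Chromosome:
    """GA genome: rigid placement + torsion angles (degrees in [-180, 180))."""

    translation: np.ndarray
    orientation: Rotation
    torsions: np.ndarray

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        self.torsions = wrap_angles(np.asarray(self.torsions, dtype=float))
        q = self.orientation.as_quat()
        if abs(np.linalg.norm(q) - 1.0) > 1e-9:
            raise ValueError("orientation quaternion not normalised")


def wrap_angles(a: np.ndarray) -> np.ndarray:
    return (np.asarray(a, float) + 180.0) % 360.0 - 180.0


def _rotate_about_axis(points: np.ndarray, origin: np.ndarray, axis: np.ndarray,
                       angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis)
    return rot.apply(points - origin) + origin


def apply_chromosome(
    t: LigandTopology,
    c: Chromosome,
    reference_coords: np.ndarray | None = None,
    root: int = 0,
) -> np.ndarray:
    """Place the ligand: torsions root-outward, then rigid rotation about the
    centroid, then translation.  A zero chromosome reproduces the reference
    coordinates; bond lengths and angles are preserved.
    """
    if len(c.torsions) != len(t.rotatable):
        raise ValueError(
            f"chromosome has {len(c.torsions)} torsions but topology defines "
            f"{len(t.rotatable)} rotatable bonds"
        )
    coords = np.array(t.coords if reference_coords is None else reference_coords,
                      dtype=float)
    if coords.shape != (len(t.atoms), 3):
        raise ValueError("reference coordinate shape mismatch")
    if t.rotatable:
        dist = t.bond_distances()[root]
        order = sorted(range(len(t.rotatable)),
                       key=lambda k: min(dist[t.bonds[t.rotatable[k]][0]],
                                         dist[t.bonds[t.rotatable[k]][1]]))
        for k in order:
            angle = float(c.torsions[k])
            if angle == 0.0:
                continue
            bidx = t.rotatable[k]
            i, j, _ = t.bonds[bidx]
            near, far = (i, j) if dist[i] <= dist[j] else (j, i)
            moving = t.moving_side(bidx, root=root)
            axis = coords[far] - coords[near]
            coords[moving] = _rotate_about_axis(coords[moving], coords[near],
                                                axis, angle)
    centroid = coords.mean(axis=0)
    coords = c.orientation.apply(coords - centroid) + centroid + c.translation
    return coords


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------


@dataclass
class GAConfig:
    population: int = 800
    generations: int = 10
    n_solutions: int = 10
    max_sites: int = 100
    energy_bound: float = 100.0  # magnitude cap on reported |E_total|
    max_torsions: int = 5
    crossover_rate: float = 0.7
    mutation_rate: float = 0.1
    elitism: int = 2
    seed: int = 0
    site_rmsd: float = 2.0  # distinct-site leader-clustering threshold, A
    box_margin: float = 5.0
    mut_sigma_trans: float = 1.0  # A
    mut_sigma_orient: float = 15.0  # degrees
    mut_sigma_torsion: float = 30.0  # degrees

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError("population must be positive")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


@dataclass
class Pose:
    """A placed ligand conformation with its score breakdown."""

    pose_id: int
    coords: np.ndarray
    score: ScoreBreakdown
    chromosome: Chromosome
    excipient: str = "LIG"

    @property
    def e_total(self) -> float:
        return self.score.e_total

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def as_structure(self, topology: LigandTopology, model_id: int = 1) -> Structure:
        return topology.as_structure(self.coords, model_id=model_id)


def _random_chromosome(rng: np.random.Generator, box: SearchBox, n_torsions: int) -> Chromosome:
    return Chromosome(
        translation=box.sample(rng, 1)[0],
        orientation=Rotation.from_quat(_random_quat(rng)),
        torsions=rng.uniform(-180.0, 180.0, size=n_torsions),
    )


def _random_quat(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def _crossover(rng: np.random.Generator, a: Chromosome, b: Chromosome) -> Chromosome:
    u = rng.uniform()
    trans = u * a.translation + (1 - u) * b.translation
    times = [0.0, 1.0]
    slerp = Slerp(times, Rotation.concatenate([a.orientation, b.orientation]))
    orient = slerp(rng.uniform())
    # torsions blended along the shortest arc
    diff = wrap_angles(b.torsions - a.torsions)
    tors = wrap_angles(a.torsions + rng.uniform(size=len(a.torsions)) * diff)
    return Chromosome(trans, orient, tors)


def _mutate(rng: np.random.Generator, c: Chromosome, cfg: GAConfig) -> Chromosome:
    trans = c.translation.copy()
    for k in range(3):
        if rng.uniform() < cfg.mutation_rate:
            trans[k] += rng.normal(0.0, cfg.mut_sigma_trans)
    orient = c.orientation
    if rng.uniform() < cfg.mutation_rate:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(rng.normal(0.0, cfg.mut_sigma_orient))
        orient = Rotation.from_rotvec(angle * axis) * orient
    tors = c.torsions.copy()
    for k in range(len(tors)):
        if rng.uniform() < cfg.mutation_rate:
            tors[k] += rng.normal(0.0, cfg.mut_sigma_torsion)
    return Chromosome(trans, orient, tors)


def _leader_cluster_coords(coord_list: list[np.ndarray], threshold: float) -> list[int]:
    """Greedy leader clustering by heavy-atom RMSD; returns leader indices."""
    leaders: list[int] = []
    for idx, c in enumerate(coord_list):
        new = True
        for lead in leaders:
            rms = float(np.sqrt(((c - coord_list[lead]) ** 2).sum(axis=1).mean()))
            if rms <= threshold:
                new = False
                break
        if new:
            leaders.append(idx)
    return leaders


def ga_dock(
    target: Structure,
    ligand: LigandTopology,
    cfg: GAConfig,
    scoring: ScoringConfig = DEFAULT_SCORING,
    pharma: PharmacophoreSpec | None = None,
    excipient: str | None = None,
) -> list[Pose]:
    """Blind GA docking over the whole target surface.

    Tournament selection (size 2), arithmetic crossover on translation,
    quaternion slerp on orientation, per-gene Gaussian mutation, and elitism
    minimise E_total.  After the final generation distinct poses are
    extracted by greedy leader clustering (all-heavy-atom RMSD threshold
    `site_rmsd`), scores with |E_total| > energy_bound are discarded, at
    most `max_sites` distinct sites are retained and the best `n_solutions`
    are returned sorted ascending by energy.  Fully reproducible from
    cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    logger.info("ga_dock seed=%d population=%d generations=%d",
                cfg.seed, cfg.population, cfg.generations)
    box = SearchBox.around(target, margin=cfg.box_margin)
    lig_types = assign_atom_types(ligand.as_structure())
    ctx = ScoringContext(target, lig_types, box,
                         intra_pairs=ligand.long_range_pairs(),
                         pharma=pharma, cfg=scoring)
    ref = ligand.coords
    n_tors = len(ligand.rotatable)

    def evaluate(c: Chromosome) -> tuple[np.ndarray, ScoreBreakdown]:
        coords = apply_chromosome(ligand, c, ref)
        return coords, ctx.score(coords)

    pop = [_random_chromosome(rng, box, n_tors) for _ in range(cfg.population)]
    evals = [evaluate(c) for c in pop]
    energies = np.array([e.e_total for _, e in evals])

    for _ in range(cfg.generations):
        order = np.argsort(energies, kind="stable")
        next_pop: list[Chromosome] = [pop[i] for i in order[: cfg.elitism]]
        while len(next_pop) < cfg.population:
            i1, i2 = rng.integers(0, cfg.population, size=2)
            p1 = pop[i1] if energies[i1] <= energies[i2] else pop[i2]
            if rng.uniform() < cfg.crossover_rate:
                j1, j2 = rng.integers(0, cfg.population, size=2)
                p2 = pop[j1] if energies[j1] <= energies[j2] else pop[j2]
                child = _crossover(rng, p1, p2)
            else:
                child = p1
            next_pop.append(_mutate(rng, child, cfg))
        pop = next_pop
        evals = [evaluate(c) for c in pop]
        energies = np.array([e.e_total for _, e in evals])

    order = np.argsort(energies, kind="stable")
    kept = [i for i in order if abs(energies[i]) <= cfg.energy_bound]
    coords_sorted = [evals[i][0] for i in kept]
    leader_pos = _leader_cluster_coords(coords_sorted, cfg.site_rmsd)
    leader_pos = leader_pos[: cfg.max_sites]
    poses = [
        Pose(
            pose_id=rank + 1,
            coords=coords_sorted[p],
            score=evals[kept[p]][1],
            chromosome=pop[kept[p]],
            excipient=excipient or ligand.name,
        )
        for rank, p in enumerate(leader_pos[: cfg.n_solutions])
    ]
    if not poses:
        logger.warning("ga_dock: no pose survived the energy bound |E| <= %g",
                       cfg.energy_bound)
    return poses


def dock_panel(
    target: Structure,
    ligands: list[LigandTopology],
    cfg: GAConfig,
    scoring: ScoringConfig = DEFAULT_SCORING,
) -> dict[str, list[Pose]]:
    """Dock a panel of excipient ligands; one deterministic seed per ligand.

    Per-ligand seeds are cfg.seed + ligand index, so pinning a ligand's seed
    pins its pose list independent of panel order.
    """
    if not ligands:
        raise ValueError("empty ligand panel")
    out: dict[str, list[Pose]] = {}
    for idx, lig in enumerate(ligands):
        sub = replace_seed(cfg, cfg.seed + idx)
        out[lig.name] = ga_dock(target, lig, sub, scoring=scoring, excipient=lig.name)
    return out


def replace_seed(cfg: GAConfig, seed: int) -> GAConfig:
    return replace(cfg, seed=seed)


# ---------------------------------------------------------------------------
# Ligand file input
# ---------------------------------------------------------------------------


def topology_from_sdf(text: str, name: str | None = None,
                      max_torsions: int = 5) -> LigandTopology:
    """Minimal MDL V2000 reader (first molecule): atoms, bonds, charges."""
    lines = text.splitlines()
    if len(lines) < 4:
        raise ValueError("SDF text too short")
    counts = lines[3]
    n_atoms = int(counts[0:3])
    n_bonds = int(counts[3:6])
    atoms: list[AtomRecord] = []
    for i in range(n_atoms):
        ln = lines[4 + i]
        x, y, z = float(ln[0:10]), float(ln[10:20]), float(ln[20:30])
        el = ln[31:34].strip()
        atoms.append(AtomRecord(
            serial=i + 1, name=f"{el}{i + 1}", element=el.capitalize(),
            res_name="LIG", chain_id="X", res_seq=1, coords=(x, y, z), het=True,
        ))
    bonds: list[tuple[int, int, int]] = []
    for i in range(n_bonds):
        ln = lines[4 + n_atoms + i]
        bonds.append((int(ln[0:3]) - 1, int(ln[3:6]) - 1, int(ln[6:9])))
    # M  CHG lines override charges
    charges: dict[int, int] = {}
    for ln in lines[4 + n_atoms + n_bonds:]:
        if ln.startswith("M  CHG"):
            fields = ln.split()
            n = int(fields[2])
            for k in range(n):
                charges[int(fields[3 + 2 * k]) - 1] = int(fields[4 + 2 * k])
        if ln.startswith("M  END"):
            break
    if charges:
        atoms = [replace(a, formal_charge=charges.get(i, 0))
                 for i, a in enumerate(atoms)]
    heavy = [i for i, a in enumerate(atoms) if a.is_heavy]
    remap = {old: new for new, old in enumerate(heavy)}
    atoms = [atoms[i] for i in heavy]
    bonds = [(remap[i], remap[j], o) for i, j, o in bonds
             if i in remap and j in remap]
    topo = LigandTopology(atoms=atoms, bonds=bonds, name=name or "LIG")
    topo.rotatable = detect_rotatable_bonds(topo, max_torsions=max_torsions)
    return topo


def topology_to_sdf(t: LigandTopology) -> str:
    """Serialise a topology as a single V2000 molecule."""
    lines = [t.name, "  excidock", "", f"{len(t.atoms):3d}{len(t.bonds):3d}  0  0  0  0  0  0  0  0999 V2000"]
    for a in t.atoms:
        x, y, z = a.coords
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j, o in t.bonds:
        lines.append(f"{i + 1:3d}{j + 1:3d}{o:3d}  0  0  0  0")
    charged = [(i, a.formal_charge) for i, a in enumerate(t.atoms) if a.formal_charge]
    if charged:
        parts = "".join(f" {i + 1:3d} {q:3d}" for i, q in charged)
        lines.append(f"M  CHG{len(charged):3d}{parts}")
    lines.append("M  END")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"


def topology_from_pdb(text: str, name: str | None = None,
                      max_torsions: int = 5) -> LigandTopology:
    """Ligand from PDB text with CONECT records (heavy atoms; order 1 bonds)."""
    from .structio import read_pdb

    s = read_pdb(text)[0]
    heavy = list(s.heavy_indices)
    serial_to_idx = {s.atoms[i].serial: k for k, i in enumerate(heavy)}
    atoms = [s.atoms[i] for i in heavy]
    bonds_set: set[tuple[int, int]] = set()
    for line in text.splitlines():
        if not line.startswith("CONECT"):
            continue
        fields = [line[6:11]] + [line[11 + 5 * k:16 + 5 * k] for k in range(4)]
        serials = [int(f) for f in fields if f.strip()]
        if not serials:
            continue
        a = serials[0]
        for b in serials[1:]:
            if a in serial_to_idx and b in serial_to_idx:
                bonds_set.add((min(serial_to_idx[a], serial_to_idx[b]),
                               max(serial_to_idx[a], serial_to_idx[b])))
    if not bonds_set:
        raise ValueError("ligand PDB lacks CONECT records")
    bonds = [(i, j, 1) for i, j in sorted(bonds_set)]
    topo = LigandTopology(atoms=atoms, bonds=bonds, name=name or atoms[0].res_name)
    topo.rotatable = detect_rotatable_bonds(topo, max_torsions=max_torsions)
    return topo
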