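"""Energy models for rigid and flexible docking.

Two scorers live here:

* a softened Lennard-Jones pair potential used for rigid protein-protein
  docking,

      V(r) = 1/(a*s^6 + r^6) * (4*e*s^12/(a*s^6 + r^6) - 4*e*s^6),

  finite everywhere for softening a > 0 and reducing to the standard 12-6
  potential as a -> 0;

* an empirical flexible-docking score

      E_tot = E_bind + E_pharma + E_ligpre,

  where E_bind sums piecewise-linear hydrogen-bond / steric pair wells (plus
  a Coulomb term between charged atoms) over intermolecular and
  intramolecular heavy-atom pairs together with a fixed out-of-box penalty
  E_penal = 10000, E_pharma optionally rewards pharmacophore hot-spot atoms,
  and E_ligpre = WP_elec + WP_hb penalises ligands whose electrostatic or
  hydrogen-bonding capacity goes unsatisfied in the pose.

The linear-well knot positions and depths are constants of this package and
are all exposed in :class:`ScoringConfig`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.distance import cdist

from .structio import Structure

logger = logging.getLogger(__name__)

COULOMB_CONSTANT = 332.0636  # kcal*mol^-1*A*e^-2
COULOMB_MIN_R = 2.5  # A; heavy-atom contact clamp below which the screened term is held fixed


@dataclass(frozen=True)
class SoftLJParams:
    """Softened Lennard-Jones parameters.

    sigma is stored in the same length unit as the r passed to
    :func:`soft_lj`; the default 3.3 A corresponds to 0.33 nm.
    """

    alpha: float = 0.4
    sigma: float = 3.3
    epsilon: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.sigma <= 0 or self.epsilon < 0:
            raise ValueError("require alpha >= 0, sigma > 0, epsilon >= 0")


def soft_lj(r, p: SoftLJParams = SoftLJParams()):
    """Softened 12-6 potential; finite at r = 0 whenever alpha > 0.

    At r = 0 the value is 4*eps*(1 - alpha)/alpha**2; with alpha = 0 and
    r > 0 it equals the standard Lennard-Jones potential.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("r must be non-negative")
    if p.alpha == 0.0:
        # exact standard 12-6 form in the hard limit
        if np.any(r_arr == 0):
            raise ZeroDivisionError("soft_lj singular at r = 0 with alpha = 0")
        sr = p.sigma / r_arr
        v = 4.0 * p.epsilon * (sr ** 12 - sr ** 6)
    else:
        s6 = p.sigma ** 6
        u = p.alpha * s6 + r_arr ** 6
        v = (4.0 * p.epsilon * s6 * s6 / u - 4.0 * p.epsilon * s6) / u
    return float(v) if np.isscalar(r) or r_arr.ndim == 0 else v


def soft_lj_from_r2(r2: np.ndarray, p: SoftLJParams) -> np.ndarray:
    """Vector form taking squared distances (avoids sqrt in hot loops)."""
    s6 = p.sigma ** 6
    u = p.alpha * s6 + r2 ** 3
    with np.errstate(divide="ignore"):
        return (4.0 * p.epsilon * s6 * s6 / u - 4.0 * p.epsilon * s6) / u


def coulomb(q1: float, q2: float, r: float) -> float:
    """Screened point-charge interaction with distance-dependent dielectric.

    eps(r) = 4r, so E = 332.0636 * q1 * q2 / (4 * r^2) kcal/mol.  Below the
    2-A contact clamp the magnitude is held at its r = 2 value: formal
    point charges sit on heavy-atom centres, and without a clamp the
    screened term would diverge through the zero-energy core of the
    hydrogen-bond well.
    """
    if r <= 0:
        raise ZeroDivisionError("coulomb singular at r = 0")
    if q1 == 0 or q2 == 0:
        return 0.0
    r_eff = max(r, COULOMB_MIN_R)
    return COULOMB_CONSTANT * q1 * q2 / (4.0 * r_eff * r_eff)


# ---------------------------------------------------------------------------
# Atom typing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomTyping:
    donor: bool = False
    acceptor: bool = False
    hydrophobic: bool = False
    charge: int = 0

    @property
    def charged(self) -> bool:
        return self.charge != 0


# Side-chain donor atoms (N/O with H-bearing capacity) for the 20 amino acids.
_SIDECHAIN_DONORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("ASN", "ND2"), ("GLN", "NE2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("TRP", "NE1"),
}

# One atom per ionisable side chain carries the integer formal charge
# (Asp/Glu -1, Lys/Arg +1, His 0 by default).
_SIDECHAIN_CHARGES = {
    ("ASP", "OD2"): -1,
    ("GLU", "OE2"): -1,
    ("LYS", "NZ"): +1,
    ("ARG", "NH2"): +1,
}

# Carbons bonded into charged groups are not hydrophobic.
_POLARISED_CARBONS = {("ASP", "CG"), ("GLU", "CD"), ("ARG", "CZ")}

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_KNOWN_ELEMENTS = {"C", "N", "O", "S", "P", "H"}


def assign_atom_types(s: Structure) -> list[AtomTyping]:
    """Deterministic per-atom donor/acceptor/hydrophobic/charge assignment.

    Amino-acid atoms follow residue templates (backbone N is a donor except
    in proline; all N/O are acceptors).  Non-amino-acid (ligand) atoms are
    typed by element: N and O are donor+acceptor, C and S hydrophobic, with
    the charge taken from the atom's formal_charge field.  Unknown elements
    are typed hydrophobic with a logged warning.
    """
    out: list[AtomTyping] = []
    for a in s.atoms:
        el = a.element.upper()
        res = a.res_name.upper()
        name = a.name.upper()
        if el not in _KNOWN_ELEMENTS:
            logger.warning("unknown element %r on atom %s; typed hydrophobic", el, a.serial)
            out.append(AtomTyping(hydrophobic=True))
            continue
        if res in _AMINO_ACIDS:
            charge = _SIDECHAIN_CHARGES.get((res, name), 0)
            if el in ("N", "O"):
                donor = (name == "N" and res != "PRO") or (res, name) in _SIDECHAIN_DONORS
                out.append(AtomTyping(donor=donor, acceptor=True, charge=charge))
            elif el in ("C", "S"):
                hydro = (res, name) not in _POLARISED_CARBONS
                out.append(AtomTyping(hydrophobic=hydro, charge=charge))
            else:
                out.append(AtomTyping(hydrophobic=True, charge=charge))
        else:
            charge = a.formal_charge
            if el in ("N", "O"):
                out.append(AtomTyping(donor=True, acceptor=True, charge=charge))
            elif el == "P":
                out.append(AtomTyping(acceptor=True, charge=charge))
            elif el == "H":
                out.append(AtomTyping())
            else:
                out.append(AtomTyping(hydrophobic=True, charge=charge))
    return out


def typing_arrays(types: list[AtomTyping]) -> dict[str, np.ndarray]:
    """Boolean/charge arrays for vectorised scoring."""
    return {
        "donor": np.array([t.donor for t in types], dtype=bool),
        "acceptor": np.array([t.acceptor for t in types], dtype=bool),
        "hydrophobic": np.array([t.hydrophobic for t in types], dtype=bool),
        "charge": np.array([t.charge for t in types], dtype=float),
    }


# ---------------------------------------------------------------------------
# Pairwise empirical wells
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoringConfig:
    """All constants of the empirical flexible-docking score.

    Hydrogen-bond well: flat at hbond_depth on [hb_r1, hb_r2], linear ramps
    to zero at hb_r0 and hb_r3.  Steric well: steric_clash at r <= st_r0
    ramping to 0 at st_r1, descending to steric_depth at st_r2, flat to
    st_r3, back to 0 at st_r4.  Hydrogen bonds are ~6x deeper than the
    steric well.
    """

    hb_r0: float = 2.0
    hb_r1: float = 2.3
    hb_r2: float = 3.1
    hb_r3: float = 3.6
    hbond_depth: float = -2.5
    st_r0: float = 2.0
    st_r1: float = 3.3
    st_r2: float = 3.6
    st_r3: float = 4.5
    st_r4: float = 6.0
    steric_clash: float = 5.0
    steric_depth: float = -0.4
    inter_cutoff: float = 6.0
    box_penalty: float = 10000.0
    ligpre_penalty: float = 5.0
    ligpre_contact_cutoff: float = 4.0
    ligpre_min_polar: int = 3
    dielectric_slope: float = 4.0  # eps(r) = dielectric_slope * r

    @property
    def hbond_knots(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.array([self.hb_r0, self.hb_r1, self.hb_r2, self.hb_r3]),
                np.array([0.0, self.hbond_depth, self.hbond_depth, 0.0]))

    @property
    def steric_knots(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.array([self.st_r0, self.st_r1, self.st_r2, self.st_r3, self.st_r4]),
                np.array([self.steric_clash, 0.0, self.steric_depth,
                          self.steric_depth, 0.0]))

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


DEFAULT_SCORING = ScoringConfig()


@dataclass(frozen=True)
class PairwiseInteraction:
    type: str  # "hbond" | "steric" | "electrostatic"
    r: float
    energy: float


def _hbond_well(r, cfg: ScoringConfig):
    xp, fp = cfg.hbond_knots
    return np.interp(r, xp, fp)


def _steric_well(r, cfg: ScoringConfig):
    xp, fp = cfg.steric_knots
    return np.interp(r, xp, fp)


def pair_energy(
    type_i: AtomTyping,
    type_j: AtomTyping,
    r: float,
    cfg: ScoringConfig = DEFAULT_SCORING,
) -> PairwiseInteraction:
    """Energy of one heavy-atom pair.

    Donor<->acceptor pairs take the hydrogen-bond well, all other pairs the
    steric well; if both atoms carry formal charge a screened Coulomb term
    is added.  Type label priority: hbond > electrostatic > steric.
    """
    if r < 0:
        raise ValueError("r must be non-negative")
    is_hb = (type_i.donor and type_j.acceptor) or (type_j.donor and type_i.acceptor)
    e = float(_hbond_well(r, cfg) if is_hb else _steric_well(r, cfg))
    kind = "hbond" if is_hb else "steric"
    if type_i.charged and type_j.charged:
        r_eff = max(r, COULOMB_MIN_R)
        e += (COULOMB_CONSTANT * type_i.charge * type_j.charge
              / (cfg.dielectric_slope * r_eff * r_eff))
        if not is_hb:
            kind = "electrostatic"
    return PairwiseInteraction(type=kind, r=r, energy=e)


# ---------------------------------------------------------------------------
# Pose scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PharmacophoreSpec:
    """Optional hot-spot atom term: (target atom index, weight, required type)."""

    hotspot_atoms: tuple[tuple[int, float, str], ...] = ()
    enabled: bool = False


@dataclass(frozen=True)
class ScoreBreakdown:
    e_inter: float
    e_intra: float
    e_penal: float
    e_pharma: float
    wp_elec: float
    wp_hb: float

    @property
    def e_bind(self) -> float:
        return self.e_inter + self.e_intra + self.e_penal

    @property
    def e_ligpre(self) -> float:
        return self.wp_elec + self.wp_hb

    @property
    def e_total(self) -> float:
        # exact decomposition identity: E_tot = E_bind + E_pharma + E_ligpre
        return (self.e_inter + self.e_intra + self.e_penal) + self.e_pharma + (
            self.wp_elec + self.wp_hb
        )

    def to_json(self) -> str:
        d = asdict(self)
        d["e_total"] = self.e_total
        return json.dumps(d, sort_keys=True)


@dataclass(frozen=True)
class SearchBox:
    """Axis-aligned box; ligand atoms outside it trigger the fixed penalty."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    @classmethod
    def around(cls, s: Structure, margin: float = 5.0) -> "SearchBox":
        c = s.heavy_coords()
        return cls(tuple(c.min(axis=0) - margin), tuple(c.max(axis=0) + margin))

    def contains_all(self, coords: np.ndarray) -> bool:
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return bool(np.all(coords >= lo) and np.all(coords <= hi))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return rng.uniform(lo, hi, size=(n, 3))


class ScoringContext:
    """Precomputed target/ligand typing for fast repeated pose scoring."""

    def __init__(
        self,
        target: Structure,
        ligand_types: list[AtomTyping],
        box: SearchBox,
        intra_pairs: np.ndarray | None = None,
        pharma: PharmacophoreSpec | None = None,
        cfg: ScoringConfig = DEFAULT_SCORING,
        target_types: list[AtomTyping] | None = None,
    ) -> None:
        self.cfg = cfg
        self.box = box
        self.pharma = pharma or PharmacophoreSpec()
        if target_types is None:
            target_types = assign_atom_types(target)
        heavy = target.heavy_indices
        self.t_coords = target.coords[heavy]
        t_arr = typing_arrays([target_types[i] for i in heavy])
        self.t_donor = t_arr["donor"]
        self.t_acceptor = t_arr["acceptor"]
        self.t_charge = t_arr["charge"]
        l_arr = typing_arrays(ligand_types)
        self.l_donor = l_arr["donor"]
        self.l_acceptor = l_arr["acceptor"]
        self.l_charge = l_arr["charge"]
        self.n_polar_lig = int(np.sum(self.l_donor | self.l_acceptor))
        self.lig_has_charge = bool(np.any(self.l_charge != 0))
        # intra_pairs: (k, 2) atom index pairs separated by >= 4 bonds
        self.intra_pairs = (np.empty((0, 2), dtype=int)
                            if intra_pairs is None else np.asarray(intra_pairs, int))
        self._hb_pair = (self.t_donor[:, None] & self.l_acceptor[None, :]) | (
            self.t_acceptor[:, None] & self.l_donor[None, :]
        )
        self._qq = self.t_charge[:, None] * self.l_charge[None, :]
        self._l_hb_pair = (l_arr["donor"][:, None] & l_arr["acceptor"][None, :]) | (
            l_arr["acceptor"][:, None] & l_arr["donor"][None, :]
        )
        self._l_qq = self.l_charge[:, None] * self.l_charge[None, :]

    def score(self, ligand_coords: np.ndarray) -> ScoreBreakdown:
        cfg = self.cfg
        L = np.asarray(ligand_coords, dtype=float)
        D = cdist(self.t_coords, L)
        within = D <= cfg.inter_cutoff
        hb = self._hb_pair & within
        st = ~self._hb_pair & within
        e_inter = float(_hbond_well(D[hb], cfg).sum() + _steric_well(D[st], cfg).sum())
        qmask = within & (self._qq != 0)
        had_opposite = bool(np.any((self._qq < 0) & (D <= cfg.ligpre_contact_cutoff)))
        if np.any(qmask):
            r_eff = np.maximum(D[qmask], COULOMB_MIN_R)
            e_inter += float(
                (COULOMB_CONSTANT * self._qq[qmask]
                 / (cfg.dielectric_slope * r_eff ** 2)).sum()
            )
        e_intra = 0.0
        if len(self.intra_pairs):
            i, j = self.intra_pairs.T
            r = np.linalg.norm(L[i] - L[j], axis=1)
            w = r <= cfg.inter_cutoff
            hbp = self._l_hb_pair[i, j] & w
            stp = ~self._l_hb_pair[i, j] & w
            e_intra = float(_hbond_well(r[hbp], cfg).sum() + _steric_well(r[stp], cfg).sum())
            qq = self._l_qq[i, j]
            qm = w & (qq != 0)
            if np.any(qm):
                r_eff = np.maximum(r[qm], COULOMB_MIN_R)
                e_intra += float(
                    (COULOMB_CONSTANT * qq[qm] / (cfg.dielectric_slope * r_eff ** 2)).sum()
                )
        e_penal = 0.0 if self.box.contains_all(L) else cfg.box_penalty
        # ligand-preference penalties
        wp_elec = 0.0
        if self.lig_has_charge and not had_opposite:
            wp_elec = cfg.ligpre_penalty
        wp_hb = 0.0
        if self.n_polar_lig >= cfg.ligpre_min_polar:
            formed = np.any(hb & (_hbond_well(D, cfg) < 0))
            if not formed:
                wp_hb = cfg.ligpre_penalty
        e_pharma = 0.0
        if self.pharma.enabled:
            for atom_idx, weight, required in self.pharma.hotspot_atoms:
                d = D[atom_idx]
                if required == "hbond":
                    ok = np.any(self._hb_pair[atom_idx] & (_hbond_well(d, cfg) < 0))
                else:  # steric
                    ok = np.any(~self._hb_pair[atom_idx] & (_steric_well(d, cfg) < 0))
                if ok:
                    e_pharma += weight
        return ScoreBreakdown(e_inter, e_intra, e_penal, e_pharma, wp_elec, wp_hb)


def score_pose(
    target: Structure,
    ligand_pose: Structure,
    box: SearchBox,
    pharma: PharmacophoreSpec | None = None,
    topology=None,
    cfg: ScoringConfig = DEFAULT_SCORING,
    target_types: list[AtomTyping] | None = None,
) -> ScoreBreakdown:
    """Score one placed ligand conformation against a typed target.

    E_inter sums pair wells over target-ligand heavy-atom pairs within the
    6 A cutoff; E_intra over ligand pairs separated by >= 4 bonds (requires
    `topology`, a :class:`~excidock.flex_dock.LigandTopology`); E_penal is
    the fixed 10000 if any ligand atom lies outside `box`.
    """
    heavy = ligand_pose.heavy_indices
    lig_types = assign_atom_types(ligand_pose)
    lig_types = [lig_types[i] for i in heavy]
    intra = topology.long_range_pairs() if topology is not None else None
    ctx = ScoringContext(
        target, lig_types, box,
        intra_pairs=intra, pharma=pharma, cfg=cfg, target_types=target_types,
    )
    return ctx.score(ligand_pose.coords[heavy])
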