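"""Structure data model, PDB I/O, and core geometry.

The package works on plain heavy-atom coordinate models: an ordered list of
:class:`AtomRecord` grouped into residues identified by author numbering
(chain, residue number, insertion code).  Coordinates are Angstroms
throughout.  Multi-model PDB files double as trajectory input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree


class PDBParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


class PDBFormatError(ValueError):
    """Raised when a Structure cannot be expressed in fixed-width PDB columns."""


class ResidueKey(NamedTuple):
    """Author identity of one residue: (chain, name, number, insertion code)."""

    chain_id: str
    res_name: str
    res_seq: int
    i_code: str = ""

    def __str__(self) -> str:  # e.g. "A:GLU40"
        return f"{self.chain_id}:{self.res_name}{self.res_seq}{self.i_code.strip()}"

    @classmethod
    def from_string(cls, text: str) -> "ResidueKey":
        """Parse 'A:GLU40' or 'A:GLU40B' (trailing letter = insertion code)."""
        chain, _, rest = text.partition(":")
        if not rest:
            raise ValueError(f"cannot parse residue spec {text!r}")
        name = rest[:3]
        tail = rest[3:]
        i_code = ""
        if tail and tail[-1].isalpha():
            i_code = tail[-1]
            tail = tail[:-1]
        return cls(chain, name.upper(), int(tail), i_code)


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str = ""
    coords: tuple[float, float, float] = (0.0, 0.0, 0.0)
    formal_charge: int = 0
    het: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element must be non-empty")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def residue_key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.res_name, self.res_seq, self.i_code)


@dataclass
class Structure:
    """An ordered atom list; atoms of one residue are contiguous."""

    atoms: list[AtomRecord]
    model_id: int = 1
    _coords: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("Structure requires at least one atom")
        seen: dict[ResidueKey, int] = {}
        prev: ResidueKey | None = None
        for i, a in enumerate(self.atoms):
            k = a.residue_key
            if k != prev:
                if k in seen:
                    raise ValueError(f"residue {k} atoms are not contiguous")
                seen[k] = i
                prev = k

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) float64 coordinate array (cached)."""
        if self._coords is None:
            self._coords = np.array([a.coords for a in self.atoms], dtype=float)
        return self._coords

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.is_heavy], dtype=int)

    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.heavy_indices]

    def residue_keys(self) -> list[ResidueKey]:
        """Unique residue keys in atom order."""
        out: list[ResidueKey] = []
        prev = None
        for a in self.atoms:
            k = a.residue_key
            if k != prev:
                out.append(k)
                prev = k
        return out

    def atom_residue_keys(self) -> list[ResidueKey]:
        return [a.residue_key for a in self.atoms]

    def select(self, predicate) -> Structure:
        kept = [a for a in self.atoms if predicate(a)]
        if not kept:
            raise ValueError("selection matched no atoms")
        return Structure(kept, model_id=self.model_id)

    def with_coords(self, coords: np.ndarray) -> Structure:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coords=tuple(map(float, xyz)))
                 for a, xyz in zip(self.atoms, coords)]
        return Structure(atoms, model_id=self.model_id)

    def centroid(self) -> np.ndarray:
        return self.heavy_coords().mean(axis=0)


# ---------------------------------------------------------------------------
# PDB reading / writing (fixed columns, ATOM/HETATM/MODEL/ENDMDL/TER)
# ---------------------------------------------------------------------------

_ELEMENT_FROM_NAME_2 = {"CL", "BR", "NA", "MG", "ZN", "FE", "CA", "MN", "SE"}


def _guess_element(name: str, res_name: str) -> str:
    stripped = name.strip()
    if not stripped:
        return ""
    # amino-acid "CA" is carbon; ionic CA would carry an element field
    two = stripped[:2].upper()
    if two in _ELEMENT_FROM_NAME_2 and res_name.strip().upper() == two:
        return two.capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_float(text: str, what: str, line_no: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(
            f"line {line_no}: non-numeric {what} field {text.strip()!r}"
        ) from None


def _parse_charge(text: str) -> int:
    t = text.strip()
    if not t:
        return 0
    try:
        if len(t) == 2 and t[1] in "+-":  # PDB writes "1+" / "2-"
            return int(t[1] + t[0])
        return int(t)
    except ValueError:
        return 0


def read_pdb(text: str) -> list[Structure]:
    """Parse PDB text into one Structure per MODEL block.

    ATOM and HETATM records are both kept; alternate locations are resolved
    by keeping altLoc blank or 'A'.  Raises :class:`PDBParseError` if no atom
    records are present or a coordinate field is non-numeric (the error names
    the offending line number).
    """
    models: list[list[AtomRecord]] = []
    model_ids: list[int] = []
    current: list[AtomRecord] = []
    current_id = 1
    in_model = False
    for line_no, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            if current:
                models.append(current)
                model_ids.append(current_id)
                current = []
            in_model = True
            try:
                current_id = int(line[10:14])
            except ValueError:
                current_id = len(models) + 1
        elif rec == "ENDMDL":
            models.append(current)
            model_ids.append(current_id)
            current = []
            in_model = False
        elif rec in ("ATOM  ", "HETATM"):
            alt = line[16:17]
            if alt not in (" ", "", "A"):
                continue
            x = _parse_float(line[30:38], "x coordinate", line_no)
            y = _parse_float(line[38:46], "y coordinate", line_no)
            z = _parse_float(line[46:54], "z coordinate", line_no)
            try:
                serial = int(line[6:11])
            except ValueError:
                serial = len(current) + 1
            name = line[12:16]
            res_name = line[17:20].strip()
            chain_id = line[21:22]
            try:
                res_seq = int(line[22:26])
            except ValueError:
                raise PDBParseError(
                    f"line {line_no}: non-numeric residue number {line[22:26].strip()!r}"
                ) from None
            i_code = line[26:27].strip()
            element = line[76:78].strip() if len(line) >= 77 else ""
            if not element:
                element = _guess_element(name, res_name)
            charge = _parse_charge(line[78:80] if len(line) >= 79 else "")
            current.append(
                AtomRecord(
                    serial=serial,
                    name=name.strip(),
                    element=element.capitalize(),
                    res_name=res_name,
                    chain_id=chain_id if chain_id.strip() else " ",
                    res_seq=res_seq,
                    i_code=i_code,
                    coords=(x, y, z),
                    formal_charge=charge,
                    het=(rec == "HETATM"),
                )
            )
    if current:
        models.append(current)
        model_ids.append(current_id if in_model else 1)
    models = [m for m in models if m]  # tolerate empty MODEL blocks
    if not models:
        raise PDBParseError("no ATOM/HETATM records found")
    if len(models) == 1:
        return [Structure(models[0], model_id=1)]
    return [Structure(m, model_id=i + 1) for i, m in enumerate(models)]


def _format_atom_name(a: AtomRecord) -> str:
    name = a.name
    # PDB convention: element right-justified in cols 13-14 for 1-char elements
    if len(name) >= 4:
        return name[:4]
    if len(a.element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structures: Structure | Sequence[Structure]) -> str:
    """Serialise one or several Structures (multi-model) as PDB text.

    Round-trip stable with :func:`read_pdb` at the fixed-width precision
    (coordinates to 3 decimals).  Coordinates with magnitude >= 10000 A do
    not fit the 8-column field and raise :class:`PDBFormatError`.
    """
    if isinstance(structures, Structure):
        seq = [structures]
        multi = False
    else:
        seq = list(structures)
        multi = len(seq) > 1
    lines: list[str] = []
    for idx, s in enumerate(seq, start=1):
        if multi:
            lines.append(f"MODEL     {idx:4d}")
        for a in s.atoms:
            x, y, z = a.coords
            if max(abs(x), abs(y), abs(z)) >= 10000.0:
                raise PDBFormatError(
                    f"coordinate magnitude >= 10000 A for atom {a.serial}"
                )
            if a.res_seq > 9999 or a.res_seq < -999:
                raise PDBFormatError(f"residue number {a.res_seq} out of PDB range")
            rec = "HETATM" if a.het else "ATOM  "
            charge = ""
            if a.formal_charge:
                charge = f"{abs(a.formal_charge)}{'+' if a.formal_charge > 0 else '-'}"
            lines.append(
                f"{rec}{a.serial % 100000:5d} {_format_atom_name(a)}"
                f" {a.res_name:>3s} {a.chain_id:1s}{a.res_seq:4d}{a.i_code or ' ':1s}"
                f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element.upper():>2s}{charge:<2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _check_rotation(rotation: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol) or abs(np.linalg.det(R) - 1.0) > tol:
        raise ValueError("rotation matrix is not orthonormal with determinant +1")
    return R


def transform(s: Structure, rotation: np.ndarray, translation: Iterable[float]) -> Structure:
    """Apply x -> R x + t to every atom.  R must be a proper rotation."""
    R = _check_rotation(rotation)
    t = np.asarray(list(translation), dtype=float)
    if t.shape != (3,):
        raise ValueError("translation must be a 3-vector")
    return s.with_coords(s.coords @ R.T + t)


def ca_rmsd(a: Structure, b: Structure) -> float:
    """C-alpha RMSD between two structures in a common frame (no superposition).

    Atoms are matched by residue key; an error lists unmatched residues.
    """
    ca_a = {at.residue_key: np.array(at.coords) for at in a.atoms if at.name == "CA"}
    ca_b = {at.residue_key: np.array(at.coords) for at in b.atoms if at.name == "CA"}
    if set(ca_a) != set(ca_b):
        missing = sorted(map(str, set(ca_a) ^ set(ca_b)))
        raise ValueError(f"C-alpha sets differ; unmatched residues: {', '.join(missing)}")
    if not ca_a:
        raise ValueError("no C-alpha atoms to compare")
    keys = [at.residue_key for at in a.atoms if at.name == "CA"]
    diff = np.array([ca_a[k] - ca_b[k] for k in keys])
    return float(np.sqrt((diff ** 2).sum(axis=1).mean()))


def coords_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Plain RMSD between two matched coordinate arrays (no superposition)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("coordinate arrays must have identical shape")
    return float(np.sqrt(((x - y) ** 2).sum(axis=1).mean()))


def contact_residues(
    target: Structure,
    probe_coords: np.ndarray | Sequence[Sequence[float]],
    cutoff: float = 4.0,
) -> set[ResidueKey]:
    """Residues with any heavy atom within `cutoff` (closed, <=) of any probe point."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    probe = np.asarray(probe_coords, dtype=float)
    if probe.size == 0:
        return set()
    probe = probe.reshape(-1, 3)
    heavy = target.heavy_indices
    coords = target.coords[heavy]
    keys = target.atom_residue_keys()
    tree = cKDTree(coords)
    hit = set()
    for idx_list in tree.query_ball_point(probe, r=cutoff):
        for i in idx_list:
            hit.add(keys[heavy[i]])
    return hit
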