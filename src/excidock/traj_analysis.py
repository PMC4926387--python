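"""Trajectory validation of docked contacts.

Trajectories are multi-model PDB snapshot series.  The analyses mirror the
standard post-docking checks: per-frame minimum distance between a residue
group and the ligand, fraction of frames keeping that distance within the
4 A contact cutoff ("contact persistence"; 1.0 means the docked contact is
maintained throughout), RMSD against a reference after optimal
superposition, and per-residue C-alpha RMSF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structio import AtomRecord, ResidueKey, Structure, read_pdb


@dataclass
class Trajectory:
    frames: list[Structure]
    frame_interval_ps: float = 5.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        ref = [(a.residue_key, a.name) for a in self.frames[0].atoms]
        for k, f in enumerate(self.frames[1:], start=2):
            if [(a.residue_key, a.name) for a in f.atoms] != ref:
                raise ValueError(f"frame {k} atom set differs from frame 1")

    def __len__(self) -> int:
        return len(self.frames)

    @classmethod
    def from_pdb(cls, text: str, frame_interval_ps: float = 5.0) -> "Trajectory":
        return cls(read_pdb(text), frame_interval_ps=frame_interval_ps)


@dataclass
class DistanceSeries:
    values: np.ndarray
    residue_label: str = ""
    ligand_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")


def _atom_indices(s: Structure, predicate: Callable[[AtomRecord], bool]) -> np.ndarray:
    return np.array(
        [i for i, a in enumerate(s.atoms) if a.is_heavy and predicate(a)], dtype=int
    )


def min_distance_series(
    traj: Trajectory,
    residues: set[ResidueKey],
    ligand_sel: Callable[[AtomRecord], bool],
) -> DistanceSeries:
    """Per-frame minimum heavy-atom distance between residue group and ligand."""
    f0 = traj.frames[0]
    res_idx = _atom_indices(f0, lambda a: a.residue_key in residues)
    lig_idx = _atom_indices(f0, ligand_sel)
    if len(res_idx) == 0:
        raise ValueError("residue selection matched no heavy atoms")
    if len(lig_idx) == 0:
        raise ValueError("ligand selection matched no heavy atoms")
    values = np.empty(len(traj))
    for k, frame in enumerate(traj.frames):
        c = frame.coords
        values[k] = cdist(c[res_idx], c[lig_idx]).min()
    label = ",".join(sorted(map(str, residues)))
    return DistanceSeries(values, residue_label=label, ligand_label="ligand")


def contact_persistence(series: DistanceSeries, cutoff: float = 4.0) -> float:
    """Fraction of frames with distance <= cutoff (closed interval)."""
    if len(series.values) == 0:
        raise ValueError("empty distance series")
    return float(np.mean(series.values <= cutoff))


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of mobile onto ref (no reflection).

    Returns (rotation, mobile centroid, ref centroid)."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mobile - mc)
    return rot.as_matrix(), mc, rc


def rmsd_series(
    traj: Trajectory,
    reference: Structure,
    selection: Callable[[AtomRecord], bool] = lambda a: a.name == "CA",
) -> np.ndarray:
    """Per-frame RMSD vs reference after optimal superposition on `selection`."""
    sel_ref = _atom_indices(reference, selection)
    sel_frame = _atom_indices(traj.frames[0], selection)
    if len(sel_ref) == 0 or len(sel_frame) == 0:
        raise ValueError("selection matched no heavy atoms")
    if len(sel_ref) != len(sel_frame):
        raise ValueError("selection size differs between trajectory and reference")
    ref = reference.coords[sel_ref]
    out = np.empty(len(traj))
    for k, frame in enumerate(traj.frames):
        mob = frame.coords[sel_frame]
        R, mc, rc = _kabsch(mob, ref)
        fitted = (mob - mc) @ R.T + rc
        out[k] = np.sqrt(((fitted - ref) ** 2).sum(axis=1).mean())
    return out


def rmsf(
    traj: Trajectory,
    selection: Callable[[AtomRecord], bool] = lambda a: a.name == "CA",
    superpose: bool = False,
) -> dict[ResidueKey, float]:
    """Per-residue C-alpha RMSF about the trajectory mean position.

    By default coordinates are used as given (snapshot series are assumed
    pre-aligned); with superpose=True each frame is first fitted onto the
    first frame over the selection.
    """
    sel = _atom_indices(traj.frames[0], selection)
    if len(sel) == 0:
        raise ValueError("selection matched no heavy atoms")
    X = np.stack([f.coords[sel] for f in traj.frames])  # (F, N, 3)
    if superpose and len(traj) > 1:
        ref = X[0]
        for k in range(1, len(X)):
            R, mc, rc = _kabsch(X[k], ref)
            X[k] = (X[k] - mc) @ R.T + rc
    mean = X.mean(axis=0)
    dev = np.sqrt(((X - mean) ** 2).sum(axis=2).mean(axis=0))
    keys = [traj.frames[0].atoms[i].residue_key for i in sel]
    return dict(zip(keys, map(float, dev)))
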