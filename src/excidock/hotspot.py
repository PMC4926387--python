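"""Interaction maps, binding spots, and cross-excipient hotspots.

Docked poses are turned into residue-level summaries in three steps:
per-pose typed interaction maps at 3.5 A, per-excipient "spots" (connected
groups of poses sharing contact residues or lying within 8 A of each
other), and consolidated hotspots merging spots across excipients by the
same connectivity rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .scoring import AtomTyping, ScoringConfig, DEFAULT_SCORING, assign_atom_types
from .structio import ResidueKey, Structure, contact_residues


@dataclass(frozen=True)
class MapEntry:
    residue: ResidueKey
    kind: str  # "hbond" | "electrostatic" | "hydrophobic"
    distance: float


@dataclass
class InteractionMap:
    pose_id: int
    entries: list[MapEntry]

    def residues(self) -> set[ResidueKey]:
        return {e.residue for e in self.entries}


def interaction_map(
    target: Structure,
    pose: Structure,
    cutoff: float = 3.5,
    pose_id: int = 0,
    hbond_min: float = 2.0,
    target_types: list[AtomTyping] | None = None,
) -> InteractionMap:
    """Typed residue-level contacts within `cutoff`.

    Classification per target-residue/ligand-atom pair: donor<->acceptor at
    distance in [hbond_min, cutoff] -> hbond; oppositely charged atoms ->
    electrostatic; anything else -> hydrophobic.  When several types apply
    the priority is hbond > electrostatic > hydrophobic; one entry per
    (residue, type) keeps the minimum distance.
    """
    if target_types is None:
        target_types = assign_atom_types(target)
    pose_types = assign_atom_types(pose)
    theavy = target.heavy_indices
    pheavy = pose.heavy_indices
    D = cdist(target.coords[theavy], pose.coords[pheavy])
    tkeys = target.atom_residue_keys()
    best: dict[tuple[ResidueKey, str], float] = {}
    for a in range(len(theavy)):
        ti = target_types[theavy[a]]
        for b in range(len(pheavy)):
            d = D[a, b]
            if d > cutoff:
                continue
            pj = pose_types[pheavy[b]]
            is_hb = ((ti.donor and pj.acceptor) or (pj.donor and ti.acceptor)) \
                and d >= hbond_min
            if is_hb:
                kind = "hbond"
            elif ti.charge * pj.charge < 0:
                kind = "electrostatic"
            else:
                kind = "hydrophobic"
            key = (tkeys[theavy[a]], kind)
            if d < best.get(key, np.inf):
                best[key] = d
    entries = [MapEntry(res, kind, float(d))
               for (res, kind), d in sorted(best.items(),
                                            key=lambda kv: (str(kv[0][0]), kv[0][1]))]
    return InteractionMap(pose_id=pose_id, entries=entries)


@dataclass
class PoseRecord:
    """Minimal pose summary feeding spot/hotspot analysis."""

    excipient: str
    pose_id: int
    e_total: float
    centroid: np.ndarray
    contacts: frozenset[ResidueKey]


def pose_record(target: Structure, pose, contact_cutoff: float = 4.0,
                excipient: str | None = None) -> PoseRecord:
    """Build a PoseRecord from a flex-dock Pose against its target."""
    coords = pose.coords
    contacts = contact_residues(target, coords, cutoff=contact_cutoff)
    return PoseRecord(
        excipient=excipient or pose.excipient,
        pose_id=pose.pose_id,
        e_total=pose.e_total,
        centroid=coords.mean(axis=0),
        contacts=frozenset(contacts),
    )


def _connected_labels(records: list[PoseRecord], merge_distance: float) -> list[int]:
    """Union-find over the pose connectivity rule (shared residue OR nearby
    centroids); returns raw component index per record."""
    n = len(records)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    finite = [bool(np.all(np.isfinite(r.centroid))) for r in records]
    for i in range(n):
        for j in range(i + 1, n):
            if records[i].contacts & records[j].contacts:
                union(i, j)
            elif finite[i] and finite[j] and np.linalg.norm(
                    records[i].centroid - records[j].centroid) <= merge_distance:
                union(i, j)
    return [find(i) for i in range(n)]


def assign_spots(records: list[PoseRecord], merge_distance: float = 8.0) -> list[int]:
    """Spot label (1-based) per pose.

    Poses are connected iff they share a contact residue or their centroids
    are within `merge_distance`; spots are the connected components,
    numbered by best (lowest) member energy.
    """
    if not records:
        raise ValueError("need at least one pose")
    roots = _connected_labels(records, merge_distance)
    best: dict[int, float] = {}
    for rec, root in zip(records, roots):
        best[root] = min(best.get(root, np.inf), rec.e_total)
    order = {root: rank + 1
             for rank, root in enumerate(sorted(best, key=lambda r: best[r]))}
    return [order[r] for r in roots]


@dataclass
class Hotspot:
    id: int
    members: list[tuple[str, int, float]]  # (excipient, pose id, e_total)
    residues: set[ResidueKey]
    excipients: set[str]
    best_energy: float

    def residue_ranges(self) -> dict[str, str]:
        return {chain: ranges for chain, ranges in _per_chain_ranges(self.residues).items()}


def _per_chain_ranges(residues: set[ResidueKey]) -> dict[str, str]:
    """Compress residues into per-chain maximal runs allowing gaps <= 1,
    e.g. "Lys43-Trp47; Arg67"."""
    by_chain: dict[str, list[ResidueKey]] = {}
    for r in residues:
        by_chain.setdefault(r.chain_id, []).append(r)
    out: dict[str, str] = {}
    for chain, keys in sorted(by_chain.items()):
        keys.sort(key=lambda k: (k.res_seq, k.i_code))
        runs: list[list[ResidueKey]] = []
        for k in keys:
            if runs and k.res_seq - runs[-1][-1].res_seq <= 2:
                runs[-1].append(k)
            else:
                runs.append([k])
        parts = []
        for run in runs:
            a, b = run[0], run[-1]
            label_a = f"{a.res_name.capitalize()}{a.res_seq}{a.i_code}"
            if a is b:
                parts.append(label_a)
            else:
                parts.append(f"{label_a}-{b.res_name.capitalize()}{b.res_seq}{b.i_code}")
        out[chain] = "; ".join(parts)
    return out


def consolidate_hotspots(
    per_excipient: dict[str, list[PoseRecord]],
    merge_distance: float = 8.0,
) -> list[Hotspot]:
    """Merge spots across excipients into hotspots.

    All poses of all excipients enter one connectivity graph (shared contact
    residue OR centroid proximity); each connected component becomes a
    Hotspot recording its member poses, residue union, excipient set and
    best energy.  Output ordered ascending by best energy, ids 1-based.
    """
    if not per_excipient:
        raise ValueError("need at least one excipient")
    records = [r for recs in per_excipient.values() for r in recs]
    if not records:
        raise ValueError("no poses to consolidate")
    roots = _connected_labels(records, merge_distance)
    groups: dict[int, list[PoseRecord]] = {}
    for rec, root in zip(records, roots):
        groups.setdefault(root, []).append(rec)
    spots = sorted(groups.values(), key=lambda g: min(r.e_total for r in g))
    out: list[Hotspot] = []
    for hid, grp in enumerate(spots, start=1):
        members = sorted(((r.excipient, r.pose_id, r.e_total) for r in grp),
                         key=lambda m: m[2])
        residues: set[ResidueKey] = set()
        for r in grp:
            residues |= r.contacts
        out.append(Hotspot(
            id=hid,
            members=members,
            residues=residues,
            excipients={r.excipient for r in grp},
            best_energy=min(r.e_total for r in grp),
        ))
    return out


def hotspots_as_records(hotspots: list[Hotspot]) -> list[PoseRecord]:
    """Re-express hotspots as pose records (for idempotence checks)."""
    out = []
    for h in hotspots:
        for exc, pid, e in h.members:
            out.append(PoseRecord(
                excipient=exc, pose_id=pid, e_total=e,
                centroid=np.zeros(3) + np.inf,  # centroid rule disabled
                contacts=frozenset(h.residues),
            ))
    return out


def spot_table(records: list[PoseRecord], spots: list[int]) -> pd.DataFrame:
    """Rows (excipient, pose id, E_total, spot), energy-sorted per excipient."""
    if len(records) != len(spots):
        raise ValueError("records and spot labels must align")
    df = pd.DataFrame({
        "excipient": [r.excipient for r in records],
        "pose_id": [r.pose_id for r in records],
        "e_total": [r.e_total for r in records],
        "spot": spots,
    })
    return (df.sort_values(["excipient", "e_total"], kind="stable")
              .reset_index(drop=True))


def hotspot_table(hotspots: list[Hotspot]) -> pd.DataFrame:
    """Report-style table: one row per member pose with hotspot metadata."""
    rows = []
    for h in hotspots:
        ranges = h.residue_ranges()
        desc = " | ".join(f"Chain {c}: {r}" for c, r in ranges.items())
        for exc, pid, e in h.members:
            rows.append({
                "hotspot": h.id,
                "excipient": exc,
                "pose_id": pid,
                "e_total": e,
                "residue_ranges": desc,
            })
    return pd.DataFrame(rows)
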