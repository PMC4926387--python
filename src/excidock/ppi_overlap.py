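"""Overlap between excipient hotspots and protein-protein interfaces.

An excipient that binds inside a region a second protein copy also docks to
may shield that region from self-association.  This module counts, per
rigid-docking solution, which hotspots share residues with the
receptor-side interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .hotspot import Hotspot
from .structio import ResidueKey


@dataclass
class HotspotMatch:
    hotspot_id: int
    overlap_count: int
    overlap_fraction: float  # count / |hotspot residues|


@dataclass
class InterfaceReport:
    solution_id: int
    receptor_residues: set[ResidueKey]
    ligand_residues: set[ResidueKey]
    chain_counts: dict[str, int]
    dominant_chain: str
    matches: list[HotspotMatch]

    def matched_ids(self) -> list[int]:
        return [m.hotspot_id for m in self.matches]


def overlap_report(
    hotspots: list[Hotspot],
    interfaces: list[tuple[set[ResidueKey], set[ResidueKey]]],
    universe: set[ResidueKey] | None = None,
    min_overlap: int = 1,
) -> list[InterfaceReport]:
    """Per docking solution: hotspot/interface residue overlap bookkeeping.

    `interfaces` holds (receptor-side, ligand-side) residue sets per
    solution.  A hotspot matches a solution iff it shares at least
    `min_overlap` residues with the receptor-side set.  If `universe` is
    given (the receptor's residue keys), foreign keys raise an error.
    """
    if universe is not None:
        for h in hotspots:
            bad = h.residues - universe
            if bad:
                raise ValueError(
                    f"hotspot {h.id} has residue keys outside the structure: "
                    f"{sorted(map(str, bad))[:5]}"
                )
        for sid, (rec_side, _) in enumerate(interfaces, start=1):
            bad = rec_side - universe
            if bad:
                raise ValueError(
                    f"interface {sid} has residue keys outside the structure: "
                    f"{sorted(map(str, bad))[:5]}"
                )
    reports: list[InterfaceReport] = []
    for sid, (rec_side, lig_side) in enumerate(interfaces, start=1):
        counts: dict[str, int] = {}
        for r in rec_side:
            counts[r.chain_id] = counts.get(r.chain_id, 0) + 1
        dominant = max(sorted(counts), key=lambda c: counts[c]) if counts else ""
        matches = []
        for h in hotspots:
            inter = len(h.residues & rec_side)
            if inter >= min_overlap:
                matches.append(HotspotMatch(
                    hotspot_id=h.id,
                    overlap_count=inter,
                    overlap_fraction=inter / len(h.residues) if h.residues else 0.0,
                ))
        reports.append(InterfaceReport(
            solution_id=sid,
            receptor_residues=set(rec_side),
            ligand_residues=set(lig_side),
            chain_counts=counts,
            dominant_chain=dominant,
            matches=matches,
        ))
    return reports


def summarize_matches(reports: list[InterfaceReport]) -> pd.DataFrame:
    """One row per solution: dominant chain and matched hotspot ids."""
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for r in reports:
        rows.append({
            "solution": r.solution_id,
            "dominant_chain": r.dominant_chain,
            "matching_hotspots": ", ".join(str(i) for i in r.matched_ids()) or "none",
            "n_interface_residues": len(r.receptor_residues),
        })
    return pd.DataFrame(rows)
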