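"""Shared fixtures: small deterministic structures and ligands."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from excidock import fixtures as fx
from excidock.structio import AtomRecord, Structure

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_atom(serial, name, element, res_name, chain, res_seq, xyz, charge=0, het=False):
    return AtomRecord(serial=serial, name=name, element=element, res_name=res_name,
                      chain_id=chain, res_seq=res_seq,
                      coords=tuple(float(v) for v in xyz),
                      formal_charge=charge, het=het)


def random_protein(rng: np.random.Generator, n_residues: int = 10,
                   chain: str = "A", spread: float = 12.0) -> Structure:
    """Random CA + CB pseudo-protein (no self-avoidance; geometry tests only)."""
    atoms = []
    serial = 1
    names = ["ALA", "SER", "ASP", "LYS", "GLY"]
    for i in range(n_residues):
        ca = rng.uniform(-spread, spread, 3)
        res = names[int(rng.integers(len(names)))]
        atoms.append(make_atom(serial, "CA", "C", res, chain, i + 1, ca))
        serial += 1
        if res != "GLY":
            side = {"ALA": ("CB", "C"), "SER": ("OG", "O"),
                    "ASP": ("OD2", "O"), "LYS": ("NZ", "N")}[res]
            atoms.append(make_atom(serial, side[0], side[1], res, chain, i + 1,
                                   ca + rng.normal(0, 1.5, 3)))
            serial += 1
    return Structure(atoms)


@pytest.fixture(scope="session")
def toy_receptor():
    return fx.make_toy_receptor(42)


@pytest.fixture(scope="session")
def amino_ligand():
    return fx.make_ligand("amino-acid-like")


@pytest.fixture(scope="session")
def ppi_pair():
    return fx.make_ppi_pair(21)
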