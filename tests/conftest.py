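"""Shared helpers for hand-building tiny structure models in tests."""

from __future__ import annotations

import numpy as np
import pytest

from looptag.structure import Atom, Chain, Residue, StructureMetadata, StructureModel


def make_atom(name: str, element: str, xyz, occ: float = 1.0, b: float = 20.0, altloc: str = "") -> Atom:
    return Atom(name, element, np.asarray(xyz, float), occ, b, altloc)


def make_residue(name3: str, num: int, atoms, is_polymer: bool = True, icode: str = "") -> Residue:
    built = [a if isinstance(a, Atom) else make_atom(*a) for a in atoms]
    return Residue(name3=name3, author_seq=num, icode=icode, is_polymer=is_polymer, atoms=built)


def make_model(chains, entry_id: str = "TEST", method: str = "X-RAY DIFFRACTION",
               resolution: float | None = 1.0) -> StructureModel:
    return StructureModel(
        StructureMetadata(entry_id=entry_id, method=method, resolution=resolution),
        chains,
    )


def poly_ala_chain(n: int, chain_id: str = "A", spacing: float = 3.8) -> Chain:
    residues = [
        make_residue("ALA", i + 1, [("CA", "C", [i * spacing, 0.0, 0.0])])
        for i in range(n)
    ]
    return Chain(chain_id, polymer_residues=residues)


@pytest.fixture
def poly_ala_model(tmp_path):
    """10-residue poly-alanine helix written to disk as a PDB file."""
    from looptag.fixtures import make_ideal_helix
    from looptag.structure import write_pdb

    model = make_ideal_helix(10, entry_id="PALA")
    path = tmp_path / "polyala.pdb"
    write_pdb(model, path)
    return model, path
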