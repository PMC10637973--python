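"""Structure I/O: a uniform in-memory model over PDB and mmCIF files.

Parsing is delegated to :mod:`gemmi`; the parsed hierarchy is converted to a
small, explicit model (``StructureModel`` -> ``Chain`` -> ``Residue`` ->
``Atom``) that the rest of the package operates on.  Only the first model of
a multi-model file is kept (the crystallographic use case).  Waters are kept
separate from other heteroatoms so that ligand bookkeeping never counts
solvent.  Author residue numbering (with insertion codes) is the public
coordinate system throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional

import gemmi
import numpy as np

from ._data import (
    AA3_TO_1,
    AMINO_ACID_CODES,
    MODIFIED_PARENT,
    NUCLEOTIDE_CODES,
    WATER_CODES,
)


class LoopTagError(Exception):
    """Base class for all package errors."""


class ParseError(LoopTagError):
    """Raised when a structure file cannot be read or parsed."""


class EmptyStructureError(LoopTagError):
    """Raised when a parsed file contains no polymer residues."""


class UnsupportedPolymerError(LoopTagError):
    """Raised when a chain is not a protein polymer (e.g. nucleic acid)."""


@dataclass
class Atom:
    """A single atom site.

    Coordinates are Cartesian ångströms; ``altloc`` is a one-character
    alternate-location identifier or the empty string.
    """

    name: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite numbers")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if self.bfactor < 0:
            raise ValueError(f"atom {self.name}: negative B-factor {self.bfactor}")


@dataclass
class Residue:
    name3: str
    author_seq: int
    icode: str = ""
    is_polymer: bool = True
    atoms: list[Atom] = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.name3} {self.author_seq}{self.icode}"

    def get_atom(self, name: str) -> Optional[Atom]:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None


@dataclass
class Chain:
    chain_id: str
    polymer_residues: list[Residue] = field(default_factory=list)
    het_residues: list[Residue] = field(default_factory=list)

    def residue_by_author_seq(self, author_seq: int, icode: str = "") -> Optional[Residue]:
        for res in self.polymer_residues:
            if res.author_seq == author_seq and res.icode == icode:
                return res
        return None

    def iter_atoms(self, het: bool = True) -> Iterator[tuple[Residue, Atom]]:
        for res in self.polymer_residues:
            for atom in res.atoms:
                yield res, atom
        if het:
            for res in self.het_residues:
                for atom in res.atoms:
                    yield res, atom


@dataclass
class StructureMetadata:
    entry_id: str = ""
    method: str = ""
    resolution: Optional[float] = None
    model_count: int = 1

    def __post_init__(self) -> None:
        if self.resolution is not None and not self.resolution > 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")


@dataclass
class StructureModel:
    metadata: StructureMetadata
    chains: list[Chain]

    def get_chain(self, chain_id: str) -> Chain:
        for chain in self.chains:
            if chain.chain_id == chain_id:
                return chain
        raise KeyError(f"no chain {chain_id!r} in entry {self.metadata.entry_id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def n_polymer_residues(self) -> int:
        return sum(len(c.polymer_residues) for c in self.chains)

    def iter_atoms(self, het: bool = True) -> Iterator[tuple[Chain, Residue, Atom]]:
        for chain in self.chains:
            for res, atom in chain.iter_atoms(het=het):
                yield chain, res, atom


def _detect_format(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if any(s in (".cif", ".mmcif") for s in suffixes):
        return "mmcif"
    if any(s in (".pdb", ".ent") for s in suffixes):
        return "pdb"
    # Content sniffing: mmCIF files start with a data block or comments.
    try:
        head = path.read_text(errors="replace")[:4096]
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmcif"
    return "pdb"


_GEMMI_FORMATS = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}


def _is_polymer_residue(name: str, het_flag: str) -> bool:
    # Amino acids (incl. common modified ones such as MSE, often deposited as
    # HETATM) count as polymer; everything else keeps its HETATM standing.
    if name in WATER_CODES:
        return False
    if name in AMINO_ACID_CODES or name in NUCLEOTIDE_CODES:
        return True
    return het_flag == "A"


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ``format`` may be ``"pdb"``, ``"mmcif"`` or ``"auto"`` (extension first,
    then content sniffing).  Only the first model of multi-model files is
    retained.  Raises :class:`ParseError` for unreadable input and
    :class:`EmptyStructureError` when no polymer residue is present.
    """
    path = Path(path)
    if not path.is_file():
        raise ParseError(f"no such file: {path}")
    if format == "auto":
        format = _detect_format(path)
    if format not in _GEMMI_FORMATS:
        raise ValueError(f"unknown format {format!r} (expected pdb, mmcif or auto)")
    try:
        st = gemmi.read_structure(str(path), format=_GEMMI_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"failed to parse {path} as {format}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: file contains no coordinate model")

    info = dict(st.info)
    metadata = StructureMetadata(
        entry_id=info.get("_entry.id", st.name) or st.name,
        method=info.get("_exptl.method", ""),
        resolution=st.resolution if st.resolution and st.resolution > 0 else None,
        model_count=len(st),
    )

    chains: list[Chain] = []
    for gchain in st[0]:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            icode = gres.seqid.icode.strip()
            residue = Residue(
                name3=gres.name,
                author_seq=gres.seqid.num,
                icode=icode,
                is_polymer=_is_polymer_residue(gres.name, gres.het_flag),
            )
            for gatom in gres:
                altloc = gatom.altloc if gatom.altloc not in ("\x00", " ") else ""
                residue.atoms.append(
                    Atom(
                        name=gatom.name,
                        element=gatom.element.name.upper(),
                        xyz=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        occupancy=min(max(gatom.occ, 0.0), 1.0),
                        bfactor=max(gatom.b_iso, 0.0),
                        altloc=altloc,
                    )
                )
            if residue.is_polymer:
                chain.polymer_residues.append(residue)
            else:
                chain.het_residues.append(residue)
        if chain.polymer_residues or chain.het_residues:
            chains.append(chain)

    model = StructureModel(metadata=metadata, chains=chains)
    if model.n_polymer_residues() == 0:
        raise EmptyStructureError(f"{path}: no polymer residues (only solvent/ligands)")
    return model


def resolve_altlocs(model: StructureModel, policy: str = "highest_occupancy") -> StructureModel:
    """Collapse alternate locations to a single atom per name per residue.

    The only supported policy keeps the highest-occupancy location; ties are
    broken by altloc character order (``A`` before ``B``).  Residues without
    altlocs are returned unchanged.
    """
    if policy != "highest_occupancy":
        raise ValueError(f"unknown altloc policy {policy!r}")

    def resolve_residue(res: Residue) -> Residue:
        if all(a.altloc == "" for a in res.atoms):
            return res
        best: dict[str, Atom] = {}
        for atom in res.atoms:
            cur = best.get(atom.name)
            if cur is None:
                best[atom.name] = atom
            elif (atom.occupancy, _neg_ord(atom.altloc)) > (cur.occupancy, _neg_ord(cur.altloc)):
                best[atom.name] = atom
        seen: set[str] = set()
        atoms = []
        for atom in res.atoms:  # preserve file order of first occurrence
            if atom.name not in seen:
                seen.add(atom.name)
                atoms.append(replace(best[atom.name], altloc=""))
        return replace(res, atoms=atoms)

    chains = [
        Chain(
            chain_id=c.chain_id,
            polymer_residues=[resolve_residue(r) for r in c.polymer_residues],
            het_residues=[resolve_residue(r) for r in c.het_residues],
        )
        for c in model.chains
    ]
    return StructureModel(metadata=model.metadata, chains=chains)


def _neg_ord(altloc: str) -> int:
    # Higher is better; blank sorts above 'A' (a lone unlabelled atom wins).
    return -ord(altloc) if altloc else 0


def residue_one_letter(name3: str) -> str:
    parent = MODIFIED_PARENT.get(name3, name3)
    return AA3_TO_1.get(parent, "X")


def polymer_sequence(chain: Chain) -> str:
    """One-letter amino-acid sequence over the chain's polymer residues.

    Modified residues map to their parent (MSE -> M); unknown codes map to
    ``X``.  Nucleic-acid chains raise :class:`UnsupportedPolymerError`.
    """
    if not chain.polymer_residues:
        raise ValueError(f"chain {chain.chain_id}: no polymer residues")
    n_nuc = sum(1 for r in chain.polymer_residues if r.name3 in NUCLEOTIDE_CODES)
    if n_nuc > len(chain.polymer_residues) / 2:
        raise UnsupportedPolymerError(
            f"chain {chain.chain_id} looks like a nucleic acid, not a protein"
        )
    return "".join(residue_one_letter(r.name3) for r in chain.polymer_residues)


# ---------------------------------------------------------------------------
# Minimal fixed-column PDB writer (used for synthetic fixtures and round-trips)

def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_line(record: str, serial: int, atom: Atom, res: Residue, chain_id: str) -> str:
    x, y, z = atom.xyz
    return (
        f"{record:<6s}{min(serial, 99999):5d} {_format_atom_name(atom.name, atom.element)}"
        f"{atom.altloc or ' ':1s}{res.name3:>3s} {chain_id[:1]:1s}"
        f"{res.author_seq:4d}{res.icode or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a strict fixed-column PDB file.

    Emits EXPDTA and REMARK 2 so that experimental method and resolution
    survive a round trip; output is fully deterministic.
    """
    lines: list[str] = []
    meta = model.metadata
    if meta.entry_id:
        lines.append(f"HEADER    {'PROTEIN':<40s}{'':9s}   {meta.entry_id[:4].upper():>4s}")
    if meta.method:
        lines.append(f"EXPDTA    {meta.method}")
    if meta.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {meta.resolution:7.2f} ANGSTROMS.")
    serial = 1
    for chain in model.chains:
        last_res = None
        for res in chain.polymer_residues:
            for atom in res.atoms:
                lines.append(_atom_line("ATOM", serial, atom, res, chain.chain_id))
                serial += 1
            last_res = res
        if last_res is not None:
            lines.append(
                f"TER   {min(serial, 99999):5d}      {last_res.name3:>3s} "
                f"{chain.chain_id[:1]:1s}{last_res.author_seq:4d}{last_res.icode or ' ':1s}"
            )
            serial += 1
        for res in chain.het_residues:
            for atom in res.atoms:
                lines.append(_atom_line("HETATM", serial, atom, res, chain.chain_id))
                serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def transform_model(model: StructureModel, rotation: np.ndarray, translation: np.ndarray) -> StructureModel:
    """Return a copy of the model with ``x -> R x + t`` applied to every atom."""
    rotation = np.asarray(rotation, float)
    translation = np.asarray(translation, float)

    def tr_res(res: Residue) -> Residue:
        return replace(
            res,
            atoms=[replace(a, xyz=rotation @ a.xyz + translation) for a in res.atoms],
        )

    chains = [
        Chain(
            chain_id=c.chain_id,
            polymer_residues=[tr_res(r) for r in c.polymer_residues],
            het_residues=[tr_res(r) for r in c.het_residues],
        )
        for c in model.chains
    ]
    return StructureModel(metadata=model.metadata, chains=chains)
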