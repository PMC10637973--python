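"""Deterministic synthetic structures with planted, manifest-recorded truth.

Every generator takes an explicit seed and produces byte-identical PDB
output for the same seed.  Geometry is minimal but sufficient for the
geometric operators: Cα traces with derived N/C/O backbone atoms, plus the
functional side-chain atoms a test plants (SG for disulfides, charged or
polar atoms for contacts).  The screen-library generator emits chains that
violate exactly the criteria requested, together with a manifest that
serves as the test oracle.  Nothing here attempts physical realism — no
folding, no sterics, no energies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from ._data import AA1_TO_3
from .structure import (
    Atom,
    Chain,
    Residue,
    StructureMetadata,
    StructureModel,
    write_pdb,
)

HELIX_RISE = 1.5  # Å per residue along the axis
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å, Cα ring radius


@dataclass
class FixtureEntry:
    filename: str
    entry_id: str
    chain_id: str
    n_residues: int
    planted: dict
    expected_fail: list[str]
    expected_pass: bool


@dataclass
class FixtureManifest:
    seed: int
    entries: list[FixtureEntry] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "entries": [asdict(e) for e in self.entries]},
            indent=2,
            sort_keys=True,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    return v / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])


def _perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(v, ref))


def _model_from_ca(
    ca: np.ndarray,
    sequence: str,
    entry_id: str,
    chain_id: str = "A",
    resolution: Optional[float] = 1.0,
    method: str = "X-RAY DIFFRACTION",
    bfactor: float = 20.0,
    start_number: int = 1,
) -> StructureModel:
    """Build a model with N/CA/C/O backbone atoms derived from a Cα trace."""
    n = len(ca)
    assert len(sequence) == n
    residues = []
    for i in range(n):
        prev_dir = _unit(ca[i] - ca[i - 1]) if i > 0 else _unit(ca[min(1, n - 1)] - ca[0])
        next_dir = _unit(ca[i + 1] - ca[i]) if i < n - 1 else prev_dir
        n_xyz = ca[i] - 1.46 * prev_dir
        c_xyz = ca[i] + 1.52 * next_dir
        o_xyz = c_xyz + 1.23 * _perp(next_dir)
        atoms = [
            Atom("N", "N", n_xyz, 1.0, bfactor),
            Atom("CA", "C", ca[i], 1.0, bfactor),
            Atom("C", "C", c_xyz, 1.0, bfactor),
            Atom("O", "O", o_xyz, 1.0, bfactor),
        ]
        residues.append(
            Residue(
                name3=AA1_TO_3.get(sequence[i], "ALA"),
                author_seq=start_number + i,
                atoms=atoms,
            )
        )
    chain = Chain(chain_id=chain_id, polymer_residues=residues)
    metadata = StructureMetadata(
        entry_id=entry_id, method=method, resolution=resolution, model_count=1
    )
    return StructureModel(metadata=metadata, chains=[chain])


def make_ideal_helix(
    n: int,
    seed: int = 0,
    sequence: Optional[str] = None,
    entry_id: str = "HLX1",
    resolution: Optional[float] = 1.0,
) -> StructureModel:
    """Ideal straight α-helix: 1.5 Å rise and 100° twist per residue."""
    if n < 2:
        raise ValueError("helix needs at least 2 residues")
    sequence = sequence or "A" * n
    i = np.arange(n, dtype=float)
    theta = np.radians(HELIX_TWIST) * i
    ca = np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
    )
    return _model_from_ca(ca, sequence, entry_id, resolution=resolution)


def make_hairpin(
    n: int,
    target_termini_d: float = 6.3,
    seed: int = 0,
    sequence: Optional[str] = None,
    entry_id: str = "HPN1",
    resolution: Optional[float] = 1.0,
) -> StructureModel:
    """Extended two-strand hairpin: termini adjacent, shape highly elongated.

    Useful as a chain that satisfies the termini-proximity criterion while
    failing compactness.  The terminal Cα–Cα distance is exact.
    """
    if n < 4:
        raise ValueError("hairpin needs at least 4 residues")
    sequence = sequence or "A" * n
    half = n // 2
    ca = np.zeros((n, 3))
    for i in range(n):
        if i < half:
            ca[i] = [0.0, 0.0, 3.5 * i]
        else:
            ca[i] = [4.8, 0.0, 3.5 * (n - 1 - i)]
    ca[-1] = ca[0] + target_termini_d * _unit(ca[-2] - ca[0])
    return _model_from_ca(ca, sequence, entry_id, resolution=resolution)


def make_compact_bundle(
    n: int,
    target_termini_d: float = 6.3,
    seed: int = 0,
    sequence: Optional[str] = None,
    entry_id: str = "BDL1",
    resolution: Optional[float] = 1.0,
    bfactor: float = 20.0,
) -> StructureModel:
    """Compact serpentine Cα trace with the terminal Cα distance planted exactly.

    Residues traverse a cubic grid (3.8 Å spacing) boustrophedon, giving a
    globular envelope; interior positions receive a small seeded jitter and
    the final Cα is placed exactly ``target_termini_d`` from the first.
    """
    if n < 8:
        raise ValueError("bundle needs at least 8 residues")
    if target_termini_d < 3.8:
        raise ValueError("target termini distance below a single Cα–Cα step")
    sequence = sequence or "A" * n
    k = max(2, math.ceil(n ** (1.0 / 3.0)))
    spacing = 3.8
    ca = np.zeros((n, 3))
    idx = 0
    for iz in range(k):
        for iy_raw in range(k):
            iy = iy_raw if iz % 2 == 0 else k - 1 - iy_raw
            for ix_raw in range(k):
                ix = ix_raw if iy_raw % 2 == 0 else k - 1 - ix_raw
                if idx < n:
                    ca[idx] = [ix * spacing, iy * spacing, iz * spacing]
                    idx += 1
    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, 0.05, size=(n, 3))
    jitter[0] = jitter[-1] = 0.0
    ca += jitter
    direction = _unit(ca[-2] - ca[0])
    if np.linalg.norm(ca[-2] - ca[0]) < 1e-6:
        direction = _unit(np.array([1.0, 1.0, 1.0]))
    ca[-1] = ca[0] + target_termini_d * direction
    feasible_reach = (n - 1) * spacing
    if target_termini_d > feasible_reach:
        raise ValueError(
            f"termini distance {target_termini_d} infeasible for {n} residues"
        )
    return _model_from_ca(ca, sequence, entry_id, resolution=resolution, bfactor=bfactor)


# ---------------------------------------------------------------------------
# In-place planting operations (all return the model for chaining)

def plant_disulfide(
    model: StructureModel,
    chain_id: str,
    res_i: int,
    res_j: int,
    sg_distance: float = 2.04,
) -> StructureModel:
    """Turn two residues into cysteines with SG atoms ``sg_distance`` apart."""
    chain = model.get_chain(chain_id)
    ri = chain.residue_by_author_seq(res_i)
    rj = chain.residue_by_author_seq(res_j)
    if ri is None or rj is None:
        raise KeyError(f"residues {res_i}/{res_j} not found in chain {chain_id}")
    ca_i, ca_j = ri.get_atom("CA"), rj.get_atom("CA")
    assert ca_i is not None and ca_j is not None
    direction = _unit(ca_j.xyz - ca_i.xyz)
    sg_i = ca_i.xyz + 1.8 * direction
    sg_j = sg_i + sg_distance * direction
    for res, sg in ((ri, sg_i), (rj, sg_j)):
        res.name3 = "CYS"
        existing = res.get_atom("SG")
        if existing is not None:
            existing.xyz = sg
        else:
            res.atoms.append(Atom("SG", "S", sg, 1.0, 20.0))
    return model


_LIGAND_ELEMENT = {"SO4": "S", "PO4": "P", "GOL": "C", "NO3": "N", "CD": "CD", "ZN": "ZN"}


def add_het_ligand(
    model: StructureModel,
    code: str,
    xyz: Optional[np.ndarray] = None,
    chain_id: Optional[str] = None,
) -> StructureModel:
    """Append a single-atom het residue with the given code."""
    chain = model.get_chain(chain_id) if chain_id else model.chains[0]
    if xyz is None:
        coords = np.array([a.xyz for _, a in chain.iter_atoms()])
        xyz = coords.mean(axis=0) + np.array([np.ptp(coords[:, 0]) + 15.0, 0.0, 0.0])
    number = 900 + len(chain.het_residues)
    element = _LIGAND_ELEMENT.get(code.upper(), "C")
    atom_name = element if len(element) > 1 else f"{element}1"
    chain.het_residues.append(
        Residue(
            name3=code.upper(),
            author_seq=number,
            is_polymer=False,
            atoms=[Atom(atom_name, element, np.asarray(xyz, float), 1.0, 30.0)],
        )
    )
    return model


def add_waters(model: StructureModel, n: int, seed: int = 0) -> StructureModel:
    """Scatter n water molecules around the first chain."""
    chain = model.chains[0]
    rng = np.random.default_rng(seed)
    coords = np.array([a.xyz for _, a in chain.iter_atoms()])
    center, span = coords.mean(axis=0), np.ptp(coords, axis=0) + 10.0
    for i in range(n):
        xyz = center + rng.uniform(-0.5, 0.5, 3) * span
        chain.het_residues.append(
            Residue("HOH", 500 + i, is_polymer=False,
                    atoms=[Atom("O", "O", xyz, 1.0, 40.0)])
        )
    return model


def perturb(model: StructureModel, sigma: float, seed: int = 0) -> StructureModel:
    """Add i.i.d. Gaussian noise (σ in Å) to every atom coordinate."""
    rng = np.random.default_rng(seed)
    for _, _, atom in model.iter_atoms():
        atom.xyz = atom.xyz + rng.normal(0.0, sigma, 3)
    return model


def random_rotation(seed: int = 0) -> np.ndarray:
    """Uniform random proper rotation matrix from a normalized quaternion."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def rigid_transform(
    model: StructureModel, seed: int = 0
) -> tuple[StructureModel, np.ndarray, np.ndarray]:
    """Apply a seeded random rotation + translation; returns (model, R, t)."""
    from .structure import transform_model

    rotation = random_rotation(seed)
    rng = np.random.default_rng(seed + 1)
    translation = rng.uniform(-20.0, 20.0, 3)
    return transform_model(model, rotation, translation), rotation, translation


def make_cys_cloud(
    n_cys: int, box: float = 15.0, seed: int = 0, entry_id: str = "CYS1"
) -> StructureModel:
    """n cysteines with CA+SG at random positions in a cubic box (oracle food)."""
    rng = np.random.default_rng(seed)
    residues = []
    for i in range(n_cys):
        ca = rng.uniform(0.0, box, 3)
        sg = ca + _unit(rng.normal(size=3)) * 1.8
        residues.append(
            Residue(
                "CYS", i + 1,
                atoms=[Atom("CA", "C", ca, 1.0, 20.0), Atom("SG", "S", sg, 1.0, 20.0)],
            )
        )
    chain = Chain("A", polymer_residues=residues)
    return StructureModel(
        StructureMetadata(entry_id=entry_id, method="X-RAY DIFFRACTION", resolution=1.0),
        [chain],
    )


# ---------------------------------------------------------------------------
# Screen library with per-criterion planted violations

_VIOLATIONS = ("fail_i", "fail_ii", "fail_iii", "fail_iv", "fail_v", "fail_vi")


def _make_screen_chain(kind: str, seed: int, entry_id: str) -> tuple[StructureModel, dict, list[str]]:
    planted: dict = {"kind": kind}
    fails: list[str] = []
    if kind == "pass":
        model = make_compact_bundle(121, 6.3, seed=seed, entry_id=entry_id)
        planted.update(n_residues=121, termini_d=6.3, resolution=1.0)
    elif kind == "fail_i":
        model = make_compact_bundle(450, 6.3, seed=seed, entry_id=entry_id)
        planted.update(n_residues=450, termini_d=6.3, resolution=1.0)
        fails = ["i"]
    elif kind == "fail_ii":
        model = make_compact_bundle(121, 6.3, seed=seed, entry_id=entry_id)
        plant_disulfide(model, "A", 20, 90, 2.04)
        planted.update(n_residues=121, termini_d=6.3, resolution=1.0,
                       disulfide=[20, 90], sg_distance=2.04)
        fails = ["ii"]
    elif kind == "fail_iii":
        model = make_compact_bundle(121, 6.3, seed=seed, entry_id=entry_id)
        add_het_ligand(model, "SO4")
        planted.update(n_residues=121, termini_d=6.3, resolution=1.0, ligands={"SO4": 1})
        fails = ["iii"]
    elif kind == "fail_iv":
        model = make_compact_bundle(121, 6.3, seed=seed, entry_id=entry_id, resolution=2.0)
        planted.update(n_residues=121, termini_d=6.3, resolution=2.0)
        fails = ["iv"]
    elif kind == "fail_v":
        model = make_compact_bundle(121, 15.0, seed=seed, entry_id=entry_id)
        planted.update(n_residues=121, termini_d=15.0, resolution=1.0)
        fails = ["v"]
    elif kind == "fail_vi":
        model = make_hairpin(121, 6.3, seed=seed, entry_id=entry_id)
        planted.update(n_residues=121, termini_d=6.3, resolution=1.0, shape="hairpin")
        fails = ["vi"]
    else:
        raise ValueError(f"unknown screen-library chain kind {kind!r}")
    return model, planted, fails


def make_screen_library(
    spec: dict[str, int], seed: int, out_dir: Optional[str | Path] = None
) -> tuple[list[StructureModel], FixtureManifest, list[Path]]:
    """Generate a library of chains violating exactly the requested criteria.

    ``spec`` maps kinds (``"pass"``, ``"fail_i"`` … ``"fail_vi"``) to counts.
    When ``out_dir`` is given, PDB files plus ``manifest.json`` are written
    there; the manifest is the oracle for screening tests.
    """
    if not spec or sum(spec.values()) == 0:
        raise ValueError("screen-library spec is empty")
    unknown = set(spec) - ({"pass"} | set(_VIOLATIONS))
    if unknown:
        raise ValueError(f"unknown spec keys: {sorted(unknown)}")
    manifest = FixtureManifest(seed=seed)
    models: list[StructureModel] = []
    paths: list[Path] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    index = 0
    for kind in ("pass",) + _VIOLATIONS:
        for _ in range(spec.get(kind, 0)):
            entry_id = f"FX{index:02d}"
            model, planted, fails = _make_screen_chain(kind, seed + index, entry_id)
            filename = f"{entry_id.lower()}.pdb"
            manifest.entries.append(
                FixtureEntry(
                    filename=filename,
                    entry_id=entry_id,
                    chain_id="A",
                    n_residues=planted["n_residues"],
                    planted=planted,
                    expected_fail=fails,
                    expected_pass=not fails,
                )
            )
            models.append(model)
            if out is not None:
                path = out / filename
                write_pdb(model, path)
                paths.append(path)
            index += 1
    if out is not None:
        manifest.write(out / "manifest.json")
    return models, manifest, paths


# ---------------------------------------------------------------------------
# Synthetic sequences with the numbering spans used in the worked examples

def synthetic_target_sequence(start: int, end: int, seed: int = 0) -> str:
    """Random protein sequence spanning author numbers start..end (synthetic
    stand-in for a real deposited sequence; only the numbering span and
    length are meaningful)."""
    rng = np.random.default_rng(seed)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    n = end - start + 1
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def synthetic_tag_sequence(
    range_start: int = 3, range_end: int = 123, lysine_sites: tuple[int, ...] = (94, 96), seed: int = 1
) -> str:
    """Synthetic carrier-tag sequence for the given author range, with
    lysines planted at the requested author positions (so that SER-style
    mutations such as K94A validate)."""
    seq = list(synthetic_target_sequence(range_start, range_end, seed))
    for site in lysine_sites:
        seq[site - range_start] = "K"
    return "".join(seq)
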