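"""Per-chain structural descriptors consumed by tag screening.

Implements the measurable side of the screening criteria: chain length and
mass (i), disulfide bonds (ii), ligand census (iii), resolution is carried
from metadata (iv), N/C-termini Cα proximity (v), and a compactness ratio
standing in for globularity (vi), plus the secondary observables (B-factor
statistics, surface charge distribution) and surface-entropy-reduction
candidate sites.

Solvent accessibility uses Shrake–Rupley point sampling on a deterministic
golden-spiral sphere; relative per-residue accessibility is taken against
fixed theoretical maxima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from ._data import (
    ACIDIC_RESIDUES,
    AVG_AA_MASS,
    BASIC_RESIDUES,
    DEFAULT_MAX_SASA,
    DEFAULT_VDW_RADIUS,
    MAX_SASA,
    MODIFIED_PARENT,
    UNKNOWN_AA_MASS,
    VDW_RADII,
    WATER_MASS,
)
from .structure import Atom, Chain, Residue, StructureModel, polymer_sequence

ResidueKey = tuple[str, int, str]  # (chain_id, author_seq, icode)


def _residue_key(chain_id: str, res: Residue) -> ResidueKey:
    return (chain_id, res.author_seq, res.icode)


# ---------------------------------------------------------------------------
# Criterion (ii): disulfide bonds

def detect_disulfides(
    model: StructureModel, sg_sg_max: float = 2.5
) -> list[tuple[ResidueKey, ResidueKey]]:
    """Find disulfide bonds as CYS SG–SG contacts within ``sg_sg_max`` Å.

    Pairing is greedy nearest-first and each cysteine participates in at
    most one bond.  Pairs are unordered and reported once, sorted by
    residue key for determinism.
    """
    sg: list[tuple[ResidueKey, np.ndarray]] = []
    for chain in model.chains:
        for res in chain.polymer_residues:
            if MODIFIED_PARENT.get(res.name3, res.name3) != "CYS":
                continue
            atom = res.get_atom("SG")
            if atom is not None:
                sg.append((_residue_key(chain.chain_id, res), atom.xyz))
    candidates = []
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            d = float(np.linalg.norm(sg[i][1] - sg[j][1]))
            if d <= sg_sg_max:
                candidates.append((d, sg[i][0], sg[j][0]))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used: set[ResidueKey] = set()
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    for _, a, b in candidates:
        if a in used or b in used:
            continue
        used.update((a, b))
        pairs.append(tuple(sorted((a, b))))  # type: ignore[arg-type]
    pairs.sort()
    return pairs


# ---------------------------------------------------------------------------
# Criterion (iii): ligands

def ligand_census(
    model: StructureModel, ignore: frozenset[str] | set[str] = frozenset()
) -> dict[str, int]:
    """Count het residue instances per code; waters never count.

    ``ignore`` removes codes (e.g. cryoprotectants) from the census.
    """
    counts: dict[str, int] = {}
    for chain in model.chains:
        for res in chain.het_residues:
            if res.name3 in ignore or _is_water(res):
                continue
            counts[res.name3] = counts.get(res.name3, 0) + 1
    return counts


def _is_water(res: Residue) -> bool:
    return res.name3 in ("HOH", "DOD", "WAT")


# ---------------------------------------------------------------------------
# Criterion (v): termini proximity

def _termini_info(chain: Chain) -> tuple[float, bool]:
    polymer = chain.polymer_residues
    with_ca = [r for r in polymer if r.get_atom("CA") is not None]
    if len(polymer) < 2 or len(with_ca) < 2:
        raise ValueError(
            f"chain {chain.chain_id}: need at least two residues with Cα atoms"
        )
    resolved = polymer[0].get_atom("CA") is not None and polymer[-1].get_atom("CA") is not None
    n_ca = with_ca[0].get_atom("CA")
    c_ca = with_ca[-1].get_atom("CA")
    assert n_ca is not None and c_ca is not None
    return float(np.linalg.norm(n_ca.xyz - c_ca.xyz)), resolved


def termini_ca_distance(chain: Chain) -> float:
    """Cα–Cα distance (Å) between the first and last resolved residues.

    If a terminal residue lacks a Cα the walk moves inward to the nearest
    residue that has one (``describe_chain`` flags this case).
    """
    return _termini_info(chain)[0]


# ---------------------------------------------------------------------------
# Criterion (vi): compactness

def radius_of_gyration(chain: Chain) -> float:
    """Unweighted radius of gyration (Å) over the chain's heavy atoms."""
    coords = np.array(
        [a.xyz for _, a in chain.iter_atoms(het=False) if a.element not in ("H", "D")]
    )
    if len(coords) < 3:
        raise ValueError(f"chain {chain.chain_id}: need ≥3 heavy atoms for Rg")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


def globularity(chain: Chain) -> float:
    """Compactness ratio Rg_obs / Rg_ref with Rg_ref = 2.2·N^0.38 Å.

    The reference is the empirical scaling of globular proteins with chain
    length N; ratios near or below 1 indicate a compact globular fold,
    larger values an extended or elongated shape.
    """
    n = len(chain.polymer_residues)
    if n < 1:
        raise ValueError(f"chain {chain.chain_id}: empty chain")
    return radius_of_gyration(chain) / (2.2 * n**0.38)


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake–Rupley)

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(
    coords: np.ndarray, radii: np.ndarray, probe: float = 1.4, n_points: int = 960
) -> np.ndarray:
    """Per-atom solvent-accessible area (Å²) by point sampling.

    For each atom, ``n_points`` quasi-uniform points on its probe-inflated
    sphere are tested for occlusion by neighbouring spheres; the accessible
    fraction scales the analytic sphere area.
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float) + probe
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * accessible.sum() / n_points
    return areas


@dataclass
class SasaResult:
    """Per-atom accessibility with the atom references it was computed over."""

    atoms: list[tuple[str, Residue, Atom]]  # (chain_id, residue, atom)
    areas: np.ndarray

    @property
    def total(self) -> float:
        return float(self.areas.sum())

    def per_residue(self) -> dict[ResidueKey, float]:
        out: dict[ResidueKey, float] = {}
        for (chain_id, res, _), area in zip(self.atoms, self.areas):
            key = _residue_key(chain_id, res)
            out[key] = out.get(key, 0.0) + float(area)
        return out

    def relative_per_residue(self) -> dict[ResidueKey, float]:
        """Per-residue SASA divided by the fixed per-residue maximum."""
        names = {}
        for chain_id, res, _ in self.atoms:
            names[_residue_key(chain_id, res)] = res.name3
        return {
            key: area / MAX_SASA.get(MODIFIED_PARENT.get(names[key], names[key]), DEFAULT_MAX_SASA)
            for key, area in self.per_residue().items()
        }


def sasa(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    include_het: bool = True,
) -> SasaResult:
    """Solvent-accessible surface of the model's heavy atoms (waters excluded)."""
    refs: list[tuple[str, Residue, Atom]] = []
    for chain in model.chains:
        for res, atom in chain.iter_atoms(het=include_het):
            if atom.element in ("H", "D") or _is_water(res):
                continue
            refs.append((chain.chain_id, res, atom))
    coords = np.array([a.xyz for _, _, a in refs]) if refs else np.zeros((0, 3))
    radii = np.array([VDW_RADII.get(a.element, DEFAULT_VDW_RADIUS) for _, _, a in refs])
    return SasaResult(atoms=refs, areas=shrake_rupley(coords, radii, probe, n_points))


# ---------------------------------------------------------------------------
# Surface charge and SER candidates

def _chain_only_model(model_or_chain: Chain) -> StructureModel:
    from .structure import StructureMetadata

    return StructureModel(metadata=StructureMetadata(), chains=[model_or_chain])


def surface_charge(
    chain: Chain,
    rel_sasa_min: float = 0.25,
    probe: float = 1.4,
    n_points: int = 960,
    sasa_result: Optional[SasaResult] = None,
) -> tuple[int, int, int]:
    """Count exposed charged residues on the isolated chain.

    Returns ``(net, n_basic, n_acidic)`` where basic = {Arg, Lys, His} and
    acidic = {Asp, Glu} with relative accessibility ≥ ``rel_sasa_min``;
    net = basic − acidic.
    """
    if sasa_result is None:
        sasa_result = sasa(_chain_only_model(chain), probe=probe, n_points=n_points, include_het=False)
    rel = sasa_result.relative_per_residue()
    basic = acidic = 0
    for res in chain.polymer_residues:
        parent = MODIFIED_PARENT.get(res.name3, res.name3)
        exposure = rel.get(_residue_key(chain.chain_id, res), 0.0)
        if exposure < rel_sasa_min:
            continue
        if parent in BASIC_RESIDUES:
            basic += 1
        elif parent in ACIDIC_RESIDUES:
            acidic += 1
    return basic - acidic, basic, acidic


# Suggested surface-entropy-reduction substitutions per residue type.
SER_SUBSTITUTIONS = {"LYS": ("A", "S"), "GLU": ("A",), "GLN": ("A",)}


@dataclass
class SerCandidate:
    author_seq: int
    name3: str
    rel_sasa: float
    suggestions: tuple[str, ...]  # e.g. ("K94A", "K94S")


def ser_candidates(
    chain: Chain,
    rel_sasa_min: float = 0.25,
    max_gap: int = 2,
    probe: float = 1.4,
    n_points: int = 960,
    sasa_result: Optional[SasaResult] = None,
) -> list[list[SerCandidate]]:
    """Surface-entropy-reduction candidate sites, grouped into clusters.

    Candidates are exposed Lys/Glu/Gln residues (relative SASA ≥ threshold);
    clusters are runs of candidates whose author numbers differ by at most
    ``max_gap``.  Each candidate carries the suggested substitutions
    (Lys→Ala/Ser, Glu→Ala, Gln→Ala) in mutation notation.
    """
    if sasa_result is None:
        sasa_result = sasa(_chain_only_model(chain), probe=probe, n_points=n_points, include_het=False)
    rel = sasa_result.relative_per_residue()
    from .structure import residue_one_letter

    singles: list[SerCandidate] = []
    for res in chain.polymer_residues:
        parent = MODIFIED_PARENT.get(res.name3, res.name3)
        if parent not in SER_SUBSTITUTIONS:
            continue
        exposure = rel.get(_residue_key(chain.chain_id, res), 0.0)
        if exposure < rel_sasa_min:
            continue
        letter = residue_one_letter(res.name3)
        singles.append(
            SerCandidate(
                author_seq=res.author_seq,
                name3=res.name3,
                rel_sasa=exposure,
                suggestions=tuple(
                    f"{letter}{res.author_seq}{sub}" for sub in SER_SUBSTITUTIONS[parent]
                ),
            )
        )
    clusters: list[list[SerCandidate]] = []
    for cand in singles:
        if clusters and cand.author_seq - clusters[-1][-1].author_seq <= max_gap:
            clusters[-1].append(cand)
        else:
            clusters.append([cand])
    return clusters


# ---------------------------------------------------------------------------
# Aggregate descriptor

@dataclass
class ChainDescriptor:
    """All per-chain quantities that the screening criteria consume."""

    entry_id: str
    chain_id: str
    length: int
    mw: float
    method: str
    resolution: Optional[float]
    n_disulfides: int
    ligands: dict[str, int]
    termini_ca_distance: float
    termini_resolved: bool
    rg: float
    globularity: float
    bfactor_mean: float
    bfactor_sd: float
    net_surface_charge: int
    exposed_basic: int
    exposed_acidic: int

    @property
    def n_ligands(self) -> int:
        return sum(self.ligands.values())


def sequence_mw(sequence: str) -> float:
    """Average peptide mass (Da): residue masses minus one water per bond."""
    if not sequence:
        return 0.0
    total = sum(AVG_AA_MASS.get(aa, UNKNOWN_AA_MASS) for aa in sequence)
    return total - (len(sequence) - 1) * WATER_MASS


def describe_chain(
    model: StructureModel,
    chain_id: str,
    rel_sasa_min: float = 0.25,
    probe: float = 1.4,
    n_points: int = 960,
    ligand_ignore: frozenset[str] | set[str] = frozenset(),
) -> ChainDescriptor:
    """Compute the full :class:`ChainDescriptor` for one polymer chain.

    Disulfide and ligand counts are taken over the whole entry (a ligand
    anywhere in the deposited file disqualifies it as a clean tag source),
    while geometry, B-factors and surface charge are chain-local.
    """
    chain = model.get_chain(chain_id)
    seq = polymer_sequence(chain)
    dist, resolved = _termini_info(chain)
    bfactors = np.array(
        [a.bfactor for _, a in chain.iter_atoms(het=False) if a.element not in ("H", "D")]
    )
    disulfides = detect_disulfides(model)
    n_ss = sum(1 for a, b in disulfides if a[0] == chain_id or b[0] == chain_id)
    net, basic, acidic = surface_charge(chain, rel_sasa_min, probe, n_points)
    return ChainDescriptor(
        entry_id=model.metadata.entry_id,
        chain_id=chain_id,
        length=len(seq),
        mw=sequence_mw(seq),
        method=model.metadata.method,
        resolution=model.metadata.resolution,
        n_disulfides=n_ss,
        ligands=ligand_census(model, ignore=ligand_ignore),
        termini_ca_distance=dist,
        termini_resolved=resolved,
        rg=radius_of_gyration(chain),
        globularity=globularity(chain),
        bfactor_mean=float(bfactors.mean()) if len(bfactors) else 0.0,
        bfactor_sd=float(bfactors.std()) if len(bfactors) else 0.0,
        net_surface_charge=net,
        exposed_basic=basic,
        exposed_acidic=acidic,
    )
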