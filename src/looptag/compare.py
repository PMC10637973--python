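"""Superposition, sequence identity, and protein–protein interface census.

Rigid-body superposition is the closed-form least-squares (Kabsch) rotation
constrained to det(R) = +1, with sequence-guided Cα matching and iterative
outlier rejection so that the reported RMSD reflects the conserved core
("over n atoms out of m" style).  Sequence identity is a BLOSUM62 global
alignment with affine gaps; the identity denominator is the number of
aligned non-gap pairs (convention-sensitive and therefore configurable).

The interface census reports buried surface area (total over both partners
by default), hydrogen bonds (geometric donor/acceptor criterion,
distance-only when hydrogens are absent, the usual case for crystal
structures), and salt bridges between oppositely charged groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree

from ._data import (
    ACIDIC_ATOMS,
    BASIC_ATOMS,
    MODIFIED_PARENT,
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
)
from .descriptors import ResidueKey, sasa
from .structure import (
    Chain,
    LoopTagError,
    StructureMetadata,
    StructureModel,
    polymer_sequence,
)


class DegenerateGeometryError(LoopTagError):
    """Point sets too small or too degenerate for a unique superposition."""


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, proper (det = +1)
    translation: np.ndarray  # 3-vector, Å
    rmsd: float
    n_pairs_used: int
    n_pairs_total: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def matrix_3x4(self) -> np.ndarray:
        """Rotation and translation as the conventional 3×4 block [R | t]."""
        return np.hstack([self.rotation, self.translation.reshape(3, 1)])


def kabsch(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Optimal proper rotation + translation mapping P onto Q (least squares).

    Reflections are forbidden: the smallest singular direction is flipped
    when the raw solution would have det(R) = −1.  Requires ≥3 pairs that
    are not collinear.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matched (n, 3) arrays")
    n = len(P)
    if n < 3:
        raise DegenerateGeometryError(f"need ≥3 point pairs, got {n}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # Collinearity check: the centred set must span a plane.
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise DegenerateGeometryError("point set is collinear; rotation not unique")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs_used=n, n_pairs_total=n)


# ---------------------------------------------------------------------------
# Sequence alignment

@dataclass
class AlignmentResult:
    pairs: list[tuple[int, int]]  # aligned (index_a, index_b), 0-based
    identity_pct: float
    alignment_length: int
    n_identical: int


def sequence_align(
    a: str,
    b: str,
    mode: str = "global",
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Protein alignment; identity = identical / aligned (non-gap) pairs.

    The default is a global (Needleman–Wunsch) alignment with BLOSUM62 and
    affine gap penalties (open 10, extend 0.5).  Percent-identity figures
    are convention-sensitive, so matrix and gap parameters are exposed.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aligner.mode = "global" if mode == "global" else "local"
    alphabet = set(aligner.substitution_matrix.alphabet)
    a_clean = "".join(c if c in alphabet else "X" for c in a.upper())
    b_clean = "".join(c if c in alphabet else "X" for c in b.upper())
    alignment = aligner.align(a_clean, b_clean)[0]
    pairs: list[tuple[int, int]] = []
    n_identical = 0
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for i, j in zip(range(a_start, a_end), range(b_start, b_end)):
            pairs.append((i, j))
            if a_clean[i] == b_clean[j]:
                n_identical += 1
    identity = 100.0 * n_identical / len(pairs) if pairs else 0.0
    return AlignmentResult(
        pairs=pairs,
        identity_pct=identity,
        alignment_length=alignment.length,
        n_identical=n_identical,
    )


# ---------------------------------------------------------------------------
# Sequence-guided structural superposition with outlier rejection

def _ca_coords(chain: Chain) -> tuple[list[int], np.ndarray]:
    idx, coords = [], []
    for i, res in enumerate(chain.polymer_residues):
        ca = res.get_atom("CA")
        if ca is not None:
            idx.append(i)
            coords.append(ca.xyz)
    return idx, np.array(coords) if coords else np.zeros((0, 3))


def structure_superpose(
    chain_a: Chain,
    chain_b: Chain,
    outlier_sd: float = 2.0,
    max_iter: int = 10,
    min_reject_dist: float = 3.5,
) -> SuperpositionResult:
    """Superpose two chains on sequence-aligned Cα pairs with outlier pruning.

    After each fit, pairs deviating by more than
    ``max(outlier_sd · SD(deviations), min_reject_dist)`` are discarded and
    the fit repeated until a fixed point (or ``max_iter``).  The result
    reports the core RMSD together with used/total pair counts.
    """
    alignment = sequence_align(polymer_sequence(chain_a), polymer_sequence(chain_b))
    ca_a = {i: res.get_atom("CA") for i, res in enumerate(chain_a.polymer_residues)}
    ca_b = {i: res.get_atom("CA") for i, res in enumerate(chain_b.polymer_residues)}
    P, Q = [], []
    for i, j in alignment.pairs:
        a, b = ca_a.get(i), ca_b.get(j)
        if a is not None and b is not None:
            P.append(a.xyz)
            Q.append(b.xyz)
    P, Q = np.array(P), np.array(Q)
    n_total = len(P)
    if n_total < 3:
        raise DegenerateGeometryError(
            f"only {n_total} aligned Cα pairs; need ≥3 for superposition"
        )
    mask = np.ones(n_total, dtype=bool)
    result = kabsch(P, Q)
    for _ in range(max_iter):
        sub = kabsch(P[mask], Q[mask])
        deviations = np.linalg.norm(sub.apply(P) - Q, axis=1)
        threshold = max(outlier_sd * float(deviations[mask].std()), min_reject_dist)
        new_mask = deviations <= threshold
        if new_mask.sum() < 3:
            result = sub
            break
        if (new_mask == mask).all():
            result = sub
            break
        mask = new_mask
        result = sub
    return SuperpositionResult(
        rotation=result.rotation,
        translation=result.translation,
        rmsd=result.rmsd,
        n_pairs_used=int(mask.sum()),
        n_pairs_total=n_total,
    )


# ---------------------------------------------------------------------------
# Interface census

def _split_model(model: StructureModel, chain_ids: Sequence[str]) -> StructureModel:
    chains = [c for c in model.chains if c.chain_id in set(chain_ids)]
    if not chains:
        raise LoopTagError(f"no chains {sorted(chain_ids)} in model")
    return StructureModel(metadata=StructureMetadata(), chains=chains)


def _check_partition(model: StructureModel, group_a: Sequence[str], group_b: Sequence[str]) -> None:
    set_a, set_b = set(group_a), set(group_b)
    if not set_a or not set_b:
        raise LoopTagError("both partitions must be non-empty")
    if set_a & set_b:
        raise LoopTagError(f"partitions overlap: {sorted(set_a & set_b)}")
    missing = (set_a | set_b) - set(model.chain_ids)
    if missing:
        raise LoopTagError(f"chains not in model: {sorted(missing)}")


@dataclass
class BsaResult:
    """Buried surface area of an interface.

    ``total_buried`` is SASA(A) + SASA(B) − SASA(AB), i.e. the area lost
    over both partners; ``per_side`` (half of it) is the common
    "interface area" convention.
    """

    total_buried: float
    per_side: float
    sasa_a: float
    sasa_b: float
    sasa_complex: float


def buried_surface_area(
    model: StructureModel,
    group_a: Sequence[str],
    group_b: Sequence[str],
    probe: float = 1.4,
    n_points: int = 960,
    include_het: bool = False,
) -> BsaResult:
    """Buried surface area between two chain groups (both conventions)."""
    _check_partition(model, group_a, group_b)
    area_a = sasa(_split_model(model, group_a), probe, n_points, include_het).total
    area_b = sasa(_split_model(model, group_b), probe, n_points, include_het).total
    area_ab = sasa(
        _split_model(model, list(group_a) + list(group_b)), probe, n_points, include_het
    ).total
    total = max(0.0, area_a + area_b - area_ab)
    return BsaResult(
        total_buried=total,
        per_side=total / 2.0,
        sasa_a=area_a,
        sasa_b=area_b,
        sasa_complex=area_ab,
    )


@dataclass(frozen=True)
class Contact:
    """One cross-partition contact (donor/acceptor or charged pair)."""

    res_a: ResidueKey
    atom_a: str
    res_b: ResidueKey
    atom_b: str
    distance: float


def _polar_atoms(model: StructureModel, chain_ids: set[str], role: str):
    """Yield (residue_key, atom_name, xyz) for donors or acceptors."""
    table = SIDECHAIN_DONORS if role == "donor" else SIDECHAIN_ACCEPTORS
    for chain in model.chains:
        if chain.chain_id not in chain_ids:
            continue
        for res in chain.polymer_residues:
            parent = MODIFIED_PARENT.get(res.name3, res.name3)
            names = set(table.get(parent, ()))
            names.add("N" if role == "donor" else "O")
            if role == "acceptor":
                names.add("OXT")
            for atom in res.atoms:
                if atom.name in names:
                    yield (chain.chain_id, res.author_seq, res.icode), atom.name, atom.xyz


def _model_has_hydrogens(model: StructureModel) -> bool:
    return any(a.element in ("H", "D") for _, _, a in model.iter_atoms())


def _hydrogens_near(res_atoms, donor_xyz, max_dh: float = 1.3):
    return [a.xyz for a in res_atoms if a.element in ("H", "D")
            and np.linalg.norm(a.xyz - donor_xyz) <= max_dh]


def find_hbonds(
    model: StructureModel,
    group_a: Sequence[str],
    group_b: Sequence[str],
    d_max: float = 3.5,
    dha_min: float = 120.0,
) -> list[Contact]:
    """Cross-partition hydrogen bonds by donor–acceptor geometry.

    A bond is a donor N/O on one side and acceptor N/O on the other within
    ``d_max`` Å.  When explicit hydrogens are present the D–H…A angle must
    exceed ``dha_min``; crystal structures usually lack hydrogens, in which
    case the criterion is distance-only.  Each atom pair is reported once.
    """
    _check_partition(model, group_a, group_b)
    set_a, set_b = set(group_a), set(group_b)
    use_angles = _model_has_hydrogens(model)
    residue_atoms = {
        (c.chain_id, r.author_seq, r.icode): r.atoms
        for c in model.chains
        for r in c.polymer_residues
    }
    seen: set[tuple] = set()
    contacts: list[Contact] = []
    for donors_side, acceptors_side in ((set_a, set_b), (set_b, set_a)):
        donors = list(_polar_atoms(model, donors_side, "donor"))
        acceptors = list(_polar_atoms(model, acceptors_side, "acceptor"))
        if not donors or not acceptors:
            continue
        acc_tree = cKDTree(np.array([x for _, _, x in acceptors]))
        for d_key, d_name, d_xyz in donors:
            for j in acc_tree.query_ball_point(d_xyz, d_max):
                a_key, a_name, a_xyz = acceptors[j]
                dist = float(np.linalg.norm(d_xyz - a_xyz))
                if use_angles:
                    hs = _hydrogens_near(residue_atoms.get(d_key, []), d_xyz)
                    if hs and not _angle_ok(d_xyz, hs, a_xyz, dha_min):
                        continue
                pair_id = tuple(sorted([(d_key, d_name), (a_key, a_name)]))
                if pair_id in seen:
                    continue
                seen.add(pair_id)
                # report with the group-A atom first
                if d_key[0] in set_a:
                    contacts.append(Contact(d_key, d_name, a_key, a_name, dist))
                else:
                    contacts.append(Contact(a_key, a_name, d_key, d_name, dist))
    contacts.sort(key=lambda c: (c.res_a, c.atom_a, c.res_b, c.atom_b))
    return contacts


def _angle_ok(d_xyz, h_list, a_xyz, dha_min: float) -> bool:
    for h in h_list:
        v1 = d_xyz - h
        v2 = a_xyz - h
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle >= dha_min:
            return True
    return False


def _charged_atoms(model: StructureModel, chain_ids: set[str], sign: str):
    table = BASIC_ATOMS if sign == "basic" else ACIDIC_ATOMS
    for chain in model.chains:
        if chain.chain_id not in chain_ids:
            continue
        polymer = chain.polymer_residues
        for i, res in enumerate(polymer):
            parent = MODIFIED_PARENT.get(res.name3, res.name3)
            names = set(table.get(parent, ()))
            # chain termini carry formal charges
            if sign == "basic" and i == 0:
                names.add("N")
            if sign == "acidic" and i == len(polymer) - 1:
                names.add("OXT")
            for atom in res.atoms:
                if atom.name in names:
                    yield (chain.chain_id, res.author_seq, res.icode), atom.name, atom.xyz


@dataclass(frozen=True)
class SaltBridge:
    basic_res: ResidueKey
    acidic_res: ResidueKey
    min_distance: float


def find_salt_bridges(
    model: StructureModel,
    group_a: Sequence[str],
    group_b: Sequence[str],
    d_max: float = 4.0,
) -> list[SaltBridge]:
    """Cross-partition salt bridges: unique (basic, acidic) residue pairs
    with any charged-atom distance ≤ ``d_max`` Å.

    Charged groups are Arg NE/NH1/NH2, Lys NZ, His ND1/NE2 versus Asp
    OD1/OD2, Glu OE1/OE2, plus the chain termini (N-terminal amine,
    C-terminal carboxylate OXT).  Like-charge contacts never count.
    """
    _check_partition(model, group_a, group_b)
    set_a, set_b = set(group_a), set(group_b)
    best: dict[tuple[ResidueKey, ResidueKey], float] = {}
    for basic_side, acidic_side in ((set_a, set_b), (set_b, set_a)):
        basics = list(_charged_atoms(model, basic_side, "basic"))
        acidics = list(_charged_atoms(model, acidic_side, "acidic"))
        if not basics or not acidics:
            continue
        tree = cKDTree(np.array([x for _, _, x in acidics]))
        for b_key, _, b_xyz in basics:
            for j in tree.query_ball_point(b_xyz, d_max):
                a_key, _, a_xyz = acidics[j]
                dist = float(np.linalg.norm(b_xyz - a_xyz))
                pair = (b_key, a_key)
                if pair not in best or dist < best[pair]:
                    best[pair] = dist
    bridges = [SaltBridge(b, a, d) for (b, a), d in best.items()]
    bridges.sort(key=lambda s: (s.basic_res, s.acidic_res))
    return bridges


@dataclass
class InterfaceReport:
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    bsa: BsaResult
    hbonds: list[Contact]
    salt_bridges: list[SaltBridge]

    def to_record(self) -> dict:
        return {
            "partners": {"A": list(self.group_a), "B": list(self.group_b)},
            "bsa_total_A2": round(self.bsa.total_buried, 1),
            "bsa_per_side_A2": round(self.bsa.per_side, 1),
            "n_hbonds": len(self.hbonds),
            "n_salt_bridges": len(self.salt_bridges),
            "hbonds": [
                {
                    "a": f"{c.res_a[0]}/{c.res_a[1]}{c.res_a[2]}/{c.atom_a}",
                    "b": f"{c.res_b[0]}/{c.res_b[1]}{c.res_b[2]}/{c.atom_b}",
                    "distance_A": round(c.distance, 2),
                }
                for c in self.hbonds
            ],
            "salt_bridges": [
                {
                    "basic": f"{s.basic_res[0]}/{s.basic_res[1]}{s.basic_res[2]}",
                    "acidic": f"{s.acidic_res[0]}/{s.acidic_res[1]}{s.acidic_res[2]}",
                    "min_distance_A": round(s.min_distance, 2),
                }
                for s in self.salt_bridges
            ],
        }


def interface_report(
    model: StructureModel,
    group_a: Sequence[str],
    group_b: Sequence[str],
    hbond_d_max: float = 3.5,
    salt_d_max: float = 4.0,
    sasa_points: int = 960,
) -> InterfaceReport:
    """Full interface census between two chain groups of one model."""
    return InterfaceReport(
        group_a=tuple(group_a),
        group_b=tuple(group_b),
        bsa=buried_surface_area(model, group_a, group_b, n_points=sasa_points),
        hbonds=find_hbonds(model, group_a, group_b, d_max=hbond_d_max),
        salt_bridges=find_salt_bridges(model, group_a, group_b, d_max=salt_d_max),
    )
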