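"""Fusion-construct design with full segment provenance.

Builds chimeric sequences in which an internal flexible insertion of a
target protein is replaced by a compact carrier tag (optionally flanked by
linkers), validates the geometric compatibility of the tag with the
insertion site, applies point mutations in author numbering, and records
the provenance of every emitted segment.

All positions are author/isoform numbering (the numbering printed on
mutations like K94A), converted internally via an explicit offset; there is
no silent renumbering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._data import VALID_AA1
from .descriptors import sequence_mw
from .structure import LoopTagError, StructureModel

# Human ubiquitin, residues 1-76 (invariant across vertebrates).
UBIQUITIN_1_76 = (
    "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQKESTLHLVLRLRGG"
)

MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")

# Per-residue reach of a flexible linker, Å (near-extended backbone).
LINKER_REACH_PER_RESIDUE = 3.5


class MutationError(LoopTagError):
    """A point mutation does not match the sequence it is applied to."""


class AnchorError(LoopTagError):
    """An insertion-site anchor residue is missing or mis-ordered."""


@dataclass(frozen=True)
class Segment:
    """Provenance of one contiguous block of a designed sequence."""

    source: str  # e.g. "USP11", "RDFrzS", "linker"
    start: int  # author number of first residue (1 for linkers)
    end: int  # author number of last residue
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class InsertionSpec:
    """Target protein and the insertion to excise.

    ``offset`` is the author number of ``sequence[0]``; ``n_anchor`` is the
    last retained residue N-terminal of the insertion and ``c_anchor`` the
    first retained residue C-terminal of it.
    """

    name: str
    sequence: str
    offset: int
    n_anchor: int
    c_anchor: int
    n_linker: str = ""
    c_linker: str = ""

    def __post_init__(self) -> None:
        if self.n_anchor >= self.c_anchor:
            raise AnchorError(
                f"n_anchor {self.n_anchor} must precede c_anchor {self.c_anchor}"
            )
        last = self.offset + len(self.sequence) - 1
        for anchor in (self.n_anchor, self.c_anchor):
            if not self.offset <= anchor <= last:
                raise AnchorError(
                    f"anchor {anchor} outside sequence range {self.offset}-{last}"
                )

    @property
    def replaced_length(self) -> int:
        """Number of residues excised (exclusive of both anchors)."""
        return self.c_anchor - self.n_anchor - 1


@dataclass
class TagSpec:
    """Carrier tag: sequence of the used residue range plus its geometry."""

    name: str
    sequence: str
    range_start: int
    range_end: int
    termini_ca_distance: Optional[float] = None
    mutations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = self.range_end - self.range_start + 1
        if len(self.sequence) != expected:
            raise ValueError(
                f"tag {self.name}: sequence length {len(self.sequence)} does not match "
                f"range {self.range_start}-{self.range_end} ({expected} residues)"
            )

    def mutated_sequence(self) -> tuple[str, list[str]]:
        return apply_point_mutations(self.sequence, self.range_start, self.mutations)


@dataclass
class FusionConstruct:
    """A designed chimera: final sequence plus per-segment provenance."""

    name: str
    sequence: str
    segments: list[Segment]
    mutation_log: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        joined = "".join(s.sequence for s in self.segments)
        if joined != self.sequence:
            raise ValueError(f"{self.name}: segments do not concatenate to the sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def mw(self) -> float:
        return sequence_mw(self.sequence)

    def to_record(self) -> dict:
        return {
            "name": self.name,
            "length": self.length,
            "mw_da": round(self.mw, 1),
            "sequence": self.sequence,
            "segments": [
                {"source": s.source, "start": s.start, "end": s.end, "length": len(s)}
                for s in self.segments
            ],
            "mutations": self.mutation_log,
            "notes": self.notes,
        }


# ---------------------------------------------------------------------------

def anchor_distance(
    structure: StructureModel, chain_id: str, n_anchor: int, c_anchor: int
) -> float:
    """Cα–Cα distance (Å) between the two insertion-site anchor residues."""
    chain = structure.get_chain(chain_id)
    coords = []
    for anchor in (n_anchor, c_anchor):
        res = chain.residue_by_author_seq(anchor)
        if res is None:
            raise AnchorError(f"anchor residue {anchor} not resolved in chain {chain_id}")
        ca = res.get_atom("CA")
        if ca is None:
            raise AnchorError(f"anchor residue {res.label} in chain {chain_id} has no Cα")
        coords.append(ca.xyz)
    return float(np.linalg.norm(coords[0] - coords[1]))


@dataclass(frozen=True)
class CompatibilityVerdict:
    passed: bool
    slack: float  # Å of remaining reach; negative when incompatible
    anchor_distance: float
    tag_termini_distance: float
    linker_residues: int


def compatibility(
    anchor_d: float,
    tag_termini_d: float,
    tolerance: float = 4.0,
    linker_residues: int = 0,
) -> CompatibilityVerdict:
    """Geometric fit of a tag between two anchors.

    The gap the tag must bridge is compatible when
    ``|anchor_d − tag_termini_d| ≤ tolerance + 3.5·linker_residues``;
    the reported slack is the remaining margin in Å.
    """
    if anchor_d < 0 or tag_termini_d < 0:
        raise ValueError("distances must be non-negative")
    budget = tolerance + LINKER_REACH_PER_RESIDUE * linker_residues
    mismatch = abs(anchor_d - tag_termini_d)
    return CompatibilityVerdict(
        passed=mismatch <= budget,
        slack=budget - mismatch,
        anchor_distance=anchor_d,
        tag_termini_distance=tag_termini_d,
        linker_residues=linker_residues,
    )


def apply_point_mutations(
    sequence: str, numbering_offset: int, mutations: list[str]
) -> tuple[str, list[str]]:
    """Apply ``X<pos>Y`` point mutations in author numbering.

    ``numbering_offset`` is the author number of ``sequence[0]``.  The
    wild-type letter of every mutation must match the sequence at its
    position — a mismatch raises :class:`MutationError` naming expected vs
    found, which guards against off-by-one numbering mistakes.
    """
    seq = list(sequence)
    log: list[str] = []
    for mut in mutations:
        m = MUTATION_RE.match(mut.strip().upper())
        if not m:
            raise MutationError(f"malformed mutation {mut!r} (expected e.g. K94A)")
        wt, pos, new = m.group(1), int(m.group(2)), m.group(3)
        idx = pos - numbering_offset
        if not 0 <= idx < len(seq):
            raise MutationError(
                f"mutation {mut}: position {pos} outside range "
                f"{numbering_offset}-{numbering_offset + len(seq) - 1}"
            )
        if seq[idx] != wt:
            raise MutationError(
                f"mutation {mut}: expected {wt} at position {pos}, found {seq[idx]}"
            )
        seq[idx] = new
        log.append(mut.strip().upper())
    return "".join(seq), log


def _slice_author(sequence: str, offset: int, start: int, end: int) -> str:
    return sequence[start - offset : end - offset + 1]


def build_fusion(spec: InsertionSpec, tag: Optional[TagSpec], name: str = "") -> FusionConstruct:
    """Assemble target[N…n_anchor] + linker + tag + linker + target[c_anchor…C].

    ``tag=None`` (with empty linkers and ``c_anchor == n_anchor + 1``)
    reproduces the contiguous target; a linker with no tag models a simple
    deletion construct.  Length conservation over the provenance segments is
    asserted at construction.
    """
    last = spec.offset + len(spec.sequence) - 1
    segments: list[Segment] = [
        Segment(spec.name, spec.offset, spec.n_anchor,
                _slice_author(spec.sequence, spec.offset, spec.offset, spec.n_anchor))
    ]
    mutation_log: list[str] = []
    notes: list[str] = [
        f"replaces {spec.replaced_length} residues "
        f"({spec.n_anchor + 1}-{spec.c_anchor - 1}, exclusive of anchors)"
    ]
    if spec.n_linker:
        segments.append(Segment("linker", 1, len(spec.n_linker), spec.n_linker))
    if tag is not None:
        tag_seq, mutation_log = tag.mutated_sequence()
        segments.append(Segment(tag.name, tag.range_start, tag.range_end, tag_seq))
    if spec.c_linker:
        segments.append(Segment("linker", 1, len(spec.c_linker), spec.c_linker))
    segments.append(
        Segment(spec.name, spec.c_anchor, last,
                _slice_author(spec.sequence, spec.offset, spec.c_anchor, last))
    )
    segments = [s for s in segments if len(s) > 0]
    construct = FusionConstruct(
        name=name or f"{spec.name}-{tag.name if tag else 'del'}",
        sequence="".join(s.sequence for s in segments),
        segments=segments,
        mutation_log=mutation_log,
        notes=notes,
    )
    assert construct.length == sum(len(s) for s in construct.segments)
    return construct


def c_terminal_extension(
    base_sequence: str, extension: str, name: str = "", base_name: str = "base"
) -> FusionConstruct:
    """Extend a sequence C-terminally (e.g. ubiquitin 1–76 + "GGG").

    An empty extension is the identity; non-amino-acid letters in the
    extension are rejected.
    """
    bad = set(extension) - VALID_AA1
    if bad:
        raise ValueError(f"extension contains non-amino-acid characters: {sorted(bad)}")
    segments = [Segment(base_name, 1, len(base_sequence), base_sequence)]
    if extension:
        segments.append(Segment("extension", 1, len(extension), extension))
    return FusionConstruct(
        name=name or (f"{base_name}-{extension}" if extension else base_name),
        sequence=base_sequence + extension,
        segments=segments,
    )
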