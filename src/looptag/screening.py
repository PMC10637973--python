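"""Hard-criteria screening and soft ranking of insertion-tag candidates.

A candidate chain passes when it satisfies all six hard criteria:

(i)   size strictly below the length cap (default 400 residues),
(ii)  no disulfide bonds,
(iii) no non-water ligands,
(iv)  X-ray structure at resolution strictly better than the cap (1.6 Å),
(v)   N/C-termini Cα distance within the cap (10 Å, inclusive),
(vi)  globular compactness ratio within the cap (1.25, inclusive).

Passing candidates are ordered by a heuristic soft score over the secondary
observables (B-factors, surface charge balance, compactness); the score has
no literature definition and every weight is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .descriptors import ChainDescriptor, describe_chain
from .structure import LoopTagError, StructureModel, read_structure, resolve_altlocs

logger = logging.getLogger(__name__)

CRITERION_IDS = ("i", "ii", "iii", "iv", "v", "vi")
CRITERION_LABELS = {
    "i": "size",
    "ii": "disulfides",
    "iii": "ligands",
    "iv": "resolution",
    "v": "termini_distance",
    "vi": "globularity",
}


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds for the six hard screening criteria."""

    max_length: int = 400
    max_resolution: float = 1.6
    require_xray: bool = True
    forbid_disulfides: bool = True
    forbid_ligands: bool = True
    max_termini_distance: float = 10.0
    max_globularity: float = 1.25

    def __post_init__(self) -> None:
        for name in ("max_length", "max_resolution", "max_termini_distance", "max_globularity"):
            if not getattr(self, name) > 0:
                raise ValueError(f"criteria.{name} must be positive")


@dataclass(frozen=True)
class Verdict:
    criterion: str  # "i" .. "vi"
    passed: bool
    measured: object
    threshold: object


@dataclass
class CandidateReport:
    source_id: str
    chain_id: str
    verdicts: dict[str, Verdict]
    overall_pass: bool
    descriptor: ChainDescriptor
    soft_score: Optional[float] = None

    @property
    def failed_criteria(self) -> list[str]:
        return [cid for cid in CRITERION_IDS if not self.verdicts[cid].passed]


def _is_xray(method: str) -> bool:
    return "X-RAY" in method.upper().replace(" ", "-")


def evaluate_candidate(descriptor: ChainDescriptor, criteria: ScreenCriteria) -> CandidateReport:
    """Apply the six hard criteria to one chain descriptor.

    Size and resolution are strict ``<`` comparisons; the termini-distance
    and globularity caps are inclusive.  A missing resolution fails (iv).
    """
    d = descriptor
    resolution_ok = d.resolution is not None and d.resolution < criteria.max_resolution
    if criteria.require_xray:
        resolution_ok = resolution_ok and _is_xray(d.method)
    verdicts = {
        "i": Verdict("i", d.length < criteria.max_length, d.length, criteria.max_length),
        "ii": Verdict(
            "ii",
            (not criteria.forbid_disulfides) or d.n_disulfides == 0,
            d.n_disulfides,
            0,
        ),
        "iii": Verdict(
            "iii",
            (not criteria.forbid_ligands) or d.n_ligands == 0,
            d.n_ligands,
            0,
        ),
        "iv": Verdict("iv", resolution_ok, d.resolution, criteria.max_resolution),
        "v": Verdict(
            "v",
            d.termini_ca_distance <= criteria.max_termini_distance,
            d.termini_ca_distance,
            criteria.max_termini_distance,
        ),
        "vi": Verdict(
            "vi",
            d.globularity <= criteria.max_globularity,
            d.globularity,
            criteria.max_globularity,
        ),
    }
    return CandidateReport(
        source_id=d.entry_id,
        chain_id=d.chain_id,
        verdicts=verdicts,
        overall_pass=all(v.passed for v in verdicts.values()),
        descriptor=d,
    )


DEFAULT_WEIGHTS = {"bfactor": 1.0 / 3.0, "charge": 1.0 / 3.0, "globularity": 1.0 / 3.0}


def rank_candidates(
    reports: Sequence[CandidateReport],
    weights: Optional[dict[str, float]] = None,
) -> list[CandidateReport]:
    """Order the passing candidates by the heuristic soft score (best first).

    score = w_b·(−B̄, min–max normalised over the batch)
          + w_c·(−|net surface charge| / length)
          + w_g·(−globularity)

    Ties break by (entry id, chain id) lexicographic order.  Failing
    candidates are excluded; an empty pass set yields an empty ranking.
    """
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    passing = [r for r in reports if r.overall_pass]
    if not passing:
        return []
    bvals = [r.descriptor.bfactor_mean for r in passing]
    bmin, bmax = min(bvals), max(bvals)
    span = bmax - bmin

    def score(r: CandidateReport) -> float:
        d = r.descriptor
        b_norm = (d.bfactor_mean - bmin) / span if span > 0 else 0.0
        return (
            w["bfactor"] * (-b_norm)
            + w["charge"] * (-abs(d.net_surface_charge) / d.length)
            + w["globularity"] * (-d.globularity)
        )

    ranked = [replace_score(r, score(r)) for r in passing]
    ranked.sort(key=lambda r: (-r.soft_score, r.source_id, r.chain_id))  # type: ignore[operator]
    return ranked


def replace_score(report: CandidateReport, score: float) -> CandidateReport:
    return CandidateReport(
        source_id=report.source_id,
        chain_id=report.chain_id,
        verdicts=report.verdicts,
        overall_pass=report.overall_pass,
        descriptor=report.descriptor,
        soft_score=score,
    )


@dataclass
class ScreenResult:
    reports: list[CandidateReport]
    n_files: int
    n_unreadable: int
    criteria: ScreenCriteria

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            d = r.descriptor
            row = {
                "entry": r.source_id,
                "chain": r.chain_id,
                "length": d.length,
                "mw_da": round(d.mw, 1),
                "resolution_A": d.resolution,
                "n_disulfides": d.n_disulfides,
                "n_ligands": d.n_ligands,
                "termini_ca_A": round(d.termini_ca_distance, 2),
                "globularity": round(d.globularity, 3),
                "bfactor_mean": round(d.bfactor_mean, 2),
                "net_surface_charge": d.net_surface_charge,
            }
            for cid in CRITERION_IDS:
                row[f"pass_{cid}_{CRITERION_LABELS[cid]}"] = r.verdicts[cid].passed
            row["overall_pass"] = r.overall_pass
            if r.soft_score is not None:
                row["soft_score"] = round(r.soft_score, 4)
            rows.append(row)
        return pd.DataFrame(rows)


def screen_library(
    paths: Sequence[str | Path],
    criteria: Optional[ScreenCriteria] = None,
    rel_sasa_min: float = 0.25,
    sasa_points: int = 960,
    ligand_ignore: frozenset[str] | set[str] = frozenset(),
) -> ScreenResult:
    """Screen every polymer chain of every readable file against the criteria.

    Unreadable files are logged and skipped; if *all* files are unreadable
    (or none are given) a :class:`LoopTagError` is raised.  Row order is the
    input file order, then chain order, so repeated runs are byte-identical.
    """
    if criteria is None:
        criteria = ScreenCriteria()
    paths = list(paths)
    if not paths:
        raise LoopTagError("no structure files to screen")
    reports: list[CandidateReport] = []
    n_unreadable = 0
    for path in paths:
        try:
            model = resolve_altlocs(read_structure(path))
        except LoopTagError as exc:
            logger.warning("skipping %s: %s", path, exc)
            n_unreadable += 1
            continue
        for chain in model.chains:
            if not chain.polymer_residues:
                continue
            descriptor = describe_chain(
                model,
                chain.chain_id,
                rel_sasa_min=rel_sasa_min,
                n_points=sasa_points,
                ligand_ignore=ligand_ignore,
            )
            reports.append(evaluate_candidate(descriptor, criteria))
    if n_unreadable == len(paths):
        raise LoopTagError("none of the given files could be read")
    return ScreenResult(
        reports=reports,
        n_files=len(paths),
        n_unreadable=n_unreadable,
        criteria=criteria,
    )
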