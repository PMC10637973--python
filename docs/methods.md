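# Methods

This note documents the models, conventions and numerical choices behind
`looptag`, and what the synthetic test bed does and does not establish about
real crystallographic data.

## Structure model and parsing

PDB and mmCIF files are parsed with gemmi and converted to an explicit
four-level model (structure → chain → residue → atom). Only the first model
of a multi-model file is retained, because the intended inputs are X-ray
entries where additional models do not occur. Residues are classified as
polymer when their code is a standard or common modified amino acid (MSE,
SEP, …, mapped to their parent for sequence purposes) or when the deposited
record is ATOM; waters (HOH/DOD/WAT) are always kept apart from other
heteroatoms so that the ligand criterion can never be tripped by solvent.
Author numbering with insertion codes is the only public residue coordinate
system; internal indices are never exposed.

Alternate locations are resolved to the highest-occupancy conformer, ties
broken by altloc character order (A before B). Resolution is taken from
gemmi's merged view of the refinement record and REMARK 2 (refinement
record preferred when both exist); a missing resolution is represented as
`None` and fails the resolution criterion rather than being guessed.

The package writes strict fixed-column PDB (with EXPDTA and REMARK 2) for
fixtures and round-trips; coordinates survive a write/read cycle to the
format's native 3 decimal places.

## Screening criteria

The six hard criteria operate on per-chain descriptors:

| criterion | quantity | default threshold | comparison |
|---|---|---|---|
| i | chain length | 400 residues | strict `<` |
| ii | disulfide bonds | 0 | equality |
| iii | non-water het residues | 0 | equality |
| iv | X-ray resolution | 1.6 Å | strict `<` (method must be X-ray) |
| v | termini Cα–Cα distance | 10 Å | inclusive `≤` |
| vi | globularity ratio | 1.25 | inclusive `≤` |

The strict-vs-inclusive choices mirror the phrasing of the criteria as
usually stated ("below 400", "better than 1.6 Å", "no further than 10 Å
apart"). Disulfide and ligand counts are entry-wide (a ligand anywhere in
the deposited file disqualifies the entry as a clean carrier source), while
geometry and B-factor statistics are chain-local.

**Disulfides** are CYS SG–SG pairs within 2.5 Å — a typical S–S bond is
2.05 Å, and the slack absorbs coordinate error — paired greedily
nearest-first with at most one bond per cysteine.

**Globularity** has no universal definition; here it is the ratio of the
observed heavy-atom radius of gyration to the empirical globular-protein
scaling R_ref = 2.2·N^0.38 Å (N = residue count). Compact folds score
≈ 0.6–1.0, elongated shapes well above 1.25. The 1.25 cut-off and the
reference law are both configurable.

**Termini distance** uses the first and last *resolved* residues carrying a
Cα; when a true terminus is unresolved the walk moves inward and the
descriptor is flagged (`termini_resolved=False`) rather than extrapolated.

**Soft ranking.** The literature motivates considering B-factors, surface
charge and compactness among criteria survivors but gives no formula, so
the score is explicitly heuristic:
`w_b·(−B̄ min–max normalised over the batch) + w_c·(−|net charge|/length) +
w_g·(−globularity)`, default weights ⅓ each, ties broken lexicographically
by entry id. It should be treated as a triage order, not a measurement.

## Solvent accessibility and surface charge

SASA uses Shrake–Rupley point sampling with a deterministic golden-spiral
of 960 points per atom (doubling the count changes totals by < 1 %),
probe radius 1.4 Å, Bondi van der Waals radii, hydrogens and waters
excluded. An isolated sphere reproduces 4π(r+probe)² essentially exactly
because the spiral is quasi-uniform. An independent implementation
(biotite, element radii) agrees within a few percent on the same
coordinates in the test suite.

A residue is "exposed" when its summed atomic SASA reaches 25 % of a fixed
per-residue theoretical maximum (Tien et al. 2013 Gly-X-Gly values). Net
surface charge is exposed {Arg, Lys, His} minus exposed {Asp, Glu}.
Surface-entropy-reduction candidates are exposed Lys/Glu/Gln, clustered
when author numbers are ≤ 2 apart, with the standard substitutions
(Lys→Ala/Ser, Glu→Ala, Gln→Ala) emitted in mutation notation.

## Construct design

All design arithmetic runs in author numbering with explicit offsets, so a
mutation string like `K94A` is validated letter-by-letter against the
sequence; a wild-type mismatch is an error, which catches off-by-one
numbering mistakes early. Fusion builds conserve length by construction
(segments must re-concatenate to the emitted sequence; this is asserted).
One worked example in the tests assembles a 643-residue target (numbered
295–937, anchors 489/778) with a 121-residue tag (author range 3–123,
mutations K94A/K96S) into 195 + 121 + 160 = 476 residues. Counting the
excised insertion exclusively of both anchors gives 288 residues
(490–777); sources that quote 289 for this span are counting inclusively
of one anchor, and the builder reports the exclusive count in the
construct notes rather than silently matching either convention.

Geometric compatibility of a tag with an insertion site is
`|d_anchor − d_tag| ≤ 4.0 Å + 3.5·L` with L the total linker residue
count: 4 Å of tolerance reflects loop plasticity at the graft point, and
3.5 Å/residue is a near-extended backbone reach. Both constants are
arguments, not policy.

Real target sequences are deliberately not bundled: the package ships only
the invariant 76-residue ubiquitin sequence, and the fixtures module
generates clearly-labelled synthetic stand-in sequences with the correct
author numbering spans (e.g. lysines planted at positions 94/96 of a 3–123
tag) for worked examples — all length/provenance arithmetic is independent
of residue identity.

## Superposition and identity

Kabsch superposition is computed by SVD of the covariance of centred
matched coordinates with the determinant correction that forbids
reflections; collinear or < 3-point inputs are rejected. The test suite
cross-checks rotations against an independent least-squares implementation
(scipy's rotation alignment) to 1e-6.

`structure_superpose` matches Cα pairs through a BLOSUM62 global alignment
(gap open 10, extend 0.5), then iterates: fit, compute per-pair deviations,
discard pairs above `max(2·SD, 3.5 Å)`, refit, until a fixed point or 10
iterations. The 3.5 Å floor prevents the rejection loop from eating into a
well-fitted core when deviations are uniformly small; 2·SD is the usual
outlier convention. The result reports used and total pair counts, mirroring
the "RMSD over n atoms out of m" style of structure papers.

Sequence identity is identical pairs divided by aligned non-gap pairs.
Published identity percentages are sensitive to matrix, gap costs, and
denominator convention (aligned pairs vs shorter sequence vs alignment
length), which is why all three knobs are exposed; comparisons against
literature values should state the convention used.

## Interface census

Buried surface area is SASA(A) + SASA(B) − SASA(A∪B), reported both as the
two-sided total and as the per-side value (total/2), since both conventions
circulate; the two-sided total is the default headline number. Hydrogen
bonds are donor–acceptor N/O pairs across the partition within 3.5 Å; the
D–H…A ≥ 120° angle test applies only when explicit hydrogens exist, which
crystal structures typically lack, so in practice the criterion is
distance-only — the same fallback PISA-style tools use. Salt bridges are
unique residue pairs with any Arg/Lys/His side-chain nitrogen within 4.0 Å
of any Asp/Glu carboxylate oxygen, plus the N-terminal amine and C-terminal
carboxylate (OXT) as charged termini. These geometric counts approximate,
but are not identical to, any specific published interface server's output,
whose exact criteria are generally unpublished.

## Synthetic fixtures: what they do and do not show

The generators produce backbone-plus-functional-atom models: Cα traces
(ideal helix: 1.5 Å rise, 100° twist; compact serpentine bundles on a
3.8 Å grid with small seeded jitter; extended hairpins) with N/C/O derived
geometrically, plus exactly the side-chain atoms a test plants (SG, NZ,
OE1, …). Termini distances are planted exactly; all randomness flows from
one explicit seed and output PDB files are byte-identical per seed.

This test bed establishes that the *measurements* are correct: detector
outputs equal brute-force oracles, quadrature matches closed forms,
screening verdicts match the planted manifest. It does not establish
behaviour on real crystallographic pathologies — alternate conformations
beyond simple altlocs, chain breaks, zero-occupancy atoms, exotic ligands,
or genuinely ambiguous "globularity" shapes — and fixture side chains are
not rotamerically realistic, so absolute SASA values of fixtures should not
be compared with those of real structures. Accession-based checks on real
entries (termini distance of a deposited carrier domain, buried area of a
deposited complex) require downloads and are intentionally outside the
offline test surface; the CLI operates on any local PDB/mmCIF file.

## Problem sizes and determinism

The shipped tests and the acceptance script run entirely on generated
fixtures: 6-chain screening libraries of 121–450-residue chains, 100-seed
oracle sweeps with 12–20 polar/cysteine residues per fixture, 500 random
construct builds, and SASA point counts of 200–4000 chosen so each check's
quadrature error is well below its assertion tolerance. Everything is
seeded; repeated runs are bit-identical apart from filesystem paths.
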