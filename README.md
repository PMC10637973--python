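# looptag

A toolkit for **carrier-driven crystallization by loop insertion**: finding
compact, highly crystallizable protein domains that can be grafted into a
flexible internal loop of a crystallization-recalcitrant target, designing
the resulting fusion constructs, and quantitatively comparing the structures
and interfaces that come out the other end.

## The problem

Many proteins — deubiquitinases with long disordered insertions are a classic
case — refuse to crystallize because a flexible segment disrupts lattice
formation. One remedy is to excise the flexible insertion and replace it with
a small, rigid, crystallization-friendly *carrier domain* whose N- and
C-termini happen to sit close together in space, so the carrier can bridge
the two anchor residues of the excised loop without straining the fold.

`looptag` implements the screening and bookkeeping side of that strategy:

1. **Screening** (`looptag.screening`): every polymer chain of a structure
   library is tested against six hard criteria —
   (i) length < 400 residues, (ii) no disulfide bonds, (iii) no non-water
   ligands, (iv) X-ray structure at resolution < 1.6 Å, (v) N/C-termini
   Cα–Cα distance ≤ 10 Å, and (vi) globular compactness
   (R_g / 2.2·N^0.38 ≤ 1.25). Survivors are ranked by a configurable soft
   score over B-factors, surface-charge balance and compactness.
2. **Descriptors** (`looptag.descriptors`): the measurable quantities behind
   those criteria — disulfide detection (SG–SG ≤ 2.5 Å, greedy pairing),
   ligand census, termini proximity, radius of gyration, Shrake–Rupley
   solvent accessibility, exposed-charge counts and
   surface-entropy-reduction (SER) candidate sites (exposed Lys/Glu/Gln
   clusters with suggested Lys→Ala/Ser, Glu→Ala, Gln→Ala substitutions).
3. **Construct design** (`looptag.design`): assembles
   `target[N…n_anchor] + linker + tag + linker + target[c_anchor…C]`
   chimeras with per-segment provenance, validates point mutations such as
   `K94A` against author numbering, checks tag/anchor geometric
   compatibility (|d_anchor − d_tag| ≤ 4 Å + 3.5 Å per linker residue), and
   builds C-terminally extended substrate variants (e.g. ubiquitin 1–76 +
   `GGG` → a 79-residue linear substrate mimetic).
4. **Comparison** (`looptag.compare`): Kabsch superposition (det(R) = +1)
   with sequence-guided Cα matching and iterative outlier rejection
   ("RMSD over *n* of *m* atoms"), BLOSUM62 global sequence identity, and an
   interface census — buried surface area (both the two-sided total and the
   per-side convention), hydrogen bonds and salt bridges across a chain
   partition.
5. **Fixtures** (`looptag.fixtures`): deterministic synthetic PDB generators
   (ideal helices, compact bundles with exactly planted termini distances,
   hairpins, disulfide/ligand planting, seeded perturbation and rigid
   transforms) with a JSON manifest of the planted ground truth, so the
   whole pipeline is testable offline.

Structure parsing (PDB and mmCIF) is backed by [gemmi]; alignments by
Biopython. All thresholds above are defaults, exposed in `ScreenCriteria`
and per-function keyword arguments.

[gemmi]: https://gemmi.readthedocs.io

## Worked example

Generate a planted six-chain library (two chains satisfy all six criteria,
four each violate exactly one) and screen it:

```sh
looptag fixtures make-library --seed 17 --out lib
looptag screen --sasa-points 300 lib > report.tsv
```

The report (key columns):

```
entry  length  resolution_A  n_disulfides  n_ligands  termini_ca_A  globularity  overall_pass  soft_score
 FX00     121           1.0             0          0           6.3        0.663          True     -0.2211
 FX01     121           1.0             0          0           6.3        0.664          True     -0.2213
 FX02     121           1.0             1          0           6.3        0.664         False
 FX03     121           1.0             0          1           6.3        0.664         False
 FX04     121           1.0             0          0          15.0        0.664         False
 FX05     121           1.0             0          0           6.3        4.489         False
```

`FX02`–`FX05` fail exactly one criterion each (a planted disulfide, a
sulfate ligand, 15 Å termini, an elongated hairpin fold); the two passing
121-residue bundles with 6.3 Å termini spacing — the geometry of a good
loop-insertion carrier — are ranked by soft score.

Designing the fusion construct (a 643-residue target numbered 295–937, with
the insertion between anchors 489 and 778 replaced by a 121-residue tag
spanning author positions 3–123 carrying two SER mutations):

```python
from looptag import InsertionSpec, TagSpec, build_fusion, c_terminal_extension, UBIQUITIN_1_76
from looptag.fixtures import synthetic_target_sequence, synthetic_tag_sequence

target = synthetic_target_sequence(295, 937, seed=11)        # synthetic stand-in
tag = TagSpec("tag", synthetic_tag_sequence(3, 123, (94, 96), seed=12),
              3, 123, termini_ca_distance=6.3, mutations=["K94A", "K96S"])
construct = build_fusion(InsertionSpec("target", target, 295, 489, 778), tag)
print(construct.length, [len(s) for s in construct.segments], construct.mutation_log)
# 476 [195, 121, 160] ['K94A', 'K96S']

print(c_terminal_extension(UBIQUITIN_1_76, "GGG", base_name="Ub").length)
# 79
```

The three provenance segments are the target's N-subdomain (195 residues,
295–489), the mutated tag (121 residues, 3–123) and the target's
C-subdomain (160 residues, 778–937); the excised insertion (288 residues,
490–777) is recorded in the construct notes. The ubiquitin + `GGG`
substrate mimetic is 79 residues.

## Layout

```
src/looptag/structure.py    PDB/mmCIF model, altloc resolution, sequences, PDB writer
src/looptag/descriptors.py  per-chain criteria quantities, SASA, SER sites
src/looptag/screening.py    hard criteria, soft ranking, library screening
src/looptag/design.py       fusion constructs, mutations, compatibility
src/looptag/compare.py      Kabsch/RMSD, identity, BSA, H-bonds, salt bridges
src/looptag/fixtures.py     deterministic synthetic structures + manifests
src/looptag/cli.py          describe / screen / design / superpose / interface / fixtures
docs/methods.md             models, conventions, parameter rationale, limitations
```
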