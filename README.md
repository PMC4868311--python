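# hcdr3torso

Knowledge-based dihedral restraints for the antibody heavy-chain CDR3
(HCDR3) **torso**, and evaluation tooling for HCDR3 loop-model decoy sets.

## The problem

The HCDR3 is the most sequence- and length-diverse loop of the antibody
paratope and resists canonical-structure classification. Its base, the
*torso* — the first three (T1–T3) and last four (T4–T7) loop residues —
is far less diverse and adopts two canonical conformations: **bulged**
(the prevalent form, in which the C-terminal β-strand pairing is broken,
often stabilized by an Arg/Lys(T2)–Asp(T6) side-chain interaction) and
**non-bulged**. De novo loop modelling engines rarely sample the bulged
conformation on their own. Restricting the torso φ/ψ angles to
experimentally observed ranges — as circular-harmonic dihedral restraints —
steers sampling toward native-like conformations.

This package is for structural bioinformaticians and antibody engineers
who model HCDR3 loops with an external engine (e.g. Rosetta LoopModel):
it derives the restraints the engine consumes and evaluates the decoy
sets the engine produces.

## What it computes

**Circular statistics.** Backbone dihedrals live on the circle, so per-position
summaries use the circular mean

  μ = atan2(Σₙ sin αₙ, Σₙ cos αₙ)

and the approximate circular standard deviation σ = √(2(1 − R̄)), where R̄ is
the mean resultant length of the unit vectors (sin αₙ, cos αₙ). The shipped
consensus profiles come from clustering curated antibody crystal-structure
torsos at a 2 Å radius (218 bulged, 38 non-bulged); e.g. bulged
ψ(T6) = −30° ± 26°, φ(T1) = −145° ± 9°.

**Restraints.** Each non-excluded (position, angle) pair becomes a
circular-harmonic restraint with penalty (Δ/σ)², Δ the circular deviation
from the class mean. ψ(T4) is excluded — it is bimodal within both classes,
with modes ~180° apart — so a bulged torso yields exactly 13 restraints
(7 φ + 6 ψ), serialized in Rosetta constraint-file format.

**Evaluation.** Loop Cα RMSD after framework superposition, length-normalized
as RMSD16 = RMSD / (1 + ln √(L/16)); sampling metrics (models below 2 Å,
best RMSD16, mean of the best 10); score-ranked recovery metrics; funnel
labels (top-10 %-by-score ∧ RMSD16 ≤ 2 Å → blue); greedy RMSD clustering of
decoys with a 1 % minimum-size filter and lowest-average-score "correct"
cluster selection.

## Worked example

Write the bulged-consensus restraints for a 16-residue HCDR3 starting at
(sequentially renumbered) residue 100:

```sh
torso restrain --start 100 --length 16 --out hcdr3.cst
# 13 restraints (bulged) -> hcdr3.cst
```

The first and last lines of `hcdr3.cst`:

```text
Dihedral C 99 N 100 CA 100 C 100 CIRCULARHARMONIC -2.530727 0.157080
...
Dihedral N 115 CA 115 C 115 N 116 CIRCULARHARMONIC 2.338741 0.174533
```

The first line restrains φ(T1) — atoms C(99), N(100), CA(100), C(100) — to
x₀ = −2.530727 rad (−145°) with width σ = 0.157080 rad (9°); the last
restrains ψ(T7), whose fourth atom is the N of the first framework-4
residue (116). Residues 100–102 are T1–T3 and 112–115 are T4–T7; residue
112 (T4) has a φ line but no ψ line.

Hand `hcdr3.cst` to the modelling engine, then evaluate its decoys:

```sh
torso evaluate --native native.pdb --decoys decoys/ \
    --scores scores.tsv --loop 100-115 --out report.csv
# 30 decoys; 18 below 2 A; best RMSD16 0.00 -> report.csv
```

`report.csv` holds the sampling/scoring metrics; `report.scatter.csv` the
per-model (score, RMSD16, label) funnel data; `report.clusters.csv` the
cluster table with the correct-cluster flag. Other subcommands: `extract`,
`profile`, `cluster`, `classify`, `motif`, `fixtures` (synthetic test data
with known ground truth; no downloads needed).

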