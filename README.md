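# aushell

Atomistic model construction and ligand-shell analysis for multifunctional
thiolate-protected gold nanoclusters.

Water-soluble clusters such as Au₁₄₄(*p*-MBA)₆₀ are promising nanocarriers
for targeted drug delivery: their surface is protected by 30 RS–Au–SR
"staple" units (one gold adatom bridging two thiolate sulfurs), and a
ligand-exchange reaction can swap individual thiolates for functional
ligands — targeting peptides and therapeutic payloads tethered through PEG
thiol spacers. Designing such a formulation means choosing a peptide, a
drug, and a peptide:drug ratio, then building a physically sensible
all-atom model of the decorated cluster. `aushell` is a library (plus a
thin CLI) for exactly that workflow, aimed at computational chemists
preparing nanocluster models for simulation or screening.

## What it does

**Model construction.** Exchange sites are drawn uniformly at random, at
most one thiolate per staple. Each incoming PEG conjugate is anchored with
its sulfur on the leaving thiolate's sulfur and its S→C axis along the
original bonding direction; orientations are then searched on a nested
rotational grid — S–Au rotations in 10° steps (outer loop), S–C rotations
in 3.6° steps (inner loop) — and the first orientation whose atoms all
clear

d(min) ≥ 1.75 Å

from every atom outside the incoming ligand is accepted immediately, which
biases placements toward the natural bonding direction. All peptide
conjugates are placed before any drug conjugate; an unplaceable site
restarts the whole build with fresh random sites. Gold atoms never move.

**Ligand chemistry (topology-level).** PEG thiol linkers
HS–C₁₁–(EG)ₙ–OCH₂–COOH are built in idealized all-anti geometry; payloads
couple to the terminal carboxyl through amide-bond formation with loss of
one water (carbodiimide-style coupling as a pure bond-topology operation);
conformers are elongated by setting every backbone dihedral anti, which
maximizes outreach from the cluster surface.

**Shell metrics.** Radius of gyration
R_g = √(Σᵢ wᵢ |rᵢ − r_com|² / Σᵢ wᵢ),
Shrake–Rupley solvent-accessible surface area attributed per shell
component (original *p*-MBA vs PEG-peptide vs PEG-drug), per-component
center-of-mass distance to the gold core over a trajectory, and radial
distribution functions g(r) with minimum-image periodic handling — the
quantities used to read a formulation's shell organisation (peptides
outermost, drugs in the middle, *p*-MBA inner).

**Fixtures.** An idealized Au₁₄₄(*p*-MBA)₆₀ reference cluster
(12+42+60-atom icosahedral core, 30 staples), small toy clusters, and toy
trajectories with analytically known Rg/SASA/RDF, so everything is testable
without downloads.

## Worked example

```bash
python examples/02_build_formulation.py
```

```
original p-MBA left: 45
PEG-peptide added:   10
PEG-drug added:      5
min external dist:   1.764 A (floor 1.75 A)
orientation trials:  [37, 4, 34, 38, 4, 1, 15, 13, 22, 12, 9, 1, 1, 4, 22]
```

The build replaced 15 of the 60 *p*-MBA thiolates (one per staple) with a
2:1 peptide:drug formulation; every incoming ligand sits at least 1.75 Å
from everything around it, and most placements succeeded within a few
dozen of the 3600 possible grid orientations — meaning the shell had room
near the native bonding directions. The other examples generate the
reference cluster (`01`), enumerate the 2 × 7 × 2 = 28-formulation design
space (`03`), and compute Rg ≈ 1.21 nm / SASA ≈ 58.4 nm² for the static
reference model plus an RDF peak-recovery check (`04`).

The same operations are scriptable from a shell:

```bash
aushell enumerate --out specs.tsv
aushell build --ratio 2:1 --seed 7 --out model.pdb --trace trace.json
aushell analyze rg --topology model.pdb --traj traj.pdb --out rg.tsv
```

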