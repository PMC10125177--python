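# Methods

## Scope and model

`aushell` builds all-atom models of multifunctional thiolate-protected
gold nanoclusters by ligand exchange and measures ligand-shell
organisation. It is a *construction and analysis* package: no energy
model, no dynamics, no charges. The chemistry is represented at the
bond-topology and idealized-geometry level, which is sufficient for the
two questions the package answers — *can this formulation be placed
clash-free on the cluster surface?* and *how is the resulting shell
organised?* Structures meant for simulation should be relaxed downstream
with a proper force field.

Internally all coordinates are Angstrom; analysis results are reported in
nm and nm², matching how cluster sizes and surface areas are conventionally
quoted.

## The idealized reference cluster

No public deposition exists for the Au₁₄₄(p-MBA)₆₀ coordinates, so the
package generates an idealized surrogate following the accepted structural
model of Au₁₄₄(SR)₆₀: a 114-atom metal core made of a 12-atom inner
icosahedron, a 42-atom Mackay second shell, and a 60-atom
rhombicosidodecahedral outer shell, plus 30 gold adatoms above the
icosahedral edge directions, each bridging two thiolate sulfurs (the
RS-Au-SR staple). Frozen geometric constants (Angstrom):

| constant | value | rationale |
|---|---|---|
| inner icosahedron radius | 2.78 | Au-Au near-neighbor spacing 2.74-2.80 |
| Mackay shell scale | 2 × 2.78 | standard Mackay construction |
| 60-shell radius | 7.10 | in/inter-shell spacing, core diameter |
| adatom radius | 8.30 | max Au-Au distance 16.6 A (~1.7 nm core) |
| Au-S bond | 2.33 | thiolate-gold bond length |
| S lift angle | 12° | keeps sulfurs > 2.6 A from core golds so staple detection sees exactly the 30 adatoms |
| dimer tilt | 20° | the two p-MBA of a staple lean together |
| ring roll | 55° | staggers neighbouring aryl rings |

The dimer tilt and ring roll deserve a note: with strictly radial ligands
the aryl rings splay apart, leaving deep solvent-accessible crevices
between ligands and ring-hydrogen contacts below the 1.75 A floor. Letting
each staple's two p-MBA leans toward each other pairs the rings
face-to-face — the pi-stacking motif aromatic thiolate shells adopt in
solution — which simultaneously removes the clashes (minimum
inter-molecular distance rises to 2.33 A, the S-adatom bond itself) and
closes the crevices the way a solvated, thermally relaxed shell does. On
the frozen geometry the static model measures: core diameter 1.66 nm,
geometric Rg 1.208 nm, total Shrake-Rupley SASA 58.4 nm².

p-MBA is modelled deprotonated (carboxylate), the form the shell takes at
neutral pH.

## Ligand templates and conjugation

PEG thiol linkers HS-(CH₂)ₐ-(O-CH₂-CH₂)ₙ-O-CH₂-COOH are constructed with
idealized bond lengths (C-C 1.54, C-O 1.43, C-S 1.81 A), tetrahedral
angles, and an all-anti backbone; a = 11 with n = 6 (peptide, long) or
n = 3 (drug, short) are the study linkers. Templates are stored as
thiolates (no S-H), ready to bind the staple gold.

Amide conjugation is a topology operation: the linker's hydroxyl O-H and
one amine hydrogen of the payload leave (net loss of one water; atom count
= linker + payload − 3), the new C-N bond is set to 1.33 A, and the
payload is rigid-rotated so it points away from the linker; remaining
amine hydrogens are re-idealized perpendicular to the amide axis. If every
rotation about the new bond leaves an intra-template contact below 1.5 A
the operation fails and asks for conformer elongation first. Which payload
amine reacts is explicit user input (`PayloadSpec.attach_atom`), since
payloads can carry several.

Conformer elongation sets every backbone dihedral to 180° by rotating the
distal side of each bond; bond lengths and angles are untouched (verified
to 1e-6 A in tests), and the all-anti state maximizes the anchor-to-tip
outreach, confirmed against exhaustive dihedral-grid scans.

## Placement algorithm

One exchange per staple, sites uniform without replacement, the leaving
thiolate of a pair chosen uniformly; all selections are driven by a single
integer seed. Each placement aligns the template's anchor sulfur and S→C
axis to the leaving ligand's, then scans the nested orientation grid —
outer rotation about the S-Au(adatom) axis in 10° steps, inner rotation
about the S-C axis in 3.6° steps, both starting at 0° and increasing, the
inner sweep repeated per outer angle (≤ 36 × 100 = 3600 trials). The first
orientation whose atoms (hydrogens included) all clear 1.75 A from every
atom outside the template is accepted immediately, so placements stay as
close to the native bonding direction as space allows. Peptides are all
placed before drugs. A site that exhausts its grid aborts the attempt and
the build restarts with fresh sites (seed advanced by +1), up to 100
restarts; per-site retry was rejected because the restart is what makes
the site *set* jointly feasible. Acceptance is re-verifiable post hoc:
`min_external_distance` recomputes the criterion over the finished model,
with both a KD-tree and an exhaustive double-loop evaluation that must
agree exactly.

The loop nesting, start angles, and rotation pivots (S-Au axis through the
replaced sulfur and the staple adatom; S-C axis through the anchor sulfur
and its first carbon) are fixed conventions chosen for determinism:
identical inputs and seed give byte-identical models.

## Shell metrics

* **Rg** — weighted RMS distance from the (weighted) center of mass.
  `masses=None` gives unit weights (the geometric Rg). Note that for this
  cluster class a gold-mass-weighted Rg is dominated by the metal core
  (~0.85 nm regardless of shell detail, since three quarters of the mass
  lies inside a 0.87 nm radius); the geometric Rg (~1.2 nm) is the variant
  that tracks the ligand shell and is what the size comparisons in this
  package use.
* **SASA** — Shrake-Rupley with a deterministic golden-spiral point shell:
  probe 0.14 nm, 960 points per atom, Bondi van der Waals radii (Au 0.166
  nm), all configurable. Validated against the closed-form isolated-sphere
  and two-sphere-overlap areas (≤1%), against an independent
  implementation, and for exact per-component additivity.
* **Component-core distance** — per frame, |com(ligand copy) − com(gold
  core)| averaged over the copies of a component; summarised as mean ±
  sample sd over frames at or after the equilibration cutoff (default
  30 ns, where shell metrics level off; configurable).
* **RDF** — pair histogram in 0.002 nm bins (default), minimum-image under
  periodic boundaries, normalized by shell volume and mean pair density so
  an ideal gas gives g = 1; r_max must not exceed half the smallest box
  edge. Both group choices of interest (ions vs staple sulfurs, ions vs
  gold core) are expressible since groups are arbitrary index sets; the
  CLI defaults to staple sulfurs.

## Synthetic data

The fixture generators define what the tests can and cannot show. The toy
payloads (an aniline-like ring "drug", an oligoglycine "peptide") have
realistic local geometry but none of the conformational flexibility,
charge, or size of real therapeutics; passing builds demonstrate the
placement algorithm's correctness and determinism, not that any real
formulation fits. Toy trajectories are constructed with known answers
(rigid translations → constant Rg; ions on a 0.27 nm shell → RDF mode at
0.27 nm; uniform gas → flat RDF) and carry their ground truth in a sidecar
JSON. The static reference model stands in for solution-average structure;
it cannot exhibit the ligand folding, solvent screening, or counterion
structure a 500 ns simulation would, which is why trajectory-dependent
quantities are validated on constructed fixtures rather than on it.

## Numerical choices and degenerate inputs

KD-trees accelerate all distance scans; results are bit-identical to the
brute-force forms (asserted in tests). Bond detection uses covalent-radius
sums × 1.2 with a fixed 2.6 A Au-S cutoff; gold bonds only to sulfur, and
free Na/Cl never bond. Molecule partitioning ignores Au-X bonds so each
thiolate remains its own molecule while all gold (core + adatoms) is one.
Staple detection requires a gold bonded to exactly two carbon-bearing
sulfurs from distinct molecules; a sulfur claimed by two candidate apexes
is reported as malformed geometry. Empty models write header-only files;
empty selections, non-integer ratio splits, and r_max beyond the
minimum-image horizon raise with explicit messages.

## Known limitations

Idealized geometry only (no relaxation); the reference cluster is a
surrogate, not the DFT-optimized structure; builds sample orientations
greedily, so the result is the first feasible shell, not an ensemble;
trajectory support covers multi-model PDB and concatenated XYZ (compressed
binary formats are out of scope); SASA cost grows as atoms × points ×
neighbours (~1 s for the 984-atom reference at defaults).
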