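"""Build one multifunctional cluster by ligand exchange.

Fifteen of the sixty p-MBA thiolates (one per staple, never both) are
replaced by PEG conjugates: ten peptide conjugates on the long
HS-C11-(EG)6-OCH2-COOH linker, then five drug conjugates on the short
(EG)3 linker — a 2:1 peptide:drug formulation.  Placement uses nested
rotational sampling (10 degree S-Au steps outside, 3.6 degree S-C steps
inside) and accepts the first orientation clearing 1.75 A from everything.
"""

from aushell import (
    conjugate_payload,
    elongate_conformer,
    generate_reference_cluster,
    make_peg_linker,
)
from aushell.builder import (
    BuilderConfig,
    FormulationSpec,
    build_functionalized_cluster,
    min_external_distance,
)
from aushell.fixtures import toy_drug_payload, toy_peptide_payload
from aushell.structures import Component

reference = generate_reference_cluster()

# synthetic stand-in payloads keep the example self-contained; real drug
# and peptide structures enter the same way via SDF/PDB + PayloadSpec
peptide = elongate_conformer(conjugate_payload(
    elongate_conformer(make_peg_linker(6, 11)), toy_peptide_payload()))
drug = elongate_conformer(conjugate_payload(
    elongate_conformer(make_peg_linker(3, 11)), toy_drug_payload()))

config = BuilderConfig(seed=7)  # 15 exchanges, 1.75 A floor by default
formulation = FormulationSpec("gly5", "ringamine", (2, 1), 10, 5)
built, traces = build_functionalized_cluster(reference, formulation,
                                             peptide, drug, config)

print(f"original p-MBA left: {len(built.molecules_with_component(Component.OL))}")
print(f"PEG-peptide added:   {len(built.molecules_with_component(Component.PL))}")
print(f"PEG-drug added:      {len(built.molecules_with_component(Component.DL))}")
print(f"min external dist:   {min_external_distance(built):.3f} A (floor 1.75 A)")
print(f"orientation trials:  {[t.trials for t in traces]}")
print("a low trial count means the first near-native orientations were free")
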