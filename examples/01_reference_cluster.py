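"""Generate the idealized Au144(p-MBA)60 reference cluster and inspect it.

The cluster is the parent structure for all functionalized models: a
144-gold icosahedral core whose surface is protected by 30 RS-Au-SR
"staples", each carrying two para-mercaptobenzoate thiolates.
"""

from aushell import (
    core_diameter,
    detect_protective_units,
    generate_reference_cluster,
    write_structure,
)
from aushell.structures import Component, min_intermolecular_distance

model = generate_reference_cluster()
units = detect_protective_units(model)

print(f"atoms:              {model.n_atoms}")
print(f"gold atoms:         {int((model.elements == 'Au').sum())}")
print(f"thiolate ligands:   {len(model.molecules_with_component(Component.OL))}")
print(f"protective units:   {len(units)} (two ligands each)")
print(f"core diameter:      {core_diameter(model):.2f} nm  (max Au-Au distance)")
print(f"min intermolecular: {min_intermolecular_distance(model):.2f} A "
      f"(clash floor is 1.75 A)")

write_structure(model, "reference.xyz")
print("wrote reference.xyz (element x y z molecule component per line)")
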