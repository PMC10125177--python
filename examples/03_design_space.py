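"""Enumerate the 28-formulation design space.

Two targeting peptides x seven drugs x two peptide:drug ratios, with the
15 exchange sites split according to the ratio (1:2 -> 5 peptides + 10
drugs; 2:1 -> 10 + 5).
"""

from aushell.builder import (
    DEFAULT_DRUGS,
    DEFAULT_PEPTIDES,
    DEFAULT_RATIOS,
    enumerate_formulations,
)

specs = enumerate_formulations(DEFAULT_PEPTIDES, DEFAULT_DRUGS, DEFAULT_RATIOS)
print(f"{len(specs)} formulations\n")
print(f"{'peptide':8s} {'drug':5s} {'ratio':6s} {'n_pep':>5s} {'n_drug':>6s}")
for s in specs[:6]:
    print(f"{s.peptide:8s} {s.drug:5s} {s.ratio[0]}:{s.ratio[1]:<4d} "
          f"{s.n_peptide:5d} {s.n_drug:6d}")
print(f"... ({len(specs) - 6} more)")
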