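"""Protein-domain mapping and cross-species conservation.

Maps mutated residues of myosin XVa onto the shipped domain table
(N-terminal extension, motor domain, IQ motifs, MyTH4, FERM and SH3
domains) and scores conservation of a residue as column identity in a
small nine-species alignment: the fraction of aligned residues equal to
the human one, plus a strict all-mammals flag.
"""

from quadvar.protein import (
    conservation_at,
    map_residue_to_domain,
    myo15a_domain_table,
)
from quadvar.types import MSA

table = myo15a_domain_table()
for residue in (2792, 1500, 1905):
    hits = map_residue_to_domain(residue, table)
    pretty = ", ".join(f"{n} ({s}-{e})" for n, s, e in hits) or "linker region"
    print(f"residue {residue}: {pretty}")

# a toy alignment column: mammals conserve the valine, fish does not
species = "human chimpanzee macaque cow dog mouse rat chicken zebrafish"
column = dict(zip(species.split(), "VVVVVVVVI"))
msa = MSA({sp: "LQ" + column[sp] + "KE" for sp in column}, reference="human")
result = conservation_at(msa, 3)
print(f"\nresidue 3 ({result.reference_residue}): "
      f"identity {result.identity_fraction:.3f}, "
      f"mammal_conserved={result.mammal_conserved}")
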