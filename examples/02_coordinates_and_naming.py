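"""Coordinate arithmetic and variant nomenclature.

Shows the CDS-to-codon mapping behind protein-level names and the three
notations the reports use: HGVS c. for coding substitutions, HGVS p. for
the amino-acid change, and legacy IVS for intronic positions. The
numbers are the published MYO15A worked example: coding position 8375
lies in codon 2792, so a T>C at that base in a valine codon (GTG) gives
p.V2792A, and the splice variant three bases into intron 25 is written
IVS25+3G>A.
"""

from quadvar.annotation import (
    CdsCoordinate,
    cds_to_codon,
    hgvs_c_name,
    hgvs_p_name,
    ivs_name,
)

residue, offset = cds_to_codon(8375)
print(f"CDS position 8375 -> codon {residue}, base {offset} of 3")

coding = CdsCoordinate("coding", cds_pos=8375)
print("coding name:  ", hgvs_c_name(coding, "T", "C"))
print("protein name: ", hgvs_p_name(("V", residue, "A")))

intronic = CdsCoordinate("intronic", intron_index=25, offset=3)
print("intronic name:", ivs_name(intronic, "G", "A"))
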