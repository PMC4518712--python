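# Default constraint set for auditing candidate models of the homodimerized
# p85a:PTEN assembly.  Chain convention (user models must follow it or edit
# this file): A and B = the two p85a protomers, C = PTEN.
#
# Residue numbering is PDB author numbering (p85a: UniProt P27986; PTEN:
# UniProt P60484, as in entry 1D5R).

# The PTEN phosphatase domain binds the BH surface outlined by I127/I133/E137
# of one p85a protomer.
interface_contains   A:C   A:127,A:133,A:137

# Binding buries the PTEN ubiquitination site K13 (inaccessible in the
# complex).
buried               C:13  0.07

# p85a W298 (start of the flexible PR2 region) lies near the PTEN
# phosphatase domain; PTEN residue 14 is the first ordered residue.
contact              A:298 C:14  25.0

# The GTPase-binding site on BH (around the conserved R151 "arginine
# finger" region) and the proposed PTEN site are distinct surfaces.
disjoint_interfaces  A:151,A:155,A:158  A:127,A:133,A:137

# The p85a homodimer is two-fold symmetric: the protomers superpose.
symmetric            A:B   1.0
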