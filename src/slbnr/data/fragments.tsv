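# Molecular fragment library: name  formula  volume[A^3]  n_exchangeable
# Head/tail split follows the POPC convention (carbonyls and glycerol backbone
# in the head; acyl chains minus carbonyl in the tails). Volumes default to the
# POPC literature values (head 319 A^3, both chains 937 A^3); cardiolipin is one
# molecule with four chains and a double glycerophosphate head.
PE_head   C9H14NO8P     319   3
PG_head   C8H13O10P     319   3
CL_head   C13H10O17P2   638   2
PE_tails  C32H64        937   0
PG_tails  C32H64        937   0
CL_tails  C64H128       1874  0
H2O       H2O           30.0  2
D2O       D2O           30.0  2
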