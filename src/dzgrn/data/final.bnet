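# Final dehiscence-zone GRN (12 nodes): the literature-compiled network
# extended with NTT and a small set of hypothetical interactions.
# RECONSTRUCTION: the published rule listing is not publicly deposited;
# these rules were rebuilt from the interaction catalogue and the
# reported wild-type/mutant attractor behavior (see docs/methods.md for
# the provenance of every term).
targets, factors
FUL, (FUL | (JFY & AS)) & !NTT
SHP, JFY & (NTT | !FUL)
IND, SHP & !FUL
ALC, (IND | SHP) & NTT & !FUL
SPT, (IND | SHP) & !FUL
RPL, BP & !JFY
BP, NTT & !AS & !JFY & !FUL & !SHP
JFY, !BP & !RPL
AS, !SHP & !BP & !RPL
AP2, !MIR172 & !FUL
MIR172, FUL & !AP2
NTT, NTT
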