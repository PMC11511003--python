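# Initial dehiscence-zone GRN (11 nodes): experimentally supported
# interactions only, before the NTT node and the hypothetical rewiring.
# This model is expected to FAIL: it cannot separate the lignification
# layer from the separation layer (the merged valve-margin attractor).
# RECONSTRUCTION: see docs/methods.md.
targets, factors
FUL, JFY & AS
SHP, JFY & !FUL
IND, SHP & !FUL
ALC, (IND | SHP) & !FUL
SPT, (IND | SHP) & !FUL
RPL, BP & !JFY
BP, BP & !AS & !JFY
JFY, !BP & !RPL
AS, !SHP & !BP & !RPL
AP2, !MIR172 & !FUL
MIR172, FUL & !AP2
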