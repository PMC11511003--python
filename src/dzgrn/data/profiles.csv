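node,V,LL,SL,R,VM
FUL,1,0,0,0,0
SHP,0,1,1,0,1
IND,0,1,1,0,1
ALC,0,0,1,0,1
SPT,,,,,
RPL,0,0,0,1,0
BP,0,0,0,1,0
JFY,1,1,1,0,1
AS,1,0,0,0,0
AP2,,,,,
MIR172,,,,,
NTT,0,0,1,1,
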