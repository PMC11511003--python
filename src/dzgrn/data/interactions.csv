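regulator,target,sign,evidence,in_initial_model,reference
IND,ALC,activation,well_supported,true,B5;B24
SHP,ALC,activation,well_supported,true,B6;B7
MIR172,AP2,repression,well_supported,true,B19
AP2,ARF68,repression,well_supported,true,B29;B30
AP2,AS,repression,well_supported,true,B18;B29
AP2,BP,repression,well_supported,false,B18
AS,BP,repression,well_supported,true,B12
SHP,IND,activation,well_supported,true,B5;B6;B8
BP,RPL,activation,well_supported,true,B12
JFY,BP,repression,well_supported,true,B15
NTT,BP,activation,well_supported,false,B21
BP,JFY,repression,well_supported,true,B15
FUL,FUL,activation,well_supported,false,B31
ALC,IND,repression,well_supported,false,B24
AP2,IND,repression,well_supported,true,B18
FUL,IND,repression,well_supported,true,B8
FUL,MIR172,activation,well_supported,true,B19
AP2,RPL,repression,well_supported,true,B18
JFY,RPL,repression,well_supported,true,B15
AP2,SHP,repression,well_supported,true,B18
FUL,SHP,repression,well_supported,true,B8;B13;B31
JFY,SHP,activation,well_supported,true,B13;B14;B15
FUL,ALC,repression,well_supported,true,B8;B13
AP2,AP2,repression,well_supported,false,B32;B33;B34;B35
FUL,AP2,repression,well_supported,false,B36;B37;B38
AS,JFY,repression,well_supported,false,B37;B38;B39;B40
JFY,FUL,activation,well_supported,true,B13;B14;B15;B41;B42
NTT,JFY,repression,well_supported,false,B43
AP2,MIR172,repression,well_supported,false,B29;B37
NTT,NTT,activation,well_supported,false,B44
FUL,SPT,repression,well_supported,false,B10
IND,SPT,activation,well_supported,false,B11;B24;B45
SHP,SPT,activation,well_supported,false,B10;B45
RPL,JFY,repression,suggested,true,B13
AS,FUL,activation,suggested,true,B12
BP,BP,activation,suggested,false,B37;B38;B46;B47
SHP,AS,repression,suggested,false,B37;B38
IND,SHP,,ppi,false,B37;B38
BP,AP2,,ppi,false,B46
JFY,AP2,,ppi,false,B46
NTT,AS,,ppi,false,B47
RPL,BP,,ppi,false,B37;B48
SHP,BP,,ppi,false,B48
AP2,JFY,,ppi,false,B48
SHP,FUL,,ppi,false,B37
RPL,IND,,ppi,false,B38
JFY,JFY,,ppi,false,B37
NTT,FUL,,ppi,false,B21;B44;B48;B49
NTT,RPL,,ppi,false,B49
NTT,SHP,,ppi,false,B48;B49
BP,SHP,,ppi,false,B46
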