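# Lipid class registry: acyl slot counts and alkaline-hydrolysis behaviour.
# saponifiable_slots < acyl_slots marks chains not released by hydrolysis
# (sphingolipid N-acyls are amide-bound; FA is already a free acid).
code,acyl_slots,saponifiable_slots,category
FA,1,0,free acid
MAG,1,1,glycerolipid
DG,2,2,glycerolipid
TG,3,3,glycerolipid
PC,2,2,glycerophospholipid
PE,2,2,glycerophospholipid
PI,2,2,glycerophospholipid
PS,2,2,glycerophospholipid
PA,2,2,glycerophospholipid
PG,2,2,glycerophospholipid
CL,4,4,glycerophospholipid
BMP,2,2,glycerophospholipid
LPC,1,1,lysophospholipid
LPE,1,1,lysophospholipid
LPI,1,1,lysophospholipid
LPA,1,1,lysophospholipid
LPS,1,1,lysophospholipid
LPG,1,1,lysophospholipid
SM,1,0,sphingolipid
Cer,1,0,sphingolipid
GluCer,1,0,sphingolipid
LacCer,1,0,sphingolipid
SL,1,0,sphingolipid
CE,1,1,sterol ester
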