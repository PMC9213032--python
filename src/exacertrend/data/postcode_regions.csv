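postcode_area,region
CB,East England
CO,East England
IP,East England
NR,East England
LE,East Midlands
NG,East Midlands
DE,East Midlands
E,London
EC,London
N,London
NW,London
SE,London
SW,London
W,London
WC,London
NE,North East
SR,North East
DH,North East
M,North West
L,North West
PR,North West
BL,North West
GU,South East
RG,South East
BN,South East
CT,South East
ME,South East
OX,South East
BS,South West
EX,South West
PL,South West
TR,South West
B,West Midlands
CV,West Midlands
WV,West Midlands
LS,Yorkshire and the Humber
S,Yorkshire and the Humber
HU,Yorkshire and the Humber
BD,Yorkshire and the Humber
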