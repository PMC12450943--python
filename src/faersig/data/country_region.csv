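country,region
US,North America
CA,North America
MX,North America
GB,Europe
DE,Europe
FR,Europe
IT,Europe
ES,Europe
NL,Europe
PL,Europe
SE,Europe
CH,Europe
BE,Europe
AT,Europe
IE,Europe
PT,Europe
DK,Europe
NO,Europe
FI,Europe
GR,Europe
JP,Asia
CN,Asia
IN,Asia
KR,Asia
TW,Asia
IL,Asia
SA,Asia
TR,Asia
BR,South America
AR,South America
CO,South America
CL,South America
PE,South America
AU,Oceania
NZ,Oceania
ZA,Africa
NG,Africa
EG,Africa
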