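# Default 44-descriptor vocabulary for QSAR screening datasets.
# Autocorrelation / E-state / VSA / path-count names plus common
# constitutional descriptors; override via the descriptor_list config key.
ATSC4dv
ATSC1m
ATSC7are
Xch-6d
SssO
fMF
PEOE_VSA3
SMR_VSA7
EState_VSA4
MATS1i
Mp
SaaN
JGI10
AATS0dv
ATSC3v
GATS2dv
SdCH2
SssNH
SdS
IC2
EState_VSA2
piPC8
SsNH2
ZMIC3
PEOE_VSA4
PEOE_VSA5
PEOE_VSA11
SMR_VSA4
EState_VSA9
SRW07
AATSC2pe
AATSC1are
GATS1i
AATS1dv
JGT10
MolWt
HeavyAtomCount
NumHAcceptors
NumHDonors
NumRotatableBonds
RingCount
TPSA
MolLogP
FractionCSP3
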