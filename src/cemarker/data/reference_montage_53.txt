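Fp2
AF7
AF3
AFz
AF4
AF8
C5
C3
C1
Cz
C2
C4
C6
CP5
CP3
CP1
CPz
CP2
CP4
F5
F3
Fz
F1
F2
F4
F6
F8
FT7
FC5
FC3
FC1
FC2
FC4
FC6
FT8
P7
P5
P3
P1
Pz
P2
P4
P6
P8
PO9
PO7
POz
PO3
PO4
PO8
O1
Oz
O2
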