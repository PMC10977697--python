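target,EETI-II,AVR9,Circulin-A,Conotoxin-MVIIA,Huwentoxin,Charybdotoxin,CBD
HGFA,6,0,0,0,0,0,1
HtrA1,6,18,15,6,1,0,4
ApoL1,47,0,0,0,0,0,1
R-spondin,2,0,0,0,0,0,0
Insulin,0,0,0,0,0,0,0
Her3-Fc,11,1,0,0,0,2,1
Lgr5ECD-Fc,26,0,0,2,0,0,18
Fz7CRD-Fc,7,1,0,1,0,0,11
PCSK9,20,0,0,12,0,0,28
PCSK9 dCRD,0,14,0,3,0,0,2
BamA-amphipol,1,0,0,0,0,0,0
CD28-Fc,16,0,0,0,4,0,0
CD16A,44,0,0,0,4,0,11
EpCAM,39,0,0,0,0,0,90
Notch2Long,8,0,0,0,0,0,0
Notch2NRR,9,9,0,0,0,0,5
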