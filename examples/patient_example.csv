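ID,TIME,AMT,DV,AGE,CRCL,FLUC
P001,0,1.5,,6.0,110.0,1
P001,12,1.5,,,,
P001,24,,8.4,,,
P001,24,1.5,,,,
P001,36,1.5,,,,
P001,48,,9.1,,,
P001,48,1.5,,,,
P001,60,1.5,,,,
P001,72,,10.2,,,
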