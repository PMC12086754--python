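symbol,Z,A,I
H,1,1.008,19.2
C,6,12.011,78.0
N,7,14.007,82.0
O,8,15.999,95.0
Na,11,22.990,149.0
Mg,12,24.305,156.0
Si,14,28.086,173.0
P,15,30.974,173.0
S,16,32.060,180.0
Cl,17,35.450,174.0
K,19,39.098,190.0
Ca,20,40.078,191.0
Fe,26,55.845,286.0
I,53,126.904,491.0
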