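neuron
I1L
I1R
I2L
I2R
I3
I4
I5
I6
M1
M2L
M2R
M3L
M3R
M4
M5
MCL
MCR
MI
NSML
NSMR
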