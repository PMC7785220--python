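gene,ligand,channel,excluded
glr-1,glutamate,cation,0
glr-2,glutamate,cation,0
glr-3,glutamate,cation,0
glr-4,glutamate,cation,0
glr-5,glutamate,cation,0
glr-6,glutamate,cation,0
glr-7,glutamate,cation,0
glr-8,glutamate,cation,0
nmr-1,glutamate,cation,0
nmr-2,glutamate,cation,0
acr-1,acetylcholine,cation,0
acr-2,acetylcholine,cation,0
acr-3,acetylcholine,cation,0
acr-4,acetylcholine,cation,0
acr-5,acetylcholine,cation,0
acr-6,acetylcholine,cation,0
acr-7,acetylcholine,cation,0
acr-8,acetylcholine,cation,0
acr-9,acetylcholine,cation,0
acr-10,acetylcholine,cation,0
acr-11,acetylcholine,cation,0
acr-12,acetylcholine,cation,0
acr-13,acetylcholine,cation,0
acr-14,acetylcholine,cation,0
acr-15,acetylcholine,cation,0
acr-16,acetylcholine,cation,0
acr-17,acetylcholine,cation,0
acr-18,acetylcholine,cation,0
acr-19,acetylcholine,cation,0
acr-20,acetylcholine,cation,0
acr-21,acetylcholine,cation,0
acr-23,acetylcholine,cation,0
acr-25,acetylcholine,cation,0
deg-3,acetylcholine,cation,0
des-2,acetylcholine,cation,0
eat-2,acetylcholine,cation,0
lev-8,acetylcholine,cation,0
unc-29,acetylcholine,cation,0
unc-38,acetylcholine,cation,0
unc-63,acetylcholine,cation,0
exp-1,GABA,cation,0
lgc-35,GABA,cation,0
glc-1,glutamate,anion,0
glc-2,glutamate,anion,0
glc-3,glutamate,anion,0
glc-4,glutamate,anion,0
avr-14,glutamate,anion,0
avr-15,glutamate,anion,0
acc-1,acetylcholine,anion,0
acc-2,acetylcholine,anion,0
acc-3,acetylcholine,anion,0
lgc-47,acetylcholine,anion,0
lgc-48,acetylcholine,anion,0
lgc-49,acetylcholine,anion,0
gab-1,GABA,anion,0
ggr-1,GABA,anion,0
ggr-2,GABA,anion,0
ggr-3,GABA,anion,0
lgc-36,GABA,anion,0
lgc-37,GABA,anion,0
lgc-38,GABA,anion,0
unc-49,GABA,anion,0
acc-4,acetylcholine,anion,1
lgc-46,acetylcholine,anion,1
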