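index,source,target,sign
1,Ras,PI3K,activation
2,MEK,Grb2SOS,inhibition
3,PI3K,Ras,activation
4,PI3K,MEK,activation
5,PIP3,GabSOS,activation
6,AKT,GabSOS,inhibition
7,AKT,Raf,inhibition
8,PLCg,PI3K,activation
9,PKC,MEK,activation
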