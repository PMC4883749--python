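condition_name,node,clamp_value
ND,DOX,0
ND,Wortmannin,0
ND,U0126,0
ND,GF109,0
ND,Go6976,0
ND,bPTEN,1
ND,bPDK,1
DV-WT,DOX,1
DV-WT,Wortmannin,0
DV-WT,U0126,0
DV-WT,GF109,0
DV-WT,Go6976,0
DV-WT,bPTEN,1
DV-WT,bPDK,1
DV-dMAPK,DOX,1
DV-dMAPK,SHP2,0
DV-dMAPK,Wortmannin,0
DV-dMAPK,U0126,0
DV-dMAPK,GF109,0
DV-dMAPK,Go6976,0
DV-dMAPK,bPTEN,1
DV-dMAPK,bPDK,1
DV-dPI3K,DOX,1
DV-dPI3K,PI3Krec,0
DV-dPI3K,Wortmannin,0
DV-dPI3K,U0126,0
DV-dPI3K,GF109,0
DV-dPI3K,Go6976,0
DV-dPI3K,bPTEN,1
DV-dPI3K,bPDK,1
DV-WT+Wortmannin,DOX,1
DV-WT+Wortmannin,Wortmannin,1
DV-WT+Wortmannin,U0126,0
DV-WT+Wortmannin,GF109,0
DV-WT+Wortmannin,Go6976,0
DV-WT+Wortmannin,bPTEN,1
DV-WT+Wortmannin,bPDK,1
DV-WT+U0126,DOX,1
DV-WT+U0126,Wortmannin,0
DV-WT+U0126,U0126,1
DV-WT+U0126,GF109,0
DV-WT+U0126,Go6976,0
DV-WT+U0126,bPTEN,1
DV-WT+U0126,bPDK,1
DV-dMAPK+Wortmannin,DOX,1
DV-dMAPK+Wortmannin,SHP2,0
DV-dMAPK+Wortmannin,Wortmannin,1
DV-dMAPK+Wortmannin,U0126,0
DV-dMAPK+Wortmannin,GF109,0
DV-dMAPK+Wortmannin,Go6976,0
DV-dMAPK+Wortmannin,bPTEN,1
DV-dMAPK+Wortmannin,bPDK,1
DV-dMAPK+U0126,DOX,1
DV-dMAPK+U0126,SHP2,0
DV-dMAPK+U0126,Wortmannin,0
DV-dMAPK+U0126,U0126,1
DV-dMAPK+U0126,GF109,0
DV-dMAPK+U0126,Go6976,0
DV-dMAPK+U0126,bPTEN,1
DV-dMAPK+U0126,bPDK,1
DV-dPI3K+Wortmannin,DOX,1
DV-dPI3K+Wortmannin,PI3Krec,0
DV-dPI3K+Wortmannin,Wortmannin,1
DV-dPI3K+Wortmannin,U0126,0
DV-dPI3K+Wortmannin,GF109,0
DV-dPI3K+Wortmannin,Go6976,0
DV-dPI3K+Wortmannin,bPTEN,1
DV-dPI3K+Wortmannin,bPDK,1
DV-dPI3K+U0126,DOX,1
DV-dPI3K+U0126,PI3Krec,0
DV-dPI3K+U0126,Wortmannin,0
DV-dPI3K+U0126,U0126,1
DV-dPI3K+U0126,GF109,0
DV-dPI3K+U0126,Go6976,0
DV-dPI3K+U0126,bPTEN,1
DV-dPI3K+U0126,bPDK,1
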