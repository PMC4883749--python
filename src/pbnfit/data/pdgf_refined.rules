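# Deregulated PDGF signalling in GIST, refined variant: adds a basal PKC
# activity rule that is independent of receptor activation but remains
# sensitive to the PKC inhibitors.  25 optimisable selection probabilities.

DOX = 0 , INPUT
Wortmannin = 0 , INPUT
U0126 = 0 , INPUT
GF109 = 0 , INPUT
Go6976 = 0 , INPUT
bPTEN = 1 , INPUT
bPDK = 1 , INPUT

mPDGFR = DOX , H
mPDGFR = DOX AND NOT ERK , L
mPDGFR = DOX AND NOT STAT5 , L

STAT5 = mPDGFR , H
STAT5 = mPDGFR AND NOT SHP2 , L

SHP2 = mPDGFR , FIXED
Grb2SOS = SHP2 , H
Grb2SOS = mPDGFR AND NOT ERK , L
GabSOS = mPDGFR , H
GabSOS = Grb2SOS AND NOT ERK , L
Ras = Grb2SOS , H
Ras = GabSOS , L
Raf = Ras , H
Raf = Ras AND NOT ERK , L
MEK = Raf AND NOT U0126 , FIXED
ERK = MEK , FIXED

PI3Krec = mPDGFR , FIXED
PI3K = PI3Krec AND NOT Wortmannin , H
PI3K = PI3Krec , L
PIP3 = PI3K , H
PIP3 = PI3K AND NOT PTEN , L
PTEN = bPTEN , FIXED
PDK = PIP3 , H
PDK = bPDK , L
AKT = PIP3 AND PDK , H
AKT = PDK , L

PLCg = mPDGFR , H
PLCg = SHP2 , L
IP3 = PLCg , FIXED
DAG = PLCg , FIXED
Ca = IP3 , FIXED
# basal PKC activity (receptor-independent, PKC-inhibitor sensitive)
PKC = NOT GF109 AND NOT Go6976 , H
PKC = DAG AND Ca AND PDK AND NOT Wortmannin AND NOT GF109 AND NOT Go6976 , L
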