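# Deregulated PDGF signalling in GIST, final variant: refined model plus the
# PI3K -> MEK1,2 crosstalk.  27 optimisable selection probabilities.
#
# The weights below are the packaged reference calibration used by the
# synthetic stand-in data generator: the MEK crosstalk/main pair, the
# Wortmannin->PI3K pair and the basal-PKC pair carry the published final
# interaction strengths; the remaining weights are synthetic placeholders
# chosen inside their flag bounds (see docs/methods.md).

DOX = 0 , INPUT
Wortmannin = 0 , INPUT
U0126 = 0 , INPUT
GF109 = 0 , INPUT
Go6976 = 0 , INPUT
bPTEN = 1 , INPUT
bPDK = 1 , INPUT

mPDGFR = DOX , H:0.90
mPDGFR = DOX AND NOT ERK , L:0.05
mPDGFR = DOX AND NOT STAT5 , L:0.05

STAT5 = mPDGFR , H:0.90
STAT5 = mPDGFR AND NOT SHP2 , L:0.10

SHP2 = mPDGFR , FIXED
Grb2SOS = SHP2 , H:0.70
Grb2SOS = mPDGFR AND NOT ERK , L:0.30
GabSOS = mPDGFR , H:0.70
GabSOS = Grb2SOS AND NOT ERK , L:0.30
Ras = Grb2SOS , H:0.60
Ras = GabSOS , L:0.40
Raf = Ras , H:0.90
Raf = Ras AND NOT ERK , L:0.10
MEK = Raf AND NOT U0126 , H:0.774
MEK = PI3K AND NOT U0126 , L:0.226
ERK = MEK , FIXED

PI3Krec = mPDGFR , FIXED
PI3K = PI3Krec AND NOT Wortmannin , H:0.893
PI3K = PI3Krec , L:0.107
PIP3 = PI3K , H:0.70
PIP3 = PI3K AND NOT PTEN , L:0.30
PTEN = bPTEN , FIXED
PDK = PIP3 , H:0.60
PDK = bPDK , L:0.40
AKT = PIP3 AND PDK , H:0.80
AKT = PDK , L:0.20

PLCg = mPDGFR , H:0.55
PLCg = SHP2 , L:0.45
IP3 = PLCg , FIXED
DAG = PLCg , FIXED
Ca = IP3 , FIXED
PKC = NOT GF109 AND NOT Go6976 , H:0.997
PKC = DAG AND Ca AND PDK AND NOT Wortmannin AND NOT GF109 AND NOT Go6976 , L:0.003
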