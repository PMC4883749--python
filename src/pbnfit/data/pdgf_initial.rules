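# Deregulated PDGF signalling in GIST (PDGFRalpha D842V), initial variant.
# 27 nodes / 40 edges; 23 optimisable selection probabilities (H/L flags).
# Reconstructed from the published topology: where the published rule list is
# not available, rules follow canonical PDGFR biology (see docs/methods.md).

# --- clampable inputs -----------------------------------------------------
DOX = 0 , INPUT
Wortmannin = 0 , INPUT
U0126 = 0 , INPUT
GF109 = 0 , INPUT
Go6976 = 0 , INPUT
bPTEN = 1 , INPUT
bPDK = 1 , INPUT

# --- receptor (doxycycline-induced, ERK- and STAT5-mediated feedbacks) ----
mPDGFR = DOX , H
mPDGFR = DOX AND NOT ERK , L
mPDGFR = DOX AND NOT STAT5 , L

# --- STAT5 (SHP2 as negative modulator) -----------------------------------
STAT5 = mPDGFR , H
STAT5 = mPDGFR AND NOT SHP2 , L

# --- MAPK pathway ---------------------------------------------------------
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

# --- PI3K/AKT pathway -----------------------------------------------------
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

# --- PLCgamma/PKC pathway -------------------------------------------------
PLCg = mPDGFR , H
PLCg = SHP2 , L
IP3 = PLCg , FIXED
DAG = PLCg , FIXED
Ca = IP3 , FIXED
PKC = DAG AND Ca AND PDK AND NOT Wortmannin AND NOT GF109 AND NOT Go6976 , FIXED
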