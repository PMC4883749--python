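"""The packaged PDGF-GIST case study: simulating treatment conditions.

Loads the final contextualised model of deregulated PDGF signalling
(PDGFRalpha D842V in Hek293 Flp-In cells) and prints the steady-state
phosphorylation levels it predicts for the positive control and the two
MEK/PI3K inhibitor treatments, next to the untreated negative control.
"""

from pbnfit import estimate_marginals
from pbnfit import pdgf

model = pdgf.reference_model()
conditions = {c.name: c for c in pdgf.build_conditions()}
readout_nodes = dict(pdgf.READOUT_NODES)

header = f"{'condition':20s}" + "".join(f"{m:>9s}" for m in pdgf.READOUTS)
print(header)
for name in ("ND", "DV-WT", "DV-WT+Wortmannin", "DV-WT+U0126"):
    nodes = [readout_nodes[m] for m in pdgf.READOUTS]
    est = estimate_marginals(model, conditions[name], nodes, seed=11)
    row = f"{name:20s}" + "".join(f"{est[n]:9.3f}" for n in nodes)
    print(row)
print()
print("Each value is the stationary probability of the phospho-form being")
print("ON, the model's analogue of a normalised Western-blot intensity.")
print("Wortmannin (PI3K inhibitor) lowers pAKT and - through the PI3K->MEK1,2")
print("crosstalk - also pERK; U0126 abolishes pERK while the other readouts")
print("track receptor activity; without doxycycline (ND) everything is dark.")
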