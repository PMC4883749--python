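# pbnfit

Contextualisation of signalling networks with steady-state protein data
using probabilistic Boolean networks (PBNs).

Quantitative steady-state readouts — normalised Western-blot intensities,
phospho-proteomic panels — sit awkwardly between modelling frameworks:
plain Boolean networks are too coarse to capture partial inhibition, while
ODE models demand kinetic detail such data cannot constrain.  A PBN assigns
each molecule several Boolean predictor rules, one selected at random per
update according to *selection probabilities*; the stationary distribution
of the resulting Markov chain yields a continuous ON-probability per
molecule that can be compared directly to normalised data in [0, 1].  The
fitted selection probabilities quantify the relative strength of competing
routes — main pathways, crosstalks, inhibitor actions — with a minimal
parameterisation.

`pbnfit` implements the full pipeline around that idea, packaged with a
reconstructed case study of deregulated PDGF signalling in gastrointestinal
stromal tumour (GIST: the constitutively active PDGFRα D842V receptor, its
MAPK, PI3K/AKT and PLCγ/PKC pathways, STAT5, receptor-site knockout mutants
and four kinase inhibitors) and a synthetic-data generator so every stage
is testable without external downloads.

## The model and the method

* **Semantics** — a synchronous, independent PBN over binary nodes
  x₁…x_n.  Each node *i* carries rules f_i1…f_im with weights
  (selection probabilities) c_ij, Σ_j c_ij = 1.  A per-node perturbation
  probability *p* flips random nodes; if any node is perturbed the network
  function is skipped that step.  With p > 0 the chain is irreducible and
  aperiodic, so a unique stationary distribution π exists regardless of the
  initial state.  Experimental treatments are *clamps*: nodes held constant
  and exempt from update and perturbation.
* **Steady state** — exact solution of πP = π on small (≤ 2¹⁴ states)
  clamped networks as an oracle, and the two-state Markov chain estimator
  for realistic sizes: from a trace's 0↔1 transition rates (α, β) it
  computes the burn-in m and sample count N needed to estimate the
  ON-probability within half-width r (default 0.025) at coverage s
  (default 0.95), then extends the trajectory until the plan is satisfied.
* **Fitting** — cost SSE = Σ (simulated marginal − measured mean)² over all
  non-missing (condition, readout) cells; flag-constrained weights
  (main-pathway rules H ∈ [0.5, 1], crosstalk rules L ∈ [0, 0.5]) fitted by
  differential evolution or a (μ+λ) evolutionary algorithm, every evaluated
  parameter set archived for best-k spread analysis.
* **Model selection** — candidate crosstalks added one-at-a-time or
  pairwise as extra L rules and refitted; variants ranked by SSE,
  least-squares AIC = n·ln(SSE/n) + 2k and the F-test of nested regression
  models.
* **Prediction** — a model fitted on single perturbations is scored on
  combined perturbations: a cell counts as correct when the simulated value
  lies within the measurement's standard deviation.

## Worked example

`examples/04_pdgf_case_study.py` loads the final contextualised PDGF-GIST
model and simulates four treatment conditions:

```
condition              pSTAT5   pPDGFR    pPLCg     pERK     pAKT
ND                      0.000    0.000    0.002    0.006    0.089
DV-WT                   0.842    0.926    0.915    0.726    0.567
DV-WT+Wortmannin        0.851    0.934    0.930    0.582    0.131
DV-WT+U0126             0.867    0.957    0.953    0.002    0.588
```

Each number is the stationary probability of the phospho-form being ON —
the model's analogue of a normalised blot intensity.  Doxycycline
induction (DV-WT) switches the network on; Wortmannin suppresses pAKT
(0.567 → 0.131) and, through the fitted PI3K → MEK1,2 crosstalk (selection
probability 0.226 vs 0.774 for the canonical Raf route), also lowers pERK
(0.726 → 0.582); U0126 abolishes pERK while leaving receptor-proximal
readouts intact.  The other example scripts cover steady-state estimation
against the exact oracle, weight fitting on synthetic truths, crosstalk
scanning, and the raw-blot normalisation pipeline; each prints its numbers
with a short interpretation.

A thin CLI mirrors the stages (`pbnfit simulate|fit|scan|predict|synth|run-study`),
e.g.

```bash
pbnfit synth --n-nodes 6 --out-dir problem
pbnfit fit --model problem/truth.rules --data problem/data.csv \
           --conditions problem/conditions.csv --n-eval 2000 --seed 1
```

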