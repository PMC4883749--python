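# Methods

## Model semantics

`pbnfit` implements independent, synchronous probabilistic Boolean networks
with random perturbation.  A model is a set of nodes, each with one or more
Boolean predictor rules (AND/OR/NOT over parent nodes, constants 0/1) and a
selection probability per rule, normalised per node.  One step of the chain:

1. every non-clamped node draws an independent Bernoulli(p) perturbation
   indicator;
2. if at least one fires, the next state is the current state with exactly
   the perturbed nodes flipped — the network function is *not* applied;
3. otherwise every non-clamped node independently selects one of its rules
   with probability equal to its weight and takes the rule's value.

Clamped nodes (experimental inputs, inhibitors, knocked-out recruitment
sites) are exempt from both update and perturbation, so a condition is a
well-defined restriction of the chain.  With p > 0 the chain on the
non-clamped state space is primitive, hence has a unique stationary
distribution; the package's default p = 0.001 perturbs each marginal by at
most ~p while guaranteeing ergodicity.  p lives on the model; estimator
settings carry it only for configuration plumbing.

Assumptions worth stating: rule selection is independent across nodes and
steps (an "independent PBN" — no context switching), updates are
synchronous, and perturbation is a pure state flip.  These are the standard
conventions for steady-state contextualisation of signalling networks; none
of them is fitted.

## Steady-state estimation

Two routes, deliberately independent of each other so one can test the
other:

* **Exact** (`exact_stationary`): the transition matrix over the non-clamped
  state space marginalises rule selection (per-node ON-probabilities
  combined by outer product) and perturbation (XOR kernel with mass
  p^k (1−p)^(n−k)); the stationary vector solves the balance equations by
  dense LU (p > 0 guarantees uniqueness; p = 0 falls back to a null-space
  computation and raises if the invariant space has dimension > 1).  Cost
  grows as 4^n_free; the cap defaults to 14 free nodes, and a size error
  directs larger problems to the sampler.  Tests require the fixed-point
  residual ‖πP − π‖∞ < 1e-10.

* **Sampling** (`estimate_marginals`): the two-state Markov chain
  diagnostic.  A pilot trajectory (default 1,000 steps) yields each binary
  output trace's empirical transition rates α (0→1) and β (1→0); the plan
  is

      m = ⌈ log(ε(α+β)/max(α,β)) / log|1−α−β| ⌉         (burn-in)
      N = ⌈ αβ(2−α−β)/(α+β)³ · (z/r)² ⌉                  (samples)

  with z the normal quantile at (1+s)/2, ε = 0.001 the burn-in tolerance
  (the source method's convention; not stated by the study), defaults
  r = 0.025 and s = 0.95.  All outputs share one trajectory; the trajectory
  grows until the largest plan is satisfied, re-estimating (α, β) from all
  collected samples each round (at most `max_iterations` = 10 rounds, after
  which the estimate is returned flagged unconverged).  Degenerate pilots
  (α or β outside (0, 1), e.g. a constant trace) fall back to the
  conservative worst case α = β = 0.5.  Worked values pin the
  implementation: N = 1537 at α = β = 0.5, r = 0.025, s = 0.95;
  m = 28 at α = β = 0.1, ε = 0.001; N = 13830 at α = β = 0.1 (the direct
  evaluation of the formula; an off-by-one quote of 13831 circulates and is
  wrong).  Clamped outputs short-circuit to their clamp value.

Trajectories are generated by a numba-compiled kernel over a flattened
model representation (per-rule truth tables over parent indices, cumulative
weights); the kernel reproduces the Python `step()` semantics exactly, which
a property test checks against the exact transition matrix at 3 binomial
standard errors.

## Normalisation of raw blot data

The pipeline for raw intensities mirrors standard quantitative Western-blot
practice: (1) discard points whose loading-control (tubulin) signal is
below 20% of the maximum on the same blot; (2) divide signal by tubulin;
(3) divide by the calibrator sample of the same blot and molecule (a
cross-blot reference lysate; a `calibrate=False` variant skips this for
experiments quantified without one); (4) average technical replicates
within each biological replicate; (5) pool biological means and divide by
the per-molecule maximum, reporting the pooled mean and sample SD (n−1
denominator, scaled by the same maximum).  QC and calibration are strictly
per-blot; rescaling a whole blot leaves the output invariant (property
test).  Cells whose every point was discarded are *absent*, never imputed,
and the fitting cost skips them.  Negative-control readouts are fixed to
zero by convention rather than measured.

## Fitting

Optimisable weights are the H/L-flagged rules; raw values are bounded by
flag (H ∈ [0.5, 1], L ∈ [0, 0.5]) so that after per-node normalisation a
main-pathway rule can never fall below a crosstalk rule on the same node.
FIXED and INPUT rules keep their stored weights.  Out-of-bounds proposals
are clipped with a warning.

The SSE cost evaluates each condition with the exact solver when the
clamped network has ≤ 10 free nodes and with the sampler otherwise;
sampling seeds derive from the fit seed plus the evaluation index, so a fit
is bit-reproducible from its seed while successive evaluations see fresh
noise.  Two optimisers are provided, both archiving every evaluation
(archive size equals the budget exactly):

* differential evolution, rand/1/bin, F = 0.8, CR = 0.9, population
  10×dimension capped at 40;
* a (μ+λ) evolutionary algorithm, μ = 10, λ = 20, Gaussian mutation with
  σ = 0.1 of the bound range.

These hyperparameters are conventional defaults (the algorithms' names are
fixed by the pipeline, their settings were not) and are all exposed.  A fit
can be warm-started (`init=`): the supplied vectors seed the initial
population with Gaussian jitter (5% of range).  This enables the
coarse-to-fine protocol used for the case-study refit: a broad search at
relaxed estimator precision (r = 0.05, s = 0.9) followed by refinement at
r = 0.0125 from the coarse optimum — tight precision is wasted on random
vectors and coarse precision cannot resolve the last ~0.001 of SSE.
`summarize_top` reports mean and SD of the *normalised* weights over the
best-k archived vectors (SSE ascending, ties by evaluation order).

## Crosstalk model selection

A candidate interaction enters the base model as one extra rule with flag L
(raw weight 0.25, the centre of the L range, before refitting):

* activation: `target = source`, additionally gated by `NOT i` for every
  inhibitor input *i* that is negated in **all** existing rules of the
  target.  Rationale: a kinase inhibitor blocks the target molecule's
  activity whichever route activated it — an activation crosstalk onto MEK
  must stay U0126-sensitive.
* inhibition: `target = (main expression) AND NOT source`, the main
  expression being the target's highest-priority existing rule.

If the target previously had a single FIXED rule, that rule is promoted to
H so that both weights become free (k grows by 2); otherwise k grows by 1.
A candidate duplicating an existing edge is rejected.  Variants are ranked
by best SSE, by AIC = n·ln(SSE/n) + 2k (n = non-missing training cells,
k = free weights — this least-squares form reproduces the case study's
published AIC values exactly at (n, k) = (30, 23) and (33, 25)), and by
the F-test of nested regression models with (k_full−k_base, n−k_full)
degrees of freedom.  A scan can run several optimisation rounds per
variant (`n_repeats`) and keep the best, which is how multi-round
optimisation protocols are mirrored.

## The PDGF-GIST case study

The packaged network describes doxycycline-inducible, constitutively
active PDGFRα D842V in Hek293 Flp-In cells: the receptor (with ERK- and
STAT5-mediated negative feedback), SHP2/Grb2-SOS/Gab-SOS/Ras/Raf/MEK/ERK,
PI3K recruitment (a dedicated PI3Krec node so the YY731/742FF knockout can
clamp recruitment while leaving the catalytic node addressable by
crosstalks), PI3K/PIP3/PTEN/PDK/AKT with constitutive bPTEN/bPDK inputs,
PLCγ/IP3/DAG/Ca/PKC, STAT5, and four inhibitor inputs (Wortmannin → PI3K
with an off-target on PKC, U0126 → MEK, GF109203X and Gö6976 → PKC).

Three variants ship as rule files: `initial` (27 nodes, 40 edges counted
as distinct source→target dependencies, 23 free weights), `refined` (adds
a receptor-independent basal-PKC rule, still inhibitable by the PKC
inhibitors; 25 free weights) and `final` (refined plus the PI3K → MEK1,2
crosstalk, gated by NOT U0126; 27 free weights).  The condition catalogue
holds the 10 modelling conditions (6 single-perturbation/control training,
4 combined-perturbation validation; knockouts clamp SHP2 or PI3Krec OFF,
inhibitors clamp their input ON) plus the three PKC-inhibitor conditions
of the follow-up experiment, and the 9 literature-proposed crosstalk
candidates.

**Provenance.** The published account fixes the topology sketch, the
node/edge counts, the H/L flag discipline, the gate conventions (OR for
non-exclusive inputs, AND-NOT for inhibition), the variant progression and
the free-weight counts; the full per-node rule list is in supplementary
material that is not redistributable.  Where the rules are not pinned they
were reconstructed once from canonical PDGFR biology — ERK-mediated
feedback on SOS, Gab1 and Raf; SHP2's contribution to PLCγ and STAT5
regulation; PDK1 priming of conventional PKC — under three published
behavioural constraints: the knockout mutants reduce their pathway only
partially (hence Ras mixes its two SOS inputs probabilistically rather
than by OR), the initial variant must have *no* path from Wortmannin to
ERK (this forced the receptor feedbacks to be ERK- and STAT5-mediated, not
PKC-mediated), and U0126 inhibition of ERK is essentially complete (hence
the inhibitor gate on the MEK crosstalk rule).  This reconstruction is a
faithful model *of the same system*, not a copy of the original rule file.

The `final` rule file carries the packaged reference weights used by the
stand-in data generator: the MEK crosstalk/main pair (0.226/0.774), the
Wortmannin→PI3K pair (0.893/0.107) and the basal-PKC pair (0.997/0.003)
are the published interaction strengths; all other weights are synthetic
placeholders chosen once inside their flag bounds to give every readout a
usable dynamic range.  Two further published strengths — U0126 on MEK
(0.851) and the Wortmannin off-target on PKC (0.152) — cannot be
represented as free weights without breaking the 23/25/27 free-parameter
progression; in this reconstruction both inhibitions are all-or-none terms
inside existing rules.

**Stand-in data.** `synthetic_study_dataset` simulates the reference model
under the 10 conditions (estimator at r = 0.0125), forces the
negative-control phospho readouts to zero by the convention above, adds
truncated Gaussian noise, and labels the cells with the base (30 training)
or refined (33 training, adding the three pPKC cells) split.  It is
synthetic data with the study's layout — value range, condition panel,
readout set, noise scale — generated by the package itself.  Consequences:
re-fitting it can test weight recovery and prediction logic, but it cannot
reproduce the study's absolute fitting costs, which reflect real
measurement error; those numbers are out of reach without the original
data.

## Synthetic-data generator

`generate_random_pbn` draws layered networks (parents from topological
predecessors, 1–2 rules per node, H/L pairs with raw weights in
[0.55, 0.95] / [0.05, 0.45]) with one or two clampable inputs;
`default_conditions` enumerates input clamp patterns and then adds
knockout-style internal clamps, mimicking a mutant panel.  Defaults mirror
the case study's scale: ~10 conditions, 5 readouts, noise SD 0.1 (the
0.05–0.15 band of typical normalised blot spread).  What the generator
does *not* emulate: blot-level artefacts (loading variation, saturation),
correlated noise across readouts, and the max-normalisation coupling
between conditions — so passing recovery tests demonstrate estimator and
optimiser correctness, not robustness to real-world measurement structure.

`recovery_experiment` reports per-weight recovery together with an
identifiability flag: a weight counts as identifiable when sweeping it
across its full flag range (others at truth) moves at least one noiseless
data cell by ≥ 0.2 (≈ 4× the default noise SD — a weight below that moves
the data less than the noise and cannot be pinned).  Recovery claims are
made for identifiable weights; unidentifiable ones are reported, not
asserted on.

## Problem sizes used by tests and the acceptance script

Chosen as the package's standard verification scale: oracle coverage on
four ≤ 4-node networks × 200 (tests) / 50 (script) seeded repeats;
parameter recovery on twenty 5-node truths at noise SD 0.05 with DE budget
2,000; planted-crosstalk scans over 10 runs at budget 400; the case-study
refit as a coarse-to-fine 4,000 + 1,500-evaluation protocol; the refined
nine-candidate scan at 1,500 evaluations × 2 rounds per variant.  One full
acceptance run takes ≈ 6 minutes on a single core.

## Known limitations

* The Wortmannin→PI3K strength is the most weakly identified published
  weight under the stand-in conditions: its training signal concentrates
  in a single Wortmannin pERK cell plus partially compensable pAKT chains
  (a high-precision probe shows the truth beating the best compensated
  solution by only ~0.001 SSE).  The fixed-seed verification recovers it
  within 0.04; across other generator seeds the error can reach ~0.16.
* The published claim that *only* the two PI3K→MAPK crosstalks improve the
  refined fit holds here as a ranking (they take the two best costs by a
  clear margin) but not as strict exclusivity: PIP3→Gab-SOS carries a
  weak genuine PI3K→MAPK channel in this reconstruction because Ras mixes
  its SOS inputs probabilistically.
* Absolute study fitting costs (0.198/0.130/0.208/0.162) require the
  original measurement data and are not reproduced.
* Context-sensitive PBNs (switching probability q), asynchronous updates
  and attractor analysis of deterministic Boolean networks are out of
  scope.
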