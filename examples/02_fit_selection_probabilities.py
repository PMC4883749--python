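"""Recovering selection probabilities from noisy steady-state data.

A random 5-node ground-truth PBN is simulated under a panel of clamp
conditions; Gaussian noise (SD 0.05) mimics normalised Western-blot spread.
Differential evolution then refits the H/L-bounded rule weights from the
noisy dataset alone, and the recovered values are compared with the truth.
"""

from pbnfit import fit
from pbnfit.fitting import ParameterSpace
from pbnfit.synth import (SyntheticSpec, default_conditions,
                          generate_random_pbn, simulate_dataset)

spec = SyntheticSpec(n_nodes=5, noise_sd=0.05, seed=7)
truth = generate_random_pbn(spec)
conditions = default_conditions(truth, n_conditions=10, seed=7)
readouts = [n for n in truth.nodes if n not in truth.input_nodes()]
data = simulate_dataset(truth, conditions, readouts, noise_sd=0.05, seed=7)

result = fit(truth, data, conditions, algorithm="de", n_eval=2000, seed=1)
space = ParameterSpace(truth)
true_weights = space.normalised_weights(space.initial())
recovered = result.space.normalised_weights(result.best_theta)

print(f"best SSE after {result.n_eval} evaluations: {result.best_sse:.4f}")
print(f"{'parameter':16s} {'truth':>6s} {'fit':>6s} {'error':>6s}")
for name, t, r in zip(space.names, true_weights, recovered):
    print(f"{name:16s} {t:6.3f} {r:6.3f} {abs(t - r):6.3f}")
print("Each row is one optimisable rule weight (H = main route, L = minor");
print("route). Identifiable weights come back within ~0.1 at this noise level.")
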