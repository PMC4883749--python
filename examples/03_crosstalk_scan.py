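"""Re-discovering a planted crosstalk by one-at-a-time model scanning.

Two independent input-driven cascades are simulated with a hidden
activating crosstalk X -> Y (selection probability 0.3).  Each candidate
interaction is added to the crosstalk-free base model as an extra L rule,
the weights are refit, and the variants are ranked by SSE, least-squares
AIC and an F-test against the base.
"""

from pbnfit import comparison_table, crosstalk_scan
from pbnfit.selection import add_crosstalk
from pbnfit.synth import planted_crosstalk_problem, simulate_dataset

base, true_candidate, decoys, conditions, readouts = planted_crosstalk_problem()
truth = add_crosstalk(base, true_candidate, raw_weight=0.3)
data = simulate_dataset(truth, conditions, readouts, noise_sd=0.05, seed=3)

rows = crosstalk_scan(base, [true_candidate, *decoys], data, conditions,
                      mode="single", n_eval=400, seed=3)
table = comparison_table(rows)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
winner = min(rows[1:], key=lambda r: r.sse)
print(f"\nscan winner: variant {winner.variant} ({winner.description})")
print("The planted interaction (candidate 1, X -> Y) attains the lowest")
print("fitting cost and AIC; decoys cannot explain why Y is elevated when")
print("only pathway 1 is stimulated, so they stay at the base-model cost.")
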