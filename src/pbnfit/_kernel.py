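"""JIT-compiled trajectory simulation.

A :class:`PBNModel` plus a condition is flattened into integer/float arrays
(per-rule truth tables over parent indices, cumulative selection weights,
clamp values) and stepped by a numba kernel.  The kernel implements the exact
step semantics of :meth:`pbnfit.core.PBNModel.step`: per-node Bernoulli(p)
perturbation draws, pure-flip transitions whenever at least one node is
perturbed, otherwise an independent synchronous rule-selection update, with
clamped nodes exempt from both.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .core import Condition, PBNModel, UNCONSTRAINED
from .expr import truth_table


@njit(cache=False)
def _simulate(cur, n_steps, p, clamped, rule_ptr, cumw,
              parent_ptr, parent_cnt, parents, table_ptr, tables,
              out_idx, out, seed):  # pragma: no cover - exercised via wrapper
    np.random.seed(seed)
    n = cur.shape[0]
    nxt = np.empty_like(cur)
    for t in range(n_steps):
        for i in range(n):
            nxt[i] = cur[i]
        perturbed = False
        for i in range(n):
            if clamped[i] >= 0:
                continue
            if np.random.random() < p:
                nxt[i] = 1 - cur[i]
                perturbed = True
        if not perturbed:
            for i in range(n):
                if clamped[i] >= 0:
                    continue
                r0 = rule_ptr[i]
                r1 = rule_ptr[i + 1]
                r = r1 - 1
                if r1 - r0 > 1:
                    u = np.random.random()
                    for k in range(r0, r1):
                        if u < cumw[k]:
                            r = k
                            break
                else:
                    r = r0
                idx = 0
                p0 = parent_ptr[r]
                for b in range(parent_cnt[r]):
                    idx |= cur[parents[p0 + b]] << b
                nxt[i] = tables[table_ptr[r] + idx]
        for j in range(out_idx.shape[0]):
            out[t, j] = nxt[out_idx[j]]
        for i in range(n):
            cur[i] = nxt[i]
    return cur


class CompiledModel:
    """Array form of one (model, condition) pair for the numba kernel.

    The structural arrays are built once; :meth:`update_weights` refreshes
    only the cumulative selection weights, which is what repeated cost
    evaluations during fitting need.
    """

    def __init__(self, model: PBNModel, condition: Condition = UNCONSTRAINED):
        self.model = model
        self.condition = condition
        nodes = model.nodes
        index = {name: i for i, name in enumerate(nodes)}
        self.clamped = np.full(len(nodes), -1, dtype=np.int8)
        for name, value in condition.clamps.items():
            self.clamped[index[name]] = value

        rule_ptr = [0]
        parent_ptr, parent_cnt, parents_flat = [], [], []
        table_ptr, tables_flat = [], []
        self._rule_order: list[tuple[str, int]] = []
        for name in nodes:
            for k, rule in enumerate(model.rules[name]):
                self._rule_order.append((name, k))
                rule_parents = sorted(rule.parents)
                parent_ptr.append(len(parents_flat))
                parent_cnt.append(len(rule_parents))
                parents_flat.extend(index[q] for q in rule_parents)
                table_ptr.append(len(tables_flat))
                tables_flat.extend(truth_table(rule.expression, rule_parents))
            rule_ptr.append(len(self._rule_order))
        self.rule_ptr = np.asarray(rule_ptr, dtype=np.int64)
        self.parent_ptr = np.asarray(parent_ptr, dtype=np.int64)
        self.parent_cnt = np.asarray(parent_cnt, dtype=np.int64)
        self.parents = np.asarray(parents_flat, dtype=np.int64)
        self.table_ptr = np.asarray(table_ptr, dtype=np.int64)
        self.tables = np.asarray(tables_flat, dtype=np.uint8)
        self.cumw = np.empty(len(self._rule_order))
        self.update_weights([model.rules[t][k].weight for t, k in self._rule_order])
        self.p = model.p

    def update_weights(self, weights) -> None:
        """Replace per-rule selection weights (normalised per target)."""
        weights = np.asarray(weights, dtype=float)
        for i in range(len(self.rule_ptr) - 1):
            lo, hi = self.rule_ptr[i], self.rule_ptr[i + 1]
            block = weights[lo:hi]
            self.cumw[lo:hi] = np.cumsum(block / block.sum())

    def run(self, state: np.ndarray, n_steps: int, out_nodes: list[str],
            seed: int) -> tuple[np.ndarray, np.ndarray]:
        """Simulate ``n_steps`` transitions from ``state``.

        Returns ``(trace, end_state)`` where ``trace`` has shape
        ``(n_steps, len(out_nodes))`` holding the post-step values of the
        requested nodes.
        """
        index = {name: i for i, name in enumerate(self.model.nodes)}
        out_idx = np.asarray([index[name] for name in out_nodes], dtype=np.int64)
        out = np.empty((n_steps, len(out_nodes)), dtype=np.uint8)
        cur = np.asarray(state, dtype=np.uint8).copy()
        end = _simulate(cur, n_steps, self.p, self.clamped, self.rule_ptr,
                        self.cumw, self.parent_ptr, self.parent_cnt,
                        self.parents, self.table_ptr, self.tables,
                        out_idx, out, np.uint32(seed % (2 ** 31)))
        return out, end
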