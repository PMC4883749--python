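"""Selection-probability fitting.

The optimisable quantities are the raw weights of H/L-flagged rules, bounded
by flag (H in [0.5, 1], L in [0, 0.5]) so that main-pathway rules always end
up with at least the selection probability of crosstalk rules after per-target
normalisation.  The cost is the sum of squared errors between stationary
output marginals and measured means over all non-missing (condition,
readout) cells of the training data.  Global optimisation is done with
differential evolution (rand/1/bin) or a (mu+lambda) evolutionary algorithm;
every evaluated parameter set is archived so the spread of near-optimal
weights can be analysed afterwards.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from ._kernel import CompiledModel
from .core import Condition, FLAG_BOUNDS, ModelError, PBNModel
from .data import NormalisedDataset
from .steady import EstimatorSettings, estimate_from_compiled, exact_stationary


class ParameterSpace:
    """Flag-constrained encoding of a model's optimisable rule weights."""

    def __init__(self, model: PBNModel):
        self.model = model
        self.entries: list[tuple[str, int]] = model.free_parameters()
        self.flags = [model.rules[t][i].flag for t, i in self.entries]
        self.names = [f"{t}[{i}]:{f}" for (t, i), f in zip(self.entries, self.flags)]
        if self.entries:
            self.bounds = np.array([FLAG_BOUNDS[f] for f in self.flags])
        else:
            self.bounds = np.zeros((0, 2))

    @property
    def dimension(self) -> int:
        return len(self.entries)

    def initial(self) -> np.ndarray:
        """Current model weights clipped into the flag bounds."""
        theta = np.array([self.model.rules[t][i].weight for t, i in self.entries])
        return np.clip(theta, self.bounds[:, 0], self.bounds[:, 1]) if len(theta) else theta

    def clip(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.dimension,):
            raise ValueError(f"expected {self.dimension} parameters, got {theta.shape}")
        clipped = np.clip(theta, self.bounds[:, 0], self.bounds[:, 1])
        if not np.allclose(clipped, theta):
            warnings.warn("parameter vector clipped to flag bounds", stacklevel=2)
        return clipped

    def _raw_by_target(self, theta: np.ndarray) -> dict[str, list[float]]:
        """Raw (pre-normalisation) weights per target: free values from theta,
        FIXED/INPUT rules keep their stored weight as raw value."""
        free = {entry: value for entry, value in zip(self.entries, theta)}
        out: dict[str, list[float]] = {}
        for name in self.model.nodes:
            out[name] = [free.get((name, i), rule.weight)
                         for i, rule in enumerate(self.model.rules[name])]
        return out

    def apply(self, theta: np.ndarray) -> PBNModel:
        """Model with theta written into the optimisable raw weights."""
        theta = self.clip(theta)
        raw = self._raw_by_target(theta)
        rules = []
        for name in self.model.nodes:
            for rule, weight in zip(self.model.rules[name], raw[name]):
                rules.append(replace(rule, weight=weight))
        return self.model.with_rules(rules)

    def flat_weights(self, theta: np.ndarray) -> np.ndarray:
        """Per-rule normalised weights in model rule order (kernel layout)."""
        raw = self._raw_by_target(np.asarray(theta, dtype=float))
        out = []
        for name in self.model.nodes:
            block = np.asarray(raw[name])
            out.append(block / block.sum())
        return np.concatenate(out)

    def normalised_weights(self, theta: np.ndarray) -> np.ndarray:
        """Normalised selection probabilities of the free rules only."""
        raw = self._raw_by_target(np.asarray(theta, dtype=float))
        sums = {name: sum(raw[name]) for name in raw}
        return np.array([raw[t][i] / sums[t] for t, i in self.entries])


def apply_parameters(model: PBNModel, theta: np.ndarray) -> PBNModel:
    """Write a bounded parameter vector into a model's rule weights."""
    return ParameterSpace(model).apply(theta)


# --- cost function --------------------------------------------------------


def _conditions_by_name(conditions: Sequence[Condition] | Mapping[str, Condition]) -> dict[str, Condition]:
    if isinstance(conditions, Mapping):
        return dict(conditions)
    return {c.name: c for c in conditions}


class _ExactConditionCost:
    """Precompiled exact stationary marginals for one condition.

    Rule values over the full state space are tabulated once; a cost
    evaluation only recombines them with the current weights, rebuilds the
    transition matrix and solves the balance equations.
    """

    def __init__(self, model: PBNModel, condition: Condition, outputs: list[str]):
        self.model = model
        self.condition = condition
        P, free = model.transition_matrix(condition)  # validates size via cap
        self.free = free
        nf = len(free)
        m = 1 << nf
        self.n_states = m
        cols = np.arange(m)
        masks = cols[:, None] ^ cols[None, :]
        popcount = np.array([bin(x).count("1") for x in range(m)])
        p = model.p
        kern = p ** popcount * (1.0 - p) ** (nf - popcount)
        kern[0] = 0.0
        self.pert = kern[masks]
        self.no_pert = (1.0 - p) ** nf
        # rule truth values per free node over all states
        base = dict(condition.clamps)
        mappings = []
        for i in range(m):
            mapping = dict(base)
            for j, name in enumerate(free):
                mapping[name] = (i >> j) & 1
            mappings.append(mapping)
        self.rule_values = {}  # node -> (n_rules, m) float array
        for name in free:
            rules = model.rules[name]
            vals = np.array([[r.evaluate(mp) for mp in mappings] for r in rules], dtype=float)
            self.rule_values[name] = vals
        self.outputs = [o for o in outputs if o in free]
        self.clamped_outputs = {o: float(condition.clamps[o])
                                for o in outputs if o in condition.clamps}
        self.bits = {name: (cols >> free.index(name)) & 1 for name in self.free}

    def marginals(self, weights_by_node: dict[str, np.ndarray]) -> dict[str, float]:
        m = self.n_states
        P_rule = np.ones((m, m))
        for j, name in enumerate(self.free):
            q = weights_by_node[name] @ self.rule_values[name]  # (m,)
            bit = self.bits[name][None, :]
            P_rule *= np.where(bit == 1, q[:, None], 1.0 - q[:, None])
        P = self.no_pert * P_rule + self.pert
        A = P.T - np.eye(m)
        A[-1, :] = 1.0
        b = np.zeros(m)
        b[-1] = 1.0
        pi = scipy.linalg.solve(A, b)
        pi = np.clip(pi, 0.0, None)
        pi /= pi.sum()
        out = dict(self.clamped_outputs)
        for name in self.outputs:
            out[name] = float(pi[self.bits[name] == 1].sum())
        return out


class SSECost:
    """Sum-of-squared-error cost of a parameter vector against a dataset.

    Small condition state spaces (``<= exact_cap`` non-clamped nodes) are
    scored with exact stationary marginals, larger ones with the two-state
    sampling estimator.  Sampling seeds are derived from ``base_seed`` plus
    the evaluation index, so a whole fit is reproducible from its seed.
    """

    def __init__(self, model: PBNModel, dataset: NormalisedDataset,
                 conditions: Sequence[Condition] | Mapping[str, Condition],
                 settings: EstimatorSettings = EstimatorSettings(),
                 readout_map: Mapping[str, str] | None = None,
                 method: str = "auto", exact_cap: int = 10, base_seed: int = 0):
        if method not in ("auto", "exact", "sample"):
            raise ValueError(f"unknown method {method!r}")
        self.space = ParameterSpace(model)
        self.settings = settings
        self.base_seed = base_seed
        self.readout_map = dict(readout_map or {})
        by_name = _conditions_by_name(conditions)
        cells: dict[str, list[tuple[str, float]]] = {}
        for cond_name, molecule, mean, _sd in dataset.cells():
            if cond_name not in by_name:
                raise ModelError(f"dataset condition {cond_name!r} has no clamp definition")
            node = self.readout_map.get(molecule, molecule)
            if node not in model.nodes:
                raise ModelError(f"readout {molecule!r} maps to unknown node {node!r}")
            cells.setdefault(cond_name, []).append((node, mean))
        self._jobs = []  # (strategy, evaluator, condition, [(node, mean)])
        for cond_name, pairs in cells.items():
            condition = by_name[cond_name]
            outputs = sorted({node for node, _ in pairs})
            n_free = sum(1 for n in model.nodes if n not in condition.clamps)
            exact = method == "exact" or (method == "auto" and n_free <= exact_cap)
            if exact:
                evaluator = _ExactConditionCost(model, condition, outputs)
            else:
                evaluator = CompiledModel(model, condition)
            self._jobs.append((exact, evaluator, condition, outputs, pairs))
        self.n_cells = sum(len(pairs) for pairs in cells.values())

    def __call__(self, theta: np.ndarray, eval_index: int = 0) -> float:
        flat = self.space.flat_weights(theta)
        by_node = {}
        model = self.space.model
        offset = 0
        for name in model.nodes:
            k = len(model.rules[name])
            by_node[name] = flat[offset:offset + k]
            offset += k
        sse = 0.0
        for job_index, (exact, evaluator, condition, outputs, pairs) in enumerate(self._jobs):
            if exact:
                marg = evaluator.marginals(by_node)
            else:
                evaluator.update_weights(flat)
                seed = (self.base_seed + 7919 * job_index + eval_index) % (2 ** 31)
                est = estimate_from_compiled(evaluator, outputs, self.settings, seed)
                marg = est.marginals
            for node, mean in pairs:
                sse += (marg[node] - mean) ** 2
        return sse


def sse_cost(model: PBNModel, theta: np.ndarray, dataset: NormalisedDataset,
             conditions: Sequence[Condition] | Mapping[str, Condition],
             settings: EstimatorSettings = EstimatorSettings(),
             seed: int = 0, **kwargs) -> float:
    """One-shot SSE evaluation (see :class:`SSECost` for the semantics)."""
    return SSECost(model, dataset, conditions, settings=settings,
                   base_seed=seed, **kwargs)(theta)


# --- optimisers -----------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a fit: best vector plus the full evaluation archive."""

    space: ParameterSpace
    param_names: list[str]
    thetas: np.ndarray          # (n_eval, d) in evaluation order
    sses: np.ndarray            # (n_eval,)
    algorithm: str
    seed: int
    n_eval: int
    settings: EstimatorSettings = field(default_factory=EstimatorSettings)

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.sses)) if len(self.sses) else 0

    @property
    def best_theta(self) -> np.ndarray:
        return self.thetas[self.best_index] if len(self.sses) else np.zeros(0)

    @property
    def best_sse(self) -> float:
        return float(self.sses[self.best_index]) if len(self.sses) else float("nan")

    def best_model(self) -> PBNModel:
        return self.space.apply(self.best_theta) if self.space.dimension else self.space.model

    def archive_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.thetas, columns=self.param_names)
        frame.insert(0, "sse", self.sses)
        frame.insert(0, "eval", np.arange(len(self.sses)))
        return frame

    def to_json(self) -> str:
        return json.dumps({
            "algorithm": self.algorithm, "seed": self.seed, "n_eval": self.n_eval,
            "param_names": self.param_names,
            "best_theta": self.best_theta.tolist(),
            "best_sse": self.best_sse,
            "best_normalised_weights": self.space.normalised_weights(self.best_theta).tolist()
            if self.space.dimension else [],
        }, indent=2)

    def save(self, path: str | Path, archive: bool = True) -> None:
        path = Path(path)
        path.write_text(self.to_json())
        if archive:
            self.archive_frame().to_csv(path.with_suffix(".archive.csv"), index=False)


def _sample_population(rng: np.random.Generator, bounds: np.ndarray, size: int) -> np.ndarray:
    lo, hi = bounds[:, 0], bounds[:, 1]
    return lo + rng.random((size, len(lo))) * (hi - lo)


def fit(model: PBNModel, dataset: NormalisedDataset,
        conditions: Sequence[Condition] | Mapping[str, Condition],
        algorithm: str = "de", n_eval: int = 5000, seed: int = 0,
        settings: EstimatorSettings = EstimatorSettings(),
        readout_map: Mapping[str, str] | None = None,
        method: str = "auto", exact_cap: int = 10,
        de_F: float = 0.8, de_CR: float = 0.9, pop_cap: int = 40,
        ea_mu: int = 10, ea_lambda: int = 20, ea_sigma: float = 0.1,
        init: np.ndarray | None = None, init_jitter: float = 0.05) -> FitResult:
    """Fit the optimisable selection probabilities to a training dataset.

    ``algorithm`` is ``"de"`` (differential evolution, rand/1/bin, F=0.8,
    CR=0.9, population 10 x dimension capped at ``pop_cap``) or ``"ea"``
    ((mu+lambda) with Gaussian mutation of scale ``ea_sigma`` times the bound
    range).  Exactly ``n_eval`` cost evaluations are archived.  Reproducible
    for a fixed seed.

    ``init`` warm-starts the optimiser: the given vector(s) are placed in
    the initial population and the remaining members are drawn around them
    with Gaussian jitter of ``init_jitter`` times the bound range — used to
    refine a coarse fit at tighter estimator precision.
    """
    algorithm = algorithm.lower()
    if algorithm not in ("de", "ea"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    cost = SSECost(model, dataset, conditions, settings=settings,
                   readout_map=readout_map, method=method,
                   exact_cap=exact_cap, base_seed=seed)
    space = cost.space
    d = space.dimension
    if d == 0:
        value = cost(np.zeros(0))
        return FitResult(space, [], np.zeros((1, 0)), np.array([value]),
                         algorithm, seed, 1, settings)

    rng = np.random.default_rng(seed)
    bounds = space.bounds
    lo, hi = bounds[:, 0], bounds[:, 1]
    thetas = np.empty((n_eval, d))
    sses = np.empty(n_eval)
    evals = 0

    def evaluate(theta: np.ndarray) -> float:
        nonlocal evals
        theta = np.clip(theta, lo, hi)
        value = cost(theta, evals)
        thetas[evals] = theta
        sses[evals] = value
        evals += 1
        return value

    def initial_population(size: int) -> np.ndarray:
        if init is None:
            return _sample_population(rng, bounds, size)
        seeds_arr = np.atleast_2d(np.asarray(init, dtype=float))
        scale = init_jitter * (hi - lo)
        rows = [np.clip(row, lo, hi) for row in seeds_arr[:size]]
        while len(rows) < size:
            base_row = seeds_arr[rng.integers(len(seeds_arr))]
            rows.append(np.clip(base_row + rng.normal(0.0, scale), lo, hi))
        return np.array(rows)

    if algorithm == "de":
        pop_size = max(4, min(10 * d, pop_cap, n_eval))
        pop = initial_population(pop_size)
        pop_cost = np.array([evaluate(x) for x in pop])
        while evals < n_eval:
            for i in range(pop_size):
                if evals >= n_eval:
                    break
                choices = [j for j in range(pop_size) if j != i]
                r1, r2, r3 = rng.choice(choices, size=3, replace=False)
                mutant = pop[r1] + de_F * (pop[r2] - pop[r3])
                cross = rng.random(d) < de_CR
                cross[rng.integers(d)] = True
                trial = np.where(cross, mutant, pop[i])
                trial = np.clip(trial, lo, hi)
                value = evaluate(trial)
                if value <= pop_cost[i]:
                    pop[i] = trial
                    pop_cost[i] = value
    else:
        mu, lam = max(2, min(ea_mu, n_eval)), ea_lambda
        parents = initial_population(mu)
        parent_cost = np.array([evaluate(x) for x in parents])
        scale = ea_sigma * (hi - lo)
        while evals < n_eval:
            children, child_cost = [], []
            for _ in range(min(lam, n_eval - evals)):
                parent = parents[rng.integers(mu)]
                child = np.clip(parent + rng.normal(0.0, scale), lo, hi)
                children.append(child)
                child_cost.append(evaluate(child))
            allx = np.vstack([parents, np.array(children)])
            allc = np.concatenate([parent_cost, np.array(child_cost)])
            order = np.argsort(allc, kind="stable")[:mu]
            parents, parent_cost = allx[order], allc[order]

    return FitResult(space, space.names, thetas[:evals], sses[:evals],
                     algorithm, seed, evals, settings)


def summarize_top(result: FitResult, k: int = 500) -> pd.DataFrame:
    """Mean and SD of normalised weights over the best-k archived vectors.

    Vectors are ranked by SSE ascending with ties broken by evaluation
    order; statistics are computed on the per-target normalised selection
    probabilities, not the raw bounded values.
    """
    total = len(result.sses)
    if k > total:
        warnings.warn(f"k={k} exceeds archive size {total}; using the full archive")
        k = total
    order = np.argsort(result.sses, kind="stable")[:k]
    if result.space.dimension == 0:
        return pd.DataFrame(columns=["parameter", "mean", "sd"])
    weights = np.array([result.space.normalised_weights(result.thetas[i]) for i in order])
    return pd.DataFrame({
        "parameter": result.param_names,
        "mean": weights.mean(axis=0),
        "sd": weights.std(axis=0, ddof=1) if k > 1 else np.zeros(weights.shape[1]),
    })
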