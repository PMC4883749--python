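"""Crosstalk model selection: AIC, F-test, one-at-a-time and pairwise scans.

Candidate crosstalk interactions are added to a base network one at a time
(or in pairs), the selection probabilities are refit, and the variants are
ranked by fitting cost, least-squares AIC and an F-test against the nested
base model.  A candidate always enters with the low-priority flag L so that
it can never dominate the canonical route it feeds into.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import scipy.stats

from .core import BooleanRule, Condition, ModelError, PBNModel
from .data import NormalisedDataset
from .expr import Not, And, Var
from .fitting import FitResult, fit
from .steady import EstimatorSettings


def aic(sse: float, n: int, k: int) -> float:
    """Akaike information criterion for a least-squares model:
    ``n * ln(SSE / n) + 2k``.

    ``n`` counts fitted data points, ``k`` optimised parameters.  A perfect
    fit (SSE = 0) returns ``-inf`` with a warning.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if sse < 0:
        raise ValueError("SSE cannot be negative")
    if sse == 0:
        warnings.warn("SSE is exactly zero; AIC is -inf")
        return -math.inf
    return n * math.log(sse / n) + 2 * k


def f_test(sse_base: float, k_base: int, sse_full: float, k_full: int,
           n: int) -> tuple[float, float]:
    """F-test of a full regression model against a nested base model.

    ``F = ((SSE_base - SSE_full) / (k_full - k_base)) / (SSE_full / (n - k_full))``
    with p from the F distribution at (k_full - k_base, n - k_full) degrees
    of freedom.  A negative F (the richer model fitting worse, possible with
    a stochastic optimiser at finite budget) is returned as-is with a
    warning; its p-value is 1.
    """
    if k_full <= k_base:
        raise ValueError("full model must have more parameters than the base")
    if n <= k_full:
        raise ValueError("need more data points than parameters for the F-test")
    df1, df2 = k_full - k_base, n - k_full
    if sse_full == 0:
        return math.inf, 0.0
    F = ((sse_base - sse_full) / df1) / (sse_full / df2)
    if F < 0:
        warnings.warn("full model fits worse than base (optimiser noise); F < 0")
    p = float(scipy.stats.f.sf(F, df1, df2))
    return F, p


@dataclass(frozen=True)
class CrosstalkCandidate:
    """A literature-proposed crosstalk edge to be tested on the base model."""

    index: int
    source: str
    target: str
    sign: str  # "activation" or "inhibition"

    def __post_init__(self):
        if self.sign not in ("activation", "inhibition"):
            raise ValueError(f"sign must be activation or inhibition, got {self.sign!r}")

    @property
    def label(self) -> str:
        arrow = "->" if self.sign == "activation" else "-|"
        return f"{self.source} {arrow} {self.target}"


def read_candidates_csv(path: str | Path) -> list[CrosstalkCandidate]:
    df = pd.read_csv(path)
    return [CrosstalkCandidate(int(r.index), str(r.source), str(r.target), str(r.sign))
            for r in df.rename(columns=str.lower).itertuples(index=False)]


def _common_inhibitor_gates(model: PBNModel, target: str) -> list[str]:
    """Clampable inputs negated in *every* existing rule of ``target``.

    Such an input inhibits the target molecule's activity itself (e.g. a
    kinase inhibitor), so any new activation route must stay sensitive to
    it.
    """
    inputs = set(model.input_nodes())
    common: set[str] | None = None
    for rule in model.rules[target]:
        negated = {node.operand.name
                   for node in _walk(rule.expression)
                   if isinstance(node, Not) and isinstance(node.operand, Var)}
        negated &= inputs
        common = negated if common is None else common & negated
    return sorted(common or ())


def _walk(expression):
    yield expression
    for attr in ("operand", "left", "right"):
        child = getattr(expression, attr, None)
        if child is not None:
            yield from _walk(child)


def add_crosstalk(model: PBNModel, candidate: CrosstalkCandidate,
                  raw_weight: float = 0.25) -> PBNModel:
    """Insert a candidate crosstalk as an extra L-flagged rule.

    Activation adds the rule ``target = source``, additionally gated by
    ``NOT i`` for every inhibitor input ``i`` negated in all of the
    target's existing rules (a kinase inhibitor blocks the target whichever
    route activated it).  Inhibition adds ``target = <main expression> AND
    NOT source`` where the main expression is taken from the target's
    highest-priority existing rule.  If the target previously had a single
    fixed rule, that rule is promoted to flag H so both weights become
    optimisable (k grows by 2); otherwise only the new rule's weight is
    added (k grows by 1).
    """
    for endpoint in (candidate.source, candidate.target):
        if endpoint not in model.nodes:
            raise ModelError(f"crosstalk endpoint {endpoint!r} not in the model")
    if (candidate.source, candidate.target) in model.edges():
        raise ModelError(
            f"crosstalk {candidate.label} duplicates an existing edge")
    existing = model.rules[candidate.target]
    if any(r.flag == "INPUT" for r in existing):
        raise ModelError(f"cannot add crosstalk onto input node {candidate.target!r}")
    main = next((r for r in existing if r.flag in ("H", "FIXED")), existing[0])
    if candidate.sign == "activation":
        expression = Var(candidate.source)
        for gate in _common_inhibitor_gates(model, candidate.target):
            expression = And(expression, Not(Var(gate)))
    else:
        expression = And(main.expression, Not(Var(candidate.source)))
    new_rule = BooleanRule(candidate.target, expression, weight=raw_weight, flag="L")

    rules = []
    for name in model.nodes:
        for rule in model.rules[name]:
            if (name == candidate.target and len(existing) == 1
                    and rule.flag == "FIXED"):
                # single fixed rule gains an optimisable sibling: promote it
                rule = replace(rule, flag="H", weight=1.0 - raw_weight)
            rules.append(rule)
    rules.append(new_rule)
    return PBNModel(rules, p=model.p, nodes=model.nodes)


@dataclass
class ModelComparison:
    """One scan row: a variant's fit quality and its test against the base."""

    variant: str
    description: str
    sse: float
    n: int
    k: int
    aic: float
    f_statistic: float | None = None
    p_value: float | None = None
    fit_result: FitResult | None = None


def comparison_table(rows: Sequence[ModelComparison]) -> pd.DataFrame:
    return pd.DataFrame([{
        "variant": r.variant, "description": r.description,
        "fitting_cost": r.sse, "n": r.n, "k": r.k, "AIC": r.aic,
        "F": r.f_statistic, "p": r.p_value,
    } for r in rows])


def crosstalk_scan(base_model: PBNModel,
                   candidates: Sequence[CrosstalkCandidate],
                   dataset: NormalisedDataset,
                   conditions: Sequence[Condition] | Mapping[str, Condition],
                   mode: str = "single",
                   n_eval: int = 1000, seed: int = 0,
                   settings: EstimatorSettings = EstimatorSettings(),
                   algorithm: str = "de",
                   readout_map: Mapping[str, str] | None = None,
                   keep_fits: bool = False,
                   n_repeats: int = 1,
                   **fit_kwargs) -> list[ModelComparison]:
    """Refit the base model with candidate crosstalks added one or two at a time.

    Returns the base row followed by one row per candidate (``mode="single"``)
    or per unordered candidate pair (``mode="pairwise"``), each with SSE, AIC
    and the F-test against the base fit.  ``n_repeats`` independent
    optimisation rounds are run per variant and the best kept.
    """
    if mode not in ("single", "pairwise"):
        raise ValueError(f"unknown scan mode {mode!r}")

    def run(label: str, description: str, model: PBNModel,
            variant_seed: int) -> ModelComparison:
        result = min(
            (fit(model, dataset, conditions, algorithm=algorithm,
                 n_eval=n_eval, seed=variant_seed + 53 * rep,
                 settings=settings, readout_map=readout_map, **fit_kwargs)
             for rep in range(n_repeats)),
            key=lambda res: res.best_sse)
        cost_obj_n = sum(1 for _ in dataset.cells())
        k = len(model.free_parameters())
        row = ModelComparison(label, description, result.best_sse,
                              n=cost_obj_n, k=k,
                              aic=aic(result.best_sse, cost_obj_n, k))
        if keep_fits:
            row.fit_result = result
        return row

    rows = [run("base", "No crosstalk", base_model, seed)]
    base_row = rows[0]
    if mode == "single":
        variant_list = [(str(c.index), c.label, (c,)) for c in candidates]
    else:
        variant_list = [(f"{a.index}+{b.index}", f"{a.label} & {b.label}", (a, b))
                        for a, b in combinations(candidates, 2)]
    for offset, (label, description, group) in enumerate(variant_list, start=1):
        model = base_model
        for candidate in group:
            model = add_crosstalk(model, candidate)
        row = run(label, description, model, seed + offset)
        if row.k > base_row.k and base_row.n > row.k:
            row.f_statistic, row.p_value = f_test(
                base_row.sse, base_row.k, row.sse, row.k, base_row.n)
        rows.append(row)
    return rows
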