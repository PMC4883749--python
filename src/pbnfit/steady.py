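"""Steady-state marginal estimation.

Two routes to the stationary ON-probability of output nodes:

* :func:`exact_stationary` — solves the balance equations of the exact
  transition matrix; feasible only for small non-clamped state spaces, and
  used throughout the test-suite as the oracle.
* :func:`estimate_marginals` — the sampling estimator used for realistic
  network sizes.  A pilot trajectory yields the 0<->1 transition
  probabilities (alpha, beta) of each binary output trace; the two-state
  Markov chain diagnostic converts them into a burn-in length m and a sample
  count n sufficient to estimate the ON-probability within half-width ``r``
  with coverage ``s``; the trajectory is extended and the plan re-evaluated
  until it is satisfied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.stats import norm

from ._kernel import CompiledModel
from .core import Condition, ModelError, PBNModel, UNCONSTRAINED, marginal_from_distribution


@dataclass(frozen=True)
class EstimatorSettings:
    """Estimator tuning knobs.

    ``p`` is the perturbation probability used when models are built from
    config files; simulation itself always honours the model's own ``p``.
    ``r`` is the half-width of the target accuracy interval, ``s`` the
    probability the estimate falls within it, ``epsilon`` the burn-in
    convergence tolerance of the two-state diagnostic, ``pilot`` the length
    of the pilot trajectory seeding (alpha, beta).
    """

    p: float = 0.001
    r: float = 0.025
    s: float = 0.95
    epsilon: float = 0.001
    max_iterations: int = 10
    pilot: int = 1000

    def __post_init__(self):
        if not (0.0 < self.r < 0.5):
            raise ValueError(f"r={self.r} outside (0, 0.5)")
        if not (0.5 < self.s < 1.0):
            raise ValueError(f"s={self.s} outside (0.5, 1)")


@dataclass(frozen=True)
class TwoStateDiagnostics:
    alpha: float
    beta: float
    burn_in: int
    n_samples: int
    rounds: int
    converged: bool = True


@dataclass
class SteadyStateEstimate:
    """Per-output stationary ON-probabilities plus estimator diagnostics."""

    marginals: dict[str, float]
    diagnostics: dict[str, TwoStateDiagnostics] = field(default_factory=dict)

    def __getitem__(self, node: str) -> float:
        return self.marginals[node]


@dataclass
class ExactStationary:
    pi: np.ndarray
    free: list[str]
    marginals: dict[str, float]

    def __getitem__(self, node: str) -> float:
        return self.marginals[node]


def exact_stationary(model: PBNModel, condition: Condition = UNCONSTRAINED,
                     cap: int = 14) -> ExactStationary:
    """Unique stationary distribution of the exact chain, plus marginals.

    Solves pi P = pi, sum(pi) = 1 on the non-clamped state space.  With
    ``p > 0`` the chain is primitive so the solution is unique; with
    ``p = 0`` a reducible chain raises a non-uniqueness error.
    """
    P, free = model.transition_matrix(condition, cap=cap)
    m = P.shape[0]
    if model.p > 0:
        A = P.T - np.eye(m)
        A[-1, :] = 1.0
        b = np.zeros(m)
        b[-1] = 1.0
        pi = scipy.linalg.solve(A, b)
    else:
        ns = scipy.linalg.null_space(P.T - np.eye(m))
        if ns.shape[1] != 1:
            raise ModelError(
                "p=0 chain has no unique stationary distribution "
                f"({ns.shape[1]} invariant directions); set p > 0")
        pi = ns[:, 0] / ns[:, 0].sum()
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    marginals = {name: marginal_from_distribution(pi, free, name) for name in free}
    for node, value in condition.clamps.items():
        marginals[node] = float(value)
    return ExactStationary(pi=pi, free=free, marginals=marginals)


def two_state_plan(alpha: float, beta: float,
                   settings: EstimatorSettings = EstimatorSettings()) -> tuple[int, int]:
    """Burn-in m and sample count n of the two-state Markov chain diagnostic.

    For a binary chain with transition probabilities alpha (0->1) and beta
    (1->0):

        m = ceil( log(eps (alpha+beta) / max(alpha, beta)) / log|1-alpha-beta| )
        n = ceil( alpha beta (2-alpha-beta) / (alpha+beta)^3 * (z/r)^2 )

    with z the standard-normal quantile at (1+s)/2.  Degenerate (alpha, beta)
    outside (0, 1) fall back to the conservative worst case 0.5/0.5.
    """
    if not (0.0 < alpha < 1.0) or not (0.0 < beta < 1.0):
        alpha = beta = 0.5
    ab = alpha + beta
    lam = abs(1.0 - ab)
    if lam < 1e-12:
        m = 1  # memoryless chain: one step suffices
    else:
        m = math.ceil(math.log(settings.epsilon * ab / max(alpha, beta)) / math.log(lam))
        m = max(m, 1)
    z = norm.ppf((1.0 + settings.s) / 2.0)
    n = math.ceil(alpha * beta * (2.0 - ab) / ab ** 3 * (z / settings.r) ** 2)
    return m, max(n, 1)


def _alpha_beta(trace: np.ndarray) -> tuple[float, float]:
    """Empirical 0->1 / 1->0 transition probabilities of a binary trace."""
    if len(trace) < 2:
        return math.nan, math.nan
    prev = trace[:-1]
    nxt = trace[1:]
    zeros = int((prev == 0).sum())
    ones = int((prev == 1).sum())
    alpha = float(((prev == 0) & (nxt == 1)).sum()) / zeros if zeros else math.nan
    beta = float(((prev == 1) & (nxt == 0)).sum()) / ones if ones else math.nan
    return alpha, beta


def estimate_from_compiled(comp: CompiledModel, outputs: list[str],
                           settings: EstimatorSettings = EstimatorSettings(),
                           seed: int = 0,
                           init_state: np.ndarray | None = None) -> SteadyStateEstimate:
    """Two-state estimate on a pre-compiled (model, condition) pair.

    Lets repeated cost evaluations reuse the compiled structure (only the
    weights change between calls); see :func:`estimate_marginals` for the
    estimator semantics.
    """
    model, condition = comp.model, comp.condition
    if not outputs:
        raise ValueError("outputs must be non-empty")
    unknown = [o for o in outputs if o not in model.nodes]
    if unknown:
        raise ModelError(f"unknown output node(s) {unknown}")

    marginals: dict[str, float] = {}
    diagnostics: dict[str, TwoStateDiagnostics] = {}
    live = [o for o in outputs if o not in condition.clamps]
    for o in outputs:
        if o in condition.clamps:  # clamp conservation: the marginal is the clamp
            marginals[o] = float(condition.clamps[o])
            diagnostics[o] = TwoStateDiagnostics(0.0, 0.0, 0, 1, 0)
    if not live:
        return SteadyStateEstimate(marginals, diagnostics)

    seeds = np.random.SeedSequence(seed).generate_state(settings.max_iterations + 1)
    state = model.default_state(condition) if init_state is None \
        else model.apply_clamps(init_state, condition)

    chunk, state = comp.run(state, settings.pilot, live, int(seeds[0]))
    chunks = [chunk]
    total = settings.pilot
    plans: dict[str, tuple[float, float, int, int]] = {}
    rounds = 0
    converged = False
    trace = chunks[0]
    while rounds < settings.max_iterations:
        trace = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]
        plans = {}
        for j, name in enumerate(live):
            a, b = _alpha_beta(trace[:, j])
            m, n = two_state_plan(a, b, settings)
            plans[name] = (a, b, m, n)
        need = max(m + n for (_, _, m, n) in plans.values()) - total
        if need <= 0:
            converged = True
            break
        rounds += 1
        chunk, state = comp.run(state, need, live, int(seeds[rounds]))
        chunks.append(chunk)
        total += need
    if len(chunks) > 1:
        trace = np.concatenate(chunks)

    for j, name in enumerate(live):
        a, b, m, n = plans[name]
        samples = trace[m:, j]
        marginals[name] = float(samples.mean())
        diagnostics[name] = TwoStateDiagnostics(
            alpha=a, beta=b, burn_in=m, n_samples=len(samples),
            rounds=rounds, converged=converged)
    return SteadyStateEstimate(marginals, diagnostics)


def estimate_marginals(model: PBNModel, condition: Condition, outputs: list[str],
                       settings: EstimatorSettings = EstimatorSettings(),
                       seed: int = 0,
                       init_state: np.ndarray | None = None) -> SteadyStateEstimate:
    """Two-state Markov chain estimate of stationary output marginals.

    One trajectory is shared by all outputs; each output gets its own
    (burn-in, sample-count) plan and the trajectory is grown until the
    largest plan is satisfied (re-estimating alpha/beta from all collected
    samples each round) or ``settings.max_iterations`` is reached, in which
    case the estimate is returned with ``converged=False`` diagnostics.
    Deterministic for a fixed seed.
    """
    return estimate_from_compiled(CompiledModel(model, condition), outputs,
                                  settings=settings, seed=seed, init_state=init_state)
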