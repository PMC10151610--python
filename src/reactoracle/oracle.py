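"""Interpretation layer: surprise, disruption, anomalies, exploration replay.

Surprise is the negative log predictive likelihood of an observation's
outcome: *a priori* under the prior predictive (before any data), *online*
under the posterior conditioned on everything observed earlier, and *a
posteriori* under the final posterior.  A discovery shows up as an
observation whose a-priori surprise is large but whose a-posteriori surprise
is small — initially improbable, eventually explained as a rule.  An anomaly
stays surprising even in retrospect.

The disruption score ranks unexplored experiments by how much their outcome
would shift predicted reactivity over the rest of the space, estimated by
importance-reweighting the posterior draws under each hypothetical outcome
(no refitting inside the ranking loop).

`parsimonious_explanation` extracts the Occam's-razor reading of a fitted
theory — the minimum set of abstract properties needed to explain every
reactive observation — via seeded multistart L1-penalised maximum likelihood.
"""

from __future__ import annotations

import itertools
import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .inference import MCMCConfig, Posterior, fit_posterior
from .space import ChemicalSpace, Experiment, Observation, ObservationLog, ReactivityVector, enumerate_experiments
from .theory import CompiledTheory, Theory

__all__ = [
    "ANOMALY_THRESHOLD",
    "SurpriseTrace",
    "DisruptionRanking",
    "ReplayResult",
    "ParsimoniousExplanation",
    "surprise_trace",
    "anomaly_shortlist",
    "select_disruptive",
    "replay_exploration",
    "parsimonious_explanation",
]

logger = logging.getLogger(__name__)

#: Default anomaly cutoff: the surprise of an outcome judged 5% likely.
ANOMALY_THRESHOLD = float(-np.log(0.05))


@dataclass(frozen=True)
class SurpriseTrace:
    """Per-observation surprise (negative log predictive likelihood).

    ``online`` may be None when the sequential trace was not requested (it
    costs one refit per ``refit_every`` observations).
    """

    observations: tuple[Observation, ...]
    a_priori: np.ndarray
    a_posteriori: np.ndarray
    online: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.observations)
        for name in ("a_priori", "a_posteriori", "online"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per observation")
            if np.any(arr < -1e-9):
                raise ValueError(f"{name} contains negative surprise")
            object.__setattr__(self, name, np.maximum(arr, 0.0))


def _neg_log_predictive(posterior: Posterior, log: ObservationLog) -> np.ndarray:
    probs = posterior.predictive_outcome_probability(
        list(log.experiments), log.outcome_matrix()
    )
    return -np.log(np.clip(probs, 1e-300, None))


def surprise_trace(
    theory: Theory,
    log: ObservationLog,
    config: MCMCConfig,
    online: bool = True,
    refit_every: int = 1,
    posterior: Posterior | None = None,
) -> SurpriseTrace:
    """Compute a-priori / online / a-posteriori surprise for every observation.

    The a-priori trace uses draws from the prior only (hence it is invariant
    to observation order); the online trace at step t conditions on
    observations 0..t-1, refitting every ``refit_every`` accepted
    observations and importance-reweighting the current draws in between; the
    a-posteriori trace uses the posterior over the full log (pass
    ``posterior`` to reuse an existing fit).
    """
    compiled = (
        posterior.structure if posterior is not None else CompiledTheory(theory, log.space)
    )
    n_total = config.chains * config.draws
    prior_post = Posterior.from_prior(compiled, n_total, seed=config.seed, chains=config.chains)
    a_priori = _neg_log_predictive(prior_post, log)

    if posterior is None:
        posterior = fit_posterior(theory, log, config)
    a_posteriori = _neg_log_predictive(posterior, log)

    online_arr = None
    if online:
        online_arr = np.empty(len(log))
        current = prior_post
        for t, obs in enumerate(log):
            y_t = np.array([obs.outcome.bits], dtype=float)
            probs = current.predictive_outcome_probability([obs.experiment], y_t)
            online_arr[t] = -np.log(max(float(probs[0]), 1e-300))
            if t == len(log) - 1:
                break
            if (t + 1) % refit_every == 0:
                current = fit_posterior(theory, log.head(t + 1), config)
            else:
                per_draw = current.predictive_outcome_probability(
                    [obs.experiment], y_t, per_draw=True
                )[:, 0]
                current = current.reweighted(np.log(np.clip(per_draw, 1e-300, None)))
    return SurpriseTrace(log.observations, a_priori, a_posteriori, online_arr)


def anomaly_shortlist(
    trace: SurpriseTrace, threshold: float = ANOMALY_THRESHOLD
) -> list[tuple[Observation, float]]:
    """Observations that remain surprising under the final posterior,
    sorted by decreasing a-posteriori surprise.  Empty when the final theory
    explains everything at the given cutoff."""
    hits = [
        (obs, float(s))
        for obs, s in zip(trace.observations, trace.a_posteriori)
        if s > threshold
    ]
    hits.sort(key=lambda item: (-item[1], item[0].experiment.key()))
    return hits


@dataclass(frozen=True)
class DisruptionRanking:
    """Candidate experiments scored by expected predictive disruption,
    sorted descending (ties broken by canonical experiment order)."""

    entries: tuple[tuple[Experiment, float], ...]

    @property
    def experiments(self) -> tuple[Experiment, ...]:
        return tuple(e for e, _ in self.entries)

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries])

    def top(self) -> Experiment:
        return self.entries[0][0]


def select_disruptive(
    posterior: Posterior,
    candidates: Sequence[Experiment],
    remaining: Sequence[Experiment],
    chunk: int = 256,
) -> DisruptionRanking:
    """Rank candidates by how much their outcome would change beliefs.

    For each candidate and each (binary-collapsed) outcome branch, posterior
    draws are importance-reweighted by the branch's likelihood; the score is
    the outcome-probability-weighted total-variation shift of predictive
    reactivity over the remaining unexplored experiments:

        score(e) = sum_o  p(o) * sum_{e' != e} | p(e' | o) - p(e') |

    A candidate whose outcome probability is identical across draws cannot
    reweight anything and scores 0, as does an empty remaining set.
    """
    candidates = list(candidates)
    remaining = list(remaining)
    rem_set = set(remaining)
    missing = [e for e in candidates if e not in rem_set]
    if missing:
        raise ValueError(f"candidates not in remaining set: {missing[:3]}")
    if not candidates:
        return DisruptionRanking(())

    # per-draw binary-collapsed reactivity probabilities
    p_rem = posterior.predictive_draws(remaining, chunk=chunk)  # (S, Nr, B)
    p_rem = 1.0 - np.exp(np.sum(np.log1p(-np.clip(p_rem, 0, 1 - 1e-12)), axis=-1))
    w = posterior._weights()
    pos = {e: i for i, e in enumerate(remaining)}
    cand_idx = np.array([pos[e] for e in candidates])
    p_cand = p_rem[:, cand_idx]  # (S, Nc)

    baseline = w @ p_rem  # (Nr,)
    wp = (w[:, None] * p_cand)  # (S, Nc)
    mass1 = wp.sum(axis=0)  # p̄(o=1) per candidate
    mass0 = 1.0 - mass1
    # reweighted predictive means for each candidate/branch: (Nr, Nc)
    num1 = p_rem.T @ wp
    num0 = p_rem.T @ (w[:, None] * (1.0 - p_cand))
    scores = np.zeros(len(candidates))
    for j in range(len(candidates)):
        tv = np.zeros(2)
        for o, (mass, num) in enumerate(((mass0, num0), (mass1, num1))):
            if mass[j] <= 1e-12:
                logger.debug("degenerate outcome branch o=%d for %s", o, candidates[j])
                continue
            shift = np.abs(num[:, j] / mass[j] - baseline)
            shift[cand_idx[j]] = 0.0
            tv[o] = mass[j] * shift.sum()
        scores[j] = tv.sum()
    order = sorted(
        range(len(candidates)), key=lambda j: (-scores[j], candidates[j].key())
    )
    return DisruptionRanking(tuple((candidates[j], float(scores[j])) for j in order))


@dataclass
class ReplayResult:
    """Outcome of an exploration replay: the accumulated log, per-step online
    surprise, the JSONL-ready event records, and discovery events (step at
    which each distinct reactive experiment was first observed)."""

    log: ObservationLog
    online_surprise: np.ndarray
    events: list[dict]
    discoveries: list[dict]
    trace: SurpriseTrace | None = None


def replay_exploration(
    theory: Theory,
    space: ChemicalSpace,
    outcome_source: Callable[[Experiment], ReactivityVector],
    config: MCMCConfig,
    steps: int,
    strategy: str = "random",
    seed_log: ObservationLog | None = None,
    refit_every: int = 1,
    experiments: Sequence[Experiment] | None = None,
    anomaly_threshold: float = ANOMALY_THRESHOLD,
    repeat_attempts: bool = True,
    final_trace: bool = False,
) -> ReplayResult:
    """Closed-loop exploration of a chemical space against an outcome source.

    Each step picks an unexplored experiment (uniformly at random, or the
    top of the disruption ranking), records its outcome and online surprise,
    and periodically refits the posterior (importance reweighting in
    between).  An observation whose online surprise exceeds the anomaly
    threshold is scheduled once more before being accepted — the
    repeat-attempt policy guarding against one-off anomalies.  Runs stop
    early (logged) once the space is exhausted.
    """
    if strategy not in ("random", "disruptive"):
        raise ValueError(f"unknown strategy: {strategy}")
    pool = list(experiments) if experiments is not None else enumerate_experiments(space)
    rng = np.random.default_rng(config.seed)
    log = seed_log if seed_log is not None else ObservationLog(space)
    compiled = CompiledTheory(theory, space)
    if len(log):
        current = fit_posterior(theory, log, config)
    else:
        current = Posterior.from_prior(
            compiled, config.chains * config.draws, seed=config.seed, chains=config.chains
        )

    observed: dict[Experiment, int] = {}
    for o in log:
        observed[o.experiment] = observed.get(o.experiment, 0) + 1
    discovered: set[Experiment] = {o.experiment for o in log if o.outcome.reactive}
    pending: deque[Experiment] = deque()
    events: list[dict] = []
    discoveries: list[dict] = [
        {"step": -1, "experiment": str(e), "seeded": True} for e in sorted(discovered, key=Experiment.key)
    ]
    online = []
    since_refit = 0

    for step in range(steps):
        remaining = [e for e in pool if e not in observed]
        is_repeat = bool(pending)
        if is_repeat:
            chosen = pending.popleft()
        elif not remaining:
            logger.info("space exhausted after %d steps; stopping early", step)
            break
        elif strategy == "random":
            chosen = remaining[int(rng.integers(len(remaining)))]
        else:
            ranking = select_disruptive(current, remaining, remaining)
            chosen = ranking.top()

        outcome = outcome_source(chosen)
        y = np.array([outcome.bits], dtype=float)
        prob = float(current.predictive_outcome_probability([chosen], y)[0])
        surprise = -np.log(max(prob, 1e-300))
        online.append(surprise)
        surprising = surprise > anomaly_threshold
        attempts = observed.get(chosen, 0)
        if repeat_attempts and surprising and attempts == 0:
            pending.append(chosen)

        log = log.append(chosen, outcome)
        observed[chosen] = attempts + 1
        if outcome.reactive and chosen not in discovered:
            discovered.add(chosen)
            discoveries.append({"step": step, "experiment": str(chosen)})

        since_refit += 1
        refit = since_refit >= refit_every
        if refit:
            current = fit_posterior(theory, log, config)
            since_refit = 0
        else:
            per_draw = current.predictive_outcome_probability([chosen], y, per_draw=True)[:, 0]
            current = current.reweighted(np.log(np.clip(per_draw, 1e-300, None)))
        events.append(
            {
                "step": step,
                "experiment": str(chosen),
                "outcome": str(outcome),
                "online_surprise": float(surprise),
                "strategy": strategy,
                "refit": bool(refit),
                "repeat": bool(is_repeat),
            }
        )

    trace = None
    if final_trace and len(log):
        trace = surprise_trace(theory, log, config, online=False, posterior=current)
    return ReplayResult(log, np.array(online), events, discoveries, trace)


# ---------------------------------------------------------------------------
# parsimonious explanation (Occam readout)


@dataclass(frozen=True)
class ParsimoniousExplanation:
    """Minimal-property reading of a fitted theory.

    ``property_mask`` marks the smallest property subset under which every
    reactive observation keeps a (binary-collapsed) signal of at least
    ``threshold``; ``n_properties`` is its size and ``compound_properties``
    counts, per compound, the active properties it possesses at membership
    >= threshold.  ``theta`` is the underlying penalised-ML parameter vector.
    """

    theta: np.ndarray
    objective: float
    threshold: float
    property_mask: np.ndarray
    n_properties: int
    compound_properties: dict[str, int]
    converged: bool


def _collapse_binary(signal: np.ndarray) -> np.ndarray:
    return 1.0 - np.exp(np.sum(np.log1p(-np.clip(signal, 0, 1 - 1e-12)), axis=-1))


def parsimonious_explanation(
    theory: Theory,
    log: ObservationLog,
    seed: int,
    l1: float = 0.5,
    restarts: int = 12,
    threshold: float = 0.5,
    maxiter: int = 1000,
) -> ParsimoniousExplanation:
    """Extract the minimum property structure explaining an observation log.

    Fits theta by multistart L1-penalised maximum likelihood (penalty
    ``l1 * sum(theta)``; starts mix near-zero entries with a sparse sprinkling
    of crisp ones, seeded), then searches all property subsets for the
    smallest one that keeps every reactive observation explained at
    ``threshold``.  The L1 penalty zeroes parameters the data never ask for,
    so the count realises the conservative bias: only the minimum number of
    properties needed to explain the reactivity observations is used.
    """
    compiled = CompiledTheory(theory, log.space)
    batch, y = compiled.batch_for_log(log)
    bounds = [(1e-6, 1 - 1e-6)] * compiled.ndim
    rng = np.random.default_rng(seed)

    def objective(t: np.ndarray) -> float:
        return -float(compiled.log_likelihood(t, batch, y)) + l1 * float(t.sum())

    best = None
    for _ in range(restarts):
        x0 = np.where(
            rng.random(compiled.ndim) < 0.2,
            rng.uniform(0.7, 0.95, compiled.ndim),
            rng.uniform(0.005, 0.05, compiled.ndim),
        )
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": maxiter})
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x

    reactive_idx = [i for i, o in enumerate(log) if o.outcome.reactive]
    k = compiled.k
    if reactive_idx:
        reactive_batch = compiled.batch([log[i].experiment for i in reactive_idx])
        masks = np.array(list(itertools.product([0, 1], repeat=k)), dtype=float)
        thetas = np.tile(theta, (masks.shape[0], 1))
        m_block = compiled.blocks["membership"]
        m = thetas[:, m_block.sl].reshape(masks.shape[0], *m_block.shape)
        m *= masks[:, None, :]
        thetas[:, m_block.sl] = m.reshape(masks.shape[0], -1)
        signal = _collapse_binary(compiled.signal(thetas, reactive_batch))  # (2^k, Nr)
        explained = np.all(signal >= threshold, axis=1)
        sizes = masks.sum(axis=1)
        if not np.any(explained):
            best_mask = np.ones(k)
            n_props = k
        else:
            order = np.lexsort((np.arange(masks.shape[0]), np.where(explained, sizes, np.inf)))
            best_mask = masks[order[0]]
            n_props = int(best_mask.sum())
    else:
        best_mask = np.zeros(k)
        n_props = 0

    membership = compiled.block(theta, "membership")
    rows = compiled.compound_rows(theta) if compiled.incidence is not None else membership
    compound_props = {
        cid: int(np.sum((rows[i] >= threshold) & (best_mask == 1)))
        for i, cid in enumerate(log.space.ids)
    }
    return ParsimoniousExplanation(
        theta=theta,
        objective=float(best.fun),
        threshold=threshold,
        property_mask=best_mask,
        n_properties=n_props,
        compound_properties=compound_props,
        converged=bool(best.success),
    )
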