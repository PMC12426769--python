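"""Set decoding and end-to-end candidate construction.

Agent sets are decoded autoregressively: starting from the empty set,
each step either adds one not-yet-chosen agent (with the probability the
stage-1 model assigns to it given the current partial set) or emits the
end-of-set symbol to terminate. Ordered decodes that reach the same
unordered set are merged by summing their joint probabilities. Because
the step model conditions only on the *set* of already-chosen agents,
hypotheses can be merged as soon as they collide, which keeps the beam
exact whenever its width covers all live sets.

A complete recommendation then combines the top agent sets with the top
temperature and amount bin assignments (10×2×2×2 = 80 candidates by
default) and ranks them by a weighted geometric mean of the four stage
confidences.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class AgentSetHypothesis:
    """An unordered agent set with its order-merged joint probability."""

    agents: frozenset[int]
    probability: float
    complete: bool = True

    def sort_key(self):
        # higher probability first; ties: smaller set, then lexicographic indices
        return (-self.probability, len(self.agents), tuple(sorted(self.agents)))


@dataclass(frozen=True)
class ConditionSet:
    """One complete condition recommendation."""

    agents: frozenset[int]
    temperature_bin: int
    reactant_bins: tuple[int, ...]
    agent_bins: tuple[tuple[int, int], ...]  # (agent index, bin), sorted by agent
    confidences: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    score: float = 1.0

    def __post_init__(self):
        if frozenset(i for i, _ in self.agent_bins) != self.agents:
            raise ValueError("agent-amount entries must exactly cover the agent set")

    @property
    def agent_bin_map(self) -> dict[int, int]:
        return dict(self.agent_bins)


@dataclass(frozen=True)
class ConfidenceWeights:
    w1: float = 1.0
    w2: float = 1.0
    w3: float = 1.0
    w4: float = 1.0

    def __post_init__(self):
        ws = (self.w1, self.w2, self.w3, self.w4)
        if any(w < 0 or not math.isfinite(w) for w in ws):
            raise ValueError("weights must be finite and non-negative")
        if sum(ws) == 0:
            raise ValueError("weights must not all be zero")

    def as_tuple(self):
        return (self.w1, self.w2, self.w3, self.w4)


def beam_search_agents(
    step_fn: Callable[[np.ndarray], np.ndarray],
    n_agents: int,
    width: int = 10,
    max_len: int = 6,
) -> list[AgentSetHypothesis]:
    """Beam-search decoding of agent sets.

    ``step_fn`` maps a multi-hot partial-set vector of length
    ``n_agents`` to a probability vector of length ``n_agents + 1``
    (the last entry is end-of-set). Returns complete hypotheses ranked
    by merged probability.
    """
    if width < 1:
        raise ValueError("beam width must be >= 1")
    live: dict[frozenset[int], float] = {frozenset(): 1.0}
    completed: dict[frozenset[int], float] = {}
    for _ in range(max_len + 1):
        if not live:
            break
        extensions: dict[frozenset[int], float] = {}
        for partial, p in live.items():
            multihot = np.zeros(n_agents)
            for i in partial:
                multihot[i] = 1.0
            probs = step_fn(multihot)
            completed[partial] = completed.get(partial, 0.0) + p * float(probs[n_agents])
            if len(partial) < max_len:
                for a in range(n_agents):
                    if a not in partial:
                        grown = partial | {a}
                        extensions[grown] = extensions.get(grown, 0.0) + p * float(probs[a])
        ranked = sorted(
            extensions.items(), key=lambda kv: (-kv[1], len(kv[0]), tuple(sorted(kv[0])))
        )
        live = dict(ranked[:width])
    hyps = [AgentSetHypothesis(s, p) for s, p in completed.items()]
    hyps.sort(key=AgentSetHypothesis.sort_key)
    return hyps


def top_m_joint_assignment(
    distributions: Sequence[np.ndarray], m: int = 2
) -> list[tuple[tuple[int, ...], float]]:
    """The ``m`` best joint bin assignments over independent components.

    The joint probability is the product of per-component probabilities;
    assignments are found by a per-component beam of width ``m`` (exact
    for ``m ≤ 2`` on up to four components, verified against brute
    force). No components → the single empty assignment.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    for d in distributions:
        if len(d) == 0:
            raise ValueError("empty component distribution")
    partial: list[tuple[tuple[int, ...], float]] = [((), 1.0)]
    for dist in distributions:
        grown = [
            (bins + (b,), p * float(dist[b]))
            for bins, p in partial
            for b in range(len(dist))
        ]
        grown.sort(key=lambda kv: (-kv[1], kv[0]))
        partial = grown[:m]
    return partial


def confidence_score(
    confidences: Sequence[float], weights: ConfidenceWeights = ConfidenceWeights()
) -> float:
    """Weighted geometric mean exp(Σ wᵢ ln cᵢ / Σ wᵢ) of stage confidences."""
    ws = weights.as_tuple()
    if len(confidences) != len(ws):
        raise ValueError("need one confidence per weight")
    for c in confidences:
        if c <= 0:
            raise ValueError(f"confidence must be positive, got {c}")
    total = sum(ws)
    return float(math.exp(sum(w * math.log(c) for w, c in zip(ws, confidences)) / total))


@dataclass(frozen=True)
class StageOutputs:
    """Per-agent-set stage outputs for one query, before combination.

    ``agent_hypothesis`` carries the stage-1 confidence; the three
    distributions are computed with that hypothesis's agents as input.
    """

    agent_hypothesis: AgentSetHypothesis
    temperature_dist: np.ndarray  # simplex over temperature bins
    reactant_dists: tuple[np.ndarray, ...]  # one simplex per reactant
    agent_dists: tuple[tuple[int, np.ndarray], ...]  # (agent index, simplex)


def combine_conditions(
    stage_outputs: Sequence[StageOutputs],
    counts: tuple[int, int, int, int] = (10, 2, 2, 2),
    weights: ConfidenceWeights = ConfidenceWeights(),
) -> list[ConditionSet]:
    """Cartesian combination of top stage predictions, ranked by confidence.

    With full beams and default counts this yields 10×2×2×2 = 80
    candidates. Stage confidences: c₁ = merged set probability, c₂ =
    chosen temperature-bin probability, c₃ = joint reactant-assignment
    probability, c₄ = joint agent-assignment probability.
    """
    n_sets, n_temp, n_react, n_agent = counts
    candidates: list[ConditionSet] = []
    for out in stage_outputs[:n_sets]:
        c1 = out.agent_hypothesis.probability
        temp_order = np.argsort(-out.temperature_dist, kind="stable")[:n_temp]
        temp_opts = [(int(b), float(out.temperature_dist[b])) for b in temp_order]
        react_opts = top_m_joint_assignment(out.reactant_dists, n_react)
        agent_ids = tuple(i for i, _ in out.agent_dists)
        agent_opts = top_m_joint_assignment([d for _, d in out.agent_dists], n_agent)
        for (tb, c2), (rbins, c3), (abins, c4) in itertools.product(
            temp_opts, react_opts, agent_opts
        ):
            confs = (c1, c2, c3, c4)
            candidates.append(
                ConditionSet(
                    agents=out.agent_hypothesis.agents,
                    temperature_bin=tb,
                    reactant_bins=rbins,
                    agent_bins=tuple(sorted(zip(agent_ids, abins))),
                    confidences=confs,
                    score=confidence_score(confs, weights),
                )
            )
    candidates.sort(
        key=lambda c: (
            -c.score,
            len(c.agents),
            tuple(sorted(c.agents)),
            c.temperature_bin,
            c.reactant_bins,
            c.agent_bins,
        )
    )
    return candidates


DEFAULT_WEIGHT_LATTICE = tuple(
    ConfidenceWeights(*ws) for ws in itertools.product((0.25, 0.5, 1.0, 2.0), repeat=4)
)


def fit_confidence_weights(
    validation_outputs: Sequence[Sequence[StageOutputs]],
    truths: Sequence[ConditionSet],
    grid: Sequence[ConfidenceWeights] = DEFAULT_WEIGHT_LATTICE,
    counts: tuple[int, int, int, int] = (10, 2, 2, 2),
    top_k: int = 10,
) -> ConfidenceWeights:
    """Grid-search the weights maximizing end-to-end top-k exact accuracy.

    Ties resolve to the first point in lattice order, so the result is
    deterministic and independent of duplicated grid entries.
    """
    from .evaluation import end_to_end_correct

    grid = list(grid)
    if not grid:
        raise ValueError("empty weight grid")
    best, best_acc = None, -1.0
    for w in grid:
        hits = 0
        for outs, truth in zip(validation_outputs, truths):
            ranked = combine_conditions(outs, counts, w)[:top_k]
            if any(end_to_end_correct(c, truth).overall for c in ranked):
                hits += 1
        acc = hits / max(len(truths), 1)
        if acc > best_acc:
            best, best_acc = w, acc
    return best
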