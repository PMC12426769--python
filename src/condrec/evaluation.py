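"""Metrics: relaxed/strict set accuracy, off-by-N, reaction-level
categories, end-to-end exact match, and pairwise win rates.

Two agent-set match criteria coexist. The *relaxed* criterion compares
SMILES sets after dropping water ("O") from both sides — water is
reported too inconsistently in reaction data for its presence to be
meaningful. The *strict* criterion used in end-to-end scoring compares
vocabulary index sets exactly.

End-to-end correctness is the conjunction of four stage checks; the
reactant-amount stage compares the *multiset* of bins (frequency
distribution) rather than a per-reactant correspondence, because
retrieval baselines return whole condition sets and cannot assign a bin
to a specific reactant. The same relaxation applies to models and
baselines alike.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .decoding import ConditionSet

WATER = "O"


def relaxed_set_equal(pred: Iterable[str], truth: Iterable[str]) -> bool:
    """Agent-set equality disregarding the presence or absence of water."""
    return set(pred) - {WATER} == set(truth) - {WATER}


def strict_set_equal(pred: Iterable, truth: Iterable) -> bool:
    return set(pred) == set(truth)


def topk_accuracy(
    ranked_predictions: Sequence[Sequence],
    truths: Sequence,
    k: int,
    matcher: Callable = strict_set_equal,
) -> float:
    """Fraction of queries whose truth matches any of the first k predictions."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(ranked_predictions) != len(truths):
        raise ValueError("predictions and truths must align")
    hits = sum(
        any(matcher(p, t) for p in preds[:k])
        for preds, t in zip(ranked_predictions, truths)
    )
    return hits / len(truths) if truths else 0.0


def off_by_n_accuracy(pred_bins: Sequence[int], true_bins: Sequence[int], n: int) -> float:
    """Fraction of predictions within n bins of the true label."""
    pred = np.asarray(pred_bins)
    true = np.asarray(true_bins)
    if pred.shape != true.shape:
        raise ValueError("length mismatch")
    if pred.size == 0:
        return 0.0
    return float(np.mean(np.abs(pred - true) <= n))


def bin_mae(pred_bins: Sequence[int], true_bins: Sequence[int]) -> float:
    """Mean absolute error in bin units."""
    pred = np.asarray(pred_bins)
    true = np.asarray(true_bins)
    if pred.shape != true.shape:
        raise ValueError("length mismatch")
    return float(np.mean(np.abs(pred - true))) if pred.size else 0.0


EXACT, OFF_BY_ONE, MAJOR = "exact", "off_by_one", "major"


def reaction_level_category(pred_bins: Sequence[int], true_bins: Sequence[int]) -> str:
    """Bucket a whole reaction's per-component bin predictions.

    ``exact``: every component in the correct bin. ``off_by_one``: all
    within ±1 bin, excluding exact matches. ``major``: at least one
    component off by more than one bin. The three buckets are mutually
    exclusive and exhaustive.
    """
    pred = list(pred_bins)
    true = list(true_bins)
    if len(pred) != len(true):
        raise ValueError("misaligned components")
    devs = [abs(p - t) for p, t in zip(pred, true)]
    if all(d == 0 for d in devs):
        return EXACT
    if all(d <= 1 for d in devs):
        return OFF_BY_ONE
    return MAJOR


@dataclass(frozen=True)
class MatchVerdict:
    agents: bool
    temperature: bool
    reactant_amounts: bool
    agent_amounts: bool
    amount_category: str

    @property
    def overall(self) -> bool:
        return self.agents and self.temperature and self.reactant_amounts and self.agent_amounts


def end_to_end_correct(pred: ConditionSet, truth: ConditionSet) -> MatchVerdict:
    """Stage-wise exact-match verdict for a complete condition set.

    Stage 1: agent index sets equal (no water relaxation). Stage 2:
    same temperature bin. Stage 3: multisets of reactant bins equal.
    Stage 4: agent sets equal and every agent's bin equal.
    """
    s1 = pred.agents == truth.agents
    s2 = pred.temperature_bin == truth.temperature_bin
    s3 = Counter(pred.reactant_bins) == Counter(truth.reactant_bins)
    s4 = s1 and pred.agent_bin_map == truth.agent_bin_map
    cat = (
        reaction_level_category(sorted(pred.reactant_bins), sorted(truth.reactant_bins))
        if len(pred.reactant_bins) == len(truth.reactant_bins)
        else MAJOR
    )
    return MatchVerdict(
        agents=s1, temperature=s2, reactant_amounts=s3, agent_amounts=s4, amount_category=cat
    )


@dataclass(frozen=True)
class WinRateResult:
    win_rate: float
    ci_low: float
    ci_high: float
    n_counted: int
    n_wins_a: float


def win_rate(
    preds_a: Sequence[Sequence[ConditionSet]],
    preds_b: Sequence[Sequence[ConditionSet]],
    truths: Sequence[ConditionSet],
    groups: Optional[Sequence[str]] = None,
    top_k: int = 10,
    tie_mode: str = "split",
    ci_method: str = "wilson",
) -> dict[Optional[str], WinRateResult]:
    """Pairwise top-k win rate of method A over method B, with 95% CI.

    Per query, A wins when its top-k contains a correct condition set
    and B's does not (and symmetrically for B); queries where neither is
    correct are excluded. Both-correct queries count as half a win for
    each side (``tie_mode='split'``) or are excluded
    (``tie_mode='exclude'``). Groups with zero counted queries are
    absent from the result.
    """
    if not len(preds_a) == len(preds_b) == len(truths):
        raise ValueError("query sets must align")
    if tie_mode not in ("split", "exclude"):
        raise ValueError(f"unknown tie_mode {tie_mode!r}")
    groups = groups if groups is not None else [None] * len(truths)
    tallies: dict = {}
    for pa, pb, truth, g in zip(preds_a, preds_b, truths, groups):
        a_ok = any(end_to_end_correct(c, truth).overall for c in pa[:top_k])
        b_ok = any(end_to_end_correct(c, truth).overall for c in pb[:top_k])
        if not a_ok and not b_ok:
            continue
        wins, n = tallies.get(g, (0.0, 0))
        if a_ok and b_ok:
            if tie_mode == "exclude":
                continue
            tallies[g] = (wins + 0.5, n + 1)
        elif a_ok:
            tallies[g] = (wins + 1.0, n + 1)
        else:
            tallies[g] = (wins, n + 1)
    out = {}
    for g, (wins, n) in tallies.items():
        lo, hi = proportion_confint(wins, n, alpha=0.05, method=ci_method)
        out[g] = WinRateResult(
            win_rate=wins / n, ci_low=float(lo), ci_high=float(hi), n_counted=n, n_wins_a=wins
        )
    return out
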