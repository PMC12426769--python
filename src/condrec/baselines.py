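"""Popularity and nearest-neighbor condition recommenders.

Both baselines are class-conditional: they only ever look at training
reactions sharing the query's most-detailed reaction class. The
popularity baseline ranks conditions by frequency within the class; the
nearest-neighbor baseline ranks same-class training reactions by
Tanimoto similarity over concatenated reactant/product Morgan
fingerprints and adopts their conditions. Both can act per-task or
*holistically*, retrieving a complete internally consistent condition
set as one unit.

Unseen classes yield an empty prediction flagged as such (scored as
incorrect downstream); there is no global fallback by default.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .binning import BinSchemes
from .chem import AgentVocabulary, ReactionRecord, reaction_fingerprint, tanimoto
from .decoding import ConditionSet
from .preprocess import equivalence_ratios
from .stages import FeatureConfig, agent_index_set

TASKS = ("agents", "temperature", "reactant_amount", "agent_amount", "holistic")


@dataclass(frozen=True)
class BaselinePrediction:
    """Ranked items plus a flag distinguishing 'class never seen' from
    'seen but wrong'."""

    items: tuple
    class_seen: bool

    def __len__(self):
        return len(self.items)


@dataclass
class _Entry:
    record: ReactionRecord
    fingerprint: np.ndarray
    conditions: ConditionSet
    agent_smiles: frozenset


class ClassIndex:
    """Per-class training index with precomputed fingerprints and conditions."""

    def __init__(
        self,
        records: Sequence[ReactionRecord],
        vocab: AgentVocabulary,
        schemes: Optional[BinSchemes] = None,
        fc: FeatureConfig = FeatureConfig(),
    ):
        self.vocab = vocab
        self.schemes = schemes or BinSchemes.default()
        self.fc = fc
        self.by_class: dict[str, list[_Entry]] = defaultdict(list)
        for r in records:
            entry = _Entry(
                record=r,
                fingerprint=reaction_fingerprint(r, fc.fp_radius, fc.fp_bits),
                conditions=self._conditions_of(r),
                agent_smiles=r.agent_smiles,
            )
            self.by_class[r.class_id].append(entry)

    def _conditions_of(self, r: ReactionRecord) -> ConditionSet:
        s = self.schemes
        agents = agent_index_set(r, self.vocab)
        ratios = equivalence_ratios(r)
        return ConditionSet(
            agents=agents,
            temperature_bin=(
                -1 if r.temperature_c is None else s.temperature.assign(r.temperature_c)
            ),
            reactant_bins=tuple(
                -1 if x is None else s.reactant.assign(x) for x in ratios.reactants
            ),
            agent_bins=tuple(
                sorted(
                    (self.vocab.index(m.smiles), -1 if x is None else s.agent.assign(x))
                    for (m, _), x in zip(r.agents, ratios.agents)
                )
            ),
        )


def _rank_by_count(counter: Counter, k: Optional[int]) -> tuple:
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], _sort_token(kv[0])))
    items = tuple(item for item, _ in ranked)
    return items if k is None else items[:k]


def _sort_token(x):
    # lexicographic tie-break that works for sets, tuples and ConditionSets
    if isinstance(x, frozenset):
        return (0, tuple(sorted(x)))
    if isinstance(x, ConditionSet):
        return (1, tuple(sorted(x.agents)), x.temperature_bin,
                tuple(sorted(x.reactant_bins)), x.agent_bins)
    return (2, repr(x))


def popularity_predict(
    index: ClassIndex, class_id: str, task: str, k: Optional[int] = None
) -> BaselinePrediction:
    """Most frequent conditions within the query's reaction class.

    ``agents`` ranks whole agent SMILES sets; ``temperature`` ranks
    bins; ``reactant_amount`` is the constant bin containing 1.0 eq (a
    majority baseline — every reaction has a limiting reactant);
    ``agent_amount`` maps each vocabulary agent to its most frequent
    bin; ``holistic`` ranks complete condition sets.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    entries = index.by_class.get(class_id)
    if not entries:
        return BaselinePrediction(items=(), class_seen=False)
    if task == "agents":
        counts = Counter(e.agent_smiles for e in entries)
        return BaselinePrediction(_rank_by_count(counts, k), True)
    if task == "temperature":
        counts = Counter(
            e.conditions.temperature_bin for e in entries if e.conditions.temperature_bin >= 0
        )
        return BaselinePrediction(_rank_by_count(counts, k), True)
    if task == "reactant_amount":
        one_bin = index.schemes.reactant.assign(1.0)
        return BaselinePrediction((one_bin,), True)
    if task == "agent_amount":
        per_agent: dict[int, Counter] = defaultdict(Counter)
        for e in entries:
            for agent_idx, b in e.conditions.agent_bins:
                if b >= 0:
                    per_agent[agent_idx][b] += 1
        best = {
            a: min(c.items(), key=lambda kv: (-kv[1], kv[0]))[0] for a, c in per_agent.items()
        }
        return BaselinePrediction((best,), True)
    counts = Counter(e.conditions for e in entries)
    return BaselinePrediction(_rank_by_count(counts, k), True)


def nn_predict(
    index: ClassIndex, query: ReactionRecord, k: int = 10, task: str = "holistic"
) -> BaselinePrediction:
    """Conditions adopted from the most Tanimoto-similar same-class reactions.

    Neighbors are ranked by similarity; ties prefer the more frequent
    condition within the class, then insertion order. The top-k
    *distinct* predictions are returned. Temperature retrieval uses
    reaction fingerprints only — no agent information enters the
    similarity.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if query.class_id is None:
        raise ValueError("query must carry a class_id")
    entries = index.by_class.get(query.class_id)
    if not entries:
        return BaselinePrediction(items=(), class_seen=False)
    qfp = reaction_fingerprint(query, index.fc.fp_radius, index.fc.fp_bits)
    cond_freq = Counter(e.conditions for e in entries)
    ranked = sorted(
        range(len(entries)),
        key=lambda i: (-tanimoto(qfp, entries[i].fingerprint),
                       -cond_freq[entries[i].conditions], i),
    )
    picked: list = []
    seen = set()
    for i in ranked:
        e = entries[i]
        if task == "agents":
            item = e.agent_smiles
        elif task == "temperature":
            if e.conditions.temperature_bin < 0:
                continue
            item = e.conditions.temperature_bin
        elif task == "reactant_amount":
            item = tuple(sorted(e.conditions.reactant_bins))
        elif task == "agent_amount":
            item = e.conditions.agent_bins
        else:
            item = e.conditions
        if item not in seen:
            seen.add(item)
            picked.append(item)
        if len(picked) >= k:
            break
    return BaselinePrediction(tuple(picked), True)
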