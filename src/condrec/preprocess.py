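"""Raw records → model-ready examples.

Covers mole standardization, equivalence-ratio computation relative to
the limiting reactant, condition-level deduplication, quality filters,
agent-vocabulary construction and the document-level train/val/test
split. Stage-specific eligibility predicates select the sub-datasets
each of the four prediction tasks can actually be trained on.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .binning import BinSchemes
from .chem import AgentVocabulary, Molecule, ReactionRecord


@dataclass(frozen=True)
class QuantitySpec:
    """A reported quantity with enough context to convert it to moles."""

    amount: float
    unit: str  # one of mol, mmol, g, mL
    molecular_weight: Optional[float] = None  # g/mol, required for g
    molarity: Optional[float] = None  # mol/L, required for mL

    def __post_init__(self):
        if self.amount <= 0:
            raise ValueError(f"amount must be positive, got {self.amount}")


def to_moles(q: QuantitySpec) -> float:
    """Standardize a quantity into moles.

    Only the four units mol/mmol/g/mL are supported; anything else
    (solution strings, densities) errors loudly rather than guessing.
    """
    if q.unit == "mol":
        return q.amount
    if q.unit == "mmol":
        return q.amount / 1000.0
    if q.unit == "g":
        if q.molecular_weight is None:
            raise ValueError("molecular_weight required to convert grams to moles")
        return q.amount / q.molecular_weight
    if q.unit == "mL":
        if q.molarity is None:
            raise ValueError("molarity required to convert mL to moles")
        return q.amount / 1000.0 * q.molarity
    raise ValueError(f"unsupported unit {q.unit!r}")


def limiting_reactant(r: ReactionRecord) -> int:
    """Index of the minimum-mole reactant; ties go to the lowest index."""
    moles = []
    for i, (mol, q) in enumerate(r.reactants):
        if q is None:
            raise ValueError(f"reactant {mol.smiles} has no recorded moles")
        moles.append(q)
    return int(np.argmin(moles))  # argmin returns the first minimum


@dataclass(frozen=True)
class EquivalenceRatios:
    """Per-species molar ratios relative to the limiting reactant.

    ``None`` entries mark species whose moles were not recorded.
    Exactly one reactant ratio equals 1.0: the limiting reactant.
    """

    reactants: tuple[Optional[float], ...]
    agents: tuple[Optional[float], ...]
    limiting_index: int


def equivalence_ratios(r: ReactionRecord) -> EquivalenceRatios:
    idx = limiting_reactant(r)
    lim = r.reactants[idx][1]
    if lim is None or lim <= 0:
        raise ValueError("limiting reactant moles must be positive")
    rr = tuple(None if q is None else q / lim for _, q in r.reactants)
    ar = tuple(None if q is None else q / lim for _, q in r.agents)
    return EquivalenceRatios(reactants=rr, agents=ar, limiting_index=idx)


# --- deduplication -------------------------------------------------------

def condition_key(r: ReactionRecord, schemes: BinSchemes) -> tuple:
    """Dedup key: reaction identity plus binned conditions; excludes document."""
    reactant_smiles = tuple(sorted(m.smiles for m, _ in r.reactants))
    product_smiles = tuple(sorted(m.smiles for m in r.products))
    agent_smiles = tuple(sorted(m.smiles for m, _ in r.agents))
    temp_bin = None if r.temperature_c is None else schemes.temperature.assign(r.temperature_c)
    try:
        ratios = equivalence_ratios(r)
        r_bins = tuple(sorted(schemes.reactant.assign(x) for x in ratios.reactants))
        a_bins = tuple(
            sorted(
                ((m.smiles, -1 if x is None else schemes.agent.assign(x))
                 for (m, _), x in zip(r.agents, ratios.agents)),
            )
        )
    except ValueError:  # some reactant moles missing: fall back to identity only
        r_bins = None
        a_bins = tuple(sorted((m.smiles, -1) for m, _ in r.agents))
    return (reactant_smiles, agent_smiles, product_smiles, temp_bin, r_bins, a_bins)


def deduplicate(
    records: Sequence[ReactionRecord], schemes: Optional[BinSchemes] = None
) -> tuple[list[ReactionRecord], int]:
    """Keep the first record per condition-level key.

    Returns the survivors plus the number of removed duplicates. The key
    covers the reaction species and the *binned* conditions, so the same
    reaction reported at a different temperature bin survives as a
    separate record, while the same conditions reported in two documents
    collapse to one.
    """
    schemes = schemes or BinSchemes.default()
    seen: set = set()
    out: list[ReactionRecord] = []
    for r in records:
        k = condition_key(r, schemes)
        if k not in seen:
            seen.add(k)
            out.append(r)
    return out, len(records) - len(out)


# --- quality filters -----------------------------------------------------

@dataclass(frozen=True)
class FilterConfig:
    max_heavy_atoms: int = 100
    max_reactants: int = 5
    max_agents: int = 8
    require_parsable: bool = True

    def __post_init__(self):
        if min(self.max_heavy_atoms, self.max_reactants, self.max_agents) <= 0:
            raise ValueError("filter limits must be positive")


def filter_records(
    records: Sequence[ReactionRecord], cfg: FilterConfig = FilterConfig()
) -> tuple[list[ReactionRecord], Counter]:
    """Apply size/parsability/component-count filters.

    Rejections are counted per rule, not raised. Records are constructed
    from canonical SMILES, so parsability failures can only arise when
    loading raw text; the rule is still counted for raw-dict loading
    paths that pre-screen with :func:`record_parses`.
    """
    kept: list[ReactionRecord] = []
    rejects: Counter = Counter()
    for r in records:
        reason = rejection_reason(r, cfg)
        if reason is None:
            kept.append(r)
        else:
            rejects[reason] += 1
    return kept, rejects


def rejection_reason(r: ReactionRecord, cfg: FilterConfig) -> Optional[str]:
    mols = [m for m, _ in r.reactants] + [m for m, _ in r.agents] + list(r.products)
    if any(m.heavy_atoms > cfg.max_heavy_atoms for m in mols):
        return "molecular_size"
    if not (1 <= len(r.reactants) <= cfg.max_reactants):
        return "component_count"
    if len(r.agents) > cfg.max_agents:
        return "component_count"
    if len(r.products) < 1:  # unreachable via ReactionRecord, kept for raw dicts
        return "component_count"
    return None


def record_parses(raw: dict) -> bool:
    """True if every SMILES in a raw JSONL dict parses."""
    from .chem import SmilesParseError, canonicalize_smiles

    smiles = (
        [x["smiles"] for x in raw.get("reactants", [])]
        + [x["smiles"] for x in raw.get("agents", [])]
        + [x["smiles"] for x in raw.get("products", [])]
    )
    try:
        for s in smiles:
            canonicalize_smiles(s)
    except SmilesParseError:
        return False
    return True


# --- vocabulary ----------------------------------------------------------

def build_vocabulary(
    records: Sequence[ReactionRecord], min_count: int = 50
) -> AgentVocabulary:
    """Agents occurring with measurable quantities at least ``min_count`` times.

    Ordered by descending count, ties broken lexicographically, so the
    index assignment is reproducible across runs.
    """
    counts: Counter = Counter()
    for r in records:
        for mol, moles in r.agents:
            if moles is not None:
                counts[mol.smiles] += 1
    agents = sorted(
        (s for s, c in counts.items() if c >= min_count),
        key=lambda s: (-counts[s], s),
    )
    if not agents:
        raise ValueError(f"no agent reaches min_count={min_count}; vocabulary empty")
    return AgentVocabulary(agents)


# --- document split ------------------------------------------------------

@dataclass(frozen=True)
class SplitAssignment:
    assignment: dict  # document_id -> "train" | "val" | "test"

    def split_of(self, document_id: str) -> str:
        return self.assignment[document_id]

    def select(self, records: Sequence[ReactionRecord], split: str) -> list[ReactionRecord]:
        return [r for r in records if self.assignment[r.document_id] == split]


def document_split(
    records: Sequence[ReactionRecord],
    fractions: tuple[float, float, float] = (0.75, 0.05, 0.20),
    seed: int = 0,
) -> SplitAssignment:
    """Shuffle documents with a seeded RNG, partition by cumulative fractions.

    All records of a document share a split; the split is deterministic
    for a fixed seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    docs = sorted({r.document_id for r in records})
    if len(docs) < 3:
        raise ValueError("need at least 3 documents to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(docs))
    docs = [docs[i] for i in order]
    n = len(docs)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_val = min(n_val, n - n_train - 1) if n_train + n_val >= n else n_val
    assignment = {}
    for i, d in enumerate(docs):
        if i < n_train:
            assignment[d] = "train"
        elif i < n_train + n_val:
            assignment[d] = "val"
        else:
            assignment[d] = "test"
    return SplitAssignment(assignment)


# --- stage eligibility ---------------------------------------------------

def stage1_eligible(r: ReactionRecord, vocab: AgentVocabulary) -> bool:
    """Nonempty agent set, all agents in vocabulary."""
    smiles = r.agent_smiles
    return bool(smiles) and all(s in vocab for s in smiles)


def stage2_eligible(r: ReactionRecord, vocab: AgentVocabulary) -> bool:
    return stage1_eligible(r, vocab) and r.temperature_c is not None


def stage3_eligible(r: ReactionRecord, vocab: AgentVocabulary) -> bool:
    return stage1_eligible(r, vocab) and all(q is not None for _, q in r.reactants)


def stage4_eligible(r: ReactionRecord, vocab: AgentVocabulary) -> bool:
    return (
        stage1_eligible(r, vocab)
        and all(q is not None for _, q in r.reactants)
        and all(q is not None for _, q in r.agents)
    )
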