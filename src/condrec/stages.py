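"""The four stage classifiers and their training procedures.

All four stages share the same encoder idea: the reaction is a binary
vector (concatenated reactant/product Morgan-fingerprint blocks), and
condition context enters as a multi-hot agent vector. The encoder is
pluggable via ``FeatureConfig``; only the fingerprint FFN encoder is
implemented here.

* Stage 1 (agent identity): multi-label head over ``|V|+1`` outputs
  (vocabulary plus end-of-set). Training enumerates every partition of
  the true agent set into an input subset and the remaining targets, so
  the model learns to complete any partial set in any order.
* Stage 2 (temperature): 30-way softmax, teacher-forced agent vector.
* Stage 3 (reactant amount): 15-way softmax per reactant; the input
  additionally carries the fingerprint of the specific reactant.
* Stage 4 (agent amount): ``|V|×27`` logits; the agent multi-hot acts
  as a mask so only present agents contribute loss and gradient.

Teacher forcing is structural: the training APIs only ever accept
ground-truth agent sets; predicted agents enter in the inference
pipeline, never here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .binning import BinSchemes
from .chem import (
    AgentVocabulary,
    ReactionRecord,
    molecule_fingerprint,
    reaction_fingerprint,
)
from .nn import MLP, TrainConfig, sigmoid, softmax
from .preprocess import equivalence_ratios

MAX_PARTITION_SET_SIZE = 6


@dataclass(frozen=True)
class FeatureConfig:
    """Encoder configuration shared by all stages (fingerprint FFN)."""

    fp_radius: int = 2
    fp_bits: int = 2048
    encoder: str = "morgan_ffn"  # the only implemented encoder

    def __post_init__(self):
        if self.encoder != "morgan_ffn":
            raise NotImplementedError(
                f"encoder {self.encoder!r} not implemented (only 'morgan_ffn')"
            )


@dataclass(frozen=True)
class ClassTable:
    """Ordered table of most-detailed class labels seen in training.

    Unseen labels at inference encode as the all-zero vector rather than
    erroring (graceful degradation for novel reaction classes).
    """

    classes: tuple[str, ...]

    @classmethod
    def from_records(cls, records: Sequence[ReactionRecord]) -> "ClassTable":
        return cls(tuple(sorted({r.class_id for r in records if r.class_id is not None})))

    def onehot(self, class_id: Optional[str]) -> np.ndarray:
        vec = np.zeros(len(self.classes))
        if class_id is not None and class_id in self.classes:
            vec[self.classes.index(class_id)] = 1.0
        return vec


def enumerate_partitions(
    agent_set: frozenset[int],
    eos_index: int,
    max_set_size: int = MAX_PARTITION_SET_SIZE,
) -> Optional[list[tuple[frozenset[int], frozenset[int]]]]:
    """All (input subset, target set) pairs for one true agent set.

    For each of the ``2^|A|`` subsets S of the true set A, the pair is
    ``(S, A∖S)``, except S = A which pairs with ``{eos}``: given the
    complete set, the correct next step is to stop. Sets larger than
    ``max_set_size`` return ``None`` (caller skips the record) to avoid
    the exponential blow-up.
    """
    agents = sorted(agent_set)
    if len(agents) > max_set_size:
        return None
    pairs = []
    for mask in range(1 << len(agents)):
        subset = frozenset(agents[i] for i in range(len(agents)) if mask >> i & 1)
        rest = agent_set - subset
        if rest:
            pairs.append((subset, rest))
        else:
            pairs.append((subset, frozenset([eos_index])))
    return pairs


@dataclass
class StageModel:
    """A trained stage classifier plus everything needed to rebuild inputs."""

    stage: int
    mlp: MLP
    vocab_hash: str
    scheme_hash: str
    feature_config: FeatureConfig
    class_table: Optional[ClassTable] = None  # stage 1 only
    n_bins: Optional[int] = None  # stages 2-4

    def check_compatible(self, vocab: AgentVocabulary, schemes: BinSchemes) -> None:
        if self.vocab_hash != vocab.content_hash():
            raise ValueError("checkpoint vocabulary hash does not match")
        if self.scheme_hash != schemes.content_hash():
            raise ValueError("checkpoint bin-scheme hash does not match")

    def save(self, path) -> None:
        path = Path(path)
        meta = {
            "stage": self.stage,
            "vocab_hash": self.vocab_hash,
            "scheme_hash": self.scheme_hash,
            "fp_radius": self.feature_config.fp_radius,
            "fp_bits": self.feature_config.fp_bits,
            "encoder": self.feature_config.encoder,
            "classes": list(self.class_table.classes) if self.class_table else None,
            "n_bins": self.n_bins,
        }
        np.savez(path, _meta=json.dumps(meta), **self.mlp.state_dict())

    @classmethod
    def load(cls, path) -> "StageModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["_meta"]))
            mlp = MLP.from_state_dict({k: data[k] for k in data.files if k != "_meta"})
        return cls(
            stage=meta["stage"],
            mlp=mlp,
            vocab_hash=meta["vocab_hash"],
            scheme_hash=meta["scheme_hash"],
            feature_config=FeatureConfig(
                fp_radius=meta["fp_radius"], fp_bits=meta["fp_bits"], encoder=meta["encoder"]
            ),
            class_table=ClassTable(tuple(meta["classes"])) if meta["classes"] else None,
            n_bins=meta["n_bins"],
        )


# --- feature builders ----------------------------------------------------

def _rxn_fp(r: ReactionRecord, fc: FeatureConfig) -> np.ndarray:
    return reaction_fingerprint(r, fc.fp_radius, fc.fp_bits).astype(np.float64)


@dataclass(frozen=True)
class StageDatasets:
    """Model-ready arrays for each stage, built once per record set."""

    vocab: AgentVocabulary
    schemes: BinSchemes
    feature_config: FeatureConfig
    class_table: ClassTable


def agent_index_set(r: ReactionRecord, vocab: AgentVocabulary) -> frozenset[int]:
    return frozenset(vocab.index(s) for s in r.agent_smiles)


def build_stage1_arrays(
    records: Sequence[ReactionRecord],
    vocab: AgentVocabulary,
    class_table: ClassTable,
    fc: FeatureConfig,
    max_set_size: int = MAX_PARTITION_SET_SIZE,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Partition-augmented (X, Y) for stage 1; returns skipped-record count."""
    xs, ys = [], []
    skipped = 0
    v = len(vocab)
    for r in records:
        aset = agent_index_set(r, vocab)
        pairs = enumerate_partitions(aset, vocab.eos_index, max_set_size)
        if pairs is None:
            skipped += 1
            continue
        base = np.concatenate([_rxn_fp(r, fc), class_table.onehot(r.class_id)])
        for subset, target in pairs:
            multihot = np.zeros(v)
            for i in subset:
                multihot[i] = 1.0
            y = np.zeros(v + 1)
            for i in target:
                y[i] = 1.0
            xs.append(np.concatenate([base, multihot]))
            ys.append(y)
    if not xs:
        raise ValueError("no usable stage-1 examples")
    return np.array(xs), np.array(ys), skipped


def build_stage2_arrays(records, vocab, fc: FeatureConfig, schemes: BinSchemes):
    xs, ys = [], []
    for r in records:
        if r.temperature_c is None:
            continue
        multihot = np.zeros(len(vocab))
        for i in agent_index_set(r, vocab):
            multihot[i] = 1.0
        xs.append(np.concatenate([_rxn_fp(r, fc), multihot]))
        ys.append(schemes.temperature.assign(r.temperature_c))
    if not xs:
        raise ValueError("no usable stage-2 examples")
    return np.array(xs), np.array(ys, dtype=np.int64)


def build_stage3_arrays(records, vocab, fc: FeatureConfig, schemes: BinSchemes):
    """One row per (reaction, reactant)."""
    xs, ys = [], []
    for r in records:
        ratios = equivalence_ratios(r)
        multihot = np.zeros(len(vocab))
        for i in agent_index_set(r, vocab):
            multihot[i] = 1.0
        base = np.concatenate([_rxn_fp(r, fc), multihot])
        for (mol, _), ratio in zip(r.reactants, ratios.reactants):
            if ratio is None:
                continue
            rfp = molecule_fingerprint(mol, fc.fp_radius, fc.fp_bits).astype(np.float64)
            xs.append(np.concatenate([base, rfp]))
            ys.append(schemes.reactant.assign(ratio))
    if not xs:
        raise ValueError("no usable stage-3 examples")
    return np.array(xs), np.array(ys, dtype=np.int64)


def build_stage4_arrays(records, vocab, fc: FeatureConfig, schemes: BinSchemes):
    """Labels are (N, |V|) bin indices with −1 for absent agents."""
    xs, ys = [], []
    v = len(vocab)
    for r in records:
        ratios = equivalence_ratios(r)
        multihot = np.zeros(v)
        labels = np.full(v, -1, dtype=np.int64)
        usable = True
        for (mol, _), ratio in zip(r.agents, ratios.agents):
            idx = vocab.index(mol.smiles)
            multihot[idx] = 1.0
            if ratio is None:
                usable = False
                break
            labels[idx] = schemes.agent.assign(ratio)
        if not usable or not r.agents:
            continue
        xs.append(np.concatenate([_rxn_fp(r, fc), multihot]))
        ys.append(labels)
    if not xs:
        raise ValueError("no usable stage-4 examples")
    return np.array(xs), np.array(ys)


# --- trainers ------------------------------------------------------------

def train_stage1(
    records: Sequence[ReactionRecord],
    vocab: AgentVocabulary,
    cfg: TrainConfig,
    schemes: Optional[BinSchemes] = None,
    fc: FeatureConfig = FeatureConfig(),
    class_table: Optional[ClassTable] = None,
) -> StageModel:
    schemes = schemes or BinSchemes.default()
    class_table = class_table or ClassTable.from_records(records)
    x, y, _ = build_stage1_arrays(records, vocab, class_table, fc)
    mlp = MLP(x.shape[1], cfg.hidden_sizes, len(vocab) + 1, seed=cfg.seed)
    mlp.fit(x, y, "bce", cfg)
    return StageModel(
        stage=1, mlp=mlp, vocab_hash=vocab.content_hash(),
        scheme_hash=schemes.content_hash(), feature_config=fc, class_table=class_table,
    )


def train_stage2(
    records, vocab, cfg: TrainConfig,
    schemes: Optional[BinSchemes] = None, fc: FeatureConfig = FeatureConfig(),
) -> StageModel:
    schemes = schemes or BinSchemes.default()
    x, y = build_stage2_arrays(records, vocab, fc, schemes)
    mlp = MLP(x.shape[1], cfg.hidden_sizes, schemes.temperature.n_bins, seed=cfg.seed)
    mlp.fit(x, y, "ce", cfg)
    return StageModel(
        stage=2, mlp=mlp, vocab_hash=vocab.content_hash(),
        scheme_hash=schemes.content_hash(), feature_config=fc,
        n_bins=schemes.temperature.n_bins,
    )


def train_stage3(
    records, vocab, cfg: TrainConfig,
    schemes: Optional[BinSchemes] = None, fc: FeatureConfig = FeatureConfig(),
) -> StageModel:
    schemes = schemes or BinSchemes.default()
    x, y = build_stage3_arrays(records, vocab, fc, schemes)
    mlp = MLP(x.shape[1], cfg.hidden_sizes, schemes.reactant.n_bins, seed=cfg.seed)
    mlp.fit(x, y, "ce", cfg)
    return StageModel(
        stage=3, mlp=mlp, vocab_hash=vocab.content_hash(),
        scheme_hash=schemes.content_hash(), feature_config=fc,
        n_bins=schemes.reactant.n_bins,
    )


def train_stage4(
    records, vocab, cfg: TrainConfig,
    schemes: Optional[BinSchemes] = None, fc: FeatureConfig = FeatureConfig(),
) -> StageModel:
    schemes = schemes or BinSchemes.default()
    x, y = build_stage4_arrays(records, vocab, fc, schemes)
    n_bins = schemes.agent.n_bins
    mlp = MLP(x.shape[1], cfg.hidden_sizes, len(vocab) * n_bins, seed=cfg.seed)
    mlp.fit(x, y, "masked_ce", cfg, n_bins=n_bins)
    return StageModel(
        stage=4, mlp=mlp, vocab_hash=vocab.content_hash(),
        scheme_hash=schemes.content_hash(), feature_config=fc, n_bins=n_bins,
    )


# --- inference -----------------------------------------------------------

def stage1_step_probs(
    model: StageModel, rxn_fp: np.ndarray, class_onehot: np.ndarray, multihot: np.ndarray
) -> np.ndarray:
    """Per-agent (and end-of-set) selection probabilities given a partial set."""
    x = np.concatenate([rxn_fp, class_onehot, multihot])[None, :]
    if x.shape[1] != model.mlp.in_dim:
        raise ValueError(f"input dim {x.shape[1]} != model dim {model.mlp.in_dim}")
    return sigmoid(model.mlp.forward(x))[0]


def stage2_probs(model: StageModel, rxn_fp: np.ndarray, multihot: np.ndarray) -> np.ndarray:
    x = np.concatenate([rxn_fp, multihot])[None, :]
    if x.shape[1] != model.mlp.in_dim:
        raise ValueError(f"input dim {x.shape[1]} != model dim {model.mlp.in_dim}")
    return softmax(model.mlp.forward(x), axis=1)[0]


def stage3_probs(
    model: StageModel, rxn_fp: np.ndarray, multihot: np.ndarray, reactant_fp: np.ndarray
) -> np.ndarray:
    x = np.concatenate([rxn_fp, multihot, reactant_fp])[None, :]
    if x.shape[1] != model.mlp.in_dim:
        raise ValueError(f"input dim {x.shape[1]} != model dim {model.mlp.in_dim}")
    return softmax(model.mlp.forward(x), axis=1)[0]


def stage4_probs(
    model: StageModel, rxn_fp: np.ndarray, multihot: np.ndarray
) -> dict[int, np.ndarray]:
    """One simplex per *present* agent (mask applied to the logit grid)."""
    x = np.concatenate([rxn_fp, multihot])[None, :]
    if x.shape[1] != model.mlp.in_dim:
        raise ValueError(f"input dim {x.shape[1]} != model dim {model.mlp.in_dim}")
    logits = model.mlp.forward(x)[0].reshape(-1, model.n_bins)
    return {int(i): softmax(logits[int(i)]) for i in np.flatnonzero(multihot)}
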