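"""End-to-end orchestration: simulate → preprocess → train → recommend → evaluate.

At inference the flow follows the deployment order: stage 1 decodes
candidate agent sets by beam search, then stages 2–4 consume the
*predicted* agents (in contrast to teacher-forced training) and run
independently of each other. A single config seed drives every source
of randomness so a rerun reproduces the report bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .baselines import ClassIndex, nn_predict, popularity_predict
from .binning import BinSchemes
from .chem import AgentVocabulary, ReactionRecord, molecule_fingerprint, reaction_fingerprint
from .decoding import (
    AgentSetHypothesis,
    ConditionSet,
    ConfidenceWeights,
    StageOutputs,
    beam_search_agents,
    combine_conditions,
)
from .evaluation import (
    bin_mae,
    end_to_end_correct,
    relaxed_set_equal,
    topk_accuracy,
    win_rate,
)
from .nn import TrainConfig
from .preprocess import (
    FilterConfig,
    deduplicate,
    document_split,
    equivalence_ratios,
    filter_records,
    stage1_eligible,
    stage2_eligible,
    stage3_eligible,
    stage4_eligible,
)
from .stages import (
    ClassTable,
    FeatureConfig,
    StageModel,
    agent_index_set,
    stage1_step_probs,
    stage2_probs,
    stage3_probs,
    stage4_probs,
    train_stage1,
    train_stage2,
    train_stage3,
    train_stage4,
)
from .synthetic import WorldConfig, generate_world, sample_records


def record_conditions(
    r: ReactionRecord, vocab: AgentVocabulary, schemes: Optional[BinSchemes] = None
) -> ConditionSet:
    """The ground-truth ConditionSet of a fully annotated record."""
    s = schemes or BinSchemes.default()
    ratios = equivalence_ratios(r)
    if any(x is None for x in ratios.reactants) or any(x is None for x in ratios.agents):
        raise ValueError("record is missing quantities required for full conditions")
    if r.temperature_c is None:
        raise ValueError("record has no temperature")
    return ConditionSet(
        agents=agent_index_set(r, vocab),
        temperature_bin=s.temperature.assign(r.temperature_c),
        reactant_bins=tuple(s.reactant.assign(x) for x in ratios.reactants),
        agent_bins=tuple(
            sorted(
                (vocab.index(m.smiles), s.agent.assign(x))
                for (m, _), x in zip(r.agents, ratios.agents)
            )
        ),
    )


@dataclass
class Recommender:
    """The four trained stage models bundled for end-to-end inference."""

    stage1: StageModel
    stage2: StageModel
    stage3: StageModel
    stage4: StageModel
    vocab: AgentVocabulary
    schemes: BinSchemes
    beam_width: int = 10
    max_agents: int = 6

    def __post_init__(self):
        for m in (self.stage1, self.stage2, self.stage3, self.stage4):
            m.check_compatible(self.vocab, self.schemes)

    def stage_outputs(
        self, record: ReactionRecord, n_sets: int = 10
    ) -> list[StageOutputs]:
        """Beam-decode agent sets, then condition stages 2–4 on each."""
        fc = self.stage1.feature_config
        rxn_fp = reaction_fingerprint(record, fc.fp_radius, fc.fp_bits).astype(float)
        class_onehot = self.stage1.class_table.onehot(record.class_id)

        def step_fn(multihot: np.ndarray) -> np.ndarray:
            return stage1_step_probs(self.stage1, rxn_fp, class_onehot, multihot)

        hyps = beam_search_agents(
            step_fn, len(self.vocab), width=self.beam_width, max_len=self.max_agents
        )
        reactant_fps = [
            molecule_fingerprint(m, fc.fp_radius, fc.fp_bits).astype(float)
            for m, _ in record.reactants
        ]
        outputs = []
        for hyp in hyps[:n_sets]:
            multihot = np.zeros(len(self.vocab))
            for i in hyp.agents:
                multihot[i] = 1.0
            temp = stage2_probs(self.stage2, rxn_fp, multihot)
            reacts = tuple(
                stage3_probs(self.stage3, rxn_fp, multihot, rfp) for rfp in reactant_fps
            )
            agent_dists = tuple(sorted(stage4_probs(self.stage4, rxn_fp, multihot).items()))
            outputs.append(
                StageOutputs(
                    agent_hypothesis=hyp,
                    temperature_dist=temp,
                    reactant_dists=reacts,
                    agent_dists=agent_dists,
                )
            )
        return outputs

    def recommend(
        self,
        record: ReactionRecord,
        counts: tuple[int, int, int, int] = (10, 2, 2, 2),
        weights: ConfidenceWeights = ConfidenceWeights(),
    ) -> list[ConditionSet]:
        return combine_conditions(self.stage_outputs(record, counts[0]), counts, weights)


def describe_prediction(
    cs: ConditionSet, vocab: AgentVocabulary, schemes: BinSchemes
) -> dict:
    """Human-readable rendering using each bin's representative value.

    The 0–10 °C temperature bin is reported as 5 °C, the bin around 1.0
    eq as 1.0 eq, and so on — single values inside the predicted
    intervals rather than the intervals themselves.
    """
    agents = sorted(vocab.agents[i] for i in cs.agents)
    return {
        "agents": agents if agents else "no agents",
        "temperature_c": schemes.temperature.representatives[cs.temperature_bin],
        "reactant_equivalents": [
            schemes.reactant.representatives[b] for b in cs.reactant_bins
        ],
        "agent_equivalents": {
            vocab.agents[i]: schemes.agent.representatives[b] for i, b in cs.agent_bins
        },
        "score": cs.score,
    }


# --- full pipeline -------------------------------------------------------

@dataclass
class RunConfig:
    """Single config driving a full simulate→evaluate run."""

    world: WorldConfig = field(default_factory=WorldConfig)
    n_records: int = 10_000
    filter: FilterConfig = field(default_factory=FilterConfig)
    deduplicate: bool = False  # synthetic corpora repeat protocols by design
    vocab_min_count: int = 50
    split_fractions: tuple[float, float, float] = (0.75, 0.05, 0.20)
    train: TrainConfig = field(default_factory=TrainConfig)
    feature: FeatureConfig = field(default_factory=FeatureConfig)
    beam_width: int = 10
    counts: tuple[int, int, int, int] = (10, 2, 2, 2)
    weights: ConfidenceWeights = field(default_factory=ConfidenceWeights)
    top_k: int = 10
    max_eval_queries: Optional[int] = None
    seed: int = 0

    def config_hash(self) -> str:
        payload = repr(self).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Execute the whole workflow and write artifacts under ``out_dir``.

    Returns the evaluation report (also written as ``report.json``).
    Any stage failure propagates with the stage named in the message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

    schemes = BinSchemes.default()
    world = _stage("simulate", lambda: generate_world(cfg.world))
    records = _stage("simulate", lambda: sample_records(world, cfg.n_records, seed=cfg.seed))

    def _preprocess():
        kept, rejects = filter_records(records, cfg.filter)
        n_dup = 0
        if cfg.deduplicate:
            kept, n_dup = deduplicate(kept, schemes)
        vocab = world.vocabulary  # the simulated corpus shares the world vocabulary
        split = document_split(kept, cfg.split_fractions, seed=cfg.seed)
        return kept, rejects, n_dup, vocab, split

    kept, rejects, n_dup, vocab, split = _stage("preprocess", _preprocess)
    train_recs = split.select(kept, "train")
    val_recs = split.select(kept, "val")
    test_recs = split.select(kept, "test")
    vocab.save(out / "vocab.txt")

    def _eligible(recs, pred):
        return [r for r in recs if pred(r, vocab)]

    models = {}
    trainers = {
        1: (train_stage1, stage1_eligible),
        2: (train_stage2, stage2_eligible),
        3: (train_stage3, stage3_eligible),
        4: (train_stage4, stage4_eligible),
    }
    for stage_id, (trainer, elig) in trainers.items():
        data = _eligible(train_recs, elig)
        if stage_id == 1:
            model = _stage(f"train_stage{stage_id}",
                           lambda: trainer(data, vocab, cfg.train, schemes, cfg.feature))
        else:
            model = _stage(f"train_stage{stage_id}",
                           lambda: trainer(data, vocab, cfg.train, schemes, cfg.feature))
        model.save(out / f"stage{stage_id}.npz")
        models[stage_id] = model

    rec = Recommender(
        models[1], models[2], models[3], models[4], vocab, schemes,
        beam_width=cfg.beam_width,
    )

    eval_recs = _eligible(test_recs, stage4_eligible)
    eval_recs = [r for r in eval_recs if r.temperature_c is not None]
    if cfg.max_eval_queries is not None:
        eval_recs = eval_recs[: cfg.max_eval_queries]

    def _evaluate():
        index = ClassIndex(_eligible(train_recs, stage4_eligible), vocab, schemes, cfg.feature)
        truths, model_preds, pop_preds, nn_preds = [], [], [], []
        for r in eval_recs:
            truths.append(record_conditions(r, vocab, schemes))
            model_preds.append(rec.recommend(r, cfg.counts, cfg.weights)[: cfg.top_k])
            pop_preds.append(
                list(popularity_predict(index, r.class_id, "holistic", cfg.top_k).items)
            )
            nn_preds.append(list(nn_predict(index, r, cfg.top_k, "holistic").items))
        report = {"n_queries": len(truths), **stamp,
                  "n_rejected": sum(rejects.values()), "n_deduplicated": n_dup}
        for name, preds in (("model", model_preds), ("popularity", pop_preds), ("nn", nn_preds)):
            for k in (1, 5, cfg.top_k):
                hits = sum(
                    any(end_to_end_correct(p, t).overall for p in ps[:k])
                    for ps, t in zip(preds, truths)
                )
                report[f"{name}_top{k}_exact"] = hits / len(truths) if truths else 0.0
        wr = win_rate(model_preds, nn_preds, truths, top_k=cfg.top_k)
        if None in wr:
            report["model_vs_nn_win_rate"] = wr[None].win_rate
            report["model_vs_nn_ci"] = [wr[None].ci_low, wr[None].ci_high]
        return report

    report = _stage("evaluate", _evaluate)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
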