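"""Train the four stage models on a synthetic world and recommend
conditions for a held-out reaction.

Stage 1 decodes candidate agent sets by beam search; stages 2-4 then
predict temperature and equivalence-ratio bins conditioned on the
predicted agents. The top candidates are Cartesian combinations
(10 agent sets × 2 temperatures × 2 reactant × 2 agent assignments)
ranked by the weighted geometric mean of stage confidences.
"""

from condrec import (
    BinSchemes,
    Recommender,
    TrainConfig,
    WorldConfig,
    describe_prediction,
    generate_world,
    record_conditions,
    sample_records,
    train_stage1,
    train_stage2,
    train_stage3,
    train_stage4,
)
from condrec.stages import FeatureConfig

world = generate_world(WorldConfig(n_classes=2, vocab_size=16, seed=5))
train = sample_records(world, 2000, seed=51)
query = sample_records(world, 10, seed=52)[3]

fc = FeatureConfig(fp_bits=512)
tc = TrainConfig(hidden_sizes=(256,), epochs=10, seed=5)
schemes = BinSchemes.default()
vocab = world.vocabulary
models = [
    trainer(train, vocab, tc, schemes, fc)
    for trainer in (train_stage1, train_stage2, train_stage3, train_stage4)
]
rec = Recommender(*models, vocab=vocab, schemes=schemes)

print(f"query reaction: {query.rxn_smiles().split('>')[0]} >> products, class {query.class_id}")
truth = record_conditions(query, vocab, schemes)
print(f"recorded conditions: agents {sorted(vocab.agents[i] for i in truth.agents)}, "
      f"temperature bin {truth.temperature_bin}")

for rank, cs in enumerate(rec.recommend(query)[:3], 1):
    d = describe_prediction(cs, vocab, schemes)
    print(f"rank {rank} (confidence {d['score']:.3f}): agents {d['agents']}, "
          f"{d['temperature_c']:.0f} °C, reactant eq {d['reactant_equivalents']}")
    exact = cs.agents == truth.agents and cs.temperature_bin == truth.temperature_bin
    print(f"  agents+temperature match recorded conditions: {exact}")
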