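"""Generate a synthetic reaction corpus and run it through preprocessing.

The generator manufactures document-grouped records from latent
substrate→condition rules; preprocessing filters, deduplicates at the
condition level, builds the quantified-agent vocabulary and splits by
document so evaluation is on held-out patents.
"""

from condrec import (
    WorldConfig,
    build_vocabulary,
    deduplicate,
    document_split,
    equivalence_ratios,
    filter_records,
    generate_world,
    sample_records,
)

world = generate_world(WorldConfig(n_classes=3, vocab_size=24, seed=7))
records = sample_records(world, 3000, seed=7)
print(f"simulated {len(records)} records across "
      f"{len({r.document_id for r in records})} documents")

kept, rejects = filter_records(records)
deduped, n_dup = deduplicate(kept)
print(f"filters kept {len(kept)} (rejections: {dict(rejects)}); "
      f"condition-level dedup removed {n_dup}")

vocab = build_vocabulary(kept, min_count=5)
print(f"vocabulary: {len(vocab)} agents with measurable quantities, e.g. {vocab.agents[:3]}")

split = document_split(kept, seed=7)
sizes = {s: len(split.select(kept, s)) for s in ("train", "val", "test")}
print(f"document split sizes: {sizes} (75/5/20 by documents, records follow their document)")

r = kept[0]
ratios = equivalence_ratios(r)
print(f"example reaction {r.rxn_smiles()[:60]}...")
print(f"  reactant equivalence ratios {tuple(round(x, 3) for x in ratios.reactants)} "
      f"(limiting reactant is exactly 1.0)")
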