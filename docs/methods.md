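# Methods

## Task decomposition

A reaction condition is modeled as a tuple (agent set, temperature bin,
reactant amount bins, agent amount bins). The four components are
predicted by separate classifiers chained in deployment order: agents
first, then temperature and the two amount tasks conditioned on the
predicted agents. There are no dependencies among the last three stages
— temperature predictions never influence quantity predictions.

The discretized (rather than regressed) formulation is deliberate:
empirical distributions of reaction temperatures and equivalence ratios
are highly irregular, with sharp peaks at conventional set points
(−78 °C, 0 °C, room temperature, 80–120 °C; 1.0/1.5/2.0/2.5 eq), and a
regression head smears across them. Binned classification with
representative values preserves the multimodality and makes "how wrong"
auditable in bin units (off-by-N accuracy, bin-MAE).

### Reaction representation

Molecules are canonicalized with RDKit at construction; a reaction is
encoded as the bitwise OR of the Morgan fingerprints of its reactants
concatenated with the same for its products (radius 2, 2048 bits per
block by default; both configurable). OR-combination within a block
makes the encoding invariant to species order and duplication. The
encoder is a pluggable configuration point (`FeatureConfig.encoder`);
only the fingerprint encoder is implemented — a graph-network encoder
would slot into the same interface.

Radius 2 and binary (not count) fingerprints are conventions chosen
here; both are parameters of every fingerprint call.

### Stage models and training

All four stages are ReLU MLPs trained with Adam. The package implements
the network and backprop directly in numpy (`condrec.nn`): the models
are small dense networks over binary inputs, three loss heads are
needed (sigmoid BCE; softmax CE; grouped masked CE), and having the
gradients in hand makes the masking contract checkable by finite
differences. Everything is deterministic given the config seed.

- **Stage 1** trains on all 2^|A| partitions of the true agent set into
  an input subset and the remaining targets (the complete set pairs
  with the end-of-set symbol). Sets larger than 6 agents are skipped —
  the enumeration is exponential and reported agent-set sizes
  concentrate at 2–3. The head is |V|+1 independent sigmoids under BCE;
  each output is read as the probability of selecting that agent (or
  stopping) given the partial set. A softmax alternative would
  renormalize over non-members; the sigmoid default matches the
  multi-label training objective.
- **Stages 2–4** are trained with teacher forcing: the training APIs
  accept ground-truth agent vectors only, so no stage-1 prediction can
  leak into training by construction.
- **Stage 4** reshapes its output to (|V|, 27); the loss averages the
  per-agent cross-entropy over *present* agents only. Absent agents'
  logits receive exactly zero gradient — verified numerically in the
  test suite (finite differences < 1e−8).

Default hyperparameters (hidden (256,), lr 1e−3, batch 256, 10–15
epochs) are modest because the fingerprint targets here are low-entropy;
they are all `TrainConfig` fields.

### Beam-search set decoding

Inference decodes agent sets autoregressively: extend the partial set
with any non-member (probability = the stage-1 output for that agent
given the partial set) or terminate with end-of-set. The joint
probability of an ordered decode is the product of its step
probabilities; decodes reaching the same unordered set are merged by
summing. Because the step model conditions only on the *set* of chosen
agents (not their order), partial hypotheses that collide on the same
set can be merged during the search without changing any merged total —
this implementation does so, which also makes the beam exact whenever
its width covers all reachable sets. The test suite checks rank and
probability agreement with exhaustive enumeration over all ordered
decodes to 1e−9. Ties in ranking break toward smaller sets, then
lexicographic indices, so decoding is fully deterministic.

### End-to-end combination and confidence

For each of the top 10 agent sets, the top 2 temperature bins, top 2
joint reactant-bin assignments and top 2 joint agent-bin assignments
are combined (≤80 candidates). Joint assignments over independent
per-component simplexes use a per-component beam of width m, exact for
m ≤ 2 on up to four components (verified against brute force). Each
candidate is scored exp(Σ wᵢ ln cᵢ / Σ wᵢ) with c₁ = merged set
probability, c₂ = chosen temperature-bin probability, c₃/c₄ = joint
assignment probabilities — these per-stage confidence definitions are
this package's own. Weights come from a grid search over
{0.25, 0.5, 1, 2}⁴ maximizing end-to-end top-10 exact accuracy on
validation data, ties to the first lattice point.

## Data handling

Quantities standardize to moles from mol/mmol/g/mL only; anything else
errors loudly rather than guessing (solution parsing from free text is
out of scope). Equivalence ratios divide by the limiting reactant (the
minimum-mole reactant, ties to the lowest index), so exactly one
reactant ratio is 1.0 by construction. Deduplication keys on the
reaction species plus all binned conditions — the same reaction at a
different temperature bin survives; the same protocol in two documents
does not. Filters (≤100 heavy atoms, ≤5 reactants, ≤8 agents,
parsability) count rejections per rule instead of raising. The agent
vocabulary keeps agents observed with measurable quantities at least 50
times, ordered count-descending then lexicographic so indices are
reproducible. Splits are by document (75/5/20), shuffled with the
config seed, so test reactions come from unseen patents.

Stage eligibility is realized as predicates: stage 1 needs a nonempty
in-vocabulary agent set; stage 2 adds a recorded temperature; stage 3
all reactant moles; stage 4 all agent moles.

## Baselines

Both baselines are class-conditional (the most detailed class label)
and are pure functions of the training index. Popularity ranks agent
sets / temperature bins / complete condition sets by in-class
frequency; its reactant-amount variant is the constant 1.0 eq bin (a
majority baseline — every reaction has a limiting reactant). Nearest
neighbor ranks same-class training reactions by Tanimoto over reaction
fingerprints — deliberately agent-blind for temperature — and adopts
their conditions, holistically or per task. Unseen classes return an
empty prediction flagged as such; a global fallback exists as an option
but defaults off, matching the class-conditional definition.

## Evaluation

Relaxed agent accuracy ignores water on both sides (its reporting in
reaction data is too inconsistent to score). End-to-end correctness is
the conjunction of: strict index-level agent-set equality; temperature
bin equality; equality of the *multiset* of reactant bins (retrieval
baselines cannot assign bins to specific reactants, so no
reactant-to-bin correspondence is enforced — applied identically to
models and baselines); and per-agent bin equality. Reaction-level
amount predictions bucket into exact / off-by-one (all within ±1,
excluding exact) / major deviation — mutually exclusive and exhaustive.

Win rates compare two methods' top-10 lists per query: a method wins
when only it contains a correct set; queries where neither is correct
are excluded; both-correct queries count half a win each (the
alternative — excluding ties — is a flag). Intervals are Wilson 95%
(Clopper–Pearson available via the same flag); an advantage is called
significant when the lower bound exceeds 50%.

## Synthetic worlds

The generator manufactures corpora with the statistical structure of
patent-mined reaction data: document-grouped records, variable-length
agent sets from a real-chemical vocabulary (a built-in table of 120
canonicalized solvents/bases/acids/catalysts/reagents), temperatures at
the conventional set points, reactant ratios peaked at 1.0–2.5 eq, and
agent amounts spanning catalytic (0.03 eq), stoichiometric (1–2.5 eq)
and solvent-scale (12–60 eq) regimes. Nominal targets sit strictly
inside their default bins so that with zero noise the binned conditions
equal the rule conditions exactly, independent of floating-point
rounding of mole ratios.

Each class contains two (configurable) substrate families realized as
disjoint scaffold sets with different agent sets, distinct temperature
means and distinct co-reactant stoichiometries. This is the property
under test: class popularity caps at the majority-family share while a
fingerprint-reading model can recover the family rule. Noise enters as
an agent-swap probability (label noise), Gaussian temperature jitter,
and uniform multiplicative amount jitter (±2% by default, small enough
to stay within the nominal narrow bins).

What the generator does *not* emulate: chemically valid products (the
product is the fragment union of the reactants — fingerprint-consistent
but not a real transformation), imbalanced family frequencies, OCR and
text-mining artifacts, long-tail vocabulary distributions, and
correlations between condition components beyond the family rule.
Passing the recovery tests therefore demonstrates that the pipeline
learns substrate-conditional structure through fingerprints; it does
not certify accuracy on real literature data.

## Problem sizes and numerical choices

Tests and the acceptance script run the recovery experiment at 8000
training / 2000 test records, a 32-agent vocabulary and 512-bit
fingerprint blocks with a single 256-unit hidden layer — sizes at which
the separable worlds are comfortably learnable and a full run takes a
few minutes on one CPU; the library defaults remain 2048 bits.
Out-of-range values clip to the boundary bins (extreme solvent ratios
are expected, not errors). All bins are half-open [lo, hi); a value on
an interior edge belongs to the upper bin. Tanimoto of two all-zero
fingerprints is defined as 0. Unseen class labels at inference encode
as an all-zero one-hot rather than erroring.

## Known limitations

- Only the fingerprint FFN encoder is implemented; the encoder
  interface exists for graph-based alternatives.
- Agent sets larger than 6 are excluded from stage-1 training and beam
  decoding length is capped at 6.
- The per-stage confidence definitions and the win-rate tie handling
  are package conventions (documented above), configurable where a
  reasonable alternative exists.
- Evaluation scores against the single recorded condition set per
  record; unions of reported alternatives and chemical-similarity-aware
  credit are out of scope.
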