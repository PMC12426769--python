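"""Synthetic reaction corpora with known substrate→condition rules.

Commercial reaction corpora cannot ship with the package, so this module
manufactures document-grouped reaction records whose statistical
structure mirrors what patent-mined data looks like: variable-length
agent sets drawn from a fixed vocabulary of real reagents/solvents/
catalysts, temperatures concentrated at the familiar set points (−78 °C
dry ice, 0 °C ice bath, room temperature, 80–120 °C heating),
reactant equivalence ratios peaked at 1.0/1.5/2.0/2.5, and agent
amounts spanning catalytic through solvent-scale regimes.

Crucially, each reaction class contains two (or more) *substrate
families* realized as disjoint scaffold sets with different condition
rules, so the correct conditions depend on the substrate and not just
the class label. A class-popularity recommender therefore caps out at
the majority-family frequency, while a model reading the fingerprint
can recover the rule — the qualitative behavior the learned stages must
reproduce. Products are scaffold-derived placeholders (the fragment
union of the reactants), not chemically valid transformations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .binning import BinSchemes
from .chem import AgentVocabulary, Molecule, ReactionRecord, canonicalize_smiles

# Common solvents, bases, acids, catalysts/ligands and stock reagents.
# All parse with RDKit; canonicalized (and checked unique) at world build.
AGENT_TABLE: tuple[str, ...] = (
    # solvents
    "O", "CO", "CCO", "CC(C)O", "CCCCO", "C1CCOC1", "ClCCl", "ClC(Cl)Cl",
    "CN(C)C=O", "CS(C)=O", "CC#N", "Cc1ccccc1", "C1COCCO1", "CCOC(C)=O",
    "CCOCC", "CN1CCCC1=O", "CC(=O)N(C)C", "CC(C)=O", "CCCCCC", "CCCCCCC",
    "c1ccccc1", "Cc1ccccc1C", "Cc1cccc(C)c1", "c1ccncc1", "COC(C)(C)C",
    "COCCOC", "OCCO", "ClCCCl", "CC(C)CO", "OCC(F)(F)F",
    # bases
    "O=C([O-])[O-].[K+].[K+]", "O=C([O-])[O-].[Na+].[Na+]",
    "O=C([O-])[O-].[Cs+].[Cs+]", "O=C([O-])O.[Na+]", "[K+].[OH-]",
    "[Na+].[OH-]", "[Li+].[OH-]", "[H-].[Na+]", "CC(C)(C)[O-].[K+]",
    "C[O-].[Na+]", "CC[O-].[Na+]", "CCN(CC)CC", "CCN(C(C)C)C(C)C",
    "C1CCC2=NCCCN2CC1", "Cn1ccnc1", "Cc1ccc(N)cc1", "c1ccc(N)cc1",
    "O=P([O-])([O-])[O-].[K+].[K+].[K+]", "[F-].[K+]", "[F-].[Cs+]",
    "[Li]CCCC", "CC(C)[N-]C(C)C.[Li+]", "C[Si](C)(C)[N-][Si](C)(C)C.[Li+]",
    "CC(=O)[O-].[Na+]", "CC(=O)[O-].[K+]", "N", "NCCN", "CNC",
    # acids
    "Cl", "Br", "OS(=O)(=O)O", "Cc1ccc(S(=O)(=O)O)cc1", "CS(=O)(=O)O",
    "OC(=O)C(F)(F)F", "CC(=O)O", "O=C(O)C=CC(=O)O", "OC(=O)C(O)C(O)C(=O)O",
    "O=[N+]([O-])O", "OP(=O)(O)O", "O=C(O)O",
    # catalysts, metals, ligands
    "CC(=O)O[Pd]OC(C)=O", "[Pd]", "Cl[Pd]Cl", "[Pt]", "O=[Pt]",
    "c1ccc(P(c2ccccc2)c2ccccc2)cc1", "CC(C)(C)P(C(C)(C)C)C(C)(C)C",
    "[Cu]I", "[Cu]Br", "[Cu]", "[Zn]", "[Fe]", "[Ni]", "[Mg]",
    "Cl[Ni]Cl", "O=[Mn]=O", "CC(=O)O[Cu]OC(C)=O",
    "[Rh]", "[Ru]", "Cl[Zn]Cl", "Cl[Fe](Cl)Cl",
    # stock reagents
    "[Na+].[BH4-]", "[Li+].[AlH4-]", "[H][H]", "[NH4+].[Cl-]",
    "O=S(Cl)Cl", "O=C(Cl)C(=O)Cl", "C(=NC1CCCCC1)=NC1CCCCC1",
    "CCN=C=NCCCN(C)C", "On1nnc2ccccc21", "O=C(n1ccnc1)n1ccnc1",
    "CC(C)(C)OC(=O)OC(=O)OC(C)(C)C", "O=C1CCC(=O)N1Br", "O=C1CCC(=O)N1Cl",
    "O=C1CCC(=O)N1I", "OO", "II", "BrBr", "P(Br)(Br)Br", "O=P(Cl)(Cl)Cl",
    "C[Si](C)(C)Cl", "O=S(=O)([O-])[O-].[Mg+2]", "O=S(=O)([O-])[O-].[Na+].[Na+]",
    "[Na+].[Cl-]", "[K+].[I-]", "[Na+].[N-]=[N+]=[N-]", "N#C[Na]",
    "O=[N+]([O-])[O-].[Na+]", "C=O", "CC(C)=O.CC(C)=O",
)

# Reactant scaffolds: structurally distinct series so Morgan fingerprints
# separate families. Disjoint subsets are dealt to substrate families.
SCAFFOLD_TABLE: tuple[str, ...] = (
    "Brc1ccccc1", "Brc1ccc(F)cc1", "Brc1ccc(C)cc1", "Brc1ccc(OC)cc1",
    "Brc1ccc(C#N)cc1", "Brc1cccnc1", "Brc1ccncc1", "Brc1ccc2ccccc2c1",
    "Clc1ccccc1", "Clc1ccc(F)cc1", "Clc1ccc(OC)cc1", "Clc1ncccn1",
    "Ic1ccccc1", "Ic1ccc(C)cc1", "Ic1ccc(F)cc1",
    "O=Cc1ccccc1", "O=Cc1ccc(F)cc1", "O=Cc1ccc(OC)cc1", "O=Cc1cccnc1",
    "CC(=O)c1ccccc1", "CC(=O)c1ccc(C)cc1",
    "O=C(O)c1ccccc1", "O=C(O)c1ccc(F)cc1", "O=C(O)c1cccnc1",
    "COC(=O)c1ccccc1", "COC(=O)c1ccc(C)cc1",
    "Nc1ccccc1F", "Nc1ccc(Cl)cc1", "Nc1cccc2ccccc12",
    "Oc1ccccc1Cl", "Oc1ccc(Br)cc1", "Oc1ccc2ccccc2c1",
    "O=[N+]([O-])c1ccccc1", "O=[N+]([O-])c1ccc(Cl)cc1",
    "C=Cc1ccccc1", "C#Cc1ccccc1", "OCc1ccccc1Br", "NCc1ccccc1Cl",
    "c1ccc2[nH]ccc2c1", "c1ccc2occc2c1", "c1ccc2sccc2c1",
    "O=C1CCCCC1", "O=C1CCCC1", "C1CCNCC1",
)

# Co-reactants: coupling partners / nucleophiles used as the second,
# excess reactant of each family.
COREACTANT_TABLE: tuple[str, ...] = (
    "OB(O)c1ccccc1", "OB(O)c1ccc(C)cc1", "OB(O)c1ccc(F)cc1",
    "NCc1ccccc1", "OCc1ccccc1", "C=Cc1ccccc1C", "C1COCCN1",
    "NC1CCCCC1", "Nc1ccccc1C", "OCCN", "CC(=O)Cl", "CCI",
)

TEMPERATURE_PEAKS: tuple[float, ...] = (-78.0, 0.0, 25.0, 80.0, 100.0, 120.0)
COREACTANT_EQ_TARGETS: tuple[float, ...] = (1.1, 1.5, 2.0, 2.5)
# Nominal targets sit strictly inside their default bins (never on an
# edge), so the recovered bin label is insensitive to floating-point
# rounding of moles ratios.
STOICH_EQ_TARGETS: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5)
SOLVENT_EQ_TARGETS: tuple[float, ...] = (12.0, 30.0, 60.0)
CATALYTIC_EQ = 0.03


@dataclass(frozen=True)
class WorldConfig:
    n_classes: int = 4
    vocab_size: int = 32
    families_per_class: int = 2
    scaffolds_per_family: int = 2
    agent_swap_prob: float = 0.05
    temperature_jitter_c: float = 5.0
    amount_jitter_frac: float = 0.02
    n_documents: int = 100
    records_per_document: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.agent_swap_prob <= 1:
            raise ValueError("agent_swap_prob must be a probability")
        if min(self.n_classes, self.vocab_size, self.families_per_class,
               self.scaffolds_per_family, self.n_documents, self.records_per_document) <= 0:
            raise ValueError("sizes must be positive")
        if self.temperature_jitter_c < 0 or self.amount_jitter_frac < 0:
            raise ValueError("noise magnitudes must be non-negative")


@dataclass(frozen=True)
class ConditionRule:
    """The latent ground-truth protocol of one (class, family)."""

    agent_indices: tuple[int, ...]  # sorted vocabulary indices
    temperature_mean_c: float
    coreactant_eq: float  # limiting reactant is fixed at 1.0
    agent_eqs: tuple[float, ...]  # aligned with agent_indices
    coreactant: Molecule
    scaffolds: tuple[Molecule, ...]


@dataclass(frozen=True)
class GroundTruthConditions:
    """Noiseless rule conditions, binned with the default schemes."""

    agent_indices: frozenset[int]
    temperature_bin: int
    reactant_bins: tuple[int, ...]
    agent_bins: dict  # vocabulary index -> bin


@dataclass
class SyntheticWorld:
    config: WorldConfig
    vocabulary: AgentVocabulary
    rules: dict  # (class, family) -> ConditionRule
    scaffold_to_family: dict  # scaffold SMILES -> (class, family)
    schemes: BinSchemes = field(default_factory=BinSchemes.default)

    def class_label(self, c: int) -> str:
        return f"{c + 1}.{c + 1}.{c + 1}"


def generate_world(cfg: WorldConfig) -> SyntheticWorld:
    """Build a deterministic world of substrate-conditional rules.

    Within each class, families draw *distinct* temperature means,
    distinct co-reactant equivalence targets and agent sets differing in
    at least one member, so conditions genuinely depend on the substrate
    family rather than the class label alone.
    """
    rng = np.random.default_rng(cfg.seed)
    canon_agents = []
    seen = set()
    for s in AGENT_TABLE:
        c = canonicalize_smiles(s)
        if c not in seen:
            seen.add(c)
            canon_agents.append(c)
    if cfg.vocab_size > len(canon_agents):
        raise ValueError(
            f"vocab_size {cfg.vocab_size} exceeds built-in agent table ({len(canon_agents)})"
        )
    pick = rng.choice(len(canon_agents), size=cfg.vocab_size, replace=False)
    vocab = AgentVocabulary([canon_agents[i] for i in sorted(pick)])

    n_scaffolds = cfg.n_classes * cfg.families_per_class * cfg.scaffolds_per_family
    if n_scaffolds > len(SCAFFOLD_TABLE):
        raise ValueError("not enough built-in scaffolds for this configuration")
    scaffold_order = rng.permutation(len(SCAFFOLD_TABLE))[:n_scaffolds]

    rules: dict = {}
    scaffold_to_family: dict = {}
    cursor = 0
    for c in range(cfg.n_classes):
        temps = rng.choice(
            len(TEMPERATURE_PEAKS), size=cfg.families_per_class, replace=False
        )
        eqs = rng.choice(
            len(COREACTANT_EQ_TARGETS),
            size=min(cfg.families_per_class, len(COREACTANT_EQ_TARGETS)),
            replace=False,
        )
        family_sets: list[tuple[int, ...]] = []
        for f in range(cfg.families_per_class):
            scaffolds = []
            for _ in range(cfg.scaffolds_per_family):
                smi = canonicalize_smiles(SCAFFOLD_TABLE[scaffold_order[cursor]])
                scaffolds.append(Molecule(smi))
                scaffold_to_family[smi] = (c, f)
                cursor += 1
            while True:
                size = int(rng.integers(1, 5))
                agent_idx = tuple(sorted(int(i) for i in rng.choice(len(vocab), size=size, replace=False)))
                if agent_idx not in family_sets:
                    break
            family_sets.append(agent_idx)
            roles = rng.random(len(agent_idx))
            agent_eqs = []
            for j, r in enumerate(roles):
                if r < 0.3:
                    agent_eqs.append(CATALYTIC_EQ)
                elif r < 0.7:
                    agent_eqs.append(float(rng.choice(STOICH_EQ_TARGETS)))
                else:
                    agent_eqs.append(float(rng.choice(SOLVENT_EQ_TARGETS)))
            coreactant = Molecule(
                canonicalize_smiles(
                    COREACTANT_TABLE[int(rng.integers(len(COREACTANT_TABLE)))]
                )
            )
            rules[(c, f)] = ConditionRule(
                agent_indices=agent_idx,
                temperature_mean_c=TEMPERATURE_PEAKS[temps[f]],
                coreactant_eq=COREACTANT_EQ_TARGETS[eqs[f % len(eqs)]],
                agent_eqs=tuple(agent_eqs),
                coreactant=coreactant,
                scaffolds=tuple(scaffolds),
            )
    world = SyntheticWorld(
        config=cfg, vocabulary=vocab, rules=rules, scaffold_to_family=scaffold_to_family
    )
    _ensure_regime_spread(world, rng)
    return world


def _ensure_regime_spread(world: SyntheticWorld, rng: np.random.Generator) -> None:
    """Guarantee agent amounts span at least two stoichiometric regimes."""
    regimes = set()
    for rule in world.rules.values():
        for eq in rule.agent_eqs:
            regimes.add("cat" if eq < 0.5 else ("solv" if eq > 5 else "stoich"))
    if len(regimes) >= 2:
        return
    key = next(iter(world.rules))
    rule = world.rules[key]
    new_eqs = list(rule.agent_eqs)
    new_eqs[0] = CATALYTIC_EQ if new_eqs[0] >= 0.5 else SOLVENT_EQ_TARGETS[0]
    world.rules[key] = ConditionRule(
        agent_indices=rule.agent_indices,
        temperature_mean_c=rule.temperature_mean_c,
        coreactant_eq=rule.coreactant_eq,
        agent_eqs=tuple(new_eqs),
        coreactant=rule.coreactant,
        scaffolds=rule.scaffolds,
    )


def sample_records(world: SyntheticWorld, n: int, seed: int = 0) -> list[ReactionRecord]:
    """Draw ``n`` reaction records from the world's rules.

    Per record: a (class, family, scaffold) is drawn uniformly; the
    limiting (scaffold) mole is log-uniform in [1e−4, 1e−1] mol; amounts
    and temperature get the configured jitter; with probability
    ``agent_swap_prob`` one agent is replaced by a random vocabulary
    member (label noise). Documents are contiguous blocks of
    ``records_per_document`` records.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    cfg = world.config
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        c = int(rng.integers(cfg.n_classes))
        f = int(rng.integers(cfg.families_per_class))
        rule = world.rules[(c, f)]
        scaffold = rule.scaffolds[int(rng.integers(len(rule.scaffolds)))]
        lim = 10.0 ** rng.uniform(-4, -1)

        def jitter(x: float) -> float:
            if cfg.amount_jitter_frac == 0:
                return x
            return x * (1.0 + rng.uniform(-cfg.amount_jitter_frac, cfg.amount_jitter_frac))

        co_moles = lim * jitter(rule.coreactant_eq)
        agent_idx = list(rule.agent_indices)
        agent_eqs = list(rule.agent_eqs)
        if rng.random() < cfg.agent_swap_prob:
            j = int(rng.integers(len(agent_idx)))
            candidates = [k for k in range(len(world.vocabulary)) if k not in agent_idx]
            agent_idx[j] = int(rng.choice(candidates))
        agents = tuple(
            (Molecule(world.vocabulary.agents[k]), lim * jitter(eq))
            for k, eq in zip(agent_idx, agent_eqs)
        )
        temp = rule.temperature_mean_c
        if cfg.temperature_jitter_c > 0:
            temp += rng.normal(0.0, cfg.temperature_jitter_c)
        product = Molecule(canonicalize_smiles(scaffold.smiles + "." + rule.coreactant.smiles))
        records.append(
            ReactionRecord(
                document_id=f"doc{i // cfg.records_per_document:05d}",
                reactants=((scaffold, lim), (rule.coreactant, co_moles)),
                agents=agents,
                products=(product,),
                temperature_c=float(temp),
                class_id=world.class_label(c),
            )
        )
    return records


def world_ground_truth(world: SyntheticWorld, record: ReactionRecord) -> GroundTruthConditions:
    """The noiseless rule conditions behind a record generated by this world."""
    scaffold = record.reactants[0][0].smiles
    try:
        c, f = world.scaffold_to_family[scaffold]
    except KeyError:
        raise ValueError(f"record not generated by this world (scaffold {scaffold!r})")
    rule = world.rules[(c, f)]
    s = world.schemes
    return GroundTruthConditions(
        agent_indices=frozenset(rule.agent_indices),
        temperature_bin=s.temperature.assign(rule.temperature_mean_c),
        reactant_bins=(s.reactant.assign(1.0), s.reactant.assign(rule.coreactant_eq)),
        agent_bins={k: s.agent.assign(eq) for k, eq in zip(rule.agent_indices, rule.agent_eqs)},
    )
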